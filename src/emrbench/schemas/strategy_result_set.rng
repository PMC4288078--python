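<?xml version="1.0" encoding="UTF-8"?>
<grammar xmlns="http://relaxng.org/ns/structure/1.0"
         datatypeLibrary="http://www.w3.org/2001/XMLSchema-datatypes">
  <start>
    <element name="strategy_result_set">
      <attribute name="family_id"><data type="string"><param name="minLength">1</param></data></attribute>
      <attribute name="strategy_id"><data type="string"><param name="minLength">1</param></data></attribute>
      <zeroOrMore>
        <element name="scenario_results">
          <attribute name="scenario_id"><data type="string"><param name="minLength">1</param></data></attribute>
          <zeroOrMore>
            <element name="item_result">
              <attribute name="item_id"><data type="string"><param name="minLength">1</param></data></attribute>
              <attribute name="hit"><choice><value>true</value><value>false</value></choice></attribute>
            </element>
          </zeroOrMore>
        </element>
      </zeroOrMore>
    </element>
  </start>
</grammar>
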