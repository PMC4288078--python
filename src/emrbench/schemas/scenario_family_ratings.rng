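<?xml version="1.0" encoding="UTF-8"?>
<grammar xmlns="http://relaxng.org/ns/structure/1.0"
         datatypeLibrary="http://www.w3.org/2001/XMLSchema-datatypes">
  <start>
    <element name="scenario_family_ratings">
      <attribute name="family_id"><data type="string"><param name="minLength">1</param></data></attribute>
      <zeroOrMore>
        <element name="scenario_ratings">
          <attribute name="scenario_id"><data type="string"><param name="minLength">1</param></data></attribute>
          <zeroOrMore>
            <element name="rater_data">
              <attribute name="rater_id"><data type="string"><param name="minLength">1</param></data></attribute>
              <zeroOrMore>
                <element name="item_rating">
                  <attribute name="item_id"><data type="string"><param name="minLength">1</param></data></attribute>
                  <attribute name="label">
                    <choice>
                      <value>Irrelevant</value>
                      <value>Unlikely relevant</value>
                      <value>Probably relevant</value>
                      <value>Certainly relevant</value>
                    </choice>
                  </attribute>
                </element>
              </zeroOrMore>
            </element>
          </zeroOrMore>
        </element>
      </zeroOrMore>
    </element>
  </start>
</grammar>
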