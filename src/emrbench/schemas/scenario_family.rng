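<?xml version="1.0" encoding="UTF-8"?>
<grammar xmlns="http://relaxng.org/ns/structure/1.0"
         datatypeLibrary="http://www.w3.org/2001/XMLSchema-datatypes">
  <start>
    <element name="scenario_family">
      <attribute name="family_id"><data type="string"><param name="minLength">1</param></data></attribute>
      <element name="clinical_context"><text/></element>
      <oneOrMore>
        <element name="scenario_reference">
          <attribute name="scenario_id"><data type="string"><param name="minLength">1</param></data></attribute>
        </element>
      </oneOrMore>
    </element>
  </start>
</grammar>
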