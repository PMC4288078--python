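<?xml version="1.0" encoding="UTF-8"?>
<grammar xmlns="http://relaxng.org/ns/structure/1.0"
         datatypeLibrary="http://www.w3.org/2001/XMLSchema-datatypes">
  <start>
    <element name="clinical_scenario">
      <attribute name="scenario_id"><data type="string"><param name="minLength">1</param></data></attribute>
      <attribute name="patient_age"><data type="integer"/></attribute>
      <attribute name="patient_sex"><data type="token"><param name="pattern">\S+</param></data></attribute>
      <zeroOrMore>
        <element name="demographic">
          <attribute name="name"><data type="string"><param name="minLength">1</param></data></attribute>
          <attribute name="value"><data type="string"/></attribute>
        </element>
      </zeroOrMore>
      <element name="index_examination">
        <attribute name="exam_id"><data type="string"><param name="minLength">1</param></data></attribute>
        <attribute name="modality"><data type="token"><param name="pattern">\S+</param></data></attribute>
        <element name="description"><text/></element>
      </element>
      <zeroOrMore>
        <element name="medical_record_item">
          <attribute name="item_id"><data type="string"><param name="minLength">1</param></data></attribute>
          <attribute name="record_type"><data type="token"><param name="pattern">\S+</param></data></attribute>
          <attribute name="days_offset"><data type="integer"/></attribute>
          <element name="title"><text/></element>
          <element name="text"><text/></element>
        </element>
      </zeroOrMore>
    </element>
  </start>
</grammar>
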