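<?xml version="1.0" encoding="UTF-8"?>
<grammar xmlns="http://relaxng.org/ns/structure/1.0"
         datatypeLibrary="http://www.w3.org/2001/XMLSchema-datatypes">
  <define name="score-or-undefined">
    <choice>
      <attribute name="undefined"><value>true</value></attribute>
      <attribute name="value"><data type="decimal"/></attribute>
    </choice>
  </define>
  <start>
    <element name="metrics_report">
      <attribute name="family_id"><data type="string"><param name="minLength">1</param></data></attribute>
      <attribute name="strategy_id"><data type="string"><param name="minLength">1</param></data></attribute>
      <attribute name="normalization"><choice><value>abs</value><value>count</value></choice></attribute>
      <element name="s_total"><ref name="score-or-undefined"/></element>
      <element name="s_included"><ref name="score-or-undefined"/></element>
      <element name="s_excluded"><ref name="score-or-undefined"/></element>
      <element name="counts">
        <attribute name="n_scenarios"><data type="nonNegativeInteger"/></attribute>
        <attribute name="n_items_total"><data type="nonNegativeInteger"/></attribute>
        <attribute name="n_raters_effective"><data type="nonNegativeInteger"/></attribute>
      </element>
      <element name="pool_sizes">
        <attribute name="included"><data type="nonNegativeInteger"/></attribute>
        <attribute name="excluded"><data type="nonNegativeInteger"/></attribute>
        <attribute name="neutral"><data type="nonNegativeInteger"/></attribute>
      </element>
      <element name="per_scenario_scores">
        <zeroOrMore>
          <element name="scenario_score">
            <attribute name="scenario_id"><data type="string"><param name="minLength">1</param></data></attribute>
            <ref name="score-or-undefined"/>
          </element>
        </zeroOrMore>
      </element>
      <optional>
        <element name="mismatch_exemplars">
          <zeroOrMore>
            <element name="mismatch">
              <attribute name="scenario_id"><data type="string"><param name="minLength">1</param></data></attribute>
              <attribute name="item_id"><data type="string"><param name="minLength">1</param></data></attribute>
              <attribute name="hit"><choice><value>true</value><value>false</value></choice></attribute>
              <attribute name="rating_sum"><data type="string"/></attribute>
              <attribute name="contribution"><data type="string"/></attribute>
            </element>
          </zeroOrMore>
        </element>
      </optional>
    </element>
  </start>
</grammar>
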