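<?xml version='1.0' encoding='UTF-8'?>
<nexml xmlns="http://www.nexml.org/2009" xmlns:nex="http://www.nexml.org/2009" xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" xmlns:ps="https://phenosynth.dev/terms#" xmlns:xsd="http://www.w3.org/2001/XMLSchema#" version="0.9" generator="phenosynth 0.1.0">
  <meta xsi:type="nex:LiteralMeta" property="ps:entityExpression" datatype="xsd:string" content="part_of some ('forelimb')"/>
  <meta xsi:type="nex:LiteralMeta" property="ps:taxonExpression" datatype="xsd:string" content="TOY:clade"/>
  <meta xsi:type="nex:LiteralMeta" property="ps:sourceMatrices" datatype="xsd:string" content="toy01 toy02"/>
  <otus id="otus1">
    <otu id="t0" label="TOY:taxonA"/>
    <otu id="t1" label="TOY:taxonB"/>
    <otu id="t2" label="TOY:taxonC"/>
  </otus>
  <characters id="chars1" otus="otus1" xsi:type="nex:StandardCells">
    <format>
      <states id="states1">
        <state id="s0" symbol="0"/>
        <state id="s1" symbol="1"/>
        <polymorphic_state_set id="sb" symbol="2">
          <member state="s0"/>
          <member state="s1"/>
        </polymorphic_state_set>
      </states>
      <char id="c0" states="states1" label="TOY:entepicondyle"/>
      <char id="c1" states="states1" label="TOY:forelimb_skeleton"/>
      <char id="c2" states="states1" label="TOY:humerus"/>
    </format>
    <matrix>
      <row id="r0" otu="t0">
        <cell char="c1" state="s1">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [[&quot;TOY:humerus&quot;, &quot;part_of&quot;, &quot;TOY:forelimb_skeleton&quot;]], &quot;char_id&quot;: &quot;ch1&quot;, &quot;matrix_id&quot;: &quot;toy01&quot;, &quot;mode&quot;: &quot;inferred&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:humerus&quot;, &quot;quality&quot;: &quot;PATO:0000052&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonA&quot;, &quot;value&quot;: &quot;present&quot;}"/>
        </cell>
        <cell char="c2" state="s1">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [], &quot;char_id&quot;: &quot;ch1&quot;, &quot;matrix_id&quot;: &quot;toy01&quot;, &quot;mode&quot;: &quot;inferred&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:humerus&quot;, &quot;quality&quot;: &quot;PATO:0000052&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonA&quot;, &quot;value&quot;: &quot;present&quot;}"/>
        </cell>
      </row>
      <row id="r1" otu="t1">
        <cell char="c0" state="s1">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [], &quot;char_id&quot;: &quot;ch2&quot;, &quot;matrix_id&quot;: &quot;toy01&quot;, &quot;mode&quot;: &quot;asserted&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:entepicondyle&quot;, &quot;quality&quot;: &quot;PATO:0000467&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonB&quot;, &quot;value&quot;: &quot;present&quot;}"/>
        </cell>
        <cell char="c1" state="s1">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [[&quot;TOY:entepicondyle&quot;, &quot;part_of&quot;, &quot;TOY:humerus&quot;], [&quot;TOY:humerus&quot;, &quot;part_of&quot;, &quot;TOY:forelimb_skeleton&quot;]], &quot;char_id&quot;: &quot;ch2&quot;, &quot;matrix_id&quot;: &quot;toy01&quot;, &quot;mode&quot;: &quot;inferred&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:entepicondyle&quot;, &quot;quality&quot;: &quot;PATO:0000467&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonB&quot;, &quot;value&quot;: &quot;present&quot;}"/>
        </cell>
        <cell char="c2" state="s1">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [[&quot;TOY:entepicondyle&quot;, &quot;part_of&quot;, &quot;TOY:humerus&quot;]], &quot;char_id&quot;: &quot;ch2&quot;, &quot;matrix_id&quot;: &quot;toy01&quot;, &quot;mode&quot;: &quot;inferred&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:entepicondyle&quot;, &quot;quality&quot;: &quot;PATO:0000467&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonB&quot;, &quot;value&quot;: &quot;present&quot;}"/>
        </cell>
      </row>
      <row id="r2" otu="t2">
        <cell char="c0" state="s0">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [[&quot;TOY:forelimb&quot;, &quot;develops_from&quot;, &quot;TOY:forelimb_bud&quot;], [&quot;TOY:forelimb_skeleton&quot;, &quot;part_of&quot;, &quot;TOY:forelimb&quot;], [&quot;TOY:humerus&quot;, &quot;part_of&quot;, &quot;TOY:forelimb_skeleton&quot;], [&quot;TOY:entepicondyle&quot;, &quot;part_of&quot;, &quot;TOY:humerus&quot;]], &quot;char_id&quot;: &quot;ch1&quot;, &quot;matrix_id&quot;: &quot;toy02&quot;, &quot;mode&quot;: &quot;inferred&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:forelimb_bud&quot;, &quot;quality&quot;: &quot;PATO:0000462&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonC&quot;, &quot;value&quot;: &quot;absent&quot;}"/>
        </cell>
        <cell char="c1" state="s0">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [[&quot;TOY:forelimb&quot;, &quot;develops_from&quot;, &quot;TOY:forelimb_bud&quot;], [&quot;TOY:forelimb_skeleton&quot;, &quot;part_of&quot;, &quot;TOY:forelimb&quot;]], &quot;char_id&quot;: &quot;ch1&quot;, &quot;matrix_id&quot;: &quot;toy02&quot;, &quot;mode&quot;: &quot;inferred&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:forelimb_bud&quot;, &quot;quality&quot;: &quot;PATO:0000462&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonC&quot;, &quot;value&quot;: &quot;absent&quot;}"/>
        </cell>
        <cell char="c2" state="s0">
          <meta xsi:type="nex:LiteralMeta" property="ps:support" datatype="xsd:string" content="{&quot;chain&quot;: [[&quot;TOY:forelimb&quot;, &quot;develops_from&quot;, &quot;TOY:forelimb_bud&quot;], [&quot;TOY:forelimb_skeleton&quot;, &quot;part_of&quot;, &quot;TOY:forelimb&quot;], [&quot;TOY:humerus&quot;, &quot;part_of&quot;, &quot;TOY:forelimb_skeleton&quot;]], &quot;char_id&quot;: &quot;ch1&quot;, &quot;matrix_id&quot;: &quot;toy02&quot;, &quot;mode&quot;: &quot;inferred&quot;, &quot;phenotype&quot;: {&quot;entity&quot;: &quot;TOY:forelimb_bud&quot;, &quot;quality&quot;: &quot;PATO:0000462&quot;}, &quot;state_id&quot;: &quot;s1&quot;, &quot;taxon&quot;: &quot;TOY:taxonC&quot;, &quot;value&quot;: &quot;absent&quot;}"/>
        </cell>
      </row>
    </matrix>
  </characters>
</nexml>
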