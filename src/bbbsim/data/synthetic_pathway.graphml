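<?xml version='1.0' encoding='utf-8'?>
<graphml xmlns="http://graphml.graphdrawing.org/xmlns" xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" xsi:schemaLocation="http://graphml.graphdrawing.org/xmlns http://graphml.graphdrawing.org/xmlns/1.0/graphml.xsd"><key id="d2" for="edge" attr.name="relationship" attr.type="string"/>
<key id="d1" for="node" attr.name="molecule_kind" attr.type="string"/>
<key id="d0" for="node" attr.name="symbol" attr.type="string"/>
<graph edgedefault="directed"><node id="EGFR">
  <data key="d0">EGFR</data>
  <data key="d1">protein</data>
</node>
<node id="ERBB2">
  <data key="d0">ERBB2</data>
  <data key="d1">protein</data>
</node>
<node id="PDGFRA">
  <data key="d0">PDGFRA</data>
  <data key="d1">protein</data>
</node>
<node id="GRB2">
  <data key="d0">GRB2</data>
  <data key="d1">protein</data>
</node>
<node id="NRAS">
  <data key="d0">NRAS</data>
  <data key="d1">protein</data>
</node>
<node id="BRAF">
  <data key="d0">BRAF</data>
  <data key="d1">protein</data>
</node>
<node id="PIK3CA">
  <data key="d0">PIK3CA</data>
  <data key="d1">protein</data>
</node>
<node id="AKT1">
  <data key="d0">AKT1</data>
  <data key="d1">protein</data>
</node>
<node id="PTEN">
  <data key="d0">PTEN</data>
  <data key="d1">protein</data>
</node>
<node id="MDM2">
  <data key="d0">MDM2</data>
  <data key="d1">protein</data>
</node>
<node id="TP53">
  <data key="d0">TP53</data>
  <data key="d1">protein</data>
</node>
<node id="FOXO3">
  <data key="d0">FOXO3</data>
  <data key="d1">protein</data>
</node>
<node id="TSC1">
  <data key="d0">TSC1</data>
  <data key="d1">protein complex</data>
</node>
<node id="LPA">
  <data key="d0">LPA</data>
  <data key="d1">small molecule</data>
</node>
<node id="UNKNOWN1">
  <data key="d0">UNKNOWN1</data>
  <data key="d1">protein</data>
</node>
<edge source="EGFR" target="GRB2">
  <data key="d2">binds</data>
</edge>
<edge source="EGFR" target="PIK3CA">
  <data key="d2">activates</data>
</edge>
<edge source="ERBB2" target="GRB2">
  <data key="d2">binds</data>
</edge>
<edge source="PDGFRA" target="PIK3CA">
  <data key="d2">activates</data>
</edge>
<edge source="GRB2" target="NRAS">
  <data key="d2">activates</data>
</edge>
<edge source="NRAS" target="BRAF">
  <data key="d2">activates</data>
</edge>
<edge source="PIK3CA" target="AKT1">
  <data key="d2">activates</data>
</edge>
<edge source="AKT1" target="MDM2">
  <data key="d2">activates</data>
</edge>
<edge source="AKT1" target="FOXO3">
  <data key="d2">inhibits</data>
</edge>
<edge source="AKT1" target="TSC1">
  <data key="d2">inhibits</data>
</edge>
<edge source="PTEN" target="AKT1">
  <data key="d2">inhibits</data>
</edge>
<edge source="MDM2" target="TP53">
  <data key="d2">inhibits</data>
</edge>
<edge source="LPA" target="EGFR">
  <data key="d2">activates</data>
</edge>
<edge source="UNKNOWN1" target="AKT1">
  <data key="d2">activates</data>
</edge>
</graph></graphml>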