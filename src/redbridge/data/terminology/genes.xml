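<terminology system="GENE" version="fixture-1">
  <term code="ABCA4" label="ABCA4 gene"/>
  <term code="CEP290" label="CEP290 gene"/>
  <term code="USH2A" label="USH2A gene"/>
  <term code="RPGR" label="RPGR gene"/>
  <term code="RPE65" label="RPE65 gene"/>
  <term code="CRB1" label="CRB1 gene"/>
  <term code="PAX6" label="PAX6 gene"/>
  <term code="NPHP1" label="NPHP1 gene"/>
  <term code="MYO7A" label="MYO7A gene"/>
  <term code="CDH23" label="CDH23 gene"/>
  <term code="PCDH15" label="PCDH15 gene"/>
  <term code="GUCY2D" label="GUCY2D gene"/>
  <term code="CRX" label="CRX gene"/>
  <term code="RHO" label="RHO gene"/>
  <term code="PRPH2" label="PRPH2 gene"/>
  <term code="BEST1" label="BEST1 gene"/>
  <term code="CHM" label="CHM gene"/>
  <term code="RS1" label="RS1 gene"/>
  <term code="NR2E3" label="NR2E3 gene"/>
  <term code="EYS" label="EYS gene"/>
  <term code="PDE6B" label="PDE6B gene"/>
  <term code="CNGA3" label="CNGA3 gene"/>
  <term code="CNGB3" label="CNGB3 gene"/>
  <term code="OPA1" label="OPA1 gene"/>
  <term code="TIMP3" label="TIMP3 gene"/>
  <term code="VCAN" label="VCAN gene"/>
  <term code="FZD4" label="FZD4 gene"/>
  <term code="NDP" label="NDP gene"/>
  <term code="BBS1" label="BBS1 gene"/>
  <term code="CACNA1F" label="CACNA1F gene"/>
</terminology>
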