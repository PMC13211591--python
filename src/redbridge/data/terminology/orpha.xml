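<terminology system="ORPHA" version="fixture-1">
  <term code="ORPHA:65" label="Leber congenital amaurosis"/>
  <term code="ORPHA:77" label="Aniridia"/>
  <term code="ORPHA:98666" label="Congenital cataract"/>
  <term code="ORPHA:791" label="Retinitis pigmentosa"/>
  <term code="ORPHA:827" label="Stargardt disease"/>
  <term code="ORPHA:886" label="Usher syndrome"/>
  <term code="ORPHA:1872" label="Cone rod dystrophy"/>
  <term code="ORPHA:49382" label="Achromatopsia"/>
  <term code="ORPHA:215" label="Choroideremia"/>
  <term code="ORPHA:534" label="Congenital stationary night blindness"/>
  <term code="ORPHA:3459" label="Wagner disease"/>
  <term code="ORPHA:890" label="X-linked juvenile retinoschisis"/>
  <term code="ORPHA:364055" label="Retinal macular dystrophy"/>
  <term code="ORPHA:147" label="Coloboma of macula"/>
  <term code="ORPHA:98641" label="Early-onset severe retinal dystrophy"/>
  <term code="ORPHA:179" label="Best vitelliform macular dystrophy"/>
  <term code="ORPHA:52427" label="Gyrate atrophy of choroid and retina"/>
  <term code="ORPHA:41751" label="Blue cone monochromatism"/>
  <term code="ORPHA:3157" label="Microphthalmia-anophthalmia spectrum"/>
  <term code="ORPHA:2542" label="Oculocutaneous albinism type 1"/>
  <term code="ORPHA:54" label="Oculocutaneous albinism type 2"/>
  <term code="ORPHA:2334" label="Kearns-Sayre syndrome"/>
  <term code="ORPHA:104" label="Leber hereditary optic neuropathy"/>
  <term code="ORPHA:98672" label="Autosomal dominant optic atrophy"/>
  <term code="ORPHA:1572" label="Axenfeld-Rieger anomaly"/>
  <term code="ORPHA:2363" label="Peters anomaly"/>
  <term code="ORPHA:708" label="Primary congenital glaucoma"/>
  <term code="ORPHA:98976" label="Juvenile glaucoma"/>
  <term code="ORPHA:91497" label="Keratoconus"/>
  <term code="ORPHA:293381" label="Fuchs endothelial corneal dystrophy"/>
  <term code="ORPHA:98623" label="Macular corneal dystrophy"/>
  <term code="ORPHA:397758" label="PAX6-related aniridia spectrum"/>
  <term code="ORPHA:1067" label="Norrie disease"/>
  <term code="ORPHA:891" label="Familial exudative vitreoretinopathy"/>
  <term code="ORPHA:136" label="CHARGE syndrome"/>
  <term code="ORPHA:110" label="Bardet-Biedl syndrome"/>
  <term code="ORPHA:3156" label="Senior-Loken syndrome"/>
  <term code="ORPHA:64753" label="Alstrom syndrome"/>
  <term code="ORPHA:2377" label="Joubert syndrome with ocular defect"/>
  <term code="ORPHA:731" label="Wolfram syndrome"/>
  <term code="ORPHA:1478" label="Duane retraction syndrome"/>
  <term code="ORPHA:35737" label="Brown syndrome"/>
  <term code="ORPHA:91495" label="Congenital ptosis"/>
  <term code="ORPHA:98617" label="Congenital fibrosis of extraocular muscles"/>
  <term code="ORPHA:829" label="Retinoblastoma"/>
  <term code="ORPHA:39044" label="Uveal melanoma"/>
  <term code="ORPHA:91491" label="Marfan syndrome with ectopia lentis"/>
  <term code="ORPHA:1885" label="Ectopia lentis"/>
  <term code="ORPHA:231736" label="Galactosemia with cataract"/>
  <term code="ORPHA:79397" label="Cystinosis with ocular involvement"/>
</terminology>
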