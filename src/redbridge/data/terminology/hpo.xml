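<terminology system="HPO" version="fixture-1">
  <term code="HP:0000505" label="Visual impairment"/>
  <term code="HP:0000510" label="Rod-cone dystrophy"/>
  <term code="HP:0000512" label="Abnormal electroretinogram"/>
  <term code="HP:0000518" label="Cataract"/>
  <term code="HP:0000529" label="Progressive visual loss"/>
  <term code="HP:0000539" label="Abnormality of refraction"/>
  <term code="HP:0000541" label="Retinal detachment"/>
  <term code="HP:0000546" label="Conjunctival telangiectasia"/>
  <term code="HP:0000556" label="Retinal dystrophy"/>
  <term code="HP:0000565" label="Esotropia"/>
  <term code="HP:0000568" label="Microphthalmia"/>
  <term code="HP:0000572" label="Visual loss"/>
  <term code="HP:0000577" label="Exotropia"/>
  <term code="HP:0000589" label="Coloboma"/>
  <term code="HP:0000593" label="Abnormality of the anterior chamber"/>
  <term code="HP:0000613" label="Photophobia"/>
  <term code="HP:0000618" label="Blindness"/>
  <term code="HP:0000622" label="Blurred vision"/>
  <term code="HP:0000639" label="Nystagmus"/>
  <term code="HP:0000662" label="Night blindness"/>
  <term code="HP:0007663" label="Reduced visual acuity"/>
  <term code="HP:0007754" label="Macular dystrophy"/>
  <term code="HP:0007924" label="Optic atrophy"/>
  <term code="HP:0008046" label="Abnormal retinal vascular morphology"/>
  <term code="HP:0030466" label="Abnormal full-field electroretinogram"/>
  <term code="HP:0030469" label="Abnormal visual field test"/>
  <term code="HP:0030500" label="Yellow-white lesions of the retina"/>
  <term code="HP:0030612" label="Abnormal fundus fluorescein angiography"/>
  <term code="HP:0011509" label="Cone dystrophy"/>
  <term code="HP:0000479" label="Abnormal retinal morphology"/>
  <term code="HP:1000501" label="Fixture ocular phenotype 1"/>
  <term code="HP:1000503" label="Fixture ocular phenotype 2"/>
  <term code="HP:1000505" label="Fixture ocular phenotype 3"/>
  <term code="HP:1000507" label="Fixture ocular phenotype 4"/>
  <term code="HP:1000509" label="Fixture ocular phenotype 5"/>
  <term code="HP:1000511" label="Fixture ocular phenotype 6"/>
  <term code="HP:1000513" label="Fixture ocular phenotype 7"/>
  <term code="HP:1000515" label="Fixture ocular phenotype 8"/>
  <term code="HP:1000517" label="Fixture ocular phenotype 9"/>
  <term code="HP:1000519" label="Fixture ocular phenotype 10"/>
  <term code="HP:1000521" label="Fixture ocular phenotype 11"/>
  <term code="HP:1000523" label="Fixture ocular phenotype 12"/>
  <term code="HP:1000525" label="Fixture ocular phenotype 13"/>
  <term code="HP:1000527" label="Fixture ocular phenotype 14"/>
  <term code="HP:1000529" label="Fixture ocular phenotype 15"/>
  <term code="HP:1000531" label="Fixture ocular phenotype 16"/>
  <term code="HP:1000533" label="Fixture ocular phenotype 17"/>
  <term code="HP:1000535" label="Fixture ocular phenotype 18"/>
  <term code="HP:1000537" label="Fixture ocular phenotype 19"/>
  <term code="HP:1000539" label="Fixture ocular phenotype 20"/>
  <term code="HP:1000541" label="Fixture ocular phenotype 21"/>
  <term code="HP:1000543" label="Fixture ocular phenotype 22"/>
  <term code="HP:1000545" label="Fixture ocular phenotype 23"/>
  <term code="HP:1000547" label="Fixture ocular phenotype 24"/>
  <term code="HP:1000549" label="Fixture ocular phenotype 25"/>
  <term code="HP:1000551" label="Fixture ocular phenotype 26"/>
  <term code="HP:1000553" label="Fixture ocular phenotype 27"/>
  <term code="HP:1000555" label="Fixture ocular phenotype 28"/>
  <term code="HP:1000557" label="Fixture ocular phenotype 29"/>
  <term code="HP:1000559" label="Fixture ocular phenotype 30"/>
  <term code="HP:1000561" label="Fixture ocular phenotype 31"/>
  <term code="HP:1000563" label="Fixture ocular phenotype 32"/>
  <term code="HP:1000565" label="Fixture ocular phenotype 33"/>
  <term code="HP:1000567" label="Fixture ocular phenotype 34"/>
  <term code="HP:1000569" label="Fixture ocular phenotype 35"/>
  <term code="HP:1000571" label="Fixture ocular phenotype 36"/>
  <term code="HP:1000573" label="Fixture ocular phenotype 37"/>
  <term code="HP:1000575" label="Fixture ocular phenotype 38"/>
  <term code="HP:1000577" label="Fixture ocular phenotype 39"/>
  <term code="HP:1000579" label="Fixture ocular phenotype 40"/>
  <term code="HP:1000581" label="Fixture ocular phenotype 41"/>
  <term code="HP:1000583" label="Fixture ocular phenotype 42"/>
  <term code="HP:1000585" label="Fixture ocular phenotype 43"/>
  <term code="HP:1000587" label="Fixture ocular phenotype 44"/>
  <term code="HP:1000589" label="Fixture ocular phenotype 45"/>
  <term code="HP:1000591" label="Fixture ocular phenotype 46"/>
  <term code="HP:1000593" label="Fixture ocular phenotype 47"/>
  <term code="HP:1000595" label="Fixture ocular phenotype 48"/>
  <term code="HP:1000597" label="Fixture ocular phenotype 49"/>
  <term code="HP:1000599" label="Fixture ocular phenotype 50"/>
  <term code="HP:1000601" label="Fixture ocular phenotype 51"/>
  <term code="HP:1000603" label="Fixture ocular phenotype 52"/>
  <term code="HP:1000605" label="Fixture ocular phenotype 53"/>
  <term code="HP:1000607" label="Fixture ocular phenotype 54"/>
  <term code="HP:1000609" label="Fixture ocular phenotype 55"/>
  <term code="HP:1000611" label="Fixture ocular phenotype 56"/>
  <term code="HP:1000613" label="Fixture ocular phenotype 57"/>
  <term code="HP:1000615" label="Fixture ocular phenotype 58"/>
  <term code="HP:1000617" label="Fixture ocular phenotype 59"/>
  <term code="HP:1000619" label="Fixture ocular phenotype 60"/>
  <term code="HP:1000621" label="Fixture ocular phenotype 61"/>
  <term code="HP:1000623" label="Fixture ocular phenotype 62"/>
  <term code="HP:1000625" label="Fixture ocular phenotype 63"/>
  <term code="HP:1000627" label="Fixture ocular phenotype 64"/>
  <term code="HP:1000629" label="Fixture ocular phenotype 65"/>
  <term code="HP:1000631" label="Fixture ocular phenotype 66"/>
  <term code="HP:1000633" label="Fixture ocular phenotype 67"/>
  <term code="HP:1000635" label="Fixture ocular phenotype 68"/>
  <term code="HP:1000637" label="Fixture ocular phenotype 69"/>
  <term code="HP:1000639" label="Fixture ocular phenotype 70"/>
</terminology>
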