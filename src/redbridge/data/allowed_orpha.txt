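# Allowed rare-eye-disease ORPHA codes (one per line).
# Codes absent from this list fail the confirmed/probable pathway.
ORPHA:65  # Leber congenital amaurosis
ORPHA:77  # Aniridia
ORPHA:98666  # Congenital cataract
ORPHA:791  # Retinitis pigmentosa
ORPHA:827  # Stargardt disease
ORPHA:886  # Usher syndrome
ORPHA:1872  # Cone rod dystrophy
ORPHA:49382  # Achromatopsia
ORPHA:215  # Choroideremia
ORPHA:534  # Congenital stationary night blindness
ORPHA:3459  # Wagner disease
ORPHA:890  # X-linked juvenile retinoschisis
ORPHA:364055  # Retinal macular dystrophy
ORPHA:147  # Coloboma of macula
ORPHA:98641  # Early-onset severe retinal dystrophy
ORPHA:179  # Best vitelliform macular dystrophy
ORPHA:52427  # Gyrate atrophy of choroid and retina
ORPHA:41751  # Blue cone monochromatism
ORPHA:3157  # Microphthalmia-anophthalmia spectrum
ORPHA:2542  # Oculocutaneous albinism type 1
ORPHA:54  # Oculocutaneous albinism type 2
ORPHA:2334  # Kearns-Sayre syndrome
ORPHA:104  # Leber hereditary optic neuropathy
ORPHA:98672  # Autosomal dominant optic atrophy
ORPHA:1572  # Axenfeld-Rieger anomaly
ORPHA:2363  # Peters anomaly
ORPHA:708  # Primary congenital glaucoma
ORPHA:98976  # Juvenile glaucoma
ORPHA:91497  # Keratoconus
ORPHA:293381  # Fuchs endothelial corneal dystrophy
ORPHA:98623  # Macular corneal dystrophy
ORPHA:397758  # PAX6-related aniridia spectrum
ORPHA:1067  # Norrie disease
ORPHA:891  # Familial exudative vitreoretinopathy
ORPHA:136  # CHARGE syndrome
ORPHA:110  # Bardet-Biedl syndrome
ORPHA:3156  # Senior-Loken syndrome
ORPHA:64753  # Alstrom syndrome
ORPHA:2377  # Joubert syndrome with ocular defect
ORPHA:731  # Wolfram syndrome
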