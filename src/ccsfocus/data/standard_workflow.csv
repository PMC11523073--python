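species,n_carbons,double_bonds,exp_ccs,calc_ccs
Vaccenic acid,18,trans-11,174.95,235.72
Oleic acid,18,cis-9,175.22,177.16
Petroselinic acid,18,cis-6,175.50,183.34
Elaidic acid,18,trans-6,175.90,188.99
alpha-Linolenic acid,18,"9,12,15",174.26,168.99
gamma-Linolenic acid,18,"6,9,12",174.77,181.54
Dihomo-gamma-linolenic acid,20,"8,11,14",182.36,184.54
Eicosatrienoic acid,20,"11,14,17",178.70,178.13
5(S)-HETE,20,"6,8,11,14",186.27,177.50
12(R)-HETE,20,"5,8,10,14",183.18,184.93
15(S)-HETE,20,"5,8,11,13",184.77,190.10
15-OxoETE,20,"5,8,11,13",183.13,195.25
14(15)-EpETE,20,"5,8,11,17",183.90,177.20
5-OxoETE,20,"6,8,11,14",185.13,180.58
15(S)-HEPE,20,"5,8,11,13,17",183.07,189.06
7(R)-Maresin-1,22,"4,8,10,12,16,19",192.57,199.05
8(S)-HETE,20,"5,9,11,14",184.14,188.89
7(S)-Maresin-1,22,"4,8,10,12,16,19",192.54,199.75
PGE1,20,"9,11,15",190.23,192.52
PGF2alpha,20,"9,11,15",192.34,190.13
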