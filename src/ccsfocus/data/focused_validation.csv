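species,n_carbons,double_bonds,exp_ccs,calc_ccs
Vaccenic acid,18,trans-11,174.95,175.55
Oleic acid,18,cis-9,175.22,171.77
Petroselinic acid,18,cis-6,175.50,171.78
Elaidic acid,18,trans-6,175.90,172.53
gamma-Linolenic acid,18,"6,9,12",174.77,173.81
Eicosatrienoic acid,20,"11,14,17",178.70,192.41
5(S)-HETE,20,"6,8,11,14",186.27,184.77
15-OxoETE,20,"5,8,11,13",183.13,184.16
14(15)-EpETE,20,"5,8,11,17",183.90,187.64
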