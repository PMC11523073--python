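species,n_carbons,double_bonds,exp_ccs,calc_ccs
Adrenic acid,22,"7,10,13,16",189.97,185.26
DHA,22,"4,7,10,13,16,19",190.17,189.75
Carboxy Thromboxane A2,22,,201.10,197.87
Artemisic acid,18,"9,11",182.20,189.44
14S-HDHA,22,"4,7,10,12,16,19",189.29,180.43
13-Oxo-ODE,18,"9,11",179.53,175.42
17S-HDHA,22,"4,7,10,13,15,19",193.67,191.94
Gondoic acid,20,cis-11,183.69,187.64
Glutarylcarnitine,5,,165.30,167.25
Lipoxin A4,20,"7,9,11,13",193.03,192.01
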