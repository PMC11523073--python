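species,n_carbons,double_bonds,exp_ccs,calc_ccs
gamma-Tocopherol,22,,207.14,241.98
Lignoceric acid,24,,200.36,283.11
Nervonic acid,24,15,197.48,245.13
Tricosylic acid,23,,196.88,263.54
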