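species,n_carbons,double_bonds,exp_ccs,calc_ccs
gamma-Tocopherol,22,,207.14,214.47
Lignoceric acid,24,,200.36,288.92
Nervonic acid,24,15,197.48,232.92
Tricosylic acid,23,,196.88,276.03
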