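"""Focus a fresh ensemble around a reference CCS value.

The filter band is derived from the model's held-out batch-error
statistics; only conformers whose predicted CCS falls inside the band
survive.
"""

import numpy as np

import ccsfocus as cf

# a quick model (see 03_train_regressor.py for a fuller setup)
train_ens = cf.generate_ensemble(cf.SyntheticSpec(18, (9,), 200, seed=11))
mask = ("mz", "d_het_max", "d_atom_max", "msa")
model = cf.train(
    cf.featurize_ensemble(train_ens),
    np.array([c.label_ccs for c in train_ens]),
    cf.RegressorConfig(seed=5, feature_mask=mask),
)

# an unseen query ensemble; pretend the median oracle CCS is "experiment"
query = cf.generate_ensemble(cf.SyntheticSpec(18, (9,), 300, seed=99))
ccs_user = float(np.median([c.label_ccs for c in query]))

focused, report = cf.focus(query, model, ccs_user)
print(f"reference CCS: {ccs_user:.1f} A^2")
print(f"filter band:   [{report.band.lower:.1f}, {report.band.upper:.1f}] A^2")
print(f"retained:      {report.n_out} of {report.n_in} conformers")
print(f"ensemble predicted CCS spread: {report.pred_min:.1f}-{report.pred_max:.1f} A^2")
# Conformers outside the band would have wasted downstream optimisation
# time on geometries that cannot match the measured mobility.
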