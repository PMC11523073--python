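"""The full focused structure-prediction workflow on synthetic data.

focus -> RMSD leader clustering -> lowest-energy candidate +
Boltzmann-weighted ensemble CCS -> % error against the reference value.
"""

import json

import numpy as np

import ccsfocus as cf

train_ens = cf.generate_ensemble(cf.SyntheticSpec(18, (9,), 250, seed=21))
mask = ("mz", "d_het_max", "d_atom_max", "msa")
model = cf.train(
    cf.featurize_ensemble(train_ens),
    np.array([c.label_ccs for c in train_ens]),
    cf.RegressorConfig(seed=5, feature_mask=mask),
)

query = cf.generate_ensemble(
    cf.SyntheticSpec(18, (9,), 300, seed=77), assign_energies=True
)
ccs_user = float(np.median([c.label_ccs for c in query]))

config = cf.RunConfig(ccs_user=ccs_user, energy_source="metadata",
                      rmsd_threshold=1.0, output_dir="workflow_out")
report = cf.run_augmented_workflow(query, model, config)
print(json.dumps(report, indent=2, sort_keys=True))
# n_input >= n_filtered >= n_representatives; the candidate is the
# lowest-energy representative and passes_3pct applies the 3% agreement
# threshold used for computed-vs-experimental CCS.
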