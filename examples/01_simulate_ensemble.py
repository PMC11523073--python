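"""Generate a synthetic fatty-acid conformer ensemble with oracle labels.

Builds 50 conformers of a C18:1 (delta-9) fatty-acid anion, labels each
with its projection-approximation CCS, and writes a multi-frame XYZ file.
"""

import numpy as np

import ccsfocus as cf

spec = cf.SyntheticSpec(
    n_carbons=18, double_bond_positions=(9,), n_conformers=50, seed=1
)
ensemble = cf.generate_ensemble(spec, assign_energies=True)
cf.write_xyz_ensemble(ensemble, "oleate_ensemble.xyz")

labels = np.array([c.label_ccs for c in ensemble])
print(f"species: {ensemble.species_name}, formula {dict(ensemble.formula)}")
print(f"{len(ensemble)} conformers; oracle CCS {labels.min():.1f}-{labels.max():.1f} A^2 "
      f"(mean {labels.mean():.1f})")
# Extended torsion sequences project larger areas, so the label spread
# reflects the conformational diversity the filter will later act on.
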