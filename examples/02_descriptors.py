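"""Compute the five CCS-relevant descriptors for one conformer.

The regressor sees each conformer only through these five numbers:
m/z, the two maximum distances from the centre of mass, the heteroatom
count, and the accessible surface area.
"""

import ccsfocus as cf

spec = cf.SyntheticSpec(n_carbons=18, double_bond_positions=(9,), n_conformers=1, seed=1)
conformer = cf.generate_chain_conformer(spec, 0)
fv = cf.featurize(conformer)

print(f"m/z ([M-H]-):            {fv.mz:10.4f} Da")
print(f"farthest heteroatom-COM: {fv.d_het_max:10.3f} A")
print(f"farthest atom-COM:       {fv.d_atom_max:10.3f} A")
print(f"heteroatom count:        {fv.n_het:10d}")
print(f"molecular surface area:  {fv.msa:10.1f} A^2")
# d_het_max <= d_atom_max always; for a fatty acid the heteroatoms are the
# two carboxylate oxygens, so d_het_max tracks how far the head group sits
# from the mass centre of the coiled chain.
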