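"""Score the bundled experimental/computed CCS reference tables.

Each table pairs published experimental CCS values for lipid [M-H]- ions
with the CCS computed for predicted candidate structures; the summary
means document the error regimes with and without CCS focusing.
"""

import ccsfocus as cf

for name in cf.datasets.TABLE_NAMES:
    df = cf.load_reference_ccs(name)
    table, mean, sd = cf.evaluate_candidates(
        zip(df["species"], df["exp_ccs"], df["calc_ccs"])
    )
    n_pass = int(table["pass_3pct"].sum())
    print(f"{name:28s} n={len(table):2d}  mean % error {mean:6.2f} +/- {sd:5.2f}  "
          f"pass 3%: {n_pass}/{len(table)}")
# Focusing drops the mean error from ~4.6% to ~2.0% on the rerun species;
# the extrapolation set (~29%) shows the filter correctly refusing
# ensembles outside the model's training domain.
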