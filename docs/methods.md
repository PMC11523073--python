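# Methods

This note documents the models, defaults and design choices behind
`ccsfocus`, and what the synthetic studies do and do not demonstrate.

## Problem setting

Ion-mobility mass spectrometry measures a collision cross section (CCS,
Å²) — a rotationally averaged effective area — for an ion drifting through
a buffer gas (nitrogen throughout this package's conventions). Assigning a
3D structure to a measured CCS requires a conformer ensemble, quantum
refinement, and per-conformer CCS computation. For flexible lipids the
ensemble must be large (thousands to tens of thousands of conformers), yet
only a thin slice is compatible with the measurement. `ccsfocus`
implements the conformational-focusing idea: predict CCS cheaply for every
raw conformer and discard, before any expensive step, everything outside a
band around the reference value.

## The descriptors

Five per-conformer descriptors feed the regressor:

| descriptor  | units | definition |
|---|---|---|
| `mz`        | Da  | monoisotopic mass of the neutral formula − 1.00728 (proton); electron mass neglected |
| `d_het_max` | Å   | distance from the centre of mass (COM) to the farthest heteroatom; 0 if none |
| `d_atom_max`| Å   | distance from the COM to the farthest atom |
| `n_het`     | —   | number of atoms other than C and H |
| `msa`       | Å²  | solvent-accessible surface area |

Conventions chosen where more than one was defensible:

* **Heteroatom** means any element other than carbon or hydrogen (the
  standard organic-chemistry convention).
* **COM** uses monoisotopic masses from the embedded element table, so
  results do not depend on an external mass compilation.
* **m/z** assumes the input geometry is already the deprotonated species
  (as charge models for negative-mode lipids are built); the neutral
  formula is the input formula plus one H. A `geometry_is_neutral` switch
  disables the correction.
* **MSA** is a Shrake–Rupley accessible surface: each atom's sphere
  (Bondi vdW radius + 1.4 Å probe) is sampled at 960 points from a fixed
  golden-spiral lattice, and the unburied fraction contributes. The
  computation is deterministic; the lattice carries ≈1% orientation
  dependence (rotating a molecule moves the value by up to ~1%), which is
  far below the descriptor's ~25% dynamic range across conformers.
* The feature set is configurable by a mask. Free fatty acids all carry
  exactly two heteroatoms, so `n_het` is zero-variance in single-class
  synthetic studies and is masked there; training errors out loudly on any
  unmasked zero-variance feature rather than silently dividing by zero.

## The regressor

A fully connected network — input layer, six hidden layers of widths
(64, 128, 128, 64, 32, 16) with activations (relu, gelu, relu, gelu, relu,
relu), one linear output — trained with Adam (lr 10⁻³, batch 32) on a mean
absolute error loss, an 80/20 train/validation split, up to 400 epochs
with early stopping on validation MAE (patience 40, best weights
restored). All of this is overridable through `RegressorConfig`; nothing
downstream depends on the exact widths.

Numerical choices:

* Implemented in plain numpy so that a seed fixes the split, the
  initialisation (He), the batch order, and therefore the entire loss
  history bit-for-bit. GELU uses the exact erf form.
* Features **and labels** are z-scored with training-split statistics
  (labels are de-standardised at prediction). With an MAE loss, Adam steps
  are bounded by the learning rate, so an unscaled output bias could never
  traverse the ~180 Å² label magnitude within the epoch budget.
* The validation split is by instance (conformer) by default; a
  `group_split` mode holds out whole species instead, for testing
  generalisation rather than interpolation.
* Reported held-out metrics: MAE (Å²), mean % error, R². "Accuracy" is not
  meaningful for regression and is not reported.

## Error statistics and the filter band

From a batch of labelled predictions: `error_i = |pred−label|/label`,
`error` the arithmetic mean, `σ_error = sd(error_i)/√N` (sample sd, 0 for
N = 1). The band around the user CCS is symmetric and multiplicative:
`[Ω_user·(1−error−σ_error), Ω_user·(1+error+σ_error)]`, closed at both
ends. A capacity limit keeps the k survivors whose predictions are nearest
Ω_user (ties by input order). The statistics default to the model's most
recent held-out evaluation and can be supplied from a CSV instead.

Two conventions here were genuinely open and are flagged as this package's
choices: the "standard error" is the standard error of the mean (not the
sd), and the band is closed (boundary predictions are retained). Both live
in single functions (`error_statistics`, `filter_bounds`) so an alternate
reading is a one-line swap.

## Post-focusing workflow

* **Clustering**: greedy leader clustering in input order under Kabsch
  optimal-superposition RMSD (scipy's `Rotation.align_vectors`, residual
  measured after applying the optimal rotation). A conformer founds a new
  cluster iff it is more than the threshold (default 1.0 Å) from every
  existing representative — so representatives are pairwise separated and
  every conformer is covered. Hydrogens are included by default
  (switchable). This is a deliberately simple stand-in for graph-based
  cluster-centre methods; only the role (reduce ~10³–10⁴ conformers to a
  QM-sized representative set) is preserved.
* **Boltzmann weighting**: wᵢ ∝ exp(−(Eᵢ−E_min)/RT), R = 0.0019872
  kcal mol⁻¹ K⁻¹, default T = 298.15 K (no temperature is implied by the
  measurement; 298 K is the conventional reporting point). Energies are
  relative kcal/mol; hartree input is converted via 627.5095. The E_min
  shift is exact and avoids underflow.
* **Candidate**: the lowest-energy conformer, ties by input order.
* **Scoring**: % error = 100·|calc−exp|/exp, rounded to 2 decimals per
  row; table averages are means of the rounded rows with sample sd, which
  reproduces the published summary values of the bundled reference tables
  exactly — with one documented exception: the large-lipid standard-method
  table's published average (26.44) is not the mean of its printed rows
  under any rounding order (row-wise computation gives 26.47); the
  discrepancy is surfaced in a test rather than hidden.
* The workflow report treats an empty post-filter ensemble as a first-class
  outcome (`"no viable conformers"`): for out-of-domain lipids the
  predicted CCS distribution can sit tens of percent away from experiment,
  far outside any reasonable band, and the correct behaviour is to stop
  early and say so.

## Synthetic data: what it emulates, and what it does not

`SyntheticSpec` builds all-atom fatty-acid [M-H]⁻ conformers: a
carboxylate head (C–O 1.26 Å, O–C–O plane), a carbon backbone with C–C
1.54 Å / C=C 1.33 Å, sp³ angles 111.5° / sp² 120°, backbone torsions drawn
trans/gauche± with probabilities (0.6, 0.2, 0.2) — mimicking flexible
chains with ~14 rotatable bonds — cis-fixed double-bond torsions, and
geometrically placed hydrogens (C–H 1.09/1.086 Å). Geometries with any
atom pair under 1.0 Å are rejected and resampled. Everything is
deterministic in (seed, conformer index). The hydrogen count follows
CₙH₂ₙ₋₂ᵤO₂ for the neutral acid with u double bonds; the anion drops the
acidic proton.

Labels come from `pa_ccs`, a projection-approximation oracle: the mean
over ~100 viewing orientations of the union-of-disks area of all atoms
(Bondi radius + 1.4 Å augment as an N₂ collision-size proxy) projected on
the viewing plane. The union area is computed by a scanline integration —
exact interval union along y, x discretised at 0.25 Å — and orientations
are a golden-spiral direction set rotated by one seeded random rotation
(randomised quasi-Monte Carlo), giving rotation invariance to ~0.1% at 100
orientations. Surrogate conformer energies, when requested, are
`E = 0.5·(Rg − Rg_min)` kcal/mol — a documented monotone function of
compactness standing in for dispersion-stabilised folding, not physics.

Limits to keep in mind: the projection approximation differs
systematically from trajectory-method CCS (it ignores ion–gas potentials
and multiple scattering), the torsion model has no energy coupling between
neighbouring bonds, and the surrogate energies encode exactly the
compactness ordering. Passing synthetic tests therefore demonstrates that
the pipeline recovers a smooth geometry→CCS mapping from the five
descriptors and that the filter/cluster/score machinery is correct — not
that any particular experimental CCS would be reproduced.

## Problem sizes and observed behaviour

The end-to-end recovery study trains on 5000 conformers (10 species × 500)
with three training seeds; held-out mean % error lands well under 1% with
R² ≈ 0.99, comfortably inside the ≤3%/R²≥0.9 acceptance surface and in the
~2% regime the filter band is designed around. The acceptance script runs
the same study plus a 400-conformer end-to-end workflow in a few minutes
on one CPU; sizes were chosen so the whole suite stays desk-scale while
leaving the statistical conclusions unchanged at larger n.

## Known limitations

* XYZ metadata (`key=value` comment tokens) is this package's own
  convention; other tools' comment lines are ignored rather than parsed.
* No ring-containing lipids (e.g. tocopherols), positive-mode adducts, or
  stereochemistry beyond the cis/trans torsion placeholder.
* The regressor ships no pretrained weights: reproducing a specific
  published model's predictions is out of scope; the package trains its
  own models from labelled data.
* Feature-shift surveys (train-vs-query % difference of `d_het_max`,
  `d_atom_max`, `msa`) use (query−reference)/reference on collection
  means; the sign convention is: positive = query larger.
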