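"""Post-focusing ensemble processing.

Representative selection by greedy leader clustering under the Kabsch
(optimal-superposition) RMSD, Boltzmann weighting of per-conformer CCS
values, lowest-energy candidate selection, and percent-error scoring of
computed CCS against experimental reference values with the field's 3%
agreement threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .elements import element_lookup
from .structures import Conformer, ConformerEnsemble

#: Gas constant, kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 0.0019872
#: Default temperature for Boltzmann weighting, K.
DEFAULT_TEMPERATURE = 298.15
#: Agreement threshold between computed and experimental CCS, percent.
CCS_ERROR_THRESHOLD_PCT = 3.0
#: kcal/mol per hartree, for energies supplied in atomic units.
HARTREE_TO_KCAL = 627.5095


def kabsch_rmsd(a: Conformer, b: Conformer, include_hydrogens: bool = True) -> float:
    """Minimum RMSD (Angstrom) between two same-ordered conformers over all
    rigid rotations and translations (Kabsch optimal superposition).

    Symmetric in its arguments; zero iff the geometries are congruent under
    a proper rotation plus translation.
    """
    if a.elements != b.elements:
        raise ValueError("conformers must share formula and atom ordering")
    pa, pb = a.coordinates, b.coordinates
    if not include_hydrogens:
        keep = np.array([e != "H" for e in a.elements])
        pa, pb = pa[keep], pb[keep]
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    rot, _ = Rotation.align_vectors(pa, pb)
    # measure the residual directly: the rssd returned by align_vectors
    # loses half its precision to cancellation near zero
    return float(np.sqrt(((rot.apply(pb) - pa) ** 2).sum() / len(pa)))


def cluster_representatives(
    ensemble: ConformerEnsemble,
    rmsd_threshold: float = 1.0,
    include_hydrogens: bool = True,
) -> ConformerEnsemble:
    """Greedy leader clustering: reduce an ensemble to representatives.

    Walking the ensemble in input order, a conformer becomes a new
    representative iff its Kabsch RMSD to every existing representative
    exceeds *rmsd_threshold*; consequently every input conformer lies
    within the threshold of at least one representative.
    """
    if rmsd_threshold <= 0:
        raise ValueError("rmsd_threshold must be positive")
    if len(ensemble) == 0:
        raise ValueError("cannot cluster an empty ensemble")
    rep_idx: list[int] = []
    for i, conf in enumerate(ensemble):
        if all(
            kabsch_rmsd(conf, ensemble[j], include_hydrogens) > rmsd_threshold
            for j in rep_idx
        ):
            rep_idx.append(i)
    return ensemble.subset(rep_idx)


def boltzmann_weights(
    energies: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
    units: str = "kcal/mol",
) -> np.ndarray:
    """Normalised Boltzmann population weights from relative energies.

    w_i = exp(-(E_i - E_min) / (R T)) / sum_j exp(-(E_j - E_min) / (R T)),
    with R = 0.0019872 kcal mol^-1 K^-1.  Energies may be given in
    ``kcal/mol`` (default) or ``hartree``.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one energy")
    if not np.all(np.isfinite(e)):
        raise ValueError("energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if units == "hartree":
        e = e * HARTREE_TO_KCAL
    elif units != "kcal/mol":
        raise ValueError(f"unknown energy units {units!r}")
    x = -(e - e.min()) / (GAS_CONSTANT_KCAL * temperature)
    w = np.exp(x)
    return w / w.sum()


def boltzmann_ccs(
    ccs_values: Sequence[float],
    energies: Sequence[float],
    temperature: float = DEFAULT_TEMPERATURE,
    units: str = "kcal/mol",
) -> float:
    """Boltzmann-weighted (ensemble-averaged) CCS, A^2."""
    ccs = np.asarray(ccs_values, dtype=float)
    if ccs.size != np.asarray(energies, dtype=float).size:
        raise ValueError("ccs_values and energies must have equal length")
    w = boltzmann_weights(energies, temperature, units)
    return float(w @ ccs)


def select_candidate(ensemble: ConformerEnsemble) -> Conformer:
    """The lowest-energy conformer (ties broken by input order)."""
    if len(ensemble) == 0:
        raise ValueError("cannot select from an empty ensemble")
    energies = []
    for c in ensemble:
        if c.energy is None:
            raise ValueError(f"conformer {c.id!r} has no energy")
        energies.append(c.energy)
    return ensemble[int(np.argmin(energies))]


def percent_ccs_error(calc_ccs: float, exp_ccs: float) -> float:
    """Percent difference of a computed CCS from the experimental CCS:
    100 * |calc - exp| / exp."""
    if exp_ccs <= 0:
        raise ValueError("experimental CCS must be positive")
    return 100.0 * abs(calc_ccs - exp_ccs) / exp_ccs


@dataclass(frozen=True)
class CandidateResult:
    """Scored structure prediction for one species."""

    species_name: str
    candidate_id: str
    candidate_energy: Optional[float]
    candidate_ccs: float
    boltzmann_ccs: float
    exp_ccs: float
    percent_error: float
    passes_3pct: bool


def evaluate_candidates(
    rows: Iterable[tuple[str, float, float]],
) -> tuple[pd.DataFrame, float, float]:
    """Score (species, experimental CCS, calculated CCS) rows.

    Per-row percent error is rounded to 2 decimals, as reported in summary
    tables; the returned mean and sample standard deviation are taken over
    the rounded values.

    Returns
    -------
    (table, mean_pct_error, sd_pct_error)
        ``table`` has columns species, exp_ccs, calc_ccs, percent_error,
        pass_3pct.
    """
    records = []
    for species, exp_ccs, calc_ccs in rows:
        err = round(percent_ccs_error(calc_ccs, exp_ccs), 2)
        records.append(
            {
                "species": species,
                "exp_ccs": exp_ccs,
                "calc_ccs": calc_ccs,
                "percent_error": err,
                "pass_3pct": err <= CCS_ERROR_THRESHOLD_PCT,
            }
        )
    if not records:
        raise ValueError("no rows to evaluate")
    table = pd.DataFrame(records)
    mean = float(table["percent_error"].mean())
    sd = float(table["percent_error"].std(ddof=1)) if len(table) > 1 else 0.0
    return table, mean, sd
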