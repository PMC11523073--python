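"""The end-to-end CCS-focused structure-prediction workflow.

Stages: featurize + batch-predict + filter (focus) -> greedy RMSD leader
clustering -> energy assignment (from metadata, a CSV, or a surrogate
compactness model) -> lowest-energy candidate selection and
Boltzmann-weighted ensemble CCS -> percent-error scoring against the user
(experimental) CCS.  An empty post-filter ensemble is a reportable
outcome ("no viable conformers"), not an error: it is the workflow's way
of flagging an ensemble whose predicted CCS distribution is incompatible
with experiment before any expensive downstream step.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .ensemble import (
    CCS_ERROR_THRESHOLD_PCT,
    DEFAULT_TEMPERATURE,
    boltzmann_ccs,
    cluster_representatives,
    percent_ccs_error,
    select_candidate,
)
from .focusing import ErrorStats, focus
from .regressor import TrainedRegressor
from .structures import ConformerEnsemble
from .synthetic import assign_compactness_energies
from .xyz import write_xyz_ensemble


@dataclass(frozen=True)
class RunConfig:
    """Settings for one workflow run."""

    ccs_user: float
    capacity: Optional[int] = None
    rmsd_threshold: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    energy_source: str = "metadata"  # "metadata" | "compactness" | CSV path
    seed: int = 0
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ccs_user <= 0:
            raise ValueError("ccs_user must be positive")
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")


def _resolve_energies(ensemble: ConformerEnsemble, source: str) -> ConformerEnsemble:
    if source == "metadata":
        missing = [c.id for c in ensemble if c.energy is None]
        if missing:
            raise ValueError(
                f"energy_source='metadata' but conformers lack energies: {missing[:5]}"
            )
        return ensemble
    if source == "compactness":
        return assign_compactness_energies(ensemble)
    # otherwise a CSV path with columns id, energy (kcal/mol)
    table = pd.read_csv(source).set_index("id")["energy"]
    conformers = []
    for c in ensemble:
        if c.id not in table.index:
            raise ValueError(f"no energy for conformer {c.id!r} in {source}")
        conformers.append(c.with_coordinates(c.coordinates, energy=float(table[c.id])))
    return ConformerEnsemble(ensemble.species_name, conformers)


def run_augmented_workflow(
    ensemble: ConformerEnsemble,
    model: TrainedRegressor,
    config: RunConfig,
    stats: Optional[ErrorStats] = None,
) -> dict:
    """Run focus -> cluster -> score on *ensemble* and return a JSON-ready
    report.

    The report carries the stage counts (monotone non-increasing), the
    filter band, the selected candidate, the Boltzmann-weighted CCS, and
    the % error of both against ``config.ccs_user``.  When
    ``config.output_dir`` is set, the focused and representative ensembles
    are written as XYZ next to a ``report.json``.
    """
    focused, focus_report = focus(
        ensemble, model, config.ccs_user, stats=stats, capacity=config.capacity
    )
    report: dict = {
        "species": ensemble.species_name,
        "config": {
            "ccs_user": config.ccs_user,
            "capacity": config.capacity,
            "rmsd_threshold": config.rmsd_threshold,
            "temperature": config.temperature,
            "energy_source": config.energy_source,
            "seed": config.seed,
        },
        "focus": focus_report.as_dict(),
        "n_input": len(ensemble),
        "n_filtered": len(focused),
    }

    if len(focused) == 0:
        report["status"] = "no viable conformers"
        report["n_representatives"] = 0
        _write_outputs(report, None, None, config)
        return report

    representatives = cluster_representatives(focused, config.rmsd_threshold)
    representatives = _resolve_energies(representatives, config.energy_source)
    report["n_representatives"] = len(representatives)

    candidate = select_candidate(representatives)
    ccs_values = [c.pred_ccs for c in representatives]
    energies = [c.energy for c in representatives]
    bw_ccs = boltzmann_ccs(ccs_values, energies, temperature=config.temperature)
    cand_err = percent_ccs_error(candidate.pred_ccs, config.ccs_user)
    bw_err = percent_ccs_error(bw_ccs, config.ccs_user)

    report["status"] = "ok"
    report["candidate"] = {
        "id": candidate.id,
        "energy": candidate.energy,
        "pred_ccs": candidate.pred_ccs,
        "percent_error": round(cand_err, 2),
        "passes_3pct": cand_err <= CCS_ERROR_THRESHOLD_PCT,
    }
    report["boltzmann"] = {
        "ccs": bw_ccs,
        "percent_error": round(bw_err, 2),
        "passes_3pct": bw_err <= CCS_ERROR_THRESHOLD_PCT,
    }
    _write_outputs(report, focused, representatives, config)
    return report


def _write_outputs(report, focused, representatives, config: RunConfig) -> None:
    if config.output_dir is None:
        return
    os.makedirs(config.output_dir, exist_ok=True)
    files = {}
    if focused is not None and len(focused):
        path = os.path.join(config.output_dir, "focused.xyz")
        write_xyz_ensemble(focused, path)
        files["focused_xyz"] = path
    if representatives is not None and len(representatives):
        path = os.path.join(config.output_dir, "representatives.xyz")
        write_xyz_ensemble(representatives, path)
        files["representatives_xyz"] = path
    report["files"] = files
    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
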