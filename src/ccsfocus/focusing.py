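"""CCS-knowledge-based conformational focusing.

Given a user CCS value (typically the experimental reference) and the
regressor's recent batch-error statistics, a symmetric multiplicative band
is placed around the user value,

    upper = CCS_user * (1 + error + sigma_error)
    lower = CCS_user * (1 - error - sigma_error),

where ``error`` is the mean relative prediction error of a batch,
error_i = |CCS_pred,i - CCS_label,i| / CCS_label,i, and ``sigma_error`` is
its standard error of the mean (sd / sqrt(N)).  Conformers whose predicted
CCS falls inside the closed band are retained; everything else is deadwood
and is dropped before any expensive downstream processing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .descriptors import featurize_ensemble
from .regressor import TrainedRegressor, predict_batch
from .structures import ConformerEnsemble


@dataclass(frozen=True)
class ErrorStats:
    """Batch prediction-error statistics (all dimensionless fractions)."""

    per_item_errors: tuple
    mean_error: float
    n: int
    sem_error: float

    def __post_init__(self) -> None:
        if self.n != len(self.per_item_errors) or self.n < 1:
            raise ValueError("n must equal the number of per-item errors (>= 1)")
        if any(e < 0 for e in self.per_item_errors) or self.sem_error < 0:
            raise ValueError("errors and their SEM are non-negative")


@dataclass(frozen=True)
class FilterBand:
    """The CCS filter: user value with derived lower/upper limits, A^2."""

    ccs_user: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 < self.lower <= self.ccs_user <= self.upper:
            raise ValueError(
                f"need 0 < lower <= ccs_user <= upper, got "
                f"({self.lower}, {self.ccs_user}, {self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower


def error_statistics(predictions, labels) -> ErrorStats:
    """Per-item relative errors, their mean, count, and SEM.

    error_i = |pred_i - label_i| / label_i; SEM uses the sample standard
    deviation (ddof=1) over sqrt(N), and is 0 when N = 1.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.size == 0:
        raise ValueError("predictions and labels must be non-empty, equal-length")
    if np.any(y <= 0):
        raise ValueError("labels must be positive")
    errs = np.abs(p - y) / y
    n = errs.size
    sem = float(errs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ErrorStats(
        per_item_errors=tuple(float(e) for e in errs),
        mean_error=float(errs.mean()),
        n=n,
        sem_error=sem,
    )


def stats_from_model(model: TrainedRegressor) -> ErrorStats:
    """Error statistics from the model's most recent held-out evaluation."""
    if model.heldout_predictions.size == 0:
        raise ValueError("model carries no held-out predictions")
    return error_statistics(model.heldout_predictions, model.heldout_labels)


def filter_bounds(ccs_user: float, stats: ErrorStats) -> FilterBand:
    """Derive the CCS filter band from the user CCS and batch-error stats.

    The band is symmetric and multiplicative; its half-width is
    ``ccs_user * (mean_error + sem_error)``, so it widens monotonically
    with either statistic.
    """
    if ccs_user <= 0:
        raise ValueError("ccs_user must be positive")
    spread = stats.mean_error + stats.sem_error
    if spread >= 1.0:
        raise ValueError(
            f"mean_error + sem_error = {spread:.3f} >= 1 gives a nonpositive lower limit"
        )
    return FilterBand(
        ccs_user=ccs_user,
        lower=ccs_user * (1.0 - spread),
        upper=ccs_user * (1.0 + spread),
    )


def apply_filter(
    ensemble: ConformerEnsemble,
    predictions,
    band: FilterBand,
    capacity: Optional[int] = None,
) -> ConformerEnsemble:
    """Retain conformers whose predicted CCS lies inside the closed band.

    Every retained conformer is annotated with its ``pred_ccs``.  With a
    ``capacity`` limit k, the k survivors with predicted CCS nearest to
    ``band.ccs_user`` are kept (ties by input order); input order is
    preserved in the output either way.
    """
    p = np.asarray(predictions, dtype=float)
    if p.shape != (len(ensemble),):
        raise ValueError(f"{len(ensemble)} conformers but {p.size} predictions")
    keep = np.where((p >= band.lower) & (p <= band.upper))[0]
    if capacity is not None and capacity >= 0 and keep.size > capacity:
        dist = np.abs(p[keep] - band.ccs_user)
        nearest = np.argsort(dist, kind="stable")[:capacity]
        keep = np.sort(keep[nearest])
    survivors = [
        ensemble[i].with_coordinates(ensemble[i].coordinates, pred_ccs=float(p[i]))
        for i in keep
    ]
    return ConformerEnsemble(species_name=ensemble.species_name, conformers=survivors)


@dataclass(frozen=True)
class FocusReport:
    """Summary of one focusing pass."""

    n_in: int
    n_out: int
    band: FilterBand
    pred_min: float
    pred_mean: float
    pred_max: float

    def as_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "ccs_user": self.band.ccs_user,
            "band_lower": self.band.lower,
            "band_upper": self.band.upper,
            "pred_min": self.pred_min,
            "pred_mean": self.pred_mean,
            "pred_max": self.pred_max,
        }


def focus(
    ensemble: ConformerEnsemble,
    model: TrainedRegressor,
    ccs_user: float,
    stats: Optional[ErrorStats] = None,
    capacity: Optional[int] = None,
    **featurize_kwargs,
) -> tuple[ConformerEnsemble, FocusReport]:
    """Featurize, batch-predict, derive the band, and filter an ensemble.

    ``stats`` defaults to the model's latest held-out error statistics.
    Returns the focused ensemble together with a :class:`FocusReport`
    (counts, band, and the predicted-CCS range of the input ensemble).
    """
    if stats is None:
        stats = stats_from_model(model)
    feats = featurize_ensemble(ensemble, **featurize_kwargs)
    preds = predict_batch(model, feats)
    band = filter_bounds(ccs_user, stats)
    out = apply_filter(ensemble, preds, band, capacity=capacity)
    report = FocusReport(
        n_in=len(ensemble),
        n_out=len(out),
        band=band,
        pred_min=float(preds.min()),
        pred_mean=float(preds.mean()),
        pred_max=float(preds.max()),
    )
    return out, report
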