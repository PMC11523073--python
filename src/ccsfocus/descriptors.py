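"""The five molecular-level descriptors feeding the CCS regressor.

For a conformer of a lipid [M-H]- ion the feature vector is

* ``mz`` — mass-to-charge ratio of the deprotonated anion, Da;
* ``d_het_max`` — distance from the centre of mass (COM) to the farthest
  heteroatom, Angstrom (0 when there are no heteroatoms);
* ``d_atom_max`` — distance from the COM to the farthest atom, Angstrom;
* ``n_het`` — number of heteroatoms (any element other than C or H);
* ``msa`` — molecular surface area, A^2, computed as a solvent-accessible
  surface area by Shrake-Rupley sphere-point sampling with a 1.4 A probe.

The geometry-derived descriptors are invariant under rigid translation and
(to sampling tolerance) rotation; ``mz`` and ``n_het`` depend only on the
formula.  All descriptors are deterministic: the sphere point set is a
seed-free golden-spiral construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .elements import PROTON_MASS, element_lookup
from .structures import Conformer

FEATURE_NAMES = ("mz", "d_het_max", "d_atom_max", "n_het", "msa")

#: Default probe radius for the accessible-surface computation, Angstrom.
DEFAULT_PROBE_RADIUS = 1.4
#: Default number of sphere points per atom.
DEFAULT_POINTS_PER_ATOM = 960

#: Features compared in the train-vs-query feature-shift survey.
SURVEY_FEATURES = ("d_het_max", "d_atom_max", "msa")


@dataclass(frozen=True)
class FeatureVector:
    """The five descriptors for one conformer."""

    mz: float
    d_het_max: float
    d_atom_max: float
    n_het: int
    msa: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if not 0 <= self.d_het_max <= self.d_atom_max + 1e-9:
            raise ValueError(
                f"need 0 <= d_het_max <= d_atom_max, got {self.d_het_max}, {self.d_atom_max}"
            )
        if self.n_het < 0:
            raise ValueError("n_het must be >= 0")
        if self.msa <= 0:
            raise ValueError(f"msa must be positive, got {self.msa}")

    def as_array(self, mask: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        """Feature values in *mask* order (default: all five)."""
        return np.array([float(getattr(self, name)) for name in mask])


def _masses(conformer: Conformer) -> np.ndarray:
    return np.array([element_lookup(e).monoisotopic_mass for e in conformer.elements])


def _vdw_radii(conformer: Conformer) -> np.ndarray:
    return np.array([element_lookup(e).vdw_radius for e in conformer.elements])


def center_of_mass(conformer: Conformer) -> np.ndarray:
    """Mass-weighted mean position, using monoisotopic masses.  Angstrom."""
    m = _masses(conformer)
    return m @ conformer.coordinates / m.sum()


def max_distance_from_com(conformer: Conformer, heteroatoms_only: bool = False) -> float:
    """Maximum distance from the COM over all atoms (or heteroatoms only).

    Returns 0.0 by convention when ``heteroatoms_only`` is set and the
    molecule has no heteroatoms.
    """
    com = center_of_mass(conformer)
    coords = conformer.coordinates
    if heteroatoms_only:
        keep = [element_lookup(e).is_heteroatom for e in conformer.elements]
        if not any(keep):
            return 0.0
        coords = coords[np.asarray(keep)]
    return float(np.linalg.norm(coords - com, axis=1).max())


def mz_anion(conformer: Conformer, geometry_is_neutral: bool = False) -> float:
    """m/z of the singly deprotonated anion [M-H]-, Da.

    The input geometry is assumed to already be the deprotonated species
    (the acidic proton removed), so the neutral formula is the input
    formula plus one hydrogen; set ``geometry_is_neutral`` if the geometry
    carries all protons.  m/z = (neutral monoisotopic mass) - 1.00728 Da,
    charge 1; the electron mass is neglected.
    """
    neutral_mass = float(_masses(conformer).sum())
    if not geometry_is_neutral:
        neutral_mass += element_lookup("H").monoisotopic_mass
    return neutral_mass - PROTON_MASS


def count_heteroatoms(conformer: Conformer) -> int:
    """Number of atoms that are neither carbon nor hydrogen."""
    return sum(element_lookup(e).is_heteroatom for e in conformer.elements)


def _golden_spiral_points(n: int) -> np.ndarray:
    """n nearly uniform unit-sphere points (golden-spiral lattice), (n, 3)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def molecular_surface_area(
    conformer: Conformer,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    points_per_atom: int = DEFAULT_POINTS_PER_ATOM,
) -> float:
    """Solvent-accessible surface area by Shrake-Rupley sampling, A^2.

    For each atom, the fraction of points on a sphere of radius
    (r_vdw + probe) not buried inside any neighbour's expanded sphere,
    times that sphere's area.  Deterministic: the point set is a fixed
    golden-spiral lattice.
    """
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    coords = conformer.coordinates
    radii = _vdw_radii(conformer) + probe_radius
    n = len(conformer)
    sphere = _golden_spiral_points(points_per_atom)

    # neighbour prefilter: only spheres that can overlap matter
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    total = 0.0
    for i in range(n):
        cutoff = (radii[i] + radii) ** 2
        nb = np.where((d2[i] < cutoff) & (np.arange(n) != i))[0]
        area_i = 4.0 * np.pi * radii[i] ** 2
        if nb.size == 0:
            total += area_i
            continue
        pts = coords[i] + radii[i] * sphere
        dd = pts[:, None, :] - coords[nb][None, :, :]
        buried = np.any(
            np.einsum("pjk,pjk->pj", dd, dd) < (radii[nb] ** 2)[None, :], axis=1
        )
        total += area_i * (1.0 - buried.mean())
    return float(total)


def featurize(
    conformer: Conformer,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    points_per_atom: int = DEFAULT_POINTS_PER_ATOM,
    geometry_is_neutral: bool = False,
) -> FeatureVector:
    """Assemble the five-descriptor :class:`FeatureVector` for a conformer."""
    return FeatureVector(
        mz=mz_anion(conformer, geometry_is_neutral=geometry_is_neutral),
        d_het_max=max_distance_from_com(conformer, heteroatoms_only=True),
        d_atom_max=max_distance_from_com(conformer, heteroatoms_only=False),
        n_het=count_heteroatoms(conformer),
        msa=molecular_surface_area(conformer, probe_radius, points_per_atom),
    )


def featurize_ensemble(ensemble, **kwargs) -> list[FeatureVector]:
    """Feature vectors for every conformer of an ensemble, in order."""
    return [featurize(c, **kwargs) for c in ensemble]


def features_to_frame(
    ids: Iterable[str],
    features: Iterable[FeatureVector],
    label_ccs: Iterable | None = None,
) -> pd.DataFrame:
    """Tabulate feature vectors as a DataFrame (CSV-ready).

    Columns: id, mz, d_het_max, d_atom_max, n_het, msa, label_ccs (NaN when
    absent).
    """
    rows = [
        {"id": i, **{k: getattr(f, k) for k in FEATURE_NAMES}}
        for i, f in zip(ids, features)
    ]
    df = pd.DataFrame(rows)
    if label_ccs is not None:
        df["label_ccs"] = [np.nan if v is None else v for v in label_ccs]
    else:
        df["label_ccs"] = np.nan
    return df


@dataclass(frozen=True)
class FeatureShiftReport:
    """Percent difference of mean feature values, query relative to reference.

    Positive means the query ensemble's mean exceeds the reference mean.
    """

    d_het_max: float
    d_atom_max: float
    msa: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in SURVEY_FEATURES}


def feature_shift_survey(
    reference_features: Sequence[FeatureVector],
    query_features: Sequence[FeatureVector],
) -> FeatureShiftReport:
    """Survey how far a query ensemble's geometry descriptors sit from a
    reference (training) collection.

    For each of ``d_het_max``, ``d_atom_max`` and ``msa`` the report holds
    ``100 * (mean_query - mean_reference) / mean_reference``.
    """
    if not reference_features or not query_features:
        raise ValueError("both feature collections must be non-empty")
    shifts = {}
    for name in SURVEY_FEATURES:
        ref = float(np.mean([getattr(f, name) for f in reference_features]))
        qry = float(np.mean([getattr(f, name) for f in query_features]))
        if ref == 0:
            raise ValueError(f"reference mean for {name} is zero")
        shifts[name] = 100.0 * (qry - ref) / ref
    return FeatureShiftReport(**shifts)
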