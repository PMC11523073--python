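"""In-memory containers for conformers and conformer ensembles.

A :class:`Conformer` is one 3D geometry of a molecular ion ([M-H]- by
default); a :class:`ConformerEnsemble` is an ordered collection of
conformers of one species.  Ensembles enforce that every member shares the
same molecular formula, so a mixed-species file fails fast rather than
poisoning downstream descriptors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .elements import element_lookup


@dataclass(frozen=True)
class Atom:
    """One atom: chemical symbol plus Cartesian coordinates in Angstrom."""

    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        element_lookup(self.element)  # validates the symbol
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError(f"non-finite coordinates for atom {self.element}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Conformer:
    """A single conformer geometry with optional energy/CCS metadata.

    Parameters
    ----------
    id : str
        Identifier, unique within an ensemble.
    atoms : sequence of Atom
        Ordered atom list.
    formal_charge : int
        Net charge; -1 for the deprotonated [M-H]- species (default).
    energy : float, optional
        Relative energy, kcal/mol.
    label_ccs : float, optional
        Reference / training-label CCS, A^2 (must be positive).
    pred_ccs : float, optional
        Model-predicted CCS, A^2.
    """

    id: str
    atoms: Sequence[Atom]
    formal_charge: int = -1
    energy: Optional[float] = None
    label_ccs: Optional[float] = None
    pred_ccs: Optional[float] = None

    def __post_init__(self) -> None:
        if len(self.atoms) < 1:
            raise ValueError("a conformer needs at least one atom")
        for name in ("energy", "label_ccs", "pred_ccs"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.label_ccs is not None and self.label_ccs <= 0:
            raise ValueError(f"label_ccs must be positive, got {self.label_ccs}")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array, Angstrom."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms])

    @property
    def formula(self) -> Counter:
        """Element multiset of this geometry (the as-given, e.g. anionic, formula)."""
        return Counter(self.elements)

    def with_coordinates(self, coords: np.ndarray, **meta) -> "Conformer":
        """Copy with new coordinates (and optionally other fields)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected shape {(len(self.atoms), 3)}, got {coords.shape}")
        atoms = [Atom(a.element, *xyz) for a, xyz in zip(self.atoms, coords)]
        return replace(self, atoms=atoms, **meta)


class FormulaMismatchError(ValueError):
    """Raised when an ensemble member does not share the ensemble formula."""


@dataclass
class ConformerEnsemble:
    """Ordered conformers of one molecular species (identical formula)."""

    species_name: str
    conformers: list[Conformer] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if not self.conformers:
            return
        ids = [c.id for c in self.conformers]
        if len(set(ids)) != len(ids):
            dup = [i for i, n in Counter(ids).items() if n > 1]
            raise ValueError(f"duplicate conformer ids in ensemble: {dup}")
        ref = self.conformers[0].formula
        for i, c in enumerate(self.conformers):
            if c.formula != ref:
                raise FormulaMismatchError(
                    f"conformer {i} ({c.id!r}) formula {dict(c.formula)} differs "
                    f"from ensemble formula {dict(ref)}"
                )

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self) -> Iterator[Conformer]:
        return iter(self.conformers)

    def __getitem__(self, i):
        return self.conformers[i]

    @property
    def formula(self) -> Counter:
        if not self.conformers:
            raise ValueError("empty ensemble has no formula")
        return self.conformers[0].formula

    def subset(self, indices: Sequence[int], species_name: Optional[str] = None) -> "ConformerEnsemble":
        """New ensemble keeping the conformers at *indices*, in the given order."""
        return ConformerEnsemble(
            species_name=species_name or self.species_name,
            conformers=[self.conformers[i] for i in indices],
        )
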