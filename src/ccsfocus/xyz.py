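"""Multi-frame XYZ reading and writing.

The dialect is standard XYZ (atom-count line, free-form comment line, then
one ``element x y z`` line per atom) with per-frame metadata carried on the
comment line as whitespace-separated ``key=value`` tokens.  Recognised keys:
``energy`` (kcal/mol), ``ccs`` (label CCS, A^2), ``charge`` (formal charge)
and ``id``.  Unknown tokens are ignored on read so files from other tools
still parse.
"""

from __future__ import annotations

import os
from typing import Union

from .elements import UnknownElementError, element_lookup
from .structures import Atom, Conformer, ConformerEnsemble

PathLike = Union[str, os.PathLike]


class XYZParseError(ValueError):
    """Malformed XYZ input; the message names the offending frame."""


def _parse_comment(comment: str) -> dict:
    meta = {}
    for token in comment.split():
        if "=" not in token:
            continue
        key, _, value = token.partition("=")
        if key in ("energy", "ccs"):
            try:
                meta[key] = float(value)
            except ValueError:
                raise XYZParseError(f"non-numeric {key} value {value!r}")
        elif key == "charge":
            try:
                meta[key] = int(value)
            except ValueError:
                raise XYZParseError(f"non-integer charge value {value!r}")
        elif key == "id":
            meta[key] = value
    return meta


def read_xyz_ensemble(path: PathLike, species_name: str | None = None) -> ConformerEnsemble:
    """Read a multi-frame XYZ file into a :class:`ConformerEnsemble`.

    One conformer per frame, in file order.  Comment-line ``key=value``
    tokens populate metadata; absent keys leave fields at their defaults
    (charge -1, no energy, no label CCS, id ``conf_<frame>``).

    Raises
    ------
    XYZParseError
        On a malformed count line, non-numeric coordinates, an unknown
        element symbol, or a formula inconsistent with earlier frames; the
        message names the (0-based) frame index.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    conformers: list[Conformer] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate blank lines between frames
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError(
                f"frame {frame}: expected an atom count, got {lines[pos]!r}"
            ) from None
        if natoms < 1:
            raise XYZParseError(f"frame {frame}: atom count must be >= 1, got {natoms}")
        if pos + 2 + natoms > len(lines):
            raise XYZParseError(
                f"frame {frame}: declares {natoms} atoms but the file ends early"
            )
        try:
            meta = _parse_comment(lines[pos + 1])
        except XYZParseError as exc:
            raise XYZParseError(f"frame {frame}: {exc}") from None

        atoms = []
        for j in range(natoms):
            line = lines[pos + 2 + j]
            parts = line.split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"frame {frame}: atom line {j} has {len(parts)} fields: {line!r}"
                )
            symbol = parts[0]
            try:
                element_lookup(symbol)
            except UnknownElementError:
                raise XYZParseError(
                    f"frame {frame}: unknown element symbol {symbol!r}"
                ) from None
            try:
                x, y, z = (float(p) for p in parts[1:4])
            except ValueError:
                raise XYZParseError(
                    f"frame {frame}: non-numeric coordinates in {line!r}"
                ) from None
            atoms.append(Atom(symbol, x, y, z))

        conformers.append(
            Conformer(
                id=meta.get("id", f"conf_{frame}"),
                atoms=atoms,
                formal_charge=meta.get("charge", -1),
                energy=meta.get("energy"),
                label_ccs=meta.get("ccs"),
            )
        )
        pos += 2 + natoms
        frame += 1

    if not conformers:
        raise XYZParseError("no frames found in file")

    name = species_name or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    try:
        return ConformerEnsemble(species_name=name, conformers=conformers)
    except ValueError as exc:  # formula mismatch / duplicate ids, with frame context
        raise XYZParseError(str(exc)) from None


def write_xyz_ensemble(ensemble: ConformerEnsemble, path: PathLike) -> None:
    """Write *ensemble* as multi-frame XYZ; inverse of :func:`read_xyz_ensemble`.

    Metadata is serialised as ``key=value`` tokens on the comment line.
    Coordinates are written to 6 decimal places.
    """
    if len(ensemble) == 0:
        raise ValueError("refusing to write an empty ensemble")
    with open(path, "w") as fh:
        for conf in ensemble:
            tokens = [f"id={conf.id}", f"charge={conf.formal_charge}"]
            if conf.energy is not None:
                tokens.append(f"energy={conf.energy:.6g}")
            if conf.label_ccs is not None:
                tokens.append(f"ccs={conf.label_ccs:.6g}")
            fh.write(f"{len(conf)}\n")
            fh.write(" ".join(tokens) + "\n")
            for atom in conf.atoms:
                fh.write(f"{atom.element:<2s} {atom.x:14.6f} {atom.y:14.6f} {atom.z:14.6f}\n")
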