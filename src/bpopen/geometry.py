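"""Geometric primitives for a G-C base pair.

The three Watson-Crick hydrogen bonds are measured between heavy
(donor/acceptor) atoms:

    B1  DG:O6 - DC:N4   (top,    O-H-N)
    B2  DG:N1 - DC:N1   (middle, N-H-N)
    B3  DG:N2 - DC:O2   (bottom, N-H-O)

The signed opening angle theta quantifies how asymmetrically the pair opens.
Its magnitude is the angle between the guanine donor-acceptor vector
G = DG:N2 -> DG:O6 and the cytosine vector C = DC:O2 -> DC:N4; the sign is
negative when the cross product G x C is anti-aligned with the direction of
the double helix.  theta < 0 corresponds to B1 staying closed while B3 opens
(the direction favoured by static electronic-structure optimisations),
theta > 0 to the mirror-image opening.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "HBondSpec",
    "BasePairGeometry",
    "OpeningAngleRecord",
    "DEFAULT_HBONDS",
    "OPENING_ANGLE_ATOMS",
    "hbond_lengths",
    "opening_angle",
    "read_pdb_geometry",
    "read_xyz_geometry",
]


class AtomResolutionError(KeyError):
    """An atom label required by a measurement is absent from the geometry."""


class DegenerateGeometryError(ValueError):
    """A direction vector needed for the opening angle has zero length."""


@dataclass(frozen=True)
class HBondSpec:
    """Definition of one base-pair hydrogen bond between heavy atoms.

    Atom labels use the ``residue:atom`` convention, e.g. ``DG:O6``.
    ``equilibrium_length`` is the unstrained donor-acceptor distance in
    Angstrom.
    """

    name: str
    donor_atom: str
    acceptor_atom: str
    equilibrium_length: float

    def __post_init__(self) -> None:
        if self.equilibrium_length <= 0:
            raise ValueError(
                f"equilibrium_length must be positive, got {self.equilibrium_length}"
            )


#: Canonical G-C bond definitions with gas/implicit-solvent equilibrium lengths.
DEFAULT_HBONDS: tuple[HBondSpec, ...] = (
    HBondSpec("B1", "DG:O6", "DC:N4", 2.89),
    HBondSpec("B2", "DG:N1", "DC:N1", 2.96),
    HBondSpec("B3", "DG:N2", "DC:O2", 2.89),
)

#: Atoms required to form the opening-angle vectors.
OPENING_ANGLE_ATOMS = ("DG:N2", "DG:O6", "DC:O2", "DC:N4")


@dataclass
class BasePairGeometry:
    """A single base-pair snapshot: labelled Cartesian positions plus helix axis.

    ``atoms`` maps ``residue:atom`` labels to positions in Angstrom.  The
    helix axis is caller-supplied (from trajectory metadata or configuration);
    it is normalised on construction.
    """

    atoms: dict[str, np.ndarray]
    helix_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.atoms = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.atoms.items()}
        ax = np.asarray(self.helix_axis, dtype=float).reshape(3)
        norm = np.linalg.norm(ax)
        if norm == 0:
            raise ValueError("helix_axis must be non-zero")
        self.helix_axis = ax / norm

    def position(self, label: str) -> np.ndarray:
        try:
            return self.atoms[label]
        except KeyError:
            raise AtomResolutionError(
                f"atom label {label!r} not found in geometry "
                f"(available: {sorted(self.atoms)})"
            ) from None


@dataclass(frozen=True)
class OpeningAngleRecord:
    """Signed opening angle (degrees) of one frame, optionally tied to an event."""

    theta: float
    frame_index: int = 0
    event_ref: str | None = None

    def __post_init__(self) -> None:
        if not -180.0 <= self.theta <= 180.0:
            raise ValueError(f"theta out of range [-180, 180]: {self.theta}")


def hbond_lengths(
    geom: BasePairGeometry, specs: Sequence[HBondSpec] = DEFAULT_HBONDS
) -> dict[str, float]:
    """Euclidean donor-acceptor distance (Angstrom) for each hydrogen bond."""
    out: dict[str, float] = {}
    for spec in specs:
        d = geom.position(spec.donor_atom)
        a = geom.position(spec.acceptor_atom)
        out[spec.name] = float(np.linalg.norm(d - a))
    return out


def opening_angle(
    geom: BasePairGeometry, frame_index: int = 0, event_ref: str | None = None
) -> OpeningAngleRecord:
    """Signed opening angle theta (degrees) of a base-pair geometry.

    Magnitude: angle between G = DG:N2->DG:O6 and C = DC:O2->DC:N4.
    Sign: negative iff (G x C) . helix_axis < 0.  A vanishing cross product
    (G parallel to C) is the symmetric-opening limit and gets sign +.
    """
    g = geom.position("DG:O6") - geom.position("DG:N2")
    c = geom.position("DC:N4") - geom.position("DC:O2")
    ng = np.linalg.norm(g)
    nc = np.linalg.norm(c)
    if ng == 0 or nc == 0:
        raise DegenerateGeometryError(
            "zero-length donor-acceptor vector; opening angle undefined"
        )
    cosang = float(np.dot(g, c) / (ng * nc))
    theta = math.degrees(math.acos(min(1.0, max(-1.0, cosang))))
    if float(np.dot(np.cross(g, c), geom.helix_axis)) < 0:
        theta = -theta
    return OpeningAngleRecord(theta=theta, frame_index=frame_index, event_ref=event_ref)


def read_pdb_geometry(
    path: str | Path,
    helix_axis: Sequence[float],
    label_map: Mapping[str, str] | None = None,
) -> BasePairGeometry:
    """Load a base-pair geometry from a PDB file.

    Atom labels are formed as ``<resname>:<atomname>``; ``label_map`` can
    rename them (e.g. ``{"G:O6": "DG:O6"}``) when the file uses different
    residue naming.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("bp", str(path))
    atoms: dict[str, np.ndarray] = {}
    for atom in structure.get_atoms():
        res = atom.get_parent()
        label = f"{res.get_resname().strip()}:{atom.get_name().strip()}"
        if label_map:
            label = label_map.get(label, label)
        atoms[label] = np.asarray(atom.get_coord(), dtype=float)
    return BasePairGeometry(atoms=atoms, helix_axis=np.asarray(helix_axis, float))


def read_xyz_geometry(
    path: str | Path,
    helix_axis: Sequence[float],
    labels: Sequence[str] | None = None,
) -> BasePairGeometry:
    """Load a single-frame XYZ geometry.

    XYZ files carry element symbols only, so ``labels`` supplies the
    ``residue:atom`` label for each atom line in order; if omitted the bare
    element symbols are used as labels (suitable for synthetic templates).
    """
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise ValueError(f"XYZ file {path} truncated: expected {n} atom lines")
    atoms: dict[str, np.ndarray] = {}
    for i, line in enumerate(body):
        parts = line.split()
        label = labels[i] if labels is not None else parts[0]
        atoms[label] = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
    return BasePairGeometry(atoms=atoms, helix_axis=np.asarray(helix_axis, float))
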