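"""Molecular structures, lanthanide centers and coordination polyhedra.

Structures are plain Cartesian coordinate sets (Å), unit-cell-free; crystal
structures are expected pre-converted to XYZ or to the JSON dialect described
in :func:`read_structure_json`.  The coordination polyhedron — the lanthanide
center plus its directly bonded donor atoms — is the geometric object every
accuracy metric in this package is computed on.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ComplexStructure",
    "CoordinationPolyhedron",
    "StructurePair",
    "CutoffScheme",
    "LANTHANIDES",
    "ANGLE_ELEMENTS",
    "LN_LN_RANGE",
    "read_xyz",
    "write_xyz",
    "read_structure_json",
    "write_structure_json",
    "detect_center",
    "detect_polyhedron",
    "detect_polyhedra",
    "pair_structures",
]

#: All lanthanide element symbols; any of them is recognised as a center.
LANTHANIDES = (
    "La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd",
    "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu",
)

#: Elements allowed as angle endpoints in A-Ln-B angles.
ANGLE_ELEMENTS = frozenset({"O", "N", "C", "S", "Cl", "Br"})

#: Ln-Ln separation range (Å) within which a partner lanthanide is recorded
#: as an "Ln-Ln" bond of the polyhedron.
LN_LN_RANGE = (3.6, 6.6)

#: Maximum plausible donor count; larger sets trigger a cutoff warning.
MAX_DONORS = 16


class StructureError(ValueError):
    """Malformed structure input or inconsistent pairing."""


def _check_element(symbol: str) -> str:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise StructureError(f"unknown element symbol {symbol!r}")
    return el.name


@dataclass(frozen=True)
class Atom:
    """A labelled atom with Cartesian coordinates in Å."""

    element: str
    label: str
    xyz: np.ndarray

    def __post_init__(self):
        _check_element(self.element)
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise StructureError(f"atom {self.label!r}: coordinates must be a finite 3-vector")
        object.__setattr__(self, "xyz", xyz)


@dataclass
class ComplexStructure:
    """An ordered atom list with one or two identified lanthanide centers."""

    id: str
    atoms: list[Atom]
    center_indices: tuple[int, ...]

    def __post_init__(self):
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise StructureError(f"{self.id}: duplicate atom labels {dupes}")
        for i in self.center_indices:
            if not (0 <= i < len(self.atoms)):
                raise StructureError(f"{self.id}: center index {i} out of range")
            if self.atoms[i].element not in LANTHANIDES:
                raise StructureError(
                    f"{self.id}: center atom {self.atoms[i].label} "
                    f"({self.atoms[i].element}) is not a lanthanide"
                )

    @property
    def center_index(self) -> int:
        """First (or only) center index."""
        return self.center_indices[0]

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def with_coordinates(self, coords: np.ndarray) -> "ComplexStructure":
        coords = np.asarray(coords, float)
        atoms = [replace(a, xyz=c) for a, c in zip(self.atoms, coords, strict=True)]
        return ComplexStructure(self.id, atoms, self.center_indices)

    def index_of(self, label: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.label == label:
                return i
        raise KeyError(label)


@dataclass
class CoordinationPolyhedron:
    """A center, its donor atoms and the typed bonds/angles among them.

    ``bonds[k]`` corresponds to ``donor_indices[k]`` and is a
    ``(bond_class, distance)`` pair with bond class ``"Ln-X"`` (``"Ln-Ln"``
    for a partner lanthanide).  Angles are A-Ln-B vertex angles in degrees for
    all donor pairs whose elements both lie in :data:`ANGLE_ELEMENTS`.
    """

    structure: ComplexStructure
    center_index: int
    donor_indices: list[int]
    bonds: list[tuple[str, float]]
    angles: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        for cls, d in self.bonds:
            if d <= 0:
                raise StructureError(f"non-positive bond distance in class {cls}")
        for _, _, ang in self.angles:
            if not (0.0 < ang <= 180.0):
                raise StructureError(f"angle {ang} out of (0, 180]")

    @property
    def donor_count(self) -> int:
        return len(self.donor_indices)


@dataclass
class StructurePair:
    """Experimental/calculated structures with an atom correspondence.

    The correspondence maps experimental atom index -> calculated atom index
    and is validated to preserve elements; it is the unit on which all error
    metrics operate.
    """

    experimental: ComplexStructure
    calculated: ComplexStructure
    correspondence: dict[int, int]

    def calc_index(self, exp_index: int) -> int:
        return self.correspondence[exp_index]


# --------------------------------------------------------------------------
# I/O: standard XYZ and the JSON structure dialect
# --------------------------------------------------------------------------

def detect_center(atoms: Sequence[Atom]) -> tuple[int, ...]:
    """Indices of all lanthanide atoms; error if there are none."""
    idx = tuple(i for i, a in enumerate(atoms) if a.element in LANTHANIDES)
    if not idx:
        raise StructureError("no lanthanide center found (and none supplied)")
    return idx


def read_xyz(path, structure_id: str | None = None,
             center_indices: Sequence[int] | None = None) -> ComplexStructure:
    """Read a standard XYZ file (count line, comment, ``El x y z`` records).

    Labels are auto-generated as element symbol + ordinal (``Dy1``, ``O2``…).
    The lanthanide center(s) are auto-detected unless ``center_indices`` is
    given.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise StructureError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise StructureError(f"{path}, line 1: malformed atom count {lines[0]!r}") from None
    if len(lines) < count + 2:
        raise StructureError(f"{path}: expected {count} atom records, file has {len(lines) - 2}")
    atoms = []
    for n, line in enumerate(lines[2:2 + count], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise StructureError(f"{path}, line {n}: malformed record {line!r}")
        el = _check_element(parts[0])
        try:
            xyz = np.array([float(x) for x in parts[1:4]])
        except ValueError:
            raise StructureError(f"{path}, line {n}: non-numeric coordinates") from None
        atoms.append(Atom(el, f"{el}{n - 2}", xyz))
    if center_indices is None:
        center_indices = detect_center(atoms)
    return ComplexStructure(structure_id or path.stem, atoms, tuple(center_indices))


def write_xyz(structure: ComplexStructure, path, comment: str = "") -> None:
    with open(path, "w") as f:
        f.write(f"{len(structure.atoms)}\n{comment or structure.id}\n")
        for a in structure.atoms:
            f.write(f"{a.element:<2s} {a.xyz[0]:15.6f} {a.xyz[1]:15.6f} {a.xyz[2]:15.6f}\n")


def read_structure_json(path) -> tuple[ComplexStructure, list[str] | None]:
    """Read the JSON dialect ``{id, atoms, centers, donors?}``.

    Returns the structure and the explicit donor-label list if present (an
    explicit list overrides the distance cutoff in
    :func:`detect_polyhedron`).
    """
    doc = json.loads(Path(path).read_text())
    atoms = [Atom(a["element"], a["label"], np.array(a["xyz"], float)) for a in doc["atoms"]]
    labels = [a.label for a in atoms]
    centers = tuple(labels.index(l) for l in doc["centers"])
    return ComplexStructure(doc["id"], atoms, centers), doc.get("donors")


def write_structure_json(structure: ComplexStructure, path,
                         donors: Iterable[str] | None = None) -> None:
    doc = {
        "id": structure.id,
        "atoms": [
            {"label": a.label, "element": a.element, "xyz": [float(x) for x in a.xyz]}
            for a in structure.atoms
        ],
        "centers": [structure.atoms[i].label for i in structure.center_indices],
    }
    if donors is not None:
        doc["donors"] = list(donors)
    Path(path).write_text(json.dumps(doc, indent=1))


# --------------------------------------------------------------------------
# Coordination polyhedron detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CutoffScheme:
    """Per-element-pair maximum bond length.

    Default: sum of covalent radii plus ``tolerance`` Å, which reproduces
    typical 2.2-2.9 Å lanthanide-donor ranges.  ``overrides`` maps an
    (element, element) pair to an explicit cutoff.
    """

    tolerance: float = 0.45
    overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def max_distance(self, el_a: str, el_b: str) -> float:
        key = (el_a, el_b)
        if key in self.overrides:
            return self.overrides[key]
        if key[::-1] in self.overrides:
            return self.overrides[key[::-1]]
        return (gemmi.Element(el_a).covalent_r + gemmi.Element(el_b).covalent_r
                + self.tolerance)


DEFAULT_CUTOFFS = CutoffScheme()


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def detect_polyhedron(structure: ComplexStructure,
                      cutoff_scheme: CutoffScheme = DEFAULT_CUTOFFS,
                      center_index: int | None = None,
                      donor_labels: Sequence[str] | None = None) -> CoordinationPolyhedron:
    """Extract the coordination polyhedron around one center.

    Donors are the non-hydrogen atoms within the cutoff of the center
    (hydrogens are never donors).  A partner lanthanide center within the
    3.6-6.6 Å Ln-Ln window is recorded as a donor of class ``"Ln-Ln"``.
    An explicit ``donor_labels`` list (e.g. from the JSON dialect) replaces
    the cutoff criterion; the Ln-Ln window still applies to other centers
    not listed.
    """
    ci = structure.center_index if center_index is None else center_index
    center = structure.atoms[ci]
    donor_idx: list[int] = []
    if donor_labels is not None:
        donor_idx = [structure.index_of(l) for l in donor_labels]
    else:
        for i, a in enumerate(structure.atoms):
            if i == ci or a.element == "H":
                continue
            if i in structure.center_indices:
                continue  # partner centers handled via the Ln-Ln window below
            r = float(np.linalg.norm(a.xyz - center.xyz))
            if r <= cutoff_scheme.max_distance(center.element, a.element):
                donor_idx.append(i)
    for j in structure.center_indices:
        if j == ci or j in donor_idx:
            continue
        r = float(np.linalg.norm(structure.atoms[j].xyz - center.xyz))
        if LN_LN_RANGE[0] <= r <= LN_LN_RANGE[1]:
            donor_idx.append(j)
    if not donor_idx:
        raise StructureError(f"{structure.id}: empty donor set around {center.label}")
    if len(donor_idx) > MAX_DONORS:
        warnings.warn(
            f"{structure.id}: {len(donor_idx)} donors around {center.label} — "
            "suspicious cutoff scheme", stacklevel=2)

    bonds = []
    for i in donor_idx:
        a = structure.atoms[i]
        cls = "Ln-Ln" if a.element in LANTHANIDES else f"Ln-{a.element}"
        bonds.append((cls, float(np.linalg.norm(a.xyz - center.xyz))))

    angles = []
    for p in range(len(donor_idx)):
        for q in range(p + 1, len(donor_idx)):
            i, j = donor_idx[p], donor_idx[q]
            if (structure.atoms[i].element in ANGLE_ELEMENTS
                    and structure.atoms[j].element in ANGLE_ELEMENTS):
                ang = _angle_deg(structure.atoms[i].xyz - center.xyz,
                                 structure.atoms[j].xyz - center.xyz)
                angles.append((i, j, ang))
    return CoordinationPolyhedron(structure, ci, donor_idx, bonds, angles)


def detect_polyhedra(structure: ComplexStructure,
                     cutoff_scheme: CutoffScheme = DEFAULT_CUTOFFS,
                     donor_labels: Sequence[str] | None = None) -> list[CoordinationPolyhedron]:
    """One polyhedron per center (dilanthanide complexes yield two)."""
    return [detect_polyhedron(structure, cutoff_scheme, ci, donor_labels)
            for ci in structure.center_indices]


# --------------------------------------------------------------------------
# Pairing
# --------------------------------------------------------------------------

def pair_structures(experimental: ComplexStructure,
                    calculated: ComplexStructure) -> StructurePair:
    """Build the atom correspondence between an experimental and a
    calculated structure, by label when the label sets agree, by position
    otherwise.  Corresponding atoms must share the element.
    """
    exp_labels = {a.label: i for i, a in enumerate(experimental.atoms)}
    calc_labels = {a.label: i for i, a in enumerate(calculated.atoms)}
    if set(exp_labels) == set(calc_labels):
        corr = {i: calc_labels[lab] for lab, i in exp_labels.items()}
    elif len(experimental.atoms) == len(calculated.atoms):
        corr = {i: i for i in range(len(experimental.atoms))}
    else:
        missing = sorted(set(exp_labels) ^ set(calc_labels))
        raise StructureError(
            f"cannot pair {experimental.id}/{calculated.id}: label sets differ "
            f"({missing}) and atom counts differ")
    bad = [experimental.atoms[i].label for i, j in corr.items()
           if experimental.atoms[i].element != calculated.atoms[j].element]
    if bad:
        raise StructureError(
            f"element mismatch between paired atoms: {sorted(bad)}")
    return StructurePair(experimental, calculated, corr)
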