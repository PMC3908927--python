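"""Coordination-polyhedron accuracy metrics.

Two families of measures compare an experimental crystal geometry with a
model-calculated one, using internal distances and angles only (no
superposition):

* **UME** (unsigned mean error): the mean absolute deviation between
  experimental and calculated interatomic distances.  ``UME_(Ln-L)``
  restricts to center-donor (and Ln-Ln) distances; the full ``UME`` adds
  every donor-donor (L-L') distance of the coordination polyhedron, thereby
  sensing the angles indirectly.

* **R_i**: a per-complex scalar that sums |Δd|/σ_j over all typed bonds
  (Ln-O, Ln-N, Ln-C, …) and |Δθ|/σ_angle over all A-Ln-B angles with
  A, B ∈ {O, N, C, S, Cl, Br}.  The σ's are standard deviations of the
  experimental values pooled over the whole universe of complexes, so the
  normalised terms are mutually comparable.  R_i drives both training-set
  selection and the parameterization objective.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .structures import (
    ANGLE_ELEMENTS,
    ComplexStructure,
    CoordinationPolyhedron,
    CutoffScheme,
    DEFAULT_CUTOFFS,
    StructurePair,
    detect_polyhedra,
)

__all__ = [
    "TypeSigmas",
    "UMEResult",
    "RiResult",
    "compute_sigmas",
    "ume",
    "ri",
    "aggregate",
    "pool_rows",
    "per_complex_table",
    "write_per_complex_csv",
    "write_per_type_csv",
]

LNL_CLASS_PREFIX = "Ln-"
DONOR_PAIR_CLASS = "L-L'"


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class TypeSigmas:
    """Pooled experimental standard deviations used to normalise R_i terms.

    ``sigma_by_bond_class`` maps e.g. ``"Ln-O"`` to a σ in Å; ``sigma_angle``
    is the single pooled A-Ln-B angle σ in degrees (the angles form one
    homogeneous set and are not split into types).
    """

    sigma_by_bond_class: dict[str, float]
    sigma_angle: float | None

    def __post_init__(self):
        for cls, s in self.sigma_by_bond_class.items():
            if not s > 0:
                raise MetricError(f"sigma for {cls} must be > 0")
        if self.sigma_angle is not None and not self.sigma_angle > 0:
            raise MetricError("sigma_angle must be > 0")


@dataclass
class UMEResult:
    complex_id: str
    ume_lnl: float
    ume_full: float
    n_lnl: int
    n_full: int
    per_class: dict[str, tuple[int, float]]  # class -> (n, mean |Δd|)

    def __post_init__(self):
        if self.ume_lnl < 0 or self.ume_full < 0 or self.n_full < self.n_lnl:
            raise MetricError("inconsistent UME result")


@dataclass
class RiResult:
    complex_id: str
    r_value: float
    distance_term: float
    angle_term: float


# --------------------------------------------------------------------------
# Sigmas
# --------------------------------------------------------------------------

def compute_sigmas(polyhedra: Iterable[CoordinationPolyhedron]) -> TypeSigmas:
    """Pooled population standard deviations from experimental polyhedra only.

    One σ per bond class over all bond lengths of that class across the
    universe, and a single σ over all A-Ln-B angles.  A class with fewer
    than two values, or with zero variance, is dropped with a warning (and
    is later skipped by :func:`ri`).
    """
    dist_by_class: dict[str, list[float]] = {}
    angles: list[float] = []
    for poly in polyhedra:
        for cls, d in poly.bonds:
            dist_by_class.setdefault(cls, []).append(d)
        angles.extend(a for _, _, a in poly.angles)

    sigmas: dict[str, float] = {}
    for cls, vals in sorted(dist_by_class.items()):
        if len(vals) < 2:
            warnings.warn(f"bond class {cls}: <2 values, dropped from sigmas", stacklevel=2)
            continue
        s = float(np.std(vals))  # population convention (divide by N)
        if s == 0.0:
            warnings.warn(f"bond class {cls}: zero variance, dropped from sigmas", stacklevel=2)
            continue
        sigmas[cls] = s
    if len(angles) >= 2:
        sa = float(np.std(angles))
        if sa == 0.0:
            warnings.warn("angles have zero variance, sigma_angle unset", stacklevel=2)
            sa = None
    else:
        if angles:
            warnings.warn("<2 angles in universe, sigma_angle unset", stacklevel=2)
        sa = None
    return TypeSigmas(sigmas, sa)


# --------------------------------------------------------------------------
# Distance inventories
# --------------------------------------------------------------------------

def _distance_errors(pair: StructurePair,
                     cutoff_scheme: CutoffScheme = DEFAULT_CUTOFFS,
                     polyhedra: Sequence[CoordinationPolyhedron] | None = None,
                     ) -> dict[str, list[float]]:
    """Absolute distance errors keyed by class.

    Polyhedra are detected on the *experimental* structure; the same atom
    set, mapped through the correspondence, is measured on the calculated
    one.  Classes: ``Ln-X`` per donor element, ``Ln-Ln`` for center-center
    and center-partner distances, ``L-L'`` for donor-donor pairs (center
    excluded).  Index pairs are de-duplicated across centers.
    """
    exp = pair.experimental
    calc = pair.calculated
    if polyhedra is None:
        polyhedra = detect_polyhedra(exp, cutoff_scheme)
    xe = exp.coordinates
    xc = calc.coordinates

    pairs: dict[tuple[int, int], str] = {}

    def add(i: int, j: int, cls: str) -> None:
        key = (i, j) if i < j else (j, i)
        pairs.setdefault(key, cls)

    all_donors: list[int] = []
    for poly in polyhedra:
        ci = poly.center_index
        for k, i in enumerate(poly.donor_indices):
            add(ci, i, poly.bonds[k][0])
            if i not in all_donors and i not in exp.center_indices:
                all_donors.append(i)
    if len(exp.center_indices) == 2:
        add(*exp.center_indices, "Ln-Ln")

    for p in range(len(all_donors)):
        for q in range(p + 1, len(all_donors)):
            add(all_donors[p], all_donors[q], DONOR_PAIR_CLASS)

    errors: dict[str, list[float]] = {}
    for (i, j), cls in pairs.items():
        ic, jc = pair.calc_index(i), pair.calc_index(j)
        de = float(np.linalg.norm(xe[i] - xe[j]))
        dc = float(np.linalg.norm(xc[ic] - xc[jc]))
        errors.setdefault(cls, []).append(abs(de - dc))
    return errors


def ume(pair: StructurePair,
        mode: Literal["lnl", "full"] = "full",
        cutoff_scheme: CutoffScheme = DEFAULT_CUTOFFS,
        polyhedra: Sequence[CoordinationPolyhedron] | None = None) -> UMEResult:
    """Unsigned mean errors for one structure pair.

    Both ``UME_(Ln-L)`` and the full ``UME`` are always filled in the
    result; ``mode`` selects which of them downstream consumers treat as
    primary and is kept for interface symmetry.
    """
    errors = _distance_errors(pair, cutoff_scheme, polyhedra)
    lnl = [e for cls, vals in errors.items() if cls != DONOR_PAIR_CLASS for e in vals]
    full = lnl + errors.get(DONOR_PAIR_CLASS, [])
    if not (lnl if mode == "lnl" else full):
        raise MetricError(f"{pair.experimental.id}: empty distance set")
    per_class = {cls: (len(v), float(np.mean(v))) for cls, v in sorted(errors.items())}
    return UMEResult(
        complex_id=pair.experimental.id,
        ume_lnl=float(np.mean(lnl)) if lnl else 0.0,
        ume_full=float(np.mean(full)),
        n_lnl=len(lnl),
        n_full=len(full),
        per_class=per_class,
    )


def ri(pair: StructurePair,
       sigmas: TypeSigmas,
       cutoff_scheme: CutoffScheme = DEFAULT_CUTOFFS,
       polyhedra: Sequence[CoordinationPolyhedron] | None = None,
       power: int = 1) -> RiResult:
    """The per-complex selection/objective metric R_i.

    ``R_i = Σ_j Σ_k |Δd_jk|^p / σ_j^p + Σ_l |Δθ_l|^p / σ_angle^p`` with
    ``p = power`` (absolute errors by default).  Bond classes without a σ
    are skipped with a warning.  Only Ln-L (and Ln-Ln) distances enter; the
    angle sum runs over A-Ln-B angles with A, B ∈ {O, N, C, S, Cl, Br}.
    """
    exp = pair.experimental
    if polyhedra is None:
        polyhedra = detect_polyhedra(exp, cutoff_scheme)
    errors = _distance_errors(pair, cutoff_scheme, polyhedra)

    dist_term = 0.0
    for cls, vals in errors.items():
        if cls == DONOR_PAIR_CLASS:
            continue
        s = sigmas.sigma_by_bond_class.get(cls)
        if s is None:
            warnings.warn(f"{exp.id}: no sigma for class {cls}, skipped in R_i", stacklevel=2)
            continue
        dist_term += float(np.sum((np.abs(vals) / s) ** power))

    xe = exp.coordinates
    xc = pair.calculated.coordinates
    angle_term = 0.0
    n_angles = 0
    for poly in polyhedra:
        ci = poly.center_index
        for i, j, ang_exp in poly.angles:
            ic, jc, cc = pair.calc_index(i), pair.calc_index(j), pair.calc_index(ci)
            v1, v2 = xc[ic] - xc[cc], xc[jc] - xc[cc]
            cosv = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang_calc = float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))
            n_angles += 1
            if sigmas.sigma_angle is None:
                continue
            angle_term += (abs(ang_exp - ang_calc) / sigmas.sigma_angle) ** power
    if n_angles and sigmas.sigma_angle is None:
        raise MetricError(f"{exp.id}: angles present but sigma_angle missing")
    return RiResult(exp.id, dist_term + angle_term, dist_term, angle_term)


# --------------------------------------------------------------------------
# Aggregation (per-type pooled tables)
# --------------------------------------------------------------------------

def pool_rows(rows: Iterable[tuple[int, float]]) -> tuple[int, float]:
    """Count-weighted pooling of (n, mean) rows -> (N, pooled mean)."""
    rows = list(rows)
    n_tot = sum(n for n, _ in rows)
    if n_tot == 0:
        raise MetricError("cannot pool empty rows")
    return n_tot, sum(n * m for n, m in rows) / n_tot


def aggregate(results: Sequence[UMEResult], label: str = "Ln") -> pd.DataFrame:
    """Pooled per-type error table for a set of complexes.

    One row per bond class with the count-weighted mean |Δd| (equivalent to
    the flat mean over all individual distances of the class), then an
    ``"{label}-L"`` row pooling every center-involving class including
    Ln-Ln, the donor-donor ``"L-L'"`` row, and a combined row pooling
    everything.
    """
    if not results:
        raise MetricError("aggregate: empty input")
    by_class: dict[str, list[tuple[int, float]]] = {}
    for r in results:
        for cls, (n, m) in r.per_class.items():
            by_class.setdefault(cls, []).append((n, m))

    def pretty(cls: str) -> str:
        if cls == DONOR_PAIR_CLASS:
            return cls
        return cls.replace("Ln-Ln", f"{label}-{label}").replace("Ln-", f"{label}-")

    out_rows = []
    lnl_rows: list[tuple[int, float]] = []
    all_rows: list[tuple[int, float]] = []
    for cls in sorted(by_class):
        if cls == DONOR_PAIR_CLASS:
            continue
        n, m = pool_rows(by_class[cls])
        out_rows.append((pretty(cls), n, m))
        lnl_rows.append((n, m))
        all_rows.append((n, m))
    n, m = pool_rows(lnl_rows)
    out_rows.append((f"{label}-L", n, m))
    if DONOR_PAIR_CLASS in by_class:
        n, m = pool_rows(by_class[DONOR_PAIR_CLASS])
        out_rows.append((DONOR_PAIR_CLASS, n, m))
        all_rows.append((n, m))
    n, m = pool_rows(all_rows)
    out_rows.append((f"{label}-L, {label}-{label} and L-L'", n, m))
    return pd.DataFrame(out_rows, columns=["distance_type", "n", "ume"])


def per_complex_table(results: Sequence[UMEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.complex_id, r.ume_lnl, r.ume_full) for r in results],
        columns=["complex_id", "ume_lnl", "ume_full"],
    )


def write_per_complex_csv(results: Sequence[UMEResult], path) -> None:
    per_complex_table(results).to_csv(path, index=False)


def write_per_type_csv(results: Sequence[UMEResult], path, label: str = "Ln") -> None:
    aggregate(results, label).to_csv(path, index=False)
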