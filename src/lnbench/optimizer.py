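"""Parameterization engine: Σ R_i minimisation by GSA + Simplex.

The objective of a parameterization is the sum of R_i over a training set
of complexes, where the "calculated" geometries entering R_i are produced
by a pluggable backend contract::

    backend(structure, params) -> (relaxed ComplexStructure, converged flag)

The in-repo surrogate engine (:mod:`lnbench.sparkle_surrogate`) is the
reference implementation of this contract; a MOPAC adapter
(:mod:`lnbench.param_io_report`) is I/O only.  The search combines
generalized simulated annealing — Tsallis-statistics annealing with a
heavy-tailed visiting distribution, which explores globally — with a
Nelder–Mead simplex refinement, first on a small training set, then
re-optimising on a larger one.

Parameters are searched in scaled units (each active parameter mapped to
[0, 1] by its bound window) to condition the problem; a failed backend
relaxation contributes a large finite penalty rather than aborting the
search.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize as sp_optimize
from scipy.special import gammaln

from .metrics import TypeSigmas, ri
from .structures import ComplexStructure, CutoffScheme, DEFAULT_CUTOFFS, detect_polyhedra, pair_structures

__all__ = [
    "PARAMETER_NAMES",
    "ParameterSet",
    "ObjectiveSpec",
    "GSASchedule",
    "OptimizationTrace",
    "objective",
    "make_vector_objective",
    "gsa_minimize",
    "simplex_minimize",
    "parameterize",
]

#: The 22 semiempirical parameters of one lanthanide trication, in canonical
#: order: one-center one-electron integrals, Slater exponents, resonance
#: integrals, two-electron sd integrals, the core additive term and the
#: core-core α, the second exponent set, and the two core-core Gaussians
#: (height a_i, inverse broadness b_i, displacement c_i).
PARAMETER_NAMES = (
    "U_ss", "U_pp", "U_dd",
    "zeta_s", "zeta_p", "zeta_d",
    "beta_s", "beta_p", "beta_d",
    "F0_sd", "G2_sd",
    "rho_core", "alpha",
    "zeta_s_prime", "zeta_p_prime", "zeta_d_prime",
    "a1", "b1", "c1", "a2", "b2", "c2",
)

PARAMETER_UNITS = {
    "U_ss": "eV", "U_pp": "eV", "U_dd": "eV",
    "zeta_s": "bohr^-1", "zeta_p": "bohr^-1", "zeta_d": "bohr^-1",
    "beta_s": "eV", "beta_p": "eV", "beta_d": "eV",
    "F0_sd": "eV", "G2_sd": "eV",
    "rho_core": "bohr", "alpha": "angstrom^-1",
    "zeta_s_prime": "bohr^-1", "zeta_p_prime": "bohr^-1", "zeta_d_prime": "bohr^-1",
    "a1": "dimensionless", "b1": "angstrom^-2", "c1": "angstrom",
    "a2": "dimensionless", "b2": "angstrom^-2", "c2": "angstrom",
}

SUPPORTED_IONS = ("Dy3+", "Ho3+", "Er3+")


@dataclass(frozen=True)
class ParameterSet:
    """The 22 semiempirical parameters for one lanthanide trication."""

    ion: str
    U_ss: float
    U_pp: float
    U_dd: float
    zeta_s: float
    zeta_p: float
    zeta_d: float
    beta_s: float
    beta_p: float
    beta_d: float
    F0_sd: float
    G2_sd: float
    rho_core: float
    alpha: float
    zeta_s_prime: float
    zeta_p_prime: float
    zeta_d_prime: float
    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float

    def __post_init__(self):
        if self.ion not in SUPPORTED_IONS:
            raise ValueError(f"unsupported ion {self.ion!r} (expected one of {SUPPORTED_IONS})")
        for z in ("zeta_s", "zeta_p", "zeta_d", "zeta_s_prime", "zeta_p_prime", "zeta_d_prime"):
            if getattr(self, z) <= 0:
                raise ValueError(f"{z} must be > 0")
        for g in ("b1", "b2", "c1", "c2"):
            if getattr(self, g) <= 0:
                raise ValueError(f"{g} must be > 0")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    def replace(self, **kw) -> "ParameterSet":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_dict(cls, ion: str, values: Mapping[str, float]) -> "ParameterSet":
        missing = [n for n in PARAMETER_NAMES if n not in values]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        return cls(ion=ion, **{n: float(values[n]) for n in PARAMETER_NAMES})


# --------------------------------------------------------------------------
# Objective
# --------------------------------------------------------------------------

Backend = Callable[[ComplexStructure, object], tuple[ComplexStructure, bool]]


@dataclass
class ObjectiveSpec:
    """Everything needed to evaluate Σ R_i for a candidate parameter set.

    ``structures`` maps complex id to the experimental structure;
    ``base_params`` is the parameter object handed to the backend, with the
    ``active`` fields overridden by the optimizer within ``bounds``.
    """

    structures: Mapping[str, ComplexStructure]
    training_ids: Sequence[str]
    sigmas: TypeSigmas
    backend: Backend
    base_params: object
    active: Sequence[str]
    bounds: Mapping[str, tuple[float, float]]
    penalty: float = 1e6
    cutoff_scheme: CutoffScheme = DEFAULT_CUTOFFS
    _poly_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        missing = [i for i in self.training_ids if i not in self.structures]
        if missing:
            raise ValueError(f"unresolvable training ids: {missing}")
        for name in self.active:
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lo < hi")

    def polyhedra(self, cid: str):
        if cid not in self._poly_cache:
            self._poly_cache[cid] = detect_polyhedra(self.structures[cid], self.cutoff_scheme)
        return self._poly_cache[cid]

    def with_params(self, values: Mapping[str, float]):
        return dataclasses.replace(self.base_params, **dict(values))


def objective(params: object, spec: ObjectiveSpec) -> float:
    """Σ R_i over the training set with backend-relaxed geometries.

    A non-converged or failing relaxation contributes ``spec.penalty``;
    if every complex fails, an error is raised.
    """
    total = 0.0
    n_fail = 0
    for cid in spec.training_ids:
        exp = spec.structures[cid]
        try:
            relaxed, ok = spec.backend(exp, params)
        except Exception:
            ok = False
        if not ok:
            n_fail += 1
            total += spec.penalty
            continue
        pair = pair_structures(exp, relaxed)
        total += ri(pair, spec.sigmas, spec.cutoff_scheme,
                    polyhedra=spec.polyhedra(cid)).r_value
    if n_fail == len(spec.training_ids):
        raise RuntimeError("backend failed on every training complex")
    return total


def make_vector_objective(spec: ObjectiveSpec) -> Callable[[np.ndarray], float]:
    """Objective over the scaled [0, 1]^d vector of active parameters."""
    names = list(spec.active)
    lows = np.array([spec.bounds[n][0] for n in names])
    highs = np.array([spec.bounds[n][1] for n in names])

    def f(x: np.ndarray) -> float:
        x = np.clip(np.asarray(x, float), 0.0, 1.0)
        values = dict(zip(names, lows + x * (highs - lows)))
        return objective(spec.with_params(values), spec)

    return f


def scale_params(spec: ObjectiveSpec, params: object) -> np.ndarray:
    return np.array([
        (getattr(params, n) - spec.bounds[n][0]) / (spec.bounds[n][1] - spec.bounds[n][0])
        for n in spec.active
    ])


def unscale_params(spec: ObjectiveSpec, x: np.ndarray):
    values = {n: spec.bounds[n][0] + xi * (spec.bounds[n][1] - spec.bounds[n][0])
              for n, xi in zip(spec.active, x)}
    return spec.with_params(values)


# --------------------------------------------------------------------------
# Generalized simulated annealing (Tsallis)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GSASchedule:
    """Annealing schedule: T(t) = T0·(2^(qv−1) − 1)/((1+t)^(qv−1) − 1)."""

    t0: float = 5000.0
    qv: float = 2.62      # visiting-distribution index (heavy tails)
    qa: float = -5.0      # acceptance index; -inf means strictly greedy
    max_iter: int = 1000

    def temperature(self, t: int) -> float:
        num = 2.0 ** (self.qv - 1.0) - 1.0
        den = (1.0 + t) ** (self.qv - 1.0) - 1.0
        return self.t0 * num / den


@dataclass
class TraceRecord:
    phase: str
    step: int
    temperature: float
    objective: float
    best: float


@dataclass
class OptimizationTrace:
    records: list[TraceRecord] = field(default_factory=list)
    seed: int | None = None
    termination: str = ""

    def log(self, phase: str, step: int, temperature: float,
            value: float, best: float) -> None:
        self.records.append(TraceRecord(phase, step, temperature, value, best))

    @property
    def best_values(self) -> list[float]:
        return [r.best for r in self.records]


class _TsallisVisitor:
    """Samples displacements from the Tsallis visiting distribution.

    Implements the Tsallis–Stariolo construction: a heavy-tailed deviate is
    built from two Gaussians with a temperature-dependent width, giving the
    q_v-generalised visiting distribution used by generalized simulated
    annealing.
    """

    TAIL_LIMIT = 1e8

    def __init__(self, qv: float):
        self.qv = qv
        f2 = math.exp((4.0 - qv) * math.log(qv - 1.0))
        f3 = math.exp((2.0 - qv) * math.log(2.0) / (qv - 1.0))
        self.factor4p = math.sqrt(math.pi) * f2 / (f3 * (3.0 - qv))
        f5 = 1.0 / (qv - 1.0) - 0.5
        d1 = 2.0 - f5
        self.factor6 = (math.pi * (1.0 - f5) / math.sin(math.pi * (1.0 - f5))
                        / math.exp(gammaln(d1)))

    def sample(self, rng: np.random.Generator, temperature: float, dim: int) -> np.ndarray:
        factor1 = math.exp(math.log(temperature) / (self.qv - 1.0))
        factor4 = self.factor4p * factor1
        sigmax = math.exp(-(self.qv - 1.0) * math.log(self.factor6 / factor4)
                          / (3.0 - self.qv))
        x = sigmax * rng.normal(size=dim)
        y = rng.normal(size=dim)
        den = np.exp((self.qv - 1.0) * np.log(np.abs(y)) / (3.0 - self.qv))
        visit = x / den
        return np.clip(visit, -self.TAIL_LIMIT, self.TAIL_LIMIT)


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Fold out-of-box coordinates back in (triangle-wave reflection)."""
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return lo + y


def gsa_minimize(func: Callable[[np.ndarray], float],
                 bounds: Sequence[tuple[float, float]],
                 seed: int,
                 schedule: GSASchedule = GSASchedule(),
                 x0: np.ndarray | None = None,
                 trace: OptimizationTrace | None = None,
                 phase: str = "gsa",
                 ) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Generalized simulated annealing inside a bounds box.

    Candidate moves are drawn from the Tsallis visiting distribution at the
    current temperature and reflected into the box; uphill moves are
    accepted with the generalized Metropolis probability
    ``[1 − (1 − q_a)·ΔE/T_a]^(1/(1−q_a))`` (strictly greedy when
    ``q_a = -inf``).  Bit-identical for identical seed and schedule.
    Returns the best-ever point.
    """
    bounds_arr = np.asarray(bounds, float)
    lo, hi = bounds_arr[:, 0], bounds_arr[:, 1]
    if np.any(hi <= lo):
        raise ValueError("empty bounds box")
    rng = np.random.default_rng(seed)
    x = np.array(x0, float) if x0 is not None else 0.5 * (lo + hi)
    fx = float(func(x))
    if not math.isfinite(fx):
        raise ValueError("objective is not finite at the starting point")
    best_x, best_f = x.copy(), fx
    if trace is None:
        trace = OptimizationTrace(seed=seed)
    visitor = _TsallisVisitor(schedule.qv)
    for t in range(1, schedule.max_iter + 1):
        temp = schedule.temperature(t)
        cand = _reflect(x + visitor.sample(rng, temp, len(x)), lo, hi)
        fc = float(func(cand))
        de = fc - fx
        if de <= 0.0:
            accept = True
        elif math.isinf(schedule.qa) and schedule.qa < 0:
            accept = False
        else:
            t_accept = temp / float(t)
            bracket = 1.0 - (1.0 - schedule.qa) * de / t_accept
            prob = 0.0 if bracket <= 0.0 else math.exp(math.log(bracket) / (1.0 - schedule.qa))
            accept = rng.random() < prob
        if accept:
            x, fx = cand, fc
            if fx < best_f:
                best_x, best_f = x.copy(), fx
        trace.log(phase, t, temp, fx, best_f)
    trace.termination = "max_iter"
    return best_x, best_f, trace


def simplex_minimize(func: Callable[[np.ndarray], float],
                     start: np.ndarray,
                     bounds: Sequence[tuple[float, float]] | None = None,
                     xatol: float = 1e-8,
                     fatol: float = 1e-10,
                     max_iter: int | None = None,
                     initial_spread: float | None = None,
                     trace: OptimizationTrace | None = None,
                     ) -> tuple[np.ndarray, float, bool]:
    """Nelder–Mead refinement with the standard coefficients.

    Reflection 1, expansion 2, contraction 0.5, shrink 0.5 (scipy's
    defaults); convergence when the simplex collapses below ``xatol`` and
    the objective spread below ``fatol``.  ``initial_spread`` sets the edge
    length of a fresh axis-aligned initial simplex (useful for restarts in
    narrow curved valleys).  Hitting the iteration cap returns the best
    point with ``converged=False``.
    """
    start = np.asarray(start, float)
    if not np.all(np.isfinite(start)):
        raise ValueError("start point must be finite")
    options = {"xatol": xatol, "fatol": fatol, "maxiter": max_iter, "maxfev": max_iter}
    if initial_spread is not None:
        d = len(start)
        options["initial_simplex"] = np.vstack(
            [start] + [start + initial_spread * np.eye(d)[i] for i in range(d)])
    res = sp_optimize.minimize(
        func, start, method="Nelder-Mead", bounds=bounds, options=options,
    )
    if trace is not None:
        prev_best = trace.records[-1].best if trace.records else float("inf")
        trace.log("simplex", res.nit, 0.0, float(res.fun), min(prev_best, float(res.fun)))
    return np.asarray(res.x, float), float(res.fun), bool(res.success)


# --------------------------------------------------------------------------
# Two-stage parameterization protocol
# --------------------------------------------------------------------------

#: Initial-simplex edge lengths (in scaled [0, 1] units) for the Simplex
#: polish ladder.  A single Nelder–Mead run tends to collapse early inside
#: the narrow curved valley of the Σ R_i landscape; restarting with a fresh
#: simplex of decreasing size walks much further down the valley.
POLISH_SPREADS = (0.05, 0.02, 0.008, 0.003, 0.001)


def parameterize(initial: object,
                 small_set: Sequence[str],
                 large_set: Sequence[str],
                 spec: ObjectiveSpec,
                 schedule: GSASchedule = GSASchedule(),
                 seed: int = 0,
                 polish_spreads: Sequence[float] = POLISH_SPREADS,
                 polish_maxfev: int = 600,
                 ) -> tuple[object, OptimizationTrace]:
    """Small-set GSA+Simplex, then re-optimization on the large set.

    Stage 1 anneals and refines over the small training set; stage 2
    restarts both searches from the stage-1 optimum on the large set.  The
    Simplex refinement of each stage is a ladder of restarts with fresh
    initial simplexes of decreasing spread, stopping early once the
    objective stops improving.  Returns the final parameter object and the
    full trace.  With no active parameters the initial object is returned
    unchanged.
    """
    trace = OptimizationTrace(seed=seed)
    if not spec.active:
        trace.termination = "no active parameters"
        return initial, trace
    spec.base_params = initial
    x = scale_params(spec, initial)
    for stage, ids in (("small", list(small_set)), ("large", list(large_set))):
        spec.training_ids = ids
        f = make_vector_objective(spec)
        box = [(0.0, 1.0)] * len(spec.active)
        x, fx, trace = gsa_minimize(f, box, seed=seed + (0 if stage == "small" else 1),
                                    schedule=schedule, x0=x, trace=trace,
                                    phase=f"gsa-{stage}")
        for spread in polish_spreads:
            x_new, f_new, _ = simplex_minimize(f, x, bounds=box, max_iter=polish_maxfev,
                                               initial_spread=spread, trace=trace)
            if f_new < fx:
                x, fx = np.clip(x_new, 0.0, 1.0), f_new
            if fx <= 1e-12:
                break
    trace.termination = "completed"
    return unscale_params(spec, x), trace
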