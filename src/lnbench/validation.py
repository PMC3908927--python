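"""Statistical validation of UME populations.

UMEs are non-negative by construction, so a well-behaved error population
should follow a gamma distribution.  The fit is by moment matching (shape
k = m²/v, scale θ = v/m reproduce the sample mean and variance exactly) and
its quality is assessed with a one-sample Kolmogorov–Smirnov test: if
p > 0.05 the gamma description — and hence the use of the mean and variance
as accuracy measures — is statistically justified at the 95% level.

The default p-value is the asymptotic Kolmogorov distribution of √n·D; an
exact small-n method is available and flagged in the report.  Because the
gamma parameters are estimated from the same sample, p-values are
approximate (no Lilliefors-style recalibration is applied).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import special, stats

__all__ = ["GammaFit", "KSReport", "gamma_moment_fit", "ks_one_sample", "validate_population"]


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class GammaFit:
    """Moment-matched gamma distribution (shape dimensionless, scale in Å)."""

    shape: float
    scale: float
    source_mean: float
    source_variance: float

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ValidationError("gamma fit requires positive shape and scale")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2

    def cdf(self, x):
        return stats.gamma.cdf(x, a=self.shape, scale=self.scale)


@dataclass(frozen=True)
class KSReport:
    D: float
    p: float
    n: int
    method: str = "asymptotic"

    @property
    def passed(self) -> bool:
        return self.p > 0.05


def gamma_moment_fit(values: Sequence[float], ddof: int = 0) -> GammaFit:
    """Gamma fit reproducing the sample mean and variance exactly.

    ``ddof=0`` (population variance) is the default convention; the chosen
    ddof is visible through ``source_variance``.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValidationError("need at least two values")
    if np.any(x <= 0):
        raise ValidationError("gamma fit requires strictly positive values")
    m = float(x.mean())
    v = float(x.var(ddof=ddof))
    if v <= 0:
        raise ValidationError("zero variance")
    return GammaFit(shape=m * m / v, scale=v / m, source_mean=m, source_variance=v)


def ks_one_sample(values: Sequence[float],
                  cdf: Callable[[np.ndarray], np.ndarray],
                  method: Literal["asymptotic", "exact"] = "asymptotic") -> KSReport:
    """One-sample KS test of ``values`` against a fully specified CDF.

    ``D = max_i max(i/n − F(x_(i)), F(x_(i)) − (i−1)/n)`` over the sorted
    sample; the p-value comes from the asymptotic Kolmogorov distribution of
    ``√n·D`` (default) or from the exact finite-n distribution.
    """
    x = np.sort(np.asarray(values, float))
    n = x.size
    if n == 0:
        raise ValidationError("empty sample")
    f = np.asarray(cdf(x), float)
    i = np.arange(1, n + 1)
    d = float(np.max(np.maximum(i / n - f, f - (i - 1) / n)))
    if method == "asymptotic":
        p = float(special.kolmogorov(np.sqrt(n) * d))
    elif method == "exact":
        p = float(stats.kstwo.sf(d, n))
    else:
        raise ValueError(f"unknown method {method!r}")
    return KSReport(D=d, p=min(1.0, p), n=n, method=method)


@dataclass(frozen=True)
class PopulationReport:
    """A Table-5/6 style row: N, mean, variance, gamma fit and KS outcome."""

    n: int
    mean: float
    variance: float
    fit: GammaFit
    ks: KSReport
    variance_convention: str


def validate_population(values: Sequence[float],
                        ddof: int = 0,
                        method: Literal["asymptotic", "exact"] = "asymptotic") -> PopulationReport:
    """Moment-fit a gamma to the values and KS-test the fit."""
    fit = gamma_moment_fit(values, ddof=ddof)
    ks = ks_one_sample(values, fit.cdf, method=method)
    return PopulationReport(
        n=len(values),
        mean=fit.source_mean,
        variance=fit.source_variance,
        fit=fit,
        ks=ks,
        variance_convention="population" if ddof == 0 else f"ddof={ddof}",
    )
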