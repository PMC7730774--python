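"""Confidence intervals for the LOAM, the variance components and ICC(A,1).

Four constructions are used, matching the closed-form inference toolbox of
the method:

* **Graybill–Wang** for the LOAM: an approximate CI for the nonnegative
  linear combination (SSB + SSE)/N inside the square root, built from
  per-component F-quantile multipliers, then transformed through
  ``z * sqrt(.)``.  Asymmetric by construction.
* **Exact chi-square pivot** for sigma_E (the residual SD has a known
  scaled-chi distribution).
* **Delta method** for sigma_A and sigma_B: symmetric +/- intervals around
  the square-rooted component estimate; undefined when the component
  estimate is not strictly positive.
* **McGraw & Wong** (two-way random, absolute agreement, single rater;
  their Case 2A) for ICC(A,1): F-based with a Satterthwaite denominator df.

All quantile machinery comes from scipy.stats; F-quantiles with an
infinite denominator df are evaluated through the exact identity
F_{q; nu, inf} = chi2_{q; nu} / nu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .estimation import (
    SumsOfSquares,
    VarianceComponents,
    icc_a1,
    loam_estimate,
    z_multiplier,
)

__all__ = [
    "IntervalEstimate",
    "loam_ci",
    "sigma_E_ci",
    "sigma_B_ci",
    "sigma_A_ci",
    "icc_ci",
    "graybill_wang_multipliers",
]

UNDEFINED = "undefined"
NEGATIVE_COMPONENT = "negative_component"


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a (possibly asymmetric) confidence interval.

    ``flags`` may contain ``"undefined"`` (bounds are NaN because the
    construction's precondition failed, e.g. a nonpositive variance
    component) and/or ``"negative_component"``.
    """

    point: float
    lower: float
    upper: float
    level: float
    method: str
    flags: frozenset = field(default_factory=frozenset)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    def __post_init__(self):
        if not self.flags and not (self.lower <= self.point <= self.upper):
            raise AssertionError(
                f"interval ({self.lower}, {self.upper}) does not bracket point {self.point}"
            )


def _f_quantile_inf_denominator(q: float, nu: int) -> float:
    # F_{q; nu, inf} = chi2_{q; nu} / nu, exactly
    return stats.chi2.ppf(q, nu) / nu


def graybill_wang_multipliers(nu: int, level: float = 0.95) -> tuple[float, float]:
    """(l, h) multipliers for one variance component with df ``nu``.

    l = 1 - 1/F_{1-alpha/2; nu, inf},  h = 1/F_{alpha/2; nu, inf} - 1,
    so 0 < l < 1 and h > 0; both shrink to 0 as nu grows.
    """
    alpha = 1.0 - level
    l = 1.0 - 1.0 / _f_quantile_inf_denominator(1.0 - alpha / 2, nu)
    h = 1.0 / _f_quantile_inf_denominator(alpha / 2, nu) - 1.0
    return l, h


def loam_ci(
    ss: SumsOfSquares, level: float = 0.95, loam_level: float = 0.95
) -> IntervalEstimate:
    """Graybill–Wang CI for the upper LOAM.

    ``loam_level`` sets the inner coverage of the limits themselves (the z
    multiplier); ``level`` sets the confidence of the interval around the
    estimated limit.  Both default to the conventional 95%.

    The lower bound's radicand SSB + SSE - L is provably nonnegative
    (each l < 1, so L <= sqrt(SSB^2 + SSE^2) <= SSB + SSE); the CI for the
    lower LOAM is the negation of the returned endpoints.
    """
    z = z_multiplier(loam_level)
    lB, hB = graybill_wang_multipliers(ss.nu_B, level)
    lE, hE = graybill_wang_multipliers(ss.nu_E, level)
    L = math.sqrt(lB**2 * ss.SSB**2 + lE**2 * ss.SSE**2)
    H = math.sqrt(hB**2 * ss.SSB**2 + hE**2 * ss.SSE**2)
    s = ss.SSB + ss.SSE
    lower = z * math.sqrt(max(s - L, 0.0) / ss.N)  # max() guards rounding at s ~ L
    upper = z * math.sqrt((s + H) / ss.N)
    return IntervalEstimate(
        point=loam_estimate(ss, z=z),
        lower=lower,
        upper=upper,
        level=level,
        method="graybill_wang",
    )


def sigma_E_ci(ss: SumsOfSquares, level: float = 0.95) -> IntervalEstimate:
    """Exact chi-square CI for the residual (intra-observer) SD sigma_E.

    (sigma_E_hat * sqrt(nu_E / chi2_{1-alpha/2; nu_E}),
     sigma_E_hat * sqrt(nu_E / chi2_{alpha/2; nu_E})).
    """
    alpha = 1.0 - level
    sigma_E = math.sqrt(ss.MSE)
    lower = sigma_E * math.sqrt(ss.nu_E / stats.chi2.ppf(1 - alpha / 2, ss.nu_E))
    upper = sigma_E * math.sqrt(ss.nu_E / stats.chi2.ppf(alpha / 2, ss.nu_E))
    return IntervalEstimate(
        point=sigma_E, lower=lower, upper=upper, level=level, method="chi_square_exact"
    )


def _delta_sd_ci(
    sigma2: float,
    sigma2_E: float,
    scale: int,
    nu: int,
    nu_E: int,
    level: float,
    method: str = "delta",
) -> IntervalEstimate:
    """Shared delta-method interval for sqrt of an ANOVA variance component.

    ``scale`` is the cell count dividing (MS - MSE): ac for the observer
    component, bc for the subject component.  Undefined (NaN bounds) when
    the component estimate is not strictly positive; the lower bound may be
    negative and is reported as computed.
    """
    if sigma2 <= 0:
        flags = {UNDEFINED}
        if sigma2 < 0:
            flags.add(NEGATIVE_COMPONENT)
        point = 0.0 if sigma2 == 0 else math.nan
        return IntervalEstimate(
            point=point,
            lower=math.nan,
            upper=math.nan,
            level=level,
            method=method,
            flags=frozenset(flags),
        )
    z = z_multiplier(level)
    sigma = math.sqrt(sigma2)
    half = (z / (scale * sigma)) * math.sqrt(
        (scale * sigma2 + sigma2_E) ** 2 / (2 * nu) + sigma2_E**2 / (2 * nu_E)
    )
    return IntervalEstimate(
        point=sigma, lower=sigma - half, upper=sigma + half, level=level, method=method
    )


def sigma_B_ci(
    vc: VarianceComponents, ss: SumsOfSquares, level: float = 0.95
) -> IntervalEstimate:
    """Delta-method CI for the inter-observer SD sigma_B.

    sigma_B_hat +/- z/(ac sigma_B_hat) *
        sqrt((ac sigma2_B + sigma2_E)^2 / (2 nu_B) + sigma2_E^2 / (2 nu_E)).
    """
    return _delta_sd_ci(
        vc.sigma2_B, vc.sigma2_E, ss.a * ss.c, ss.nu_B, ss.nu_E, level
    )


def sigma_A_ci(
    vc: VarianceComponents, ss: SumsOfSquares, level: float = 0.95
) -> IntervalEstimate:
    """Delta-method CI for the inter-subject SD sigma_A (context for scale).

    sigma_A_hat +/- z/(bc sigma_A_hat) *
        sqrt((bc sigma2_A + sigma2_E)^2 / (2 nu_A) + sigma2_E^2 / (2 nu_E)).
    """
    return _delta_sd_ci(
        vc.sigma2_A, vc.sigma2_E, ss.b * ss.c, ss.nu_A, ss.nu_E, level
    )


def icc_ci(ss: SumsOfSquares, level: float = 0.95) -> IntervalEstimate:
    """Approximate CI for ICC(A,1) (two-way random, absolute agreement).

    Uses the F-based construction with a Satterthwaite denominator df,
    with n = ac effective rows and k = bc effective columns so that the
    implied point estimate coincides with the variance-component plug-in;
    at c = 1 this is exactly the McGraw–Wong single-rater formula.
    """
    if ss.SSA + ss.SSB + ss.SSE == 0:
        raise ZeroDivisionError("zero total variance; ICC undefined")
    r = icc_a1(
        VarianceComponents(
            sigma2_A=(ss.MSA - ss.MSE) / (ss.b * ss.c),
            sigma2_B=(ss.MSB - ss.MSE) / (ss.a * ss.c),
            sigma2_E=ss.MSE,
            a=ss.a,
            b=ss.b,
            c=ss.c,
        )
    )
    alpha = 1.0 - level
    n, k = ss.a * ss.c, ss.b * ss.c
    MSR, MSC, MSE = ss.MSA, ss.MSB, ss.MSE

    if r >= 1.0:  # zero observer and residual variance: degenerate perfect agreement
        return IntervalEstimate(
            point=1.0, lower=1.0, upper=1.0, level=level, method="mcgraw_wong"
        )

    av = k * r / (n * (1.0 - r))
    bv = 1.0 + k * r * (n - 1) / (n * (1.0 - r))
    num = (av * MSC + bv * MSE) ** 2
    den = (av * MSC) ** 2 / ss.nu_B + (bv * MSE) ** 2 / ss.nu_E
    if den == 0 or not math.isfinite(num / den):
        return IntervalEstimate(
            point=r,
            lower=math.nan,
            upper=math.nan,
            level=level,
            method="mcgraw_wong",
            flags=frozenset({UNDEFINED}),
        )
    v = num / den
    F_L = stats.f.ppf(1 - alpha / 2, ss.nu_A, v)
    F_U = stats.f.ppf(1 - alpha / 2, v, ss.nu_A)
    mix = k * MSC + (k * n - k - n) * MSE
    lower = n * (MSR - F_L * MSE) / (F_L * mix + n * MSR)
    upper = n * (F_U * MSR - MSE) / (mix + n * F_U * MSR)
    flags = set()
    if r < 0:
        flags.add(NEGATIVE_COMPONENT)
        lower, upper = min(lower, r), max(upper, r)
    return IntervalEstimate(
        point=r,
        lower=lower,
        upper=upper,
        level=level,
        method="mcgraw_wong",
        flags=frozenset(flags),
    )
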