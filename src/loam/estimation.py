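"""ANOVA estimation for the two-way random effects agreement model.

The model for a measurement by observer j on subject i (replicate k) is

    Y_ijk = mu + A_i + B_j + E_ijk,

with independent zero-mean Gaussian subject effects A_i ~ N(0, sigma_A^2),
observer effects B_j ~ N(0, sigma_B^2) and residuals E_ijk ~ N(0, sigma_E^2).
The difference between a single measurement and its subject mean,
D_ijk = Y_ijk - Ybar_i.., is N(0, ((b-1)/b) sigma_B^2 + ((bc-1)/(bc)) sigma_E^2),
and the 95% limits of agreement with the mean (LOAM) are the +/- z quantile
band of that distribution.  All estimators here are the closed-form ANOVA
(method-of-moments) ones; no iterative model fitting is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import AgreementData

__all__ = [
    "SumsOfSquares",
    "VarianceComponents",
    "sums_of_squares",
    "sums_of_squares_array",
    "variance_components",
    "loam_estimate",
    "loam_population",
    "jones_loam",
    "icc_a1",
    "z_multiplier",
]

#: Conventional 95% normal multiplier, used verbatim for level=0.95.
Z_95 = 1.96


def z_multiplier(level: float = 0.95) -> float:
    """Normal quantile z_{1-alpha/2}; the literal 1.96 at the default 95%.

    The published formulas carry 1.96 throughout; the exact quantile
    1.95996... differs only in the sixth significant digit, but we keep
    the literal so that default results match the printed tables bit for
    bit, while other levels get the exact quantile.
    """
    if level == 0.95:
        return Z_95
    from scipy import stats

    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2))


@dataclass(frozen=True)
class SumsOfSquares:
    """Two-way balanced ANOVA decomposition with degrees of freedom.

    SSA/SSB/SSE are the subject, observer and residual sums of squares;
    nu_A = a-1, nu_B = b-1, nu_E = abc-a-b+1; N = abc.
    """

    SSA: float
    SSB: float
    SSE: float
    a: int
    b: int
    c: int

    @property
    def nu_A(self) -> int:
        return self.a - 1

    @property
    def nu_B(self) -> int:
        return self.b - 1

    @property
    def nu_E(self) -> int:
        return self.a * self.b * self.c - self.a - self.b + 1

    @property
    def N(self) -> int:
        return self.a * self.b * self.c

    @property
    def MSA(self) -> float:
        return self.SSA / self.nu_A

    @property
    def MSB(self) -> float:
        return self.SSB / self.nu_B

    @property
    def MSE(self) -> float:
        return self.SSE / self.nu_E


@dataclass(frozen=True)
class VarianceComponents:
    """ANOVA variance-component estimates; sigma2_A / sigma2_B may be negative.

    A negative estimate signals either sampling variation of the unbiased
    moment estimators or genuine negative correlation (model misfit); it is
    reported as-is — truncating at zero would bias downstream quantities.
    """

    sigma2_A: float
    sigma2_B: float
    sigma2_E: float
    a: int
    b: int
    c: int

    @property
    def negative_A(self) -> bool:
        return self.sigma2_A < 0

    @property
    def negative_B(self) -> bool:
        return self.sigma2_B < 0

    @property
    def sigma_A(self) -> float:
        """sqrt of sigma2_A; NaN when the component estimate is negative."""
        return math.sqrt(self.sigma2_A) if self.sigma2_A >= 0 else math.nan

    @property
    def sigma_B(self) -> float:
        return math.sqrt(self.sigma2_B) if self.sigma2_B >= 0 else math.nan

    @property
    def sigma_E(self) -> float:
        return math.sqrt(self.sigma2_E)


def sums_of_squares_array(values: np.ndarray) -> SumsOfSquares:
    """ANOVA decomposition of an (a, b, c) or (a, b) measurement array.

    SSA = bc * sum_i (ybar_i.. - ybar...)^2
    SSB = ac * sum_j (ybar_.j. - ybar...)^2
    SSE = sum_ijk (y_ijk - ybar_i.. - ybar_.j. + ybar...)^2

    The residual definition is cross-checked against total SS - SSA - SSB;
    disagreement beyond floating tolerance raises (it would indicate a
    broken decomposition, not bad data).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim == 2:
        y = y[:, :, None]
    a, b, c = y.shape
    gm = y.mean()
    yi = y.mean(axis=(1, 2))
    yj = y.mean(axis=(0, 2))
    SSA = b * c * float(np.sum((yi - gm) ** 2))
    SSB = a * c * float(np.sum((yj - gm) ** 2))
    resid = y - yi[:, None, None] - yj[None, :, None] + gm
    SSE = float(np.sum(resid**2))
    total = float(np.sum((y - gm) ** 2))
    if not math.isclose(SSA + SSB + SSE, total, rel_tol=1e-9, abs_tol=1e-9 * max(total, 1.0)):
        raise AssertionError("ANOVA decomposition failed to reproduce the total sum of squares")
    return SumsOfSquares(SSA=SSA, SSB=SSB, SSE=SSE, a=a, b=b, c=c)


def sums_of_squares(data: AgreementData) -> SumsOfSquares:
    """ANOVA decomposition of a balanced agreement dataset."""
    return sums_of_squares_array(data.values)


def variance_components(ss: SumsOfSquares) -> VarianceComponents:
    """Unbiased ANOVA estimates of (sigma_A^2, sigma_B^2, sigma_E^2).

    sigma2_E = MSE, sigma2_B = (MSB - MSE)/(ac), sigma2_A = (MSA - MSE)/(bc).
    Negative subject/observer components are returned signed, never clipped.
    """
    return VarianceComponents(
        sigma2_A=(ss.MSA - ss.MSE) / (ss.b * ss.c),
        sigma2_B=(ss.MSB - ss.MSE) / (ss.a * ss.c),
        sigma2_E=ss.MSE,
        a=ss.a,
        b=ss.b,
        c=ss.c,
    )


def loam_estimate(ss: SumsOfSquares, z: float = Z_95) -> float:
    """Plug-in estimate of the upper LOAM: z * sqrt((SSB + SSE) / N).

    Identical in form for single (c=1) and replicated (c>1) designs.  The
    lower LOAM is the negation.
    """
    return z * math.sqrt((ss.SSB + ss.SSE) / ss.N)


def loam_population(
    sigma2_B: float, sigma2_E: float, b: int, c: int = 1, z: float = Z_95
) -> float:
    """Population upper LOAM: z * sqrt(((b-1)/b) sigma_B^2 + ((bc-1)/(bc)) sigma_E^2).

    Takes true (nonnegative) variances, e.g. in simulation studies; at c=1
    it reduces to z * sqrt(((b-1)/b)(sigma_B^2 + sigma_E^2)).
    """
    if sigma2_B < 0 or sigma2_E < 0:
        raise ValueError("population variances must be nonnegative")
    if b < 2:
        raise ValueError("need at least b=2 observers")
    return z * math.sqrt((b - 1) / b * sigma2_B + (b * c - 1) / (b * c) * sigma2_E)


def jones_loam(ss: SumsOfSquares, z: float = Z_95) -> float:
    """Jones et al.'s fixed-effects limit z * sigma_E_hat = z * sqrt(SSE / nu_E).

    Measures only residual variation after removing subject and observer
    effects, so it understates disagreement whenever observers differ
    systematically; provided for comparison.
    """
    return z * math.sqrt(ss.SSE / ss.nu_E)


def icc_a1(vc: VarianceComponents) -> float:
    """Plug-in ICC(A,1) = sigma2_A / (sigma2_A + sigma2_B + sigma2_E).

    Absolute-agreement intraclass correlation of single measurements under
    the two-way random model.  With negative component estimates the value
    can fall outside [0, 1]; it is returned as computed (callers can check
    the component flags).
    """
    denom = vc.sigma2_A + vc.sigma2_B + vc.sigma2_E
    if denom == 0:
        raise ZeroDivisionError("total variance estimate is zero; ICC undefined")
    return vc.sigma2_A / denom
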