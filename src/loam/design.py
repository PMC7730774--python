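"""Sample-size planning: how many observers for a target LOAM CI width.

The Graybill–Wang CI width is driven by the multipliers l_x, h_x, which
shrink only as the observer count b grows — adding subjects alone cannot
make the LOAM CI arbitrarily narrow.  Planning therefore fixes the number
of subjects ``a`` (and replicates ``c``) and solves for the smallest b
whose *expected* CI width, evaluated at pilot variance estimates, is at
most the target W.

The expected width uses the exact substitution SSE = nu_E * sigma2_E0 and
SSB = nu_B * (a c sigma2_B0 + sigma2_E0) (the expected sums of squares
under the model), so evaluating it at a dataset's own fitted variances and
dimensions reproduces that dataset's CI width identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .estimation import SumsOfSquares, z_multiplier
from .intervals import loam_ci

__all__ = ["PilotEstimates", "expected_ci_width", "required_observers", "implied_sums_of_squares"]


@dataclass(frozen=True)
class PilotEstimates:
    """Pilot-study variance estimates and the planned design dimensions.

    sigma2_B0 / sigma2_E0 are initial estimates of the inter-observer and
    residual variances (squared measurement units); ``a`` subjects and
    ``c`` replicates per cell are fixed by the planned study.
    """

    sigma2_B0: float
    sigma2_E0: float
    a: int
    c: int = 1

    def __post_init__(self):
        if self.sigma2_B0 < 0 or self.sigma2_E0 < 0:
            raise ValueError("pilot variances must be nonnegative")
        if self.sigma2_B0 == 0 and self.sigma2_E0 == 0:
            raise ValueError("at least one pilot variance must be positive")
        if self.a < 2 or self.c < 1:
            raise ValueError("need a >= 2 subjects and c >= 1 replicates")


def implied_sums_of_squares(pilot: PilotEstimates, b: int) -> SumsOfSquares:
    """Expected sums of squares at the pilot variances for ``b`` observers.

    E[SSB] = nu_B * (a c sigma2_B0 + sigma2_E0), E[SSE] = nu_E * sigma2_E0,
    with nu_E = abc - a - b + 1 (SSA does not enter the LOAM CI and is set
    to zero).
    """
    a, c = pilot.a, pilot.c
    nu_B = b - 1
    nu_E = a * b * c - a - b + 1
    return SumsOfSquares(
        SSA=0.0,
        SSB=nu_B * (a * c * pilot.sigma2_B0 + pilot.sigma2_E0),
        SSE=nu_E * pilot.sigma2_E0,
        a=a,
        b=b,
        c=c,
    )


def expected_ci_width(
    pilot: PilotEstimates, b: int, level: float = 0.95, loam_level: float = 0.95
) -> float:
    """Expected width of the upper-LOAM CI with ``b`` observers.

    Evaluates the Graybill–Wang interval at the expected sums of squares,
    with nu_B, nu_E and the (l, h) multipliers recomputed for this b.
    """
    if b < 2:
        raise ValueError("need at least b=2 observers")
    ci = loam_ci(implied_sums_of_squares(pilot, b), level=level, loam_level=loam_level)
    return ci.width


def required_observers(
    pilot: PilotEstimates,
    W: float,
    level: float = 0.95,
    loam_level: float = 0.95,
    b_max: int = 1000,
) -> int:
    """Smallest observer count b >= 2 with expected CI width <= W.

    Scans b upward (widths are cheap to evaluate and the scan is robust to
    any local wobble at tiny b).  Raises if even ``b_max`` observers leave
    the expected width above W, reporting the width reached.
    """
    if W <= 0:
        raise ValueError("target width W must be positive")
    width = math.inf
    for b in range(2, b_max + 1):
        width = expected_ci_width(pilot, b, level=level, loam_level=loam_level)
        if width <= W:
            return b
    raise ValueError(
        f"no b <= {b_max} achieves width {W}; width at b={b_max} is {width:.6g}"
    )
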