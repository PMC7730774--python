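"""Simulation under the two-way random effects model and CI coverage studies.

``simulate_dataset`` draws Y_ijk = mu + A_i + B_j + E_ijk with independent
zero-mean Gaussian effects, i.e. exactly the model the estimators assume;
``coverage_study`` repeats simulate -> estimate -> interval and counts how
often the interval covers the true parameter, the standard way to validate
an approximate CI's stated confidence level.

A single root seed is expanded into independent per-replicate streams via
numpy's SeedSequence spawning, so a study is bit-reproducible and the
replicates are statistically independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import AgreementData
from .estimation import (
    loam_population,
    sums_of_squares_array,
    variance_components,
    z_multiplier,
)
from .intervals import (
    IntervalEstimate,
    icc_ci,
    loam_ci,
    sigma_A_ci,
    sigma_B_ci,
    sigma_E_ci,
)

__all__ = ["SimulationSpec", "CoverageResult", "simulate_dataset", "simulate_values", "coverage_study"]

_TARGETS = ("loam", "sigma_A", "sigma_B", "sigma_E", "icc")


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated balanced agreement study.

    ``sigma_A``, ``sigma_B``, ``sigma_E`` are standard deviations (not
    variances) of the subject, observer and residual effects.
    """

    mu: float = 0.0
    sigma_A: float = 1.0
    sigma_B: float = 0.5
    sigma_E: float = 0.5
    a: int = 40
    b: int = 10
    c: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.sigma_A, self.sigma_B, self.sigma_E) < 0:
            raise ValueError("effect standard deviations must be nonnegative")
        if self.a < 2 or self.b < 2 or self.c < 1:
            raise ValueError(f"invalid dimensions a={self.a}, b={self.b}, c={self.c}")

    def true_value(self, target: str, loam_level: float = 0.95) -> float:
        """True parameter value the corresponding CI should cover."""
        if target == "loam":
            return loam_population(
                self.sigma_B**2, self.sigma_E**2, self.b, self.c,
                z=z_multiplier(loam_level),
            )
        if target == "sigma_A":
            return self.sigma_A
        if target == "sigma_B":
            return self.sigma_B
        if target == "sigma_E":
            return self.sigma_E
        if target == "icc":
            tot = self.sigma_A**2 + self.sigma_B**2 + self.sigma_E**2
            return self.sigma_A**2 / tot
        raise ValueError(f"unknown target {target!r}; choose from {_TARGETS}")


@dataclass(frozen=True)
class CoverageResult:
    """Aggregated outcome of a coverage study for one estimator."""

    target: str
    true_value: float
    n_reps: int
    n_covered: int
    n_excluded: int  # replicates with an undefined-flagged interval
    mean_width: float

    @property
    def n_effective(self) -> int:
        return self.n_reps - self.n_excluded

    @property
    def empirical_coverage(self) -> float:
        return self.n_covered / self.n_effective

    @property
    def exclusion_rate(self) -> float:
        return self.n_excluded / self.n_reps

    @property
    def mc_standard_error(self) -> float:
        p = self.empirical_coverage
        return math.sqrt(p * (1 - p) / self.n_effective)


def simulate_values(spec: SimulationSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw one (a, b, c) measurement array from the model using ``rng``."""
    A = rng.normal(0.0, spec.sigma_A, size=spec.a)
    B = rng.normal(0.0, spec.sigma_B, size=spec.b)
    E = rng.normal(0.0, spec.sigma_E, size=(spec.a, spec.b, spec.c))
    return spec.mu + A[:, None, None] + B[None, :, None] + E


def simulate_dataset(spec: SimulationSpec) -> AgreementData:
    """Draw one balanced dataset; the same spec (and seed) gives the same data."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return AgreementData(simulate_values(spec, rng))


def _interval_for(target: str, values: np.ndarray, level: float, loam_level: float) -> IntervalEstimate:
    ss = sums_of_squares_array(values)
    if target == "loam":
        return loam_ci(ss, level=level, loam_level=loam_level)
    if target == "sigma_E":
        return sigma_E_ci(ss, level=level)
    if target == "sigma_B":
        return sigma_B_ci(variance_components(ss), ss, level=level)
    if target == "sigma_A":
        return sigma_A_ci(variance_components(ss), ss, level=level)
    if target == "icc":
        return icc_ci(ss, level=level)
    raise ValueError(f"unknown target {target!r}; choose from {_TARGETS}")


def coverage_study(
    spec: SimulationSpec,
    n_reps: int,
    target: str = "loam",
    level: float = 0.95,
    loam_level: float = 0.95,
) -> CoverageResult:
    """Empirical coverage of one estimator's CI under repeated simulation.

    For each of ``n_reps`` independent replicates: simulate a dataset from
    ``spec``, fit the ANOVA estimators, form the target's CI at
    ``level``, and test whether it covers the true value.  Replicates with
    an undefined-flagged interval (e.g. a nonpositive variance component
    for the delta-method CIs) are counted separately and excluded from the
    coverage denominator; their rate is reported on the result.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100 for a meaningful coverage estimate")
    truth = spec.true_value(target, loam_level=loam_level)
    covered = excluded = 0
    width_sum = 0.0
    streams = np.random.SeedSequence(spec.seed).spawn(n_reps)
    for child in streams:
        values = simulate_values(spec, np.random.default_rng(child))
        ci = _interval_for(target, values, level, loam_level)
        if "undefined" in ci.flags or not (math.isfinite(ci.lower) and math.isfinite(ci.upper)):
            excluded += 1
            continue
        covered += ci.covers(truth)
        width_sum += ci.width
    n_eff = n_reps - excluded
    return CoverageResult(
        target=target,
        true_value=truth,
        n_reps=n_reps,
        n_covered=covered,
        n_excluded=excluded,
        mean_width=width_sum / n_eff if n_eff else math.nan,
    )
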