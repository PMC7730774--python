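# Methods

## Model and target quantity

Measurements are assumed to follow the additive two-way random effects model

    Y_ijk = mu + A_i + B_j + E_ijk,    i = 1..a subjects, j = 1..b observers,
                                       k = 1..c replicates,

with independent zero-mean Gaussian subject effects (variance `sigma_A^2`),
observer effects (`sigma_B^2`) and residuals (`sigma_E^2`).  The model is
homoscedastic and crossed-balanced: every observer measures every subject
exactly `c` times, and replicates within a cell are exchangeable.  Imbalance
is a hard error, not a warning — every closed-form expression below relies
on it.

Agreement is summarised by the deviation of a single measurement from its
subject's all-observer mean, `D_ijk = Y_ijk - Ybar_i..`, which is
`N(0, ((b-1)/b) sigma_B^2 + ((bc-1)/(bc)) sigma_E^2)`.  The `100q%` LOAM are
the `+/- z_q` standard-deviation band of this distribution; with the
conventional `q = 0.95`, `z = 1.96`.  The multiplier is kept as the literal
1.96 at the 95% default (it differs from the exact quantile only in the
sixth significant digit) and is the exact normal quantile at any other
level.

## Estimation

All estimation is closed-form balanced two-way ANOVA (method of moments);
no REML or iterative fitting anywhere:

    SSA = bc * sum_i (ybar_i.. - ybar...)^2        nu_A = a - 1
    SSB = ac * sum_j (ybar_.j. - ybar...)^2        nu_B = b - 1
    SSE = sum_ijk (y_ijk - ybar_i.. - ybar_.j. + ybar...)^2
                                                   nu_E = abc - a - b + 1

    sigma2_E = MSE
    sigma2_B = (MSB - MSE) / (ac)
    sigma2_A = (MSA - MSE) / (bc)

    LOAM estimate = +/- z * sqrt((SSB + SSE) / N),   N = abc.

The residual sum of squares is computed from its defining formula and
cross-checked against `total SS - SSA - SSB` at every call; a mismatch
raises, since it could only come from a broken decomposition.  At `c = 1`
everything collapses to the single-measurement formulas
(`nu_E = (a-1)(b-1)` etc.); this reduction is asserted in tests.

The Jones-style comparison limit `+/- z * sqrt(SSE / nu_E)` (residual SD
from a fixed-effects two-way fit) is reported alongside: it excludes
inter-observer variation and therefore understates disagreement whenever
observers differ systematically.

Negative `sigma2_A` / `sigma2_B` estimates can arise from sampling
variation of the unbiased estimators or from genuinely negatively
correlated measurements (model misfit).  They are reported signed with a
flag and never truncated to zero: truncation would bias every downstream
quantity.  Reports carry an explicit warning instead.

## Confidence intervals

* **LOAM (Graybill–Wang).**  A CI for the linear combination
  `(SSB + SSE)/N` is built from per-component multipliers
  `l_x = 1 - 1/F_{1-alpha/2; nu_x, inf}` and
  `h_x = 1/F_{alpha/2; nu_x, inf} - 1` (`x` in `{B, E}`),
  `L = sqrt(l_B^2 SSB^2 + l_E^2 SSE^2)`, `H` analogously with `h`, giving

      ( z sqrt((SSB+SSE-L)/N),  z sqrt((SSB+SSE+H)/N) ).

  Since `0 < l_x < 1`, `L <= SSB + SSE` and the lower radicand is provably
  nonnegative (a `max(., 0)` guards the floating-point boundary case).
  F-quantiles with infinite denominator df are evaluated through the exact
  identity `F_{q; nu, inf} = chi2_{q; nu}/nu` rather than relying on a
  library's handling of `inf` df.  The CI for the lower LOAM is the
  negation of the endpoints.  Two levels are configurable independently:
  `loam_level` fixes the `z` inside the limits, `level` the confidence of
  the interval around them.

* **sigma_E.**  Exact chi-square pivot:
  `( sigma_E_hat sqrt(nu_E / chi2_{1-alpha/2; nu_E}),
     sigma_E_hat sqrt(nu_E / chi2_{alpha/2; nu_E}) )`.
  Its coverage is used as a self-calibration check in the test suite
  (10,000-replicate study, nominal within 3 Monte-Carlo SEs).

* **sigma_B, sigma_A.**  Delta method around the square-rooted component:

      sigma_B_hat +/- z/(ac sigma_B_hat) *
          sqrt((ac sigma2_B + sigma2_E)^2/(2 nu_B) + sigma2_E^2/(2 nu_E))

  and symmetrically for `sigma_A` with `bc` and `nu_A`.  Undefined (NaN
  bounds, flagged) when the component estimate is not strictly positive; a
  negative lower endpoint is reported as computed, with a warning, rather
  than clipped — the construction is a symmetric +/- interval.

* **ICC(A,1).**  Plug-in `sigma2_A / (sigma2_A + sigma2_B + sigma2_E)`,
  with the F-based absolute-agreement CI of McGraw & Wong (their Case 2A,
  single measurement): lower/upper bounds from
  `F_{1-alpha/2; nu_A, v}` and `F_{1-alpha/2; v, nu_A}` with a
  Satterthwaite denominator df `v`.  The source formula is stated for
  `c = 1`; for replicated designs we substitute `n -> ac`, `k -> bc` in its
  coefficient structure while keeping the ANOVA dfs `nu_A`, `nu_B`, `nu_E`.
  This choice (a) reduces exactly to the published formula at `c = 1` and
  (b) makes the implied point estimate coincide with the variance-component
  plug-in for every `c`; it is an interpolation of our own design, and the
  `c > 1` ICC interval should be read as approximate on top of an
  approximation.  At `c = 1` the implementation is cross-checked against
  pingouin's independent ICC routine in the tests.

## Sample-size planning

Only the number of observers `b` can drive the LOAM-CI width to zero (the
multipliers `l_x, h_x` shrink as the dfs grow with `b`; adding subjects
alone does not).  Planning fixes `a` and `c`, takes pilot variances
`sigma2_B0`, `sigma2_E0`, and evaluates the expected CI width at the
expected sums of squares

    E[SSB] = nu_B (ac sigma2_B0 + sigma2_E0),   E[SSE] = nu_E sigma2_E0,

with `nu_B`, `nu_E` and the multipliers recomputed per candidate `b`.  The
substitution is exact: evaluated at a dataset's own fitted variances and
dimensions it reproduces that dataset's CI width to machine precision
(asserted at 1e-9 in tests).  `required_observers` returns the smallest
integer `b >= 2` meeting the target width `W` — the actionable design
answer — found by linear scan to `b_max` (widths are cheap; a scan is
robust to any local wobble at tiny `b`).  `W` is the full two-sided width
of the upper-LOAM CI.  Infeasible targets raise, reporting the width at
`b_max`.

## Simulator and coverage harness

`simulate_dataset` draws exactly from the model above — the simulator's
defaults and the coverage-study conditions (a=40, b=10, c=1, sigma_A=1.5,
sigma_B=0.3, sigma_E=0.6, 2000 replications for the LOAM CI) match the
conditions under which the interval's coverage was originally validated.
A single root seed is expanded with numpy `SeedSequence.spawn` into
independent per-replicate streams, so studies are bit-reproducible and
parallelisable without result drift.

`coverage_study` repeats simulate → estimate → interval and counts coverage
of the truth (the population LOAM computed from the spec's variances, or
the spec's `sigma`/ICC directly).  Replicates whose interval is undefined —
e.g. the delta CI when `sigma2_B_hat <= 0`, common when the true `sigma_B`
is small and `b` is small — are excluded from the coverage denominator and
reported as an exclusion rate, never silently dropped.  Coverage for the
LOAM is assessed against the upper limit only; the lower is its negation.

What the simulator does *not* emulate: heteroscedasticity, non-Gaussian
effects, subject-by-observer interaction, and missing cells.  Passing
coverage tests therefore validate the inferential machinery under the
model's own assumptions, not robustness to their violation; on real data
the agreement plot and the exported residuals are the tools for judging
those assumptions.

## Numerical and interface choices

* Quantiles come from `scipy.stats` (`chi2`, `f`, `norm`); data I/O uses
  pandas with delimiter sniffing among comma/tab/semicolon, decimal point
  only.
* All internal values are full precision; rounding (1 decimal by default,
  matching how such tables are conventionally reported) happens only in the
  text report layer, which re-derives nothing.
* Replicate labels in input files are provenance only and never enter a
  formula; when absent, replicate indices are synthesized from order of
  appearance within each cell.  Duplicate (subject, observer, replicate)
  triples are an error — silent aggregation would change `c`.
* Test problem sizes: the coverage studies use 2000 replications (LOAM,
  a=40×b=10) and 10,000 replications (sigma_E exactness, a=10×b=4);
  parameter-recovery uses 2000 replicated designs at a=15, b=5, c=2.  At
  these sizes Monte-Carlo error (3 SEs ≈ 1.5 percentage points on a 95%
  coverage) is small enough to detect a materially mis-calibrated interval
  while keeping the whole suite in seconds.

## Known limitations

* Unbalanced designs are rejected outright; no imputation or unbalanced
  moment estimators are provided.
* Observers are strictly random effects; a fixed-observer reformulation of
  the limits is out of scope.
* No subject×observer interaction term (confounded with residual at c=1).
* The delta-method intervals can have negative lower endpoints and are
  undefined for nonpositive component estimates — both reported honestly
  rather than repaired; approximations improve with more observers.
* The `c > 1` ICC(A,1) interval rests on the substitution described above
  and has no published exact counterpart here.
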