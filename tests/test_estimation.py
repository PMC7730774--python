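import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loam import (
    AgreementData,
    icc_a1,
    jones_loam,
    loam_estimate,
    loam_population,
    sums_of_squares,
    variance_components,
    z_multiplier,
)
from loam.estimation import sums_of_squares_array

from conftest import random_balanced_values


def brute_force_ss(y):
    """Defining triple sums, evaluated with explicit loops (oracle)."""
    a, b, c = y.shape
    gm = y.mean()
    yi = [y[i].mean() for i in range(a)]
    yj = [y[:, j].mean() for j in range(b)]
    SSA = b * c * sum((yi[i] - gm) ** 2 for i in range(a))
    SSB = a * c * sum((yj[j] - gm) ** 2 for j in range(b))
    SSE = sum(
        (y[i, j, k] - yi[i] - yj[j] + gm) ** 2
        for i in range(a)
        for j in range(b)
        for k in range(c)
    )
    return SSA, SSB, SSE


class TestSumsOfSquares:
    def test_toy_values(self, toy_ss):
        assert toy_ss.SSA == pytest.approx(6.25, abs=1e-12)
        assert toy_ss.SSB == pytest.approx(2.25, abs=1e-12)
        assert toy_ss.SSE == pytest.approx(0.25, abs=1e-12)
        assert (toy_ss.nu_A, toy_ss.nu_B, toy_ss.nu_E, toy_ss.N) == (1, 1, 1, 4)

    def test_constant_data_gives_zero_everywhere(self):
        ss = sums_of_squares_array(np.full((4, 3, 2), 5.0))
        assert ss.SSA == ss.SSB == ss.SSE == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_loops(self, seed):
        rng = np.random.default_rng(seed)
        y = random_balanced_values(rng)
        ss = sums_of_squares_array(y)
        SSA, SSB, SSE = brute_force_ss(y)
        assert ss.SSA == pytest.approx(SSA, rel=1e-10)
        assert ss.SSB == pytest.approx(SSB, rel=1e-10)
        assert ss.SSE == pytest.approx(SSE, rel=1e-10, abs=1e-10)

    def test_matches_statsmodels_fixed_effects_anova(self):
        # independent route: OLS two-way fixed-effects fit, c=1
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        data = AgreementData(random_balanced_values(rng, a=6, b=4, c=1))
        long = data.to_frame()
        fit = smf.ols("value ~ C(subject) + C(observer)", data=long).fit()
        table = sm.stats.anova_lm(fit, typ=2)
        ss = sums_of_squares(data)
        assert ss.SSA == pytest.approx(table.loc["C(subject)", "sum_sq"], rel=1e-8)
        assert ss.SSB == pytest.approx(table.loc["C(observer)", "sum_sq"], rel=1e-8)
        assert ss.SSE == pytest.approx(table.loc["Residual", "sum_sq"], rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_decomposition_and_within_subject_identities(self, seed):
        rng = np.random.default_rng(100 + seed)
        y = random_balanced_values(rng)
        ss = sums_of_squares_array(y)
        total = np.sum((y - y.mean()) ** 2)
        assert ss.SSA + ss.SSB + ss.SSE == pytest.approx(total, rel=1e-10)
        within = np.sum((y - y.mean(axis=(1, 2), keepdims=True)) ** 2)
        assert ss.SSB + ss.SSE == pytest.approx(within, rel=1e-10)
        assert ss.nu_A + ss.nu_B + ss.nu_E == ss.N - 1


class TestVarianceComponents:
    def test_toy_values(self, toy_vc):
        assert toy_vc.sigma2_E == pytest.approx(0.25, abs=1e-12)
        assert toy_vc.sigma2_B == pytest.approx(1.0, abs=1e-12)
        assert toy_vc.sigma2_A == pytest.approx(3.0, abs=1e-12)
        assert not (toy_vc.negative_A or toy_vc.negative_B)

    def test_negative_component_flagged_not_truncated(self):
        # observers nearly identical, strong subject effect: MSB < MSE can occur
        rng = np.random.default_rng(5)
        for seed in range(50):
            y = np.random.default_rng(seed).normal(0, 1, size=(3, 3, 1))
            vc = variance_components(sums_of_squares_array(y))
            if vc.sigma2_B < 0:
                assert vc.negative_B
                assert np.isnan(vc.sigma_B)
                break
        else:
            pytest.fail("no negative observer component in 50 small datasets (unexpected)")

    def test_sigma_E_never_negative(self):
        for seed in range(20):
            y = np.random.default_rng(seed).normal(size=(3, 3, 2))
            vc = variance_components(sums_of_squares_array(y))
            assert vc.sigma2_E >= 0


class TestLoamEstimates:
    def test_toy_loam_and_jones(self, toy_ss):
        assert loam_estimate(toy_ss) == pytest.approx(1.96 * np.sqrt(2.5 / 4), abs=1e-12)
        assert jones_loam(toy_ss) == pytest.approx(0.98, abs=1e-12)

    def test_constant_data_gives_zero_limits(self):
        ss = sums_of_squares_array(np.full((3, 3, 1), 2.0))
        assert loam_estimate(ss) == 0.0
        assert jones_loam(ss) == 0.0

    def test_population_limit_closed_forms(self):
        assert loam_population(0.0, 0.0, b=5) == 0.0
        assert loam_population(0.25, 0.75, b=4, c=1) == pytest.approx(1.96 * np.sqrt(0.75), abs=1e-12)
        # replicated form: (b-1)/b on sigma_B^2, (bc-1)/(bc) on sigma_E^2
        got = loam_population(0.25, 0.75, b=4, c=3)
        assert got == pytest.approx(1.96 * np.sqrt(0.75 * 0.25 + (11 / 12) * 0.75), abs=1e-12)

    def test_population_limit_rejects_negative_variance(self):
        with pytest.raises(ValueError):
            loam_population(-0.1, 0.5, b=4)

    def test_population_limit_covers_95pct_of_differences(self):
        # Monte-Carlo: D_ijk = Y_ijk - Ybar_i.. should fall inside +/-LOAM ~95% of the time
        rng = np.random.default_rng(42)
        sB, sE, b, c = 0.6, 0.8, 6, 2
        lim = loam_population(sB**2, sE**2, b=b, c=c)
        n = 4000
        B = rng.normal(0, sB, size=(n, b, 1))
        E = rng.normal(0, sE, size=(n, b, c))
        y = B + E  # subject effect cancels in D and is omitted
        d = y - y.mean(axis=(1, 2), keepdims=True)
        frac = np.mean(np.abs(d) <= lim)
        assert frac == pytest.approx(0.95, abs=0.01)


class TestIcc:
    def test_toy_value(self, toy_vc):
        assert icc_a1(toy_vc) == pytest.approx(3.0 / 4.25, abs=1e-12)

    def test_perfect_agreement(self):
        from loam import VarianceComponents

        vc = VarianceComponents(sigma2_A=2.0, sigma2_B=0.0, sigma2_E=0.0, a=5, b=3, c=1)
        assert icc_a1(vc) == 1.0

    def test_zero_total_variance_raises(self):
        from loam import VarianceComponents

        vc = VarianceComponents(sigma2_A=0.0, sigma2_B=0.0, sigma2_E=0.0, a=5, b=3, c=1)
        with pytest.raises(ZeroDivisionError):
            icc_a1(vc)


class TestInvarianceProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 20, allow_nan=False),
    )
    def test_translation_and_scale_equivariance(self, seed, shift, scale):
        y = random_balanced_values(np.random.default_rng(seed))
        ss0 = sums_of_squares_array(y)
        ss_shift = sums_of_squares_array(y + shift)
        for attr in ("SSA", "SSB", "SSE"):
            assert getattr(ss_shift, attr) == pytest.approx(getattr(ss0, attr), rel=1e-6, abs=1e-6)
        ss_scale = sums_of_squares_array(y * scale)
        assert loam_estimate(ss_scale) == pytest.approx(scale * loam_estimate(ss0), rel=1e-7)
        assert jones_loam(ss_scale) == pytest.approx(scale * jones_loam(ss0), rel=1e-7)
        vc0, vcs = variance_components(ss0), variance_components(ss_scale)
        if vc0.sigma2_A + vc0.sigma2_B + vc0.sigma2_E != 0:
            assert icc_a1(vcs) == pytest.approx(icc_a1(vc0), rel=1e-6, abs=1e-9)

    def test_c1_replicated_formulas_reduce_to_single_measurement(self):
        # nu_E = abc - a - b + 1 collapses to (a-1)(b-1); estimators coincide
        rng = np.random.default_rng(8)
        y2d = random_balanced_values(rng, a=7, b=4, c=1)
        ss3 = sums_of_squares_array(y2d)           # (a, b, 1)
        ss2 = sums_of_squares_array(y2d[:, :, 0])  # (a, b)
        assert ss3.nu_E == (ss3.a - 1) * (ss3.b - 1)
        for attr in ("SSA", "SSB", "SSE", "nu_A", "nu_B", "nu_E", "N"):
            assert getattr(ss3, attr) == getattr(ss2, attr)
        vc3, vc2 = variance_components(ss3), variance_components(ss2)
        assert (vc3.sigma2_A, vc3.sigma2_B, vc3.sigma2_E) == (vc2.sigma2_A, vc2.sigma2_B, vc2.sigma2_E)


def test_z_multiplier_literal_at_95_exact_elsewhere():
    from scipy import stats

    assert z_multiplier(0.95) == 1.96
    assert z_multiplier(0.90) == pytest.approx(stats.norm.ppf(0.95), abs=1e-12)
    with pytest.raises(ValueError):
        z_multiplier(1.5)
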