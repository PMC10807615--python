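"""Univariable estimators: oracle equivalence, equivariances, calibration."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import assume, given, settings, strategies as st
from scipy import stats

from mrkit import (
    TwoSampleMR,
    cochran_q,
    egger,
    ivw,
    wald_ratios,
    weighted_median,
)
from mrkit.exceptions import DegenerateInstrumentError, InsufficientInstrumentsError

from conftest import make_harmonised, random_harmonised


def wm_oracle(ratios, weights):
    """Exhaustive interpolation oracle for the weighted median: walk every
    adjacent pair of midpoint cumulative weights and interpolate at 1/2."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios, float)[order], np.asarray(weights, float)[order]
    total = w.sum()
    mids = []
    acc = 0.0
    for wi in w:
        mids.append((acc + wi / 2) / total)
        acc += wi
    if 0.5 <= mids[0]:
        return r[0]
    for j in range(len(r) - 1):
        if mids[j] <= 0.5 <= mids[j + 1]:
            t = (0.5 - mids[j]) / (mids[j + 1] - mids[j])
            return r[j] + t * (r[j + 1] - r[j])
    return r[-1]


class TestWaldRatios:
    def test_direct_division(self):
        h = make_harmonised([0.1], [0.01], [0.05], [0.02])
        ratio, se = wald_ratios(h)
        assert ratio[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        h = make_harmonised([0.1], [0.01], [0.0], [0.02])
        assert wald_ratios(h)[0][0] == 0.0

    def test_zero_exposure_effect_names_snp(self):
        h = make_harmonised([0.1, 0.0], [0.01, 0.01], [0.0, 0.0], [0.1, 0.1],
                            rsid=["rs_ok", "rs_bad"])
        with pytest.raises(DegenerateInstrumentError, match="rs_bad"):
            wald_ratios(h)

    def test_single_snp_ivw_equals_ratio(self, rng):
        h = random_harmonised(rng, k=5)
        ratios, _ = wald_ratios(h)
        for j in range(5):
            est, q = ivw(h.subset([j]))
            assert est.beta == pytest.approx(ratios[j])
            assert est.method == "wald" and q is None


class TestIVW:
    def test_symmetric_average(self):
        h = make_harmonised([1.0, 1.0], [0.01, 0.01], [0.4, 0.6], [0.1, 0.1])
        est, q = ivw(h, model="fixed")
        assert est.beta == pytest.approx(0.5)
        # Q by hand: w = 100 each; 100*(0.4-0.5)^2 + 100*(0.6-0.5)^2 = 2
        assert q.Q == pytest.approx(2.0)
        assert q.df == 1

    def test_matches_wls_oracle(self, rng):
        """Dual route: explicit-sum IVW vs statsmodels WLS through origin."""
        for _ in range(50):
            h = random_harmonised(rng, k=int(rng.integers(2, 30)))
            est, _ = ivw(h, model="fixed")
            fit = sm.WLS(h.beta_out, h.beta_exp, weights=1 / h.se_out**2).fit()
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_random_effects_inflates_se_only(self, rng):
        h = random_harmonised(rng, k=20)
        fixed, qf = ivw(h, model="fixed")
        rand, qr = ivw(h, model="random")
        assert rand.beta == fixed.beta
        assert qr.Q == qf.Q
        expected = max(1.0, np.sqrt(qf.Q / qf.df))
        assert rand.se == pytest.approx(fixed.se * expected)

    def test_auto_switches_on_heterogeneity(self):
        calm = make_harmonised([1, 1, 1], [0.01] * 3, [0.50, 0.51, 0.49], [0.5] * 3)
        wild = make_harmonised([1, 1, 1], [0.01] * 3, [0.0, 2.0, 4.0], [0.1] * 3)
        assert ivw(calm, model="auto")[0].method == "ivw_fixed"
        assert ivw(wild, model="auto")[0].method == "ivw_random"

    def test_sign_and_scale_equivariance(self, rng):
        h = random_harmonised(rng, k=12)
        est, _ = ivw(h, model="fixed")
        neg = make_harmonised(h.beta_exp, h.se_exp, -h.beta_out, h.se_out)
        est_neg, _ = ivw(neg, model="fixed")
        assert est_neg.beta == pytest.approx(-est.beta)
        assert est_neg.se == pytest.approx(est.se)
        c = 3.7
        scaled = make_harmonised(c * h.beta_exp, c * h.se_exp, h.beta_out, h.se_out)
        est_sc, _ = ivw(scaled, model="fixed")
        assert est_sc.beta == pytest.approx(est.beta / c)


class TestEgger:
    def test_exact_line_recovered(self):
        x = np.array([0.05, 0.10, 0.15, 0.20])
        h = make_harmonised(x, [0.01] * 4, 0.02 + 0.5 * x, [0.1] * 4)
        res = egger(h)
        assert res.intercept_estimate == pytest.approx(0.02, abs=1e-12)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-12)
        assert res.dispersion == 1.0  # RSS 0 floors the overdispersion

    def test_matches_wls_oracle(self, rng):
        for _ in range(50):
            h = random_harmonised(rng, k=int(rng.integers(3, 30)))
            res = egger(h)
            flip = np.sign(h.beta_exp)
            X = sm.add_constant(h.beta_exp * flip)
            fit = sm.WLS(h.beta_out * flip, X, weights=1 / h.se_out**2).fit()
            assert res.intercept_estimate == pytest.approx(fit.params[0], rel=1e-10, abs=1e-12)
            assert res.slope.beta == pytest.approx(fit.params[1], rel=1e-10)

    def test_requires_three_snps(self):
        h = make_harmonised([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)

    def test_orientation_invariance(self, rng):
        """Flipping the recorded allele of any SNP (negating both betas)
        leaves the Egger fit unchanged."""
        h = random_harmonised(rng, k=10)
        flip = rng.choice([-1.0, 1.0], 10)
        h2 = make_harmonised(h.beta_exp * flip, h.se_exp, h.beta_out * flip, h.se_out)
        a, b = egger(h), egger(h2)
        assert a.slope.beta == pytest.approx(b.slope.beta)
        assert a.intercept_estimate == pytest.approx(b.intercept_estimate)

    def test_directional_pleiotropy_slope_beats_ivw(self):
        """With InSIDE holding and directional pleiotropy (a non-zero mean
        direct effect relative to the exposure-increasing allele), the
        Egger slope is less biased than IVW in mean absolute error."""
        rng = np.random.default_rng(77)
        theta, k = 0.2, 150
        ivw_err, egger_err = [], []
        for _ in range(60):
            gamma = np.abs(rng.normal(0.02, 0.01, k)) + 0.005
            alpha = (rng.random(k) < 0.5) * rng.normal(0.002, 0.002, k)
            sx, sy = np.full(k, 0.002), np.full(k, 0.004)
            h = make_harmonised(
                rng.normal(gamma, sx), sx,
                rng.normal(theta * gamma + alpha, sy), sy,
            )
            ivw_err.append(ivw(h, model="fixed")[0].beta - theta)
            egger_err.append(egger(h).slope.beta - theta)
        assert abs(np.mean(egger_err)) < abs(np.mean(ivw_err))

    def test_balanced_pleiotropy_intercept_calibrated(self):
        """Balanced direct effects (zero mean): the intercept test rejects at
        roughly its nominal 5% rate and the slope stays near the truth."""
        rng = np.random.default_rng(3)
        theta, k, reps = 0.2, 100, 200
        rejections, slopes = 0, []
        for _ in range(reps):
            gamma = np.abs(rng.normal(0.02, 0.01, k)) + 0.005
            alpha = rng.normal(0.0, 0.003, k)  # mean zero, InSIDE holds
            sx, sy = np.full(k, 0.002), np.full(k, 0.004)
            h = make_harmonised(
                rng.normal(gamma, sx), sx,
                rng.normal(theta * gamma + alpha, sy), sy,
            )
            res = egger(h)
            rejections += res.intercept_pval <= 0.05
            slopes.append(res.slope.beta)
        # 3 binomial SDs around 5% at 200 replicates
        assert abs(rejections / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)
        assert np.mean(slopes) == pytest.approx(theta, abs=0.02)


class TestWeightedMedian:
    def test_symmetric_median(self):
        h = make_harmonised([1, 1, 1], [0.01] * 3, [1.0, 2.0, 3.0], [1.0] * 3)
        assert weighted_median(h, n_boot=0).beta == pytest.approx(2.0)

    def test_degenerate_spread(self):
        h = make_harmonised([1, 1, 1], [1e-6] * 3, [0.7, 0.7, 0.7], [1e-6] * 3)
        est = weighted_median(h, n_boot=200, seed=7)
        assert est.beta == pytest.approx(0.7)
        assert est.se < 1e-4  # bootstrap spread vanishes with the input SEs

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(3, 25))
            h = random_harmonised(rng, k=k)
            ratios, ses = wald_ratios(h)
            expected = wm_oracle(ratios, 1 / ses**2)
            assert weighted_median(h, n_boot=0).beta == pytest.approx(expected, rel=1e-12)

    def test_bootstrap_reproducible(self, rng):
        h = random_harmonised(rng, k=10)
        a = weighted_median(h, n_boot=100, seed=5)
        b = weighted_median(h, n_boot=100, seed=5)
        assert a.se == b.se

    def test_robust_to_minority_contamination(self):
        """30% of SNPs get a large common pleiotropic offset: the median
        stays close to the truth, IVW does not (low-noise regime)."""
        rng = np.random.default_rng(2024)
        theta, k = 0.2, 60
        bx = rng.uniform(0.05, 0.15, k)
        sy = np.full(k, 0.001)
        by = theta * bx + rng.normal(0, sy)
        by[:18] += 1.0 * bx[:18]  # ratio-scale offset of +1 on 30% of SNPs
        h = make_harmonised(bx, np.full(k, 1e-4), by, sy)
        wm = weighted_median(h, n_boot=0).beta
        est, _ = ivw(h, model="fixed")
        assert abs(wm - theta) < 0.02
        assert abs(est.beta - theta) > 0.1


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        q = cochran_q([0.5, 0.5, 0.5], [0.1, 0.1, 0.1])
        assert q.Q == 0.0 and q.I2 == 0.0
        assert q.pval == pytest.approx(1.0)

    def test_hand_computation(self):
        q = cochran_q([0.0, 2.0], [1.0, 1.0])
        assert q.Q == pytest.approx(2.0)
        assert q.df == 1
        assert q.pval == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_i2_definition(self):
        q = cochran_q([0.0, 1.0, 2.0, 3.0], [0.5] * 4)
        assert q.I2 == pytest.approx(max(0, (q.Q - q.df) / q.Q) * 100)

    def test_requires_two(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q([0.5], [0.1])


@settings(max_examples=150, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(0.02, 0.5),     # beta_exp
            st.floats(0.001, 0.05),   # se_exp
            st.floats(-0.3, 0.3),     # beta_out
            st.floats(0.001, 0.1),    # se_out
        ),
        min_size=3,
        max_size=40,
    )
)
def test_estimators_match_oracles_property(data):
    """On arbitrary instances, IVW equals the origin-constrained WLS
    solution, Egger the intercept WLS solution, and the weighted median
    the exhaustive interpolation oracle."""
    arr = np.array(data)
    assume(np.ptp(arr[:, 0]) > 1e-6)  # Egger needs exposure-effect variation
    h = make_harmonised(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
    w = 1 / h.se_out**2

    est, _ = ivw(h, model="fixed")
    slope = np.sum(w * h.beta_exp * h.beta_out) / np.sum(w * h.beta_exp**2)
    assert est.beta == pytest.approx(slope, rel=1e-10, abs=1e-12)

    res = egger(h)
    X = np.column_stack([np.ones(h.k), h.beta_exp])
    coef = np.linalg.lstsq(X * np.sqrt(w)[:, None], h.beta_out * np.sqrt(w), rcond=None)[0]
    assert res.intercept_estimate == pytest.approx(coef[0], rel=1e-8, abs=1e-10)
    assert res.slope.beta == pytest.approx(coef[1], rel=1e-8, abs=1e-10)

    ratios, ses = wald_ratios(h)
    assert weighted_median(h, n_boot=0).beta == pytest.approx(
        wm_oracle(ratios, 1 / ses**2), rel=1e-12
    )


def test_model_object_dispatch(sim_harmonised):
    model = TwoSampleMR(sim_harmonised)
    est = model.fit()
    assert est.method in ("ivw_fixed", "ivw_random")
    assert est.heterogeneity is not None
    assert "OR per SD" in est.summary()
    df = model.fit_all(n_boot=50, presso_n_sim=100, seed=1)
    assert set(df["method"]) == {
        est.method, "egger_slope", "weighted_median", "presso_corrected"
    }
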