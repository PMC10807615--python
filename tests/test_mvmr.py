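"""Multivariable MR: set construction, estimation, conditional strength."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mrkit import MultivariableMR, build_mv_set, conditional_f, ivw, mvmr_ivw
from mrkit.exceptions import CollinearityError, UnderIdentifiedError, ValidationError
from mrkit.instruments import LDMatrix
from mrkit.mvmr import MVHarmonisedSet
from mrkit.synthetic import SimConfig, two_exposure_pair

from conftest import make_harmonised, make_table


def snp(rsid, pval, beta=0.1, se=0.01):
    return dict(rsid=rsid, effect_allele="A", other_allele="G", eaf=0.3,
                beta=beta, se=se, pval=pval)


def mv_set(beta_exp, se_exp, beta_out, se_out, labels=None):
    beta_exp = np.atleast_2d(np.asarray(beta_exp, float))
    k, L = beta_exp.shape
    return MVHarmonisedSet(
        outcome_label="y",
        exposure_labels=labels or [f"x{i}" for i in range(L)],
        rsid=np.array([f"rs{i}" for i in range(k)]),
        beta_exp=beta_exp,
        se_exp=np.asarray(se_exp, float),
        beta_out=np.asarray(beta_out, float),
        se_out=np.asarray(se_out, float),
    )


class TestBuildSet:
    def test_disjoint_instruments_union(self):
        e1 = make_table([snp("rs1", 1e-9), snp("rs2", 1e-9), snp("rs3", 0.5)], label="a")
        e2 = make_table([snp("rs1", 0.5), snp("rs2", 0.4), snp("rs3", 1e-9)], label="b")
        out = make_table([snp(f"rs{i}", 0.5) for i in (1, 2, 3)], label="y")
        m = build_mv_set([e1, e2], out)
        assert m.k == 3 and m.L == 2

    def test_shared_instrument_appears_once(self):
        rows = [snp("rs1", 1e-9), snp("rs2", 1e-9), snp("rs3", 1e-9), snp("rs4", 1e-9)]
        e1 = make_table(rows, label="a")
        e2 = make_table(rows, label="b")
        out = make_table(rows, label="y")
        m = build_mv_set([e1, e2], out)
        assert m.k == 4
        assert all(prov == {"a", "b"} for prov in m.provenance)
        assert np.all(m.beta_exp != 0)

    def test_cross_exposure_clump_keeps_smaller_p(self):
        e1 = make_table([snp("rs1", 1e-12), snp("rs2", 0.5), snp("rs3", 1e-9),
                         snp("rs4", 1e-9)], label="a")
        e2 = make_table([snp("rs1", 0.5), snp("rs2", 1e-8), snp("rs3", 1e-9),
                         snp("rs4", 1e-9)], label="b")
        out = make_table([snp(f"rs{i}", 0.5) for i in (1, 2, 3, 4)], label="y")
        rsids = ["rs1", "rs2", "rs3", "rs4"]
        r2 = np.eye(4)
        r2[0, 1] = r2[1, 0] = 0.5  # rs1 (p=1e-12) vs rs2 (best p=1e-8)
        m = build_mv_set([e1, e2], out, ld=LDMatrix(rsids=rsids, r2=r2))
        assert "rs1" in m.rsid and "rs2" not in m.rsid
        assert list(m.dropped["rsid"]) == ["rs2"]

    def test_missing_anywhere_drops_with_reason(self):
        e1 = make_table([snp("rs1", 1e-9), snp("rs2", 1e-9), snp("rs3", 1e-9),
                         snp("rs4", 1e-9)], label="a")
        e2 = make_table([snp("rs1", 1e-9), snp("rs2", 1e-9), snp("rs3", 1e-9)], label="b")
        out = make_table([snp(f"rs{i}", 0.5) for i in (1, 2, 3)], label="y")
        m = build_mv_set([e1, e2], out)
        assert "rs4" not in m.rsid
        assert m.dropped.set_index("rsid").loc["rs4", "reason"] == "missing_in_b"

    def test_needs_two_exposures_and_identification(self):
        e1 = make_table([snp("rs1", 1e-9)], label="a")
        out = make_table([snp("rs1", 0.5)], label="y")
        with pytest.raises(ValidationError):
            build_mv_set([e1], out)
        e2 = make_table([snp("rs1", 1e-9)], label="b")
        with pytest.raises(UnderIdentifiedError):
            build_mv_set([e1, e2], out)  # k=1 <= L=2


class TestMVIVW:
    def test_matches_wls_oracle(self, rng):
        for _ in range(25):
            k, L = int(rng.integers(5, 40)), int(rng.integers(2, 4))
            X = rng.normal(0.05, 0.03, (k, L))
            m = mv_set(X, rng.uniform(0.003, 0.01, (k, L)),
                       rng.normal(0, 0.05, k), rng.uniform(0.01, 0.05, k))
            res = mvmr_ivw(m)
            fit = sm.WLS(m.beta_out, m.beta_exp, weights=1 / m.se_out**2).fit()
            for j, label in enumerate(m.exposure_labels):
                assert res.estimates[label].beta == pytest.approx(
                    fit.params[j], rel=1e-10, abs=1e-12
                )

    def test_two_effects_recovered(self):
        cfg = SimConfig(theta=0.2, seed=21, outcome_type="binary")
        e1, e2, out, truth, g2 = two_exposure_pair(cfg, theta2=-0.1, rg=0.0)
        res = MultivariableMR.from_tables([e1, e2], out).fit()
        est1 = res.estimates["sim_exposure_1"]
        est2 = res.estimates["sim_exposure_2"]
        assert est1.beta == pytest.approx(0.2, abs=3 * est1.se)
        assert est2.beta == pytest.approx(-0.1, abs=3 * est2.se)

    def test_zero_covariable_column_leaves_estimate(self, rng):
        """A covariable whose beta column is exactly zero gets coefficient 0
        and leaves the exposure coefficient untouched (oracle-checked)."""
        k = 25
        x = rng.normal(0.08, 0.03, k)
        y = rng.normal(0.02, 0.04, k)
        sy = rng.uniform(0.01, 0.05, k)
        uni = mv_set(x[:, None], np.full((k, 1), 0.01), y, sy, labels=["x0"])
        res_uni = mvmr_ivw(uni)
        X2 = np.column_stack([x, np.zeros(k)])
        res_mv = mvmr_ivw(
            mv_set(X2, np.full((k, 2), 0.01), y, sy, labels=["x0", "cov"])
        )
        assert res_mv.estimates["x0"].beta == pytest.approx(
            res_uni.estimates["x0"].beta, rel=1e-12
        )
        assert res_mv.estimates["cov"].beta == 0.0
        assert res_mv.conditional_F["cov"] == 0.0

    def test_block_independent_instruments_reduce_to_univariable(self, rng):
        """Block-diagonal design (each exposure instrumented by its own
        SNPs, zero cross-effects): each coefficient equals the univariable
        IVW on that exposure's own instrument block."""
        k = 30
        x1 = np.concatenate([rng.normal(0.08, 0.02, 15), np.zeros(15)])
        x2 = np.concatenate([np.zeros(15), rng.normal(0.06, 0.02, 15)])
        y = rng.normal(0.02, 0.04, k)
        sy = rng.uniform(0.01, 0.05, k)
        res = mvmr_ivw(
            mv_set(np.column_stack([x1, x2]), np.full((k, 2), 0.01), y, sy,
                   labels=["a", "b"])
        )
        h1 = make_harmonised(x1[:15], np.full(15, 0.01), y[:15], sy[:15])
        est1, _ = ivw(h1, model="fixed")
        assert res.estimates["a"].beta == pytest.approx(est1.beta, rel=1e-12)

    def test_univariable_degeneracy(self, rng):
        """With a single exposure column the code path reduces to IVW."""
        k = 15
        x = rng.normal(0.08, 0.03, k)
        y = 0.3 * x + rng.normal(0, 0.02, k)
        sy = rng.uniform(0.01, 0.05, k)
        m = mv_set(x[:, None], np.full((k, 1), 0.01), y, sy, labels=["x0"])
        h = make_harmonised(x, np.full(k, 0.01), y, sy)
        est, _ = ivw(h, model="fixed")
        mv = mvmr_ivw(m).estimates["x0"]
        assert mv.beta == pytest.approx(est.beta, rel=1e-12)

    def test_column_order_invariance(self, rng):
        k = 20
        X = rng.normal(0.05, 0.03, (k, 2))
        se_x = rng.uniform(0.003, 0.01, (k, 2))
        y, sy = rng.normal(0, 0.05, k), rng.uniform(0.01, 0.05, k)
        a = mvmr_ivw(mv_set(X, se_x, y, sy, labels=["p", "q"]))
        b = mvmr_ivw(mv_set(X[:, ::-1], se_x[:, ::-1], y, sy, labels=["q", "p"]))
        assert a.estimates["p"].beta == pytest.approx(b.estimates["p"].beta)
        assert a.conditional_F["q"] == pytest.approx(b.conditional_F["q"])

    def test_collinear_design_names_exposures(self, rng):
        k = 10
        x = rng.normal(0.05, 0.02, k)
        X = np.column_stack([x, 2 * x])
        m = mv_set(X, np.full((k, 2), 0.01), rng.normal(0, 0.05, k),
                   np.full(k, 0.02), labels=["tv", "education"])
        with pytest.raises(CollinearityError, match="tv|education"):
            mvmr_ivw(m)


class TestConditionalF:
    def test_identical_columns_give_zero(self, rng):
        k = 20
        x = rng.normal(0.05, 0.02, k)
        m = mv_set(np.column_stack([x, x]), np.full((k, 2), 0.01),
                   rng.normal(0, 0.05, k), np.full(k, 0.02))
        f = conditional_f(m)
        assert f["x0"] == pytest.approx(0.0, abs=1e-20)
        assert f["x1"] == pytest.approx(0.0, abs=1e-20)

    def test_orthogonal_strong_instruments_near_univariable_f(self):
        """Independent instrument blocks: conditional F approximates each
        exposure's mean univariable F."""
        rng = np.random.default_rng(123)
        k = 400
        se = 0.002
        x1 = np.where(np.arange(k) < 200, rng.normal(0.02, 0.005, k), rng.normal(0, se, k))
        x2 = np.where(np.arange(k) >= 200, rng.normal(0.02, 0.005, k), rng.normal(0, se, k))
        m = mv_set(np.column_stack([x1, x2]), np.full((k, 2), se),
                   rng.normal(0, 0.05, k), np.full(k, 0.02))
        f = conditional_f(m)
        uni_f1 = np.mean((x1 / se) ** 2)
        assert f["x0"] == pytest.approx(uni_f1, rel=0.10)

    def test_correlated_exposures_depress_conditional_f(self):
        """Genetic correlation 0.8 between exposures (television watching vs
        education in magnitude): each exposure's conditional F collapses
        below 10 even though univariable strength stays adequate. Uses a
        1%-variance-explained instrument list supplied pre-selected, the
        regime where joint weak-instrument problems appear."""
        cfg = SimConfig(theta=0.2, seed=31, J=200, h2x=0.01)
        e1, e2, out, truth, g2 = two_exposure_pair(cfg, theta2=0.0, rg=0.8, h2x2=0.01)
        m = MultivariableMR.from_tables([e1, e2], out, p_threshold=1.0)
        f = m.conditional_f()
        uni_f = np.mean(
            (m.data.beta_exp[:, 0] / m.data.se_exp[:, 0]) ** 2
        )
        assert uni_f > 10
        assert f[e1.trait_label] < 10
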