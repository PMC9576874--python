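"""Mediation decomposition and bootstrap-percentile inference."""
import numpy as np
import pandas as pd
import pytest

from telomethyl import linmod, mediation, scans


class TestFitMediation:
    def test_noiseless_arithmetic(self, two_feature_dataset):
        # a = 0.5, b = 0.4, c' = 0.1 with no noise: ie = 0.2, te = 0.3,
        # proportion mediated 2/3
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, 60).astype(float)
        dom = (d > 0).astype(float)
        m = 0.5 * dom + 0.0
        # break exact collinearity of m with dom minimally while keeping
        # the regression exact: add a covariate-free jitter orthogonalized out
        m = 0.5 * dom + 1e-9 * rng.normal(size=60)
        tl = 1.0 + 0.1 * dom + 0.4 * m
        ds = two_feature_dataset(d, m, tl)
        point = mediation.fit_mediation(ds, "rs1", "cg00000001")
        assert point.a == pytest.approx(0.5, abs=1e-6)
        assert point.b == pytest.approx(0.4, abs=1e-4)
        assert point.de == pytest.approx(0.1, abs=1e-6)
        assert point.ie == pytest.approx(0.2, abs=1e-6)
        assert point.te == pytest.approx(0.3, abs=1e-6)
        assert point.prop_mediated == pytest.approx(2 / 3, abs=1e-6)

    def test_null_mediator_gives_zero_ie(self, two_feature_dataset):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.3, 300).astype(float)
        m = 0.8 * (d > 0) + rng.normal(size=300)
        tl = 1.0 + 0.1 * (d > 0) + rng.normal(0, 0.2, 300)  # b = 0 truly
        ds = two_feature_dataset(d, m, tl)
        point = mediation.fit_mediation(ds, "rs1", "cg00000001")
        assert point.te == pytest.approx(point.de + point.ie, abs=1e-12)
        assert abs(point.ie) < 0.05  # b estimated near zero

    def test_opposite_signs_leave_proportion_undefined(self, two_feature_dataset):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, 2000).astype(float)
        dom = (d > 0).astype(float)
        m = 1.0 * dom + rng.normal(size=2000) * 0.1
        # de = -0.1, ie = +0.1*1.0: opposite directions
        tl = 1.0 - 0.1 * dom + 0.1 * m + rng.normal(0, 0.05, 2000)
        ds = two_feature_dataset(d, m, tl)
        point = mediation.fit_mediation(ds, "rs1", "cg00000001")
        assert np.sign(point.de) != np.sign(point.ie)
        assert point.prop_mediated is None

    def test_product_equals_difference_method(self, two_feature_dataset):
        """Linear-model identity: a*b == total - direct, where total is the
        SNP coefficient in TL ~ SNP (no mediator)."""
        rng = np.random.default_rng(3)
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 120
            d = r.binomial(2, 0.35, n).astype(float)
            dom = (d > 0).astype(float)
            m = 0.6 * dom + r.normal(size=n)
            tl = 1.0 + 0.1 * dom + 0.3 * m + r.normal(0, 0.2, n)
            ds = two_feature_dataset(d, m, tl)
            point = mediation.fit_mediation(ds, "rs1", "cg00000001")
            design = linmod.build_design(None, {"snp": dom})
            total = linmod.fit_ols(design, tl).coef_named("snp")[0]
            assert point.ie == pytest.approx(total - point.de, abs=1e-10)
            assert point.te == pytest.approx(total, abs=1e-10)

    def test_constant_inputs_rejected(self, two_feature_dataset):
        ds = two_feature_dataset(np.zeros(50), np.random.default_rng(0).normal(size=50),
                                 np.full(50, 1.0))
        with pytest.raises(ValueError, match="rs1"):
            mediation.fit_mediation(ds, "rs1", "cg00000001")


class TestBootstrap:
    def _dataset(self, two_feature_dataset, seed=0, n=300, a=0.8, b=0.25,
                 c=0.1):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.3, n).astype(float)
        dom = (d > 0).astype(float)
        m = a * dom + rng.normal(size=n)
        tl = 1.0 + c * dom + b * m + rng.normal(0, 0.2, n)
        return two_feature_dataset(d, m, tl)

    def test_deterministic_under_seed(self, two_feature_dataset):
        ds = self._dataset(two_feature_dataset)
        r1 = mediation.bootstrap_mediation(ds, "rs1", "cg00000001",
                                           n_boot=200, seed=7)
        r2 = mediation.bootstrap_mediation(ds, "rs1", "cg00000001",
                                           n_boot=200, seed=7)
        assert r1.ci == r2.ci and r1.boot_p == r2.boot_p

    def test_te_equals_de_plus_ie_each_replicate(self, two_feature_dataset):
        # the identity is enforced by construction in the replicate
        # aggregation; verify via the CI endpoints of te vs de+ie on a
        # degenerate-noise dataset where all replicates coincide
        ds = self._dataset(two_feature_dataset, n=500)
        res = mediation.bootstrap_mediation(ds, "rs1", "cg00000001",
                                            n_boot=150, seed=1)
        # strong planted effect: IE bootstrap interval excludes zero
        assert res.ci["ie"][0] > 0
        assert res.boot_p["ie"] < 0.05
        for eff in ("a", "b", "de", "ie", "te"):
            lo, hi = res.ci[eff]
            assert lo <= hi

    def test_minimum_boot_size_enforced(self, two_feature_dataset):
        ds = self._dataset(two_feature_dataset)
        with pytest.raises(ValueError):
            mediation.bootstrap_mediation(ds, "rs1", "cg00000001", n_boot=50)

    def test_point_recovery_across_simulations(self, two_feature_dataset):
        """Over repeated cohorts at n=1000 the mediation point estimates
        are unbiased for (a, b, c') = (0.8, 0.25, 0.1)."""
        n_sims = 40
        est = np.empty((n_sims, 3))
        for s in range(n_sims):
            ds = self._dataset(two_feature_dataset, seed=100 + s, n=1000)
            p = mediation.fit_mediation(ds, "rs1", "cg00000001")
            est[s] = (p.a, p.b, p.de)
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(n_sims)
        truth = np.array([0.8, 0.25, 0.1])
        assert (np.abs(est.mean(axis=0) - truth) < 2 * mc_se + 1e-12).all()

    def test_proportion_only_from_same_sign_replicates(self, two_feature_dataset):
        ds = self._dataset(two_feature_dataset, n=400, a=0.8, b=0.25, c=0.1)
        res = mediation.bootstrap_mediation(ds, "rs1", "cg00000001",
                                            n_boot=200, seed=3)
        if res.point.prop_mediated is not None:
            assert res.prop_ci is not None
            assert res.n_same_sign_replicates > 0
        ds_opp = self._dataset(two_feature_dataset, n=2000, a=1.0, b=0.2,
                               c=-0.3)
        res_opp = mediation.bootstrap_mediation(ds_opp, "rs1", "cg00000001",
                                                n_boot=200, seed=3)
        assert res_opp.point.prop_mediated is None
        assert res_opp.prop_ci is None


class TestSelectCandidates:
    def test_empty_without_significant_mqtl(self, two_feature_dataset):
        rng = np.random.default_rng(4)
        ds = two_feature_dataset(rng.binomial(2, 0.3, 100).astype(float),
                                 rng.normal(size=100),
                                 rng.normal(1.0, 0.2, 100))
        scan = scans.scan_mqtl(ds)
        assert scan.significant_pairs.empty
        cands = mediation.select_candidates(scan, ds)
        assert cands.empty

    def test_powered_path_selected_and_null_screen_excludes(
            self, two_feature_dataset):
        rng = np.random.default_rng(5)
        n = 1000
        d = rng.binomial(2, 0.3, n).astype(float)
        dom = (d > 0).astype(float)
        m = 0.8 * dom + rng.normal(size=n)
        tl = 1.0 + 0.15 * m + rng.normal(0, 0.2, n)
        ds = two_feature_dataset(d, m, tl)
        scan = scans.scan_mqtl(ds)
        cands = mediation.select_candidates(scan, ds)
        assert list(map(tuple, cands[["snp_id", "cpg_id"]]
                        .itertuples(index=False))) == [("rs1", "cg00000001")]
        # a CpG unrelated to TL must be screened out
        tl_null = rng.normal(1.0, 0.2, n)
        ds_null = two_feature_dataset(d, m, tl_null)
        scan_null = scans.scan_mqtl(ds_null)
        assert not scan_null.significant_pairs.empty
        cands_null = mediation.select_candidates(scan_null, ds_null)
        assert cands_null.empty
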