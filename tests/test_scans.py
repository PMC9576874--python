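"""Association, cis-mQTL and interaction scans."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from telomethyl import scans
from telomethyl.datamodel import (
    CpGRecord,
    GenomicPosition,
    PhenotypeVector,
    SNPRecord,
    StudyDataset,
)


def _snp(snp_id, dosage, chrom="chr1", pos=1_000_000):
    d = np.asarray(dosage, dtype=float)
    return SNPRecord(snp_id, GenomicPosition(chrom, pos), "A", "G", d,
                     SNPRecord.observed_maf(d))


def _cpg(cpg_id, m, chrom="chr1", pos=1_010_000):
    return CpGRecord(cpg_id, GenomicPosition(chrom, pos),
                     np.asarray(m, dtype=float))


class TestEnumerateCisPairs:
    def test_inclusive_boundary(self):
        snp = _snp("rs1", [0, 1], pos=1_000_000)
        cpgs = [_cpg("cg1", [0, 0], pos=500_000),
                _cpg("cg2", [0, 0], pos=499_999),
                _cpg("cg3", [0, 0], pos=1_500_000),
                _cpg("cg4", [0, 0], pos=1_500_001)]
        pairs = scans.enumerate_cis_pairs([snp], cpgs, 500_000)
        assert set(pairs["cpg_id"]) == {"cg1", "cg3"}
        dist = pairs.set_index("cpg_id")["distance_bp"]
        assert dist["cg1"] == -500_000 and dist["cg3"] == 500_000

    def test_other_chromosome_excluded(self):
        snp = _snp("rs1", [0, 1], chrom="chr1", pos=1_000_000)
        cpg = _cpg("cg1", [0, 0], chrom="chr2", pos=1_000_000)
        assert scans.enumerate_cis_pairs([snp], [cpg], 500_000).empty

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chroms = ["chr1", "chr2"]
        snps = [_snp(f"rs{i}", [0, 1], chrom=rng.choice(chroms),
                     pos=int(rng.integers(1, 3_000_000))) for i in range(15)]
        cpgs = [_cpg(f"cg{j}", [0, 0], chrom=rng.choice(chroms),
                     pos=int(rng.integers(1, 3_000_000))) for j in range(60)]
        window = 400_000
        got = set(map(tuple, scans.enumerate_cis_pairs(snps, cpgs, window)
                      [["snp_id", "cpg_id"]].itertuples(index=False)))
        expected = {(s.id, c.id) for s in snps for c in cpgs
                    if s.position.chrom == c.position.chrom
                    and abs(c.position.pos - s.position.pos) <= window}
        assert got == expected


class TestScanTlSnp:
    def test_intercept_only_matches_closed_form(self, two_feature_dataset):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, 200).astype(float)
        tl = 1.0 + 0.1 * d + rng.normal(0, 0.2, 200)
        ds = two_feature_dataset(d, rng.normal(size=200), tl)
        res = scans.scan_tl_snp(ds, "additive")
        slope = np.cov(tl, d)[0, 1] / np.var(d, ddof=1)
        assert res["beta"].iloc[0] == pytest.approx(slope, abs=1e-10)

    def test_codings_differ_by_factor_two_without_heterozygotes(
            self, two_feature_dataset):
        rng = np.random.default_rng(1)
        d = rng.choice([0.0, 2.0], size=100)
        tl = 1.0 + 0.05 * d + rng.normal(0, 0.1, 100)
        ds = two_feature_dataset(d, rng.normal(size=100), tl)
        dom = scans.scan_tl_snp(ds, "dominant")["beta"].iloc[0]
        add = scans.scan_tl_snp(ds, "additive")["beta"].iloc[0]
        assert dom == pytest.approx(2 * add, rel=1e-10)

    def test_constant_snp_marked_untestable(self, two_feature_dataset):
        ds = two_feature_dataset(np.zeros(50), np.random.default_rng(0).normal(size=50),
                                 np.full(50, 1.0))
        res = scans.scan_tl_snp(ds, "dominant")
        assert bool(res["untestable"].iloc[0])
        assert np.isnan(res["beta"].iloc[0])

    def test_recovers_simulated_dominant_effect(self, two_feature_dataset):
        """Generative dominant effect 0.067 T/S (the strongest published
        SNP association) is recovered without bias."""
        rng = np.random.default_rng(2)
        n_reps, n = 50, 5000
        est = np.empty(n_reps)
        for r in range(n_reps):
            d = rng.binomial(2, 0.3, n).astype(float)
            dom = (d > 0).astype(float)
            tl = 1.0 + 0.067 * dom + rng.normal(0, 0.2, n)
            ds = two_feature_dataset(d, rng.normal(size=n), tl)
            est[r] = scans.scan_tl_snp(ds, "dominant")["beta"].iloc[0]
        mc_se = est.std(ddof=1) / np.sqrt(n_reps)
        assert abs(est.mean() - 0.067) < 2 * mc_se + 1e-12


class TestScanMqtl:
    def _dataset(self, rng, n=300, n_null=40, effect=0.5):
        d = rng.binomial(2, 0.3, n).astype(float)
        snp = _snp("rs1", d, pos=1_000_000)
        cpgs = [_cpg("cg_hit", effect * d + rng.normal(size=n), pos=1_010_000)]
        for j in range(n_null):
            cpgs.append(_cpg(f"cg_null{j}", rng.normal(size=n),
                             pos=1_020_000 + j))
        return StudyDataset([snp], cpgs, None,
                            PhenotypeVector(np.full(n, 1.0)),
                            [f"S{i}" for i in range(n)])

    def test_planted_mqtl_detected(self):
        rng = np.random.default_rng(3)
        scan = scans.scan_mqtl(self._dataset(rng))
        assert ("rs1", "cg_hit") in set(map(tuple,
                scan.significant_pairs.itertuples(index=False)))

    def test_disabling_moderation_reproduces_ols(self):
        from scipy import stats
        from telomethyl import linmod
        rng = np.random.default_rng(4)
        ds = self._dataset(rng, n=100, n_null=20)
        scan = scans.scan_mqtl(ds, moderate=False)
        add = scan.results[scan.results["coding"] == "additive"]
        row = add[add["cpg_id"] == "cg_hit"].iloc[0]
        design = linmod.build_design(
            None, {"snp": ds.snps[0].dosage}, n_samples=100)
        fit = linmod.fit_ols(design, ds.cpg("cg_hit").mvalues)
        beta, se, t, p = fit.coef_named("snp")
        assert row["beta"] == pytest.approx(beta, abs=1e-12)
        assert row["p"] == pytest.approx(p, abs=1e-12)

    def test_significant_set_requires_both_codings(self):
        rng = np.random.default_rng(5)
        ds = self._dataset(rng)
        both = scans.scan_mqtl(ds, require_both_codings=True)
        either = scans.scan_mqtl(ds, require_both_codings=False)
        set_both = set(map(tuple, both.significant_pairs.itertuples(index=False)))
        set_either = set(map(tuple, either.significant_pairs.itertuples(index=False)))
        assert set_both <= set_either

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(6)
        rates = []
        for effect in (0.1, 0.25, 0.5):
            hits = 0
            for _ in range(20):
                scan = scans.scan_mqtl(self._dataset(rng, n=150, n_null=30,
                                                     effect=effect))
                hits += int(("rs1", "cg_hit") in set(map(tuple,
                            scan.significant_pairs.itertuples(index=False))))
            rates.append(hits / 20)
        assert rates[0] <= rates[1] + 0.15 and rates[1] <= rates[2] + 0.15
        assert rates[2] > rates[0]


class TestCompareToReference:
    def _results(self):
        res = pd.DataFrame({
            "snp_id": ["rs1", "rs1"], "cpg_id": ["cg1", "cg1"],
            "coding": ["dominant", "additive"], "distance_bp": [0, 0],
            "beta": [0.4, 0.5], "se": [0.1, 0.1], "t_moderated": [4, 5],
            "p": [1e-8, 1e-9], "bonferroni_significant": [True, True]})
        sig = pd.DataFrame({"snp_id": ["rs1"], "cpg_id": ["cg1"]})
        return sig, res

    def test_concordant_discordant_novel(self):
        sig, res = self._results()
        ref_same = pd.DataFrame({"snp_id": ["rs1"], "cpg_id": ["cg1"],
                                 "ref_beta": [0.6]})
        ref_opp = pd.DataFrame({"snp_id": ["rs1"], "cpg_id": ["cg1"],
                                "ref_beta": [-0.6]})
        empty = pd.DataFrame(columns=["snp_id", "cpg_id", "ref_beta"])
        assert scans.compare_to_reference(sig, res, ref_same)["status"].iloc[0] \
            == "replicated_concordant"
        assert scans.compare_to_reference(sig, res, ref_opp)["status"].iloc[0] \
            == "replicated_discordant"
        assert scans.compare_to_reference(sig, res, empty)["status"].iloc[0] \
            == "novel"


class TestScanInteraction:
    def test_mqtl_pairs_excluded_from_universe(self, two_feature_dataset):
        rng = np.random.default_rng(7)
        ds = two_feature_dataset(rng.binomial(2, 0.3, 80).astype(float),
                                 rng.normal(size=80),
                                 rng.normal(1.0, 0.2, 80))
        excluded = pd.DataFrame({"snp_id": ["rs1"], "cpg_id": ["cg00000001"]})
        res = scans.scan_interaction(ds, excluded)
        assert res.empty
        res_all = scans.scan_interaction(ds, None)
        assert len(res_all) == 1

    def test_null_type_one_error_calibrated(self, two_feature_dataset):
        rng = np.random.default_rng(8)
        n_fits, hits = 800, 0
        for _ in range(n_fits):
            n = 60
            d = rng.binomial(2, 0.3, n).astype(float)
            m = rng.normal(size=n)
            tl = rng.normal(1.0, 0.2, n)
            ds = two_feature_dataset(d, m, tl)
            res = scans.scan_interaction(ds, None)
            hits += int(res["p12"].iloc[0] < 0.05)
        rate = hits / n_fits
        assert 0.030 <= rate <= 0.072  # ~3 SD binomial band around 0.05
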