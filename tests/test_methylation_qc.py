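"""Methylation QC: M-values, detection, KNN, EB batch adjustment, trimming,
blacklists and cell-type deconvolution."""
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from telomethyl import methylation_qc as mq
from telomethyl.datamodel import CELL_TYPES, GenomicPosition


class TestMValue:
    def test_symmetry_and_known_value(self):
        assert mq.mvalue_transform(500.0, 500.0) == pytest.approx(0.0)
        assert mq.mvalue_transform(3000.0, 1000.0) == pytest.approx(
            np.log2(3001 / 1001), abs=1e-12)
        assert mq.mvalue_transform(3000.0, 1000.0) == pytest.approx(1.584, abs=1e-3)

    def test_zero_intensities_saved_by_offset(self):
        assert mq.mvalue_transform(0.0, 0.0) == pytest.approx(0.0)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            mq.mvalue_transform(-1.0, 10.0)


class TestDetectionFilter:
    def _matrices(self, fail_mask):
        G, N = fail_mask.shape
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(G, N)),
                         index=[f"cg{i}" for i in range(G)],
                         columns=[f"S{j}" for j in range(N)])
        detp = pd.DataFrame(np.where(fail_mask, 0.5, 0.0),
                            index=m.index, columns=m.columns)
        return m, detp

    def test_clean_data_untouched(self):
        m, detp = self._matrices(np.zeros((5, 10), dtype=bool))
        out, rep = mq.detection_filter(m, detp)
        pd.testing.assert_frame_equal(out, m)
        assert rep.probes_dropped_detection == []

    def test_probe_failing_6_percent_dropped(self):
        fail = np.zeros((2, 100), dtype=bool)
        fail[0, :6] = True  # call rate 0.94 < 0.95
        m, detp = self._matrices(fail)
        out, rep = mq.detection_filter(m, detp)
        assert rep.probes_dropped_detection == ["cg0"]
        assert list(out.index) == ["cg1"]

    def test_sample_failing_2_percent_dropped(self):
        # 2 of 100 probes fail in S0: sample call rate 0.98 < 0.99 while each
        # probe keeps call rate 0.99 >= 0.95
        fail = np.zeros((100, 100), dtype=bool)
        fail[:2, 0] = True
        m, detp = self._matrices(fail)
        out, rep = mq.detection_filter(m, detp)
        assert rep.probes_dropped_detection == []
        assert rep.samples_dropped_call_rate == ["S0"]
        assert "S0" not in out.columns and out.shape == (100, 99)

    def test_surviving_failed_calls_become_missing(self):
        fail = np.zeros((100, 100), dtype=bool)
        fail[0, 0] = True  # 1% probe failure, 1% sample failure: both survive
        m, detp = self._matrices(fail)
        out, _ = mq.detection_filter(m, detp)
        assert np.isnan(out.iloc[0, 0])
        assert out.notna().to_numpy().sum() == 100 * 100 - 1


class TestKNNImpute:
    def test_identity_without_missing(self):
        m = pd.DataFrame(np.arange(12.0).reshape(3, 4))
        pd.testing.assert_frame_equal(mq.knn_impute(m, k=2), m)

    def test_constant_neighborhood(self):
        rng = np.random.default_rng(1)
        # 10 nearest neighbours of the target all equal 5 at the missing column
        base = rng.normal(size=(11, 6))
        base[1:, 0] = 5.0
        base[0] = base[1] + 0.01  # target hugs the neighbour cloud
        base[0, 0] = np.nan
        far = rng.normal(loc=50.0, size=(5, 6))
        m = pd.DataFrame(np.vstack([base, far]))
        out = mq.knn_impute(m, k=10)
        assert out.iloc[0, 0] == pytest.approx(5.0)

    def test_duplicate_probe_dominates(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 5))
        X[1] = X[0]          # exact copy of probe 0
        X[0, 3] = np.nan     # missing entry on the original
        out = mq.knn_impute(pd.DataFrame(X), k=1)
        assert out.iloc[0, 3] == pytest.approx(X[1, 3])

    def test_agrees_with_sklearn_when_donor_rules_coincide(self):
        """With missing entries confined to one probe and fully observed
        donors, our neighbour rule coincides with scikit-learn's KNNImputer
        (probes as samples), which then serves as an independent oracle."""
        from sklearn.impute import KNNImputer

        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 12))
        X[0, [2, 5]] = np.nan
        ours = mq.knn_impute(pd.DataFrame(X), k=5).to_numpy()
        theirs = KNNImputer(n_neighbors=5, weights="uniform").fit_transform(X)
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_observed_entries_never_altered(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 10))
        mask = rng.random((20, 10)) < 0.1
        Xm = np.where(mask, np.nan, X)
        out = mq.knn_impute(pd.DataFrame(Xm), k=5).to_numpy()
        np.testing.assert_array_equal(out[~mask], X[~mask])
        assert not np.isnan(out).any()


class TestEBBatchAdjust:
    def test_single_level_is_identity(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(size=(20, 10)))
        out = mq.eb_batch_adjust(m, np.zeros(10, dtype=int))
        np.testing.assert_allclose(out.to_numpy(), m.to_numpy(), atol=1e-8)

    def test_injected_shift_removed(self):
        rng = np.random.default_rng(1)
        G, N = 500, 200
        batch = np.repeat([0, 1], N // 2)
        delta = 1.0
        X = rng.normal(size=(G, N))
        X[:, batch == 1] += delta
        out = mq.eb_batch_adjust(pd.DataFrame(X), batch).to_numpy()
        residual = abs(out[:, batch == 0].mean() - out[:, batch == 1].mean())
        assert residual < 0.05 * delta

    def test_second_pass_changes_much_less(self):
        """EB shrinkage is not exactly idempotent, but a second pass is a
        strong contraction of the first."""
        rng = np.random.default_rng(2)
        G, N = 200, 100
        batch = np.repeat([0, 1], N // 2)
        X = rng.normal(size=(G, N))
        X[:, batch == 1] += 0.8
        m = pd.DataFrame(X)
        a1 = mq.eb_batch_adjust(m, batch)
        a2 = mq.eb_batch_adjust(a1, batch)
        change1 = np.abs(a1.to_numpy() - X).max()
        change2 = np.abs(a2.to_numpy() - a1.to_numpy()).max()
        assert change2 < 0.5 * change1

    def test_pooled_mean_approximately_preserved(self):
        """EB shrinkage leaves per-probe batch-mean residuals, so probe
        pooled means move only by a small fraction of the probe SD and the
        grand mean is essentially untouched."""
        rng = np.random.default_rng(3)
        G, N = 100, 60
        batch = rng.integers(0, 3, N)
        X = rng.normal(size=(G, N)) + rng.normal(0, 0.5, (G, 1))
        out = mq.eb_batch_adjust(pd.DataFrame(X), batch).to_numpy()
        assert np.abs(out.mean(axis=1) - X.mean(axis=1)).max() < 0.05
        assert abs(out.mean() - X.mean()) < 0.01

    def test_singleton_level_rejected(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 5)))
        with pytest.raises(ValueError, match="single sample"):
            mq.eb_batch_adjust(m, [0, 0, 0, 0, 1])

    def test_matches_reference_combat_implementation(self, tmp_path):
        """Independent oracle: Bioconductor sva::ComBat on the same fixture."""
        rng = np.random.default_rng(42)
        G, N = 40, 30
        batch = np.array([0] * 15 + [1] * 15)
        X = rng.normal(0, 1, (G, N)) + 2.0
        X[:, batch == 1] += rng.normal(0.5, 0.3, G)[:, None]
        ours = mq.eb_batch_adjust(pd.DataFrame(X), batch).to_numpy()
        np.savetxt(tmp_path / "X.txt", X)
        np.savetxt(tmp_path / "batch.txt", batch, fmt="%d")
        script = textwrap.dedent("""
            suppressMessages(library(sva))
            X <- as.matrix(read.table("X.txt"))
            b <- scan("batch.txt", quiet=TRUE)
            adj <- sva::ComBat(dat=X, batch=factor(b))
            write.table(adj, "adj.txt", row.names=FALSE, col.names=FALSE)
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", "run.R"], cwd=tmp_path, check=True,
                       capture_output=True)
        theirs = np.loadtxt(tmp_path / "adj.txt")
        np.testing.assert_allclose(ours, theirs, atol=1e-5)


class TestIQRTrim:
    def test_no_extremes_untouched(self):
        m = pd.DataFrame(np.linspace(-1, 1, 20).reshape(1, -1))
        out, count = mq.iqr_trim(m)
        assert count == 0
        pd.testing.assert_frame_equal(out, m)

    def test_extreme_value_trimmed(self):
        # values 0..9 plus one at 10000: Q1=2.5, Q3=7.5, fence 7.5+3*5=22.5
        vals = np.array([list(range(10)) + [10_000.0]])
        out, count = mq.iqr_trim(pd.DataFrame(vals))
        assert count == 1
        assert np.isnan(out.iloc[0, 10])
        assert out.iloc[0, :10].notna().all()

    def test_constant_probe_untouched(self):
        m = pd.DataFrame(np.full((1, 15), 3.0))
        out, count = mq.iqr_trim(m)
        assert count == 0
        assert out.notna().all().all()


class TestBlacklist:
    def _matrix(self):
        return pd.DataFrame(np.zeros((3, 2)), index=["cg1", "cg2", "cg3"],
                            columns=["A", "B"])

    def test_sex_chromosome_removed(self):
        pos = {"cg1": GenomicPosition("chrX", 10),
               "cg2": GenomicPosition("chr2", 10),
               "cg3": GenomicPosition("chr3", 10)}
        out = mq.blacklist_filter(self._matrix(), pos)
        assert list(out.index) == ["cg2", "cg3"]

    def test_set_semantics_for_multiply_listed_probe(self):
        rep = mq.MethylationQCReport()
        out = mq.blacklist_filter(self._matrix(), None,
                                  snp_probes={"cg2"},
                                  cross_reactive_probes={"cg2"}, report=rep)
        assert list(out.index) == ["cg1", "cg3"]
        assert rep.probes_dropped_blacklist == ["cg2"]


class TestDeconvolution:
    def _reference(self, seed=0, n_probes=50):
        rng = np.random.default_rng(seed)
        R = rng.normal(0, 1, (n_probes, 7))
        for j in range(7):
            R[j::7, j] += 3.0  # well-separated cell-specific probes
        return mq.CellReferenceMatrix(pd.DataFrame(
            R, index=[f"cg{i}" for i in range(n_probes)],
            columns=list(CELL_TYPES)))

    def test_pure_sample_recovered(self):
        ref = self._reference()
        m = pd.DataFrame({"S1": ref.data["NK"]})
        props = mq.estimate_cell_proportions(m, ref)
        assert props.loc["S1", "NK"] == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_mixture_exact(self):
        ref = self._reference()
        mix = 0.5 * ref.data["Bcell"] + 0.5 * ref.data["CD8T"]
        props = mq.estimate_cell_proportions(pd.DataFrame({"S1": mix}), ref)
        assert props.loc["S1", "Bcell"] == pytest.approx(0.5, abs=1e-6)
        assert props.loc["S1", "CD8T"] == pytest.approx(0.5, abs=1e-6)

    def test_rows_sum_to_one_nonnegative(self):
        rng = np.random.default_rng(5)
        ref = self._reference()
        W = rng.dirichlet(np.ones(7), size=30)
        M = ref.data.to_numpy() @ W.T + rng.normal(0, 0.2, (50, 30))
        props = mq.estimate_cell_proportions(
            pd.DataFrame(M, index=ref.probe_ids,
                         columns=[f"S{i}" for i in range(30)]), ref)
        vals = props.to_numpy()
        assert (vals >= 0).all()
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-9)

    def test_rank_deficient_reference_rejected(self):
        ref_df = self._reference().data.copy()
        ref_df["CD8T"] = ref_df["CD4T"]
        ref = mq.CellReferenceMatrix.__new__(mq.CellReferenceMatrix)
        ref.data = ref_df
        m = pd.DataFrame({"S1": ref_df["NK"]})
        with pytest.raises(ValueError, match="rank"):
            mq.estimate_cell_proportions(m, ref)


def test_full_chain_runs_and_orders(small_cohort):
    """The chain consumes a simulated bundle and yields complete data with
    valid cell-proportion estimates."""
    cfg, ds, truth, extras = small_cohort
    clean, props, report = mq.run_methylation_qc(
        ds.mvalue_matrix(), extras["detection_p"], extras["batch"],
        extras["position"], extras["reference"])
    assert not clean.isna().any().any()
    assert report.imputed_count > 0
    np.testing.assert_allclose(props.to_numpy().sum(axis=1), 1.0, atol=1e-9)
    # deconvolution recovers the generative mixtures reasonably well
    common = props.index
    mae = np.abs(props.loc[common].to_numpy()
                 - truth.true_cell_proportions.loc[common].to_numpy()).mean()
    assert mae < 0.05
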