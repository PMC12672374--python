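"""Normalization, FRiP, gene activity, filtering and feature selection."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from olgstate.datatypes import MultiomeDataset, NormalizedMatrix
from olgstate.qc import (
    QcThresholds,
    filter_cells,
    frip,
    gene_activity,
    lognormalize,
    select_variable_features,
    standardize,
    tfidf,
)


def _toy_dataset():
    genes = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1"],
            "start": [1000, 10_000],
            "end": [3000, 12_000],
            "strand": ["+", "-"],
            "tss": [1000, 11_999],
        },
        index=pd.Index(["gA", "gB"], name="gene"),
    )
    # p1 inside gA body; p2 400 bp upstream of gA TSS; p3 600 bp upstream
    # of gA TSS; p4 downstream of gB's (minus strand) TSS i.e. upstream in
    # genome coordinates beyond its end
    peaks = pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "start": [1500, 550, 350, 12_100],
            "end": [1600, 650, 450, 12_200],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="peak"),
    )
    rna = sp.csr_matrix(np.array([[5, 0, 2], [0, 3, 1]]))
    atac = sp.csr_matrix(np.array([[2, 1, 0], [1, 0, 0], [4, 4, 4], [0, 2, 1]]))
    cells = pd.DataFrame(
        {"sample": ["s1", "s1", "s1"], "timepoint": ["cfa"] * 3, "replicate": ["r1"] * 3},
        index=pd.Index(["c1", "c2", "c3"], name="barcode"),
    )
    return MultiomeDataset(rna=rna, atac=atac, genes=genes, peaks=peaks, cells=cells)


class TestLognormalize:
    def test_closed_form(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 10
        counts[1, 0] = 990
        nm = lognormalize(sp.csr_matrix(counts), ["a", "b"], ["c1"])
        # 10 / 1000 * 10000 = 100 -> ln(101)
        assert nm.dense()[0, 0] == pytest.approx(np.log(101.0), abs=1e-9)

    def test_zero_count_stays_zero_and_depth_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(1.0, size=(30, 4))
        counts[:, 3] = 2 * counts[:, 2] + (counts[:, 2] == 0)  # avoid zero col
        counts[0, 0] = 0
        nm = lognormalize(sp.csr_matrix(counts + (counts.sum(0) == 0)), list(range(30)), list(range(4)))
        dense = nm.dense()
        assert dense[0, 0] == 0.0
        doubled = counts.copy()
        doubled[:, 1] = counts[:, 1] * 2
        nm2 = lognormalize(sp.csr_matrix(doubled + (doubled.sum(0) == 0)), list(range(30)), list(range(4)))
        np.testing.assert_allclose(nm.dense()[:, 1], nm2.dense()[:, 1], atol=1e-12)

    def test_zero_cell_rejected(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="zero total"):
            lognormalize(sp.csr_matrix(counts), ["a", "b"], ["c1", "c2"])

    def test_monotone_within_cell(self):
        counts = np.array([[1], [5], [9]])
        vals = lognormalize(sp.csr_matrix(counts), list("abc"), ["c"]).dense().ravel()
        assert vals[0] < vals[1] < vals[2]


class TestTfidf:
    def test_hand_computed_2x2(self):
        counts = np.array([[1, 0], [1, 1]])
        nm = tfidf(sp.csr_matrix(counts), ["pA", "pB"], ["c1", "c2"])
        sf = 10_000
        # TF: pA c1 = 1/2; pB c1 = 1/2; pB c2 = 1. IDF: pA = 2/1, pB = 2/2
        exp = np.array(
            [
                [np.log1p(0.5 * 2.0 * sf), 0.0],
                [np.log1p(0.5 * 1.0 * sf), np.log1p(1.0 * 1.0 * sf)],
            ]
        )
        np.testing.assert_allclose(nm.dense(), exp, rtol=1e-12)

    def test_uniform_peak_symmetric(self):
        counts = np.array([[2, 2, 2], [2, 2, 2]])
        vals = tfidf(sp.csr_matrix(counts), ["pA", "pB"], list("xyz")).dense()
        assert np.ptp(vals[0]) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_peak_rejected(self):
        counts = np.array([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="pA"):
            tfidf(sp.csr_matrix(counts), ["pA", "pB"], ["c1", "c2"])


class TestGeneActivity:
    def test_matches_interval_oracle(self):
        ds = _toy_dataset()
        nm = gene_activity(ds)
        # gA (+): region [500, 3000) -> p1 (body) + p2 (400 bp upstream), not p3
        # gB (-): region [10000, 12500) -> p4
        raw = np.zeros((2, 3))
        raw[0] = ds.atac.toarray()[0] + ds.atac.toarray()[1]
        raw[1] = ds.atac.toarray()[3]
        colsum = raw.sum(axis=0)
        exp = np.log1p(raw / colsum * 10_000)
        np.testing.assert_allclose(nm.dense(), exp, rtol=1e-12)

    def test_upstream_window_boundary(self):
        """Peak centered 400 bp upstream counted; 600 bp upstream not."""
        ds = _toy_dataset()
        nm = gene_activity(ds)
        # cell c2: p2 contributes 0 but p1 contributes 1 -> gA activity > 0;
        # drop p2 and p1: only p3 left upstream -> would be zero
        only_p3 = ds.atac.toarray().copy()
        only_p3[0] = 0  # remove p1 signal
        only_p3[1] = 0  # remove p2 signal
        ds2 = MultiomeDataset(
            rna=ds.rna, atac=sp.csr_matrix(only_p3), genes=ds.genes, peaks=ds.peaks, cells=ds.cells
        )
        nm2 = gene_activity(ds2)
        assert nm2.dense()[0].sum() == 0.0  # p3 at 600 bp is never counted
        assert nm.dense()[0].sum() > 0.0

    def test_missing_strand_rejected(self):
        ds = _toy_dataset()
        genes = ds.genes.copy()
        genes.loc["gA", "strand"] = "."
        ds2 = MultiomeDataset(rna=ds.rna, atac=ds.atac, genes=genes, peaks=ds.peaks, cells=ds.cells)
        with pytest.raises(ValueError, match="strand"):
            gene_activity(ds2)


class TestFrip:
    def test_arithmetic(self):
        ds = _toy_dataset()
        ds.cells["atac_fragments_total"] = [100, 10, 10]
        per_cell, per_sample = frip(ds)
        in_peaks = np.asarray(ds.atac.sum(axis=0)).ravel()
        assert per_cell["c1"] == pytest.approx(in_peaks[0] / 100)
        assert per_sample["s1"] == pytest.approx(np.mean(in_peaks / [100, 10, 10]))

    def test_all_in_peaks_is_one(self):
        ds = _toy_dataset()
        ds.cells["atac_fragments_total"] = np.asarray(ds.atac.sum(axis=0)).ravel()
        per_cell, _ = frip(ds)
        np.testing.assert_allclose(per_cell.to_numpy(), 1.0)

    def test_zero_total_flagged_nan(self):
        ds = _toy_dataset()
        ds.cells["atac_fragments_total"] = [100, 0, 10]
        per_cell, _ = frip(ds)
        assert np.isnan(per_cell["c2"])


class TestFilterCells:
    def _dataset(self, rna_totals):
        n = len(rna_totals)
        rna = sp.csr_matrix(np.tile(np.asarray(rna_totals) / 2, (2, 1)))
        atac = sp.csr_matrix(np.ones((1, n)))
        genes = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, 100], "end": [50, 200], "strand": ["+", "+"], "tss": [0, 100]},
            index=["gA", "gB"],
        )
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [10], "end": [20]}, index=["p1"])
        cells = pd.DataFrame(
            {"sample": ["s1"] * n, "timepoint": ["cfa"] * n, "replicate": ["r1"] * n},
            index=[f"c{i}" for i in range(n)],
        )
        return MultiomeDataset(rna=rna, atac=atac, genes=genes, peaks=peaks, cells=cells)

    def test_outlier_removed_by_auto_quantile(self):
        totals = [10.0] * 9 + [100.0]  # one cell at 10x the median
        ds = self._dataset(totals)
        filtered, report = filter_cells(ds, QcThresholds(max_rna_counts="auto"))
        assert filtered.n_cells == 9
        assert "c9" not in filtered.cells.index
        resolved = report.loc[report["metric"] == "rna_counts", "threshold"].iloc[0]
        assert resolved < 100

    def test_unset_thresholds_identity(self):
        ds = self._dataset([10.0] * 5)
        filtered, report = filter_cells(ds, QcThresholds())
        assert filtered.n_cells == 5
        assert report.empty

    def test_min_above_max_rejected(self):
        with pytest.raises(ValueError):
            filter_cells(self._dataset([10.0] * 3), QcThresholds(min_rna_counts=10, max_rna_counts=5))

    def test_resolved_thresholds_idempotent(self):
        ds = self._dataset([10.0] * 9 + [100.0])
        filtered, report = filter_cells(ds, QcThresholds(max_rna_counts="auto"))
        thr = float(report["threshold"].iloc[0])
        again, _ = filter_cells(filtered, QcThresholds(max_rna_counts=thr))
        assert again.n_cells == filtered.n_cells


class TestVariableFeatures:
    def test_planted_high_variance_genes_rank_first(self):
        rng = np.random.default_rng(0)
        n_genes, n_cells = 100, 300
        counts = rng.poisson(np.full((n_genes, n_cells), 15.0))
        # 5 genes are bimodal at the same mean: variance, not level, differs
        onoff = rng.random(n_cells) < 0.5
        for i in range(5):
            counts[i] = np.where(onoff, rng.poisson(28.0, n_cells), rng.poisson(2.0, n_cells))
        top, _ = select_variable_features(sp.csr_matrix(counts), [f"g{i}" for i in range(n_genes)], n=5)
        assert set(top) == {f"g{i}" for i in range(5)}

    def test_constant_gene_never_selected(self):
        counts = np.vstack([np.full(50, 7), np.arange(50)])
        top, _ = select_variable_features(sp.csr_matrix(counts), ["const", "varies"], n=1)
        assert list(top) == ["varies"]

    def test_common_peak_selected(self):
        rng = np.random.default_rng(1)
        peaks = (rng.random((50, 100)) < 0.3).astype(int)
        peaks[0] = (rng.random(100) < 0.96).astype(int)  # present in ~96% of cells
        counts = np.ones((2, 100))
        _, sel = select_variable_features(
            sp.csr_matrix(counts), ["a", "b"], n=1,
            atac_counts=sp.csr_matrix(peaks), peaks=[f"p{i}" for i in range(50)],
        )
        assert "p0" in set(sel)

    def test_n_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_variable_features(sp.csr_matrix(np.ones((3, 4))), ["a", "b", "c"], n=10)


class TestStandardize:
    def test_row_closed_form_sample_sd(self, tiny_norm):
        nm = NormalizedMatrix(
            values=np.array([[1.0, 2.0, 3.0]]), features=["g"], cells=["a", "b", "c"], method="lognorm"
        )
        out = standardize(nm)
        np.testing.assert_allclose(out.dense()[0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_row_zeroed(self):
        nm = NormalizedMatrix(
            values=np.array([[4.0, 4.0, 4.0]]), features=["g"], cells=["a", "b", "c"], method="lognorm"
        )
        np.testing.assert_array_equal(standardize(nm).dense(), np.zeros((1, 3)))

    def test_idempotent(self, tiny_norm):
        once = standardize(tiny_norm)
        twice = standardize(once)
        np.testing.assert_allclose(once.dense(), twice.dense(), atol=1e-8)
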