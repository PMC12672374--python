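"""Peak-gene linking, DORC definition and track binning."""
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from olgstate.datatypes import NormalizedMatrix
from olgstate.linking import binned_track, define_dorcs, enhancer_score, link_peaks


def brute_force_links(expr, access, peaks, genes, max_dist, min_cells, p_max):
    """All-pairs closed-form Pearson + t-test oracle."""
    recs = []
    n = expr.shape[1]
    E = expr.dense()
    A = access.dense()
    for gi, g in enumerate(genes.index):
        tss = genes.loc[g, "tss"]
        for pi, p in enumerate(peaks.index):
            if peaks.loc[p, "chrom"] != genes.loc[g, "chrom"]:
                continue
            center = (peaks.loc[p, "start"] + peaks.loc[p, "end"]) // 2
            if abs(center - tss) > max_dist:
                continue
            if (A[pi] != 0).sum() < min_cells:
                continue
            x, y = E[gi], A[pi]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            pv = 2 * stats.t.sf(abs(t), n - 2)
            if r > 0 and pv < p_max:
                recs.append((p, g, r, pv))
    return pd.DataFrame(recs, columns=["peak", "gene", "r", "p"])


def _random_matrices(n_genes=20, n_peaks=200, n_cells=300, seed=0):
    rng = np.random.default_rng(seed)
    genes = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_genes,
            "start": np.arange(n_genes) * 100_000,
            "end": np.arange(n_genes) * 100_000 + 10_000,
            "strand": ["+"] * n_genes,
            "tss": np.arange(n_genes) * 100_000,
        },
        index=[f"g{i}" for i in range(n_genes)],
    )
    pstart = rng.integers(0, n_genes * 100_000, n_peaks)
    peaks = pd.DataFrame(
        {"chrom": ["chr1"] * n_peaks, "start": pstart, "end": pstart + 500},
        index=[f"p{i}" for i in range(n_peaks)],
    )
    E = rng.gamma(2, 1, (n_genes, n_cells))
    A = rng.poisson(0.8, (n_peaks, n_cells)).astype(float)
    # plant a few strong correlations
    for k in range(5):
        A[k] = E[k % n_genes] * 0.5 + rng.normal(0, 0.1, n_cells)
    expr = NormalizedMatrix(values=E, features=genes.index, cells=[f"c{i}" for i in range(n_cells)], method="lognorm")
    acc = NormalizedMatrix(values=A, features=peaks.index, cells=expr.cells, method="tfidf")
    return expr, acc, peaks, genes


class TestLinkPeaks:
    def test_identical_to_brute_force_oracle(self):
        expr, acc, peaks, genes = _random_matrices()
        got = link_peaks(expr, acc, peaks, genes, max_dist=50_000, min_cells=10, p_max=0.05)
        exp = brute_force_links(expr, acc, peaks, genes, 50_000, 10, 0.05)
        got_k = got.set_index(["peak", "gene"]).sort_index()
        exp_k = exp.set_index(["peak", "gene"]).sort_index()
        assert set(got_k.index) == set(exp_k.index)
        np.testing.assert_allclose(got_k["r"], exp_k.loc[got_k.index, "r"], atol=1e-10)
        np.testing.assert_allclose(got_k["p"], exp_k.loc[got_k.index, "p"], atol=1e-10)

    def _two_feature_setup(self, dist, r_sign=1.0):
        n = 40
        rng = np.random.default_rng(1)
        x = rng.gamma(2, 1, n)
        genes = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [1000], "strand": ["+"], "tss": [0]}, index=["g"]
        )
        peaks = pd.DataFrame(
            {"chrom": ["chr1"], "start": [dist - 250], "end": [dist + 250]}, index=["p"]
        )
        expr = NormalizedMatrix(values=x[None, :], features=["g"], cells=[f"c{i}" for i in range(n)], method="lognorm")
        acc = NormalizedMatrix(values=(r_sign * x)[None, :], features=["p"], cells=expr.cells, method="tfidf")
        return expr, acc, peaks, genes

    def test_perfect_correlation_within_window_linked(self):
        expr, acc, peaks, genes = self._two_feature_setup(10_000)
        out = link_peaks(expr, acc, peaks, genes)
        assert len(out) == 1 and out.iloc[0]["r"] == pytest.approx(1.0)

    def test_beyond_window_not_linked(self):
        expr, acc, peaks, genes = self._two_feature_setup(60_000)
        assert link_peaks(expr, acc, peaks, genes).empty

    def test_negative_correlation_not_linked(self):
        expr, acc, peaks, genes = self._two_feature_setup(10_000, r_sign=-1.0)
        assert link_peaks(expr, acc, peaks, genes).empty


class TestEnhancerScore:
    def test_arithmetic(self):
        counts = sp.csr_matrix(np.array([[5], [95]]))  # one cell: 5 + 95 = 100 in peaks
        links = pd.DataFrame({"peak": ["pA"], "gene": ["g"]})
        nm, flagged = enhancer_score(counts, pd.Index(["pA", "pB"]), pd.Index(["c1"]), links)
        assert nm.dense()[0, 0] == pytest.approx(500.0)
        assert len(flagged) == 0

    def test_zero_total_flagged(self):
        counts = sp.csr_matrix(np.array([[5, 0], [95, 0]]))
        links = pd.DataFrame({"peak": ["pA"], "gene": ["g"]})
        nm, flagged = enhancer_score(counts, pd.Index(["pA", "pB"]), pd.Index(["c1", "c2"]), links)
        assert list(flagged) == ["c2"]
        assert np.isnan(nm.dense()[0, 1])

    def test_disjoint_link_sets_conserve_budget(self):
        rng = np.random.default_rng(0)
        counts = sp.csr_matrix(rng.poisson(2.0, (6, 5)))
        links = pd.DataFrame(
            {"peak": ["p0", "p1", "p2", "p3"], "gene": ["gA", "gA", "gB", "gB"]}
        )
        nm, _ = enhancer_score(counts, pd.Index([f"p{i}" for i in range(6)]), pd.Index([f"c{i}" for i in range(5)]), links)
        assert (np.nansum(nm.dense(), axis=0) <= 10_000 + 1e-9).all()


class TestDorcs:
    def test_planted_genes_recovered_exactly(self, linking_dataset):
        """>=5 linked peaks -> DORC; 4 -> not; zero false positives with BH."""
        ds, truth = linking_dataset
        from olgstate.qc import lognormalize, tfidf

        expr = lognormalize(ds.rna, ds.genes.index, ds.cells.index)
        acc = tfidf(ds.atac, ds.peaks.index, ds.cells.index)
        links50 = link_peaks(expr, acc, ds.peaks, ds.genes, padj_max=0.05)
        table = define_dorcs(links50, expr, acc, ds.peaks, ds.genes, atac_counts=ds.atac, padj_max=0.05)
        expected = set(truth.genes.index[truth.genes["dorc"]])
        assert set(table.dorc_genes) == expected

    def test_expanded_links_superset_with_union(self, linking_dataset):
        ds, _ = linking_dataset
        from olgstate.qc import lognormalize, tfidf

        expr = lognormalize(ds.rna, ds.genes.index, ds.cells.index)
        acc = tfidf(ds.atac, ds.peaks.index, ds.cells.index)
        links50 = link_peaks(expr, acc, ds.peaks, ds.genes, padj_max=0.05)
        table = define_dorcs(
            links50, expr, acc, ds.peaks, ds.genes, padj_max=0.05, union_with_50kb=True
        )
        near = links50[links50["gene"].isin(table.dorc_genes)]
        near_pairs = set(zip(near["peak"], near["gene"]))
        exp_pairs = set(zip(table.links["peak"], table.links["gene"]))
        assert near_pairs <= exp_pairs

    def test_no_qualifying_genes_warns(self):
        expr, acc, peaks, genes = _random_matrices(n_genes=3, n_peaks=5, n_cells=50, seed=2)
        empty_links = pd.DataFrame(columns=["peak", "gene", "r", "p", "padj", "distance", "window"])
        with pytest.warns(UserWarning, match="no genes qualify"):
            table = define_dorcs(empty_links, expr, acc, peaks, genes)
        assert len(table.dorc_genes) == 0


class TestBinnedTrack:
    def _peaks(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 1000], "end": [200, 1100]},
            index=["pA", "pB"],
        )

    def test_bigwig_arithmetic(self):
        counts = sp.csr_matrix(np.array([[10], [990]]))
        track = binned_track(counts, self._peaks(), np.array([0]), variant="bigwig")
        # pA occupies exactly bin [100, 200): 10 / 1000 * 1e4 = 100
        row = track[track["start"] == 100]
        assert row["value"].iloc[0] == pytest.approx(100.0, rel=1e-12)

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, (2, 6))
        t1 = binned_track(sp.csr_matrix(counts), self._peaks(), np.arange(6))
        t2 = binned_track(sp.csr_matrix(counts * 2), self._peaks(), np.arange(6))
        pd.testing.assert_frame_equal(t1, t2)

    def test_group_size_invariance(self):
        """Two groups with equal per-cell signal but different sizes give
        equal normalized tracks."""
        base = np.array([[3], [7]])
        small = sp.csr_matrix(np.tile(base, (1, 2)))
        large = sp.csr_matrix(np.tile(base, (1, 10)))
        t1 = binned_track(small, self._peaks(), np.arange(2))
        t2 = binned_track(large, self._peaks(), np.arange(10))
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            binned_track(sp.csr_matrix(np.ones((2, 2))), self._peaks(), np.array([]))
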