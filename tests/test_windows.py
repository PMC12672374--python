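"""TSS/enhancer window construction, region counting, TMM NB-LRT and the
memory gate."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olgstate import nbglm
from olgstate.windows import (
    MemoryThresholds,
    WindowSet,
    build_enhancer_regions,
    build_tss_windows,
    classify_memory,
    count_regions,
    tmm_nb_lrt,
)


def _ann(rows):
    return pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene"])


class TestTssWindows:
    def test_lone_tss_centered_1kb(self):
        ws = build_tss_windows(_ann([("chr1", 10_000, "+", "gA")]))
        row = ws.intervals.iloc[0]
        assert (row["chrom"], row["start"], row["end"]) == ("chr1", 9_500, 10_500)
        assert row["gene"] == "gA"

    def test_close_pair_merged_to_single_window(self):
        """Two same-strand TSSs 30 bp apart merge before resizing."""
        ws = build_tss_windows(_ann([("chr1", 10_000, "+", "gA"), ("chr1", 10_030, "+", "gB")]))
        assert len(ws) == 1
        row = ws.intervals.iloc[0]
        center = (10_000 - 25 + 10_030 + 25) // 2
        assert row["start"] == center - 500
        assert row["end"] == row["start"] + 1000

    def test_hand_enumerated_twelve_tss_layout(self):
        """12 TSSs incl. a 600-bp pair whose resized windows re-overlap."""
        rows = []
        # 8 well-separated TSSs on chr1
        for i in range(8):
            rows.append(("chr1", 5_000 + i * 10_000, "+" if i % 2 == 0 else "-", f"g{i}"))
        # a 600-bp-apart same-strand pair: seeds don't overlap, resized do
        rows.append(("chr2", 50_000, "+", "gP"))
        rows.append(("chr2", 50_600, "+", "gQ"))
        # an opposite-strand pair 40 bp apart: not merged strand-aware, but
        # the final strand-agnostic pass merges their resized windows
        rows.append(("chr2", 80_000, "+", "gR"))
        rows.append(("chr2", 80_040, "-", "gS"))
        ws = build_tss_windows(_ann(rows))
        chr1 = ws.intervals[ws.intervals["chrom"] == "chr1"]
        assert len(chr1) == 8
        for i, row in enumerate(chr1.sort_values("start").itertuples(index=False)):
            assert (row.start, row.end) == (5_000 + i * 10_000 - 500, 5_000 + i * 10_000 + 500)
        chr2 = ws.intervals[ws.intervals["chrom"] == "chr2"]
        # 600-bp pair: two 1-kb windows would span [49500,50500)+[50100,51100)
        # -> merged composite [49500, 51100)
        pair = chr2[chr2["start"] < 60_000]
        assert len(pair) == 1
        assert (pair.iloc[0]["start"], pair.iloc[0]["end"]) == (49_500, 51_100)
        opp = chr2[chr2["start"] > 60_000]
        assert len(opp) == 1  # opposite-strand windows merged in final pass

    def test_missing_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            build_tss_windows(_ann([("chr1", 100, ".", "g")]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tss=st.lists(st.integers(min_value=0, max_value=200_000), min_size=1, max_size=30),
        strands=st.lists(st.sampled_from("+-"), min_size=30, max_size=30),
    )
    def test_nonoverlap_property_random_annotations(self, tss, strands):
        ann = _ann(
            [("chr1", t, strands[i], f"g{i}") for i, t in enumerate(tss)]
        )
        ws = build_tss_windows(ann)  # WindowSet __post_init__ asserts nonoverlap
        iv = ws.intervals.sort_values("start")
        assert (iv["start"].to_numpy()[1:] >= iv["end"].to_numpy()[:-1]).all()


class TestEnhancerRegions:
    def _tss(self):
        return build_tss_windows(_ann([("chr1", 10_000, "+", "gA")]))

    def test_ccre_overlapping_tss_window_removed(self):
        # TSS window is [9500, 10500); cCRE touching by 1 bp is dropped
        ccres = pd.DataFrame({"chrom": ["chr1"], "start": [10_499], "end": [10_700]})
        consensus = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [200_000]})
        ws = build_enhancer_regions(ccres, self._tss(), consensus)
        assert len(ws) == 0

    def test_no_consensus_overlap_discarded(self):
        ccres = pd.DataFrame({"chrom": ["chr1"], "start": [50_000], "end": [50_300]})
        consensus = pd.DataFrame({"chrom": ["chr1"], "start": [90_000], "end": [91_000]})
        ws = build_enhancer_regions(ccres, self._tss(), consensus)
        assert len(ws) == 0

    def test_toy_six_ccres_hand_enumerated(self):
        ccres = pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "start": [9_800, 30_000, 30_200, 60_000, 90_000, 120_000],
                "end": [10_100, 30_150, 30_400, 60_200, 90_100, 120_050],
            }
        )
        consensus = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000]})
        links = pd.DataFrame(
            {"chrom": ["chr1"], "start": [29_000], "end": [31_000], "gene": ["gZ"]}
        )
        ws = build_enhancer_regions(ccres, self._tss(), consensus, peak_gene_links=links)
        # ccre0 hits the TSS window -> dropped; ccre at 120k fails consensus;
        # the 30k pair: separate merges (50-bp gap), resized to 1 kb around
        # centers 30075 / 30300, whose windows re-overlap -> one composite
        # [29575, 30800); survivors: composite, 60k, 90k
        assert len(ws) == 3
        merged = ws.intervals.iloc[0]
        assert (merged["start"], merged["end"]) == (29_575, 30_800)
        assert merged["gene"] == "gZ"
        assert ws.intervals.iloc[1]["gene"] == ""

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty cCRE"):
            ws = build_enhancer_regions(
                pd.DataFrame(columns=["chrom", "start", "end"]),
                self._tss(),
                pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]}),
            )
        assert len(ws) == 0


class TestCountRegions:
    def _regions(self):
        iv = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [100, 200], "end": [200, 300],
             "gene": ["gA", "gB"], "provenance": [["a"], ["b"]]}
        )
        return WindowSet(intervals=iv, kind="tss")

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 400, 100)
        frags = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + rng.integers(1, 80, 100)})
        regions_iv = pd.DataFrame({
            "chrom": ["chr1"] * 20,
            "start": np.arange(20) * 25,
            "end": np.arange(20) * 25 + 25,
            "gene": "", "provenance": [[]] * 20,
        })
        regions = WindowSet(intervals=regions_iv, kind="tss")
        got = count_regions({"s": frags}, regions)
        for i, r in enumerate(regions_iv.itertuples(index=False)):
            exp = sum(1 for f in frags.itertuples(index=False) if f.start < r.end and f.end > r.start)
            assert got.iloc[i, 0] == exp

    def test_fragment_fully_inside_counts_once(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [120], "end": [150]})
        got = count_regions({"s": frags}, self._regions())
        assert got.iloc[0, 0] == 1 and got.iloc[1, 0] == 0

    def test_spanning_fragment_counted_in_both(self):
        frags = pd.DataFrame({"chrom": ["chr1"], "start": [150], "end": [250]})
        got = count_regions({"s": frags}, self._regions())
        assert got.iloc[0, 0] == 1 and got.iloc[1, 0] == 1


class TestTmmNbLrt:
    def test_tmm_factors_near_one_for_equal_libraries(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100.0, (500, 4))
        nf = nbglm.tmm_norm_factors(counts)
        np.testing.assert_allclose(nf, 1.0, atol=0.01)

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(1)
        base = np.exp(rng.normal(np.log(80), 0.8, 800))
        mu = np.tile(base[:, None], (1, 6))
        mu[:40, 3:] *= 4.0  # 4-fold up in condition B
        counts = rng.poisson(rng.gamma(1 / 0.02, 0.02 * mu))
        cdf = pd.DataFrame(counts, index=[f"g{i}" for i in range(800)],
                           columns=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3, "replicate": ["r1", "r2", "r3"] * 2},
            index=cdf.columns,
        )
        res = tmm_nb_lrt(cdf, meta, ("B", "A"))
        planted = res.iloc[:40]
        assert planted["logFC"].mean() == pytest.approx(2.0, abs=0.3)
        assert (planted["fdr"] < 0.05).mean() > 0.95

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        base = np.exp(rng.normal(np.log(80), 0.8, 800))
        counts = rng.poisson(rng.gamma(1 / 0.02, 0.02 * np.tile(base[:, None], (1, 6))))
        cdf = pd.DataFrame(counts, index=[f"g{i}" for i in range(800)],
                           columns=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame(
            {"condition": ["A"] * 3 + ["B"] * 3, "replicate": ["r1", "r2", "r3"] * 2},
            index=cdf.columns,
        )
        res = tmm_nb_lrt(cdf, meta, ("B", "A"))
        assert (res["p"] < 0.05).mean() <= 0.08

    def test_single_replicate_rejected(self):
        cdf = pd.DataFrame(np.ones((5, 2), dtype=int), columns=["s0", "s1"])
        meta = pd.DataFrame({"condition": ["A", "B"], "replicate": ["r1", "r1"]},
                            index=["s0", "s1"])
        with pytest.raises(ValueError, match="fewer than 2 replicates"):
            tmm_nb_lrt(cdf, meta, ("B", "A"))


class TestClassifyMemory:
    def _stats(self, logfc, p, fdr, index):
        return pd.DataFrame({"logFC": logfc, "p": p, "fdr": fdr}, index=index)

    def test_rule_examples(self):
        idx = pd.Index(["gene_memory", "gene_atac_moved"])
        rna1 = self._stats([2.0, 2.0], [0.001, 0.001], [0.004, 0.004], idx)
        atac = self._stats([0.2, 0.8], [0.5, 0.001], [0.6, 0.01], idx)
        out = classify_memory(rna1, atac)
        assert bool(out.loc["gene_memory", "memory"])
        assert not bool(out.loc["gene_atac_moved", "memory"])

    def test_toy_ten_gene_table_exact_survivors(self):
        idx = pd.Index([f"g{i}" for i in range(10)])
        rna1 = self._stats(
            logfc=[2, 2, 2, 2, 2, -2, 2, 2, 0.1, 2],
            p=[0.001] * 8 + [0.5, 0.001],
            fdr=[0.01, 0.01, 0.01, 0.01, 0.06, 0.01, 0.01, 0.01, 0.9, 0.01],
            index=idx,
        )
        atac = self._stats(
            logfc=[0.1, 0.6, 0.1, -0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.2],
            p=[0.5, 0.001, 0.5, 0.5, 0.5, 0.5, 0.02, 0.5, 0.5, 0.5],
            fdr=[0.8, 0.01, 0.8, 0.8, 0.8, 0.8, 0.04, 0.8, 0.8, 0.8],
            index=idx,
        )
        rna2 = self._stats(
            logfc=[2, 2, 2, 0.1, 2, 2, 2, -1, 2, 1],
            p=[0.001, 0.001, 0.2, 0.5, 0.001, 0.001, 0.001, 0.001, 0.001, 0.01],
            fdr=[0.01, 0.01, 0.5, 0.9, 0.01, 0.01, 0.01, 0.01, 0.01, 0.2],
            index=idx,
        )
        out = classify_memory(rna1, atac, rna2)
        # by hand: memory requires up1 (fails g4 fdr, g5 sign, g8 p) and
        # stable atac (fails g1 lfc, g6 fdr) -> memory = {g0, g2, g3, g7, g9}
        assert set(out.index[out["memory"]]) == {"g0", "g2", "g3", "g7", "g9"}
        # asterisk: memory and dose2 p&fdr<0.05 and up -> {g0, g9? (fdr 0.2 no)} -> {g0}
        assert set(out.index[out["asterisk"]]) == {"g0"}
        # weak dose-2 class contains the asterisk class
        assert set(out.index[out["asterisk"]]) <= set(out.index[out["further_up_on_dose2"]])
        assert set(out.index[out["further_up_on_dose2"]]) == {"g0", "g9"}

    def test_region_gene_mapping_all_vs_any(self):
        idx = pd.Index(["g1"])
        rna1 = self._stats([2.0], [0.001], [0.004], idx)
        regions = pd.Index(["rA", "rB"])
        atac = self._stats([0.1, 0.9], [0.5, 0.001], [0.6, 0.01], regions)
        region_genes = pd.Series(["g1", "g1"], index=regions)
        strict = classify_memory(rna1, atac, region_genes=region_genes, require_all_regions=True)
        loose = classify_memory(rna1, atac, region_genes=region_genes, require_all_regions=False)
        assert not bool(strict.loc["g1", "memory"])
        assert bool(loose.loc["g1", "memory"])

    def test_custom_thresholds(self):
        idx = pd.Index(["g"])
        rna1 = self._stats([2.0], [0.001], [0.004], idx)
        atac = self._stats([0.45], [0.5], [0.6], idx)
        default = classify_memory(rna1, atac)
        tight = classify_memory(rna1, atac, thresholds=MemoryThresholds(atac_abs_logfc=0.3))
        assert bool(default.loc["g", "memory"]) and not bool(tight.loc["g", "memory"])
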