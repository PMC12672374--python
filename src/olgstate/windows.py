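"""1-kb TSS windows, enhancer regions, region counting, TMM/NB-LRT
differential accessibility and the epigenetic-memory gene gate.

TSS windows are built by extending every annotated TSS by 25 bp each side,
merging overlapping same-strand extensions, recentering the merged regions
to 1 kb, and merging once more (strand-agnostic) so the final set is
strictly nonoverlapping -- composites from that second pass may exceed
1 kb. Enhancer regions start from cCRE intervals, exclude anything
touching a TSS window, are merged/recentered the same way, and must
overlap a consensus peak to be kept.

A gene is called an epigenetic-memory gene when it is upregulated on the
first stimulus dose (RNA p < 0.05 and FDR < 0.05 vs control) while its
regulatory-region accessibility is unchanged between the end of dose 1 and
the washout (|logFC| < 0.5 and FDR > 0.05); genes further upregulated on
the second dose (p and FDR < 0.05 vs dose 1) form the asterisk subclass.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nbglm


@dataclass
class WindowSet:
    intervals: pd.DataFrame  # chrom, start, end (0-based half-open), gene, provenance
    kind: str  # "tss" or "enhancer"

    def __post_init__(self) -> None:
        df = self.intervals
        for chrom, sub in df.groupby("chrom"):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping windows on {chrom}")

    def __len__(self) -> int:
        return len(self.intervals)


def _merge_intervals(df: pd.DataFrame, by_strand: bool) -> pd.DataFrame:
    """Sweep-merge overlapping intervals; provenance lists merged members."""
    keys = ["chrom", "strand"] if by_strand and "strand" in df else ["chrom"]
    out = []
    for _, sub in df.groupby(keys, sort=True):
        sub = sub.sort_values(["start", "end"]).reset_index(drop=True)
        cur = None
        for row in sub.itertuples(index=False):
            if cur is None or row.start >= cur["end"]:
                if cur is not None:
                    out.append(cur)
                cur = {
                    "chrom": row.chrom,
                    "start": row.start,
                    "end": row.end,
                    "strand": getattr(row, "strand", "."),
                    "provenance": list(getattr(row, "provenance", []) or [getattr(row, "name", "")]),
                }
            else:
                cur["end"] = max(cur["end"], row.end)
                cur["provenance"] += list(getattr(row, "provenance", []) or [getattr(row, "name", "")])
        if cur is not None:
            out.append(cur)
    return pd.DataFrame(out, columns=["chrom", "start", "end", "strand", "provenance"])


def _recenter_1kb(df: pd.DataFrame, size: int = 1000) -> pd.DataFrame:
    center = (df["start"] + df["end"]) // 2
    out = df.copy()
    out["start"] = (center - size // 2).clip(lower=0)
    out["end"] = out["start"] + size
    return out


def _closest_gene(df: pd.DataFrame, tss_table: pd.DataFrame) -> pd.Series:
    """Gene with the TSS closest to each window center; ties break on the
    smallest gene id."""
    out = []
    for row in df.itertuples(index=False):
        center = (row.start + row.end) // 2
        sub = tss_table[tss_table["chrom"] == row.chrom]
        if sub.empty:
            out.append("")
            continue
        d = (sub["tss"] - center).abs()
        best = d.min()
        out.append(min(sub.loc[d == best, "gene"]))
    return pd.Series(out, index=df.index)


def build_tss_windows(annotation: pd.DataFrame, flank: int = 25, size: int = 1000) -> WindowSet:
    """Nonoverlapping ~1-kb promoter windows from per-transcript TSSs.

    ``annotation`` needs columns chrom, tss, strand and gene (one row per
    transcript TSS).
    """
    required = {"chrom", "tss", "strand", "gene"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    if annotation["strand"].isna().any() or (~annotation["strand"].isin(["+", "-"])).any():
        raise ValueError("every TSS needs a +/- strand")
    seeds = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": (annotation["tss"] - flank).clip(lower=0),
            "end": annotation["tss"] + flank,
            "strand": annotation["strand"],
            "name": annotation["gene"],
        }
    )
    seeds["provenance"] = [[g] for g in annotation["gene"]]
    merged = _merge_intervals(seeds, by_strand=True)
    resized = _recenter_1kb(merged, size=size)
    final = _merge_intervals(resized, by_strand=False)
    tss_table = annotation[["chrom", "tss", "gene"]]
    final = final.reset_index(drop=True)
    final["gene"] = _closest_gene(final, tss_table)
    return WindowSet(intervals=final[["chrom", "start", "end", "gene", "provenance"]], kind="tss")


def _overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: >= 1 bp overlap with any target interval."""
    hit = np.zeros(len(query), dtype=bool)
    for chrom, tsub in targets.groupby("chrom"):
        qmask = (query["chrom"] == chrom).to_numpy()
        if not qmask.any():
            continue
        qs = query.loc[qmask, "start"].to_numpy()
        qe = query.loc[qmask, "end"].to_numpy()
        ts = tsub["start"].to_numpy()
        te = tsub["end"].to_numpy()
        sub_hit = np.zeros(qmask.sum(), dtype=bool)
        for s, e in zip(ts, te):
            sub_hit |= (qs < e) & (qe > s)
        hit[np.flatnonzero(qmask)] = sub_hit
    return hit


def build_enhancer_regions(
    ccres: pd.DataFrame,
    tss_windows: WindowSet,
    consensus_peaks: pd.DataFrame,
    peak_gene_links: pd.DataFrame | None = None,
    size: int = 1000,
) -> WindowSet:
    """cCRE-derived 1-kb enhancer regions away from promoters.

    cCREs overlapping any TSS window are filtered out; survivors are
    merged, recentered to 1 kb and re-merged; regions without a
    consensus-peak overlap are discarded. Genes are assigned from
    overlapping ``peak_gene_links`` intervals (chrom/start/end/gene),
    joined with ';' when several apply.
    """
    if ccres.empty:
        warnings.warn("empty cCRE input: no enhancer regions built")
        return WindowSet(
            intervals=pd.DataFrame(columns=["chrom", "start", "end", "gene", "provenance"]),
            kind="enhancer",
        )
    ccres = ccres.copy().reset_index(drop=True)
    if "name" not in ccres:
        ccres["name"] = [f"ccre{i}" for i in range(len(ccres))]
    keep = ~_overlaps_any(ccres, tss_windows.intervals)
    surv = ccres.loc[keep].copy()
    surv["provenance"] = [[n] for n in surv["name"]]
    surv["strand"] = "."
    merged = _merge_intervals(surv, by_strand=False)
    resized = _recenter_1kb(merged, size=size)
    final = _merge_intervals(resized, by_strand=False).reset_index(drop=True)
    final = final.loc[_overlaps_any(final, consensus_peaks)].reset_index(drop=True)

    genes = []
    for row in final.itertuples(index=False):
        assigned = ""
        if peak_gene_links is not None and not peak_gene_links.empty:
            sub = peak_gene_links[peak_gene_links["chrom"] == row.chrom]
            ov = sub[(sub["start"] < row.end) & (sub["end"] > row.start)]
            assigned = ";".join(sorted(ov["gene"].unique()))
        genes.append(assigned)
    final["gene"] = genes
    return WindowSet(intervals=final[["chrom", "start", "end", "gene", "provenance"]], kind="enhancer")


def count_regions(fragments: dict[str, pd.DataFrame], regions: WindowSet) -> pd.DataFrame:
    """Integer table of fragments overlapping (>= 1 bp) each region.

    A fragment spanning two regions is counted in both.
    """
    idx = pd.Index(
        [f"{r.chrom}:{r.start}-{r.end}" for r in regions.intervals.itertuples(index=False)],
        name="region",
    )
    out = pd.DataFrame(0, index=idx, columns=list(fragments), dtype=np.int64)
    for sample, frag in fragments.items():
        for i, r in enumerate(regions.intervals.itertuples(index=False)):
            sub = frag[frag["chrom"] == r.chrom]
            n = int(((sub["start"] < r.end) & (sub["end"] > r.start)).sum())
            out.iloc[i, out.columns.get_loc(sample)] = n
    return out


def tmm_nb_lrt(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    condition_col: str = "condition",
    batch_col: str | None = "replicate",
) -> pd.DataFrame:
    """TMM-normalized NB GLM with a likelihood-ratio test for one contrast.

    Library sizes x TMM factors enter as offsets; a common dispersion is
    profiled first and per-feature estimates are shrunk toward it. Returns
    per-feature logFC (log2, numerator vs denominator), p and BH FDR.
    All-zero features are skipped (NaN results).
    """
    num, den = contrast
    meta = meta.loc[counts.columns]
    for lv in (num, den):
        if (meta[condition_col] == lv).sum() < 2:
            raise ValueError(f"condition {lv!r} has fewer than 2 replicates")
    nonzero = counts.sum(axis=1) > 0
    Y = counts.loc[nonzero].to_numpy()

    lib = counts.sum(axis=0).to_numpy(dtype=float)
    nf = nbglm.tmm_norm_factors(counts.to_numpy())
    offset = np.log(lib * nf)

    covs = [batch_col] if batch_col else []
    X_full, names = nbglm.build_design(meta, condition_col, reference=den, covariate_cols=covs)
    a_col = names.index(f"{condition_col}_{num}")
    X_reduced = np.delete(X_full, a_col, axis=1)
    lfc_vec = np.zeros(X_full.shape[1])
    lfc_vec[a_col] = 1.0

    common = nbglm.common_dispersion(Y, X_full, offset)
    sf = lib * nf
    sf = sf / np.exp(np.mean(np.log(sf)))
    disp = nbglm.tagwise_dispersion(Y, sf, meta[condition_col].to_numpy(), common)
    res = nbglm.nb_lrt_contrast(Y, X_full, X_reduced, offset, disp, lfc_vec)
    res.index = counts.index[nonzero]
    return res.reindex(counts.index)


@dataclass
class MemoryThresholds:
    rna_p: float = 0.05
    rna_fdr: float = 0.05
    atac_abs_logfc: float = 0.5
    atac_fdr: float = 0.05


def classify_memory(
    rna_dose1_vs_ctrl: pd.DataFrame,
    atac_dose1_vs_washout: pd.DataFrame,
    rna_dose2_vs_dose1: pd.DataFrame | None = None,
    region_genes: pd.Series | None = None,
    thresholds: MemoryThresholds | None = None,
    require_all_regions: bool = True,
) -> pd.DataFrame:
    """Gate epigenetic-memory genes from paired bulk statistics.

    memory = upregulated on dose 1 (RNA) AND accessibility stable between
    dose1+0h and washout (ATAC). ``region_genes`` maps ATAC region ids to
    gene ids; with several regions per gene, stability requires all of
    them (or any, when ``require_all_regions`` is False).
    """
    t = thresholds if thresholds is not None else MemoryThresholds()
    rna1 = rna_dose1_vs_ctrl
    up1 = (rna1["logFC"] > 0) & (rna1["p"] < t.rna_p) & (rna1["fdr"] < t.rna_fdr)

    atac = atac_dose1_vs_washout.copy()
    stable_region = (atac["logFC"].abs() < t.atac_abs_logfc) & (atac["fdr"] > t.atac_fdr)
    if region_genes is not None:
        stable_by_gene = stable_region.groupby(region_genes.reindex(atac.index)).agg(
            "all" if require_all_regions else "any"
        )
    else:
        stable_by_gene = stable_region  # regions already indexed by gene
    stable = stable_by_gene.reindex(rna1.index).fillna(False).astype(bool)

    out = pd.DataFrame(index=rna1.index)
    out["up_on_dose1"] = up1
    out["accessibility_stable_after_washout"] = stable
    out["memory"] = up1 & stable
    if rna_dose2_vs_dose1 is not None:
        r2 = rna_dose2_vs_dose1.reindex(rna1.index)
        weak = (r2["logFC"] > 0) & (r2["p"] < t.rna_p)
        strong = weak & (r2["fdr"] < t.rna_fdr)
        out["further_up_on_dose2"] = (weak & out["memory"]).fillna(False)
        out["asterisk"] = (strong & out["memory"]).fillna(False)
    return out
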