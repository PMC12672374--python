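"""Correlation-based peak-gene linking, enhancer/DORC scoring and
normalized genome-track binning.

A peak is linked to a gene when its center lies within a window of the
gene's TSS, it is detected in enough cells, and its normalized
accessibility correlates positively (Pearson, two-sided t-test on r with
df = n - 2) with the gene's normalized expression. Genes linked to at
least five peaks within 50 kb qualify as DORCs (domains of regulatory
chromatin) and are re-linked on a 500-kb window; the per-cell DORC score
aggregates fragments in a gene's linked peaks as a fraction of the cell's
total in-peak fragments, scaled by 10,000.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import NormalizedMatrix

logger = logging.getLogger(__name__)

LINK_COLUMNS = ["peak", "gene", "r", "p", "padj", "distance", "window"]


def _dense_rows(mat, idx) -> np.ndarray:
    sub = mat[idx] if not sp.issparse(mat) else mat[idx].toarray()
    return np.asarray(sub, dtype=float)


def link_peaks(
    expr: NormalizedMatrix,
    access: NormalizedMatrix,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    max_dist: int = 50_000,
    min_cells: int = 10,
    p_max: float = 0.05,
    padj_max: float | None = None,
    window_tag: str | None = None,
) -> pd.DataFrame:
    """Positive, significant peak-gene correlations within ``max_dist`` of
    the TSS. Returns a frame with LINK_COLUMNS; ``distance`` is the signed
    offset of the peak center from the TSS.

    BH adjustment is computed across every tested pair; links must satisfy
    r > 0 and p < p_max, and additionally padj < padj_max when given.
    """
    if not expr.cells.equals(access.cells):
        raise ValueError("expression and accessibility matrices cover different cells")
    n = len(expr.cells)
    if window_tag is None:
        window_tag = f"{max_dist // 1000}kb"

    center = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    pchrom = peaks["chrom"].to_numpy()
    acc = access.values.tocsr() if sp.issparse(access.values) else np.asarray(access.values)
    n_nonzero = (
        np.asarray((access.values != 0).sum(axis=1)).ravel()
        if sp.issparse(access.values)
        else (np.asarray(access.values) != 0).sum(axis=1)
    )

    # per-peak moments for the correlation
    if sp.issparse(access.values):
        pk_mean = np.asarray(access.values.mean(axis=1)).ravel()
        pk_sq = np.asarray(access.values.multiply(access.values).mean(axis=1)).ravel()
    else:
        A = np.asarray(access.values, dtype=float)
        pk_mean = A.mean(axis=1)
        pk_sq = (A * A).mean(axis=1)
    pk_var = np.maximum(pk_sq - pk_mean**2, 0.0)

    recs: list[tuple] = []
    df = n - 2
    for g in genes.index:
        if g not in expr.features:
            continue
        grow = genes.loc[g]
        tss = int(grow["tss"])
        cand = np.flatnonzero(
            (pchrom == grow["chrom"]) & (np.abs(center - tss) <= max_dist)
        )
        cand = cand[n_nonzero[cand] >= min_cells]
        if len(cand) == 0:
            continue
        x = expr.row(g)
        xm = x.mean()
        xs = x.std()
        if xs == 0:
            logger.info("gene %s constant; skipping its candidate pairs", g)
            continue
        Y = _dense_rows(acc, cand)
        ym = pk_mean[cand]
        ys = np.sqrt(pk_var[cand])
        ok = ys > 0
        if not ok.all():
            for pid in peaks.index[cand[~ok]]:
                logger.info("peak %s constant; pair with %s skipped", pid, g)
        cov = (Y - ym[:, None]) @ (x - xm) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(ok, cov / (ys * xs), np.nan)
        r = np.clip(r, -0.9999999, 0.9999999)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        for j, ci in enumerate(cand):
            if not ok[j]:
                continue
            recs.append(
                (peaks.index[ci], g, float(r[j]), float(p[j]), center[ci] - tss)
            )

    tested = pd.DataFrame(recs, columns=["peak", "gene", "r", "p", "distance"])
    if tested.empty:
        return pd.DataFrame(columns=LINK_COLUMNS)
    tested["padj"] = multipletests(tested["p"], method="fdr_bh")[1]
    keep = (tested["r"] > 0) & (tested["p"] < p_max)
    if padj_max is not None:
        keep &= tested["padj"] < padj_max
    out = tested.loc[keep].copy()
    out["window"] = window_tag
    return out[LINK_COLUMNS].reset_index(drop=True)


def enhancer_score(
    atac_counts,
    peaks: pd.Index,
    cells: pd.Index,
    links: pd.DataFrame,
    scale_factor: float = 10_000.0,
) -> tuple[NormalizedMatrix, pd.Index]:
    """Per-cell, per-gene linked-fragment score.

    score(gene, cell) = fragments in the gene's linked peaks
                        / total in-peak fragments of the cell * scale.
    Returns the score matrix over the linked genes and the index of cells
    flagged for having zero in-peak fragments (their scores are NaN).
    """
    counts = atac_counts.tocsr() if sp.issparse(atac_counts) else sp.csr_matrix(np.asarray(atac_counts))
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    flagged = pd.Index(cells)[total == 0]
    peak_pos = {p: i for i, p in enumerate(peaks)}
    gene_ids = pd.Index(sorted(links["gene"].unique()))
    rows, cols = [], []
    for gi, g in enumerate(gene_ids):
        for p in links.loc[links["gene"] == g, "peak"]:
            rows.append(gi)
            cols.append(peak_pos[p])
    indicator = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(gene_ids), len(peaks))
    )
    agg = np.asarray((indicator @ counts).todense(), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(total > 0, agg / total * scale_factor, np.nan)
    nm = NormalizedMatrix(
        values=vals, features=gene_ids, cells=pd.Index(cells),
        method="lognorm", scale_factor=scale_factor,
    )
    return nm, flagged


@dataclass
class DorcTable:
    """Link sets, DORC flags and the per-cell DORC score matrix."""

    links: pd.DataFrame  # expanded-window links of qualifying genes
    n_links_50kb: pd.Series  # per gene, links within the 50-kb window
    dorc_genes: pd.Index
    scores: NormalizedMatrix | None = None
    flagged_cells: pd.Index = field(default_factory=lambda: pd.Index([]))


def define_dorcs(
    links_50kb: pd.DataFrame,
    expr: NormalizedMatrix,
    access: NormalizedMatrix,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    atac_counts=None,
    min_links: int = 5,
    expanded_dist: int = 500_000,
    min_cells: int = 10,
    p_max: float = 0.05,
    padj_max: float | None = None,
    union_with_50kb: bool = False,
) -> DorcTable:
    """Genes with >= ``min_links`` links at 50 kb, re-linked at
    ``expanded_dist`` and scored with :func:`enhancer_score`."""
    n_links = links_50kb.groupby("gene").size()
    qualifying = pd.Index(sorted(n_links[n_links >= min_links].index))
    if len(qualifying) == 0:
        warnings.warn("no genes qualify as DORCs")
        return DorcTable(
            links=pd.DataFrame(columns=LINK_COLUMNS),
            n_links_50kb=n_links,
            dorc_genes=qualifying,
        )
    expanded = link_peaks(
        expr,
        access,
        peaks,
        genes.loc[qualifying],
        max_dist=expanded_dist,
        min_cells=min_cells,
        p_max=p_max,
        padj_max=padj_max,
        window_tag=f"{expanded_dist // 1000}kb",
    )
    if union_with_50kb:
        near = links_50kb[links_50kb["gene"].isin(qualifying)]
        expanded = (
            pd.concat([expanded, near], ignore_index=True)
            .drop_duplicates(subset=["peak", "gene"], keep="first")
            .reset_index(drop=True)
        )
    scores, flagged = (None, pd.Index([]))
    if atac_counts is not None and not expanded.empty:
        scores, flagged = enhancer_score(atac_counts, peaks.index, access.cells, expanded)
    return DorcTable(
        links=expanded,
        n_links_50kb=n_links,
        dorc_genes=qualifying,
        scores=scores,
        flagged_cells=flagged,
    )


def binned_track(
    atac_counts,
    peaks: pd.DataFrame,
    group_cols: np.ndarray,
    bin_size: int = 100,
    variant: str = "bigwig",
    scale_factor: float = 10_000.0,
) -> pd.DataFrame:
    """Aggregate a cell group's peak counts onto fixed genomic bins.

    Peak counts are spread over the 100-bp bins a peak overlaps,
    proportionally to overlap length. ``variant="bigwig"`` divides by the
    group's total fragments and multiplies by ``scale_factor``;
    ``variant="track"`` divides by n_cells x mean depth (which equals the
    group total). Returns bedGraph records (chrom, start, end, value) for
    nonzero bins.
    """
    group_cols = np.asarray(group_cols)
    if group_cols.size == 0:
        raise ValueError("empty cell group")
    counts = atac_counts.tocsc() if sp.issparse(atac_counts) else sp.csc_matrix(np.asarray(atac_counts))
    agg = np.asarray(counts[:, group_cols].sum(axis=1)).ravel().astype(float)
    total = agg.sum()
    if total == 0:
        raise ValueError("cell group has no fragments")
    if variant == "bigwig":
        norm = scale_factor / total
    elif variant == "track":
        norm = 1.0 / total  # n_cells * mean depth == group total fragments
    else:
        raise ValueError(f"unknown track variant {variant!r}")

    acc: dict[tuple[str, int], float] = {}
    for val, (chrom, start, end) in zip(
        agg, peaks[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if val == 0:
            continue
        length = end - start
        b0 = start // bin_size
        b1 = (end - 1) // bin_size
        for b in range(b0, b1 + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            key = (chrom, b)
            acc[key] = acc.get(key, 0.0) + val * (hi - lo) / length
    recs = [
        (chrom, b * bin_size, (b + 1) * bin_size, v * norm)
        for (chrom, b), v in sorted(acc.items())
    ]
    return pd.DataFrame(recs, columns=["chrom", "start", "end", "value"])
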