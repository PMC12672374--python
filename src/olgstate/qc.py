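"""Cell filtering, FRiP, log-normalization, TF-IDF, gene activity and
variable-feature selection.

Normalization conventions: RNA and gene-activity matrices are depth
normalized to a fixed scale factor (default 10,000) and natural-log
transformed; peak counts are TF-IDF normalized on the same scale.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import MultiomeDataset, NormalizedMatrix

DEFAULT_SCALE_FACTOR = 10_000.0
_AUTO_QUANTILES = (0.01, 0.99)  # per-sample outlier bounds in "auto" mode


@dataclass
class QcThresholds:
    """Per-sample cell-filtering bounds; each may be a number, ``"auto"``
    (1st/99th percentile within the sample) or None (not applied)."""

    min_rna_counts: object = None
    max_rna_counts: object = None
    min_atac_counts: object = None
    max_atac_counts: object = None
    min_genes_detected: object = None
    max_genes_detected: object = None
    min_tss_enrichment: object = None
    max_pct_mito: object = None

    def validate(self) -> None:
        for lo_name, hi_name in (
            ("min_rna_counts", "max_rna_counts"),
            ("min_atac_counts", "max_atac_counts"),
            ("min_genes_detected", "max_genes_detected"),
        ):
            lo, hi = getattr(self, lo_name), getattr(self, hi_name)
            if isinstance(lo, (int, float)) and isinstance(hi, (int, float)) and lo > hi:
                raise ValueError(f"{lo_name} > {hi_name}")


def _cell_metrics(dataset: MultiomeDataset) -> pd.DataFrame:
    m = pd.DataFrame(index=dataset.cells.index)
    m["rna_counts"] = np.asarray(dataset.rna.sum(axis=0)).ravel()
    m["atac_counts"] = np.asarray(dataset.atac.sum(axis=0)).ravel()
    m["genes_detected"] = np.asarray((dataset.rna > 0).sum(axis=0)).ravel()
    if "pct_mito" in dataset.cells:
        m["pct_mito"] = dataset.cells["pct_mito"]
    if "tss_enrichment" in dataset.cells:
        m["tss_enrichment"] = dataset.cells["tss_enrichment"]
    return m


def filter_cells(
    dataset: MultiomeDataset, thresholds: QcThresholds
) -> tuple[MultiomeDataset, pd.DataFrame]:
    """Remove per-sample count/feature outliers.

    Returns the filtered dataset and a report with one row per
    (sample, metric, bound) carrying the resolved numeric threshold and the
    number of cells it removed. Re-running with the resolved numeric
    thresholds is the identity; ``"auto"`` bounds are quantiles of the
    input population and should be resolved once.
    """
    thresholds.validate()
    metrics = _cell_metrics(dataset)
    samples = dataset.cells["sample"]
    keep = pd.Series(True, index=dataset.cells.index)
    report_rows = []

    spec = [
        ("rna_counts", thresholds.min_rna_counts, thresholds.max_rna_counts),
        ("atac_counts", thresholds.min_atac_counts, thresholds.max_atac_counts),
        ("genes_detected", thresholds.min_genes_detected, thresholds.max_genes_detected),
        ("tss_enrichment", thresholds.min_tss_enrichment, None),
        ("pct_mito", None, thresholds.max_pct_mito),
    ]
    for sample in samples.unique():
        in_sample = samples == sample
        for metric, lo, hi in spec:
            if metric not in metrics:
                continue
            vals = metrics.loc[in_sample, metric]
            for bound, side in ((lo, "min"), (hi, "max")):
                if bound is None:
                    continue
                if bound == "auto":
                    q = _AUTO_QUANTILES[0] if side == "min" else _AUTO_QUANTILES[1]
                    resolved = float(vals.quantile(q))
                else:
                    resolved = float(bound)
                bad = vals < resolved if side == "min" else vals > resolved
                keep.loc[bad[bad].index] = False
                report_rows.append((sample, metric, side, resolved, int(bad.sum())))

    report = pd.DataFrame(
        report_rows, columns=["sample", "metric", "bound", "threshold", "n_removed"]
    )
    for sample in samples.unique():
        if not keep[samples == sample].any():
            warnings.warn(f"all cells of sample {sample!r} removed; sample dropped")
    return dataset.subset_cells(keep.to_numpy()), report


def frip(
    dataset: MultiomeDataset, total_column: str = "atac_fragments_total"
) -> tuple[pd.Series, pd.Series]:
    """Fraction of fragments in peaks per cell, plus per-sample means.

    Cells with zero total fragments get NaN and are flagged via the NaN
    itself; they are excluded from the per-sample means.
    """
    in_peaks = np.asarray(dataset.atac.sum(axis=0)).ravel().astype(float)
    if total_column in dataset.cells:
        total = dataset.cells[total_column].to_numpy(dtype=float)
    else:
        total = in_peaks.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, in_peaks / total, np.nan)
    per_cell = pd.Series(frac, index=dataset.cells.index, name="frip")
    per_sample = per_cell.groupby(dataset.cells["sample"]).mean()
    return per_cell, per_sample


def _colsums(counts) -> np.ndarray:
    return np.asarray(counts.sum(axis=0)).ravel().astype(float)


def lognormalize(
    counts, features, cells, scale_factor: float = DEFAULT_SCALE_FACTOR,
    method: str = "lognorm",
) -> NormalizedMatrix:
    """value = ln(1 + count / column_sum * scale_factor); zeros preserved."""
    counts = counts.tocsc() if sp.issparse(counts) else sp.csc_matrix(np.asarray(counts))
    colsum = _colsums(counts)
    if (colsum == 0).any():
        offenders = pd.Index(cells)[colsum == 0]
        raise ValueError(f"cells with zero total counts: {list(offenders[:10])}")
    x = counts.astype(float).copy()
    # scale columns in CSC storage, then log1p on the nonzeros only
    x.data = x.data * np.repeat(scale_factor / colsum, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        values=x.tocsr(), features=pd.Index(features), cells=pd.Index(cells),
        method=method, scale_factor=scale_factor,
    )


def tfidf(
    counts, peaks, cells, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> NormalizedMatrix:
    """log(TF x IDF) peak normalization: TF = count / cell total,
    IDF = n_cells / n_cells_with_peak, value = ln(1 + TF*IDF*scale)."""
    counts = counts.tocsr() if sp.issparse(counts) else sp.csr_matrix(np.asarray(counts))
    colsum = _colsums(counts)
    if (colsum == 0).any():
        offenders = pd.Index(cells)[colsum == 0]
        raise ValueError(f"cells with zero total counts: {list(offenders[:10])}")
    n_with = np.asarray((counts > 0).sum(axis=1)).ravel()
    if (n_with == 0).any():
        offenders = pd.Index(peaks)[n_with == 0]
        raise ValueError(f"peaks absent from every cell: {list(offenders[:10])}")
    n_cells = counts.shape[1]
    idf = n_cells / n_with
    x = counts.astype(float).tocsc()
    x.data = x.data * np.repeat(scale_factor / colsum, np.diff(x.indptr))
    x = x.tocsr()
    x.data = x.data * np.repeat(idf, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        values=x, features=pd.Index(peaks), cells=pd.Index(cells),
        method="tfidf", scale_factor=scale_factor,
    )


def gene_activity_regions(genes: pd.DataFrame, upstream: int = 500) -> pd.DataFrame:
    """Gene body extended ``upstream`` bp past the TSS, strand-aware."""
    regions = genes[["chrom", "start", "end", "strand"]].copy()
    if regions["strand"].isna().any() or (~regions["strand"].isin(["+", "-"])).any():
        bad = regions.index[~regions["strand"].isin(["+", "-"])]
        raise ValueError(f"genes missing strand: {list(bad[:10])}")
    plus = regions["strand"] == "+"
    regions.loc[plus, "start"] = (regions.loc[plus, "start"] - upstream).clip(lower=0)
    regions.loc[~plus, "end"] = regions.loc[~plus, "end"] + upstream
    return regions


def gene_activity(
    dataset: MultiomeDataset,
    upstream: int = 500,
    scale_factor: float = DEFAULT_SCALE_FACTOR,
) -> NormalizedMatrix:
    """Per-gene accessibility: summed counts of peaks overlapping the gene
    body plus ``upstream`` bp beyond the TSS, then log-normalized."""
    regions = gene_activity_regions(dataset.genes, upstream=upstream)
    peaks = dataset.peaks
    rows, cols = [], []
    for chrom, sub in regions.groupby("chrom", sort=False):
        p = peaks[peaks["chrom"] == chrom]
        if p.empty:
            continue
        ps = p["start"].to_numpy()
        pe = p["end"].to_numpy()
        p_idx = peaks.index.get_indexer(p.index)
        g_idx = regions.index.get_indexer(sub.index)
        for gi, (rs, re) in zip(g_idx, zip(sub["start"], sub["end"])):
            hit = (ps < re) & (pe > rs)  # 0-based half-open overlap
            for pj in p_idx[hit]:
                rows.append(gi)
                cols.append(pj)
    indicator = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(regions), len(peaks))
    )
    activity_counts = indicator @ dataset.atac
    # cells may have zero activity counts even with nonzero peak totals;
    # normalize against the per-cell total of the activity matrix itself,
    # treating empty cells as all-zero columns rather than erroring
    colsum = np.asarray(activity_counts.sum(axis=0)).ravel().astype(float)
    safe = np.where(colsum > 0, colsum, 1.0)
    x = activity_counts.astype(float).tocsc()
    x.data = x.data * np.repeat(scale_factor / safe, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        values=x.tocsr(), features=dataset.genes.index, cells=dataset.cells.index,
        method="geneactivity-lognorm", scale_factor=scale_factor,
    )


def select_variable_features(
    rna_counts,
    genes,
    n: int = 2000,
    atac_counts=None,
    peaks=None,
    peak_quantile: float = 0.95,
    loess_frac: float = 0.3,
):
    """Top-``n`` genes by variance-stabilized standardized variance, plus
    all peaks at or above the (1 - peak_quantile) commonness floor.

    The gene ranking follows the usual VST recipe: a lowess trend of
    log10(variance) on log10(mean) predicts each gene's expected standard
    deviation; counts standardized with that expectation (clipped at
    sqrt(n_cells)) are re-scored by their variance.
    """
    genes = pd.Index(genes)
    if n > len(genes):
        raise ValueError(f"n={n} exceeds {len(genes)} genes")
    X = rna_counts.tocsr() if sp.issparse(rna_counts) else sp.csr_matrix(np.asarray(rna_counts))
    n_cells = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = (sq - mean**2) * n_cells / max(n_cells - 1, 1)

    expected_sd = np.sqrt(np.maximum(var, 1e-12))
    nz = (mean > 0) & (var > 0)
    if nz.sum() >= 3:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        lx = np.log10(mean[nz])
        ly = np.log10(var[nz])
        fit = lowess(ly, lx, frac=loess_frac, return_sorted=True)
        pred = np.interp(np.log10(np.maximum(mean, 1e-12)), fit[:, 0], fit[:, 1])
        expected_sd = np.sqrt(10**pred)

    clip = np.sqrt(n_cells)
    std_var = np.zeros(len(genes))
    Xc = X.tocsr()
    for i in np.flatnonzero(nz):
        row = np.zeros(n_cells)
        sl = slice(Xc.indptr[i], Xc.indptr[i + 1])
        row[Xc.indices[sl]] = Xc.data[sl]
        z = np.clip((row - mean[i]) / expected_sd[i], -clip, clip)
        std_var[i] = z.var(ddof=1)
    order = np.argsort(-std_var, kind="stable")
    top_genes = genes[order[:n]]

    selected_peaks = None
    if atac_counts is not None:
        peaks = pd.Index(peaks)
        A = atac_counts.tocsr() if sp.issparse(atac_counts) else sp.csr_matrix(np.asarray(atac_counts))
        presence = np.asarray((A > 0).sum(axis=1)).ravel()
        floor = np.quantile(presence, 1.0 - peak_quantile)
        selected_peaks = peaks[presence >= floor]
    return top_genes, selected_peaks


def standardize(norm: NormalizedMatrix, clip: float = 10.0) -> NormalizedMatrix:
    """Center each feature and scale to unit sample s.d.; constant rows
    map to zero; values are clipped at +-``clip`` after scaling."""
    x = norm.dense().astype(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(x)
    ok = (sd > 0).ravel()
    out[ok] = (x[ok] - mu[ok]) / sd[ok]
    if clip is not None:
        out = np.clip(out, -clip, clip)
    return NormalizedMatrix(
        values=out, features=norm.features, cells=norm.cells,
        method="standardized", scale_factor=norm.scale_factor,
    )
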