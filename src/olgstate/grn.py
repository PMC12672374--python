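"""Regression-based gene regulatory network and TF activity ranking.

Each target gene's normalized expression is modeled by ordinary least
squares on (TF expression x peak accessibility) product predictors, one per
admissible (peak, TF) pair: the peak must carry the TF's motif and be
assigned (nearest TSS) to the target. A TF's activity at a time point is
the mean of its fitted coefficients across retained targets multiplied by
its mean expression at that time point; TFs are ranked per time point by
the highest positive activity.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NormalizedMatrix
from .nbglm import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GrnModel:
    coefficients: pd.DataFrame  # target, tf, peak, coefficient
    model_stats: pd.DataFrame  # index target: r2, p, padj, n_predictors
    cells_used: pd.Index


def assign_peaks_to_genes(
    candidate_peaks: pd.Index, peaks: pd.DataFrame, genes: pd.DataFrame
) -> pd.Series:
    """Nearest-TSS gene per peak (upstream or downstream; ties break on the
    lexicographically smallest gene id)."""
    out = {}
    for chrom, gsub in genes.groupby("chrom", sort=False):
        tss = gsub["tss"].to_numpy()
        order = np.lexsort((gsub.index.to_numpy(), tss))
        tss_sorted = tss[order]
        ids_sorted = gsub.index.to_numpy()[order]
        psub = peaks.loc[peaks.index.intersection(candidate_peaks)]
        psub = psub[psub["chrom"] == chrom]
        centers = ((psub["start"] + psub["end"]) // 2).to_numpy()
        for pid, c in zip(psub.index, centers):
            d = np.abs(tss_sorted - c)
            best = np.min(d)
            cand = np.flatnonzero(d == best)
            out[pid] = min(ids_sorted[cand])
    return pd.Series(out, name="gene")


def subsample_cells(
    cells_meta: pd.DataFrame, max_cells_per_timepoint: int = 2000, seed: int = 0
) -> pd.Index:
    rng = np.random.default_rng(seed)
    keep = []
    for tp, idx in cells_meta.groupby("timepoint").groups.items():
        idx = pd.Index(idx)
        if len(idx) > max_cells_per_timepoint:
            chosen = rng.choice(len(idx), size=max_cells_per_timepoint, replace=False)
            idx = idx[np.sort(chosen)]
        keep.append(idx)
    return pd.Index(np.concatenate([k.to_numpy() for k in keep]))


def fit_grn(
    expr: NormalizedMatrix,
    access: NormalizedMatrix,
    candidate_regions: pd.Index,
    motifs: pd.DataFrame,
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    cells_meta: pd.DataFrame,
    max_cells_per_timepoint: int = 2000,
    seed: int = 0,
) -> GrnModel:
    """Fit per-target OLS models on (TF expression x peak accessibility)
    products over a seeded per-time-point cell subsample."""
    cells = subsample_cells(cells_meta.loc[expr.cells], max_cells_per_timepoint, seed)
    e = expr.subset_cells(cells)
    a = access.subset_cells(cells)
    n = len(cells)

    peak_gene = assign_peaks_to_genes(pd.Index(candidate_regions), peaks, genes)
    motif_by_peak = motifs.groupby("peak")["tf"].apply(list).to_dict()
    feat_set = set(e.features)

    pairs_by_target: dict[str, list[tuple[str, str]]] = {}
    for pid, g in peak_gene.items():
        for tf in motif_by_peak.get(pid, []):
            if tf in feat_set and tf != g and g in feat_set:
                pairs_by_target.setdefault(g, []).append((tf, pid))

    coef_recs, stat_recs = [], []
    for target, pairs in sorted(pairs_by_target.items()):
        y = e.row(target)
        cols, kept = [], []
        seen = set()
        for tf, pid in pairs:
            x = e.row(tf) * a.row(pid)
            key = x.tobytes()
            if key in seen:
                warnings.warn(f"duplicate predictor for {target}: ({tf},{pid}) dropped")
                continue
            seen.add(key)
            cols.append(x)
            kept.append((tf, pid))
        if not cols:
            logger.info("target %s: no admissible (peak, TF) pairs", target)
            continue
        X = np.column_stack([np.ones(n)] + cols)
        p_pred = X.shape[1] - 1
        if n <= p_pred + 1:
            logger.info("target %s skipped: more predictors than cells", target)
            continue
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss_ = np.sum((y - y.mean()) ** 2)
        rss = np.sum(resid**2)
        r2 = 1.0 - rss / tss_ if tss_ > 0 else 0.0
        dof = n - p_pred - 1
        if r2 >= 1.0 or p_pred == 0:
            p_model = 0.0
        else:
            f = (r2 / p_pred) / ((1.0 - r2) / dof)
            p_model = float(stats.f.sf(f, p_pred, dof))
        for (tf, pid), b in zip(kept, beta[1:]):
            coef_recs.append((target, tf, pid, float(b)))
        stat_recs.append((target, float(r2), p_model, p_pred))

    coefs = pd.DataFrame(coef_recs, columns=["target", "tf", "peak", "coefficient"])
    stats_df = pd.DataFrame(stat_recs, columns=["target", "r2", "p", "n_predictors"]).set_index("target")
    stats_df["padj"] = bh_adjust(stats_df["p"].to_numpy()) if len(stats_df) else []
    return GrnModel(coefficients=coefs, model_stats=stats_df, cells_used=cells)


def select_modules(model: GrnModel, alpha: float = 0.05) -> pd.DataFrame:
    """(TF, target) records for targets whose model fit has padj < alpha."""
    retained = model.model_stats.index[model.model_stats["padj"] < alpha]
    mods = model.coefficients[model.coefficients["target"].isin(retained)]
    return mods.sort_values(["tf", "target"]).reset_index(drop=True)


def tf_activity(
    model: GrnModel,
    expr: NormalizedMatrix,
    cells_meta: pd.DataFrame,
    alpha: float = 0.05,
    retained_only: bool = True,
) -> pd.DataFrame:
    """activity(TF, t) = mean coefficient over the TF's (retained) targets
    x mean normalized TF expression at time point t. Returns a long frame
    (tf, timepoint, activity, rank); rank 1 is the most positive activity."""
    mods = select_modules(model, alpha) if retained_only else model.coefficients
    if mods.empty:
        return pd.DataFrame(columns=["tf", "timepoint", "activity", "rank"])
    mean_coef = mods.groupby("tf")["coefficient"].mean()
    meta = cells_meta.loc[expr.cells]
    recs = []
    for tf, mc in mean_coef.items():
        if tf not in expr.features:
            warnings.warn(f"TF {tf} absent from expression matrix; excluded")
            continue
        x = pd.Series(expr.row(tf), index=expr.cells)
        for tp, idx in meta.groupby("timepoint").groups.items():
            recs.append((tf, tp, mc * float(x.loc[pd.Index(idx)].mean())))
    out = pd.DataFrame(recs, columns=["tf", "timepoint", "activity"])
    out["rank"] = (
        out.groupby("timepoint")["activity"].rank(ascending=False, method="first").astype(int)
    )
    return out.sort_values(["timepoint", "rank"]).reset_index(drop=True)
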