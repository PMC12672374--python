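"""Pseudobulk aggregation and NB-GLM differential testing across disease
stages, with Type 1-4 temporal classification.

Counts are summed per (sample, cell type); each cell type is tested
independently with a negative-binomial Wald test (median-of-ratios size
factors, trend-shrunk dispersions) over the four stage contrasts
early/control, peak/early, late/early and peak/late, and differential
features are classified by the stage of their maximal 0-1-scaled mean.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import nbglm
from .datatypes import MultiomeDataset

logger = logging.getLogger(__name__)

STAGE_ORDER = ("control", "early", "peak", "late")
DEFAULT_CONTRASTS = (
    ("early", "control"),
    ("peak", "early"),
    ("late", "early"),
    ("peak", "late"),
)
TYPE_OF_STAGE = {"control": 1, "early": 2, "peak": 3, "late": 4}


@dataclass
class PseudobulkMatrix:
    """Aggregated integer counts (features x groups) plus group metadata."""

    counts: pd.DataFrame
    groups: pd.DataFrame  # index = group id; sample, cell_type, timepoint, replicate, n_cells, covariates
    dropped_features: pd.Index = field(default_factory=lambda: pd.Index([]))

    def subset_cell_type(self, cell_type: str) -> "PseudobulkMatrix":
        keep = self.groups["cell_type"] == cell_type
        return PseudobulkMatrix(
            counts=self.counts.loc[:, keep.to_numpy()],
            groups=self.groups.loc[keep],
            dropped_features=self.dropped_features,
        )


def aggregate(
    dataset: MultiomeDataset,
    modality: str = "rna",
    group_keys: tuple[str, ...] = ("sample", "cell_type"),
    min_feature_counts: int = 10,
    covariate_cols: tuple[str, ...] = (),
    counts=None,
    features=None,
) -> PseudobulkMatrix:
    """Exact per-group column sums; features below ``min_feature_counts``
    total are removed (with a log entry). ``timepoint`` is mapped so the
    CFA adjuvant control becomes the "control" stage."""
    if counts is None:
        counts = dataset.rna if modality == "rna" else dataset.atac
        features = dataset.genes.index if modality == "rna" else dataset.peaks.index
    counts = counts.tocsc() if sp.issparse(counts) else sp.csc_matrix(np.asarray(counts))
    meta = dataset.cells
    for k in group_keys:
        if k not in meta:
            raise ValueError(f"group key {k!r} absent from cell metadata")
    key = meta[list(group_keys)].astype(str).agg("|".join, axis=1)
    if key.empty:
        raise ValueError("empty grouping: no cells")

    group_ids = pd.Index(pd.unique(key))
    cols = []
    rows = []
    for gid in group_ids:
        idx = np.flatnonzero((key == gid).to_numpy())
        cols.append(np.asarray(counts[:, idx].sum(axis=1)).ravel())
        first = meta.iloc[idx[0]]
        rec = {k: first[k] for k in group_keys}
        for c in covariate_cols:
            rec[c] = first[c]
        rec["timepoint"] = first.get("timepoint", None)
        rec["replicate"] = first.get("replicate", None)
        rec["n_cells"] = len(idx)
        rows.append(rec)
    mat = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=pd.Index(features), columns=group_ids
    )
    groups = pd.DataFrame(rows, index=group_ids)
    groups["timepoint"] = groups["timepoint"].replace({"cfa": "control"})

    low = mat.sum(axis=1) < min_feature_counts
    if low.any():
        logger.info("dropping %d features with < %d total counts", int(low.sum()), min_feature_counts)
    return PseudobulkMatrix(
        counts=mat.loc[~low], groups=groups, dropped_features=mat.index[low]
    )


def filter_groups(
    pb: PseudobulkMatrix,
    min_sample_cells: int = 5,
    min_timepoint_cells: int = 30,
) -> PseudobulkMatrix:
    """Drop samples with < 5 cells and time points with < 30 cells."""
    g = pb.groups
    keep = g["n_cells"] >= min_sample_cells
    tp_cells = g.loc[keep].groupby("timepoint")["n_cells"].sum()
    bad_tp = set(tp_cells[tp_cells < min_timepoint_cells].index)
    if bad_tp:
        logger.info("dropping time points with < %d cells: %s", min_timepoint_cells, sorted(bad_tp))
    keep &= ~g["timepoint"].isin(bad_tp)
    return PseudobulkMatrix(
        counts=pb.counts.loc[:, keep.to_numpy()],
        groups=g.loc[keep],
        dropped_features=pb.dropped_features,
    )


def nb_wald(
    pb: PseudobulkMatrix,
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS,
    condition_col: str = "timepoint",
    reference: str = "control",
    covariate_cols: list[str] | None = None,
    exclude_levels: tuple[str, ...] = ("naive",),
) -> pd.DataFrame:
    """NB GLM Wald tests per contrast with BH correction within contrast.

    Returns a frame with feature, contrast, log2FC, p, padj, baseMean.
    Contrasts whose levels are absent after filtering are skipped with a
    log entry.
    """
    g = pb.groups
    use = ~g[condition_col].isin(exclude_levels)
    meta = g.loc[use]
    counts = pb.counts.loc[:, use.to_numpy()].to_numpy()
    levels = set(meta[condition_col])
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent")
    for lv in levels:
        if (meta[condition_col] == lv).sum() < 2:
            raise ValueError(f"level {lv!r} has fewer than 2 samples")

    sf = nbglm.size_factors_median_ratio(counts)
    disp = nbglm.estimate_dispersions(counts, sf, meta[condition_col].to_numpy())
    X, names = nbglm.build_design(meta, condition_col, reference, covariate_cols)
    beta, cov, _ = nbglm.fit_nb_glm(counts, X, np.log(sf), disp)
    base_mean = (counts / sf).mean(axis=1)

    frames = []
    for num, den in contrasts:
        if num not in levels or den not in levels:
            logger.warning("contrast %s/%s skipped: level missing", num, den)
            continue
        lfc, z, p = nbglm.wald_contrast(beta, cov, names, num, den, condition_col, reference)
        frames.append(
            pd.DataFrame(
                {
                    "feature": pb.counts.index,
                    "contrast": f"{num}/{den}",
                    "log2FC": lfc,
                    "p": p,
                    "padj": nbglm.bh_adjust(p),
                    "baseMean": base_mean,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["feature", "contrast", "log2FC", "p", "padj", "baseMean"])
    return pd.concat(frames, ignore_index=True)


def select_differential(
    results: pd.DataFrame,
    lfc_min: float = 1.0,
    padj_max: float = 0.01,
    basemean_min: float = 1.0,
) -> pd.Index:
    """Union over contrasts of |log2FC| > 1, padj < 0.01, baseMean > 1."""
    if results.empty:
        return pd.Index([])
    hit = (
        (results["log2FC"].abs() > lfc_min)
        & (results["padj"] < padj_max)
        & (results["baseMean"] > basemean_min)
    )
    return pd.Index(sorted(results.loc[hit, "feature"].unique()))


def timepoint_means(pb: PseudobulkMatrix, exclude_levels: tuple[str, ...] = ("naive",)) -> pd.DataFrame:
    """Size-factor-normalized mean counts per stage (features x stages)."""
    g = pb.groups
    use = ~g["timepoint"].isin(exclude_levels)
    counts = pb.counts.loc[:, use.to_numpy()].to_numpy().astype(float)
    sf = nbglm.size_factors_median_ratio(counts)
    norm = counts / sf
    tps = g.loc[use, "timepoint"].to_numpy()
    out = {}
    for tp in STAGE_ORDER:
        cols = np.flatnonzero(tps == tp)
        if len(cols):
            out[tp] = norm[:, cols].mean(axis=1)
    return pd.DataFrame(out, index=pb.counts.index)


def scale_dynamics(profiles: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each feature's stage profile to [0, 1].

    Constant profiles map to all-zero (stated convention); missing stage
    values are set to 0.
    """
    x = profiles.to_numpy(dtype=float)
    x = np.where(np.isfinite(x), x, np.nan)
    lo = np.nanmin(x, axis=1, keepdims=True)
    hi = np.nanmax(x, axis=1, keepdims=True)
    rng = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(rng > 0, (x - lo) / rng, 0.0)
    scaled = np.nan_to_num(scaled, nan=0.0)
    return pd.DataFrame(scaled, index=profiles.index, columns=profiles.columns)


def assign_types(
    profiles: pd.DataFrame,
    selected: pd.Index | None = None,
    secondary_threshold: float = 0.5,
) -> pd.DataFrame:
    """Main type = stage of the maximal scaled mean (1=control .. 4=late);
    the second-ranked stage becomes a subtype when its scaled mean is at or
    above ``secondary_threshold``. Ties break by stage order."""
    if selected is not None:
        profiles = profiles.loc[profiles.index.intersection(pd.Index(selected))]
    scaled = scale_dynamics(profiles)
    stages = [s for s in STAGE_ORDER if s in scaled.columns]
    vals = scaled[stages].to_numpy()
    recs = []
    for i, feat in enumerate(scaled.index):
        order = sorted(range(len(stages)), key=lambda j: (-vals[i, j], j))
        main = stages[order[0]]
        secondary = None
        if len(order) > 1 and vals[i, order[1]] >= secondary_threshold:
            secondary = stages[order[1]]
        recs.append(
            (
                feat,
                TYPE_OF_STAGE[main],
                main,
                TYPE_OF_STAGE[secondary] if secondary else pd.NA,
                secondary,
            )
        )
    return pd.DataFrame(
        recs, columns=["feature", "type", "main_stage", "subtype", "secondary_stage"]
    ).set_index("feature")


def summarize_dynamics(scaled: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-type mean and s.d. of the scaled profiles across member features."""
    recs = []
    for t, idx in scaled.index.groupby(labels.reindex(scaled.index)).items():
        sub = scaled.loc[idx]
        for stage in scaled.columns:
            recs.append((t, stage, sub[stage].mean(), sub[stage].std(ddof=1)))
    return pd.DataFrame(recs, columns=["type", "stage", "mean", "sd"])
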