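"""Gene-set module scoring and Gaussian-null status classification.

A cell's module score is the mean normalized expression of a gene set minus
the mean of expression-matched control genes (sampled from equal-frequency
average-expression bins). Scores are min-max scaled to [0, 1] within the
scored population; a normal distribution fitted to the control population
(e.g. naive animals) supplies the null

    F(x) = 1/2 * [1 + erf((x - mu) / (sigma * sqrt(2)))]

and a cell is called positive ("immune", "damage", ...) when its upper-tail
probability P = 1 - F(x) falls below alpha. The same machinery runs on the
expression and the gene-activity (chromatin) modality.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm as _normal

from .datatypes import Modality, NormalizedMatrix


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    category: str = "immune"

    def intersect(self, features: pd.Index) -> list[str]:
        present = [g for g in self.genes if g in set(features)]
        if not present:
            raise ValueError(f"gene set {self.name!r} has no genes in the matrix")
        return present


@dataclass
class ScoreVector:
    raw: pd.Series
    scaled: pd.Series
    modality: Modality = "expression"

    def __post_init__(self) -> None:
        lo, hi = self.scaled.min(), self.scaled.max()
        if len(self.scaled) and (lo < -1e-9 or hi > 1 + 1e-9):
            raise ValueError("scaled scores must lie in [0, 1]")


@dataclass
class NullModel:
    """Normal null fitted to the control population's scaled scores."""

    mu: float
    sigma: float
    control_population: str = "control"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("degenerate null: sigma must be positive")

    def cdf(self, x):
        return _normal.cdf(x, loc=self.mu, scale=self.sigma)

    def upper_tail(self, x):
        return _normal.sf(x, loc=self.mu, scale=self.sigma)


@dataclass
class StatusCall:
    p: pd.Series
    status: pd.Series  # boolean: True = positive call
    alpha: float = 0.05
    label: str = "immune"

    @property
    def n_positive(self) -> int:
        return int(self.status.sum())


def _scale01(raw: pd.Series) -> pd.Series:
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        return (raw - lo) / (hi - lo)
    return pd.Series(0.0, index=raw.index)


def module_score(
    norm_expr: NormalizedMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    modality: Modality = "expression",
) -> ScoreVector:
    """Expression-bin-matched module score per cell.

    Genes are binned into ``n_bins`` equal-frequency bins of average
    normalized expression; for every set gene, ``n_ctrl`` control genes are
    sampled (with replacement, seeded) from its bin, and the score is the
    mean over set genes minus the mean over the pooled controls.
    """
    members = gene_set.intersect(norm_expr.features)
    dense = norm_expr.dense()
    avg = dense.mean(axis=1)

    eff_bins = n_bins
    if len(norm_expr.features) < n_bins:
        eff_bins = max(2, len(norm_expr.features) // 2)
        warnings.warn(
            f"only {len(norm_expr.features)} genes; reducing bins {n_bins} -> {eff_bins}"
        )
    order = pd.Series(avg, index=norm_expr.features).rank(method="first")
    bins = pd.qcut(order, q=eff_bins, labels=False)

    rng = np.random.default_rng(seed)
    feat_pos = {g: i for i, g in enumerate(norm_expr.features)}
    bin_members: dict[int, np.ndarray] = {
        b: np.array([feat_pos[g] for g in bins.index[bins == b]]) for b in range(eff_bins)
    }
    ctrl_rows: list[np.ndarray] = []
    for g in members:
        b = int(bins[g])
        pool = bin_members[b]
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)
    set_idx = np.array([feat_pos[g] for g in members])

    raw = dense[set_idx].mean(axis=0) - dense[ctrl_idx].mean(axis=0)
    raw = pd.Series(raw, index=norm_expr.cells, name=gene_set.name)
    return ScoreVector(raw=raw, scaled=_scale01(raw), modality=modality)


def fit_null(scores: ScoreVector, control_cells) -> NullModel:
    """Fit (mu, sigma) of the control cells' scaled scores (sample s.d.)."""
    ctrl = scores.scaled.loc[pd.Index(control_cells)]
    if len(ctrl) < 2:
        raise ValueError("need at least 2 control cells")
    sigma = float(ctrl.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate null: control scores are identical")
    return NullModel(mu=float(ctrl.mean()), sigma=sigma)


def classify_status(
    scores: ScoreVector, null: NullModel, alpha: float = 0.05, label: str = "immune"
) -> StatusCall:
    """Call cells whose upper-tail probability under the null is < alpha."""
    p = pd.Series(null.upper_tail(scores.scaled.to_numpy()), index=scores.scaled.index)
    return StatusCall(p=p, status=p < alpha, alpha=alpha, label=label)


def score_and_classify(
    norm: NormalizedMatrix,
    gene_set: GeneSet,
    cells_meta: pd.DataFrame,
    control_timepoint: str = "naive",
    alpha: float = 0.05,
    by_cell_type: bool = True,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    modality: Modality = "expression",
) -> pd.DataFrame:
    """Score, fit the control null and classify, per cell type.

    Cell types with no cells in the control time point are returned
    unlabeled (status/P set to NA), mirroring populations absent from the
    control samples. Returns a per-cell frame with columns score, scaled,
    p, status.
    """
    out = pd.DataFrame(
        index=norm.cells, columns=["score", "scaled", "p", "status"], dtype=object
    )
    groups = (
        cells_meta.groupby("cell_type").groups.items()
        if by_cell_type
        else [("all", cells_meta.index)]
    )
    for ct, idx in groups:
        idx = pd.Index(idx)
        sub = norm.subset_cells(idx)
        sv = module_score(sub, gene_set, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed, modality=modality)
        ctrl_cells = idx[cells_meta.loc[idx, "timepoint"] == control_timepoint]
        out.loc[idx, "score"] = sv.raw.to_numpy()
        out.loc[idx, "scaled"] = sv.scaled.to_numpy()
        if len(ctrl_cells) < 2:
            continue  # unlabeled population
        try:
            null = fit_null(sv, ctrl_cells)
        except ValueError:
            continue
        call = classify_status(sv, null, alpha=alpha, label=gene_set.category)
        out.loc[idx, "p"] = call.p.to_numpy()
        out.loc[idx, "status"] = call.status.to_numpy()
    return out


def status_on_chromatin(
    gene_activity: NormalizedMatrix,
    gene_set: GeneSet,
    cells_meta: pd.DataFrame,
    control_timepoint: str = "naive",
    alpha: float = 0.05,
    **kwargs,
) -> pd.DataFrame:
    """The expression workflow applied to the gene-activity matrix."""
    return score_and_classify(
        gene_activity,
        gene_set,
        cells_meta,
        control_timepoint=control_timepoint,
        alpha=alpha,
        modality="chromatin",
        **kwargs,
    )


def status_calls(status: pd.Series) -> pd.Series:
    """Boolean per-cell calls; unlabeled cells (NA) count as negative."""
    return pd.Series(
        [bool(v) if pd.notna(v) else False for v in status], index=status.index, dtype=bool
    )


JOINT_LABELS = ("both", "ifn_only", "damage_only", "neither")


def joint_status(ifn_call: pd.Series, damage_call: pd.Series) -> pd.Series:
    """Deterministic 2x2 mapping of (IFN, damage) boolean calls."""
    if not ifn_call.index.equals(damage_call.index):
        raise ValueError("IFN and damage calls cover different cells")
    a = ifn_call.astype("boolean")
    b = damage_call.astype("boolean")
    na = a.isna() | b.isna()
    af = a.fillna(False).astype(bool)
    bf = b.fillna(False).astype(bool)
    out = pd.Series("neither", index=a.index, dtype=object)
    out[af & bf] = "both"
    out[af & ~bf] = "ifn_only"
    out[~af & bf] = "damage_only"
    out[na] = pd.NA
    return out
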