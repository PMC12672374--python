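"""Sex classification from X/Y-linked gene expression and normalized-LISI
replicate-mixing assessment on a 2-D embedding.

The sex classifier is a regularized logistic regression trained on
class-balanced cells (equal numbers per sex, downsampled with a seed) and
evaluated on a held-out split with accuracy / sensitivity / specificity
(female treated as the positive class). LISI is the local inverse
Simpson's index of replicate labels in a Gaussian-kernel neighborhood
whose bandwidth is calibrated per cell to a fixed perplexity; raw values
in [1, R] are normalized to [0, 1] as (raw - 1) / (R - 1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors

from .datatypes import NormalizedMatrix

POSITIVE_CLASS = "F"


@dataclass
class SexModel:
    feature_genes: list[str]
    classifier: LogisticRegression
    metrics: dict
    train_cells: pd.Index
    holdout_cells: pd.Index


def xy_marker_genes(genes: pd.DataFrame) -> list[str]:
    """All genes annotated on chrX or chrY."""
    return list(genes.index[genes["chrom"].isin(["chrX", "chrY"])])


def train_sex_classifier(
    expr: NormalizedMatrix,
    labels: pd.Series,
    xy_genes: list[str],
    holdout_fraction: float = 0.25,
    seed: int = 0,
    C: float = 1.0,
) -> SexModel:
    """Balanced-downsampled train/holdout fit on X/Y-linked features."""
    labels = labels.loc[expr.cells]
    classes = sorted(labels.unique())
    if len(classes) < 2:
        raise ValueError("both sexes must be present in the training labels")
    rng = np.random.default_rng(seed)
    n_per = labels.value_counts().min()
    chosen = []
    for cl in classes:
        idx = labels.index[labels == cl].to_numpy()
        chosen.append(rng.choice(idx, size=n_per, replace=False))
    chosen = np.concatenate(chosen)
    rng.shuffle(chosen)
    n_hold = max(1, int(round(holdout_fraction * len(chosen))))
    holdout = pd.Index(chosen[:n_hold])
    train = pd.Index(chosen[n_hold:])

    sub = expr.subset_features(xy_genes)
    Xall = sub.dense().T  # cells x features
    pos = {c: i for i, c in enumerate(sub.cells)}
    Xtr = Xall[[pos[c] for c in train]]
    Xho = Xall[[pos[c] for c in holdout]]
    ytr = (labels.loc[train] == POSITIVE_CLASS).to_numpy(dtype=int)
    yho = (labels.loc[holdout] == POSITIVE_CLASS).to_numpy(dtype=int)

    clf = LogisticRegression(C=C, max_iter=2000, random_state=int(seed))
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xho)
    tp = int(((pred == 1) & (yho == 1)).sum())
    tn = int(((pred == 0) & (yho == 0)).sum())
    fp = int(((pred == 1) & (yho == 0)).sum())
    fn = int(((pred == 0) & (yho == 1)).sum())
    metrics = {
        "accuracy": (tp + tn) / max(len(yho), 1),
        "sensitivity": tp / max(tp + fn, 1),
        "specificity": tn / max(tn + fp, 1),
        "n_holdout": len(yho),
    }
    return SexModel(
        feature_genes=list(xy_genes),
        classifier=clf,
        metrics=metrics,
        train_cells=train,
        holdout_cells=holdout,
    )


def predict_sex(
    model: SexModel,
    expr: NormalizedMatrix,
    known_labels: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cell sex label and female-probability score.

    Cells with zero signal across every X/Y feature are labeled
    "unassigned"; when a-priori labels are given, disagreeing cells are
    flagged.
    """
    sub = expr.subset_features(model.feature_genes)
    X = sub.dense().T
    proba = model.classifier.predict_proba(X)[:, 1]
    label = np.where(proba >= 0.5, "F", "M")
    empty = (X != 0).sum(axis=1) == 0
    label = np.where(empty, "unassigned", label)
    out = pd.DataFrame({"sex": label, "score": proba}, index=sub.cells)
    if known_labels is not None:
        known = known_labels.reindex(sub.cells)
        out["flagged"] = (out["sex"] != known) & known.notna() & (out["sex"] != "unassigned")
    return out


@dataclass
class LisiResult:
    per_cell: pd.DataFrame  # raw, normalized
    n_labels: int
    fraction_ge_half: float
    median_normalized: float


def lisi(
    embedding: pd.DataFrame,
    labels: pd.Series,
    perplexity: float = 30.0,
    equalize: bool = False,
    seed: int = 0,
) -> LisiResult:
    """Perplexity-calibrated local inverse Simpson's index of ``labels``.

    ``equalize`` downsamples (seeded) to equal cell counts per label before
    computing, matching the equal-replicate assessment protocol.
    """
    labels = labels.loc[embedding.index]
    uniq = sorted(labels.unique())
    R = len(uniq)
    if R < 2:
        raise ValueError("LISI needs at least 2 labels (R - 1 normalization)")
    if equalize:
        rng = np.random.default_rng(seed)
        n_per = labels.value_counts().min()
        keep = np.concatenate(
            [rng.choice(labels.index[labels == lv].to_numpy(), size=n_per, replace=False) for lv in uniq]
        )
        embedding = embedding.loc[pd.Index(keep)]
        labels = labels.loc[pd.Index(keep)]
    coords = embedding[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("embedding contains non-finite coordinates")
    n = len(coords)
    k = int(min(n - 1, max(5, round(3 * perplexity))))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self
    lab_codes = pd.Categorical(labels, categories=uniq).codes
    target_h = np.log(min(perplexity, k))

    raw = np.empty(n)
    d2 = dist**2
    for i in range(n):
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(64):
            w = np.exp(-beta * d2[i])
            s = w.sum()
            if s <= 0:
                h = 0.0
                p = np.zeros_like(w)
            else:
                p = w / s
                nzp = p[p > 0]
                h = float(-(nzp * np.log(nzp)).sum())
            if abs(h - target_h) < 1e-5:
                break
            if h > target_h:
                lo = beta
                beta = beta * 2 if hi >= 1e10 else (beta + hi) / 2
            else:
                hi = beta
                beta = (beta + lo) / 2
        sums = np.bincount(lab_codes[idx[i]], weights=p, minlength=R)
        simpson = float((sums**2).sum())
        raw[i] = 1.0 / simpson if simpson > 0 else 1.0
    raw = np.clip(raw, 1.0, R)
    normalized = (raw - 1.0) / (R - 1.0)
    per_cell = pd.DataFrame({"raw": raw, "normalized": normalized}, index=embedding.index)
    return LisiResult(
        per_cell=per_cell,
        n_labels=R,
        fraction_ge_half=float((normalized >= 0.5).mean()),
        median_normalized=float(np.median(normalized)),
    )
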