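"""End-to-end property evaluations of the pipeline on synthetic data.

Each function regenerates its inputs from a seed, runs the relevant slice
of the pipeline, and returns measured quantities (call rates, recovered
fractions, sensitivities, biases, ranks). The acceptance script and the
acceptance test suite both drive these functions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import nbglm
from .cohort import lisi, train_sex_classifier, xy_marker_genes
from .diff import PseudobulkMatrix, nb_wald
from .grn import fit_grn, tf_activity
from .linking import define_dorcs, link_peaks
from .qc import gene_activity, lognormalize, tfidf
from .scoring import (
    GeneSet,
    NullModel,
    ScoreVector,
    classify_status,
    score_and_classify,
    status_calls,
)
from .simulate import SimulationConfig, simulate_bulk_memory, simulate_multiome
from .windows import build_tss_windows, classify_memory, tmm_nb_lrt


def _sub(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2**31 - 1))


def recovery_config(seed: int, cells_per_timepoint: int = 2000) -> SimulationConfig:
    """Default study conditions with equal cells per time point."""
    cfg = SimulationConfig(seed=seed)
    per_tp: dict[str, int] = {}
    for _, tp, _ in cfg.samples:
        per_tp[tp] = per_tp.get(tp, 0) + 1
    n_by_sample = {
        sid: cells_per_timepoint // per_tp[tp] for sid, tp, _ in cfg.samples
    }
    cfg.n_cells_by_sample = n_by_sample
    return cfg


# ---------------------------------------------------------------------------
# 1. null calibration of the status classifier
# ---------------------------------------------------------------------------

def null_calibration(seed: int, n_cells: int = 10_000, alpha: float = 0.05) -> dict:
    """Draw cells from a fitted control null; measure the call rate."""
    rng = np.random.default_rng(seed)
    null = NullModel(mu=0.35, sigma=0.08, control_population="naive")
    draws = np.clip(rng.normal(null.mu, null.sigma, size=n_cells), 0.0, 1.0)
    s = pd.Series(draws, index=[f"c{i}" for i in range(n_cells)])
    call = classify_status(ScoreVector(raw=s, scaled=s), null, alpha=alpha)
    return {"null_call_rate": float(call.status.mean()), "n": n_cells}


# ---------------------------------------------------------------------------
# 2. planted-fraction recovery on both modalities
# ---------------------------------------------------------------------------

def fraction_recovery(seed: int, cells_per_timepoint: int = 2000) -> dict:
    cfg = recovery_config(seed, cells_per_timepoint)
    ds, truth = simulate_multiome(cfg)
    gene_set = GeneSet("immune", list(truth.genes.index[truth.genes["immune_program"]]))

    expr = lognormalize(ds.rna, ds.genes.index, ds.cells.index)
    res_e = score_and_classify(expr, gene_set, ds.cells, control_timepoint="naive", seed=seed)
    activity = gene_activity(ds)
    res_c = score_and_classify(
        activity, gene_set, ds.cells, control_timepoint="naive", seed=seed, modality="chromatin"
    )

    called_e = status_calls(res_e["status"])
    called_c = status_calls(res_c["status"])
    out = {"n": ds.n_cells}
    max_dev = 0.0
    for tp in ("early", "peak", "late"):
        m = (ds.cells["timepoint"] == tp).to_numpy()
        rec = float(called_e[m].mean())
        true = float(truth.cells["immune"][m].mean())
        out[f"recovered_{tp}"] = rec
        out[f"true_{tp}"] = true
        out[f"chromatin_calls_{tp}"] = int(called_c[m].sum())
        out[f"expression_calls_{tp}"] = int(called_e[m].sum())
        max_dev = max(max_dev, abs(rec - true))
    out["max_abs_deviation"] = max_dev
    out["chromatin_le_expression"] = int(
        all(out[f"chromatin_calls_{tp}"] <= out[f"expression_calls_{tp}"] for tp in ("early", "peak", "late"))
    )
    return out


# ---------------------------------------------------------------------------
# 3. link/DORC oracle equivalence and recovery
# ---------------------------------------------------------------------------

def _brute_force_links(expr, access, peaks, genes, max_dist, min_cells, p_max):
    recs = []
    n = len(expr.cells)
    E, A = expr.dense(), access.dense()
    for gi, g in enumerate(genes.index):
        tss = genes.loc[g, "tss"]
        for pi, p in enumerate(peaks.index):
            if peaks.loc[p, "chrom"] != genes.loc[g, "chrom"]:
                continue
            center = (peaks.loc[p, "start"] + peaks.loc[p, "end"]) // 2
            if abs(center - tss) > max_dist or (A[pi] != 0).sum() < min_cells:
                continue
            x, y = E[gi], A[pi]
            if x.std() == 0 or y.std() == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            t = r * np.sqrt((n - 2) / (1 - r**2))
            pv = float(2 * sps.t.sf(abs(t), n - 2))
            if r > 0 and pv < p_max:
                recs.append((p, g, r, pv))
    return pd.DataFrame(recs, columns=["peak", "gene", "r", "p"])


def link_dorc_oracle(seed: int) -> dict:
    from .datatypes import NormalizedMatrix

    rng = np.random.default_rng(seed)
    n_genes, n_peaks, n_cells = 20, 200, 300
    genes = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": np.arange(n_genes) * 100_000,
            "end": np.arange(n_genes) * 100_000 + 10_000,
            "strand": "+",
            "tss": np.arange(n_genes) * 100_000,
        },
        index=[f"g{i}" for i in range(n_genes)],
    )
    pstart = rng.integers(0, n_genes * 100_000, n_peaks)
    peaks = pd.DataFrame(
        {"chrom": "chr1", "start": pstart, "end": pstart + 500},
        index=[f"p{i}" for i in range(n_peaks)],
    )
    E = rng.gamma(2, 1, (n_genes, n_cells))
    A = rng.poisson(0.8, (n_peaks, n_cells)).astype(float)
    for k in range(5):
        A[k] = E[k % n_genes] * 0.5 + rng.normal(0, 0.1, n_cells)
    cells = [f"c{i}" for i in range(n_cells)]
    expr = NormalizedMatrix(values=E, features=genes.index, cells=cells, method="lognorm")
    acc = NormalizedMatrix(values=A, features=peaks.index, cells=cells, method="tfidf")

    got = link_peaks(expr, acc, peaks, genes, max_dist=50_000, min_cells=10, p_max=0.05)
    exp = _brute_force_links(expr, acc, peaks, genes, 50_000, 10, 0.05)
    got_k = got.set_index(["peak", "gene"])
    exp_k = exp.set_index(["peak", "gene"])
    same_pairs = set(got_k.index) == set(exp_k.index)
    if same_pairs and len(got_k):
        dr = float(np.max(np.abs(got_k["r"] - exp_k.loc[got_k.index, "r"])))
        dp = float(np.max(np.abs(got_k["p"] - exp_k.loc[got_k.index, "p"])))
    else:
        dr = dp = float("inf")

    # DORC recovery on the full generator at ~500 cells
    cfg = SimulationConfig(
        n_cells_per_sample=125,
        samples=[("s1", "cfa", "r1"), ("s2", "cfa", "r2"), ("s3", "early", "r1"), ("s4", "peak", "r1")],
        seed=_sub(seed, 3),
    )
    ds, truth = simulate_multiome(cfg)
    e2 = lognormalize(ds.rna, ds.genes.index, ds.cells.index)
    a2 = tfidf(ds.atac, ds.peaks.index, ds.cells.index)
    links50 = link_peaks(e2, a2, ds.peaks, ds.genes, padj_max=0.05)
    table = define_dorcs(links50, e2, a2, ds.peaks, ds.genes, padj_max=0.05)
    expected = set(truth.genes.index[truth.genes["dorc"]])
    found = set(table.dorc_genes)
    return {
        "oracle_pairs_identical": int(same_pairs),
        "oracle_max_abs_dr": dr,
        "oracle_max_abs_dp": dp,
        "dorc_false_positives": len(found - expected),
        "dorc_missed": len(expected - found),
        "n": len(exp),
    }


# ---------------------------------------------------------------------------
# 4. pseudobulk NB-Wald calibration and recovery
# ---------------------------------------------------------------------------

def _sim_pseudobulk(seed, n_features=2000, n_per=4, disp=0.1, planted=(), log2fc=0.0):
    """``planted`` features get the signed effect: alternating halves are
    shifted up and down by |log2fc| (balanced DE, as in real stage contrasts)."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(50), 1.0, n_features))
    mu = np.tile(base[:, None], (1, 2 * n_per))
    if len(planted):
        planted = np.asarray(planted)
        half = len(planted) // 2
        mu[planted[:half], n_per:] *= 2.0**log2fc
        mu[planted[half:], n_per:] *= 2.0 ** (-log2fc)
    lib = np.exp(rng.normal(0, 0.1, 2 * n_per))
    counts = rng.poisson(rng.gamma(1 / disp, disp * (mu * lib)))
    cols = [f"s{i}" for i in range(2 * n_per)]
    groups = pd.DataFrame(
        {
            "sample": cols, "cell_type": "MOL2",
            "timepoint": ["control"] * n_per + ["early"] * n_per,
            "replicate": [f"r{i}" for i in range(n_per)] * 2, "n_cells": 100,
        },
        index=cols,
    )
    return PseudobulkMatrix(
        counts=pd.DataFrame(counts, index=[f"f{i}" for i in range(n_features)], columns=cols),
        groups=groups,
    )


def pseudobulk_calibration(seed: int, n_null_seeds: int = 20) -> dict:
    rates = []
    for k in range(n_null_seeds):
        pb = _sim_pseudobulk(_sub(seed, k))
        res = nb_wald(pb, contrasts=(("early", "control"),))
        rates.append(float((res["padj"] < 0.01).mean()))
    planted = np.arange(200)
    pb = _sim_pseudobulk(_sub(seed, 999), planted=planted, log2fc=2.0)
    res = nb_wald(pb, contrasts=(("early", "control"),)).set_index("feature")
    sub = res.loc[[f"f{i}" for i in planted]]
    truth_lfc = np.where(np.arange(200) < 100, 2.0, -2.0)
    strong = sub["baseMean"] >= 20
    sens = float(((sub["padj"] < 0.01) & (sub["log2FC"].abs() > 1))[strong].mean())
    bias = float((sub["log2FC"].to_numpy() - truth_lfc)[strong.to_numpy()].mean())
    return {
        "null_padj01_rate": float(np.mean(rates)),
        "sensitivity": sens,
        "log2fc_bias": bias,
        "n": n_null_seeds * 2000,
    }


# ---------------------------------------------------------------------------
# 5. memory-gate recovery
# ---------------------------------------------------------------------------

def memory_recovery(seed: int) -> dict:
    bulk = simulate_bulk_memory(n_replicates=3, effect_log2fc=2.0, seed=seed)
    meta = bulk.samples
    rna1 = tmm_nb_lrt(bulk.rna, meta, ("dose1_0h", "control"))
    atacw = tmm_nb_lrt(bulk.atac, meta, ("dose1_0h", "dose1_96h"))
    rna2 = tmm_nb_lrt(bulk.rna, meta, ("dose2", "dose1_0h"))
    atacw.index = bulk.region_genes.loc[atacw.index].to_numpy()
    calls = classify_memory(rna1, atacw, rna2)
    tr = bulk.truth
    return {
        "memory_sensitivity": float(calls["memory"][tr["memory"]].mean()),
        "memory_false_rate": float(calls["memory"][~tr["memory"]].mean()),
        "n": len(tr),
    }


# ---------------------------------------------------------------------------
# 6. sex-classifier recovery
# ---------------------------------------------------------------------------

def sex_classifier_recovery(seed: int) -> dict:
    ds, truth = simulate_multiome(SimulationConfig(n_cells_per_sample=250, seed=seed))
    expr = lognormalize(ds.rna, ds.genes.index, ds.cells.index)
    markers = xy_marker_genes(ds.genes)
    model = train_sex_classifier(expr, truth.cells["sex"], markers, seed=seed)
    rng = np.random.default_rng(_sub(seed, 1))
    shuffled = pd.Series(rng.permutation(truth.cells["sex"].to_numpy()), index=truth.cells.index)
    # a larger holdout keeps the chance-level accuracy estimate tight
    null_model = train_sex_classifier(expr, shuffled, markers, holdout_fraction=0.5, seed=seed)
    return {
        "sex_accuracy": float(model.metrics["accuracy"]),
        "sex_sensitivity": float(model.metrics["sensitivity"]),
        "sex_specificity": float(model.metrics["specificity"]),
        "sex_shuffled_accuracy": float(null_model.metrics["accuracy"]),
        "n": int(model.metrics["n_holdout"]),
    }


# ---------------------------------------------------------------------------
# 7. LISI extremes
# ---------------------------------------------------------------------------

def lisi_extremes(seed: int, n_side: int = 40) -> dict:
    xs, ys = np.meshgrid(np.arange(n_side), np.arange(n_side))
    idx = [f"c{i}" for i in range(n_side * n_side)]
    coords = pd.DataFrame({"x": xs.ravel().astype(float), "y": ys.ravel().astype(float)}, index=idx)
    inter = pd.Series(((xs.ravel() + ys.ravel()) % 2), index=idx).map({0: "r1", 1: "r2"})
    blocks = pd.Series((xs.ravel() < n_side // 2).astype(int), index=idx).map({0: "r1", 1: "r2"})
    r_inter = lisi(coords, inter)
    r_block = lisi(coords, blocks)
    both = np.concatenate(
        [r_inter.per_cell["normalized"].to_numpy(), r_block.per_cell["normalized"].to_numpy()]
    )
    return {
        "lisi_interleaved_median": r_inter.median_normalized,
        "lisi_blocks_median": r_block.median_normalized,
        "lisi_min": float(both.min()),
        "lisi_max": float(both.max()),
        "n": len(both),
    }


# ---------------------------------------------------------------------------
# 8. window-builder oracle
# ---------------------------------------------------------------------------

def window_builder_check(seed: int, n_random: int = 100) -> dict:
    rows = []
    for i in range(8):
        rows.append(("chr1", 5_000 + i * 10_000, "+" if i % 2 == 0 else "-", f"g{i}"))
    rows += [("chr2", 50_000, "+", "gP"), ("chr2", 50_600, "+", "gQ"),
             ("chr2", 80_000, "+", "gR"), ("chr2", 80_040, "-", "gS")]
    ws = build_tss_windows(pd.DataFrame(rows, columns=["chrom", "tss", "strand", "gene"]))
    expected_chr1 = [(5_000 + i * 10_000 - 500, 5_000 + i * 10_000 + 500) for i in range(8)]
    chr1 = ws.intervals[ws.intervals["chrom"] == "chr1"].sort_values("start")
    toy_exact = list(zip(chr1["start"], chr1["end"])) == expected_chr1
    chr2 = ws.intervals[ws.intervals["chrom"] == "chr2"].sort_values("start")
    toy_exact &= len(chr2) == 2 and (
        (int(chr2.iloc[0]["start"]), int(chr2.iloc[0]["end"])) == (49_500, 51_100)
    )

    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_random):
        n = int(rng.integers(1, 40))
        ann = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], n),
                "tss": rng.integers(0, 300_000, n),
                "strand": rng.choice(["+", "-"], n),
                "gene": [f"g{i}" for i in range(n)],
            }
        )
        try:
            out = build_tss_windows(ann)
        except ValueError:
            violations += 1
            continue
        iv = out.intervals.sort_values(["chrom", "start"])
        for _, sub in iv.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                violations += 1
    return {"toy_window_set_exact": int(toy_exact), "nonoverlap_violations": violations, "n": n_random}


# ---------------------------------------------------------------------------
# 9. TF-activity recovery
# ---------------------------------------------------------------------------

def tf_activity_recovery(seed: int, n_seeds: int = 10) -> dict:
    dual = 0
    for k in range(n_seeds):
        cfg = SimulationConfig(n_cells_per_sample=250, seed=_sub(seed, k))
        ds, truth = simulate_multiome(cfg)
        expr = lognormalize(ds.rna, ds.genes.index, ds.cells.index)
        acc = tfidf(ds.atac, ds.peaks.index, ds.cells.index)
        cand = pd.Index(truth.motifs["peak"].unique())
        model = fit_grn(expr, acc, cand, truth.motifs, ds.peaks, ds.genes, ds.cells, seed=_sub(seed, k))
        act = tf_activity(model, expr, ds.cells)
        pk = act[act["timepoint"] == "peak"].set_index("tf")
        cf = act[act["timepoint"] == "cfa"].set_index("tf")
        rp = int(pk.loc["TF01", "rank"]) if "TF01" in pk.index else 99
        rc = int(cf.loc["TF01", "rank"]) if "TF01" in cf.index else 99
        dual += int(rp <= 3 and rc > 3)
    return {"tf_dual_pass_seeds": dual, "n": n_seeds}


# ---------------------------------------------------------------------------
# 10. end-to-end determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int) -> dict:
    import hashlib
    import tempfile
    from pathlib import Path

    from .io import write_fixture

    def run_once(outdir: Path) -> str:
        cfg = SimulationConfig(n_cells_per_sample=150, seed=seed)
        ds, truth = simulate_multiome(cfg)
        write_fixture(ds, outdir, truth=truth)
        expr = lognormalize(ds.rna, ds.genes.index, ds.cells.index)
        acc = tfidf(ds.atac, ds.peaks.index, ds.cells.index)
        gene_set = GeneSet("immune", list(truth.genes.index[truth.genes["immune_program"]]))
        res = score_and_classify(expr, gene_set, ds.cells, control_timepoint="naive", seed=seed)
        res.to_csv(outdir / "status.tsv", sep="\t")
        links = link_peaks(expr, acc, ds.peaks, ds.genes, padj_max=0.05)
        links.to_csv(outdir / "links.tsv", sep="\t", index=False)
        h = hashlib.sha256()
        for f in sorted(outdir.iterdir()):
            h.update(f.name.encode())
            h.update(f.read_bytes())
        return h.hexdigest()

    with tempfile.TemporaryDirectory() as td:
        h1 = run_once(Path(td) / "run1")
        h2 = run_once(Path(td) / "run2")
    return {"identical_runs": int(h1 == h2), "n": 2}
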