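"""Synthetic paired single-cell RNA+ATAC generator with a ground-truth ledger.

The generator emulates the statistical structure the downstream analyses
assume: negative-binomial counts with log-normal library-size variation, a
disease time course (naive / cfa control / early / peak / late) with
replicates, a planted immune program expressed in a configurable fraction of
cells per time point, chromatin "priming" (program peaks open while
expression is off), blocks of correlated peaks for designated DORC genes,
X/Y sex-marker genes, planted transcription-factor programs, and a bulk
RNA/ATAC dose-rechallenge experiment for epigenetic-memory gating.

Every planted structure is recorded in a :class:`~olgstate.datatypes.GroundTruth`
ledger so parameter-recovery tests can compare calls against truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import TIMEPOINTS, GroundTruth, MultiomeDataset


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# internal scale of per-gene log1p-normalized expression noise; together with
# the sqrt(2/n_set) factor and the gain (which absorbs the log1p attenuation
# of a log-mean shift at default depth), one unit of immune_effect_size moves
# the downstream module score by about 1.1 control s.d.
_LOG_SD = 0.7
_SCORE_GAIN = 2.65
_ACTIVATION_LOGNORM_SD = 0.45

_GENE_SPACING = 100_000
_GENE_LENGTH = 10_000
_SEX_GENES_FEMALE = ("Xist_sim",)
_SEX_GENES_MALE = ("Uty_sim", "Eif2s3y_sim", "Ddx3y_sim", "Kdm5d_sim", "Zfy1_sim")


def _default_samples() -> list[tuple[str, str, str]]:
    out = []
    for tp, nrep in (("naive", 2), ("cfa", 3), ("early", 3), ("peak", 3), ("late", 3)):
        for r in range(1, nrep + 1):
            out.append((f"{tp}_{r}", tp, f"r{r}"))
    return out


def _default_immune_fractions() -> dict[str, float]:
    # EAE-stage fractions mirror the observed immune-OLG time course
    return {"naive": 0.0, "cfa": 0.0, "early": 0.268, "peak": 0.6691, "late": 0.3241}


def _default_damage_fractions() -> dict[str, float]:
    return {"naive": 0.0, "cfa": 0.0, "early": 0.10, "peak": 0.25, "late": 0.15}


def _default_immune_intensity() -> dict[str, float]:
    # program induction strength tracks disease severity: cells entering the
    # immune-like state at the early stage are only partially activated,
    # peak-stage cells are fully activated
    return {"naive": 1.0, "cfa": 1.0, "early": 0.75, "peak": 1.15, "late": 0.9}


def _default_cell_types() -> list[tuple[str, float]]:
    return [("OPC", 0.2), ("MOL2", 0.4), ("MOL56", 0.4)]


def _default_dorc_genes() -> list[tuple[str, int, float]]:
    # a mix of genes above and below the >=5-linked-peak DORC rule
    return [
        ("G0001", 6, 0.5),
        ("G0002", 5, 0.5),
        ("G0003", 8, 0.6),
        ("G0004", 5, 0.4),
        ("G0005", 4, 0.5),
        ("G0006", 3, 0.6),
    ]


@dataclass
class SimulationConfig:
    """Study-condition parameters of the paired multiome simulator."""

    n_cells_per_sample: int = 400
    n_cells_by_sample: dict[str, int] | None = None  # per-sample override
    samples: list[tuple[str, str, str]] = field(default_factory=_default_samples)
    cell_types: list[tuple[str, float]] = field(default_factory=_default_cell_types)
    immune_fraction_by_timepoint: dict[str, float] = field(
        default_factory=_default_immune_fractions
    )
    damage_fraction_by_timepoint: dict[str, float] = field(
        default_factory=_default_damage_fractions
    )
    immune_intensity_by_timepoint: dict[str, float] = field(
        default_factory=_default_immune_intensity
    )
    immune_effect_size: float = 3.0
    chromatin_priming: bool = True
    priming_fraction: float = 0.03
    immune_open_fraction: float = 0.55
    n_genes: int = 1200
    n_peaks: int = 3000
    immune_program_size: int = 60
    damage_program_size: int = 95
    dorc_genes: list[tuple[str, int, float]] = field(default_factory=_default_dorc_genes)
    n_tfs: int = 20
    n_tf_targets: int = 20
    sex_fraction_female: float = 0.5
    dispersion: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_sample <= 0:
            raise ConfigurationError("n_cells_per_sample must be positive")
        if self.n_cells_by_sample is not None:
            for sid, n in self.n_cells_by_sample.items():
                if n <= 0:
                    raise ConfigurationError(f"n_cells_by_sample[{sid!r}] must be positive")
        if self.n_genes <= 0 or self.n_peaks <= 0:
            raise ConfigurationError("n_genes and n_peaks must be positive")
        if not self.samples:
            raise ConfigurationError("at least one sample is required")
        props = np.array([p for _, p in self.cell_types], dtype=float)
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("cell-type proportions must sum to 1")
        for tp, f in self.immune_fraction_by_timepoint.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"immune fraction for {tp!r} outside [0, 1]")
        for tp, f in self.damage_fraction_by_timepoint.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError(f"damage fraction for {tp!r} outside [0, 1]")
        if not 0.0 <= self.sex_fraction_female <= 1.0:
            raise ConfigurationError("sex_fraction_female outside [0, 1]")
        if not 0.0 <= self.priming_fraction <= 1.0:
            raise ConfigurationError("priming_fraction outside [0, 1]")
        if self.immune_effect_size < 0:
            raise ConfigurationError("immune_effect_size must be >= 0")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        for _, tp, _ in self.samples:
            if tp not in TIMEPOINTS:
                raise ConfigurationError(f"unknown time point {tp!r}")
        for g, k, rho in self.dorc_genes:
            if k < 1:
                raise ConfigurationError(f"dorc gene {g}: n_linked_peaks must be >= 1")
            if not 0.0 < rho < 1.0:
                raise ConfigurationError(f"dorc gene {g}: strength must lie in (0, 1)")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draw with var = mu + dispersion*mu^2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mu)
    return rng.poisson(lam)


def _nb_counts_sparse(
    rng: np.random.Generator, mu_rows, dispersion: float, chunk: int = 256
) -> sp.csr_matrix:
    """Row-chunked NB sampling; ``mu_rows(lo, hi)`` yields the mean block."""
    blocks = []
    n_rows, n_cols = mu_rows.shape
    for lo in range(0, n_rows, chunk):
        hi = min(lo + chunk, n_rows)
        counts = _nb_counts(rng, mu_rows[lo:hi], dispersion)
        blocks.append(sp.csr_matrix(counts))
    return sp.vstack(blocks).tocsr()


def _build_cells(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    ct_names = [c for c, _ in config.cell_types]
    ct_props = np.array([p for _, p in config.cell_types])
    for sample_id, tp, rep in config.samples:
        n = config.n_cells_per_sample
        if config.n_cells_by_sample is not None:
            n = config.n_cells_by_sample.get(sample_id, n)
        ct = rng.choice(len(ct_names), size=n, p=ct_props)
        f_imm = config.immune_fraction_by_timepoint.get(tp, 0.0)
        f_dam = config.damage_fraction_by_timepoint.get(tp, 0.0)
        immune = rng.random(n) < f_imm
        damage = rng.random(n) < f_dam
        sex = np.where(rng.random(n) < config.sex_fraction_female, "F", "M")
        open_state = rng.random(n) < config.immune_open_fraction
        primed = np.zeros(n, dtype=bool)
        if config.chromatin_priming:
            primed = (~immune) & (rng.random(n) < config.priming_fraction)
        chromatin_immune = (immune & open_state) | primed
        intensity = config.immune_intensity_by_timepoint.get(tp, 1.0)
        activation = np.where(
            immune, intensity * np.exp(rng.normal(0.0, _ACTIVATION_LOGNORM_SD, size=n)), 0.0
        )
        dmg_activation = np.where(damage, np.exp(rng.normal(0.0, _ACTIVATION_LOGNORM_SD, size=n)), 0.0)
        rows.append(
            pd.DataFrame(
                {
                    "barcode": [f"{sample_id}_c{i:05d}" for i in range(n)],
                    "sample": sample_id,
                    "replicate": rep,
                    "timepoint": tp,
                    "cell_type": np.array(ct_names, dtype=object)[ct],
                    "sex": sex,
                    "immune": immune,
                    "damage": damage,
                    "primed": primed,
                    "chromatin_immune": chromatin_immune,
                    "activation": activation,
                    "damage_activation": dmg_activation,
                }
            )
        )
    return pd.concat(rows, ignore_index=True).set_index("barcode")


def _build_genes(config: SimulationConfig) -> pd.DataFrame:
    """Autosomal genes on chr1/chr2 at fixed spacing, plus X/Y sex markers."""
    n_auto = config.n_genes - len(_SEX_GENES_FEMALE) - len(_SEX_GENES_MALE) - config.n_tfs
    if n_auto <= config.immune_program_size + config.damage_program_size + len(
        config.dorc_genes
    ):
        raise ConfigurationError("n_genes too small for the configured programs")
    recs = []
    half = (n_auto + 1) // 2
    for i in range(n_auto):
        chrom = "chr1" if i < half else "chr2"
        pos = (i if i < half else i - half) * _GENE_SPACING + 50_000
        strand = "+" if i % 2 == 0 else "-"
        start, end = pos, pos + _GENE_LENGTH
        tss = start if strand == "+" else end - 1
        recs.append((f"G{i + 1:04d}", chrom, start, end, strand, tss))
    tf_base = half * _GENE_SPACING + 60_000
    for j in range(config.n_tfs):
        pos = tf_base + j * _GENE_SPACING
        recs.append((f"TF{j + 1:02d}", "chr2", pos, pos + _GENE_LENGTH, "+", pos))
    for j, g in enumerate(_SEX_GENES_FEMALE):
        pos = 100_000 + j * _GENE_SPACING
        recs.append((g, "chrX", pos, pos + _GENE_LENGTH, "+", pos))
    for j, g in enumerate(_SEX_GENES_MALE):
        pos = 100_000 + j * _GENE_SPACING
        recs.append((g, "chrY", pos, pos + _GENE_LENGTH, "+", pos))
    genes = pd.DataFrame(
        recs, columns=["gene", "chrom", "start", "end", "strand", "tss"]
    ).set_index("gene")
    return genes


_DORC_OFFSETS_50KB = [8_000, -12_000, 18_000, -25_000, 32_000, -40_000, 45_000, -48_000]
_DORC_OFFSETS_FAR = [150_000, -300_000]


def _build_peaks(config: SimulationConfig, genes: pd.DataFrame, roles: dict):
    """Peak intervals: per-gene promoters, program body peaks, DORC blocks,
    and random background peaks. Returns (peaks df, peak role arrays)."""
    recs = []  # (chrom, start, end, kind, gene)

    for g, row in genes.iterrows():
        tss = int(row["tss"])
        recs.append((row["chrom"], max(0, tss - 200), tss + 300, "promoter", g))
    program = set(roles["immune_program"]) | set(roles["damage_program"])
    for g in sorted(program):
        row = genes.loc[g]
        tss, strand = int(row["tss"]), row["strand"]
        if strand == "+":
            s = tss + 1_500
        else:
            s = tss - 2_000
        recs.append((row["chrom"], max(0, s), max(0, s) + 500, "program_body", g))
    dorc_peak_meta = []  # (gene, rho, within_50kb) aligned with dorc peak records
    for g, n_linked, rho in config.dorc_genes:
        row = genes.loc[g]
        tss = int(row["tss"])
        offsets = _DORC_OFFSETS_50KB[:n_linked]
        if len(offsets) < n_linked:
            raise ConfigurationError(f"dorc gene {g}: at most 8 linked peaks supported")
        for off in offsets:
            s = max(0, tss + off)
            recs.append((row["chrom"], s, s + 500, "dorc", g))
            dorc_peak_meta.append((g, rho, True))
        for off in _DORC_OFFSETS_FAR:
            s = max(0, tss + off)
            recs.append((row["chrom"], s, s + 500, "dorc", g))
            dorc_peak_meta.append((g, rho, False))

    n_background = config.n_peaks - len(recs)
    if n_background < 0:
        raise ConfigurationError(
            f"n_peaks={config.n_peaks} too small; structural peaks need {len(recs)}"
        )
    rng_bg = np.random.default_rng(config.seed + 7_777)  # layout only, not counts
    chrom_len = (max(len(genes), 2) // 2 + 2) * _GENE_SPACING
    for _ in range(n_background):
        chrom = "chr1" if rng_bg.random() < 0.5 else "chr2"
        s = int(rng_bg.integers(0, chrom_len))
        recs.append((chrom, s, s + 500, "background", ""))

    peaks = pd.DataFrame(recs, columns=["chrom", "start", "end", "kind", "gene"])
    peaks.index = pd.Index([f"P{i + 1:06d}" for i in range(len(peaks))], name="peak")
    return peaks, dorc_peak_meta


def _assign_roles(config: SimulationConfig, genes: pd.DataFrame) -> dict:
    auto = [g for g in genes.index if genes.loc[g, "chrom"] in ("chr1", "chr2")]
    auto = [g for g in auto if not g.startswith("TF")]
    dorc = [g for g, _, _ in config.dorc_genes]
    missing = set(dorc) - set(genes.index)
    if missing:
        raise ConfigurationError(f"dorc genes absent from annotation: {sorted(missing)}")
    pool = [g for g in auto if g not in set(dorc)]
    n_imm, n_dam = config.immune_program_size, config.damage_program_size
    n_targets = 4 * config.n_tf_targets
    if len(pool) < n_imm + n_dam + n_targets:
        raise ConfigurationError("gene pool too small for programs and TF targets")
    immune_program = pool[:n_imm]
    damage_program = pool[n_imm : n_imm + n_dam]
    tf_targets = {}
    planted_tfs = ["TF01", "TF02", "TF03", "TF04"]
    off = n_imm + n_dam
    for k, tf in enumerate(planted_tfs):
        tf_targets[tf] = pool[off + k * config.n_tf_targets : off + (k + 1) * config.n_tf_targets]
    return {
        "immune_program": immune_program,
        "damage_program": damage_program,
        "dorc": dorc,
        "tf_targets": tf_targets,
        "planted_tfs": planted_tfs,
    }


def simulate_multiome(config: SimulationConfig) -> tuple[MultiomeDataset, GroundTruth]:
    """Generate a paired RNA+ATAC dataset and its ground-truth ledger.

    Identical configuration (including seed) yields byte-identical output.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_cells, rng_latent, rng_rna, rng_atac, rng_emb = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    genes = _build_genes(config)
    roles = _assign_roles(config, genes)
    peaks, dorc_peak_meta = _build_peaks(config, genes, roles)
    cells = _build_cells(config, rng_cells)
    n_cells = len(cells)
    n_genes = len(genes)

    # ---- latent structure -------------------------------------------------
    timepoint = cells["timepoint"].to_numpy()
    is_female = (cells["sex"] == "F").to_numpy()
    immune_act = cells["activation"].to_numpy()  # 0 for nonimmune cells
    damage_act = cells["damage_activation"].to_numpy()
    chromatin_immune = cells["chromatin_immune"].to_numpy()

    # DORC latents: shared factor per gene; gene/peak loadings set the
    # planted correlation (with a small boost compensating count noise)
    dorc_gene_latent = {}
    dorc_peak_latents = []
    for g, n_linked, rho in config.dorc_genes:
        a = np.sqrt(min(0.98, 1.4 * rho))
        z = rng_latent.normal(size=n_cells)
        u_g = a * z + np.sqrt(1 - a * a) * rng_latent.normal(size=n_cells)
        dorc_gene_latent[g] = u_g
        n_total = n_linked + len(_DORC_OFFSETS_FAR)
        for _ in range(n_total):
            u_p = a * z + np.sqrt(1 - a * a) * rng_latent.normal(size=n_cells)
            dorc_peak_latents.append(u_p)

    # TF latents: per-cell regulator activity, elevated at the active stage
    tf_latent = {}
    stage_level = {
        "TF01": {"peak": 1.3},  # peak-stage activator
        "TF02": {tp: 0.7 for tp in TIMEPOINTS},
        "TF03": {tp: 0.7 for tp in TIMEPOINTS},
        "TF04": {tp: 0.7 for tp in TIMEPOINTS},
    }
    for tf in roles["planted_tfs"]:
        base = np.array([stage_level[tf].get(tp, 0.05) for tp in timepoint])
        tf_latent[tf] = base + 0.4 * rng_latent.normal(size=n_cells)

    # ---- RNA mean matrix --------------------------------------------------
    rng_means = np.random.default_rng(ss.spawn(1)[0])
    base_mean = np.exp(rng_means.normal(np.log(0.3), 1.0, size=n_genes))
    gene_pos = {g: i for i, g in enumerate(genes.index)}
    for g in roles["immune_program"] + roles["damage_program"]:
        base_mean[gene_pos[g]] = max(base_mean[gene_pos[g]], 0.3)
    for g in roles["dorc"]:
        base_mean[gene_pos[g]] = 40.0
    for tf in roles["planted_tfs"]:
        # the peak-stage activator is essentially silent outside its stage;
        # constitutive activators are expressed throughout
        base_mean[gene_pos[tf]] = 0.08 if tf == "TF01" else 3.0
    for tgts in roles["tf_targets"].values():
        for g in tgts:
            base_mean[gene_pos[g]] = 3.0
    for g in _SEX_GENES_FEMALE + _SEX_GENES_MALE:
        base_mean[gene_pos[g]] = 0.02

    lib_rna = np.exp(rng_cells.normal(0.0, 0.3, size=n_cells))
    log_mu = np.log(base_mean)[:, None] + np.log(lib_rna)[None, :]

    # immune/damage program induction: per-gene log-fold chosen so one unit
    # of effect size moves the module score by about one control s.d.
    delta_imm = (
        _SCORE_GAIN
        * config.immune_effect_size
        * np.sqrt(2.0 / config.immune_program_size)
        * _LOG_SD
    )
    delta_dam = (
        _SCORE_GAIN
        * config.immune_effect_size
        * np.sqrt(2.0 / config.damage_program_size)
        * _LOG_SD
    )
    imm_idx = np.array([gene_pos[g] for g in roles["immune_program"]])
    dam_idx = np.array([gene_pos[g] for g in roles["damage_program"]])
    log_mu[np.ix_(imm_idx, np.arange(n_cells))] += delta_imm * immune_act[None, :]
    log_mu[np.ix_(dam_idx, np.arange(n_cells))] += delta_dam * damage_act[None, :]

    for g, u in dorc_gene_latent.items():
        log_mu[gene_pos[g]] += 1.2 * u
    for tf in roles["planted_tfs"]:
        u = tf_latent[tf]
        log_mu[gene_pos[tf]] += (1.8 if tf == "TF01" else 0.9) * u
        coupling = 0.4 if tf == "TF01" else 0.45
        for tgt in roles["tf_targets"][tf]:
            log_mu[gene_pos[tgt]] += coupling * u + 0.15 * rng_latent.normal(size=n_cells)

    # sex markers
    xist = gene_pos[_SEX_GENES_FEMALE[0]]
    log_mu[xist, is_female] = np.log(6.0 * lib_rna[is_female])
    for g in _SEX_GENES_MALE:
        i = gene_pos[g]
        log_mu[i, ~is_female] = np.log(2.0 * lib_rna[~is_female])

    rna = _nb_counts_sparse(rng_rna, np.exp(log_mu), config.dispersion)
    del log_mu

    # ---- ATAC mean matrix -------------------------------------------------
    kind = peaks["kind"].to_numpy()
    peak_gene = peaks["gene"].to_numpy()
    base_rate = np.where(
        kind == "promoter", 0.6, np.where(kind == "dorc", 4.0, np.where(kind == "program_body", 0.5, 0.25))
    ).astype(float)
    lib_atac = np.exp(rng_cells.normal(0.0, 0.3, size=n_cells))
    log_mu_a = np.log(base_rate)[:, None] + np.log(lib_atac)[None, :]

    program = set(roles["immune_program"]) | set(roles["damage_program"])
    atac_effect = 0.4 * config.immune_effect_size
    leak = rng_atac.random((int(np.isin(kind, ["program_body"]).sum()), n_cells)) < 0.05
    body_rows = np.flatnonzero(kind == "program_body")
    for j, r in enumerate(body_rows):
        open_cells = chromatin_immune | leak[j]
        log_mu_a[r, ~open_cells] = np.log(0.02 * lib_atac[~open_cells])
        log_mu_a[r, open_cells] += atac_effect
    promoter_rows = np.flatnonzero(kind == "promoter")
    prog_promoters = promoter_rows[np.isin(peak_gene[promoter_rows], sorted(program))]
    log_mu_a[np.ix_(prog_promoters, np.flatnonzero(chromatin_immune))] += atac_effect

    dorc_rows = np.flatnonzero(kind == "dorc")
    for j, r in enumerate(dorc_rows):
        log_mu_a[r] += 1.4 * dorc_peak_latents[j]

    # TF target promoters co-vary with the TF latent
    for tf in roles["planted_tfs"]:
        u = tf_latent[tf]
        tgt_rows = promoter_rows[np.isin(peak_gene[promoter_rows], roles["tf_targets"][tf])]
        log_mu_a[np.ix_(tgt_rows, np.arange(n_cells))] += (
            0.55 * u[None, :] + 0.2 * rng_latent.normal(size=(len(tgt_rows), n_cells))
        )

    atac = _nb_counts_sparse(rng_atac, np.exp(log_mu_a), config.dispersion * 0.5)
    del log_mu_a

    # off-peak fragments so FRiP is in a realistic 0.6-0.8 band
    in_peak = np.asarray(atac.sum(axis=0)).ravel()
    off_peak = rng_atac.poisson(np.maximum(in_peak, 1) * 0.42)
    frip_total = in_peak + off_peak

    # ---- metadata ---------------------------------------------------------
    centers = {ct: (4.0 * i, 3.0 * ((i * 7) % 3)) for i, (ct, _) in enumerate(config.cell_types)}
    cx = np.array([centers[c][0] for c in cells["cell_type"]])
    cy = np.array([centers[c][1] for c in cells["cell_type"]])
    cells_meta = cells.copy()
    cells_meta["embedding_x"] = cx + rng_emb.normal(0, 1.1, n_cells)
    cells_meta["embedding_y"] = cy + rng_emb.normal(0, 1.1, n_cells)
    cells_meta["atac_fragments_total"] = frip_total
    cells_meta["pct_mito"] = rng_emb.beta(2.0, 60.0, size=n_cells)

    # ---- ledger -----------------------------------------------------------
    truth_cells = cells_meta[
        ["sample", "replicate", "timepoint", "cell_type", "sex", "immune", "damage", "primed", "chromatin_immune"]
    ].copy()
    truth_genes = pd.DataFrame(index=genes.index)
    truth_genes["immune_program"] = truth_genes.index.isin(roles["immune_program"])
    truth_genes["damage_program"] = truth_genes.index.isin(roles["damage_program"])
    dorc_ok = {g for g, k, _ in config.dorc_genes if k >= 5}
    truth_genes["dorc"] = truth_genes.index.isin(dorc_ok)
    truth_genes["tf"] = truth_genes.index.str.startswith("TF")

    link_recs = []
    dorc_peak_ids = peaks.index[dorc_rows]
    for (g, rho, near), pid in zip(dorc_peak_meta, dorc_peak_ids):
        link_recs.append((g, pid, rho, near))
    links = pd.DataFrame(link_recs, columns=["gene", "peak", "rho", "within_50kb"])

    tf_recs = []
    for tf in roles["planted_tfs"]:
        active = "peak" if tf == "TF01" else "all"
        for tgt in roles["tf_targets"][tf]:
            tf_recs.append((tf, tgt, active))
    tf_programs = pd.DataFrame(tf_recs, columns=["tf", "target", "active_timepoint"])

    motif_recs = []
    for tf in roles["planted_tfs"]:
        tgt_rows = promoter_rows[np.isin(peak_gene[promoter_rows], roles["tf_targets"][tf])]
        for r in tgt_rows:
            motif_recs.append((peaks.index[r], tf))
    rng_motif = np.random.default_rng(config.seed + 11_111)
    decoys = [f"TF{j + 1:02d}" for j in range(4, config.n_tfs)]
    bg_rows = np.flatnonzero(kind == "background")
    for tf in decoys:
        chosen = rng_motif.choice(bg_rows, size=min(config.n_tf_targets, len(bg_rows)), replace=False)
        for r in chosen:
            motif_recs.append((peaks.index[r], tf))
    motifs = pd.DataFrame(motif_recs, columns=["peak", "tf"])

    dataset = MultiomeDataset(
        rna=rna,
        atac=atac,
        genes=genes,
        peaks=peaks[["chrom", "start", "end", "kind", "gene"]],
        cells=cells_meta.drop(
            columns=["immune", "damage", "primed", "chromatin_immune", "activation", "damage_activation"]
        ),
    )
    truth = GroundTruth(
        cells=truth_cells,
        genes=truth_genes,
        links=links,
        tf_programs=tf_programs,
        motifs=motifs,
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# bulk IFN-gamma dose / washout / rechallenge experiment
# ---------------------------------------------------------------------------

BULK_CONDITIONS = ("control", "dose1_0h", "dose1_96h", "dose2")


@dataclass
class BulkMemoryData:
    """Bulk RNA and region-level ATAC count tables for the dose-rechallenge
    design, with sample metadata and the planted-gene ledger."""

    rna: pd.DataFrame  # genes x samples, integer counts
    atac: pd.DataFrame  # regions x samples, integer counts
    samples: pd.DataFrame  # sample, condition, replicate
    region_genes: pd.Series  # region id -> gene id
    truth: pd.DataFrame  # per gene: memory, asterisk, transient


def simulate_bulk_memory(
    n_genes: int = 2000,
    n_memory_genes: int = 150,
    n_replicates: int = 3,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.05,
    atac_dispersion: float = 0.02,
    seed: int = 0,
    n_transient_genes: int = 50,
    dose2_boost_fraction: float = 0.5,
) -> BulkMemoryData:
    """Simulate the 1x/2x stimulus experiment behind epigenetic-memory gating.

    Memory genes are upregulated on the first dose (RNA), keep their
    accessibility unchanged between the end of dose 1 and the washout
    (ATAC), and a ``dose2_boost_fraction`` subset is further upregulated on
    the second dose. Transient genes respond on dose 1 but lose
    accessibility after washout; remaining genes are exchangeable across
    conditions.
    """
    if n_memory_genes + n_transient_genes > n_genes:
        raise ConfigurationError("memory + transient genes exceed n_genes")
    if n_replicates < 2:
        raise ConfigurationError("at least 2 replicates are required")
    ss = np.random.SeedSequence(seed)
    rng_base, rng_rna, rng_atac = (np.random.default_rng(s) for s in ss.spawn(3))

    gene_ids = pd.Index([f"BG{i + 1:05d}" for i in range(n_genes)], name="gene")
    memory = np.zeros(n_genes, dtype=bool)
    memory[:n_memory_genes] = True
    transient = np.zeros(n_genes, dtype=bool)
    transient[n_memory_genes : n_memory_genes + n_transient_genes] = True
    n_boost = int(round(dose2_boost_fraction * n_memory_genes))
    asterisk = np.zeros(n_genes, dtype=bool)
    asterisk[:n_boost] = True

    base = np.exp(rng_base.normal(np.log(100.0), 1.0, size=n_genes))
    samples = []
    for cond in BULK_CONDITIONS:
        for r in range(1, n_replicates + 1):
            samples.append((f"{cond}_r{r}", cond, f"r{r}"))
    samples = pd.DataFrame(samples, columns=["sample", "condition", "replicate"]).set_index(
        "sample"
    )
    lib = np.exp(rng_base.normal(0.0, 0.15, size=len(samples)))

    fold1 = 2.0**effect_log2fc
    rna_mu = np.tile(base[:, None], (1, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        cond = row["condition"]
        m = np.ones(n_genes)
        if cond == "dose1_0h":
            m[memory] = fold1
            m[transient] = fold1
        elif cond == "dose1_96h":
            m[memory] = 1.0  # expression returns to baseline during washout
            m[transient] = 1.0
        elif cond == "dose2":
            m[memory] = fold1
            m[memory & asterisk] = fold1 * 2.0**1.5
            m[transient] = fold1
        rna_mu[:, j] = base * m * lib[j]
    rna = pd.DataFrame(
        _nb_counts(rng_rna, rna_mu, dispersion), index=gene_ids, columns=samples.index
    )

    # one 1-kb regulatory region per gene
    region_ids = pd.Index([f"R{i + 1:05d}" for i in range(n_genes)], name="region")
    region_genes = pd.Series(gene_ids, index=region_ids)
    abase = np.exp(rng_base.normal(np.log(50.0), 0.6, size=n_genes))
    atac_mu = np.tile(abase[:, None], (1, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        cond = row["condition"]
        m = np.ones(n_genes)
        if cond in ("dose1_0h", "dose1_96h"):
            # memory chromatin opens on dose 1 and STAYS open through washout
            m[memory] = 3.0
            m[transient] = 3.0 if cond == "dose1_0h" else 1.0
        elif cond == "dose2":
            m[memory] = 3.5
        atac_mu[:, j] = abase * m * lib[j]
    atac = pd.DataFrame(
        _nb_counts(rng_atac, atac_mu, atac_dispersion), index=region_ids, columns=samples.index
    )

    truth = pd.DataFrame(
        {"memory": memory, "asterisk": asterisk & memory, "transient": transient},
        index=gene_ids,
    )
    return BulkMemoryData(rna=rna, atac=atac, samples=samples, region_genes=region_genes, truth=truth)
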