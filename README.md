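# olgstate

Analysis pipeline for disease-stage-dependent immune states of
oligodendroglia (OLG) in paired single-cell RNA+ATAC (10x multiome) data
from the EAE mouse model of multiple sclerosis, plus the paired bulk
RNA/ATAC workflow for calling interferon-induced epigenetic-memory genes.

The pipeline covers, as importable library modules driven by numbered
analysis scripts:

* **`qc`** — per-sample cell filtering, FRiP, log-normalization
  (`ln(1 + c/N * 10^4)`), TF-IDF peak normalization, strand-aware gene
  activity (gene body + 500 bp upstream of the TSS), variable-feature
  selection.
* **`scoring`** — gene-set module scores (expression-bin-matched controls)
  and the Gaussian-null status classifier: with mu and sigma fitted to the
  control population's scaled scores,
  `F(x) = 1/2 [1 + erf((x - mu)/(sigma sqrt 2))]`, and a cell is called
  immune (or damage-associated) when `P = 1 - F(x) < 0.05`. Runs on
  expression and on gene activity (chromatin-primed states), with joint
  IFN/damage labels.
* **`linking`** — peak-gene links (positive Pearson r, p < 0.05, peak
  center within 50 kb of the TSS, >= 10 cells), per-cell enhancer scores
  (linked-peak fragments / in-peak fragments x 10^4), DORC genes
  (>= 5 linked peaks, re-linked at 500 kb), 100-bp normalized genome
  tracks.
* **`diff`** — pseudobulk (sample x cell type) NB-GLM Wald tests over the
  stage contrasts early/control, peak/early, late/early, peak/late;
  selection at |log2FC| > 1, padj < 0.01, baseMean > 1; Type 1-4 temporal
  classification on 0-1-scaled stage profiles.
* **`grn`** — regression GRN on (TF expression x peak accessibility)
  products; TF activity = mean coefficient x mean TF expression per stage,
  with per-stage ranking.
* **`cohort`** — X/Y-marker logistic-regression sex classifier with
  balanced training and holdout metrics; normalized LISI replicate-mixing
  scores on a 2-D embedding.
* **`windows`** — nonoverlapping 1-kb TSS windows and cCRE-derived
  enhancer regions, any-overlap fragment counting, TMM-normalized NB-GLM
  likelihood-ratio tests, and the epigenetic-memory gene gate (RNA up on
  dose 1 with p and FDR < 0.05; accessibility stable across washout with
  |logFC| < 0.5 and FDR > 0.05).
* **`simulate`** — a paired RNA+ATAC generator (and a bulk dose/washout/
  rechallenge generator) with a complete ground-truth ledger, so every
  procedure above is validated by parameter recovery.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/03_immune_status.py
```

prints (seed 1, 5,600 cells):

```
stage  planted_immune  recovered_expression  recovered_chromatin
early          0.2683                0.2617               0.1950
 peak          0.6758                0.6692               0.4100
 late          0.3275                0.3500               0.2158
```

Reading: at each disease stage the expression-based classifier recovers
the planted immune-cell fraction to within a few cells per hundred
(alpha = 0.05 false calls and ~5% misses roughly offset), while the
chromatin-based classifier calls roughly half as many cells — only part of
the immune population carries open program chromatin, and a small primed
population is chromatin-positive without expressing the program.

The remaining drivers follow the same pattern: `04_link_dorcs.py` recovers
exactly the planted >= 5-peak DORC genes with no false positives,
`06_tf_activity.py` ranks the planted peak-stage activator first at the
peak stage (and 7th at control), `07_cohort_qc.py` reports ~99.9% holdout
sex-classification accuracy and >= 99% of cells with normalized LISI >= 0.5
in every condition, and `08_memory_gating.py` recovers 149 of 150 planted
memory genes with a 0.2% false-call rate. Each script states what it found
on stdout and writes its tables under `results/`.

A thin CLI mirrors the library (`olgstate simulate | qc | normalize |
score | link | dorc | diff | sex | lisi | windows | memory`); run
`olgstate --help` for the file formats (MatrixMarket + TSV fixtures, BED,
GTF, bedGraph).

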