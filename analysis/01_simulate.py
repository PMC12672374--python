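#!/usr/bin/env python
"""Generate the synthetic paired multiome cohort used by the downstream
analysis steps and write it (plus its ground-truth ledger) to
results/cohort/.

The cohort mirrors the study design: naive and adjuvant (CFA) controls
plus early / peak / late disease stages with replicates, a planted immune
program whose per-stage frequency follows the observed immune-OLG time
course, chromatin priming, DORC peak blocks, X/Y sex markers and planted
transcription-factor programs.
"""
from pathlib import Path

from olgstate import SimulationConfig, simulate_multiome
from olgstate.io import write_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 1


def main() -> None:
    cfg = SimulationConfig(n_cells_per_sample=400, seed=SEED)
    dataset, truth = simulate_multiome(cfg)
    write_fixture(dataset, OUT, truth=truth)
    frac = truth.cells.groupby("timepoint")["immune"].mean()
    print(f"wrote {dataset.n_cells} cells x {len(dataset.genes)} genes / "
          f"{len(dataset.peaks)} peaks to {OUT}")
    print("planted immune fractions by stage:")
    print(frac.round(4).to_string())


if __name__ == "__main__":
    main()
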