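"""On-disk fixture format: MatrixMarket matrices plus TSV/BED/GTF sidecars.

Coordinate dialects are converted at the reader/writer boundary: BED is
0-based half-open, GTF is 1-based inclusive; all in-memory intervals are
0-based half-open.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datatypes import GroundTruth, MultiomeDataset

_GTF_SOURCE = "olgstate"


def write_fixture(dataset: MultiomeDataset, directory, truth: GroundTruth | None = None) -> None:
    """Write a dataset (and optionally its ledger) as plain-text files.

    Emits rna.mtx / atac.mtx (integer coordinate MatrixMarket), genes.tsv,
    peaks.tsv, barcodes.tsv, cells.tsv, peaks.bed (BED with a name column),
    genes.gtf (GTF2.2) and truth.json.
    """
    if dataset.n_cells == 0 or len(dataset.genes) == 0:
        raise ValueError("refusing to write an empty dataset")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(d / "rna.mtx", dataset.rna.tocoo(), field="integer")
    sio.mmwrite(d / "atac.mtx", dataset.atac.tocoo(), field="integer")
    dataset.genes.to_csv(d / "genes.tsv", sep="\t")
    dataset.peaks.to_csv(d / "peaks.tsv", sep="\t")
    pd.Series(dataset.cells.index, name="barcode").to_csv(
        d / "barcodes.tsv", sep="\t", index=False
    )
    dataset.cells.to_csv(d / "cells.tsv", sep="\t")

    bed = dataset.peaks[["chrom", "start", "end"]].copy()
    bed["name"] = dataset.peaks.index
    bed.to_csv(d / "peaks.bed", sep="\t", header=False, index=False)

    with open(d / "genes.gtf", "w") as fh:
        for g, row in dataset.genes.iterrows():
            attrs = f'gene_id "{g}"; tss "{int(row["tss"])}";'
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]),
                        _GTF_SOURCE,
                        "gene",
                        str(int(row["start"]) + 1),  # GTF is 1-based inclusive
                        str(int(row["end"])),
                        ".",
                        str(row["strand"]),
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )

    if truth is not None:
        payload = {
            "cells": truth.cells.reset_index().to_dict(orient="list"),
            "genes": truth.genes.reset_index().to_dict(orient="list"),
            "links": truth.links.to_dict(orient="list"),
            "tf_programs": truth.tf_programs.to_dict(orient="list"),
            "motifs": truth.motifs.to_dict(orient="list"),
        }
        with open(d / "truth.json", "w") as fh:
            json.dump(payload, fh)


def read_fixture(directory) -> MultiomeDataset:
    """Read a dataset previously written by :func:`write_fixture`."""
    d = Path(directory)
    rna = sp.csr_matrix(sio.mmread(d / "rna.mtx")).astype(np.int64)
    atac = sp.csr_matrix(sio.mmread(d / "atac.mtx")).astype(np.int64)
    genes = pd.read_csv(d / "genes.tsv", sep="\t", index_col=0)
    peaks = pd.read_csv(d / "peaks.tsv", sep="\t", index_col=0, keep_default_na=False)
    cells = pd.read_csv(d / "cells.tsv", sep="\t", index_col=0)
    return MultiomeDataset(rna=rna, atac=atac, genes=genes, peaks=peaks, cells=cells)


def read_truth(directory) -> GroundTruth:
    with open(Path(directory) / "truth.json") as fh:
        payload = json.load(fh)
    cells = pd.DataFrame(payload["cells"]).set_index("barcode")
    genes = pd.DataFrame(payload["genes"]).set_index("gene")
    return GroundTruth(
        cells=cells,
        genes=genes,
        links=pd.DataFrame(payload["links"]),
        tf_programs=pd.DataFrame(payload["tf_programs"]),
        motifs=pd.DataFrame(payload["motifs"]),
    )


def read_gtf_genes(path) -> pd.DataFrame:
    """Parse gene records from a GTF into the package's 0-based annotation."""
    recs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "gene":
                continue
            attrs = dict(
                kv.strip().split(" ", 1) for kv in f[8].strip().strip(";").split(";")
            )
            gid = attrs["gene_id"].strip('"')
            start = int(f[3]) - 1
            end = int(f[4])
            strand = f[6]
            if "tss" in attrs:
                tss = int(attrs["tss"].strip('"'))
            else:
                tss = start if strand == "+" else end - 1
            recs.append((gid, f[0], start, end, strand, tss))
    return pd.DataFrame(
        recs, columns=["gene", "chrom", "start", "end", "strand", "tss"]
    ).set_index("gene")


def read_bed(path, names: tuple[str, ...] = ("chrom", "start", "end")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = list(names) + [f"col{i}" for i in range(len(names), df.shape[1])]
    df.columns = cols[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, extra_cols: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra_cols or [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)
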