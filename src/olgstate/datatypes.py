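"""Core in-memory containers shared across the pipeline.

Matrices are oriented features x cells (the MatrixMarket convention used by
10x-style exports); cell metadata rows key matrix columns by position.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp

TIMEPOINTS = ("naive", "cfa", "early", "peak", "late")

Modality = Literal["expression", "chromatin"]
NormMethod = Literal["lognorm", "tfidf", "geneactivity-lognorm", "standardized"]


def _as_csr(m) -> sp.csr_matrix:
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m))


@dataclass
class NormalizedMatrix:
    """A features x cells matrix of normalized values with labelled axes.

    ``values`` is dense or CSR sparse; log-normalized and TF-IDF matrices
    preserve the sparsity pattern of the raw counts (zero count -> zero
    value), standardized matrices are dense.
    """

    values: object  # np.ndarray or sp.csr_matrix, features x cells
    features: pd.Index
    cells: pd.Index
    method: NormMethod
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.features = pd.Index(self.features)
        self.cells = pd.Index(self.cells)
        if self.values.shape != (len(self.features), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.features)} features x {len(self.cells)} cells"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def row(self, feature: str) -> np.ndarray:
        i = self.features.get_loc(feature)
        v = self.values[i]
        return v.toarray().ravel() if sp.issparse(v) else np.asarray(v).ravel()

    def subset_features(self, keep) -> "NormalizedMatrix":
        idx = self.features.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            missing = pd.Index(keep)[idx < 0]
            raise KeyError(f"features not present: {list(missing[:5])}")
        return replace(self, values=self.values[idx], features=pd.Index(keep))

    def subset_cells(self, keep) -> "NormalizedMatrix":
        idx = self.cells.get_indexer(pd.Index(keep))
        if (idx < 0).any():
            missing = pd.Index(keep)[idx < 0]
            raise KeyError(f"cells not present: {list(missing[:5])}")
        return replace(self, values=self.values[:, idx], cells=pd.Index(keep))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.features, columns=self.cells)


@dataclass
class MultiomeDataset:
    """Paired RNA and peak-accessibility count matrices over one cell set.

    rna : CSR int matrix, genes x cells
    atac : CSR int matrix, peaks x cells
    genes : DataFrame indexed by gene id with chrom, start, end, strand, tss
    peaks : DataFrame indexed by peak id with chrom, start, end
        (0-based half-open intervals)
    cells : DataFrame indexed by barcode with sample, replicate, timepoint,
        cell_type and optional sex / embedding_x / embedding_y columns
    """

    rna: sp.csr_matrix
    atac: sp.csr_matrix
    genes: pd.DataFrame
    peaks: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.rna = _as_csr(self.rna)
        self.atac = _as_csr(self.atac)
        if self.rna.shape != (len(self.genes), len(self.cells)):
            raise ValueError("rna matrix shape does not match gene/cell tables")
        if self.atac.shape != (len(self.peaks), len(self.cells)):
            raise ValueError("atac matrix shape does not match peak/cell tables")
        if (self.rna.data < 0).any() or (self.atac.data < 0).any():
            raise ValueError("count matrices must be non-negative")
        bad = self.peaks["start"] >= self.peaks["end"]
        if bad.any():
            raise ValueError(f"{int(bad.sum())} peaks with start >= end")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, mask_or_ids) -> "MultiomeDataset":
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and np.asarray(
            mask_or_ids
        ).dtype == bool:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        else:
            idx = self.cells.index.get_indexer(pd.Index(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset")
        return MultiomeDataset(
            rna=self.rna[:, idx],
            atac=self.atac[:, idx],
            genes=self.genes,
            peaks=self.peaks,
            cells=self.cells.iloc[idx],
        )

    def to_anndata(self):
        """Cells x features AnnData pair (requires anndata)."""
        import anndata as ad

        rna = ad.AnnData(X=self.rna.T.tocsr(), obs=self.cells.copy(), var=self.genes.copy())
        atac = ad.AnnData(X=self.atac.T.tocsr(), obs=self.cells.copy(), var=self.peaks.copy())
        return rna, atac


@dataclass
class GroundTruth:
    """Exhaustive ledger of every structure planted by the simulator."""

    cells: pd.DataFrame  # index barcode: immune, damage, primed, sex, cell_type
    genes: pd.DataFrame  # index gene id: immune_program, damage_program, dorc, tf
    links: pd.DataFrame  # gene, peak, rho, within_50kb
    tf_programs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["tf", "target", "active_timepoint"])
    )
    motifs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["peak", "tf"])
    )

    def planted_link_set(self, within_50kb: bool | None = None) -> set[tuple[str, str]]:
        df = self.links
        if within_50kb is not None:
            df = df[df["within_50kb"] == within_50kb]
        return set(zip(df["gene"], df["peak"]))
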