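"""Core containers: sparse genes x cells counts and per-cell metadata.

The package works on a genes-by-cells orientation throughout (matching the
Matrix Market layout written by the simulator and read by :mod:`trmtime.ingest`),
with cell metadata held in a plain :class:`pandas.DataFrame` carrying at least
``barcode``, ``tissue`` and ``day`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

REQUIRED_META_COLUMNS = ("barcode", "tissue", "day")

#: Canonical T cell markers used for the default QC filter.
CANONICAL_T_CELL_MARKERS = ("Cd3d", "Cd8a", "Trac")


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ConfigurationError(ValueError):
    """Raised when caller-supplied configuration is inconsistent."""


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes as rows, cells as columns.

    Parameters
    ----------
    genes
        Ordered, unique gene identifiers (one per row).
    barcodes
        Ordered, unique cell barcodes (one per column).
    counts
        ``genes x cells`` sparse matrix of non-negative integers.
    """

    genes: pd.Index
    barcodes: pd.Index
    counts: sp.csr_matrix = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        self.barcodes = pd.Index(self.barcodes, name="barcode")
        if not self.genes.is_unique:
            dups = self.genes[self.genes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dups[:5]}")
        if not self.barcodes.is_unique:
            dups = self.barcodes[self.barcodes.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate cell barcodes: {dups[:5]}")
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def subset_cells(self, barcodes) -> "CountMatrix":
        """Return a new matrix restricted to ``barcodes`` (order preserved)."""
        idx = self.barcodes.get_indexer(pd.Index(barcodes))
        if (idx < 0).any():
            missing = list(pd.Index(barcodes)[idx < 0][:5])
            raise ValidationError(f"unknown barcodes: {missing}")
        return CountMatrix(self.genes, pd.Index(barcodes), self.counts[:, idx])

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.genes.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            missing = list(pd.Index(genes)[idx < 0][:5])
            raise ValidationError(f"unknown genes: {missing}")
        return CountMatrix(pd.Index(genes), self.barcodes, self.counts[idx, :])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


def validate_meta(meta: pd.DataFrame, barcodes: pd.Index) -> pd.DataFrame:
    """Align cell metadata to a barcode list, enforcing the 1:1 invariant.

    Every barcode in ``barcodes`` must have exactly one metadata row; extra
    metadata rows are the caller's responsibility (see ``read_counts`` which
    drops them with a logged warning).
    """
    missing = [c for c in REQUIRED_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata is missing required columns: {missing}")
    if meta["barcode"].duplicated().any():
        dups = meta.loc[meta["barcode"].duplicated(), "barcode"].tolist()
        raise ValidationError(f"duplicate metadata barcodes: {dups[:5]}")
    table = meta.set_index("barcode", drop=False)
    absent = pd.Index(barcodes).difference(table.index)
    if len(absent):
        raise ValidationError(
            f"{len(absent)} barcode(s) without metadata, e.g. {list(absent[:5])}"
        )
    aligned = table.loc[pd.Index(barcodes)].reset_index(drop=True)
    if (pd.to_numeric(aligned["day"], errors="coerce") < 0).any():
        raise ValidationError("metadata 'day' values must be non-negative")
    aligned["day"] = pd.to_numeric(aligned["day"])
    return aligned
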