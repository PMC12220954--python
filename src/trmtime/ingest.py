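"""Reading/writing 10x-style datasets and marker-based cell QC.

A dataset on disk is a Matrix Market file (genes x cells), ``genes.tsv``,
``barcodes.tsv`` and a ``cell_meta.tsv`` with columns
``barcode, tissue, day[, cluster]``.  QC keeps cells that express every
required canonical T cell marker (count > 0) and detect at least
``min_genes`` genes, mirroring the removal of contaminating populations that
lack Cd3d/Cd8a/Trac.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import (
    ConfigurationError,
    CountMatrix,
    ValidationError,
    validate_meta,
)

logger = logging.getLogger(__name__)


def read_counts(
    matrix_path, genes_path, barcodes_path, meta_path
) -> tuple[CountMatrix, pd.DataFrame]:
    """Read a Matrix Market dataset and align its cell metadata.

    Metadata rows whose barcode is absent from the matrix are dropped with a
    logged warning count; barcodes without metadata are an error.
    """
    for p in (matrix_path, genes_path, barcodes_path, meta_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input path does not exist: {p}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise ValidationError(f"malformed Matrix Market file {matrix_path}: {exc}")
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0]
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0]
    matrix = CountMatrix(pd.Index(genes), pd.Index(barcodes), sp.csr_matrix(mat))
    meta = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str})
    if "barcode" not in meta.columns:
        raise ValidationError("cell metadata must have a 'barcode' column")
    extra = ~meta["barcode"].isin(matrix.barcodes)
    if extra.any():
        logger.warning(
            "dropping %d metadata row(s) without a matching barcode", int(extra.sum())
        )
        meta = meta.loc[~extra]
    aligned = validate_meta(meta, matrix.barcodes)
    return matrix, aligned


def write_dataset(
    counts: CountMatrix,
    meta: pd.DataFrame,
    outdir,
    truth=None,
) -> dict[str, Path]:
    """Write matrix.mtx / genes.tsv / barcodes.tsv / cell_meta.tsv (+ truth.tsv)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "genes": outdir / "genes.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "meta": outdir / "cell_meta.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), counts.counts.tocoo(), field="integer")
    paths["genes"].write_text("\n".join(counts.genes) + "\n")
    paths["barcodes"].write_text("\n".join(counts.barcodes) + "\n")
    cols = ["barcode", "tissue", "day"] + (
        ["cluster"] if "cluster" in meta.columns else []
    )
    meta[cols].to_csv(paths["meta"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


@dataclass
class QcReport:
    """Kept/removed cell counts per tissue x day stratum plus settings."""

    per_stratum: pd.DataFrame
    n_input: int
    n_kept: int
    n_removed: int
    settings: dict

    def __post_init__(self) -> None:
        assert self.n_kept + self.n_removed == self.n_input


def qc_filter_cells(
    counts: CountMatrix,
    meta: pd.DataFrame,
    required_markers=(),
    min_genes: int = 200,
    mode: str = "all",
) -> tuple[CountMatrix, pd.DataFrame, QcReport]:
    """Keep cells expressing the required markers and >= ``min_genes`` genes.

    ``mode="all"`` (default) requires a positive count for every marker;
    ``mode="any"`` requires at least one.  With no markers and
    ``min_genes=0`` this is the identity filter.
    """
    if mode not in ("all", "any"):
        raise ConfigurationError(f"unknown QC mode: {mode!r}")
    required_markers = list(required_markers)
    missing = [m for m in required_markers if m not in counts.genes]
    if missing:
        raise ConfigurationError(f"required markers absent from gene list: {missing}")
    meta = validate_meta(meta, counts.barcodes)
    keep = np.ones(counts.n_cells, dtype=bool)
    if required_markers:
        idx = counts.genes.get_indexer(required_markers)
        marker_pos = (counts.counts[idx, :] > 0).toarray()
        keep &= marker_pos.all(axis=0) if mode == "all" else marker_pos.any(axis=0)
    n_detected = np.asarray((counts.counts > 0).sum(axis=0)).ravel()
    keep &= n_detected >= min_genes
    per_stratum = (
        pd.DataFrame(
            {"tissue": meta["tissue"], "day": meta["day"], "kept": keep}
        )
        .groupby(["tissue", "day"], observed=True)["kept"]
        .agg(kept="sum", total="count")
        .reset_index()
    )
    per_stratum["removed"] = per_stratum["total"] - per_stratum["kept"]
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValidationError(
            "QC removed every cell; review required_markers/min_genes thresholds"
        )
    report = QcReport(
        per_stratum=per_stratum,
        n_input=counts.n_cells,
        n_kept=n_kept,
        n_removed=counts.n_cells - n_kept,
        settings={
            "required_markers": required_markers,
            "min_genes": min_genes,
            "mode": mode,
        },
    )
    kept_barcodes = counts.barcodes[keep]
    return (
        counts.subset_cells(kept_barcodes),
        meta.loc[keep].reset_index(drop=True),
        report,
    )
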