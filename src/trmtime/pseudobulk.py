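"""Pseudobulk aggregation, CPM normalization and per-gene summaries.

Cells are summed into one profile per (tissue, timepoint) sample — the
profiles the temporal linear model consumes — then normalized to counts per
million and transformed as ``log2(CPM + 1)`` (base and pseudocount are
declared and configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .containers import ConfigurationError, CountMatrix, ValidationError

logger = logging.getLogger(__name__)

UNITS = ("raw-sum", "CPM", "LogCPM")


@dataclass
class PseudobulkMatrix:
    """Genes x samples matrix in a declared unit with sample metadata.

    ``samples`` is indexed by sample id with columns ``tissue``, ``day`` and
    ``n_cells``; ``params`` records normalization settings once applied.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValidationError("sample metadata does not align with value columns")
        if (self.samples["n_cells"] < 1).any():
            raise ValidationError("every pseudobulk sample needs n_cells >= 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def for_tissue(self, tissue: str) -> "PseudobulkMatrix":
        keep = self.samples.index[self.samples["tissue"] == tissue]
        if not len(keep):
            raise ValidationError(f"no pseudobulk samples for tissue {tissue!r}")
        return PseudobulkMatrix(
            self.values[keep], self.samples.loc[keep], self.unit, dict(self.params)
        )


@dataclass
class CorrelationResult:
    """A single correlation with its p-value; degenerate inputs are flagged."""

    method: str
    coefficient: float
    p_value: float
    n: int
    degenerate: bool = False
    note: str = ""


def aggregate_pseudobulk(
    counts: CountMatrix, meta: pd.DataFrame, group_keys=("tissue", "day")
) -> PseudobulkMatrix:
    """Sum counts over cells within each group (default: tissue x day)."""
    group_keys = list(group_keys)
    for key in group_keys:
        if key not in meta.columns:
            raise ConfigurationError(f"group key {key!r} not in metadata")
    groups = meta.groupby(group_keys, observed=True, sort=True).indices
    cols, records = {}, []
    for key, idx in sorted(
        groups.items(), key=lambda kv: kv[0] if isinstance(kv[0], tuple) else (kv[0],)
    ):
        key_t = key if isinstance(key, tuple) else (key,)
        sample_id = "|".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                             for k, v in zip(group_keys, key_t))
        sums = np.asarray(counts.counts[:, idx].sum(axis=1)).ravel()
        cols[sample_id] = sums
        rec = dict(zip(group_keys, key_t))
        rec["sample_id"] = sample_id
        rec["n_cells"] = len(idx)
        records.append(rec)
    samples = pd.DataFrame(records).set_index("sample_id")
    if "tissue" not in samples.columns:
        samples["tissue"] = "all"
    if "day" not in samples.columns:
        samples["day"] = np.nan
    values = pd.DataFrame(cols, index=counts.genes)
    return PseudobulkMatrix(values, samples, "raw-sum")


def normalize_log_cpm(
    pb: PseudobulkMatrix, pseudocount: float = 1.0, log_base: float = 2.0
) -> PseudobulkMatrix:
    """CPM-normalize raw sums and apply ``log_base(CPM + pseudocount)``."""
    if pb.unit != "raw-sum":
        raise ValidationError(f"expected raw-sum input, got {pb.unit}")
    totals = pb.values.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero-total pseudobulk sample(s): {list(zero)}")
    cpm = 1e6 * pb.values / totals
    logged = np.log(cpm + pseudocount) / np.log(log_base)
    return PseudobulkMatrix(
        logged,
        pb.samples.copy(),
        "LogCPM",
        {"pseudocount": pseudocount, "log_base": log_base},
    )


def pct_cells_expressing(
    counts: CountMatrix, meta: pd.DataFrame, tissue: str
) -> pd.Series:
    """Percentage (0-100) of a tissue's cells with count > 0, per gene."""
    mask = (meta["tissue"] == tissue).to_numpy()
    if not mask.any():
        raise ValidationError(f"tissue {tissue!r} not present in metadata")
    sub = counts.counts[:, mask]
    n_pos = np.asarray((sub > 0).sum(axis=1)).ravel()
    return pd.Series(100.0 * n_pos / mask.sum(), index=counts.genes, name="pct_cells")


def top_variance_genes(pb: PseudobulkMatrix, k: int = 500) -> list[str]:
    """The k genes with largest across-sample variance (ties: lexicographic)."""
    if k > len(pb.genes):
        raise ConfigurationError(f"k={k} exceeds {len(pb.genes)} genes")
    var = pb.values.var(axis=1, ddof=1)
    order = pd.DataFrame({"var": var, "gene": var.index}).sort_values(
        ["var", "gene"], ascending=[False, True]
    )
    return order["gene"].head(k).tolist()


def gene_summary(
    counts: CountMatrix, meta: pd.DataFrame, pb_logcpm: PseudobulkMatrix, tissue: str
) -> pd.DataFrame:
    """Per-gene %-cells-expressing and LogCPM variance within one tissue."""
    pct = pct_cells_expressing(counts, meta, tissue)
    var = pb_logcpm.for_tissue(tissue).values.var(axis=1, ddof=1)
    return pd.DataFrame({"pct_cells": pct, "variance": var})


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-sided p-value.

    Spearman uses average ranks for ties.  Zero variance in either vector
    yields a flagged degenerate result rather than a silent NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations for a p-value")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("inputs must be finite")
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            method, float("nan"), float("nan"), len(x), True, "zero variance input"
        )
    if method == "pearson":
        res = scipy.stats.pearsonr(x, y)
    else:
        res = scipy.stats.spearmanr(x, y)
    return CorrelationResult(method, float(res.statistic), float(res.pvalue), len(x))
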