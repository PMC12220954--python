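"""Per-gene temporal linear modeling and threshold-based gene selection.

For every gene within a tissue, ordinary least squares regresses pseudobulk
log2(CPM + 1) on encoded time.  Genes are called temporally associated when
the BH-adjusted q-value, the regression slope and the fraction of cells
expressing the gene all clear their thresholds (defaults FDR < 0.1,
slope > 0.15, % cells > 5).

Time is encoded as ``scaled01`` by default — days mapped affinely onto
[0, 1] — so the slope threshold is independent of the span of the course;
``days`` and ``index`` encodings are provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigurationError, ValidationError
from .pseudobulk import PseudobulkMatrix
from .signatures import GeneSignature

TIME_ENCODINGS = ("days", "index", "scaled01")

#: Residual sum of squares below which a fit is flagged as an exact line.
DEGENERATE_RSS = 1e-10

FIT_COLUMNS = [
    "gene",
    "tissue",
    "slope",
    "intercept",
    "se",
    "t",
    "p",
    "q",
    "pct_cells",
    "n_timepoints",
    "degenerate",
]


def encode_time(days: np.ndarray, encoding: str) -> np.ndarray:
    days = np.asarray(days, dtype=float)
    if encoding == "days":
        return days
    if encoding == "index":
        # rank of each distinct day, 0-based
        uniq = np.unique(days)
        return np.searchsorted(uniq, days).astype(float)
    if encoding == "scaled01":
        span = days.max() - days.min()
        if span == 0:
            raise ValidationError("cannot scale a single-day course onto [0, 1]")
        return (days - days.min()) / span
    raise ConfigurationError(f"unknown time encoding {encoding!r}")


def fit_temporal_models(
    pb: PseudobulkMatrix,
    time_encoding: str = "scaled01",
    pct_cells: pd.Series | dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """OLS of LogCPM on encoded time, per gene per tissue.

    ``pct_cells`` may be a Series (single tissue) or a mapping
    ``tissue -> Series``; genes without a value default to 100 so that the
    expression screen is a no-op when the caller supplies none.

    Returns one row per gene x tissue with slope, SE, two-sided p from the
    t-distribution on n-2 df, and BH q-values computed per tissue across all
    genes passing the minimal expression screen (pct_cells > 0).  Genes whose
    residual variance is (numerically) zero get the exact-line slope, p = 0
    and the degenerate flag, and are excluded from q-value ranking.
    """
    if pb.unit != "LogCPM":
        raise ValidationError(f"temporal model expects LogCPM input, got {pb.unit}")
    out = []
    for tissue in pb.samples["tissue"].unique():
        sub = pb.for_tissue(tissue)
        days = sub.samples["day"].to_numpy(dtype=float)
        if len(np.unique(days)) < 3:
            raise ValidationError(
                f"tissue {tissue!r} has fewer than 3 timepoints"
            )
        x = encode_time(days, time_encoding)
        order = np.argsort(x, kind="stable")
        x = x[order]
        y = sub.values.to_numpy(dtype=float)[:, order]
        if not np.isfinite(y).all():
            g, s = np.argwhere(~np.isfinite(y))[0]
            raise ValidationError(
                f"non-finite value for gene {sub.values.index[g]!r} in sample "
                f"{sub.values.columns[order[s]]!r}"
            )
        n = len(x)
        xc = x - x.mean()
        sxx = float(xc @ xc)
        slope = (y @ xc) / sxx
        intercept = y.mean(axis=1) - slope * x.mean()
        resid = y - (intercept[:, None] + slope[:, None] * x[None, :])
        rss = (resid**2).sum(axis=1)
        degenerate = rss <= DEGENERATE_RSS * n
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(rss / (n - 2) / sxx)
            t = slope / se
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
        p[degenerate] = 0.0
        constant = degenerate & (np.abs(slope) < 1e-8)
        slope[constant] = 0.0
        t[degenerate] = np.where(slope[degenerate] > 0, np.inf,
                                 np.where(slope[degenerate] < 0, -np.inf, 0.0))
        se[degenerate] = 0.0
        if pct_cells is None:
            pct = np.full(len(slope), 100.0)
        else:
            series = pct_cells[tissue] if isinstance(pct_cells, dict) else pct_cells
            pct = series.reindex(sub.values.index).fillna(100.0).to_numpy(dtype=float)
        q = np.full(len(slope), np.nan)
        testable = (~degenerate) & (pct > 0)
        if testable.any():
            q[testable] = bh_fdr(p[testable])
        out.append(
            pd.DataFrame(
                {
                    "gene": sub.values.index,
                    "tissue": tissue,
                    "slope": slope,
                    "intercept": intercept,
                    "se": se,
                    "t": t,
                    "p": p,
                    "q": q,
                    "pct_cells": pct,
                    "n_timepoints": n,
                    "degenerate": degenerate,
                }
            )
        )
    return pd.concat(out, ignore_index=True)[FIT_COLUMNS]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be a 1-D vector")
    if len(p) == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_temporal_genes(
    fits: pd.DataFrame,
    q_max: float = 0.1,
    slope_min: float = 0.15,
    pct_min: float = 5.0,
    direction: str = "up",
    name: str | None = None,
) -> GeneSignature:
    """Threshold-select temporally associated genes from one tissue's fits.

    Keeps non-degenerate genes with ``q < q_max``, ``pct_cells > pct_min``
    and ``slope > slope_min`` (``direction="down"`` selects
    ``slope < -slope_min`` for decreasing programs).
    """
    tissues = fits["tissue"].unique()
    if len(tissues) != 1:
        raise ConfigurationError(
            "select_temporal_genes expects fits from a single tissue; "
            f"got {list(tissues)}"
        )
    if direction not in ("up", "down"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    ok = (~fits["degenerate"]) & (fits["q"] < q_max) & (fits["pct_cells"] > pct_min)
    if direction == "up":
        ok &= fits["slope"] > slope_min
    else:
        ok &= fits["slope"] < -slope_min
    genes = sorted(fits.loc[ok, "gene"])
    tissue = str(tissues[0])
    return GeneSignature(
        name=name or f"{tissue}_temporal_{direction}",
        genes=tuple(genes),
        provenance={
            "derivation": "select_temporal_genes",
            "tissue": tissue,
            "q_max": q_max,
            "slope_min": slope_min,
            "pct_min": pct_min,
            "direction": direction,
            "n_tested": int(fits["q"].notna().sum()),
        },
    )


def classify_temporal_patterns(
    pb: PseudobulkMatrix,
    genes=None,
    peak_contrast_min: float = 0.5,
    tissue: str | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label genes increasing / decreasing / transient from their trajectory.

    A gene is *transient* when its maximum sits at an interior timepoint and
    exceeds both endpoint values by at least ``peak_contrast_min`` LogCPM;
    otherwise it is *increasing* when its Pearson correlation with time is
    >= 0 and *decreasing* when negative.
    """
    if tissue is not None:
        pb = pb.for_tissue(tissue)
    if pb.samples["tissue"].nunique() != 1:
        raise ConfigurationError("classify one tissue at a time (pass tissue=...)")
    days = pb.samples["day"].to_numpy(dtype=float)
    order = np.argsort(days, kind="stable")
    days = days[order]
    if len(days) < 3:
        raise ValidationError("need at least 3 timepoints to classify patterns")
    values = pb.values.iloc[:, order]
    if genes is not None:
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        values = values.loc[list(genes)]
    y = values.to_numpy(dtype=float)
    peak_pos = y.argmax(axis=1)
    interior = (peak_pos > 0) & (peak_pos < y.shape[1] - 1)
    ymax = y.max(axis=1)
    contrast_ok = ((ymax - y[:, 0]) >= peak_contrast_min) & (
        (ymax - y[:, -1]) >= peak_contrast_min
    )
    transient = interior & contrast_ok
    dc = days - days.mean()
    denom = np.sqrt((dc**2).sum() * ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (y - y.mean(axis=1, keepdims=True)) @ dc / denom
    corr = np.nan_to_num(corr)  # constant trajectories count as increasing (corr 0)
    labels = np.where(transient, "transient", np.where(corr >= 0, "increasing", "decreasing"))
    table = pd.DataFrame(
        {
            "gene": values.index,
            "label": labels,
            "time_correlation": corr,
            "peak_contrast": ymax - np.maximum(y[:, 0], y[:, -1]),
        }
    )
    counts = table["label"].value_counts().to_dict()
    return table, {k: int(counts.get(k, 0)) for k in ("increasing", "decreasing", "transient")}
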