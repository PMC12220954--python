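"""Downstream validation statistics for derived gene signatures.

Covers signature scoring (mean of row-z-scored expression), hierarchical
segregation of labelled samples, two-group gene ranking, preranked GSEA with
a seeded permutation null and leading edge, one-vs-rest AUC marker
detection, one-vs-all pseudobulk differential expression, cluster-profile
correlations, and a proliferation-versus-apoptosis growth score.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

from .containers import ConfigurationError, ValidationError
from .signatures import GeneSignature, read_gmt
from .temporal import bh_fdr

logger = logging.getLogger(__name__)


def default_growth_sets() -> tuple[GeneSignature, GeneSignature]:
    """Bundled editable proliferation/apoptosis gene sets (GMT)."""
    ref = importlib_resources.files("trmtime") / "resources" / "growth_sets.gmt"
    with importlib_resources.as_file(ref) as path:
        sigs = {s.name: s for s in read_gmt(path)}
    return sigs["proliferation"], sigs["apoptosis"]


def _as_gene_list(signature) -> list[str]:
    if isinstance(signature, GeneSignature):
        return list(signature.genes)
    return list(signature)


def score_signature(values: pd.DataFrame, signature) -> pd.Series:
    """Mean over signature genes of row-z-scored values, per column.

    Genes absent from the matrix are logged and skipped; zero-variance rows
    are skipped with a warning (their z-score is undefined).
    """
    genes = _as_gene_list(signature)
    present = [g for g in genes if g in values.index]
    if not present:
        raise ValidationError("no signature genes present in the matrix")
    if len(present) < len(genes):
        logger.info("skipping %d absent signature gene(s)", len(genes) - len(present))
    sub = values.loc[present]
    sd = sub.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("skipping %d zero-variance row(s)", int(flat.sum()))
        sub = sub.loc[~flat]
        sd = sd.loc[~flat]
        if sub.empty:
            return pd.Series(0.0, index=values.columns, name="score")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("score")


@dataclass
class SegregationResult:
    """Average-linkage tree over columns plus the 2-cluster cut purity."""

    linkage: np.ndarray = field(repr=False)
    purity: float
    assignments: pd.Series = field(repr=False)
    settings: dict


def hierarchical_segregation(
    values: pd.DataFrame, signature, labels
) -> SegregationResult:
    """Cluster columns on signature genes and score the 2-way cut purity.

    Rows restricted to signature genes are z-scored, column distance is
    1 - Pearson, linkage is average; purity is the best label agreement of
    the 2-cluster cut (in [0.5, 1] for two balanced labels).
    """
    labels = pd.Series(np.asarray(labels), index=values.columns)
    if values.shape[1] < 4:
        raise ValidationError("need at least 4 columns to segregate")
    if labels.nunique() < 2:
        raise ValidationError("both labels must be present")
    genes = [g for g in _as_gene_list(signature) if g in values.index]
    if len(genes) < 2:
        raise ValidationError("fewer than 2 signature genes present in the matrix")
    sub = values.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    sub = sub.loc[sd > 0]
    if sub.shape[0] < 2:
        raise ValidationError("fewer than 2 varying signature genes")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)
    dist = ssd.pdist(z.to_numpy().T, metric="correlation")
    linkage = sch.linkage(dist, method="average")
    cut = sch.fcluster(linkage, t=2, criterion="maxclust")
    assignments = pd.Series(cut, index=values.columns, name="cluster")
    # purity: best mapping of the 2 clusters onto the majority label of each
    agree = 0
    for c in np.unique(cut):
        agree += labels[assignments == c].value_counts().iloc[0]
    purity = float(agree) / len(labels)
    return SegregationResult(
        linkage=linkage,
        purity=purity,
        assignments=assignments,
        settings={"distance": "1-pearson", "linkage": "average", "row_zscore": True},
    )


def rank_two_groups(
    values: pd.DataFrame, group_labels, group_a=None, group_b=None
) -> pd.DataFrame:
    """Rank genes by a signed two-sample rank statistic (group a vs b).

    The statistic is ``sign(mean_a - mean_b) * -log10(p)`` from a two-sided
    Mann-Whitney test with midranks; genes most associated with group a rank
    highest.  Ties are broken lexicographically by gene id.
    """
    labels = pd.Series(np.asarray(group_labels), index=values.columns)
    uniq = labels.unique()
    if group_a is None or group_b is None:
        if len(uniq) != 2:
            raise ValidationError("need exactly 2 groups (or pass group_a/group_b)")
        group_a, group_b = sorted(map(str, uniq))
    a = values.loc[:, (labels == group_a).to_numpy()]
    b = values.loc[:, (labels == group_b).to_numpy()]
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValidationError("need at least 3 cells per group")
    A, B = a.to_numpy(dtype=float), b.to_numpy(dtype=float)
    res = scipy.stats.mannwhitneyu(
        A, B, axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.clip(np.nan_to_num(res.pvalue, nan=1.0), 1e-300, 1.0)
    sign = np.sign(A.mean(axis=1) - B.mean(axis=1))
    stat = sign * (-np.log10(p))
    table = pd.DataFrame({"gene": values.index, "stat": stat})
    return table.sort_values(
        ["stat", "gene"], ascending=[False, True], ignore_index=True
    )


@dataclass
class GseaResult:
    """Preranked GSEA outcome for one gene set."""

    gene_set: str
    es: float
    nes: float
    p_value: float
    leading_edge: tuple[str, ...]
    n_permutations: int
    seed: int | None
    method: str


def _enrichment_score(
    stats_abs_w: np.ndarray, hit: np.ndarray, miss_step: float
) -> tuple[float, int]:
    """Running-sum ES and the index of its extremum."""
    wsum = stats_abs_w[hit].sum()
    if wsum > 0:
        steps = np.where(hit, stats_abs_w / wsum, -miss_step)
    else:  # all-zero weights inside the set: fall back to uniform hit steps
        steps = np.where(hit, 1.0 / hit.sum(), -miss_step)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx


def preranked_gsea(
    ranking: pd.Series | pd.DataFrame,
    gene_set,
    n_perm: int = 10000,
    weight_exponent: float = 1.0,
    seed: int | None = None,
    method: str = "auto",
) -> GseaResult:
    """Preranked GSEA with a permutation null over random same-size gene sets.

    The running sum increments by ``|stat|^weight_exponent`` (normalized to
    sum 1) at set members and decrements by ``1/(N - n)`` elsewhere; ES is
    the extremum.  NES divides ES by the mean |null ES| of matching sign and
    the two-sided empirical p uses an add-one correction.  When the number of
    distinct same-size sets is small (``method="auto"``/"exhaustive") the
    null enumerates all of them exactly.  The leading edge is the set members
    at or before (after, for negative ES) the extremum.
    """
    if isinstance(ranking, pd.DataFrame):
        ranking = ranking.set_index("gene")["stat"]
    ranking = ranking.astype(float)
    order = ranking.reset_index()
    order.columns = ["gene", "stat"]
    order = order.sort_values(["stat", "gene"], ascending=[False, True])
    genes = order["gene"].to_numpy()
    stats_arr = order["stat"].to_numpy()
    if np.all(stats_arr == 0):
        raise ValidationError("all ranking statistics are zero")
    members = set(_as_gene_list(gene_set))
    hit = np.isin(genes, list(members))
    n, N = int(hit.sum()), len(genes)
    if n < 2:
        raise ValidationError("gene set overlaps the ranked universe in < 2 genes")
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    w = np.abs(stats_arr) ** weight_exponent
    miss_step = 1.0 / (N - n)
    es, idx = _enrichment_score(w, hit, miss_step)
    n_exhaustive = math.comb(N, n)
    use_exhaustive = method == "exhaustive" or (
        method == "auto" and n_exhaustive <= n_perm
    )
    positions = np.arange(N)
    null = np.empty(n_exhaustive if use_exhaustive else n_perm)
    if use_exhaustive:
        for i, combo in enumerate(itertools.combinations(range(N), n)):
            h = np.zeros(N, dtype=bool)
            h[list(combo)] = True
            null[i], _ = _enrichment_score(w, h, miss_step)
        p = float((np.abs(null) >= abs(es) - 1e-12).sum()) / len(null)
        used_method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        for i in range(n_perm):
            h = np.zeros(N, dtype=bool)
            h[rng.choice(positions, size=n, replace=False)] = True
            null[i], _ = _enrichment_score(w, h, miss_step)
        p = (1.0 + float((np.abs(null) >= abs(es) - 1e-12).sum())) / (1.0 + n_perm)
        used_method = "permutation"
    same_sign = null[np.sign(null) == np.sign(es)]
    if len(same_sign):
        nes = es / float(np.mean(np.abs(same_sign)))
    else:
        nes = float("nan")
    if es >= 0:
        le = genes[: idx + 1][hit[: idx + 1]]
    else:
        le = genes[idx:][hit[idx:]]
    name = gene_set.name if isinstance(gene_set, GeneSignature) else "gene_set"
    return GseaResult(
        gene_set=name,
        es=es,
        nes=float(nes),
        p_value=float(p),
        leading_edge=tuple(le),
        n_permutations=len(null),
        seed=seed,
        method=used_method,
    )


def auc_markers(
    values: pd.DataFrame, clusters, auc_min: float = 0.75
) -> pd.DataFrame:
    """One-vs-rest AUC per gene per cluster via the rank-sum statistic.

    AUC = U / (n1 * n2) with midranks for ties; singleton clusters are
    skipped with a warning.
    """
    clusters = pd.Series(np.asarray(clusters), index=values.columns)
    uniq = [c for c in pd.unique(clusters)]
    if len(uniq) < 2:
        raise ValidationError("need at least 2 clusters")
    ranks = scipy.stats.rankdata(values.to_numpy(dtype=float), axis=1)
    out = []
    for c in uniq:
        mask = (clusters == c).to_numpy()
        n1, n2 = int(mask.sum()), int((~mask).sum())
        if n1 < 2 or n2 < 2:
            logger.warning("skipping cluster %r with < 2 cells on a side", c)
            continue
        r1 = ranks[:, mask].sum(axis=1)
        u = r1 - n1 * (n1 + 1) / 2.0
        auc = u / (n1 * n2)
        out.append(
            pd.DataFrame(
                {"gene": values.index, "cluster": c, "auc": auc, "marker": auc >= auc_min}
            )
        )
    if not out:
        raise ValidationError("no cluster had at least 2 cells on both sides")
    return pd.concat(out, ignore_index=True)


def assign_replicates(meta: pd.DataFrame, n_replicates: int = 3, seed: int = 0) -> pd.Series:
    """Seeded random pseudo-replicate labels (used when true replicates are absent)."""
    rng = np.random.default_rng(seed)
    rep = rng.integers(0, n_replicates, size=len(meta))
    return pd.Series(rep, index=meta.index, name="replicate")


def ova_pseudobulk_de(
    counts,
    meta: pd.DataFrame,
    cluster_col: str = "cluster",
    replicate_col: str | None = None,
    n_replicates: int = 3,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-all pseudobulk differential expression per cluster.

    Cells are pooled into pseudobulk replicates on each side; log2FC compares
    mean CPM (+pseudocount) and p comes from a two-sample t-test on the
    replicate LogCPM values, BH-corrected per cluster.  When no replicate
    column exists, seeded pseudo-replicates are assigned (``--replicates``).
    """
    if cluster_col not in meta.columns:
        raise ConfigurationError(f"metadata lacks cluster column {cluster_col!r}")
    if replicate_col is None:
        reps = assign_replicates(meta, n_replicates=n_replicates, seed=seed)
    else:
        reps = meta[replicate_col]
    clusters = meta[cluster_col]
    mat = counts.counts if hasattr(counts, "counts") else counts
    genes = counts.genes if hasattr(counts, "genes") else pd.RangeIndex(mat.shape[0])
    out = []
    for c in pd.unique(clusters):
        in_c = (clusters == c).to_numpy()
        side_cpm = {}
        for side, mask in (("cluster", in_c), ("rest", ~in_c)):
            cols = []
            for r in pd.unique(reps[mask]):
                sel = mask & (reps == r).to_numpy()
                if sel.sum() == 0:
                    continue
                s = np.asarray(mat[:, sel].sum(axis=1)).ravel().astype(float)
                tot = s.sum()
                if tot > 0:
                    cols.append(1e6 * s / tot)
            if len(cols) < 2:
                raise ValidationError(
                    f"cluster {c!r} ({side}) has fewer than 2 pseudobulk replicates; "
                    "assign more cells or use seeded --replicates splitting"
                )
            side_cpm[side] = np.column_stack(cols)
        log2fc = np.log2(side_cpm["cluster"].mean(axis=1) + pseudocount) - np.log2(
            side_cpm["rest"].mean(axis=1) + pseudocount
        )
        log_a = np.log2(side_cpm["cluster"] + pseudocount)
        log_b = np.log2(side_cpm["rest"] + pseudocount)
        t_res = scipy.stats.ttest_ind(log_a, log_b, axis=1)
        p = np.nan_to_num(t_res.pvalue, nan=1.0)
        out.append(
            pd.DataFrame(
                {"gene": genes, "cluster": c, "log2fc": log2fc, "p": p, "q": bh_fdr(p)}
            )
        )
    return pd.concat(out, ignore_index=True)


def cluster_profile_correlation(
    log2fc: pd.DataFrame, gene_subsets: dict | None = None
) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-cluster log2FC profiles.

    ``log2fc`` is genes x clusters.  By default the full shared gene universe
    is used; ``gene_subsets`` maps cluster -> significant genes, in which
    case each pair uses the union of its two subsets.
    """
    if log2fc.shape[0] < 10:
        raise ValidationError("need a shared gene universe of >= 10 genes")
    cols = list(log2fc.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if gene_subsets is not None:
                genes = sorted(
                    (set(gene_subsets.get(a, ())) | set(gene_subsets.get(b, ())))
                    & set(log2fc.index)
                )
                if len(genes) < 3:
                    raise ValidationError(f"pair ({a}, {b}) has < 3 genes to correlate")
                sub = log2fc.loc[genes]
            else:
                sub = log2fc
            rho = scipy.stats.spearmanr(sub[a], sub[b]).statistic
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def growth_score(
    values: pd.DataFrame, proliferation_set, apoptosis_set
) -> pd.DataFrame:
    """Proliferation-minus-apoptosis signature contrast per column (cell).

    The log growth rate is the difference of the two mean-z signature scores;
    swapping the gene sets negates every score.
    """
    prolif = score_signature(values, proliferation_set)
    apop = score_signature(values, apoptosis_set)
    return pd.DataFrame(
        {
            "proliferation": prolif,
            "apoptosis": apop,
            "log_growth_rate": prolif - apop,
        }
    )
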