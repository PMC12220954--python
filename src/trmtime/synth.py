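"""Synthetic single-cell time-course generator with known temporal ground truth.

The generator emulates the structure of an antigen-specific CD8+ T cell
time course profiled by droplet scRNA-seq in several anatomical compartments
(resident tissues such as skin and gut epithelium versus circulating
compartments such as draining lymph node and spleen) across ~10 timepoints
spanning days 0-60 after infection.

Each gene carries a per-tissue temporal class on the log2(CPM)-versus-scaled-
time scale:

``increasing`` / ``decreasing``
    log2 intensity is linear in scaled time with the stated slope.
``transient``
    a Gaussian bump added on the log2 scale, peaking at an interior timepoint.
``flat``
    constant log2 intensity (slope exactly 0).

Counts are drawn per cell from a negative binomial with mean proportional to
the exp-scale gene intensity at the cell's timepoint times the cell's
log-normal library factor.  The NB uses the linear-variance (NB1,
quasi-Poisson) form ``var = (1 + dispersion) * mean``, which is the
overdispersion regime characteristic of droplet UMI counts; the pseudobulk
log2(CPM) trajectory of each gene therefore converges to its specified mean
curve as cells per sample grow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import ConfigurationError, CountMatrix, ValidationError

GENE_CLASSES = ("increasing", "decreasing", "transient", "flat")
MEMBERSHIPS = (
    "resident_shared",
    "resident_shared_circulating",
    "resident_tissue_specific",
    "circulating",
    "none",
)

DEFAULT_TIMEPOINTS = (0.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 45.0, 60.0)


@dataclass(frozen=True)
class Tissue:
    """An anatomical compartment with a resident/circulating flag."""

    name: str
    resident: bool


DEFAULT_TISSUES = (
    Tissue("skin", True),
    Tissue("siIEL", True),
    Tissue("dLN", False),
    Tissue("spleen", False),
)


@dataclass(frozen=True)
class TimeCourseDesign:
    """Experimental design of a simulated time course.

    Defaults emulate the study conditions: 10 timepoints over days 0-60,
    two resident and two circulating compartments, 200 cells per
    (tissue, timepoint) sample, 1,000 genes, log-normal library sizes around
    ``exp(9.2) ~ 10k`` counts per cell and NB1 dispersion 0.5.
    """

    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    tissues: tuple[Tissue, ...] = DEFAULT_TISSUES
    cells_per_sample: int = 200
    n_genes: int = 1000
    library_size_log_mean: float = 9.2
    library_size_log_sd: float = 0.3
    nb_dispersion: float = 0.5

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints, dtype=float)
        if len(tp) < 3:
            raise ValidationError("need at least 3 timepoints")
        if (tp < 0).any():
            raise ValidationError("timepoints must be non-negative")
        if not (np.diff(tp) > 0).all():
            raise ValidationError("timepoints must be strictly increasing")
        if len(self.tissues) < 1:
            raise ValidationError("need at least one tissue")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValidationError("tissue names must be unique")
        if self.cells_per_sample < 1:
            raise ValidationError("cells_per_sample must be >= 1")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not self.nb_dispersion > 0:
            raise ValidationError("nb_dispersion must be > 0")

    @property
    def tissue_names(self) -> list[str]:
        return [t.name for t in self.tissues]

    @property
    def resident_tissues(self) -> list[str]:
        return [t.name for t in self.tissues if t.resident]

    @property
    def circulating_tissues(self) -> list[str]:
        return [t.name for t in self.tissues if not t.resident]

    def scaled_time(self) -> np.ndarray:
        """Timepoints mapped affinely onto [0, 1] (the slope unit used)."""
        tp = np.asarray(self.timepoints, dtype=float)
        return (tp - tp[0]) / (tp[-1] - tp[0])


@dataclass
class GroundTruth:
    """Per-gene, per-tissue temporal ground truth on the log2(CPM) scale.

    ``classes``/``slopes`` are genes x tissues frames; ``baseline`` is the
    log2 intensity shared across tissues and ``tissue_offsets`` (genes x
    tissues, log2) are gene-specific residence shifts of that baseline —
    the tissue-microenvironment effect that makes mature resident and
    circulating profiles separable irrespective of time.  Transient genes
    carry an interior ``peak`` (scaled time), ``width`` and bump
    ``amplitude``; ``membership`` records the signature role used by the
    two-compartment constructor.
    """

    genes: pd.Index
    classes: pd.DataFrame
    slopes: pd.DataFrame
    baseline: pd.Series
    tissue_offsets: pd.DataFrame
    peak: pd.Series
    width: pd.Series
    amplitude: pd.Series
    membership: pd.Series

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes, name="gene")
        bad = ~self.classes.isin(GENE_CLASSES)
        if bad.to_numpy().any():
            raise ValidationError("unknown temporal class label in ground truth")
        flat = self.classes == "flat"
        if (self.slopes.to_numpy()[flat.to_numpy()] != 0).any():
            raise ValidationError("flat genes must have slope 0")
        transient = (self.classes == "transient").any(axis=1)
        pk = self.peak[transient]
        if ((pk <= 0) | (pk >= 1)).any():
            raise ValidationError("transient peaks must be interior (0 < peak < 1)")

    def check_design(self, design: TimeCourseDesign) -> None:
        if len(self.genes) != design.n_genes:
            raise ConfigurationError(
                f"truth has {len(self.genes)} genes but design.n_genes="
                f"{design.n_genes}"
            )
        if list(self.classes.columns) != design.tissue_names:
            raise ConfigurationError(
                "truth tissues do not match design tissues: "
                f"{list(self.classes.columns)} vs {design.tissue_names}"
            )

    def log_intensity(self, design: TimeCourseDesign, tissue: str) -> pd.DataFrame:
        """Unnormalized log2 intensity, genes x timepoints, for one tissue."""
        tau = design.scaled_time()
        cls = self.classes[tissue].to_numpy()
        slope = self.slopes[tissue].to_numpy()
        base = (self.baseline + self.tissue_offsets[tissue]).to_numpy()
        m = base[:, None] + slope[:, None] * tau[None, :]
        is_tr = cls == "transient"
        if is_tr.any():
            pk = self.peak.to_numpy()[is_tr, None]
            wd = self.width.to_numpy()[is_tr, None]
            amp = self.amplitude.to_numpy()[is_tr, None]
            bump = amp * np.exp(-((tau[None, :] - pk) ** 2) / (2 * wd**2))
            m[is_tr] = base[is_tr, None] + bump
        return pd.DataFrame(m, index=self.genes, columns=list(design.timepoints))

    def relative_abundance(self, design: TimeCourseDesign, tissue: str) -> pd.DataFrame:
        """Per-timepoint expected fraction of the library for each gene."""
        u = 2.0 ** self.log_intensity(design, tissue)
        return u / u.sum(axis=0)

    def mean_log_cpm(
        self, design: TimeCourseDesign, tissue: str, pseudocount: float = 1.0
    ) -> pd.DataFrame:
        """The specified mean curve on the log2(CPM + pseudocount) scale."""
        cpm = 1e6 * self.relative_abundance(design, tissue)
        return np.log2(cpm + pseudocount)

    def genes_of_class(self, tissue: str, cls: str) -> pd.Index:
        return self.genes[self.classes[tissue] == cls]

    def expected_signature(self) -> set[str]:
        """Ground-truth temporal signature: resident-shared minus circulating."""
        return set(self.genes[self.membership == "resident_shared"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (one row per gene x tissue) for truth.tsv."""
        rows = []
        for tissue in self.classes.columns:
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.genes,
                        "tissue": tissue,
                        "class": self.classes[tissue].to_numpy(),
                        "slope": self.slopes[tissue].to_numpy(),
                        "baseline_log2": self.baseline.to_numpy(),
                        "tissue_offset_log2": self.tissue_offsets[tissue].to_numpy(),
                        "peak": self.peak.to_numpy(),
                        "width": self.width.to_numpy(),
                        "amplitude": self.amplitude.to_numpy(),
                        "membership": self.membership.to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _empty_truth(design: TimeCourseDesign, baseline: np.ndarray) -> GroundTruth:
    genes = pd.Index([f"gene{i:04d}" for i in range(design.n_genes)], name="gene")
    tissues = design.tissue_names
    return GroundTruth(
        genes=genes,
        classes=pd.DataFrame("flat", index=genes, columns=tissues),
        slopes=pd.DataFrame(0.0, index=genes, columns=tissues),
        baseline=pd.Series(baseline, index=genes),
        tissue_offsets=pd.DataFrame(0.0, index=genes, columns=tissues),
        peak=pd.Series(np.nan, index=genes),
        width=pd.Series(np.nan, index=genes),
        amplitude=pd.Series(np.nan, index=genes),
        membership=pd.Series("none", index=genes),
    )


def _draw_baselines(design: TimeCourseDesign, sd: float, rng) -> np.ndarray:
    # Center the log2 baseline so mean CPM per gene is ~1e6/n_genes; the
    # generator models the moderately expressed signature-candidate stratum.
    center = math.log2(1e6 / design.n_genes)
    return center + sd * rng.standard_normal(design.n_genes)


def _draw_tissue_offsets(
    design: TimeCourseDesign, residence_sd: float, tissue_sd: float, rng
) -> np.ndarray:
    """Gene-specific baseline shifts: a residence-class component shared by
    tissues of the same class (epithelial residence vs lymphoid circulation
    impose common programs) plus a smaller tissue-idiosyncratic term."""
    n = design.n_genes
    by_class = residence_sd * rng.standard_normal((n, 2))
    idio = tissue_sd * rng.standard_normal((n, len(design.tissues)))
    out = np.empty_like(idio)
    for j, tissue in enumerate(design.tissues):
        out[:, j] = by_class[:, 0 if tissue.resident else 1] + idio[:, j]
    return out


def _jittered(nominal: float, n: int, jitter: float, rng) -> np.ndarray:
    """Per-gene effect sizes around the nominal value (gene-intrinsic)."""
    return nominal * rng.uniform(1.0 - jitter, 1.0 + jitter, size=n)


def uniform_truth(
    design: TimeCourseDesign,
    n_increasing: int = 0,
    n_decreasing: int = 0,
    n_transient: int = 0,
    slope: float = 0.3,
    slope_jitter: float = 1 / 3,
    transient_amplitude: float = 1.5,
    transient_peak: float = 0.5,
    transient_width: float = 0.15,
    baseline_log2_sd: float = 0.6,
    residence_offset_log2_sd: float = 0.15,
    tissue_offset_log2_sd: float = 0.05,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth in which each non-flat gene has the same class everywhere.

    The first ``n_increasing`` genes increase, the next ``n_decreasing``
    decrease, the next ``n_transient`` are transient; the remainder are flat.
    Per-gene slopes are drawn uniformly in ``slope * (1 +/- slope_jitter)``
    (shared across tissues), emulating the heterogeneous effect sizes of real
    temporal programs; set ``slope_jitter=0`` for exactly equal slopes.
    """
    total = n_increasing + n_decreasing + n_transient
    if total > design.n_genes:
        raise ConfigurationError(
            f"{total} classified genes exceed n_genes={design.n_genes}"
        )
    rng = np.random.default_rng(seed)
    truth = _empty_truth(design, _draw_baselines(design, baseline_log2_sd, rng))
    truth.tissue_offsets.iloc[:, :] = _draw_tissue_offsets(
        design, residence_offset_log2_sd, tissue_offset_log2_sd, rng
    )
    g = truth.genes
    inc = g[:n_increasing]
    dec = g[n_increasing : n_increasing + n_decreasing]
    tr = g[n_increasing + n_decreasing : total]
    inc_slopes = _jittered(slope, len(inc), slope_jitter, rng)
    dec_slopes = _jittered(slope, len(dec), slope_jitter, rng)
    for tissue in design.tissue_names:
        truth.classes.loc[inc, tissue] = "increasing"
        truth.slopes.loc[inc, tissue] = inc_slopes
        truth.classes.loc[dec, tissue] = "decreasing"
        truth.slopes.loc[dec, tissue] = -dec_slopes
        truth.classes.loc[tr, tissue] = "transient"
    truth.peak.loc[tr] = transient_peak
    truth.width.loc[tr] = transient_width
    truth.amplitude.loc[tr] = transient_amplitude
    return truth


def two_compartment_truth(
    design: TimeCourseDesign,
    n_shared_resident: int = 50,
    n_tissue_specific: int = 30,
    n_circulating: int = 40,
    n_circulating_overlap: int = 10,
    slope: float = 0.3,
    slope_jitter: float = 1 / 3,
    baseline_log2_sd: float = 0.6,
    residence_offset_log2_sd: float = 0.15,
    tissue_offset_log2_sd: float = 0.05,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth for the resident-versus-circulating consensus workflow.

    * ``n_shared_resident`` genes increase in every resident tissue;
      ``n_circulating_overlap`` of them additionally increase in every
      circulating tissue (general memory genes).
    * ``n_tissue_specific`` genes per resident tissue increase in that tissue
      only (disjoint across tissues).
    * ``n_circulating - n_circulating_overlap`` further genes increase in the
      circulating tissues only.

    The expected temporal signature is the shared-resident set minus the
    circulating overlap.
    """
    residents = design.resident_tissues
    circulating = design.circulating_tissues
    if len(residents) < 2:
        raise ConfigurationError("need >= 2 resident tissues in the design")
    if len(circulating) < 1:
        raise ConfigurationError("need >= 1 circulating tissue in the design")
    if n_circulating_overlap > min(n_shared_resident, n_circulating):
        raise ConfigurationError(
            "n_circulating_overlap exceeds shared or circulating gene count"
        )
    total = (
        n_shared_resident
        + n_tissue_specific * len(residents)
        + (n_circulating - n_circulating_overlap)
    )
    if total > design.n_genes:
        raise ConfigurationError(
            f"{total} classified genes exceed n_genes={design.n_genes}"
        )
    rng = np.random.default_rng(seed)
    truth = _empty_truth(design, _draw_baselines(design, baseline_log2_sd, rng))
    truth.tissue_offsets.iloc[:, :] = _draw_tissue_offsets(
        design, residence_offset_log2_sd, tissue_offset_log2_sd, rng
    )
    g = truth.genes
    pos = 0
    shared = g[pos : pos + n_shared_resident]
    pos += n_shared_resident
    overlap = shared[:n_circulating_overlap]
    shared_slopes = _jittered(slope, len(shared), slope_jitter, rng)
    for tissue in residents:
        truth.classes.loc[shared, tissue] = "increasing"
        truth.slopes.loc[shared, tissue] = shared_slopes
    truth.membership.loc[shared] = "resident_shared"
    truth.membership.loc[overlap] = "resident_shared_circulating"
    for tissue in residents:
        spec = g[pos : pos + n_tissue_specific]
        pos += n_tissue_specific
        truth.classes.loc[spec, tissue] = "increasing"
        truth.slopes.loc[spec, tissue] = _jittered(slope, len(spec), slope_jitter, rng)
        truth.membership.loc[spec] = "resident_tissue_specific"
    circ_only = g[pos : pos + (n_circulating - n_circulating_overlap)]
    pos += len(circ_only)
    truth.membership.loc[circ_only] = "circulating"
    circ_only_slopes = _jittered(slope, len(circ_only), slope_jitter, rng)
    for tissue in circulating:
        truth.classes.loc[overlap, tissue] = "increasing"
        truth.slopes.loc[overlap, tissue] = shared_slopes[:n_circulating_overlap]
        truth.classes.loc[circ_only, tissue] = "increasing"
        truth.slopes.loc[circ_only, tissue] = circ_only_slopes
    return truth


def simulate_timecourse(
    design: TimeCourseDesign, truth: GroundTruth, seed: int
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Draw a full count matrix plus aligned cell metadata.

    Cells are generated tissue by tissue, timepoint by timepoint, from a
    single seeded generator, so identical ``(design, truth, seed)`` reproduce
    byte-identical output.
    """
    truth.check_design(design)
    rng = np.random.default_rng(seed)
    alpha = design.nb_dispersion
    p_nb = 1.0 / (1.0 + alpha)
    blocks: list[sp.csr_matrix] = []
    barcodes: list[str] = []
    meta_rows: list[tuple[str, str, float]] = []
    for tissue in design.tissues:
        rel = truth.relative_abundance(design, tissue.name).to_numpy()
        for j, day in enumerate(design.timepoints):
            n = design.cells_per_sample
            lib = rng.lognormal(
                mean=design.library_size_log_mean,
                sigma=design.library_size_log_sd,
                size=n,
            )
            mu = rel[:, j][:, None] * lib[None, :]
            counts = rng.negative_binomial(mu / alpha, p_nb)
            blocks.append(sp.csr_matrix(counts))
            for i in range(n):
                bc = f"{tissue.name}_d{day:g}_c{i:04d}"
                barcodes.append(bc)
                meta_rows.append((bc, tissue.name, float(day)))
    matrix = CountMatrix(truth.genes, pd.Index(barcodes), sp.hstack(blocks).tocsr())
    meta = pd.DataFrame(meta_rows, columns=["barcode", "tissue", "day"])
    meta["cluster"] = ""
    return matrix, meta, truth


def simulate_two_compartments(
    design: TimeCourseDesign,
    n_shared_resident: int = 50,
    n_tissue_specific: int = 30,
    n_circulating: int = 40,
    n_circulating_overlap: int = 10,
    slope: float = 0.3,
    seed: int = 0,
) -> tuple[dict[str, tuple[CountMatrix, pd.DataFrame]], GroundTruth]:
    """Simulate paired resident/circulating datasets with a known signature.

    Returns one ``(CountMatrix, meta)`` dataset per compartment plus the
    shared :class:`GroundTruth`, whose membership column marks which genes are
    increasing in all resident tissues, in one only, and in the circulating
    compartments, so consensus/subtraction logic has a known answer.
    """
    truth = two_compartment_truth(
        design,
        n_shared_resident=n_shared_resident,
        n_tissue_specific=n_tissue_specific,
        n_circulating=n_circulating,
        n_circulating_overlap=n_circulating_overlap,
        slope=slope,
        seed=seed,
    )
    matrix, meta, truth = simulate_timecourse(design, truth, seed)
    datasets: dict[str, tuple[CountMatrix, pd.DataFrame]] = {}
    for tissue in design.tissue_names:
        mask = meta["tissue"] == tissue
        sub_meta = meta.loc[mask].reset_index(drop=True)
        datasets[tissue] = (matrix.subset_cells(sub_meta["barcode"]), sub_meta)
    return datasets, truth
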