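"""End-to-end pipeline: QC -> pseudobulk -> fit -> select -> consensus ->
subtract -> validate, with a YAML config, deterministic outputs and a
hash manifest.

The config is validated strictly (unknown keys rejected).  Either a
``simulate`` block (two-compartment synthetic run with known truth) or an
``inputs`` block (one on-disk dataset per tissue) supplies the data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import synth
from .containers import ConfigurationError, CountMatrix
from .ingest import qc_filter_cells, read_counts, write_dataset
from .pseudobulk import (
    aggregate_pseudobulk,
    normalize_log_cpm,
    pct_cells_expressing,
)
from .signatures import (
    GeneSignature,
    consensus_signature,
    subtract_circulating,
    write_gmt,
    write_signatures_tsv,
)
from .temporal import fit_temporal_models, select_temporal_genes
from .validate import hierarchical_segregation, preranked_gsea, rank_two_groups

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    n_genes: int = 1000
    cells_per_sample: int = 200
    timepoints: Optional[list[float]] = None
    nb_dispersion: float = 0.5
    n_shared_resident: int = 50
    n_tissue_specific: int = 30
    n_circulating: int = 40
    n_circulating_overlap: int = 10
    slope: float = 0.3


class InputConfig(_Strict):
    matrix: str
    genes: str
    barcodes: str
    meta: str
    resident: bool


class QcConfig(_Strict):
    markers: list[str] = Field(default_factory=list)
    min_genes: int = 0
    mode: str = "all"


class PseudobulkConfig(_Strict):
    log_base: float = 2.0
    pseudocount: float = 1.0


class TemporalConfig(_Strict):
    time_encoding: str = "scaled01"
    q_max: float = 0.1
    slope_min: float = 0.15
    pct_min: float = 5.0


class ValidateConfig(_Strict):
    run: bool = True
    n_perm: int = 1000
    memory_day_min: float = 30.0
    max_cells_per_group: int = 1000


class RunConfig(_Strict):
    """Fully serializable pipeline configuration; every seed is recorded."""

    outdir: str
    seed: int = 0
    simulate: Optional[SimulateConfig] = None
    inputs: Optional[dict[str, InputConfig]] = None
    qc: QcConfig = Field(default_factory=QcConfig)
    pseudobulk: PseudobulkConfig = Field(default_factory=PseudobulkConfig)
    temporal: TemporalConfig = Field(default_factory=TemporalConfig)
    validation: ValidateConfig = Field(default_factory=ValidateConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


class PipelineError(RuntimeError):
    """A stage failed; records the stage and the last successful artifact."""

    def __init__(self, stage: str, last_artifact: str | None, cause: Exception):
        self.stage = stage
        self.last_artifact = last_artifact
        super().__init__(
            f"pipeline stage {stage!r} failed ({cause}); "
            f"last successful artifact: {last_artifact or 'none'}"
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_pseudobulk_tsv(pb, path) -> None:
    """Genes x samples LogCPM table with a 2-row (tissue, day) sample header."""
    with open(path, "w") as fh:
        fh.write("tissue\t" + "\t".join(pb.samples["tissue"].astype(str)) + "\n")
        fh.write("day\t" + "\t".join(f"{d:g}" for d in pb.samples["day"]) + "\n")
        pb.values.to_csv(fh, sep="\t", header=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, writing artifacts + manifest + run summary under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    summary: dict = {"seed": config.seed, "stages": [], "counts": {}}
    stage = "configure"
    t0 = time.time()

    def _done(name: str) -> None:
        summary["stages"].append({"stage": name, "elapsed_s": round(time.time() - t0, 3)})
        logger.info("stage %s done (%.2fs)", name, time.time() - t0)

    try:
        stage = "load"
        truth = None
        if (config.simulate is None) == (config.inputs is None):
            raise ConfigurationError("exactly one of 'simulate' or 'inputs' required")
        if config.simulate is not None:
            sim = config.simulate
            kwargs = {"n_genes": sim.n_genes, "cells_per_sample": sim.cells_per_sample,
                      "nb_dispersion": sim.nb_dispersion}
            if sim.timepoints is not None:
                kwargs["timepoints"] = tuple(sim.timepoints)
            design = synth.TimeCourseDesign(**kwargs)
            datasets, truth = synth.simulate_two_compartments(
                design,
                n_shared_resident=sim.n_shared_resident,
                n_tissue_specific=sim.n_tissue_specific,
                n_circulating=sim.n_circulating,
                n_circulating_overlap=sim.n_circulating_overlap,
                slope=sim.slope,
                seed=config.seed,
            )
            resident = {t.name: t.resident for t in design.tissues}
            for name, (counts, meta) in datasets.items():
                paths = write_dataset(counts, meta, outdir / "data" / name,
                                      truth=truth if name == design.tissue_names[0] else None)
                artifacts.extend(paths.values())
        else:
            for name, inp in config.inputs.items():
                for p in (inp.matrix, inp.genes, inp.barcodes, inp.meta):
                    if not Path(p).exists():
                        raise FileNotFoundError(f"input path does not exist: {p}")
            datasets = {}
            resident = {}
            for name, inp in config.inputs.items():
                counts, meta = read_counts(inp.matrix, inp.genes, inp.barcodes, inp.meta)
                datasets[name] = (counts, meta)
                resident[name] = inp.resident
        _done("load")

        stage = "qc"
        qc_rows = []
        for name in sorted(datasets):
            counts, meta = datasets[name]
            counts, meta, report = qc_filter_cells(
                counts, meta,
                required_markers=config.qc.markers,
                min_genes=config.qc.min_genes,
                mode=config.qc.mode,
            )
            datasets[name] = (counts, meta)
            df = report.per_stratum.copy()
            df.insert(0, "dataset", name)
            qc_rows.append(df)
        qc_path = outdir / "qc_report.tsv"
        pd.concat(qc_rows, ignore_index=True).to_csv(qc_path, sep="\t", index=False)
        artifacts.append(qc_path)
        _done("qc")

        stage = "pseudobulk"
        pbs, pcts = {}, {}
        for name in sorted(datasets):
            counts, meta = datasets[name]
            pb = normalize_log_cpm(
                aggregate_pseudobulk(counts, meta),
                pseudocount=config.pseudobulk.pseudocount,
                log_base=config.pseudobulk.log_base,
            )
            pbs[name] = pb
            pcts[name] = pct_cells_expressing(counts, meta, name)
            path = outdir / f"pseudobulk_{name}.tsv"
            write_pseudobulk_tsv(pb, path)
            artifacts.append(path)
        _done("pseudobulk")

        stage = "fit"
        fits = {}
        for name in sorted(pbs):
            fits[name] = fit_temporal_models(
                pbs[name], time_encoding=config.temporal.time_encoding,
                pct_cells=pcts[name],
            ).sort_values(["gene", "tissue"], ignore_index=True)
        fit_path = outdir / "temporal_fits.tsv"
        pd.concat([fits[n] for n in sorted(fits)], ignore_index=True).to_csv(
            fit_path, sep="\t", index=False, float_format="%.6g"
        )
        artifacts.append(fit_path)
        _done("fit")

        stage = "select"
        selected = {}
        for name in sorted(fits):
            selected[name] = select_temporal_genes(
                fits[name],
                q_max=config.temporal.q_max,
                slope_min=config.temporal.slope_min,
                pct_min=config.temporal.pct_min,
            )
            summary["counts"][f"selected_{name}"] = len(selected[name])
        _done("select")

        stage = "consensus"
        res_names = sorted(n for n in selected if resident[n])
        circ_names = sorted(n for n in selected if not resident[n])
        if len(res_names) < 2:
            raise ConfigurationError("consensus requires >= 2 resident tissues")

        def _fold(names: list[str], label: str) -> GeneSignature:
            sig = selected[names[0]]
            for other in names[1:]:
                sig, _ = consensus_signature(sig, selected[other], name=label)
            return sig

        consensus_trm = _fold(res_names, "consensus_trm")
        summary["counts"]["consensus"] = len(consensus_trm)
        if circ_names:
            consensus_tcirc = _fold(circ_names, "consensus_tcirc") if len(circ_names) > 1 \
                else selected[circ_names[0]]
        else:
            consensus_tcirc = GeneSignature(
                "consensus_tcirc", (), {"derivation": "empty (no circulating tissue)"}
            )
        _done("consensus")

        stage = "subtract"
        final, n_removed = subtract_circulating(
            consensus_trm, consensus_tcirc, name="temporal_trm_signature"
        )
        summary["counts"]["removed_by_tcirc"] = n_removed
        summary["counts"]["final_signature"] = len(final)
        sig_tsv = outdir / "signatures.tsv"
        write_signatures_tsv(
            [selected[n] for n in sorted(selected)] + [consensus_trm, consensus_tcirc, final],
            sig_tsv,
        )
        sig_gmt = outdir / "signatures.gmt"
        write_gmt([consensus_trm, consensus_tcirc, final], sig_gmt)
        artifacts.extend([sig_tsv, sig_gmt])
        _done("subtract")

        if config.validation.run and len(final) >= 2:
            stage = "validate"
            validation = validate_signature(
                final, datasets, pbs, resident,
                memory_day_min=config.validation.memory_day_min,
                n_perm=config.validation.n_perm,
                max_cells_per_group=config.validation.max_cells_per_group,
                seed=config.seed,
            )
            if truth is not None:
                expected = truth.expected_signature()
                got = set(final.genes)
                inter, union = len(expected & got), len(expected | got)
                validation["truth_jaccard"] = inter / union if union else float("nan")
            val_path = outdir / "validation.json"
            val_path.write_text(json.dumps(validation, indent=2, sort_keys=True))
            artifacts.append(val_path)
            summary["validation"] = validation
            _done("validate")
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, str(artifacts[-1]) if artifacts else None, exc) from exc

    manifest = {str(p.relative_to(outdir)): _sha256(p) for p in artifacts}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    summary["manifest"] = manifest
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def validate_signature(
    signature: GeneSignature,
    datasets: dict[str, tuple[CountMatrix, pd.DataFrame]],
    pbs: dict,
    resident: dict[str, bool],
    memory_day_min: float = 30.0,
    n_perm: int = 1000,
    max_cells_per_group: int = 1000,
    seed: int = 0,
) -> dict:
    """Segregation + GSEA validation of a signature on resident vs circulating.

    Both checks compare mature memory populations, as in the study design:
    hierarchical segregation uses memory-phase (day >= ``memory_day_min``)
    pseudobulk columns, and the GSEA ranking contrasts memory-phase resident
    against circulating cells (seeded subsample) with a permutation null.
    """
    import numpy as np

    late_cols, late_labels = [], []
    for name in sorted(pbs):
        pb = pbs[name]
        keep = pb.samples.index[pb.samples["day"] >= memory_day_min]
        vals = pb.values[keep]
        late_cols.append(vals)
        late_labels.extend(["resident" if resident[name] else "circulating"] * len(keep))
    late = pd.concat(late_cols, axis=1)
    seg = hierarchical_segregation(late, signature, late_labels)

    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for name in sorted(datasets):
        counts, meta = datasets[name]
        late_idx = np.flatnonzero((meta["day"] >= memory_day_min).to_numpy())
        take = min(len(late_idx), max_cells_per_group)
        idx = np.sort(rng.choice(late_idx, size=take, replace=False))
        mat = np.asarray(counts.counts[:, idx].todense(), dtype=float)
        tot = mat.sum(axis=0)
        tot[tot == 0] = 1.0
        blocks.append(np.log2(1e6 * mat / tot + 1.0))
        labels.extend(["resident" if resident[name] else "circulating"] * take)
    cells = pd.DataFrame(
        np.column_stack(blocks),
        index=next(iter(datasets.values()))[0].genes,
        columns=[f"c{i}" for i in range(len(labels))],
    )
    ranking = rank_two_groups(cells, labels, group_a="resident", group_b="circulating")
    gsea = preranked_gsea(ranking, signature, n_perm=n_perm, seed=seed)
    return {
        "segregation_purity": seg.purity,
        "n_segregation_columns": int(late.shape[1]),
        "gsea_es": gsea.es,
        "gsea_nes": gsea.nes,
        "gsea_p": gsea.p_value,
        "gsea_n_perm": gsea.n_permutations,
        "n_leading_edge": len(gsea.leading_edge),
        "seed": seed,
    }
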