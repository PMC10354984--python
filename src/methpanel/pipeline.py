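"""End-to-end orchestration from a config mapping to a run directory."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import MethylationDataset
from .dmp import (DEFAULT_COVARIATES, GROUP_COLUMN, build_design_matrix,
                  identify_dmps, summarize_by_gene)
from .dmr import dmrs_to_bed, identify_dmrs
from .height import HEIGHT_COVARIATES, classify_direction, cv_fisher_robustness
from .io import write_dataset, write_qc_report, write_table
from .preprocess import (assess_sample_quality, apply_sample_qc,
                         compute_control_pcs, filter_probes,
                         quantile_normalize_beta)
from .reporting import (render_dmp_table, render_dmr_table, render_gc_table,
                        render_interaction_table, render_robustness_table)
from .simulate import SimulationConfig, simulate_dataset
from .subgroups import test_gc_effect, test_interaction

log = logging.getLogger("methpanel")


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run; every default mirrors the
    documented analysis settings (or a declared convention where the
    method leaves a threshold unspecified)."""

    seed: int = 0
    simulation: dict = field(default_factory=dict)
    # preprocessing
    mid_fraction_threshold: float = 0.35  # convention, not published
    det_p_threshold: float = 0.01  # convention, not published
    fail_fraction: float = 0.01  # convention, not published
    quantile_normalize: bool = False
    k_pcs: int = 30
    # DMP stage
    fdr_threshold: float = 0.05
    covariates: tuple = DEFAULT_COVARIATES
    # DMR stage
    dmr_lambda: float = 1000.0
    dmr_C: float = 2.0
    max_gap: int = 1000
    min_cpgs: int = 2
    # subgroups
    age_cutoff: float = 6.0
    # height robustness
    n_folds: int = 10
    n_iterations: int = 100
    alpha: float = 0.05
    fold_scheme: str = "residualise"
    height_covariates: tuple = HEIGHT_COVARIATES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig, outdir, dataset: MethylationDataset = None):
    """Run simulate -> QC -> PCs -> DMP -> DMR -> subgroups -> height.

    Writes every stage's table into ``outdir`` plus a machine-readable
    run manifest; identical config and seed reproduce byte-identical
    tables.  Returns a dict of in-memory results.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results = {}

    def stage(name, fn):
        log.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, exc) from exc

    if dataset is None:
        def _sim():
            sim_cfg = SimulationConfig(**{"seed": config.seed, **config.simulation})
            ds = simulate_dataset(sim_cfg)
            write_dataset(ds, out / "simulated")
            return ds
        dataset = stage("simulate", _sim)
    log.info("input: %d samples x %d probes", dataset.n_samples, dataset.n_probes)

    def _qc():
        rep = assess_sample_quality(dataset, config.mid_fraction_threshold)
        ds = apply_sample_qc(dataset, rep)
        ds, probe_rep = filter_probes(ds, config.det_p_threshold,
                                      config.fail_fraction)
        rep.excluded_probes = probe_rep.excluded_probes
        rep.thresholds.update(probe_rep.thresholds)
        write_qc_report(rep, out / "qc_report.tsv")
        if config.quantile_normalize:
            ds = quantile_normalize_beta(ds)
        return ds, rep
    clean, qc_report = stage("qc", _qc)
    log.info("qc: %d samples, %d probes retained (%d samples, %d probes removed)",
             clean.n_samples, clean.n_probes, len(qc_report.excluded_samples),
             len(qc_report.excluded_probes))
    results["qc_report"] = qc_report

    pcs = stage("control_pcs", lambda: compute_control_pcs(clean, k=config.k_pcs))
    results["pcs"] = pcs

    def _dmp():
        design = build_design_matrix(clean.sample_sheet, pcs=pcs,
                                     covariates=config.covariates)
        stats, dmps = identify_dmps(clean, design, config.fdr_threshold)
        gene_table, tally = summarize_by_gene(dmps, clean.manifest)
        write_table(stats, out / "dmp_stats.tsv")
        write_table(gene_table, out / "dmp_by_gene.tsv")
        (out / "dmp_tally.json").write_text(json.dumps(tally, indent=2) + "\n")
        return stats, dmps, gene_table, tally
    dmp_stats, dmps, gene_table, tally = stage("dmp", _dmp)
    log.info("dmp: %d/%d probes significant at FDR %g", len(dmps),
             len(dmp_stats), config.fdr_threshold)
    results.update(dmp_stats=dmp_stats, dmps=dmps, gene_table=gene_table,
                   tally=tally)

    def _dmr():
        site_table, regions = identify_dmrs(
            dmp_stats, lam=config.dmr_lambda, C=config.dmr_C,
            fdr_threshold=config.fdr_threshold, max_gap=config.max_gap,
            min_cpgs=config.min_cpgs)
        write_table(render_dmr_table(regions), out / "dmr_table.tsv", index=False)
        write_table(dmrs_to_bed(regions), out / "dmrs.bed", index=False)
        return site_table, regions
    dmr_sites, dmrs = stage("dmr", _dmr)
    log.info("dmr: %d regions", len(dmrs))
    results.update(dmr_sites=dmr_sites, dmrs=dmrs)

    probe_ids = [d.probe_id for d in dmps]
    dmp_logfc = {d.probe_id: d.logFC_M for d in dmps}
    inter_sex = inter_age = gc = None
    if probe_ids:
        def _subgroups():
            isex = test_interaction(clean, probe_ids, "sex",
                                    covariates=config.covariates, pcs=pcs,
                                    age_cutoff=config.age_cutoff)
            iage = test_interaction(clean, probe_ids, "age_ge6",
                                    covariates=config.covariates, pcs=pcs,
                                    age_cutoff=config.age_cutoff)
            g = test_gc_effect(clean, probe_ids, dmp_logfc,
                               covariates=config.covariates, pcs=pcs)
            write_table(render_interaction_table(isex + iage),
                        out / "interactions.tsv", index=False)
            write_table(render_gc_table(g), out / "gc_effects.tsv", index=False)
            return isex, iage, g
        inter_sex, inter_age, gc = stage("subgroups", _subgroups)
        results.update(interactions_sex=inter_sex, interactions_age=inter_age,
                       gc_effects=gc)

        def _height():
            records = cv_fisher_robustness(
                clean, probe_ids, covariates=config.height_covariates, pcs=pcs,
                n_folds=config.n_folds, n_iterations=config.n_iterations,
                alpha=config.alpha, seed=config.seed,
                fold_scheme=config.fold_scheme)
            for r in records:
                if r.robust:
                    r.direction_label = classify_direction(r, dmp_logfc[r.probe_id])
            sections = {d.probe_id: d.gene_section for d in dmps}
            write_table(render_robustness_table(records, sections),
                        out / "robustness_table.tsv", index=False)
            return records
        results["robustness"] = stage("height", _height)
        n_robust = sum(r.robust for r in results["robustness"])
        log.info("height: %d/%d probes robust", n_robust, len(probe_ids))
    else:
        write_table(render_interaction_table([]), out / "interactions.tsv",
                    index=False)
        write_table(render_gc_table([]), out / "gc_effects.tsv", index=False)
        write_table(render_robustness_table([]), out / "robustness_table.tsv",
                    index=False)
        results["robustness"] = []

    write_table(render_dmp_table(dmps, inter_sex, inter_age, gc),
                out / "dmp_table.tsv", index=False)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _jsonable(asdict(config)),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
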