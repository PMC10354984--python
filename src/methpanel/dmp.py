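"""Differentially methylated position (DMP) analysis.

Per-CpG moderated multivariable linear models on M-values, with joint
empirical-Bayes variance moderation across the panel, BH-FDR control and
per-gene summaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ControlPCs, DMPRecord, MethylationDataset
from .preprocess import beta_to_m
from .stats import (
    ModerationResult,
    bh_adjust,
    fit_linear_models,
    moderate_variances,
    moderated_t_tests,
    _check_rank,
)

#: Baseline risk-factor adjustment set for the group comparison.
DEFAULT_COVARIATES = (
    "age_at_followup",
    "centre",
    "sex",
    "race_noncaucasian",
    "origin_noneuropean",
    "malignancy",
    "syndrome",
)

GROUP_COLUMN = "group_patient"


def complete_cases(sample_sheet: pd.DataFrame, covariates, max_dropped_fraction=0.05):
    """Index of rows with no missing values among ``covariates``.

    Raises if the complete-case restriction would drop more than
    ``max_dropped_fraction`` of the samples.
    """
    cols = [c for c in covariates if c in sample_sheet.columns]
    keep = sample_sheet[cols].notna().all(axis=1) if cols else pd.Series(
        True, index=sample_sheet.index)
    dropped = 1.0 - keep.mean()
    if dropped > max_dropped_fraction:
        raise ValueError(
            f"complete-case analysis would drop {dropped:.1%} of samples "
            f"(> {max_dropped_fraction:.0%}); covariates: {cols}"
        )
    return sample_sheet.index[keep]


def build_design_matrix(sample_sheet: pd.DataFrame, pcs: ControlPCs = None,
                        covariates=DEFAULT_COVARIATES,
                        group_column: str = "group") -> pd.DataFrame:
    """Model matrix: intercept + group + coded covariates + control PCs.

    Categorical covariates are dummy coded against a reference level;
    booleans become 0/1; numerics pass through.  A single-level
    categorical is dropped with a warning.  Raises naming the collinear
    columns if the coded matrix is rank deficient.
    """
    if sample_sheet[list(c for c in covariates if c in sample_sheet.columns)].isna().any().any():
        raise ValueError("missing values among requested covariates; "
                         "restrict to complete cases first")
    cols = {"intercept": np.ones(len(sample_sheet))}
    if group_column is not None:
        cols[GROUP_COLUMN] = (sample_sheet[group_column] == "patient").astype(float).to_numpy()
    for cov in covariates:
        if cov not in sample_sheet.columns:
            raise KeyError(f"covariate {cov!r} not in sample sheet")
        s = sample_sheet[cov]
        if s.dtype == bool or s.isin([True, False]).all():
            if s.nunique() < 2:
                warnings.warn(f"covariate {cov!r} is constant; dropped", UserWarning)
                continue
            cols[cov] = s.astype(float).to_numpy()
        elif s.dtype.kind in "ifu":
            cols[cov] = s.astype(float).to_numpy()
        else:
            levels = sorted(s.astype(str).unique())
            if len(levels) < 2:
                warnings.warn(f"covariate {cov!r} has a single level; dropped",
                              UserWarning)
                continue
            for lev in levels[1:]:
                cols[f"{cov}_{lev}"] = (s.astype(str) == lev).astype(float).to_numpy()
    if pcs is not None:
        scores = pcs.scores.loc[sample_sheet.index]
        for name in scores.columns:
            cols[name] = scores[name].to_numpy()
    design = pd.DataFrame(cols, index=sample_sheet.index)
    _check_rank(design.to_numpy(), list(design.columns))
    return design


def identify_dmps(dataset: MethylationDataset, design: pd.DataFrame,
                  fdr_threshold: float = 0.05,
                  group_column: str = GROUP_COLUMN):
    """Moderated per-probe group contrast with BH-FDR.

    Fits every signal probe's M-values on the shared design, moderates
    residual variances jointly across the panel, tests the group
    coefficient and adjusts across all tested probes.

    Returns
    -------
    stats : DataFrame indexed by probe id with columns gene,
        gene_section, chromosome, position, logFC_M, ci_low, ci_high,
        t, p_raw, q_bh, abs_mean_beta_diff, direction — retained for the
        downstream DMR stage.
    dmps : list of DMPRecord with ``q_bh < fdr_threshold``, ordered by
        genomic position.
    """
    if not design.index.equals(dataset.beta.index):
        raise ValueError("design rows do not align with dataset samples")
    if group_column not in design.columns:
        raise KeyError(f"design has no column {group_column!r}")

    M = beta_to_m(dataset.beta.to_numpy())
    X = design.to_numpy()
    coefs, su, s2, df = fit_linear_models(M, X, list(design.columns))
    gi = list(design.columns).index(group_column)

    moderation = moderate_variances(s2, df)
    t, p, lo, hi = moderated_t_tests(coefs[gi], su[gi], moderation)
    q = bh_adjust(p)

    grp = design[group_column].to_numpy() == 1
    beta = dataset.beta.to_numpy()
    abs_diff = np.abs(beta[grp].mean(axis=0) - beta[~grp].mean(axis=0))

    signal = dataset.manifest.loc[dataset.beta.columns]
    stats = pd.DataFrame(
        {
            "gene": signal["gene"].to_numpy(),
            "gene_section": signal["gene_section"].to_numpy(),
            "chromosome": signal["chromosome"].to_numpy(),
            "position": signal["position"].to_numpy(),
            "logFC_M": coefs[gi],
            "ci_low": lo,
            "ci_high": hi,
            "t": t,
            "p_raw": p,
            "q_bh": q,
            "abs_mean_beta_diff": abs_diff,
        },
        index=dataset.beta.columns,
    )
    stats["direction"] = np.where(stats["logFC_M"] < 0, "hypomethylated",
                                  "hypermethylated")

    hits = stats[stats["q_bh"] < fdr_threshold].sort_values(
        ["chromosome", "position"])
    dmps = [
        DMPRecord(
            probe_id=pid,
            gene=row["gene"],
            gene_section=row["gene_section"],
            direction=row["direction"],
            logFC_M=float(row["logFC_M"]),
            ci95=(float(row["ci_low"]), float(row["ci_high"])),
            abs_mean_beta_diff=float(row["abs_mean_beta_diff"]),
            p_raw=float(row["p_raw"]),
            q_bh=float(row["q_bh"]),
        )
        for pid, row in hits.iterrows()
    ]
    return stats, dmps


def _pct(numer: int, denom: int) -> float:
    """Share as a one-decimal percentage; 0.0 when the denominator is 0."""
    return round(100.0 * numer / denom, 1) if denom else 0.0


def summarize_by_gene(dmps, manifest: pd.DataFrame):
    """Per-gene DMP coverage table plus the overall direction tally.

    Returns
    -------
    gene_table : DataFrame indexed by gene with n_dmp, n_sites and
        pct_dmp (one decimal), covering every panel gene.
    tally : dict with n_hypo, n_hyper, n_total, pct_hypo, pct_hyper and
        the panel-level gene coverage pct_genes_affected.
    """
    signal = manifest[manifest["probe_class"] == "signal"]
    panel_counts = signal.groupby("gene").size()
    dmp_genes = pd.Series([d.gene for d in dmps], dtype="object")
    dmp_counts = dmp_genes.value_counts()

    gene_table = pd.DataFrame({
        "n_dmp": dmp_counts.reindex(panel_counts.index).fillna(0).astype(int),
        "n_sites": panel_counts,
    })
    gene_table["pct_dmp"] = [
        _pct(r.n_dmp, r.n_sites) for r in gene_table.itertuples()
    ]

    n_hypo = sum(1 for d in dmps if d.direction == "hypomethylated")
    n_total = len(dmps)
    tally = {
        "n_hypo": n_hypo,
        "n_hyper": n_total - n_hypo,
        "n_total": n_total,
        "pct_hypo": _pct(n_hypo, n_total),
        "pct_hyper": _pct(n_total - n_hypo, n_total),
        "n_genes_affected": int((gene_table["n_dmp"] > 0).sum()),
        "n_genes_panel": len(gene_table),
        "pct_genes_affected": _pct(int((gene_table["n_dmp"] > 0).sum()),
                                   len(gene_table)),
    }
    return gene_table, tally


def gene_coverage_pct(affected_genes, panel_genes) -> float:
    """Percentage of panel genes in ``affected_genes``, one decimal."""
    affected = set(affected_genes) & set(panel_genes)
    return _pct(len(affected), len(set(panel_genes)))
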