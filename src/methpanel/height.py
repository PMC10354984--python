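"""Methylation-to-height association with cross-validated robustness.

Per-probe multivariable linear models for height at follow-up among
patients, assessed by repeated ten-fold cross-validation: per iteration
the ten test-fold p-values for the methylation term are combined with
Fisher's method, and an association is deemed robust if the combined p
is significant in at least half of the iterations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import MethylationDataset, RobustnessRecord
from .dmp import build_design_matrix
from .preprocess import beta_to_m
from .stats import ModelFit, fisher_combine, fit_linear_model

#: Covariate set of the height models (baseline risk factors plus
#: illness type/severity, nutrition arm and malnutrition risk).
HEIGHT_COVARIATES = (
    "age_at_followup",
    "centre",
    "sex",
    "race_noncaucasian",
    "origin_noneuropean",
    "malignancy",
    "syndrome",
    "pim3",
    "pelod",
    "randomisation_arm",
    "strongkids",
    "diagnosis",
)

MIN_MODEL_N = 30


def _height_frame(dataset: MethylationDataset, probe_id: str, covariates, pcs):
    """Patient rows with non-missing height; design + methylation + y."""
    sheet = dataset.sample_sheet
    mask = (sheet["group"] == "patient") & sheet["height_4y"].notna()
    sheet = sheet[mask]
    design = build_design_matrix(sheet, pcs=pcs, covariates=covariates,
                                 group_column=None)
    m = beta_to_m(dataset.beta.loc[sheet.index, probe_id].to_numpy())
    y = sheet["height_4y"].to_numpy(dtype=float)
    return y, m, design


def fit_height_model(height, methylation_m, covariate_design: pd.DataFrame,
                     min_n: int = MIN_MODEL_N):
    """OLS of height on one probe's M-values plus the covariate design.

    Returns ``(fit, coefficient, p)`` for the methylation term.  Raises
    on rank deficiency (e.g. a degenerate constant methylation column)
    or when fewer than ``min_n`` observations are available.
    """
    y = np.asarray(height, dtype=float)
    m = np.asarray(methylation_m, dtype=float)
    if y.size < min_n:
        raise ValueError(f"n={y.size} below the model floor {min_n}")
    X = covariate_design.copy()
    X.insert(1, "methylation", m)
    fit = fit_linear_model(y, X.to_numpy(), list(X.columns))
    mi = list(X.columns).index("methylation")
    se = fit.stdev_unscaled[mi] * np.sqrt(fit.residual_variance)
    t = fit.coefficients[mi] / se
    p = 2.0 * sps.t.sf(abs(t), fit.residual_df)
    return fit, float(fit.coefficients[mi]), float(p)


def _fold_pvalues_residualise(y, M, X, folds):
    """Out-of-fold scheme: covariate-only fit on the training folds,
    residualise test heights, then test the slope of the residuals on
    the test-fold methylation (simple regression, vectorised across
    probes).

    ``M`` is (n, n_probes).  Returns (n_folds, n_probes) p-values and
    slopes.
    """
    n_probes = M.shape[1]
    ps = np.empty((len(folds), n_probes))
    slopes = np.empty((len(folds), n_probes))
    all_idx = np.arange(len(y))
    for f, test in enumerate(folds):
        train = np.setdiff1d(all_idx, test, assume_unique=True)
        beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
        r = y[test] - X[test] @ beta
        mt = M[test]
        mt_c = mt - mt.mean(axis=0, keepdims=True)
        r_c = r - r.mean()
        ss_m = np.einsum("ij,ij->j", mt_c, mt_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (mt_c * r_c[:, None]).sum(axis=0) / ss_m
        resid = r_c[:, None] - mt_c * slope[None, :]
        df = len(test) - 2
        s2 = np.einsum("ij,ij->j", resid, resid) / df
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = slope / np.sqrt(s2 / ss_m)
        ps[f] = 2.0 * sps.t.sf(np.abs(tstat), df)
        slopes[f] = slope
    return ps, slopes


def _fold_pvalues_refit(y, M, X, folds, columns):
    """Literal alternative: refit the full model inside each test fold."""
    n_probes = M.shape[1]
    ps = np.empty((len(folds), n_probes))
    slopes = np.empty((len(folds), n_probes))
    for f, test in enumerate(folds):
        for j in range(n_probes):
            Xj = np.column_stack([X[test][:, :1], M[test][:, j], X[test][:, 1:]])
            fit = fit_linear_model(y[test], Xj)
            se = fit.stdev_unscaled[1] * np.sqrt(fit.residual_variance)
            t = fit.coefficients[1] / se
            ps[f, j] = 2.0 * sps.t.sf(abs(t), fit.residual_df)
            slopes[f, j] = fit.coefficients[1]
    return ps, slopes


def cv_fisher_robustness(dataset: MethylationDataset, probe_ids,
                         covariates=HEIGHT_COVARIATES, pcs=None,
                         n_folds: int = 10, n_iterations: int = 100,
                         alpha: float = 0.05, seed: int = 0,
                         fold_scheme: str = "residualise",
                         robust_pct: float = 50.0):
    """Repeated CV with Fisher-combined fold p-values, per probe.

    For each iteration the patients with observed height are randomly
    partitioned into ``n_folds`` folds (iteration ``i`` uses
    ``seed + i``); each fold contributes one p-value for the methylation
    term (scheme selectable), and the ``n_folds`` values are combined
    with Fisher's method.  An iteration is significant iff the combined
    p is below ``alpha``; a probe is robust iff the percentage of
    significant iterations is at least ``robust_pct``.

    Returns a list of RobustnessRecord (direction labels left 'none';
    see :func:`classify_direction`).
    """
    probes = list(probe_ids)
    sheet = dataset.sample_sheet
    mask = (sheet["group"] == "patient") & sheet["height_4y"].notna()
    sheet = sheet[mask]
    design = build_design_matrix(sheet, pcs=pcs, covariates=covariates,
                                 group_column=None)
    y = sheet["height_4y"].to_numpy(dtype=float)
    M = beta_to_m(dataset.beta.loc[sheet.index, probes].to_numpy())
    X = design.to_numpy()
    n = len(y)
    if n < n_folds * 3:
        raise ValueError(f"too few patients with height ({n}) for {n_folds} folds")

    combined = np.empty((n_iterations, len(probes)))
    slope_sum = np.zeros(len(probes))
    n_slopes = 0
    for it in range(n_iterations):
        rng = np.random.default_rng(seed + it)
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        if fold_scheme == "residualise":
            ps, slopes = _fold_pvalues_residualise(y, M, X, folds)
        elif fold_scheme == "refit_within_fold":
            ps, slopes = _fold_pvalues_refit(y, M, X, folds, list(design.columns))
        else:
            raise ValueError(f"unknown fold_scheme {fold_scheme!r}")
        ps = np.clip(ps, np.finfo(float).tiny, 1.0)
        x2 = -2.0 * np.log(ps).sum(axis=0)
        combined[it] = sps.chi2.sf(x2, 2 * n_folds)
        slope_sum += slopes.sum(axis=0)
        n_slopes += len(folds)

    signal = dataset.manifest
    records = []
    for j, pid in enumerate(probes):
        pct = 100.0 * float((combined[:, j] < alpha).mean())
        q1, med, q3 = np.percentile(combined[:, j], [25, 50, 75])
        records.append(RobustnessRecord(
            probe_id=pid,
            gene=str(signal.loc[pid, "gene"]) if pid in signal.index else "",
            pct_significant_iterations=pct,
            fisher_p_median=float(med),
            fisher_p_iqr=(float(q1), float(q3)),
            robust=pct >= robust_pct,
            mean_coefficient=float(slope_sum[j] / n_slopes),
        ))
    return records


def classify_direction(record: RobustnessRecord, dmp_logFC_M: float) -> str:
    """Harm/Benefit label for a robust association.

    'Harm' when displacing methylation in the patient-abnormal direction
    predicts shorter height, i.e. ``mean_coefficient * sign(logFC) < 0``;
    'Benefit' otherwise.  Raises for non-robust records.
    """
    if not record.robust:
        raise ValueError(f"record for {record.probe_id} is not robust")
    harm = record.mean_coefficient * np.sign(dmp_logFC_M) < 0
    return "Harm" if harm else "Benefit"
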