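"""Sample and probe quality control, beta<->M transforms, control-probe PCs.

Batch adjustment is done downstream by entering the leading principal
components of the (non-negative-category) control-probe intensities as
covariates in every linear model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ControlPCs, MethylationDataset, QCReport

DEFAULT_MID_WINDOW = (0.25, 0.75)
DEFAULT_MID_THRESHOLD = 0.35
DEFAULT_DET_P_THRESHOLD = 0.01
DEFAULT_FAIL_FRACTION = 0.01
DEFAULT_EPSILON = 1e-3


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """logit2 transform: ``M = log2(beta / (1 - beta))``.

    Beta values are clamped into ``[epsilon, 1 - epsilon]`` first so the
    transform is finite; on the clamped domain ``m_to_beta`` is its
    exact inverse.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    b = np.clip(b, epsilon, 1.0 - epsilon)
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse logit2: ``beta = 2**M / (2**M + 1)``, numerically stable."""
    m = np.asarray(m, dtype=float)
    out = np.empty_like(m, dtype=float)
    pos = m >= 0
    out[pos] = 1.0 / (1.0 + 2.0 ** (-m[pos]))
    out[~pos] = 2.0 ** m[~pos] / (1.0 + 2.0 ** m[~pos])
    return out


def assess_sample_quality(
    dataset: MethylationDataset,
    mid_fraction_threshold: float = DEFAULT_MID_THRESHOLD,
    mid_window: tuple = DEFAULT_MID_WINDOW,
) -> QCReport:
    """Flag samples whose beta distribution is not bimodal.

    A good sample piles its beta values near 0 and near 1; a sample is
    flagged ``non_bimodal`` iff the fraction of its betas strictly
    inside ``mid_window`` exceeds ``mid_fraction_threshold``.  Samples
    carrying a truthy ``low_yield`` column in the sample sheet are
    flagged ``low_yield`` (and not double-flagged).
    """
    if dataset.n_samples == 0 or dataset.n_probes == 0:
        raise ValueError("empty dataset")
    lo, hi = mid_window
    b = dataset.beta.to_numpy()
    mid_frac = ((b > lo) & (b < hi)).mean(axis=1)

    excluded = []
    low_yield = (
        dataset.sample_sheet["low_yield"].fillna(False).astype(bool)
        if "low_yield" in dataset.sample_sheet.columns
        else pd.Series(False, index=dataset.sample_sheet.index)
    )
    for i, sid in enumerate(dataset.beta.index):
        if low_yield.iloc[i]:
            excluded.append((sid, "low_yield"))
        elif mid_frac[i] > mid_fraction_threshold:
            excluded.append((sid, "non_bimodal"))
    return QCReport(
        excluded_samples=excluded,
        thresholds={
            "mid_window": mid_window,
            "mid_fraction_threshold": mid_fraction_threshold,
        },
    )


def apply_sample_qc(dataset: MethylationDataset, report: QCReport) -> MethylationDataset:
    """Drop the samples listed in ``report.excluded_samples``."""
    bad = {sid for sid, _ in report.excluded_samples}
    unknown = bad - set(dataset.beta.index)
    if unknown:
        raise KeyError(f"excluded sample ids not in dataset: {sorted(unknown)}")
    keep = [sid for sid in dataset.beta.index if sid not in bad]
    return MethylationDataset(
        beta=dataset.beta.loc[keep],
        detection_p=dataset.detection_p.loc[keep],
        control_intensities=dataset.control_intensities.loc[keep],
        sample_sheet=dataset.sample_sheet.loc[keep],
        manifest=dataset.manifest,
        qc_state=dataset.qc_state,
    )


def filter_probes(
    dataset: MethylationDataset,
    det_p_threshold: float = DEFAULT_DET_P_THRESHOLD,
    fail_fraction: float = DEFAULT_FAIL_FRACTION,
):
    """Remove background-level and SNP-overlapping probes.

    A probe is removed with reason ``background`` if its detection
    p-value exceeds ``det_p_threshold`` in more than ``fail_fraction``
    of samples, and with reason ``snp`` if the manifest flags it as
    overlapping a known polymorphism.  Returns ``(filtered_dataset,
    report)`` with ``qc_state`` set to ``"filtered"``.  Idempotent.
    """
    if not 0 <= det_p_threshold <= 1 or not 0 <= fail_fraction <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    fail_frac = (dataset.detection_p.to_numpy() > det_p_threshold).mean(axis=0)
    signal = dataset.manifest.loc[dataset.beta.columns]
    snp = signal["snp_flag"].astype(bool).to_numpy()

    excluded = []
    keep = []
    for j, pid in enumerate(dataset.beta.columns):
        if fail_frac[j] > fail_fraction:
            excluded.append((pid, "background"))
        elif snp[j]:
            excluded.append((pid, "snp"))
        else:
            keep.append(pid)
    manifest = dataset.manifest.drop(index=[pid for pid, _ in excluded])
    filtered = MethylationDataset(
        beta=dataset.beta[keep],
        detection_p=dataset.detection_p[keep],
        control_intensities=dataset.control_intensities,
        sample_sheet=dataset.sample_sheet,
        manifest=manifest,
        qc_state="filtered",
    )
    report = QCReport(
        excluded_probes=excluded,
        thresholds={
            "det_p_threshold": det_p_threshold,
            "fail_fraction": fail_fraction,
        },
    )
    return filtered, report


def quantile_normalize_beta(dataset: MethylationDataset) -> MethylationDataset:
    """Optional between-sample quantile normalization of beta values.

    Each sample's betas are replaced by the mean quantile profile across
    samples (ties broken by average rank).  Default-off in the pipeline.
    """
    b = dataset.beta.to_numpy()
    order = np.argsort(b, axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(b.shape[0])[:, None]
    ranks[rows, order] = np.arange(b.shape[1])[None, :]
    mean_profile = np.sort(b, axis=1).mean(axis=0)
    normed = mean_profile[ranks]
    beta = pd.DataFrame(normed, index=dataset.beta.index, columns=dataset.beta.columns)
    return MethylationDataset(
        beta=beta,
        detection_p=dataset.detection_p,
        control_intensities=dataset.control_intensities,
        sample_sheet=dataset.sample_sheet,
        manifest=dataset.manifest,
        qc_state=dataset.qc_state,
    )


def compute_control_pcs(
    dataset: MethylationDataset,
    k: int = 30,
    exclude: tuple = ("negative",),
) -> ControlPCs:
    """Leading principal components of log2 control-probe intensities.

    Control probes in the ``exclude`` categories (negative background
    controls by default) are dropped; the remaining log2 intensities are
    centred per probe but not scaled.  Raises if ``k`` exceeds the rank
    of the centred matrix (no silent truncation) and on a constant
    (degenerate) control matrix.
    """
    controls = dataset.manifest[dataset.manifest["probe_class"] == "control"]
    keep = controls.index[~controls["control_category"].isin(exclude)]
    X = np.log2(dataset.control_intensities[keep].to_numpy())
    Xc = X - X.mean(axis=0, keepdims=True)

    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    tol = s[0] * max(Xc.shape) * np.finfo(float).eps if s.size and s[0] > 0 else 0.0
    rank = int(np.sum(s > tol))
    if rank == 0:
        raise ValueError("degenerate control matrix: identical control rows for all samples")
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank} of the centred control matrix")

    scores = u[:, :k] * s[:k]
    ev = (s**2) / max(Xc.shape[0] - 1, 1)
    return ControlPCs(
        scores=pd.DataFrame(
            scores,
            index=dataset.control_intensities.index,
            columns=[f"PC{i + 1}" for i in range(k)],
        ),
        explained_variance=list(ev[:k]),
        excluded_control_categories=list(exclude),
    )
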