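"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Everything is generated on the M-value (logit2) scale, where planted
group effects are additive for the downstream linear models, and mapped
back to beta values with the exact inverse transform.  A per-sample
latent batch factor enters both the signal M-values and the control-probe
intensities, so that control-probe principal components are an effective
batch adjustment by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import MethylationDataset
from .preprocess import m_to_beta

__all__ = [
    "PANEL_GENES",
    "PANEL_SITE_COUNTS",
    "SimulationConfig",
    "generate_manifest",
    "generate_cohort",
    "generate_methylation",
    "generate_height",
    "simulate_dataset",
]

#: The 28-gene steroidogenesis panel.
PANEL_GENES = (
    "CYP11A1", "FDX1", "FDX2", "FDXR", "HSD3B1", "HSD3B2", "CYP17A1",
    "POR", "CYB5A", "CYB5B", "HSD17B1", "HSD17B2", "HSD17B3", "HSD17B6",
    "HSD17B7", "HSD17B8", "HSD17B10", "HSD17B11", "HSD17B12", "HSD17B14",
    "CYP19A1", "CYP21A2", "CYP11B1", "CYP11B2", "SULT2A1", "SULT2B1",
    "SULT1E1", "STS",
)

# Published per-gene site counts where available; the remaining genes
# share the balance of the 627-site panel.
_KNOWN_COUNTS = {
    "CYP11A1": 37, "POR": 69, "CYB5A": 28, "HSD17B1": 15, "HSD17B2": 32,
    "HSD17B3": 19, "HSD17B6": 10, "HSD17B10": 15, "HSD17B12": 47,
    "CYP19A1": 55, "CYP21A2": 13, "CYP11B2": 11,
}


def _default_site_counts():
    counts = dict(_KNOWN_COUNTS)
    rest = [g for g in PANEL_GENES if g not in counts]
    remaining = 627 - sum(counts.values())  # 276 over 16 genes
    base, extra = divmod(remaining, len(rest))
    for i, g in enumerate(rest):
        counts[g] = base + (1 if i < extra else 0)
    return {g: counts[g] for g in PANEL_GENES}


PANEL_SITE_COUNTS = _default_site_counts()

# Cohort marginals used as generator targets (overridable per call).
PATIENT_MARGINALS = {
    "male": 0.581,
    "gc_treatment": 210 / 818,
    "race_noncaucasian": 0.081,
    "origin_noneuropean": 0.176,
    "malignancy": 0.048,
    "syndrome": 0.205,
    "strongkids_high": 0.10,
    "diagnosis_probs": (0.445, 0.142, 0.174, 0.240),
    "age_log_median": np.log(3.4),
    "age_log_sd": 0.83,
    "pim3_mean": -3.8,
    "pim3_sd": 1.26,
    "pelod_mean": 22.0,
    "pelod_sd": 14.8,
}
HEALTHY_MARGINALS = {
    "male": 0.541,
    "race_noncaucasian": 0.082,
    "origin_noneuropean": 0.130,
    "malignancy": 0.0,
    "syndrome": 0.010,
    "age_log_median": np.log(3.8),
    "age_log_sd": 0.83,
}

DIAGNOSES = ("cardiac_surgery", "elective_surgery", "urgent_surgery", "medical")


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults mirror the study's scale."""

    n_patients: int = 818
    n_healthy: int = 392
    n_genes: int = 28
    sites_per_gene: object = None  # None -> panel counts; int or per-gene list
    n_control: int = 600
    planted_dmps: dict = field(default_factory=dict)  # probe_id -> delta_M
    planted_dmr: Optional[tuple] = None  # (gene, (first, last site index), delta_M)
    batch_levels: int = 8
    batch_effect_sd: float = 0.25
    control_batch_loading: float = 1.0
    height_coefficients: dict = field(default_factory=dict)  # probe_id -> cm per M unit
    noise_sd_M: float = 0.7
    seed: int = 0
    # covariate effects on M-values (kept small by default)
    age_effect_sd_M: float = 0.01
    sex_effect_sd_M: float = 0.05
    # QC plants
    n_nonbimodal_samples: int = 0
    n_low_yield_samples: int = 0
    n_failing_probes: int = 0
    snp_fraction: float = 0.05
    manifest_gap_range: tuple = (10, 8000)
    # height model
    height_noise_sd: float = 4.0
    height_missing_fraction: float = 160 / 818

    def __post_init__(self):
        for name in ("batch_effect_sd", "noise_sd_M", "height_noise_sd",
                     "age_effect_sd_M", "sex_effect_sd_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def generate_manifest(n_genes: int, sites_per_gene, n_control: int, seed: int,
                      snp_fraction: float = 0.05,
                      gap_range: tuple = (10, 8000)) -> pd.DataFrame:
    """Synthetic probe manifest: clustered signal probes plus controls.

    Signal probes for each gene occupy a contiguous genomic window
    around a synthetic transcription start site; inter-site gaps are
    drawn from a lognormal, so some fall under and some over 1000 bp.
    Gene sections are assigned deterministically from position relative
    to the transcription start.  Returns a frame indexed by probe id.
    """
    if n_genes < 1 or n_control < 1:
        raise ValueError("counts must be >= 1")
    if isinstance(sites_per_gene, int):
        if sites_per_gene < 1:
            raise ValueError("counts must be >= 1")
        counts = [sites_per_gene] * n_genes
    else:
        counts = list(sites_per_gene)
        if len(counts) != n_genes:
            raise ValueError("per-gene counts length must equal n_genes")
        if any(c < 1 for c in counts):
            raise ValueError("counts must be >= 1")

    rng = np.random.default_rng(seed)
    genes = [PANEL_GENES[i] if i < len(PANEL_GENES) else f"GENE{i + 1:02d}"
             for i in range(n_genes)]

    rows = []
    probe_counter = 0
    for gi, (gene, n_sites) in enumerate(zip(genes, counts)):
        chrom = f"chr{(gi % 22) + 1}"
        tss = 1_000_000 + (gi // 22) * 50_000_000 + gi * 1_000_000
        # first site lands inside the 1500-bp promoter window
        start = tss - int(rng.integers(200, 1400))
        gaps = np.clip(rng.lognormal(np.log(250.0), 1.1, size=max(n_sites - 1, 0)),
                       gap_range[0], gap_range[1]).astype(int)
        positions = start + np.concatenate([[0], np.cumsum(gaps)])
        gene_end = max(int(positions[-1]) + 500, tss + 2000)
        for pos in positions:
            # promoter window is 0..1500 bp upstream of the TSS
            pos = max(int(pos), tss - 1500)
            if pos < tss:
                section = "Promoter"
            elif pos < tss + 200:
                section = "5'UTR"
            elif pos < tss + 500:
                section = "1stExon"
            elif pos < gene_end - 300:
                section = "Body"
            else:
                section = "3'UTR"
            probe_counter += 1
            rows.append({
                "probe_id": f"cg{probe_counter:08d}",
                "chromosome": chrom,
                "position": pos,
                "gene": gene,
                "gene_section": section,
                "snp_flag": bool(rng.random() < snp_fraction),
                "probe_class": "signal",
                "control_category": "none",
            })

    ctrl_categories = ["negative", "bisulphite_conversion", "staining",
                       "extension", "hybridization", "specificity"]
    for c in range(n_control):
        rows.append({
            "probe_id": f"ctrl{c + 1:05d}",
            "chromosome": "chrC",
            "position": c + 1,
            "gene": "",
            "gene_section": "",
            "snp_flag": False,
            "probe_class": "control",
            "control_category": ctrl_categories[c % len(ctrl_categories)],
        })
    manifest = pd.DataFrame(rows).set_index("probe_id")
    return manifest


def _quantize(rng, n, p):
    return rng.random(n) < p


def generate_cohort(n_patients: int, n_healthy: int, seed: int,
                    patient_marginals: dict = None,
                    healthy_marginals: dict = None,
                    n_batches: int = 8) -> pd.DataFrame:
    """Two-group sample sheet with study-like covariate marginals.

    Healthy rows carry missing values for every PICU-only field; ages
    are non-negative and age at admission is follow-up age minus the
    two-year gap.
    """
    if n_patients < 0 or n_healthy < 0:
        raise ValueError("counts must be >= 0")
    pm = dict(PATIENT_MARGINALS, **(patient_marginals or {}))
    hm = dict(HEALTHY_MARGINALS, **(healthy_marginals or {}))
    rng = np.random.default_rng(seed)

    def ages(n, marg):
        a = np.exp(rng.normal(marg["age_log_median"], marg["age_log_sd"], n))
        return np.clip(a, 2.05, 19.9)

    ids = [f"P{i + 1:04d}" for i in range(n_patients)] + \
          [f"H{i + 1:04d}" for i in range(n_healthy)]
    groups = ["patient"] * n_patients + ["healthy"] * n_healthy
    sheet = pd.DataFrame({"group": groups}, index=pd.Index(ids, name="sample_id"))

    pat = sheet["group"] == "patient"
    n_p, n_h = int(pat.sum()), int((~pat).sum())

    age_fu = np.empty(len(sheet))
    age_fu[pat.to_numpy()] = ages(n_p, pm)
    age_fu[(~pat).to_numpy()] = ages(n_h, hm)
    sheet["age_at_followup"] = age_fu
    sheet["age_at_admission"] = np.maximum(age_fu - 2.0, 0.0)

    sex = np.where(
        np.concatenate([_quantize(rng, n_p, pm["male"]), _quantize(rng, n_h, hm["male"])]),
        "male", "female")
    sheet["sex"] = sex
    sheet["centre"] = np.where(rng.random(len(sheet)) < 0.6, "centre_A", "centre_B")
    sheet["race_noncaucasian"] = np.concatenate(
        [_quantize(rng, n_p, pm["race_noncaucasian"]), _quantize(rng, n_h, hm["race_noncaucasian"])])
    sheet["origin_noneuropean"] = np.concatenate(
        [_quantize(rng, n_p, pm["origin_noneuropean"]), _quantize(rng, n_h, hm["origin_noneuropean"])])
    sheet["malignancy"] = np.concatenate(
        [_quantize(rng, n_p, pm["malignancy"]), _quantize(rng, n_h, hm["malignancy"])])
    sheet["syndrome"] = np.concatenate(
        [_quantize(rng, n_p, pm["syndrome"]), _quantize(rng, n_h, hm["syndrome"])])

    # PICU-only fields: float/object columns, NaN for healthy
    sheet["pim3"] = np.nan
    sheet["pelod"] = np.nan
    sheet["strongkids"] = pd.Series(pd.NA, index=sheet.index, dtype="object")
    sheet["randomisation_arm"] = pd.Series(pd.NA, index=sheet.index, dtype="object")
    sheet["diagnosis"] = pd.Series(pd.NA, index=sheet.index, dtype="object")
    sheet["gc_treatment"] = pd.Series(pd.NA, index=sheet.index, dtype="object")
    sheet["picu_los"] = np.nan

    if n_p:
        idx = sheet.index[pat]
        sheet.loc[idx, "pim3"] = rng.normal(pm["pim3_mean"], pm["pim3_sd"], n_p)
        sheet.loc[idx, "pelod"] = np.clip(
            np.round(rng.normal(pm["pelod_mean"], pm["pelod_sd"], n_p)), 0, 71)
        sheet.loc[idx, "strongkids"] = np.where(
            _quantize(rng, n_p, pm["strongkids_high"]), "high", "medium")
        sheet.loc[idx, "randomisation_arm"] = np.where(
            _quantize(rng, n_p, 0.5), "early_PN", "late_PN")
        diag_p = np.asarray(pm["diagnosis_probs"], dtype=float)
        sheet.loc[idx, "diagnosis"] = rng.choice(
            DIAGNOSES, size=n_p, p=diag_p / diag_p.sum())
        sheet.loc[idx, "gc_treatment"] = _quantize(rng, n_p, pm["gc_treatment"])
        sheet.loc[idx, "picu_los"] = np.clip(
            np.exp(rng.normal(np.log(5.0), 0.8, n_p)), 1, 120)

    sheet["batch"] = [f"batch{(rng.integers(n_batches)) + 1}" for _ in range(len(sheet))]
    sheet["height_4y"] = np.nan
    sheet["low_yield"] = False
    return sheet


def generate_methylation(manifest: pd.DataFrame, sample_sheet: pd.DataFrame,
                         config: SimulationConfig) -> MethylationDataset:
    """Draw a full methylation dataset under the configured generative model.

    M-values: probe baseline + planted group shift + small covariate
    effects + shared batch factor + Gaussian noise; betas are the exact
    inverse-logit2 of the M-values.  Control intensities carry the same
    per-sample batch factor.  Optionally plants non-bimodal samples and
    detection-failing probes for QC testing.
    """
    rng = np.random.default_rng(config.seed)
    signal = manifest[manifest["probe_class"] == "signal"]
    controls = manifest[manifest["probe_class"] == "control"]
    probes = signal.index
    samples = sample_sheet.index
    n, m = len(samples), len(probes)
    if n == 0 or m == 0:
        raise ValueError("empty manifest or sample sheet")

    deltas = np.zeros(m)
    probe_pos = {p: j for j, p in enumerate(probes)}
    for pid, d in config.planted_dmps.items():
        if pid not in probe_pos:
            raise KeyError(f"planted probe {pid} not in manifest")
        deltas[probe_pos[pid]] += d
    if config.planted_dmr is not None:
        gene, (a, b), d = config.planted_dmr
        gene_probes = signal.index[signal["gene"] == gene]
        if len(gene_probes) == 0:
            raise KeyError(f"planted DMR gene {gene} not in manifest")
        for pid in gene_probes[a:b + 1]:
            deltas[probe_pos[pid]] += d

    # bimodal probe baselines: mostly near the rails, some mid-range
    comp = rng.random(m)
    mu = np.where(comp < 0.4, rng.normal(-3.0, 0.5, m),
                  np.where(comp < 0.8, rng.normal(3.0, 0.5, m),
                           rng.normal(0.0, 1.0, m)))

    group = (sample_sheet["group"] == "patient").to_numpy(dtype=float)
    age = sample_sheet["age_at_followup"].to_numpy(dtype=float)
    male = (sample_sheet["sex"] == "male").to_numpy(dtype=float)

    age_slopes = rng.normal(0.0, config.age_effect_sd_M, m)
    sex_shifts = rng.normal(0.0, config.sex_effect_sd_M, m)

    batch_labels = sample_sheet["batch"].astype("category")
    level_effects = rng.normal(0.0, 1.0, len(batch_labels.cat.categories))
    batch_factor = level_effects[batch_labels.cat.codes.to_numpy()] + rng.normal(0.0, 0.3, n)
    signal_loadings = rng.normal(1.0, 0.3, m)

    M = (
        mu[None, :]
        + np.outer(group, deltas)
        + np.outer(age - age.mean(), age_slopes)
        + np.outer(male - male.mean(), sex_shifts)
        + config.batch_effect_sd * np.outer(batch_factor, signal_loadings)
        + rng.normal(0.0, config.noise_sd_M, (n, m))
    )
    beta = m_to_beta(M)

    detection_p = rng.uniform(0.0, 0.005, (n, m))
    if config.n_failing_probes:
        planted = set(config.planted_dmps) | set()
        candidates = [j for j, p in enumerate(probes) if p not in planted]
        fail = rng.choice(candidates, size=config.n_failing_probes, replace=False)
        detection_p[:, fail] = rng.uniform(0.05, 0.5, (n, len(fail)))

    sheet = sample_sheet.copy()
    sheet["sim_batch_factor"] = batch_factor  # ground truth for tests
    n_bad = config.n_nonbimodal_samples + config.n_low_yield_samples
    if n_bad:
        # disjoint picks so each planted failure gets its own sample
        picked = rng.choice(n, size=n_bad, replace=False)
        bad = picked[: config.n_nonbimodal_samples]
        flagged = picked[config.n_nonbimodal_samples:]
        beta[bad, :] = rng.uniform(0.3, 0.7, (len(bad), m))
        sheet.loc[sheet.index[flagged], "low_yield"] = True

    base = np.exp(rng.normal(np.log(2000.0), 0.3, len(controls)))
    ctrl_loadings = rng.normal(1.0, 0.2, len(controls))
    log2_ctrl = (
        np.log2(base)[None, :]
        + config.control_batch_loading * np.outer(batch_factor, ctrl_loadings)
        + rng.normal(0.0, 0.1, (n, len(controls)))
    )
    control_intensities = 2.0 ** log2_ctrl

    return MethylationDataset(
        beta=pd.DataFrame(beta, index=samples, columns=probes),
        detection_p=pd.DataFrame(detection_p, index=samples, columns=probes),
        control_intensities=pd.DataFrame(control_intensities, index=samples,
                                         columns=controls.index),
        sample_sheet=sheet,
        manifest=manifest,
        qc_state="raw",
    )


def generate_height(sample_sheet: pd.DataFrame, dataset: MethylationDataset,
                    config: SimulationConfig) -> pd.Series:
    """Height-at-follow-up outcome for patients, written into the sheet.

    ``height = baseline(age, sex) + sum(coef * M_probe) + noise`` with a
    configurable fraction left missing.  Returns the height vector and
    mutates ``sample_sheet['height_4y']`` for patient rows.
    """
    from .preprocess import beta_to_m

    rng = np.random.default_rng(config.seed + 104729)  # distinct stream
    pat = sample_sheet["group"] == "patient"
    idx = sample_sheet.index[pat]
    n_p = len(idx)
    if n_p == 0:
        return sample_sheet["height_4y"]

    age4 = sample_sheet.loc[idx, "age_at_admission"].to_numpy(dtype=float) + 4.0
    male = (sample_sheet.loc[idx, "sex"] == "male").to_numpy(dtype=float)
    height = 62.0 + 6.5 * age4 - 0.08 * age4**2 + 1.5 * male

    for pid, coef in config.height_coefficients.items():
        if pid not in dataset.beta.columns:
            raise KeyError(f"height coefficient probe {pid} not in dataset")
        mvals = beta_to_m(dataset.beta.loc[idx, pid].to_numpy())
        height = height + coef * mvals
    height = height + rng.normal(0.0, config.height_noise_sd, n_p)

    if config.height_missing_fraction > 0:
        n_miss = int(round(config.height_missing_fraction * n_p))
        if n_miss:
            miss = rng.choice(n_p, size=n_miss, replace=False)
            height[miss] = np.nan
    sample_sheet.loc[idx, "height_4y"] = height
    return sample_sheet["height_4y"]


def simulate_dataset(config: SimulationConfig) -> MethylationDataset:
    """End-to-end convenience: manifest + cohort + methylation + height."""
    counts = config.sites_per_gene
    if counts is None:
        counts = [PANEL_SITE_COUNTS[g] for g in PANEL_GENES[: config.n_genes]] \
            if config.n_genes <= len(PANEL_GENES) else 20
    manifest = generate_manifest(config.n_genes, counts, config.n_control,
                                 config.seed, snp_fraction=config.snp_fraction,
                                 gap_range=tuple(config.manifest_gap_range))
    sheet = generate_cohort(config.n_patients, config.n_healthy, config.seed + 1,
                            n_batches=config.batch_levels)
    dataset = generate_methylation(manifest, sheet, config)
    generate_height(dataset.sample_sheet, dataset, config)
    return dataset
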