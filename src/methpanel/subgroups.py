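"""Interaction tests on identified DMPs and glucocorticoid-effect models.

Sex and dichotomised age-at-exposure interactions with the group
contrast, plus patient-only glucocorticoid contrasts classified as
aggravating or attenuating the group-level abnormality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GCEffectResult, InteractionResult, MethylationDataset
from .dmp import DEFAULT_COVARIATES, GROUP_COLUMN, build_design_matrix
from .preprocess import beta_to_m
from .stats import bh_adjust, fit_linear_models, moderate_variances, moderated_t_tests

AGE_CUTOFF = 6.0

#: Patient-only covariates added to the GC contrast model.
GC_EXTRA_COVARIATES = (
    "picu_los",
    "diagnosis",
    "pim3",
    "pelod",
    "randomisation_arm",
    "strongkids",
)


def dichotomise_age(age_at_admission, cutoff: float = AGE_CUTOFF):
    """Map age at exposure to {'lt6', 'ge6'}; the boundary is inclusive."""
    age = np.asarray(age_at_admission, dtype=float)
    if np.any(age < 0):
        raise ValueError("ages must be non-negative")
    out = np.where(age >= cutoff, "ge6", "lt6")
    return out.item() if out.ndim == 0 else out


def _factor_indicator(sample_sheet: pd.DataFrame, factor: str, cutoff: float):
    if factor == "sex":
        return (sample_sheet["sex"] == "male").astype(float).to_numpy(), "male"
    if factor == "age_ge6":
        levels = dichotomise_age(sample_sheet["age_at_admission"].to_numpy(), cutoff)
        return (levels == "ge6").astype(float), "ge6"
    raise ValueError(f"unknown interaction factor {factor!r}")


def test_interaction(dataset: MethylationDataset, dmp_probes, factor: str,
                     covariates=DEFAULT_COVARIATES, pcs=None,
                     age_cutoff: float = AGE_CUTOFF):
    """Group-by-factor interaction at each identified DMP.

    Fits the DMP design plus a group x factor product term; the reported
    p is the interaction coefficient's moderated p, uncorrected.  Also
    reports the per-stratum group effect (fit separately per stratum).

    Raises when the factor is constant within either study group.
    """
    sheet = dataset.sample_sheet
    ind, high_level = _factor_indicator(sheet, factor, age_cutoff)
    grp = (sheet["group"] == "patient").to_numpy()
    for gname, gmask in (("patient", grp), ("healthy", ~grp)):
        if len(np.unique(ind[gmask])) < 2:
            raise ValueError(f"factor {factor!r} is constant within the "
                             f"{gname} group")

    design = build_design_matrix(sheet, pcs=pcs, covariates=covariates)
    if factor == "sex":
        base = design  # sex main effect already among the covariates
    else:
        base = design.copy()
        base[f"{factor}_{high_level}"] = ind
    inter = base.copy()
    inter_col = f"{GROUP_COLUMN}_x_{factor}"
    inter[inter_col] = base[GROUP_COLUMN].to_numpy() * ind

    probes = list(dmp_probes)
    M = beta_to_m(dataset.beta[probes].to_numpy())
    coefs, su, s2, df = fit_linear_models(M, inter.to_numpy(), list(inter.columns))
    ii = list(inter.columns).index(inter_col)
    moderation = moderate_variances(s2, df)
    _, p, _, _ = moderated_t_tests(coefs[ii], su[ii], moderation)

    # per-stratum group effect (ordinary fits within each stratum)
    stratum_effects = {}
    for label, mask in ((high_level, ind == 1),
                        (("female" if factor == "sex" else "lt6"), ind == 0)):
        sub_design = build_design_matrix(sheet[mask], pcs=pcs, covariates=[
            c for c in covariates if c != "sex" or factor != "sex"])
        sub_M = beta_to_m(dataset.beta.loc[mask, probes].to_numpy())
        c, _, _, _ = fit_linear_models(sub_M, sub_design.to_numpy(),
                                       list(sub_design.columns))
        gi = list(sub_design.columns).index(GROUP_COLUMN)
        stratum_effects[label] = c[gi]

    return [
        InteractionResult(
            probe_id=pid,
            factor=factor,
            interaction_p=float(p[j]),
            stratum_effects={k: float(v[j]) for k, v in stratum_effects.items()},
        )
        for j, pid in enumerate(probes)
    ]


def test_gc_effect(dataset: MethylationDataset, dmp_probes, dmp_logfc: dict,
                   covariates=DEFAULT_COVARIATES,
                   extra_covariates=GC_EXTRA_COVARIATES, pcs=None):
    """Glucocorticoid contrast among patients at each identified DMP.

    Moderated model of the M-value on GC treatment plus baseline and
    illness covariates; the direction is ``aggravated`` when the GC
    shift has the same sign as the probe's patient-vs-healthy logFC and
    ``attenuated`` otherwise.
    """
    sheet = dataset.sample_sheet
    pat = sheet["group"] == "patient"
    sheet = sheet[pat]
    gc = sheet["gc_treatment"].astype(bool)
    if gc.nunique() < 2:
        raise ValueError("no variation in glucocorticoid treatment among patients")

    all_covs = list(covariates) + list(extra_covariates)
    design = build_design_matrix(sheet, pcs=None, covariates=all_covs,
                                 group_column=None)
    design["gc"] = gc.astype(float).to_numpy()
    if pcs is not None:
        scores = pcs.scores.loc[sheet.index]
        for name in scores.columns:
            design[name] = scores[name].to_numpy()

    probes = list(dmp_probes)
    M = beta_to_m(dataset.beta.loc[sheet.index, probes].to_numpy())
    coefs, su, s2, df = fit_linear_models(M, design.to_numpy(), list(design.columns))
    gi = list(design.columns).index("gc")
    moderation = moderate_variances(s2, df)
    _, p, _, _ = moderated_t_tests(coefs[gi], su[gi], moderation)

    results = []
    for j, pid in enumerate(probes):
        ref = dmp_logfc[pid]
        same = np.sign(coefs[gi][j]) == np.sign(ref)
        results.append(GCEffectResult(
            probe_id=pid,
            gc_logFC_M=float(coefs[gi][j]),
            p=float(p[j]),
            direction="aggravated" if same else "attenuated",
        ))
    return results
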