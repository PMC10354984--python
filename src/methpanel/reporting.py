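"""Publication-style table rendering.

Effect sizes print as ``logFC [lo to hi]`` to 3 decimals, percentages
to one decimal with integral values trimmed (``100``, not ``100.0``),
and p-values to 2 significant figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def format_logfc_ci(logfc: float, lo: float, hi: float) -> str:
    return f"{logfc:.3f} [{lo:.3f} to {hi:.3f}]"


def format_pct(x: float) -> str:
    r = round(float(x), 1)
    return f"{int(r)}" if r == int(r) else f"{r:.1f}"


def format_p(p: float) -> str:
    return f"{p:.2g}"


def _status(direction: str) -> str:
    return {"hypomethylated": "Hypomethylated",
            "hypermethylated": "Hypermethylated"}[direction]


def render_dmp_table(dmps, interactions_sex=None, interactions_age=None,
                     gc_effects=None) -> pd.DataFrame:
    """Group-difference table: one row per DMP, publication layout."""
    sex_p = {r.probe_id: r.interaction_p for r in (interactions_sex or [])}
    age_p = {r.probe_id: r.interaction_p for r in (interactions_age or [])}
    gc_p = {r.probe_id: r.p for r in (gc_effects or [])}
    rows = []
    for d in dmps:
        row = {
            "gene": d.gene,
            "cpg_site": d.probe_id,
            "gene_section": d.gene_section,
            "methylation_status": _status(d.direction),
            "logFC_ci": format_logfc_ci(d.logFC_M, *d.ci95),
            "abs_mean_difference": f"{d.abs_mean_beta_diff:.3f}",
            "p_value": format_p(d.q_bh),
        }
        if sex_p:
            row["interaction_sex_p"] = format_p(sex_p[d.probe_id])
        if age_p:
            row["interaction_age_p"] = format_p(age_p[d.probe_id])
        if gc_p:
            row["gc_vs_no_gc_p"] = format_p(gc_p[d.probe_id])
        rows.append(row)
    cols = ["gene", "cpg_site", "gene_section", "methylation_status",
            "logFC_ci", "abs_mean_difference", "p_value"]
    if sex_p:
        cols.append("interaction_sex_p")
    if age_p:
        cols.append("interaction_age_p")
    if gc_p:
        cols.append("gc_vs_no_gc_p")
    return pd.DataFrame(rows, columns=cols)


def render_dmr_table(regions) -> pd.DataFrame:
    rows = [{
        "gene": r.gene,
        "chromosome": r.chromosome,
        "start": r.start,
        "end": r.end,
        "width_bp": r.width,
        "n_cpgs": r.n_cpgs,
        "direction": _status(r.direction),
        "mean_logFC_M": f"{r.mean_logFC_M:.3f}",
        "min_q": format_p(r.min_q),
        "member_probes": ";".join(r.member_probe_ids),
    } for r in regions]
    return pd.DataFrame(rows, columns=["gene", "chromosome", "start", "end",
                                       "width_bp", "n_cpgs", "direction",
                                       "mean_logFC_M", "min_q", "member_probes"])


def render_robustness_table(records, gene_sections=None) -> pd.DataFrame:
    """Outcome-association table: pct significant iterations, median
    (IQR) Fisher p and the Harm/Benefit direction label."""
    rows = []
    for r in records:
        q1, q3 = r.fisher_p_iqr
        rows.append({
            "gene": r.gene,
            "cpg_site": r.probe_id,
            "gene_section": (gene_sections or {}).get(r.probe_id, ""),
            "pct_significant_iterations": format_pct(r.pct_significant_iterations),
            "median_iqr_p": f"{format_p(r.fisher_p_median)} "
                            f"({format_p(q1)}–{format_p(q3)})",
            "direction": r.direction_label if r.robust else "none",
        })
    return pd.DataFrame(rows, columns=["gene", "cpg_site", "gene_section",
                                       "pct_significant_iterations",
                                       "median_iqr_p", "direction"])


def render_interaction_table(results) -> pd.DataFrame:
    rows = [{
        "cpg_site": r.probe_id,
        "factor": r.factor,
        "interaction_p": format_p(r.interaction_p),
        **{f"logFC_{k}": f"{v:.3f}" for k, v in r.stratum_effects.items()},
    } for r in results]
    return pd.DataFrame(rows)


def render_gc_table(results) -> pd.DataFrame:
    rows = [{
        "cpg_site": r.probe_id,
        "gc_logFC_M": f"{r.gc_logFC_M:.3f}",
        "p_value": format_p(r.p),
        "direction": r.direction,
    } for r in results]
    return pd.DataFrame(rows, columns=["cpg_site", "gc_logFC_M", "p_value",
                                       "direction"])
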