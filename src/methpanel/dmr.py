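"""Kernel-smoothed differentially methylated region (DMR) detection.

Per-site squared t-statistics are Gaussian-kernel averaged along the
genome, referred to a two-moment scaled chi-square null, BH-adjusted,
and significant sites are chained into regions at a maximum gap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import DMRRecord
from .stats import bh_adjust
from scipy import stats as sps

DEFAULT_LAMBDA = 1000.0
DEFAULT_C = 2.0
DEFAULT_MAX_GAP = 1000
DEFAULT_MIN_CPGS = 2


def kernel_smooth(positions, t, lam: float = DEFAULT_LAMBDA, C: float = DEFAULT_C):
    """Gaussian-kernel weighted average of squared statistics per site.

    ``S_i = sum_j w_ij t_j^2 / sum_j w_ij`` with
    ``w_ij = exp(-(pos_i - pos_j)^2 / (2 sigma^2))``, ``sigma = lam/C``,
    and contributions truncated at ``|pos_i - pos_j| > lam``.

    Returns
    -------
    smoothed : (m,) array of S_i
    w_sum, w2_sum : (m,) arrays of per-site kernel weight sums and
        squared-weight sums, needed by the null stage.
    """
    pos = np.asarray(positions, dtype=float)
    t = np.asarray(t, dtype=float)
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if pos.shape != t.shape:
        raise ValueError("positions and statistics must align")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted non-decreasingly")

    sigma = lam / C
    m = pos.size
    t2 = t * t
    smoothed = np.empty(m)
    w_sum = np.empty(m)
    w2_sum = np.empty(m)
    # window bounds via searchsorted: O(total neighbours) overall
    left = np.searchsorted(pos, pos - lam, side="left")
    right = np.searchsorted(pos, pos + lam, side="right")
    for i in range(m):
        d = pos[left[i]:right[i]] - pos[i]
        w = np.exp(-(d * d) / (2.0 * sigma * sigma))
        ws = w.sum()
        smoothed[i] = (w * t2[left[i]:right[i]]).sum() / ws
        w_sum[i] = ws
        w2_sum[i] = (w * w).sum()
    return smoothed, w_sum, w2_sum


def null_pvalues(smoothed, w_sum, w2_sum):
    """Satterthwaite p-values for kernel estimates against the null.

    Treats each member t^2 as chi-square(1); the weighted average then
    has null mean 1 and variance ``2 * sum(w^2) / sum(w)^2``, matched by
    a scaled chi-square with ``nu = 2/var`` degrees of freedom.

    Returns ``(p, q)`` with BH adjustment across sites.
    """
    S = np.asarray(smoothed, dtype=float)
    w_sum = np.asarray(w_sum, dtype=float)
    w2_sum = np.asarray(w2_sum, dtype=float)
    if np.any(w_sum <= 0):
        raise ValueError("zero kernel weight sum")
    var = 2.0 * w2_sum / (w_sum * w_sum)
    nu = 2.0 / var
    p = sps.chi2.sf(nu * S, nu)
    return p, bh_adjust(p)


def group_regions(sites: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP,
                  min_cpgs: int = DEFAULT_MIN_CPGS):
    """Chain significant sites into regions by single-linkage at ``max_gap``.

    ``sites`` must carry columns chromosome, position, gene, logFC_M and
    q (per-site FDR), indexed by probe id.  Two consecutive sites on a
    chromosome belong to the same region iff their gap is <= ``max_gap``
    (boundary inclusive).  Regions with fewer than ``min_cpgs`` members
    are dropped.  Start/end come from the two extreme members and
    ``width = end - start``.
    """
    records = []
    for chrom, chunk in sites.groupby("chromosome", sort=True):
        chunk = chunk.sort_values("position")
        pos = chunk["position"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.where(np.diff(pos) > max_gap)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = chunk.iloc[a:b]
            if len(members) < min_cpgs:
                continue
            start = int(members["position"].iloc[0])
            end = int(members["position"].iloc[-1])
            mean_lfc = float(members["logFC_M"].mean())
            records.append(DMRRecord(
                gene=members["gene"].mode().iloc[0],
                chromosome=chrom,
                start=start,
                end=end,
                width=end - start,
                n_cpgs=len(members),
                member_probe_ids=list(members.index),
                mean_logFC_M=mean_lfc,
                min_q=float(members["q"].min()),
                direction="hypomethylated" if mean_lfc < 0 else "hypermethylated",
            ))
    return records


def identify_dmrs(dmp_stats: pd.DataFrame, lam: float = DEFAULT_LAMBDA,
                  C: float = DEFAULT_C, fdr_threshold: float = 0.05,
                  max_gap: int = DEFAULT_MAX_GAP,
                  min_cpgs: int = DEFAULT_MIN_CPGS):
    """Full DMR pass from the per-probe DMP statistics table.

    Smooths squared moderated t per chromosome, computes null p-values,
    BH-adjusts across all sites jointly, then chains the significant
    sites into regions.

    Returns ``(site_table, regions)`` where ``site_table`` adds
    smoothed, p and q columns to the input rows.
    """
    parts = []
    for chrom, chunk in dmp_stats.groupby("chromosome", sort=True):
        chunk = chunk.sort_values("position")
        S, w, w2 = kernel_smooth(chunk["position"].to_numpy(),
                                 chunk["t"].to_numpy(), lam, C)
        part = chunk[["gene", "chromosome", "position", "logFC_M"]].copy()
        part["smoothed"] = S
        part["w_sum"] = w
        part["w2_sum"] = w2
        parts.append(part)
    table = pd.concat(parts)
    p, q = null_pvalues(table["smoothed"].to_numpy(), table["w_sum"].to_numpy(),
                        table["w2_sum"].to_numpy())
    table["p"] = p
    table["q"] = q
    sig = table[table["q"] < fdr_threshold]
    regions = group_regions(sig, max_gap=max_gap, min_cpgs=min_cpgs)
    return table, regions


def dmrs_to_bed(regions) -> pd.DataFrame:
    """BED frame (0-based half-open) from 1-based inclusive region bounds."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chromosome,
                "chromStart": r.start - 1,
                "chromEnd": r.end,
                "name": f"{r.gene}_DMR",
                "score": r.n_cpgs,
                "strand": ".",
            }
            for r in regions
        ],
        columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"],
    )
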