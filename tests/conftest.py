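import numpy as np
import pandas as pd
import pytest

from methpanel.simulate import SimulationConfig, simulate_dataset


def small_config(**kw):
    base = dict(
        n_patients=150,
        n_healthy=80,
        n_genes=8,
        sites_per_gene=12,
        n_control=60,
        batch_levels=3,
        snp_fraction=0.0,
        seed=11,
    )
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    """Clean small cohort: no planted effects, no QC plants."""
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def planted_dataset():
    """Cohort with planted DMPs, a planted DMR and a height effect."""
    cfg = small_config(
        n_patients=400,
        n_healthy=200,
        planted_dmps={"cg00000005": -0.6, "cg00000030": 0.7},
        planted_dmr=("POR", (3, 7), -0.7),
        height_coefficients={"cg00000005": 4.0},
        seed=21,
    )
    return simulate_dataset(cfg)


def bh_oracle(p):
    """Brute-force BH step-up: q_(i) = min_{j >= i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    best = 1.0
    for i in range(m - 1, -1, -1):
        best = min(best, m * p[order[i]] / (i + 1))
        q_sorted[i] = min(best, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def chain_oracle(positions, max_gap):
    """All-pairs transitive-closure grouping of 1-D positions."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(positions)))
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) <= max_gap:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: positions[c[0]])
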