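"""Independent oracles used to freeze expected values in tests.

Each oracle is deliberately naive (enumeration, simulation, quadrature or grid
search) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, stats

from pedrisk.pedigree import PedigreeGraph


def gene_drop_kinship(
    graph: PedigreeGraph, i: int, j: int, n_drops: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo kinship: drop distinct founder alleles through the pedigree
    and estimate the probability two randomly drawn alleles are identical by
    descent."""
    rng = np.random.default_rng(seed)
    alleles: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    counter = 0
    for pid in graph.order:
        f, m = graph.parents[pid]
        pair = []
        for parent in (f, m):
            if parent is None:
                pair.append(np.full(n_drops, counter, dtype=np.int64))
                counter += 1
            else:
                pa, pb = alleles[parent]
                pick = rng.integers(0, 2, n_drops)
                pair.append(np.where(pick == 0, pa, pb))
        alleles[pid] = (pair[0], pair[1])
    ai, aj = alleles[i], alleles[j]
    total = 0.0
    for p in range(2):
        for q in range(2):
            total += np.mean(ai[p] == aj[q])
    return total / 4.0


def all_pairs_relatives(graph: PedigreeGraph, proband: int, cutoff_degree: int = 5):
    """Brute force: kinship of the proband against every other id, filtered to
    relatedness above the half-bin cutoff of ``cutoff_degree``."""
    from pedrisk.pedigree import degree_of_relatedness, kinship

    out = {}
    cutoff = 2.0 ** (-cutoff_degree) * 2 ** -0.5
    for other in graph.order:
        if other == proband:
            continue
        phi = kinship(graph, proband, other)
        r = 2 * phi
        if r >= cutoff:
            deg = degree_of_relatedness(r)
            if deg is not None and deg <= cutoff_degree:
                out[other] = (phi, deg)
    return out


def truncated_normal_tail_mean(k: float) -> float:
    """E[X | X > tau] for X ~ N(0,1), tau = Phi^-1(1-K), by quadrature."""
    tau = stats.norm.isf(k)
    num, _ = integrate.quad(lambda x: x * stats.norm.pdf(x), tau, 12.0, limit=200)
    return num / k


def tetrachoric_grid_search(table, step: float = 0.001) -> float:
    """Maximize the tetrachoric likelihood over a dense rho grid."""
    from pedrisk.tetrachoric import tetrachoric_loglik

    grid = np.arange(-0.99, 0.99 + step / 2, step)
    ll = [tetrachoric_loglik(table, float(r)) for r in grid]
    return float(grid[int(np.argmax(ll))])


def nelson_aalen_hazard(time: np.ndarray, event: np.ndarray):
    """Hand-rolled Nelson–Aalen estimator (distinct event times, H)."""
    t = np.asarray(time, float)
    d = np.asarray(event, int)
    ev = np.unique(t[d == 1])
    H = np.zeros(len(ev))
    acc = 0.0
    for idx, s in enumerate(ev):
        acc += d[t == s].sum() / np.sum(t >= s)
        H[idx] = acc
    return ev, H
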