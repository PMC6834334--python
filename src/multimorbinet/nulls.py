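"""Degree-matched seed randomization shared by the MS and PS null tests.

Permutation nulls over network gene sets must respect the hubness profile
of the real seeds: hubs reach more of the network, so resampling uniformly
would confound proximity with degree. Seeds are therefore resampled within
logarithmic (log2) degree bins; a bin with fewer candidates than needed is
widened to the whole network with a logged warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .networks import CellNetwork
from .propagation import DEFAULT_DECAY, DEFAULT_Z_CUTOFF, propagate_batch

logger = logging.getLogger(__name__)

__all__ = ["degree_matched_seed_sets", "top_set_matrix", "add_one_pvalue"]


def degree_matched_seed_sets(
    cellnet: CellNetwork,
    seeds: set[str],
    n_sets: int,
    rng: np.random.Generator,
) -> list[set[str]]:
    """Draw ``n_sets`` random gene sets matching the seeds' degree profile.

    Only seeds present in the cell network are matched (the null preserves
    the effective seed set). Each replacement set has the same size and the
    same log2-degree-bin composition as the seeds; sampling is without
    replacement within a set.
    """
    deg = cellnet.degree()
    nodes = sorted(cellnet.nodes)
    node_bins = {g: int(np.log2(max(deg[g], 1))) for g in nodes}
    by_bin: dict[int, list[str]] = {}
    for g in nodes:
        by_bin.setdefault(node_bins[g], []).append(g)
    present = sorted(g for g in seeds if g in cellnet.nodes)
    need: dict[int, int] = {}
    for g in present:
        need[node_bins[g]] = need.get(node_bins[g], 0) + 1
    widened = [b for b, c in need.items() if len(by_bin.get(b, [])) < c]
    if widened:
        logger.warning(
            "degree bin(s) %s have fewer candidates than needed; widening to all nodes",
            widened,
        )
    out: list[set[str]] = []
    for _ in range(n_sets):
        chosen: list[str] = []
        for b, c in sorted(need.items()):
            pool = by_bin.get(b, [])
            if b in widened or len(pool) < c:
                pool = nodes
            chosen.extend(rng.choice(pool, size=c, replace=False))
        out.append(set(chosen))
    return out


def top_set_matrix(
    cellnet: CellNetwork,
    seed_sets: list[set[str]],
    repetitions: int = 3,
    iterations: int = 2,
    decay: float = DEFAULT_DECAY,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> tuple[list[str], np.ndarray]:
    """Propagate many seed sets and return boolean top-set membership.

    Returns ``(nodes, member)`` with ``member[i, j]`` True iff ``nodes[j]``
    is in the top-scoring set for ``seed_sets[i]``. Constant score vectors
    (e.g. empty seed sets) yield empty top sets.
    """
    nodes, scores = propagate_batch(cellnet, seed_sets, repetitions, iterations, decay)
    mu = scores.mean(axis=1, keepdims=True)
    sd = scores.std(axis=1, keepdims=True)
    ok = sd > 0
    z = np.where(ok, (scores - mu) / np.where(ok, sd, 1.0), -np.inf)
    return nodes, z >= z_cutoff


def add_one_pvalue(null_stats: np.ndarray, observed: float) -> float:
    """Add-one permutation p-value (1 + #{null >= observed}) / (1 + n).

    Never returns 0; ties count toward the null (conservative).
    """
    null_stats = np.asarray(null_stats, dtype=float)
    return float((1 + np.sum(null_stats >= observed)) / (1 + len(null_stats)))
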