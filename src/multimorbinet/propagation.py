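"""Guilt-by-association scoring of cell-network genes from disease seeds.

Disease-associated genes present in a cell network act as seeds with unit
influence; every other gene accumulates influence that decays geometrically
with network distance:

    score(g) = sum over seeds t of  decay ** d(g, t),   d(g, t) <= horizon

where d is the unweighted shortest-path distance within the cell network
and the horizon is ``repetitions * iterations`` steps (the number of
message-passing rounds a repeated local-update scheme would perform). Genes
further than the horizon from every seed score 0. The scorer is
deterministic, equivariant under graph automorphisms, and for a single seed
scores are non-increasing in shortest-path distance — the defining property
of proximity-based prioritization.

Scores are z-standardized within the cell network and the top-scoring set
S is the set of genes with z >= z_cutoff (default 1.0; see docs/methods.md
for the rationale). A pluggable random-walk-with-restart scorer is provided
for robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra

from .networks import CellNetwork

__all__ = [
    "GeneScoreVector",
    "TopScoringSet",
    "propagate",
    "propagate_batch",
    "rwr_scores",
    "standardize_scores",
    "select_top_scoring",
    "DEFAULT_DECAY",
    "DEFAULT_Z_CUTOFF",
]

DEFAULT_DECAY = 0.5
DEFAULT_Z_CUTOFF = 1.0


@dataclass
class GeneScoreVector:
    """Per-gene propagation scores for one (cell type, disease) pair."""

    cell_type: str
    disease: str
    scores: dict[str, float]
    z: dict[str, float] = field(default_factory=dict)
    repetitions: int = 3
    iterations: int = 2
    decay: float = DEFAULT_DECAY
    degenerate: bool = False  # all scores equal; z set to 0

    @property
    def genes(self) -> list[str]:
        return sorted(self.scores)


@dataclass
class TopScoringSet:
    """The top-scoring gene set S for a disease in a cell network."""

    cell_type: str
    disease: str
    genes: set[str]
    rule: str = "z>=cutoff"
    z_cutoff: float = DEFAULT_Z_CUTOFF

    def __len__(self) -> int:
        return len(self.genes)


def _graph_arrays(cellnet: CellNetwork) -> tuple[list[str], dict[str, int], sparse.csr_matrix]:
    nodes = sorted(cellnet.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    if cellnet.edges:
        ij = np.array([(index[u], index[v]) for u, v in sorted(cellnet.edges)])
        data = np.ones(len(ij))
        adj = sparse.coo_matrix(
            (np.r_[data, data], (np.r_[ij[:, 0], ij[:, 1]], np.r_[ij[:, 1], ij[:, 0]])),
            shape=(n, n),
        ).tocsr()
    else:
        adj = sparse.csr_matrix((n, n))
    return nodes, index, adj


def _decay_matrix(adj: sparse.csr_matrix, sources: np.ndarray,
                  decay: float, horizon: int) -> np.ndarray:
    """decay**distance for the given source rows, zero beyond the horizon."""
    if len(sources) == 0:
        return np.zeros((0, adj.shape[0]))
    dist = dijkstra(adj, unweighted=True, indices=sources)
    with np.errstate(invalid="ignore"):
        w = np.where(dist <= horizon, np.power(decay, dist), 0.0)
    return w


def propagate_batch(
    cellnet: CellNetwork,
    seed_sets: list[set[str]],
    repetitions: int = 3,
    iterations: int = 2,
    decay: float = DEFAULT_DECAY,
) -> tuple[list[str], np.ndarray]:
    """Score many seed sets on one cell network in a single pass.

    Returns ``(nodes, scores)`` where ``scores[i, j]`` is the score of
    ``nodes[j]`` under ``seed_sets[i]``. Shortest paths are computed once
    for the union of all seed genes, so permutation nulls (hundreds of
    degree-matched seed resamplings) cost little more than one run.
    """
    if repetitions < 1 or iterations < 1:
        raise ValueError("repetitions and iterations must be >= 1")
    if not (0 < decay < 1):
        raise ValueError("decay must be in (0, 1)")
    nodes, index, adj = _graph_arrays(cellnet)
    n = len(nodes)
    horizon = repetitions * iterations
    in_net = [sorted({g for g in s if g in index}) for s in seed_sets]
    all_seeds = sorted({g for s in in_net for g in s})
    src = np.array([index[g] for g in all_seeds], dtype=int)
    w = _decay_matrix(adj, src, decay, horizon)
    row_of = {g: i for i, g in enumerate(all_seeds)}
    out = np.zeros((len(seed_sets), n))
    for i, s in enumerate(in_net):
        if s:
            out[i] = w[[row_of[g] for g in s]].sum(axis=0)
    return nodes, out


def propagate(
    cellnet: CellNetwork,
    seeds: set[str],
    repetitions: int = 3,
    iterations: int = 2,
    decay: float = DEFAULT_DECAY,
    disease: str = "",
) -> GeneScoreVector:
    """Score all genes of a cell network by proximity to the seed genes.

    Seeds absent from the network are ignored (their absence is visible by
    comparing ``seeds`` with the network nodes); with no seed in the
    network, every score is 0.
    """
    nodes, scores = propagate_batch(cellnet, [set(seeds)], repetitions, iterations, decay)
    return GeneScoreVector(
        cell_type=cellnet.cell_type,
        disease=disease,
        scores=dict(zip(nodes, scores[0])),
        repetitions=repetitions,
        iterations=iterations,
        decay=decay,
    )


def rwr_scores(
    cellnet: CellNetwork,
    seeds: set[str],
    restart: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 1000,
    disease: str = "",
) -> GeneScoreVector:
    """Random-walk-with-restart scorer (substitute for robustness checks).

    Solves s = restart * e + (1 - restart) * P^T s by power iteration, with
    e the uniform distribution over the seeds present in the network and P
    the row-normalized adjacency matrix.
    """
    if not (0 < restart < 1):
        raise ValueError("restart must be in (0, 1)")
    nodes, index, adj = _graph_arrays(cellnet)
    n = len(nodes)
    present = sorted({g for g in seeds if g in index})
    if not present or n == 0:
        return GeneScoreVector(cellnet.cell_type, disease, {g: 0.0 for g in nodes})
    e = np.zeros(n)
    e[[index[g] for g in present]] = 1.0 / len(present)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    pt = adj.multiply(inv[:, None]).T.tocsr()  # column-stochastic transition
    s = e.copy()
    for _ in range(max_iter):
        s_new = restart * e + (1 - restart) * (pt @ s)
        if np.abs(s_new - s).max() < tol:
            s = s_new
            break
        s = s_new
    return GeneScoreVector(cellnet.cell_type, disease, dict(zip(nodes, s)))


def standardize_scores(gsv: GeneScoreVector) -> GeneScoreVector:
    """Fill z-scores: z_g = (score_g - mean) / sd over the network's genes.

    The population standard deviation (ddof=0) is used. If the scores are
    constant, all z are set to 0 and the vector is flagged degenerate.
    """
    genes = gsv.genes
    if len(genes) < 2:
        raise ValueError("need >= 2 network genes to standardize")
    vals = np.array([gsv.scores[g] for g in genes])
    sd = vals.std()
    if sd == 0:
        gsv.z = {g: 0.0 for g in genes}
        gsv.degenerate = True
    else:
        z = (vals - vals.mean()) / sd
        gsv.z = dict(zip(genes, z))
        gsv.degenerate = False
    return gsv


def select_top_scoring(gsv: GeneScoreVector, z_cutoff: float = DEFAULT_Z_CUTOFF) -> TopScoringSet:
    """Select S = { g : z_g >= z_cutoff }."""
    if not gsv.z:
        raise ValueError("z-scores not filled; call standardize_scores first")
    return TopScoringSet(
        cell_type=gsv.cell_type,
        disease=gsv.disease,
        genes={g for g, z in gsv.z.items() if z >= z_cutoff},
        z_cutoff=z_cutoff,
    )
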