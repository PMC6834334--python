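"""The Multimorbidity Score and its degree-matched permutation test.

The Multimorbidity Score MS of two diseases in a cell type is the
Sorensen-Dice overlap of their top-scoring gene sets:

    MS = 2 |S1 ∩ S2| / (|S1| + |S2|)

MS = 0 means detached molecular mechanisms, MS = 1 identical ones. For
three diseases the generalized form 3 |S1 ∩ S2 ∩ S3| / (|S1|+|S2|+|S3|) is
used by default; the mean of the three pairwise scores is available as a
variant.

Significance is assessed by re-running propagation and top-set selection
from degree-matched random seed sets of the same sizes, recomputing MS for
each permutation, and applying the add-one estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import CellNetwork
from .nulls import add_one_pvalue, degree_matched_seed_sets, top_set_matrix
from .propagation import DEFAULT_DECAY, DEFAULT_Z_CUTOFF, TopScoringSet

__all__ = ["multimorbidity_score", "MsTestResult", "ms_permutation_test"]


def multimorbidity_score(
    sets: list[TopScoringSet | set],
    variant: str = "generalized",
) -> float:
    """Sorensen-Dice overlap of 2 or 3 top-scoring gene sets.

    ``variant="generalized"`` uses k|∩S_i| / Σ|S_i| for k sets;
    ``variant="mean-pairwise"`` averages the three pairwise scores (only
    meaningful, and only different, for 3 sets). An empty input set makes
    the score 0 (degenerate overlap).
    """
    if len(sets) not in (2, 3):
        raise ValueError("MS is defined for 2 or 3 disease sets")
    if variant not in ("generalized", "mean-pairwise"):
        raise ValueError(f"unknown MS variant {variant!r}")
    genes = [s.genes if isinstance(s, TopScoringSet) else set(s) for s in sets]
    if any(len(g) == 0 for g in genes):
        return 0.0
    if variant == "mean-pairwise" and len(genes) == 3:
        pairs = [(0, 1), (0, 2), (1, 2)]
        return float(np.mean([
            2 * len(genes[i] & genes[j]) / (len(genes[i]) + len(genes[j]))
            for i, j in pairs
        ]))
    inter = set.intersection(*genes)
    return len(genes) * len(inter) / sum(len(g) for g in genes)


@dataclass
class MsTestResult:
    observed: float
    p_value: float
    n_perm: int
    null_scores: np.ndarray


def ms_permutation_test(
    cellnet: CellNetwork,
    seeds_by_disease: dict[str, set[str]],
    observed_ms: float,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    repetitions: int = 3,
    iterations: int = 2,
    decay: float = DEFAULT_DECAY,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    variant: str = "generalized",
) -> MsTestResult:
    """Degree-matched permutation test for an observed MS.

    For each permutation every disease's seeds are replaced by a random
    degree-matched gene set of equal size, propagation and top-set selection
    are re-run, and MS is recomputed. The p-value is the add-one estimator
    (1 + #{MS_perm >= MS_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    diseases = sorted(seeds_by_disease)
    members = {}
    for d in diseases:
        perm_seeds = degree_matched_seed_sets(cellnet, seeds_by_disease[d], n_perm, rng)
        _, members[d] = top_set_matrix(
            cellnet, perm_seeds, repetitions, iterations, decay, z_cutoff
        )
    k = len(diseases)
    sizes = sum(members[d].sum(axis=1) for d in diseases)
    if variant == "mean-pairwise" and k == 3:
        pairs = [(0, 1), (0, 2), (1, 2)]
        null = np.zeros(n_perm)
        for i, j in pairs:
            a, b = members[diseases[i]], members[diseases[j]]
            tot = a.sum(axis=1) + b.sum(axis=1)
            null += np.where(tot > 0, 2 * (a & b).sum(axis=1) / np.maximum(tot, 1), 0.0)
        null /= len(pairs)
    else:
        inter = members[diseases[0]]
        for d in diseases[1:]:
            inter = inter & members[d]
        null = np.where(sizes > 0, k * inter.sum(axis=1) / np.maximum(sizes, 1), 0.0)
    return MsTestResult(
        observed=observed_ms,
        p_value=add_one_pvalue(null, observed_ms),
        n_perm=n_perm,
        null_scores=null,
    )
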