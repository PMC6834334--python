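"""Pathway Perturbation Scores, their randomization null, and mechanism calls.

The Perturbation Score PS measures how strongly a pathway is implicated by
a disease's top-scoring gene set S within a cell network of N genes. Two
variants ship because two readings coexist:

* ``printed`` — PS = (n_p^net / n_p^total) / (|S| / N): the fraction of the
  pathway's annotated genes present in the cell network, relative to the
  fraction of the network occupied by S. This matches the worked arithmetic
  (9/20) / (13/225) = 7.79 and is the default, but note it does not depend
  on which genes are in S, only on |S|.
* ``overlap`` — PS = (|pathway ∩ S| / |S|) / (n_p^net / N): the fraction of
  top-scoring genes that are pathway genes, relative to the pathway's share
  of the network. This is the enrichment reading ("the fraction of pathway
  genes within the top-scoring gene sets") and is the variant that carries
  pathway-specific signal; it is the one to use for mechanism discovery.

Significance comes from re-running propagation + top-set selection from
degree-matched random seed sets and recomputing PS. A pathway significantly
perturbed (p < alpha) by two or more diseases in the same cell type is
called a candidate multimorbidity mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .networks import CellNetwork
from .nulls import add_one_pvalue, degree_matched_seed_sets, top_set_matrix
from .propagation import DEFAULT_DECAY, DEFAULT_Z_CUTOFF, TopScoringSet

__all__ = ["perturbation_score", "PsTestResult", "ps_null_test", "ps_null_tests_table", "call_mechanisms"]

PS_VARIANTS = ("printed", "overlap")


def perturbation_score(
    n_pathway_total: int,
    n_pathway_net: int,
    top: TopScoringSet | int,
    network_size: int,
    variant: str = "printed",
    pathway_genes_net: set[str] | None = None,
) -> float:
    """Compute PS for one (pathway, disease, cell network) triple.

    Parameters
    ----------
    n_pathway_total:
        Number of genes annotated to the pathway (in the analysis universe).
    n_pathway_net:
        Number of those genes present in the cell network.
    top:
        The top-scoring set S (or its size for the printed variant).
    network_size:
        Number of genes N in the cell network.
    pathway_genes_net:
        The pathway's in-network genes; required for the overlap variant.
    """
    if variant not in PS_VARIANTS:
        raise ValueError(f"unknown PS variant {variant!r}")
    s_size = len(top) if isinstance(top, TopScoringSet) else int(top)
    if n_pathway_total < n_pathway_net or n_pathway_net < 0:
        raise ValueError("need n_pathway_total >= n_pathway_net >= 0")
    if n_pathway_total == 0 or s_size == 0:
        raise ValueError("PS undefined for empty pathway or empty top-scoring set")
    if network_size < s_size:
        raise ValueError("top-scoring set cannot exceed the network")
    if variant == "printed":
        return (n_pathway_net / n_pathway_total) / (s_size / network_size)
    if not isinstance(top, TopScoringSet):
        raise ValueError("overlap variant needs the TopScoringSet itself")
    if pathway_genes_net is None:
        raise ValueError("overlap variant needs pathway_genes_net")
    if n_pathway_net == 0:
        raise ValueError("PS (overlap) undefined when no pathway gene is in the network")
    n_in_s = len(set(pathway_genes_net) & top.genes)
    return (n_in_s / s_size) / (n_pathway_net / network_size)


@dataclass
class PsTestResult:
    observed: float
    p_value: float
    n_perm: int
    variant: str
    null_scores: np.ndarray


def ps_null_test(
    cellnet: CellNetwork,
    pathway_genes: set[str],
    seeds: set[str],
    n_pathway_total: int | None = None,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    variant: str = "printed",
    repetitions: int = 3,
    iterations: int = 2,
    decay: float = DEFAULT_DECAY,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> PsTestResult:
    """Randomization test for one pathway's PS under one disease.

    The null rebuilds the top-scoring set from degree-matched random seed
    sets (same effective size as the disease's seeds) and recomputes PS each
    time; the p-value is the add-one upper-tail estimator.
    """
    if variant not in PS_VARIANTS:
        raise ValueError(f"unknown PS variant {variant!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    pw_net = set(pathway_genes) & cellnet.nodes
    n_total = len(pathway_genes) if n_pathway_total is None else int(n_pathway_total)
    n_net = len(pw_net)
    N = cellnet.n_nodes
    if n_net == 0 or n_total == 0:
        raise ValueError("pathway has no gene in the cell network; PS undefined")

    obs_sets = top_set_matrix(cellnet, [set(seeds)], repetitions, iterations, decay, z_cutoff)
    nodes, obs_member = obs_sets
    obs_size = int(obs_member[0].sum())
    if obs_size == 0:
        raise ValueError("observed top-scoring set is empty; PS undefined")
    pw_idx = np.array([i for i, g in enumerate(nodes) if g in pw_net], dtype=int)

    perm_seeds = degree_matched_seed_sets(cellnet, seeds, n_perm, rng)
    _, member = top_set_matrix(cellnet, perm_seeds, repetitions, iterations, decay, z_cutoff)
    sizes = member.sum(axis=1).astype(float)

    def ps_from(member_row_size: float, n_in_s: float) -> float:
        if variant == "printed":
            return (n_net / n_total) / (member_row_size / N)
        return (n_in_s / member_row_size) / (n_net / N)

    obs_in_s = float(obs_member[0][pw_idx].sum())
    observed = ps_from(obs_size, obs_in_s)

    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "printed":
            null = np.where(sizes > 0, (n_net / n_total) / (sizes / N), -np.inf)
        else:
            inter = member[:, pw_idx].sum(axis=1)
            null = np.where(sizes > 0, (inter / np.maximum(sizes, 1)) / (n_net / N), -np.inf)

    return PsTestResult(
        observed=float(observed),
        p_value=add_one_pvalue(null, observed),
        n_perm=n_perm,
        variant=variant,
        null_scores=null,
    )


def ps_null_tests_table(
    cellnet: CellNetwork,
    pathway_genes_by_id: dict[str, set[str]],
    seeds_by_disease: dict[str, set[str]],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    variant: str = "printed",
    repetitions: int = 3,
    iterations: int = 2,
    decay: float = DEFAULT_DECAY,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> pd.DataFrame:
    """PS and null p-values for every (pathway, disease) pair in one cell.

    The degree-matched null top-set matrix is computed once per disease and
    shared across pathways, so testing a whole catalog costs little more
    than testing one pathway. Pathways with no gene in the network are
    emitted flagged, without a p-value.
    """
    if variant not in PS_VARIANTS:
        raise ValueError(f"unknown PS variant {variant!r}")
    rng = np.random.default_rng(rng)
    N = cellnet.n_nodes
    rows = []
    for disease in sorted(seeds_by_disease):
        seeds = seeds_by_disease[disease]
        nodes, obs_member = top_set_matrix(
            cellnet, [set(seeds)], repetitions, iterations, decay, z_cutoff
        )
        obs_size = int(obs_member[0].sum())
        perm_seeds = degree_matched_seed_sets(cellnet, seeds, n_perm, rng)
        _, member = top_set_matrix(cellnet, perm_seeds, repetitions, iterations, decay, z_cutoff)
        sizes = member.sum(axis=1).astype(float)
        node_index = {g: i for i, g in enumerate(nodes)}
        for pid in sorted(pathway_genes_by_id):
            pw = set(pathway_genes_by_id[pid])
            pw_idx = np.array([node_index[g] for g in pw if g in node_index], dtype=int)
            n_net = len(pw_idx)
            row = {
                "cell_type": cellnet.cell_type,
                "pathway": pid,
                "disease": disease,
                "n_pathway_total": len(pw),
                "n_pathway_net": n_net,
                "s_size": obs_size,
                "network_size": N,
                "variant": variant,
                "ps": float("nan"),
                "p_value": float("nan"),
                "flag": "",
            }
            if n_net == 0 or obs_size == 0 or len(pw) == 0:
                row["flag"] = "undefined"
                rows.append(row)
                continue
            n_in_s = int(obs_member[0][pw_idx].sum())
            row["n_overlap"] = n_in_s
            if variant == "printed":
                observed = (n_net / len(pw)) / (obs_size / N)
                null = np.where(sizes > 0, (n_net / len(pw)) / (np.maximum(sizes, 1) / N), -np.inf)
            else:
                observed = (n_in_s / obs_size) / (n_net / N)
                inter = member[:, pw_idx].sum(axis=1)
                null = np.where(sizes > 0, (inter / np.maximum(sizes, 1)) / (n_net / N), -np.inf)
            row["ps"] = float(observed)
            row["p_value"] = add_one_pvalue(null, observed)
            rows.append(row)
    return pd.DataFrame(rows)


def call_mechanisms(perturbation: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Call candidate multimorbidity mechanisms from a PS result table.

    ``perturbation`` needs columns cell_type, pathway, disease, p_value.
    For each (cell type, pathway), the diseases with p < alpha are
    collected; a row is emitted for the *maximal* combination of >= 2
    significant diseases (e.g. diseases A, D, R all significant collapse to
    the single combination "A+D+R").
    """
    required = {"cell_type", "pathway", "disease", "p_value"}
    if not required.issubset(perturbation.columns):
        raise ValueError(f"missing columns {sorted(required - set(perturbation.columns))}")
    rows = []
    for (cell, pw), grp in perturbation.groupby(["cell_type", "pathway"], sort=True):
        sig = sorted(grp.loc[grp["p_value"] < alpha, "disease"].unique())
        if len(sig) >= 2:
            rows.append({
                "cell_type": cell,
                "pathway": pw,
                "diseases": "+".join(sig),
                "n_diseases": len(sig),
            })
    return pd.DataFrame(rows, columns=["cell_type", "pathway", "diseases", "n_diseases"])
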