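"""Cell-type-specific subnetworks and disease-gene enrichment.

A cell-type-specific network is the subgraph of the interactome induced by
the *edges* connecting two cell-type-specific genes; a specific gene with no
specific interaction partner is not part of the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DiseaseGeneSets, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["CellNetwork", "induce_cell_network", "enrichment_pvalue", "disease_gene_enrichment"]


@dataclass
class CellNetwork:
    """Induced subnetwork of a cell type's specific genes.

    Every node has degree >= 1 within the cell network by construction.
    """

    cell_type: str
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    tissue: str | None = None
    parent_n_nodes: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {n: 0 for n in self.nodes}
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def induce_cell_network(
    net: InteractionNetwork, specific: set[str], cell_label: str
) -> CellNetwork:
    """Select all interactome edges connecting two genes in ``specific``.

    Nodes are the endpoints of the selected edges, so isolated specific
    genes are dropped. An empty result is returned (with a warning) when no
    pair of specific genes interacts.
    """
    edges = {e for e in net.edges if e[0] in specific and e[1] in specific}
    nodes = {g for e in edges for g in e}
    if not edges:
        logger.warning("cell network %r is empty", cell_label)
    tissue = cell_label.split("|", 1)[0] if "|" in cell_label else None
    return CellNetwork(
        cell_type=cell_label,
        nodes=nodes,
        edges=edges,
        tissue=tissue,
        parent_n_nodes=net.n_nodes,
    )


def enrichment_pvalue(overlap, set_size: int, draw_size: int, universe: int):
    """One-sided (greater) Fisher exact p-value for a 2x2 overlap table.

    Equals the hypergeometric upper tail P(X >= overlap) for a draw of
    ``draw_size`` from a universe containing ``set_size`` marked genes.
    ``overlap`` may be an array (p-values for many overlap counts of the
    same table margins at once).
    """
    overlap_arr = np.asarray(overlap)
    if (np.any(overlap_arr < 0) or np.any(overlap_arr > min(set_size, draw_size))
            or max(set_size, draw_size) > universe):
        raise ValueError("inconsistent 2x2 table counts")
    p = stats.hypergeom.sf(overlap_arr - 1, universe, set_size, draw_size)
    return float(p) if np.isscalar(overlap) else p


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio with Haldane-Anscombe 0.5 correction on zero cells."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def disease_gene_enrichment(
    cellnets: list[CellNetwork],
    diseases: DiseaseGeneSets,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test whether each cell network contains more disease genes than
    expected by chance.

    One-sided Fisher exact test per (cell type, disease) on the 2x2 table
    (in network vs not) x (disease-associated vs not) over the restricted
    gene universe, with Benjamini-Hochberg adjustment across all pairs
    jointly.
    """
    rows = []
    N = len(universe)
    for cn in cellnets:
        net_genes = cn.nodes & universe
        for disease in diseases.diseases:
            dis = diseases.genes_by_disease[disease] & universe
            k = len(net_genes & dis)
            flag = ""
            if not dis:
                p = 1.0
                odds = float("nan")
                flag = "empty_disease_set"
            else:
                p = enrichment_pvalue(k, len(dis), len(net_genes), N)
                odds = _sample_odds_ratio(
                    k, len(dis) - k, len(net_genes) - k,
                    N - len(dis) - len(net_genes) + k,
                )
            rows.append({
                "cell_type": cn.cell_type,
                "disease": disease,
                "n_network_genes": len(net_genes),
                "n_disease_in_network": k,
                "odds_ratio": odds,
                "p_value": p,
                "flag": flag,
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < alpha
    return df
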