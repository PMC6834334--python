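"""Pathway catalog filtering and catalog-level association.

Hierarchical pathway catalogs trade specificity against pathway size;
working at one depth and removing near-duplicate gene sets keeps downstream
enrichment statistics honest. Redundancy is measured with the Sorensen-Dice
overlap 2|A∩B| / (|A|+|B|); pairs above the threshold lose their smaller
member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import Pathway, PathwayCatalog
from .networks import CellNetwork, enrichment_pvalue, _sample_odds_ratio

__all__ = [
    "sorensen_dice",
    "select_depth",
    "FilteredCatalog",
    "filter_redundant_pathways",
    "map_pathway_to_network",
    "pathway_connectivity",
    "catalog_association",
]


def sorensen_dice(a: set, b: set) -> float:
    """Sorensen-Dice overlap 2|A∩B| / (|A|+|B|), in [0, 1]."""
    if not a and not b:
        raise ValueError("Sorensen-Dice undefined for two empty sets")
    return 2.0 * len(a & b) / (len(a) + len(b))


def select_depth(catalog: PathwayCatalog, depth: int = 3) -> PathwayCatalog:
    """Keep only pathways at the given hierarchy depth."""
    if not catalog.has_depths():
        raise ValueError("catalog has no hierarchy depths; cannot select by depth")
    kept = {pid: p for pid, p in catalog.pathways.items() if p.depth == depth}
    if not kept:
        raise ValueError(f"no pathway at depth {depth}")
    return PathwayCatalog(pathways=kept)


@dataclass
class FilteredCatalog:
    """Result of redundancy filtering."""

    catalog: PathwayCatalog
    removal_log: list[tuple[str, str, float]] = field(default_factory=list)  # (removed, kept, overlap)
    threshold: float = 0.5
    mean_residual_overlap: float = 0.0


def filter_redundant_pathways(
    catalog: PathwayCatalog, threshold: float = 0.5
) -> FilteredCatalog:
    """Iteratively remove the smaller pathway of the worst-overlapping pair.

    All pairwise Sorensen-Dice overlaps are computed; while any pair exceeds
    the threshold (strict inequality), the currently worst pair is resolved
    by removing its smaller member (ties on size: remove the
    lexicographically later id, so the procedure is deterministic and
    order-independent). Overlaps are recomputed implicitly since removal
    only deletes rows/columns.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    ids = sorted(catalog.pathways)
    alive = set(ids)
    overlaps = {
        (a, b): sorensen_dice(catalog[a].genes, catalog[b].genes)
        for i, a in enumerate(ids)
        for b in ids[i + 1:]
    }
    log: list[tuple[str, str, float]] = []
    while True:
        worst = None
        worst_val = threshold
        for (a, b), v in overlaps.items():
            if a in alive and b in alive and v > worst_val:
                worst, worst_val = (a, b), v
            elif a in alive and b in alive and v == worst_val and worst is not None and v > threshold:
                # deterministic tie-break on the pair itself
                if (a, b) < worst:
                    worst = (a, b)
        if worst is None:
            break
        a, b = worst
        na, nb = len(catalog[a].genes), len(catalog[b].genes)
        if na < nb:
            removed, kept = a, b
        elif nb < na:
            removed, kept = b, a
        else:
            removed, kept = max(a, b), min(a, b)
        alive.discard(removed)
        log.append((removed, kept, worst_val))
    surv = sorted(alive)
    residual = [overlaps[(a, b)] for i, a in enumerate(surv) for b in surv[i + 1:]]
    return FilteredCatalog(
        catalog=PathwayCatalog(pathways={pid: catalog[pid] for pid in surv}),
        removal_log=log,
        threshold=threshold,
        mean_residual_overlap=float(np.mean(residual)) if residual else 0.0,
    )


def map_pathway_to_network(pathway_genes: set[str], cellnet: CellNetwork) -> set[str]:
    """Pathway genes present in the cell network."""
    return set(pathway_genes) & cellnet.nodes


def pathway_connectivity(
    pathway_genes: set[str], cellnet: CellNetwork
) -> tuple[int, float]:
    """Internal connectivity of a pathway within a cell network.

    Returns ``(n_edges_within, fraction_connected)``: the number of cell-
    network edges with both endpoints in the pathway, and the share of
    in-network pathway genes with at least one such internal edge. Both are
    reported side by side because no single canonical definition exists.
    """
    in_net = map_pathway_to_network(pathway_genes, cellnet)
    internal = [e for e in cellnet.edges if e[0] in in_net and e[1] in in_net]
    touched = {g for e in internal for g in e}
    frac = len(touched) / len(in_net) if in_net else 0.0
    return len(internal), frac


def catalog_association(
    cat_a: PathwayCatalog,
    cat_b: PathwayCatalog,
    universe: set[str],
) -> pd.DataFrame:
    """Which pathways of one catalog significantly overlap pathways of another.

    One-sided Fisher exact test per (A, B) pair over the shared gene
    universe, BH-adjusted across all pairs; the log odds ratio uses a
    Haldane-Anscombe 0.5 correction when any table cell is zero.
    """
    N = len(universe)
    rows = []
    for pid_a in cat_a.ids:
        ga = cat_a[pid_a].genes & universe
        for pid_b in cat_b.ids:
            gb = cat_b[pid_b].genes & universe
            k = len(ga & gb)
            p = enrichment_pvalue(k, len(ga), len(gb), N) if ga and gb else 1.0
            odds = _sample_odds_ratio(k, len(ga) - k, len(gb) - k, N - len(ga) - len(gb) + k)
            rows.append({
                "pathway_a": pid_a,
                "pathway_b": pid_b,
                "n_overlap": k,
                "odds_ratio": odds,
                "log_odds_ratio": float(np.log(odds)),
                "p_value": p,
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df
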