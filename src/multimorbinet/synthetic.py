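"""Synthetic benchmark generator with known ground truth.

Emulates, at desk scale, the inputs of a cell-type-resolved multimorbidity
analysis: a scale-free-ish interactome, a gene x cell-type expression
matrix with planted cell-type-specific genes, disease gene sets planted as
connected network neighborhoods with controllable pairwise overlap, and a
pathway catalog with hierarchy depths, redundant pairs, and pathways
planted inside the disease neighborhoods.

Design highlights (see docs/methods.md for full rationale):

* Technical noise is uniform (bounded), variance-matched to a normal with
  the same ``noise_sd``. Heavier-tailed noise pushes the 1.5 x IQR
  specificity rule's false-positive rate above its intended level at small
  cell-type counts.
* Each gene is specific in ``round(frac_specific * n_cell_types)`` cell
  types (default 2 of 8). Under the IQR rule a gene elevated in three or
  more of eight columns can never be called (the upper quartile absorbs the
  shift), so membership is capped by design.
* Disease modules grow by degree-penalized frontier sampling from a
  low-degree anchor: uniform frontier growth drifts into hubs, which the
  degree-matched null then overlaps, blurring planted signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import (
    DiseaseGeneSets,
    ExpressionMatrix,
    InteractionNetwork,
    Pathway,
    PathwayCatalog,
    write_edge_list,
)

__all__ = [
    "generate_interactome",
    "generate_expression",
    "generate_disease_modules",
    "generate_pathways",
    "ScenarioConfig",
    "SyntheticScenario",
    "generate_scenario",
    "write_scenario",
]

_GENE_FMT = "G{:04d}"


def _gene_names(n: int) -> list[str]:
    return [_GENE_FMT.format(i) for i in range(n)]


def generate_interactome(
    n_genes: int = 500,
    mean_degree: float = 6.0,
    model: str = "preferential-attachment",
    seed: int | np.random.Generator | None = None,
) -> InteractionNetwork:
    """Generate a connected simple interaction graph.

    ``preferential-attachment`` gives a heavy-tailed (scale-free-ish)
    degree distribution; ``configuration`` draws a truncated power-law
    degree sequence and rewires it into a simple connected graph.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)
    names = _gene_names(n_genes)
    if model == "preferential-attachment":
        m = max(1, round(mean_degree / 2))
        if m >= n_genes:
            raise ValueError("mean_degree too large for n_genes")
        g = nx.barabasi_albert_graph(n_genes, m, seed=int(rng.integers(2**31)))
    elif model == "configuration":
        # truncated power-law degrees, floor 1, cap n-1
        raw = rng.pareto(2.0, n_genes) + 1.0
        deg = np.minimum(np.maximum(np.round(raw * mean_degree / raw.mean()), 1), n_genes - 1).astype(int)
        if deg.sum() % 2:
            deg[int(np.argmin(deg))] += 1
        g = nx.configuration_model(deg, seed=int(rng.integers(2**31)))
        g = nx.Graph(g)
        g.remove_edges_from(nx.selfloop_edges(g))
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        giant = comps[0]
        for comp in comps[1:]:
            u = sorted(comp)[0]
            v = sorted(giant)[int(rng.integers(len(giant)))]
            g.add_edge(u, v)
            giant |= comp
    else:
        raise ValueError(f"unknown interactome model {model!r}")
    pairs = [(names[u], names[v]) for u, v in g.edges()]
    return InteractionNetwork.from_edges(pairs, source=f"synthetic:{model}")


def _grow_connected(
    g: nx.Graph,
    anchor: str,
    size: int,
    rng: np.random.Generator,
    core: set[str] | None = None,
    forbidden: set[str] | None = None,
) -> set[str]:
    """Grow a connected gene set by degree-penalized frontier sampling."""
    forbidden = forbidden or set()
    members = sorted(core) if core else [anchor]
    frontier: set[str] = set()
    for m in members:
        frontier |= set(g[m])
    frontier -= set(members) | forbidden
    while len(members) < size and frontier:
        cand = sorted(frontier)
        w = np.array([1.0 / g.degree(x) for x in cand])
        x = cand[int(rng.choice(len(cand), p=w / w.sum()))]
        members.append(x)
        frontier |= set(g[x])
        frontier -= set(members) | forbidden
    return set(members)


def _low_degree_anchor(g: nx.Graph, rng: np.random.Generator,
                       forbidden: set[str] | None = None) -> str:
    nodes = sorted(set(g.nodes) - (forbidden or set()))
    degs = np.array([g.degree(x) for x in nodes])
    lows = [n for n, d in zip(nodes, degs) if d <= np.median(degs)]
    return lows[int(rng.integers(len(lows)))]


def generate_disease_modules(
    net: InteractionNetwork,
    n_diseases: int = 3,
    module_size: int = 25,
    pairwise_overlap: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> tuple[DiseaseGeneSets, dict]:
    """Plant disease gene sets as connected network neighborhoods.

    All modules share a connected core of ``round(overlap * size)`` genes
    grown from a common low-degree anchor; each module then grows
    independently to its full size, so realized pairwise overlaps are at
    least the core (they may exceed it where growth collides).
    ``pairwise_overlap=0`` grows mutually disjoint modules from separate
    anchors; ``pairwise_overlap=1`` returns identical modules.
    """
    if module_size < 3:
        raise ValueError("module_size must be >= 3")
    if not (0 <= pairwise_overlap <= 1):
        raise ValueError("pairwise_overlap must be in [0, 1]")
    g = net.to_networkx()
    if module_size > g.number_of_nodes():
        raise ValueError("module_size exceeds network size")
    rng = np.random.default_rng(seed)
    core_size = round(pairwise_overlap * module_size)
    names = [f"disease_{chr(ord('A') + i)}" for i in range(n_diseases)]
    modules: dict[str, set[str]] = {}
    core: set[str] = set()
    if core_size > 0:
        anchor = _low_degree_anchor(g, rng)
        core = _grow_connected(g, anchor, core_size, rng)
        for name in names:
            if core_size >= module_size:
                modules[name] = set(core)
            else:
                modules[name] = _grow_connected(g, anchor, module_size, rng, core=core)
    else:
        used: set[str] = set()
        for name in names:
            anchor = _low_degree_anchor(g, rng, forbidden=used)
            mod = _grow_connected(g, anchor, module_size, rng, forbidden=used)
            modules[name] = mod
            used |= mod
    out = DiseaseGeneSets()
    for name, genes in modules.items():
        out.genes_by_disease[name] = set(genes)
        for gene in genes:
            out.evidence[(gene, name)] = {"curated"}
    truth = {
        "modules": {k: sorted(v) for k, v in modules.items()},
        "core": sorted(core),
        "pairwise_overlap": pairwise_overlap,
        "module_size": module_size,
    }
    return out, truth


def generate_expression(
    net: InteractionNetwork,
    cell_types: list[str],
    frac_specific: float = 0.25,
    specificity_effect: float = 8.0,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator | None = None,
    membership: dict[str, set[str]] | None = None,
) -> tuple[ExpressionMatrix, dict[str, set[str]]]:
    """Generate an expression matrix with planted cell-type-specific genes.

    Baseline levels are log-normal; technical noise is uniform with
    standard deviation ``noise_sd * baseline``; planted (gene, cell) pairs
    are shifted up by ``specificity_effect`` multiples of that per-gene
    noise scale. If ``membership`` (cell type -> genes) is not given, each
    gene is planted in ``round(frac_specific * n_cells)`` (at least 1)
    distinct random cell types.

    Returns the matrix and the planted membership as ground truth.
    """
    if not (0 < frac_specific < 1):
        raise ValueError("frac_specific must be in (0, 1)")
    if noise_sd <= 0:
        raise ValueError(
            "noise_sd must be positive: with zero technical noise the per-gene "
            "MAD is 0 and normalization excludes every gene"
        )
    if specificity_effect < 0:
        raise ValueError("specificity_effect must be >= 0")
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    n, c = len(genes), len(cell_types)
    if c < 2:
        raise ValueError("need >= 2 cell types")
    gi = {g: i for i, g in enumerate(genes)}
    if membership is None:
        per_gene = max(1, round(frac_specific * c))
        membership = {ct: set() for ct in cell_types}
        for g in genes:
            for j in rng.choice(c, size=per_gene, replace=False):
                membership[cell_types[j]].add(g)
    planted = np.zeros((n, c), dtype=bool)
    for j, ct in enumerate(cell_types):
        for g in membership.get(ct, set()):
            if g in gi:
                planted[gi[g], j] = True

    base = rng.lognormal(mean=6.0, sigma=1.0, size=n)
    scale = noise_sd * base
    half_width = np.sqrt(3.0)  # uniform(-w, w) has sd w/sqrt(3)
    noise = rng.uniform(-half_width, half_width, size=(n, c)) * scale[:, None]
    values = base[:, None] + noise + planted * (specificity_effect * scale[:, None])
    expr = ExpressionMatrix(data=pd.DataFrame(values, index=genes, columns=list(cell_types)))
    truth = {ct: set(gs) for ct, gs in membership.items()}
    return expr, truth


def generate_pathways(
    net: InteractionNetwork,
    n_pathways: int = 30,
    size_range: tuple[int, int] = (8, 25),
    planted_in_modules: list[tuple[set[str], set[str]]] | None = None,
    planted_size: int = 25,
    redundancy_pairs: int = 2,
    seed: int | np.random.Generator | None = None,
) -> tuple[PathwayCatalog, dict]:
    """Generate a pathway catalog with hierarchy depths and planted structure.

    Background pathways are random gene sets with depth labels cycling over
    {1, 2, 3}. Each entry of ``planted_in_modules`` is a ``(core, pool)``
    pair: the planted pathway contains the core plus a random sample of the
    pool, is placed at depth 3, and is recorded in the ground truth. For
    each redundancy pair a depth-3 background pathway gets a smaller
    companion with Sorensen-Dice overlap > 0.5, to exercise the redundancy
    filter.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(net.nodes)
    lo, hi = size_range
    if not (3 <= lo <= hi <= len(genes)):
        raise ValueError("invalid size_range")
    catalog = PathwayCatalog()
    depth3_ids: list[str] = []
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        pid = f"PW{i:03d}"
        depth = (i % 3) + 1
        members = set(rng.choice(genes, size=size, replace=False))
        catalog.pathways[pid] = Pathway(pid, f"background pathway {i}", members, depth)
        if depth == 3:
            depth3_ids.append(pid)
    planted_ids = []
    for j, (core, pool) in enumerate(planted_in_modules or []):
        pid = f"PLANTED{j:02d}"
        extra = sorted(set(pool) - set(core))
        take = min(max(planted_size - len(core), 0), len(extra))
        members = set(core) | set(rng.choice(extra, size=take, replace=False)) if take else set(core)
        catalog.pathways[pid] = Pathway(pid, f"planted pathway {j}", members, 3)
        planted_ids.append(pid)
    redundant: list[tuple[str, str]] = []
    for j in range(redundancy_pairs):
        if j >= len(depth3_ids):
            break
        src = catalog.pathways[depth3_ids[j]]
        members = sorted(src.genes)
        # companion keeps ~80% of the source genes: overlap 2k/(k+n) > 0.5
        keep = max(2, int(round(0.8 * len(members))))
        companion = set(rng.choice(members, size=keep, replace=False))
        pid = f"{src.id}_DUP"
        catalog.pathways[pid] = Pathway(pid, f"redundant copy of {src.id}", companion, 3)
        redundant.append((src.id, pid))
    truth = {
        "planted_pathways": planted_ids,
        "redundant_pairs": redundant,
        "n_background": n_pathways,
    }
    return catalog, truth


@dataclass
class ScenarioConfig:
    """Study conditions for a full synthetic scenario."""

    n_genes: int = 500
    mean_degree: float = 6.0
    interactome_model: str = "preferential-attachment"
    n_cell_types: int = 8
    frac_specific: float = 0.25
    specificity_effect: float = 8.0
    noise_sd: float = 0.1
    n_diseases: int = 3
    module_size: int = 25
    pairwise_overlap: float = 0.3
    n_multimorbid_cells: int = 2
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (8, 25)
    planted_pathway_size: int = 25
    redundancy_pairs: int = 2

    def validate(self) -> None:
        checks = [
            ("n_genes", self.n_genes >= 10),
            ("n_cell_types", self.n_cell_types >= 2),
            ("frac_specific", 0 < self.frac_specific < 1),
            ("noise_sd", self.noise_sd > 0),
            ("specificity_effect", self.specificity_effect >= 0),
            ("n_diseases", self.n_diseases >= 0),
            ("module_size", self.n_diseases == 0 or self.module_size >= 3),
            ("pairwise_overlap", 0 <= self.pairwise_overlap <= 1),
            ("n_multimorbid_cells", 0 <= self.n_multimorbid_cells <= self.n_cell_types),
            ("n_pathways", self.n_pathways >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid scenario config field: {name}")


@dataclass
class SyntheticScenario:
    seed: int
    config: ScenarioConfig
    network: InteractionNetwork
    expression: ExpressionMatrix
    diseases: DiseaseGeneSets
    pathways: PathwayCatalog
    truth: dict = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return self.expression.cell_types


def generate_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> SyntheticScenario:
    """Compose interactome, modules, pathways and expression into a scenario.

    Disease-module and planted-pathway genes are made specific to the first
    ``n_multimorbid_cells`` cell types (the planted multimorbid cell
    types); every other gene is specific in ``round(frac_specific *
    n_cell_types)`` random cell types. With ``n_multimorbid_cells=0`` or
    ``n_diseases<2`` the ground truth records no planted multimorbidity.
    """
    config = config or ScenarioConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    net = generate_interactome(
        config.n_genes, config.mean_degree, config.interactome_model, rng
    )
    cell_types = [f"cell_{i + 1}" for i in range(config.n_cell_types)]
    truth: dict = {"seed": seed, "multimorbid_cell_types": [], "planted_pathways": []}

    diseases = DiseaseGeneSets()
    module_union: set[str] = set()
    core: set[str] = set()
    if config.n_diseases > 0:
        diseases, mod_truth = generate_disease_modules(
            net, config.n_diseases, config.module_size, config.pairwise_overlap, rng
        )
        truth.update(mod_truth)
        module_union = diseases.all_genes()
        core = set(mod_truth["core"])

    planted_specs: list[tuple[set[str], set[str]]] = []
    multimorbid = cell_types[: config.n_multimorbid_cells]
    if config.n_diseases >= 2 and multimorbid:
        planted_specs = [(core, module_union)]
    pathways, pw_truth = generate_pathways(
        net,
        config.n_pathways,
        config.pathway_size_range,
        planted_specs,
        config.planted_pathway_size,
        config.redundancy_pairs,
        rng,
    )
    truth.update(pw_truth)

    planted_genes = module_union | set().union(
        *(pathways[pid].genes for pid in pw_truth["planted_pathways"])
    ) if (module_union or pw_truth["planted_pathways"]) else set()

    membership: dict[str, set[str]] = {ct: set() for ct in cell_types}
    per_gene = max(1, round(config.frac_specific * config.n_cell_types))
    if multimorbid and planted_genes:
        for ct in multimorbid:
            membership[ct] |= planted_genes
        background = sorted(net.nodes - planted_genes)
    else:
        background = sorted(net.nodes)
    for g in background:
        for j in rng.choice(config.n_cell_types, size=per_gene, replace=False):
            membership[cell_types[j]].add(g)

    expr, spec_truth = generate_expression(
        net,
        cell_types,
        config.frac_specific,
        config.specificity_effect,
        config.noise_sd,
        rng,
        membership=membership,
    )
    truth["specific"] = {ct: sorted(gs) for ct, gs in spec_truth.items()}
    if config.n_diseases >= 2 and multimorbid:
        truth["multimorbid_cell_types"] = list(multimorbid)
    return SyntheticScenario(
        seed=seed,
        config=config,
        network=net,
        expression=expr,
        diseases=diseases,
        pathways=pathways,
        truth=truth,
    )


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, Path]:
    """Write all scenario inputs in their standard on-disk formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactome": out / "interactome.tsv",
        "expression": out / "expr.tsv",
        "diseases": out / "disease_genes.tsv",
        "pathways": out / "pathways.gmt",
        "hierarchy": out / "hierarchy.tsv",
        "truth": out / "truth.json",
    }
    write_edge_list(scenario.network, paths["interactome"], meta={"seed": str(scenario.seed)})
    scenario.expression.data.to_csv(paths["expression"], sep="\t", index_label="gene")
    rows = []
    for disease in scenario.diseases.diseases:
        for gene in sorted(scenario.diseases.genes_by_disease[disease]):
            ev = sorted(scenario.diseases.evidence[(gene, disease)])[0]
            rows.append((gene, disease, ev))
    pd.DataFrame(rows, columns=["gene", "disease", "evidence"]).to_csv(
        paths["diseases"], sep="\t", index=False
    )
    with open(paths["pathways"], "w") as fh:
        for pid in scenario.pathways.ids:
            p = scenario.pathways[pid]
            fh.write("\t".join([p.id, p.name, *sorted(p.genes)]) + "\n")
    with open(paths["hierarchy"], "w") as fh:
        fh.write("pathway\tparent\tdepth\n")
        for pid in scenario.pathways.ids:
            fh.write(f"{pid}\t-\t{scenario.pathways[pid].depth}\n")
    truth = dict(scenario.truth)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=sorted)
    return paths
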