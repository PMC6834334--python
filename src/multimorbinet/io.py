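"""Readers, writers and containers for the pipeline's standard inputs.

All gene identity is by symbol string: case-sensitive, whitespace-trimmed.
Identifier mapping (Entrez/Ensembl/UniProt) is a pre-processing concern and
deliberately out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "DiseaseGeneSets",
    "Pathway",
    "PathwayCatalog",
    "ExpressionMatrix",
    "read_edge_list",
    "merge_networks",
    "read_gmt",
    "read_hierarchy",
    "read_gene_disease_table",
    "read_expression_matrix",
    "restrict_to_common_universe",
    "write_edge_list",
    "write_table",
]

#: evidence-source vocabulary for gene-disease association tables.
#: "gwas" marks associations derived solely from genome-wide association
#: studies; everything curated/experimental/literature-derived is "curated".
EVIDENCE_TOKENS = frozenset({"gwas", "curated"})


def _edge(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered edge representation."""
    return (u, v) if u <= v else (v, u)


@dataclass
class InteractionNetwork:
    """An undirected, unweighted gene-gene interaction graph.

    The functional interactome concept: a merged graph of protein-protein,
    signalling and metabolic interactions from one or more curated sources.
    No self-loops, no duplicate edges; ``source_tags`` records which input
    resource(s) contributed each edge.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    source_tags: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if (u, v) != _edge(u, v):
                raise ValueError(f"edge {(u, v)!r} not in canonical order")
            self.nodes.add(u)
            self.nodes.add(v)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_edges(
        cls,
        pairs: Iterable[tuple[str, str]],
        source: str | None = None,
    ) -> "InteractionNetwork":
        """Build a network from raw (possibly messy) gene pairs.

        Self-loops are dropped (with a logged count) and duplicate pairs
        collapsed.
        """
        edges: set[tuple[str, str]] = set()
        nodes: set[str] = set()
        n_loops = 0
        for u, v in pairs:
            u, v = u.strip(), v.strip()
            if not u or not v:
                raise ValueError("empty gene symbol in edge")
            if u == v:
                n_loops += 1
                continue
            edges.add(_edge(u, v))
            nodes.add(u)
            nodes.add(v)
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        tags = {e: {source} for e in edges} if source is not None else {}
        return cls(nodes=nodes, edges=edges, source_tags=tags)


def read_edge_list(path: str | Path, dialect: str = "two-column-tsv") -> InteractionNetwork:
    """Read an undirected edge list.

    Parameters
    ----------
    path:
        Tab-separated file. Dialect ``two-column-tsv`` expects at least two
        columns (gene, gene; extra columns such as confidence scores are
        ignored). Dialect ``sif`` expects ``node1<TAB>relation<TAB>node2``.
    """
    path = Path(path)
    if dialect not in ("two-column-tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if not pairs and [t.strip().lower() for t in tokens[:2]] == ["gene1", "gene2"]:
                continue  # optional header row
            if dialect == "sif":
                if len(tokens) < 3:
                    raise ValueError(f"{path}:{lineno}: SIF line needs 3 fields, got {len(tokens)}")
                u, v = tokens[0], tokens[2]
            else:
                if len(tokens) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 gene columns, got {len(tokens)}")
                u, v = tokens[0], tokens[1]
            if not u.strip() or not v.strip():
                raise ValueError(f"{path}:{lineno}: empty gene symbol")
            pairs.append((u, v))
    return InteractionNetwork.from_edges(pairs, source=path.name)


def merge_networks(networks: list[InteractionNetwork]) -> InteractionNetwork:
    """Union of node and edge sets; source tags accumulate per edge."""
    if not networks:
        raise ValueError("need at least one network to merge")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    tags: dict[tuple[str, str], set[str]] = {}
    for net in networks:
        nodes |= net.nodes
        edges |= net.edges
        for e, t in net.source_tags.items():
            tags.setdefault(e, set()).update(t)
    return InteractionNetwork(nodes=nodes, edges=edges, source_tags=tags)


@dataclass
class DiseaseGeneSets:
    """Gene sets associated to diseases, with per-association evidence.

    ``evidence`` maps (gene, disease) to the set of evidence tokens seen in
    the input. An association is GWAS-only iff every contributing record was
    tagged "gwas".
    """

    genes_by_disease: dict[str, set[str]] = field(default_factory=dict)
    evidence: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.genes_by_disease)

    def genes(self, disease: str, gwas_only: bool = False) -> set[str]:
        out = self.genes_by_disease.get(disease, set())
        if not gwas_only:
            return set(out)
        return {g for g in out if self.evidence.get((g, disease)) == {"gwas"}}

    def all_genes(self) -> set[str]:
        return set().union(*self.genes_by_disease.values()) if self.genes_by_disease else set()

    def is_gwas_only(self, gene: str, disease: str) -> bool:
        return self.evidence.get((gene, disease)) == {"gwas"}


def read_gene_disease_table(path: str | Path) -> DiseaseGeneSets:
    """Read a gene-disease association table (columns gene, disease, evidence).

    Associations for the same (gene, disease) pair coming from several
    sources are collapsed to one, accumulating evidence tokens.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene", "disease", "evidence"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = DiseaseGeneSets()
    for gene, disease, ev in df[["gene", "disease", "evidence"]].itertuples(index=False):
        gene, disease, ev = str(gene).strip(), str(disease).strip(), str(ev).strip().lower()
        if ev not in EVIDENCE_TOKENS:
            raise ValueError(f"unknown evidence token {ev!r} (allowed: {sorted(EVIDENCE_TOKENS)})")
        if not gene or not disease:
            raise ValueError("empty gene or disease label")
        out.genes_by_disease.setdefault(disease, set()).add(gene)
        out.evidence.setdefault((gene, disease), set()).add(ev)
    return out


@dataclass
class Pathway:
    id: str
    name: str
    genes: set[str]
    depth: int | None = None


@dataclass
class PathwayCatalog:
    """A collection of pathway gene sets, optionally with hierarchy depths."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.pathways.values())

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pid: str) -> Pathway:
        return self.pathways[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.pathways

    @property
    def ids(self) -> list[str]:
        return sorted(self.pathways)

    def has_depths(self) -> bool:
        return all(p.depth is not None for p in self.pathways.values()) and len(self) > 0

    def all_genes(self) -> set[str]:
        return set().union(*(p.genes for p in self)) if self.pathways else set()


def read_gmt(path: str | Path, hierarchy: str | Path | None = None) -> PathwayCatalog:
    """Read pathway gene sets in GMT format (id, description, genes...).

    Duplicate genes within a set are collapsed; a duplicate pathway id is an
    error. If ``hierarchy`` is given (TSV: pathway, parent, depth) depths are
    joined on pathway id.
    """
    catalog = PathwayCatalog()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields_ = line.split("\t")
            if len(fields_) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields_)}")
            pid, name = fields_[0].strip(), fields_[1].strip()
            if pid in catalog:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            genes = {g.strip() for g in fields_[2:] if g.strip()}
            catalog.pathways[pid] = Pathway(id=pid, name=name, genes=genes)
    if hierarchy is not None:
        depths = read_hierarchy(hierarchy)
        for pid, p in catalog.pathways.items():
            if pid in depths:
                p.depth = depths[pid]
    return catalog


def read_hierarchy(path: str | Path) -> dict[str, int]:
    """Read a pathway hierarchy table (columns pathway, parent, depth)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"pathway", "depth"}.issubset(df.columns):
        raise ValueError(f"{path}: hierarchy table needs 'pathway' and 'depth' columns")
    out: dict[str, int] = {}
    for pid, depth in df[["pathway", "depth"]].itertuples(index=False):
        d = int(depth)
        if d < 0:
            raise ValueError(f"negative depth for pathway {pid!r}")
        out[str(pid).strip()] = d
    return out


@dataclass
class ExpressionMatrix:
    """A gene x cell-type table of raw expression levels E_{g,c}.

    Columns are cell-type labels; a "tissue|cell_type" label convention
    carries the tissue as metadata, plain cell-type labels are also fine.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene labels: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate cell-type labels")
        if not self.data.map(lambda x: pd.notna(x)).all().all():
            raise ValueError("expression matrix contains missing values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)

    @staticmethod
    def tissue_of(label: str) -> str | None:
        return label.split("|", 1)[0] if "|" in label else None

    @staticmethod
    def cell_of(label: str) -> str:
        return label.split("|", 1)[1] if "|" in label else label


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header row
    cell-type labels). Genes with any non-numeric value are dropped and
    reported; duplicate gene rows are an error."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene row(s): {dupes[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        logger.warning("dropping %d gene(s) with non-numeric values: %s",
                       int(bad.sum()), list(df.index[bad])[:10])
        numeric = numeric.loc[~bad]
    return ExpressionMatrix(data=numeric.astype(float))


def restrict_to_common_universe(
    net: InteractionNetwork,
    expr: ExpressionMatrix,
    diseases: DiseaseGeneSets | None = None,
    pathways: PathwayCatalog | None = None,
):
    """Restrict all inputs to the common gene universe.

    The universe is ``nodes(net) & genes(expr)``: genes absent from the
    interactome or from the expression compendium are removed everywhere.
    Disease and pathway gene sets are intersected with the universe; sets
    left empty are dropped. Returns the four restricted objects plus a
    report of removed counts.
    """
    universe = net.nodes & set(expr.genes)
    if not universe:
        raise ValueError("empty gene universe: interactome and expression matrix share no genes")

    edges = {e for e in net.edges if e[0] in universe and e[1] in universe}
    tags = {e: t for e, t in net.source_tags.items() if e in edges}
    net_r = InteractionNetwork(nodes=set(universe), edges=edges, source_tags=tags)

    expr_r = ExpressionMatrix(data=expr.data.loc[sorted(universe & set(expr.genes))])

    report = {
        "universe_size": len(universe),
        "net_nodes_removed": net.n_nodes - len(universe),
        "expr_genes_removed": len(expr.genes) - len(expr_r.genes),
        "disease_genes_removed": 0,
        "pathway_genes_removed": 0,
        "pathways_dropped": 0,
    }

    dis_r = None
    if diseases is not None:
        dis_r = DiseaseGeneSets()
        for d, genes in diseases.genes_by_disease.items():
            kept = genes & universe
            report["disease_genes_removed"] += len(genes) - len(kept)
            if kept:
                dis_r.genes_by_disease[d] = kept
        dis_r.evidence = {
            (g, d): t for (g, d), t in diseases.evidence.items()
            if g in universe and d in dis_r.genes_by_disease
        }

    path_r = None
    if pathways is not None:
        path_r = PathwayCatalog()
        for p in pathways:
            kept = p.genes & universe
            report["pathway_genes_removed"] += len(p.genes) - len(kept)
            if kept:
                path_r.pathways[p.id] = Pathway(p.id, p.name, kept, p.depth)
            else:
                report["pathways_dropped"] += 1

    return net_r, expr_r, dis_r, path_r, report


def _provenance_line(meta: Mapping[str, str] | None = None) -> str:
    from . import __version__

    parts = [f"multimorbinet {__version__}"]
    if meta:
        parts += [f"{k}={v}" for k, v in meta.items()]
    return "# " + ", ".join(parts)


def write_edge_list(net: InteractionNetwork, path: str | Path,
                    meta: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(meta) + "\n")
        fh.write("gene1\tgene2\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def write_table(df: pd.DataFrame, path: str | Path,
                meta: Mapping[str, str] | None = None, index: bool = False) -> None:
    """Write a result table as TSV with a commented provenance line."""
    with open(path, "w") as fh:
        fh.write(_provenance_line(meta) + "\n")
        df.to_csv(fh, sep="\t", index=index)
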