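"""End-to-end orchestration of the multimorbidity analysis from one config.

Stages run in a fixed order (load/restrict, normalize, specificity,
cell networks, enrichment, pathway filtering, propagation, MS, PS +
mechanisms, candidates); every output is a TSV with a provenance line, and
a manifest records per-stage inputs, output hashes and wall time. All
randomness flows from the single config seed through per-stage derived
generators, so a re-run with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .candidates import find_candidates, rank_and_flag, score_candidate
from .multimorbidity import ms_permutation_test, multimorbidity_score
from .networks import disease_gene_enrichment, induce_cell_network
from .pathways import filter_redundant_pathways, select_depth
from .perturbation import call_mechanisms, ps_null_tests_table
from .propagation import propagate, select_top_scoring, standardize_scores
from .specificity import call_specific_genes, normalize_expression

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run; the seed is mandatory."""

    interactome: list[str]
    expression: str
    disease_genes: str
    pathways: str
    out_dir: str
    seed: int
    hierarchy: str | None = None
    k: float = 1.5
    pathway_depth: int | None = 3
    overlap_threshold: float = 0.5
    repetitions: int = 3
    iterations: int = 2
    decay: float = 0.5
    z_cutoff: float = 1.0
    n_perm: int = 1000
    alpha: float = 0.05
    ps_variant: str = "overlap"
    ms_variant: str = "generalized"
    min_network_nodes: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValueError("config must be a YAML mapping")
        if "seed" not in raw:
            raise ValueError("config schema error: 'seed' is mandatory")
        if isinstance(raw.get("interactome"), str):
            raw["interactome"] = [raw["interactome"]]
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, ok in [
            ("k", self.k > 0),
            ("overlap_threshold", 0 < self.overlap_threshold <= 1),
            ("repetitions", self.repetitions >= 1),
            ("iterations", self.iterations >= 1),
            ("decay", 0 < self.decay < 1),
            ("n_perm", self.n_perm >= 1),
            ("alpha", 0 < self.alpha < 1),
            ("ps_variant", self.ps_variant in ("printed", "overlap")),
            ("ms_variant", self.ms_variant in ("generalized", "mean-pairwise")),
        ]:
            if not ok:
                raise ValueError(f"config parameter out of range: {name}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Any stage failure raises with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config": config.config_hash(), "seed": str(config.seed)}
    manifest: list[dict] = []

    def record(stage: str, t0: float, outputs: list[Path], inputs: list[str] = ()):
        manifest.append({
            "stage": stage,
            "inputs": list(inputs),
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(time.time() - t0, 3),
        })

    def run_stage(stage, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        return t0, result

    # 1. load + restrict to the common gene universe
    t0, loaded = run_stage("load_restrict", lambda: _load_inputs(config))
    net, expr, diseases, catalog, report = loaded
    restrict_path = out / "universe_report.tsv"
    mio.write_table(pd.DataFrame([report]), restrict_path, meta)
    record("load_restrict", t0, [restrict_path], config.interactome + [config.expression])

    # 2. normalize
    t0, norm = run_stage("normalize", lambda: normalize_expression(expr))
    norm_path = out / "normalized.tsv"
    mio.write_table(norm.data, norm_path, meta, index=True)
    record("normalize", t0, [norm_path])

    # 3. specificity calls
    t0, calls = run_stage("specificity", lambda: call_specific_genes(norm, config.k))
    calls_df = pd.DataFrame(
        [(c, g) for c in sorted(calls.by_cell) for g in sorted(calls.by_cell[c])],
        columns=["cell_type", "gene"],
    )
    calls_path = out / "specificity_calls.tsv"
    mio.write_table(calls_df, calls_path, meta)
    record("specificity", t0, [calls_path])

    # 4. cell-type-specific networks
    def _networks():
        return [
            induce_cell_network(net, calls.by_cell.get(c, set()), c)
            for c in expr.cell_types
        ]
    t0, cellnets = run_stage("cell_networks", _networks)
    nets_dir = out / "networks"
    nets_dir.mkdir(exist_ok=True)
    net_paths = []
    for cn in cellnets:
        p = nets_dir / f"{cn.cell_type.replace('|', '_')}.tsv"
        mio.write_table(
            pd.DataFrame(sorted(cn.edges), columns=["gene1", "gene2"]), p, meta
        )
        net_paths.append(p)
    record("cell_networks", t0, net_paths)

    # 5. disease-gene enrichment per network
    universe = net.nodes
    t0, enrich = run_stage(
        "enrichment", lambda: disease_gene_enrichment(cellnets, diseases, universe, config.alpha)
    )
    enrich_path = out / "enrichment.tsv"
    mio.write_table(enrich, enrich_path, meta)
    record("enrichment", t0, [enrich_path])

    # 6. pathway depth selection + redundancy filter
    def _pathways():
        cat = catalog
        if config.pathway_depth is not None and cat.has_depths():
            cat = select_depth(cat, config.pathway_depth)
        return filter_redundant_pathways(cat, config.overlap_threshold)
    t0, filtered = run_stage("pathway_filter", _pathways)
    pw_path = out / "pathways_filtered.tsv"
    mio.write_table(
        pd.DataFrame(
            [(p.id, p.name, p.depth, len(p.genes)) for p in filtered.catalog],
            columns=["pathway", "name", "depth", "n_genes"],
        ),
        pw_path, meta,
    )
    removed_path = out / "pathways_removed.tsv"
    mio.write_table(
        pd.DataFrame(filtered.removal_log, columns=["removed", "kept", "overlap"]),
        removed_path, meta,
    )
    record("pathway_filter", t0, [pw_path, removed_path])

    # 7. propagation + top-scoring sets per (cell, disease)
    def _score():
        gsvs, tops = {}, {}
        for cn in cellnets:
            if cn.n_nodes < config.min_network_nodes:
                continue
            for d in diseases.diseases:
                seeds = diseases.genes_by_disease[d] & cn.nodes
                gsv = propagate(cn, seeds, config.repetitions, config.iterations,
                                config.decay, disease=d)
                gsv = standardize_scores(gsv)
                gsvs[(cn.cell_type, d)] = gsv
                tops[(cn.cell_type, d)] = select_top_scoring(gsv, config.z_cutoff)
        return gsvs, tops
    t0, (gsvs, tops) = run_stage("propagation", _score)
    scores_rows = [
        {"cell_type": c, "disease": d, "gene": g,
         "score": gsv.scores[g], "z": gsv.z[g],
         "in_top_set": g in tops[(c, d)].genes}
        for (c, d), gsv in sorted(gsvs.items()) for g in gsv.genes
    ]
    scores_path = out / "gene_scores.tsv"
    mio.write_table(pd.DataFrame(scores_rows), scores_path, meta)
    record("propagation", t0, [scores_path])

    cells_scored = sorted({c for c, _ in tops})

    # 8. multimorbidity scores + permutation test
    def _ms():
        rng = _stage_rng(config.seed, 8)
        rows = []
        for cn in cellnets:
            if cn.cell_type not in cells_scored:
                continue
            present = [d for d in diseases.diseases if (cn.cell_type, d) in tops]
            combos = list(combinations(present, 2))
            if len(present) >= 3:
                combos += list(combinations(present, 3))
            for combo in combos:
                sets_ = [tops[(cn.cell_type, d)] for d in combo]
                ms = multimorbidity_score(sets_, config.ms_variant)
                seeds_by = {d: diseases.genes_by_disease[d] & cn.nodes for d in combo}
                res = ms_permutation_test(
                    cn, seeds_by, ms, config.n_perm, rng,
                    config.repetitions, config.iterations, config.decay,
                    config.z_cutoff, config.ms_variant,
                )
                rows.append({
                    "cell_type": cn.cell_type,
                    "combination": "+".join(combo),
                    "ms": ms,
                    "sizes": "/".join(str(len(s)) for s in sets_),
                    "n_intersection": len(set.intersection(*(s.genes for s in sets_)))
                    if all(len(s) for s in sets_) else 0,
                    "p_value": res.p_value,
                    "n_perm": res.n_perm,
                })
        return pd.DataFrame(rows)
    t0, ms_df = run_stage("multimorbidity", _ms)
    ms_path = out / "multimorbidity.tsv"
    mio.write_table(ms_df, ms_path, meta)
    record("multimorbidity", t0, [ms_path])

    # 9. perturbation scores + mechanisms
    def _ps():
        rng = _stage_rng(config.seed, 9)
        frames = []
        pw_by_id = {p.id: p.genes for p in filtered.catalog}
        for cn in cellnets:
            if cn.cell_type not in cells_scored:
                continue
            seeds_by = {
                d: diseases.genes_by_disease[d] & cn.nodes for d in diseases.diseases
                if (cn.cell_type, d) in tops and len(tops[(cn.cell_type, d)]) > 0
            }
            if not seeds_by:
                continue
            frames.append(ps_null_tests_table(
                cn, pw_by_id, seeds_by, config.n_perm, rng, config.ps_variant,
                config.repetitions, config.iterations, config.decay, config.z_cutoff,
            ))
        ps = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["cell_type", "pathway", "disease", "ps", "p_value"]
        )
        mech = call_mechanisms(ps.dropna(subset=["p_value"]), config.alpha) if len(ps) else pd.DataFrame()
        return ps, mech
    t0, (ps_df, mech_df) = run_stage("perturbation", _ps)
    ps_path = out / "perturbation.tsv"
    mech_path = out / "mechanisms.tsv"
    mio.write_table(ps_df, ps_path, meta)
    mio.write_table(mech_df, mech_path, meta)
    record("perturbation", t0, [ps_path, mech_path])

    # 10. candidate genes
    def _cands():
        all_rows = []
        for cell in cells_scored:
            sets_by = {d: tops[(cell, d)] for d in diseases.diseases if (cell, d) in tops}
            if len(sets_by) < 2:
                continue
            cands = find_candidates(sets_by, cell)
            for cand in cands:
                z_by = {d: gsvs[(cell, d)].z[cand.gene] for d in cand.member_diseases}
                for combo_label in cand.combinations():
                    combo = combo_label.split("+")
                    cand.scores[combo_label] = score_candidate(z_by, combo)
            all_rows.append(rank_and_flag(cands, dict(diseases.genes_by_disease)))
        if not all_rows:
            return pd.DataFrame()
        df = pd.concat(all_rows, ignore_index=True)
        return df.sort_values(["mean_score", "gene"], ascending=[False, True]).reset_index(drop=True)
    t0, cand_df = run_stage("candidates", _cands)
    cand_path = out / "candidates.tsv"
    mio.write_table(cand_df, cand_path, meta)
    record("candidates", t0, [cand_path])

    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": asdict(config), "stages": manifest}, fh, indent=1, default=str)
    return out


def _load_inputs(config: RunConfig):
    nets = [mio.read_edge_list(p) for p in config.interactome]
    net = mio.merge_networks(nets)
    expr = mio.read_expression_matrix(config.expression)
    diseases = mio.read_gene_disease_table(config.disease_genes)
    if not diseases.genes_by_disease:
        raise ValueError("empty gene-disease table")
    catalog = mio.read_gmt(config.pathways, hierarchy=config.hierarchy)
    return mio.restrict_to_common_universe(net, expr, diseases, catalog)
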