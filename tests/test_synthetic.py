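import json

import networkx as nx
import numpy as np
import pytest

from multimorbinet import (
    ScenarioConfig,
    call_specific_genes,
    filter_redundant_pathways,
    generate_disease_modules,
    generate_expression,
    generate_interactome,
    generate_pathways,
    generate_scenario,
    normalize_expression,
    select_depth,
    write_scenario,
)


def _recovery(expr, truth):
    calls = call_specific_genes(normalize_expression(expr))
    planted = {(g, c) for c, gs in truth.items() for g in gs}
    called = {(g, c) for c, gs in calls.by_cell.items() for g in gs}
    n_pairs = len(expr.genes) * len(expr.cell_types)
    sens = len(planted & called) / len(planted)
    fp = len(called - planted) / (n_pairs - len(planted))
    return sens, fp


class TestGenerateInteractome:
    def test_size_degree_connected(self):
        net = generate_interactome(100, 4, seed=1)
        assert net.n_nodes == 100
        assert 150 <= net.n_edges <= 250
        assert nx.is_connected(net.to_networkx())

    def test_deterministic(self):
        a = generate_interactome(80, 6, seed=9)
        b = generate_interactome(80, 6, seed=9)
        assert a.edges == b.edges

    def test_near_complete_saturation(self):
        net = generate_interactome(10, 9, seed=0)
        assert net.n_edges >= 0.5 * (10 * 9 / 2)

    def test_configuration_model_connected_heavy_tail(self):
        net = generate_interactome(200, 6, model="configuration", seed=2)
        g = net.to_networkx()
        assert nx.is_connected(g)
        degs = sorted((d for _, d in g.degree()), reverse=True)
        assert degs[0] > 3 * np.median(degs)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_interactome(5)
        with pytest.raises(ValueError):
            generate_interactome(100, model="lattice")


class TestGenerateExpression:
    def _net(self):
        return generate_interactome(300, 6, seed=4)

    def test_default_effect_recovers_planted(self):
        cells = [f"c{i}" for i in range(8)]
        expr, truth = generate_expression(self._net(), cells, seed=1)
        sens, fp = _recovery(expr, truth)
        assert sens >= 0.95
        assert fp <= 0.05

    def test_zero_effect_recovery_at_chance(self):
        cells = [f"c{i}" for i in range(8)]
        expr, truth = generate_expression(self._net(), cells, specificity_effect=0.0, seed=1)
        sens, fp = _recovery(expr, truth)
        assert abs(sens - fp) < 0.05

    def test_strong_effect_limit_recovers_everything(self):
        # the effect is expressed in noise-scale multiples, so the clean
        # limit is effect >> noise rather than noise -> 0
        cells = [f"c{i}" for i in range(8)]
        expr, truth = generate_expression(self._net(), cells,
                                          specificity_effect=50.0, seed=1)
        sens, _ = _recovery(expr, truth)
        assert sens == 1.0

    def test_zero_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_expression(self._net(), ["c1", "c2"], noise_sd=0.0)

    def test_deterministic(self):
        cells = ["c1", "c2", "c3"]
        e1, _ = generate_expression(self._net(), cells, seed=7)
        e2, _ = generate_expression(self._net(), cells, seed=7)
        assert np.array_equal(e1.data.to_numpy(), e2.data.to_numpy())


class TestGenerateDiseaseModules:
    def _net(self):
        return generate_interactome(300, 6, seed=8)

    def test_modules_induce_connected_subgraphs(self):
        net = self._net()
        g = net.to_networkx()
        for seed in range(1, 6):
            dis, truth = generate_disease_modules(net, seed=seed)
            for genes in truth["modules"].values():
                assert nx.is_connected(g.subgraph(genes))

    def test_zero_overlap_disjoint(self):
        dis, _ = generate_disease_modules(self._net(), pairwise_overlap=0.0, seed=3)
        mods = list(dis.genes_by_disease.values())
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                assert not mods[i] & mods[j]

    def test_full_overlap_identical(self):
        dis, _ = generate_disease_modules(self._net(), pairwise_overlap=1.0, seed=3)
        mods = list(dis.genes_by_disease.values())
        assert all(m == mods[0] for m in mods)

    def test_partial_overlap_contains_core(self):
        dis, truth = generate_disease_modules(self._net(), pairwise_overlap=0.3, seed=3)
        core = set(truth["core"])
        assert len(core) == round(0.3 * 25)
        for genes in dis.genes_by_disease.values():
            assert core <= genes

    def test_oversized_module_rejected(self):
        with pytest.raises(ValueError):
            generate_disease_modules(generate_interactome(20, 4, seed=1), module_size=50)


class TestGeneratePathways:
    def test_redundant_pair_collapsed_by_filter(self):
        net = generate_interactome(200, 6, seed=5)
        cat, truth = generate_pathways(net, redundancy_pairs=2, seed=5)
        depth3 = select_depth(cat, 3)
        filtered = filter_redundant_pathways(depth3)
        removed = {r for r, _, _ in filtered.removal_log}
        for src, dup in truth["redundant_pairs"]:
            assert dup in removed or src in removed

    def test_planted_pathway_inside_module_pool(self):
        net = generate_interactome(200, 6, seed=5)
        _, mod_truth = generate_disease_modules(net, seed=5)
        pool = set().union(*(set(m) for m in mod_truth["modules"].values()))
        core = set(mod_truth["core"])
        cat, truth = generate_pathways(net, planted_in_modules=[(core, pool)], seed=5)
        pid = truth["planted_pathways"][0]
        assert core <= cat[pid].genes <= pool
        assert cat[pid].depth == 3

    def test_depth_labels_cycle(self):
        net = generate_interactome(100, 6, seed=1)
        cat, _ = generate_pathways(net, n_pathways=9, redundancy_pairs=0, seed=1)
        kept = select_depth(cat, 3)
        assert len(kept) == 3


class TestGenerateScenario:
    def test_file_manifest(self, tmp_path):
        sc = generate_scenario(ScenarioConfig(n_genes=120, n_pathways=9), seed=2)
        paths = write_scenario(sc, tmp_path / "sim")
        for name in ("interactome", "expression", "diseases", "pathways", "hierarchy", "truth"):
            assert paths[name].exists() and paths[name].stat().st_size > 0

    def test_same_seed_identical_truth(self, tmp_path):
        cfg = ScenarioConfig(n_genes=120, n_pathways=9)
        p1 = write_scenario(generate_scenario(cfg, seed=3), tmp_path / "a")
        p2 = write_scenario(generate_scenario(cfg, seed=3), tmp_path / "b")
        assert p1["truth"].read_bytes() == p2["truth"].read_bytes()
        assert p1["expression"].read_bytes() == p2["expression"].read_bytes()

    def test_null_config_marks_no_multimorbidity(self):
        sc = generate_scenario(
            ScenarioConfig(n_genes=120, n_multimorbid_cells=0, n_pathways=6), seed=1
        )
        assert sc.truth["multimorbid_cell_types"] == []
        assert sc.truth["planted_pathways"] == []

    def test_invalid_config_names_field(self):
        with pytest.raises(ValueError, match="frac_specific"):
            generate_scenario(ScenarioConfig(frac_specific=1.5), seed=0)

    def test_overlap_monotone_in_planted_effect(self):
        # increasing module overlap increases realized module overlap
        net = generate_interactome(300, 6, seed=11)
        mean_overlaps = []
        for ov in (0.0, 0.5, 1.0):
            reals = []
            for seed in range(4):
                dis, _ = generate_disease_modules(net, pairwise_overlap=ov, seed=seed)
                mods = list(dis.genes_by_disease.values())
                reals.append(np.mean([
                    len(mods[i] & mods[j]) / 25
                    for i in range(3) for j in range(i + 1, 3)
                ]))
            mean_overlaps.append(np.mean(reals))
        assert mean_overlaps[0] < mean_overlaps[1] < mean_overlaps[2]
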