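import numpy as np
import pytest

from multimorbinet import (
    CellNetwork,
    GeneScoreVector,
    propagate,
    propagate_batch,
    rwr_scores,
    select_top_scoring,
    standardize_scores,
)
from multimorbinet.nulls import degree_matched_seed_sets, top_set_matrix
from multimorbinet.synthetic import generate_interactome


class TestPropagate:
    def test_path_scores_strictly_decrease_with_distance(self, path_network):
        gsv = propagate(path_network, {"a"})
        s = gsv.scores
        assert s["a"] > s["b"] > s["c"] > s["d"]

    def test_empty_seed_set_all_zero(self, path_network):
        gsv = propagate(path_network, set())
        assert all(v == 0 for v in gsv.scores.values())

    def test_seeds_outside_network_ignored(self, path_network):
        gsv = propagate(path_network, {"zz"})
        assert all(v == 0 for v in gsv.scores.values())

    def test_star_leaves_symmetric(self, star_network):
        gsv = propagate(star_network, {"h"})
        leaf_scores = {v for g, v in gsv.scores.items() if g != "h"}
        assert len(leaf_scores) == 1
        assert gsv.scores["h"] > leaf_scores.pop()

    def test_deterministic_bit_identical(self, path_network):
        a = propagate(path_network, {"a", "c"}).scores
        b = propagate(path_network, {"a", "c"}).scores
        assert a == b

    def test_cycle_automorphism_equivariance(self):
        # rotating a cycle and its seed rotates the scores identically
        n = 6
        nodes = [f"n{i}" for i in range(n)]
        edges = {tuple(sorted((nodes[i], nodes[(i + 1) % n]))) for i in range(n)}
        cn = CellNetwork(cell_type="cyc", nodes=set(nodes), edges=edges)
        s0 = propagate(cn, {nodes[0]}).scores
        s2 = propagate(cn, {nodes[2]}).scores
        for i in range(n):
            assert s0[nodes[i]] == pytest.approx(s2[nodes[(i + 2) % n]])

    def test_horizon_limits_reach(self):
        nodes = [f"n{i}" for i in range(10)]
        edges = {tuple(sorted((nodes[i], nodes[i + 1]))) for i in range(9)}
        cn = CellNetwork(cell_type="long", nodes=set(nodes), edges=edges)
        gsv = propagate(cn, {nodes[0]}, repetitions=2, iterations=2)  # horizon 4
        assert gsv.scores[nodes[4]] > 0
        assert gsv.scores[nodes[5]] == 0

    def test_invalid_parameters(self, path_network):
        with pytest.raises(ValueError):
            propagate(path_network, {"a"}, repetitions=0)
        with pytest.raises(ValueError):
            propagate(path_network, {"a"}, decay=1.5)

    def test_batch_matches_single_runs(self, path_network):
        seed_sets = [{"a"}, {"b", "d"}, set()]
        nodes, scores = propagate_batch(path_network, seed_sets)
        for i, seeds in enumerate(seed_sets):
            single = propagate(path_network, seeds)
            assert np.allclose(scores[i], [single.scores[g] for g in nodes])


class TestStandardizeAndSelect:
    def test_two_gene_population_sd(self):
        gsv = GeneScoreVector("c", "d", {"g1": 0.0, "g2": 1.0})
        standardize_scores(gsv)
        assert gsv.z["g1"] == pytest.approx(-1.0)
        assert gsv.z["g2"] == pytest.approx(1.0)

    def test_constant_scores_flagged_degenerate(self):
        gsv = GeneScoreVector("c", "d", {"g1": 2.0, "g2": 2.0})
        standardize_scores(gsv)
        assert gsv.degenerate and set(gsv.z.values()) == {0.0}

    def test_location_invariance(self):
        raw = {"g1": 0.3, "g2": 1.7, "g3": 0.9}
        z1 = standardize_scores(GeneScoreVector("c", "d", dict(raw))).z
        z2 = standardize_scores(
            GeneScoreVector("c", "d", {g: v + 10 for g, v in raw.items()})
        ).z
        for g in raw:
            assert z1[g] == pytest.approx(z2[g])

    def test_select_by_cutoff(self):
        gsv = GeneScoreVector("c", "d", {"g1": 0, "g2": 0, "g3": 0})
        gsv.z = {"g1": 3.1, "g2": 0.2, "g3": -1.0}
        assert select_top_scoring(gsv, z_cutoff=2.0).genes == {"g1"}
        assert select_top_scoring(gsv, z_cutoff=-np.inf).genes == {"g1", "g2", "g3"}

    def test_raising_cutoff_never_grows_set(self):
        gsv = GeneScoreVector("c", "d", {})
        gsv.z = {f"g{i}": z for i, z in enumerate(np.linspace(-2, 4, 20))}
        sizes = [len(select_top_scoring(gsv, z).genes) for z in [0.5, 1.0, 1.5, 2.0]]
        assert sizes == sorted(sizes, reverse=True)

    def test_unstandardized_vector_rejected(self):
        with pytest.raises(ValueError):
            select_top_scoring(GeneScoreVector("c", "d", {"g": 1.0}))


class TestNullMachinery:
    def _big_network(self):
        net = generate_interactome(300, 6, seed=3)
        return CellNetwork(cell_type="all", nodes=net.nodes, edges=net.edges)

    def test_degree_matched_sets_preserve_size_and_bins(self, rng):
        cn = self._big_network()
        deg = cn.degree()
        seeds = set(sorted(cn.nodes)[:20])
        bins = lambda gs: sorted(int(np.log2(max(deg[g], 1))) for g in gs)
        draws = degree_matched_seed_sets(cn, seeds, 5, rng)
        for d in draws:
            assert len(d) == len(seeds)
            assert bins(d) == bins(seeds)

    def test_top_set_size_varies_under_null(self, rng):
        cn = self._big_network()
        seeds = set(np.random.default_rng(0).choice(sorted(cn.nodes), 15, replace=False))
        draws = degree_matched_seed_sets(cn, seeds, 50, rng)
        _, member = top_set_matrix(cn, draws)
        sizes = member.sum(axis=1)
        assert len(np.unique(sizes)) > 3  # non-degenerate null for the PS test


class TestRwrScores:
    def test_seed_outranks_periphery(self, path_network):
        gsv = rwr_scores(path_network, {"a"})
        assert gsv.scores["a"] > gsv.scores["b"] > gsv.scores["d"]

    def test_scores_sum_to_one(self, star_network):
        gsv = rwr_scores(star_network, {"h"})
        assert sum(gsv.scores.values()) == pytest.approx(1.0, abs=1e-8)
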