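import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multimorbinet import (
    CellNetwork,
    Pathway,
    PathwayCatalog,
    catalog_association,
    filter_redundant_pathways,
    map_pathway_to_network,
    pathway_connectivity,
    select_depth,
    sorensen_dice,
)


def _catalog(sets: dict[str, set], depths: dict[str, int] | None = None) -> PathwayCatalog:
    return PathwayCatalog(pathways={
        pid: Pathway(pid, pid, genes, (depths or {}).get(pid))
        for pid, genes in sets.items()
    })


class TestSorensenDice:
    def test_worked_example_sizes_6_47_overlap_1(self):
        a = set(range(6))
        b = set(range(5, 52))
        assert len(a & b) == 1
        assert round(sorensen_dice(a, b), 3) == 0.038

    def test_identity_and_disjoint(self):
        assert sorensen_dice({"a", "b"}, {"a", "b"}) == 1.0
        assert sorensen_dice({"a"}, {"b"}) == 0.0

    def test_both_empty_error(self):
        with pytest.raises(ValueError):
            sorensen_dice(set(), set())

    @settings(derandomize=True, max_examples=50)
    @given(a=st.sets(st.integers(0, 10)), b=st.sets(st.integers(0, 10)))
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        d = sorensen_dice(a, b)
        assert d == sorensen_dice(b, a)
        assert 0 <= d <= 1
        assert (d == 1) == (a == b)
        assert (d == 0) == (not a & b)


class TestSelectDepth:
    def test_keeps_requested_depth(self):
        cat = _catalog({"P1": {"a"}, "P2": {"b"}, "P3": {"c"}, "P4": {"d"}},
                       {"P1": 1, "P2": 2, "P3": 3, "P4": 3})
        assert set(select_depth(cat, 3).ids) == {"P3", "P4"}
        assert set(select_depth(cat, 1).ids) == {"P1"}

    def test_no_pathway_at_depth_error(self):
        cat = _catalog({"P1": {"a"}}, {"P1": 1})
        with pytest.raises(ValueError):
            select_depth(cat, 7)

    def test_missing_hierarchy_error(self):
        cat = _catalog({"P1": {"a"}})
        with pytest.raises(ValueError, match="no hierarchy"):
            select_depth(cat, 3)


class TestFilterRedundantPathways:
    def test_smaller_of_redundant_pair_removed(self):
        cat = _catalog({"P1": {"a", "b", "c", "d"}, "P2": {"a", "b", "c"}})
        # overlap 6/7 > 0.5 -> P2 (smaller) removed
        res = filter_redundant_pathways(cat)
        assert res.catalog.ids == ["P1"]
        assert res.removal_log == [("P2", "P1", pytest.approx(6 / 7))]

    def test_disjoint_pathways_kept(self):
        res = filter_redundant_pathways(_catalog({"P1": {"a", "b"}, "P2": {"c", "d"}}))
        assert set(res.catalog.ids) == {"P1", "P2"}

    def test_boundary_overlap_is_strict(self):
        # dice({a,b},{a,c}) = 2/4 = 0.5, not > 0.5 -> both kept
        res = filter_redundant_pathways(_catalog({"P1": {"a", "b"}, "P2": {"a", "c"}}))
        assert set(res.catalog.ids) == {"P1", "P2"}

    def test_size_tie_removes_later_id(self):
        res = filter_redundant_pathways(_catalog({"P1": {"a", "b"}, "P2": {"a", "b"}}))
        assert res.catalog.ids == ["P1"]

    def test_survivors_below_threshold_and_order_independent(self, rng):
        genes = [f"g{i}" for i in range(30)]
        sets = {
            f"P{i}": set(rng.choice(genes, size=int(rng.integers(4, 12)), replace=False))
            for i in range(12)
        }
        res1 = filter_redundant_pathways(_catalog(sets), threshold=0.4)
        for i, a in enumerate(res1.catalog.ids):
            for b in res1.catalog.ids[i + 1:]:
                assert sorensen_dice(res1.catalog[a].genes, res1.catalog[b].genes) <= 0.4
        shuffled = dict(sorted(sets.items(), key=lambda kv: hash(kv[0])))
        res2 = filter_redundant_pathways(_catalog(shuffled), threshold=0.4)
        assert set(res1.catalog.ids) == set(res2.catalog.ids)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_redundant_pathways(_catalog({"P": {"a"}}), threshold=0)


class TestPathwayNetworkMapping:
    def _net(self):
        return CellNetwork(cell_type="c", nodes={"a", "b", "c"},
                           edges={("a", "b")})

    def test_map_intersects(self):
        assert map_pathway_to_network({"a", "b", "z"}, self._net()) == {"a", "b"}
        assert map_pathway_to_network({"x", "y"}, self._net()) == set()
        assert map_pathway_to_network({"a", "b"}, self._net()) == {"a", "b"}

    def test_connectivity_counts(self):
        assert pathway_connectivity({"a", "b", "c"}, self._net()) == (1, pytest.approx(2 / 3))
        assert pathway_connectivity({"c"}, self._net()) == (0, 0.0)

    def test_clique_fully_connected(self):
        net = CellNetwork(cell_type="c", nodes={"a", "b", "c"},
                          edges={("a", "b"), ("a", "c"), ("b", "c")})
        assert pathway_connectivity({"a", "b", "c"}, net) == (3, 1.0)


class TestCatalogAssociation:
    def test_identical_sets_hypergeometric_tail(self):
        universe = {f"g{i}" for i in range(50)}
        genes = set(list(sorted(universe))[:5])
        a = _catalog({"A1": genes})
        b = _catalog({"B1": set(genes)})
        df = catalog_association(a, b, universe)
        expected = sum(
            math.comb(5, i) * math.comb(45, 5 - i) for i in range(5, 6)
        ) / math.comb(50, 5)
        assert df["p_value"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_sets_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        df = catalog_association(
            _catalog({"A1": {"g0", "g1"}}), _catalog({"B1": {"g5", "g6"}}), universe
        )
        assert df["p_value"].iloc[0] == pytest.approx(1.0)

    def test_zero_cell_lor_finite(self):
        universe = {f"g{i}" for i in range(20)}
        df = catalog_association(
            _catalog({"A1": {"g0", "g1"}}), _catalog({"B1": {"g5", "g6"}}), universe
        )
        assert np.isfinite(df["log_odds_ratio"].iloc[0])
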