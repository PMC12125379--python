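import itertools

import pytest

from pwmod import (
    Clustering,
    ProbabilisticNetwork,
    brute_force_expected_modularity,
    cell_visit_count,
    edge_trisection,
    expected_modularity_fpwp,
    expected_modularity_pwp,
    modularity_communities,
    partition_probability,
    partition_world_count,
    pmf_enumeration,
    q_cell,
    world_probability,
)
from helpers import collect_random_instances


@pytest.fixture
def worked_example():
    """Five-edge network where community c has capacities (T_x, T_y, T_z) = (1, 2, 2)."""
    net = ProbabilisticNetwork.from_edges(
        {
            ("n1", "n2"): 0.6,  # within c
            ("n2", "n3"): 0.7,  # cross
            ("n2", "n4"): 0.4,  # cross
            ("n3", "n4"): 0.5,  # outside
            ("n4", "n5"): 0.8,  # outside
        }
    )
    clu = Clustering.from_mapping(
        {"n1": "c", "n2": "c", "n3": "o", "n4": "o", "n5": "o"}
    )
    return net, clu


class TestQCell:
    @pytest.mark.parametrize(
        "xyz, expected",
        [
            ((0, 0, 0), 0.0),
            ((1, 0, 0), 0.0),
            ((0, 1, 2), -1.0 / 36.0),
            ((1, 2, 0), 1.0 / 3.0 - (4.0 / 6.0) ** 2),
        ],
    )
    def test_hand_values(self, xyz, expected):
        assert q_cell(*xyz) == pytest.approx(expected, abs=1e-15)

    def test_matches_world_modularity_contribution(self, worked_example):
        """Q_c^{xyz} equals the community's modularity term in any member world."""
        net, clu = worked_example
        # both communities see (x, y, z) = (1, 1, 1) in this world
        world = net.world([("n1", "n2"), ("n2", "n3"), ("n3", "n4")])
        assert 2 * q_cell(1, 1, 1) == pytest.approx(
            modularity_communities(world, clu), abs=1e-12
        )


class TestWorldCounts:
    def test_worked_cell(self, worked_example):
        net, clu = worked_example
        tri = edge_trisection(net, clu, "c")
        assert (tri.t_x, tri.t_y, tri.t_z) == (1, 2, 2)
        assert partition_world_count(tri, 0, 1, 2) == 2
        assert partition_world_count(tri, 0, 0, 0) == 1

    def test_counts_sum_to_all_worlds(self, worked_example):
        net, clu = worked_example
        tri = edge_trisection(net, clu, "c")
        total = sum(
            partition_world_count(tri, x, y, z)
            for x in range(tri.t_x + 1)
            for y in range(tri.t_y + 1)
            for z in range(tri.t_z + 1)
        )
        assert total == 2**net.m

    def test_out_of_capacity_rejected(self, worked_example):
        net, clu = worked_example
        tri = edge_trisection(net, clu, "c")
        with pytest.raises(ValueError):
            partition_world_count(tri, 2, 0, 0)


class TestPartitionProbability:
    def test_deterministic_edges_concentrate_at_capacity(self):
        net = ProbabilisticNetwork.from_edges(
            {("a", "b"): 1.0, ("a", "c"): 1.0, ("d", "e"): 1.0}
        )
        clu = Clustering.from_mapping({"a": "c", "b": "c", "c": "o", "d": "o", "e": "o"})
        tri = edge_trisection(net, clu, "c")
        assert partition_probability(net, tri, tri.t_x, tri.t_y, tri.t_z) == pytest.approx(
            1.0, abs=1e-12
        )
        assert partition_probability(net, tri, 0, 0, 0) == pytest.approx(0.0, abs=1e-12)

    def test_equals_sum_of_member_world_probabilities(self, worked_example):
        """Pr(d^{xyz}) pools exactly the probabilities of the cell's worlds."""
        net, clu = worked_example
        tri = edge_trisection(net, clu, "c")
        within, cross = set(tri.within), set(tri.cross)
        cell_mass: dict[tuple[int, int, int], float] = {}
        for r in range(net.m + 1):
            for sub in itertools.combinations(net.edges, r):
                x = len(set(sub) & within)
                y = len(set(sub) & cross)
                z = len(sub) - x - y
                cell_mass[(x, y, z)] = cell_mass.get((x, y, z), 0.0) + world_probability(
                    net, net.world(sub)
                )
        total = 0.0
        for x in range(tri.t_x + 1):
            for y in range(tri.t_y + 1):
                for z in range(tri.t_z + 1):
                    pr = partition_probability(net, tri, x, y, z, engine=pmf_enumeration)
                    assert pr == pytest.approx(cell_mass.get((x, y, z), 0.0), abs=1e-12)
                    total += pr
        assert total == pytest.approx(1.0, abs=1e-9)


class TestExpectedModularity:
    def test_single_cross_edge(self, single_cross_edge):
        net, clu = single_cross_edge
        assert expected_modularity_pwp(net, clu).value == pytest.approx(-0.4, abs=1e-12)
        assert expected_modularity_fpwp(net, clu).value == pytest.approx(-0.4, abs=1e-12)

    def test_all_certain_network(self, two_triangles):
        net, clu = two_triangles
        for fn in (expected_modularity_pwp, expected_modularity_fpwp):
            result = fn(net, clu)
            assert result.value == pytest.approx(0.5, abs=1e-12)
            assert result.diagnostics["cells"] == cell_visit_count(net, clu)

    def test_triple_method_agreement_on_random_instances(self):
        """Brute force, PWP and FPWP agree on random small instances."""
        for net, clu in collect_random_instances(30, start_seed=2000, max_m=12):
            brute = brute_force_expected_modularity(net, clu).value
            assert abs(expected_modularity_pwp(net, clu).value - brute) <= 1e-9
            assert abs(expected_modularity_fpwp(net, clu).value - brute) <= 1e-8

    def test_per_community_terms_sum_to_value(self, worked_example):
        net, clu = worked_example
        result = expected_modularity_fpwp(net, clu)
        assert sum(result.diagnostics["per_community"].values()) == pytest.approx(
            result.value, abs=1e-12
        )

    def test_pwp_guard_points_to_fpwp(self):
        edges = {(f"a{i:02d}", f"b{i:02d}"): 0.5 for i in range(25)}
        net = ProbabilisticNetwork.from_edges(edges)
        clu = Clustering.from_mapping({n: "c" for n in net.nodes})
        with pytest.raises(ValueError, match="FPWP"):
            expected_modularity_pwp(net, clu)

    def test_cell_count_independent_of_probabilities(self, worked_example):
        """The partition structure is a function of topology + clustering only."""
        net, clu = worked_example
        other = ProbabilisticNetwork.from_edges({e: 0.123 for e in net.edges})
        r1 = expected_modularity_fpwp(net, clu)
        r2 = expected_modularity_fpwp(other, clu)
        assert r1.diagnostics["cells"] == r2.diagnostics["cells"]
        assert r1.diagnostics["cells"] == cell_visit_count(net, clu)
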