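import numpy as np
import pytest

from pwmod import (
    Clustering,
    ProbabilisticNetwork,
    brute_force_expected_modularity,
    modularity_communities,
    sample_world,
    sampling_expected_modularity,
    sampling_time_budget,
    threshold_expected_modularity_estimate,
)
from helpers import collect_random_instances


class TestSampleWorld:
    def test_all_certain_gives_full_world(self, two_triangles):
        net, _ = two_triangles
        world = sample_world(net, np.random.default_rng(0))
        assert world.edges == net.edges

    def test_fixed_seed_reproduces_world(self, single_cross_edge):
        net, _ = single_cross_edge
        w1 = sample_world(net, np.random.default_rng(42))
        w2 = sample_world(net, np.random.default_rng(42))
        assert w1 == w2

    def test_inclusion_frequency_matches_probability(self):
        """An edge with p = 0.3 appears in ~30% of 10,000 draws (binomial CI)."""
        net = ProbabilisticNetwork.from_edges({("a", "b"): 0.3})
        rng = np.random.default_rng(7)
        hits = sum(sample_world(net, rng).m for _ in range(10_000))
        assert abs(hits / 10_000 - 0.3) <= 0.015


class TestSampling:
    def test_theta_must_be_positive(self, single_cross_edge):
        net, clu = single_cross_edge
        with pytest.raises(ValueError):
            sampling_expected_modularity(net, clu, theta=0, seed=0)

    def test_all_certain_is_exact_for_any_theta(self, two_triangles):
        net, clu = two_triangles
        res = sampling_expected_modularity(net, clu, theta=3, seed=0)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)

    def test_same_seed_same_estimate(self, single_cross_edge):
        net, clu = single_cross_edge
        a = sampling_expected_modularity(net, clu, theta=500, seed=9)
        b = sampling_expected_modularity(net, clu, theta=500, seed=9)
        assert a.estimate == b.estimate

    def test_batched_run_matches_sequential_worlds(self):
        """The batched estimator sees exactly the worlds sample_world draws."""
        nets = collect_random_instances(1, start_seed=300, max_m=10)
        net, clu = nets[0]
        seed, theta = 123, 40
        batched = sampling_expected_modularity(net, clu, theta=theta, seed=seed,
                                               keep_samples=True)
        rng = np.random.default_rng(seed)
        sequential = [
            modularity_communities(sample_world(net, rng), clu) for _ in range(theta)
        ]
        assert np.allclose(batched.per_sample, sequential, atol=1e-12)
        assert batched.estimate == pytest.approx(np.mean(sequential), abs=1e-12)

    def test_close_to_exact_value_at_large_theta(self, single_cross_edge):
        net, clu = single_cross_edge
        res = sampling_expected_modularity(net, clu, theta=100_000, seed=5,
                                           keep_samples=True)
        se = np.std(res.per_sample, ddof=1) / np.sqrt(res.theta)
        assert abs(res.estimate - (-0.4)) <= 4 * se

    def test_grand_mean_unbiased_on_random_fixture(self):
        """50 runs of theta=1000: grand mean within 4 SE of the exact value."""
        net, clu = collect_random_instances(1, start_seed=400, min_m=8, max_m=12)[0]
        exact = brute_force_expected_modularity(net, clu).value
        means = [
            sampling_expected_modularity(net, clu, theta=1000, seed=s).estimate
            for s in range(50)
        ]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - exact) <= 4 * se


class TestTimeBudget:
    def test_tiny_budget_still_samples_once(self, single_cross_edge):
        net, clu = single_cross_edge
        res = sampling_time_budget(net, clu, budget=1e-9, seed=0)
        assert res.theta >= 1

    def test_larger_budget_draws_more(self, single_cross_edge):
        net, clu = single_cross_edge
        small = sampling_time_budget(net, clu, budget=1e-9, seed=0)
        large = sampling_time_budget(net, clu, budget=0.05, seed=0)
        assert large.theta >= small.theta
        assert abs(large.estimate - (-0.4)) < 0.2

    def test_invalid_budget_rejected(self, single_cross_edge):
        net, clu = single_cross_edge
        with pytest.raises(ValueError):
            sampling_time_budget(net, clu, budget=0.0, seed=0)


class TestThresholding:
    def test_all_certain_any_threshold_is_exact(self, two_triangles):
        net, clu = two_triangles
        for t in (0.1, 0.5, 1.0):
            assert threshold_expected_modularity_estimate(net, clu, t) == pytest.approx(
                0.5, abs=1e-12
            )

    def test_keeps_edges_at_or_above_threshold(self):
        net = ProbabilisticNetwork.from_edges({("a", "b"): 0.3, ("c", "d"): 0.7})
        clu = Clustering.from_mapping({"a": "1", "b": "1", "c": "2", "d": "2"})
        # t = 0.5 keeps only the 0.7 edge: one within-edge, single community present
        assert threshold_expected_modularity_estimate(net, clu, 0.5) == pytest.approx(
            modularity_communities(net.world([("c", "d")]), clu), abs=1e-12
        )
        # t = 0.7 is inclusive: the 0.7 edge survives
        assert threshold_expected_modularity_estimate(net, clu, 0.7) == pytest.approx(
            modularity_communities(net.world([("c", "d")]), clu), abs=1e-12
        )

    def test_invalid_threshold_rejected(self, two_triangles):
        net, clu = two_triangles
        for t in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                threshold_expected_modularity_estimate(net, clu, t)

    def test_uniform_half_probability_has_two_plateaus(self, two_triangles):
        """Sweeping t over a uniform p=0.5 network yields only Q_full and 0."""
        topo, clu = two_triangles
        net = ProbabilisticNetwork.from_edges({e: 0.5 for e in topo.edges})
        values = {
            round(threshold_expected_modularity_estimate(net, clu, t / 10), 12)
            for t in range(1, 11)
        }
        assert values == {0.5, 0.0}

    def test_near_deterministic_network_is_thresholded_exactly(self):
        """With all p in {eps, 1-eps} the t=0.5 estimate matches E(Q) closely."""
        eps = 1e-6
        base = collect_random_instances(1, start_seed=500, min_m=6, max_m=12)[0]
        net0, clu = base
        rng = np.random.default_rng(3)
        probs = {
            e: (1.0 - eps if rng.random() < 0.7 else eps) for e in net0.edges
        }
        net = ProbabilisticNetwork.from_edges(probs, extra_nodes=net0.nodes)
        exact = brute_force_expected_modularity(net, clu).value
        estimate = threshold_expected_modularity_estimate(net, clu, 0.5)
        assert abs(estimate - exact) <= 1e-3
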