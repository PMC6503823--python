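"""Subset lattice construction, level statistics and trajectory enumeration."""

import numpy as np
import pytest

from lmaland.lma import ModelConfig, lma_score
from lmaland.trajectory import (
    LatticeGraph,
    build_lattice,
    enumerate_trajectories,
    level_stats,
    required_vs_observed,
    score_all_subsets,
)

from conftest import make_landscape, make_uniform_landscape

PROD = ModelConfig("combined_prod", {"intrinsic": 0.2, "interactive": 3})


def naive_terminals(graph: LatticeGraph, threshold: float) -> set[frozenset]:
    """Depth-first enumeration of every acquisition chain, stopping at the
    first node whose score meets the threshold (the independent oracle)."""
    found: set[frozenset] = set()
    def walk(current: frozenset) -> None:
        if graph.score_of(current) >= threshold:
            found.add(current)
            return
        for d in graph.drivers:
            if d not in current:
                walk(current | {d})
    for d in graph.drivers:
        walk(frozenset([d]))
    return found


class TestLatticeStructure:
    def test_node_counts(self):
        for k in (3, 5):
            land = make_landscape(k, seed=0)
            g = build_lattice(land, PROD, top_k=k)
            assert g.n_nodes == 2**k - 1

    def test_edge_count_closed_form(self):
        land = make_landscape(3, seed=0)
        g = build_lattice(land, PROD, top_k=3)
        edges = list(g.iter_edges())
        # k * 2^(k-1) = sum over sizes m of m*C(k,m): every size-m node has m
        # in-edges, counting the root edge into each singleton
        assert len(edges) == g.n_edges == 12

    def test_degrees(self):
        land = make_landscape(4, seed=1)
        g = build_lattice(land, PROD, top_k=4)
        nxg = g.to_networkx()
        sizes = g.node_sizes()
        for mask in nxg.nodes:
            m = int(sizes[mask - 1]) if mask else 0
            assert nxg.out_degree(mask) == g.k - m
            assert nxg.in_degree(mask) == m

    def test_top_k_exceeding_drivers_errors(self):
        land = make_landscape(4, seed=0)
        with pytest.raises(ValueError):
            build_lattice(land, PROD, top_k=5)

    def test_node_scores_match_direct_scoring(self):
        land = make_landscape(5, seed=7)
        g = build_lattice(land, PROD, top_k=5)
        rng = np.random.default_rng(0)
        for _ in range(15):
            size = int(rng.integers(1, 6))
            subset = frozenset(rng.choice(land.drivers, size=size, replace=False))
            assert g.score_of(subset) == pytest.approx(
                lma_score(sorted(subset), land, PROD).f
            )

    @pytest.mark.parametrize(
        "model,weights",
        [
            ("combined_mean", {"intrinsic": 0.5, "interactive": 2}),
            ("separate_mean", {"sa": 0.3, "ss": 1, "epi": 2}),
            ("separate_prod", {"sa": 0.3, "ss": 1, "epi": 2}),
        ],
    )
    def test_vectorised_scoring_matches_scalar_for_all_models(self, model, weights):
        land = make_landscape(4, seed=3)
        config = ModelConfig(model, weights)
        scores = score_all_subsets(land.drivers, land, config)
        g = LatticeGraph(land.drivers, scores, config)
        for mask in range(1, 2**4):
            subset = g.subset_of(mask)
            assert scores[mask - 1] == pytest.approx(
                lma_score(sorted(subset), land, config).f
            )


class TestLevelStats:
    def test_linear_closed_form_for_uniform_landscape(self):
        c = 1.4  # SA*SS per driver
        land = make_uniform_landscape(5, sa=1.4, ss=1.0, e=1.0)
        config = ModelConfig("combined_prod", {"intrinsic": 0.7, "interactive": 2})
        g = build_lattice(land, config, top_k=5)
        stats = level_stats(g)
        for m in range(1, 6):
            expected = m * (c * 0.7 + 2)
            assert stats.loc[m, "mean"] == pytest.approx(expected)
            assert stats.loc[m, "max"] == pytest.approx(expected)

    def test_max_at_least_mean(self):
        land = make_landscape(6, seed=5)
        stats = level_stats(build_lattice(land, PROD, top_k=6))
        assert (stats["max"] >= stats["mean"] - 1e-12).all()

    def test_antagonistic_cliques_produce_diminishing_returns(self):
        """Two 3-driver cliques with strong negative interactions between
        them: the best large combination scores below the best small one."""
        import pandas as pd

        drivers = [f"D{i:02d}_mut" for i in range(6)]
        e = np.full((6, 6), 0.01)
        e[:3, :3] = 1.0
        e[3:, 3:] = 1.0
        np.fill_diagonal(e, np.nan)
        from lmaland.landscape import Landscape

        land = Landscape(
            "CLIQUES", drivers,
            sa={d: 1.0 for d in drivers}, ss={d: 1.0 for d in drivers},
            epistasis=pd.DataFrame(e, index=drivers, columns=drivers),
            frequencies={d: 0.5 for d in drivers},
        )
        config = ModelConfig("combined_prod", {"intrinsic": 0.2, "interactive": 3})
        stats = level_stats(build_lattice(land, config, top_k=6))
        assert stats.loc[6, "max"] < stats.loc[3, "max"]


class TestTrajectories:
    def test_additive_landscape_terminates_at_three_drivers(self):
        # every driver contributes exactly 3; threshold 2.5*3 = 7.5
        land = make_uniform_landscape(5, sa=2.0, ss=1.0, e=1.0)
        config = ModelConfig("combined_prod", {"intrinsic": 1, "interactive": 1})
        g = build_lattice(land, config, top_k=5)
        report = enumerate_trajectories(g, threshold=7.5)
        assert set(report.driver_count_distribution) == {3}
        assert report.driver_count_distribution[3] == 10  # C(5,3)
        assert report.mean_terminal_drivers == 3.0

    def test_ordering_weights_count_acquisition_orders(self):
        land = make_uniform_landscape(5, sa=2.0, ss=1.0, e=1.0)
        config = ModelConfig("combined_prod", {"intrinsic": 1, "interactive": 1})
        g = build_lattice(land, config, top_k=5)
        report = enumerate_trajectories(g, threshold=7.5, weight_orderings=True)
        assert all(w == 6 for w in report.ordering_weights.values())  # 3! orders

    def test_all_singletons_terminal(self):
        land = make_uniform_landscape(4, sa=5.0, ss=1.0, e=1.0)
        config = ModelConfig("combined_prod", {"intrinsic": 1, "interactive": 1})
        g = build_lattice(land, config, top_k=4)
        report = enumerate_trajectories(g, threshold=1.0)
        assert sorted(report.terminal_sets, key=sorted) == sorted(
            [frozenset([d]) for d in land.drivers], key=sorted
        )

    def test_unreachable_threshold_yields_empty_report(self):
        land = make_uniform_landscape(4, sa=1.0, ss=1.0, e=1.0)
        config = ModelConfig("combined_prod", {"intrinsic": 1, "interactive": 1})
        g = build_lattice(land, config, top_k=4)
        with pytest.warns(UserWarning, match="no trajectory"):
            report = enumerate_trajectories(g, threshold=1e9)
        assert report.terminal_sets == []

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_naive_chain_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 7))
        land = make_landscape(k, seed=seed)
        g = build_lattice(land, PROD, top_k=k)
        threshold = float(np.quantile(g.scores, 0.7))
        if threshold <= 0:
            threshold = float(g.scores.max()) * 0.5
        report = enumerate_trajectories(g, threshold)
        assert set(report.terminal_sets) == naive_terminals(g, threshold)

    def test_terminals_meet_threshold_and_are_not_chained(self):
        land = make_landscape(6, seed=42)
        g = build_lattice(land, PROD, top_k=6)
        thr = float(np.median(g.scores))
        report = enumerate_trajectories(g, thr)
        terminals = set(report.terminal_sets)
        for t in terminals:
            assert g.score_of(t) >= thr
        # a terminal node never extends another terminal node through a
        # below-threshold chain: any strict superset chain passes a node >= thr
        for a in terminals:
            for b in terminals:
                if a < b:
                    # every chain from a to b starts at a, which already meets
                    # the threshold, so b's qualifying chain cannot pass a
                    assert g.score_of(a) >= thr


class TestRequiredVsObserved:
    def test_identity_gives_r2_one(self):
        r2, _ = required_vs_observed([2.0, 3.0, 4.0, 5.0], [2.0, 3.0, 4.0, 5.0])
        assert r2 == pytest.approx(1.0)

    def test_constant_required_gives_zero(self):
        r2, p = required_vs_observed([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])
        assert r2 == 0.0 and p == 1.0

    def test_too_few_landscapes_error(self):
        with pytest.raises(ValueError):
            required_vs_observed([1.0, 2.0], [1.0, 2.0])

    def test_required_count_decreases_with_driver_contribution(self):
        """Across landscape families with increasing per-driver contribution,
        the mean terminal size under a fixed threshold decreases."""
        config = ModelConfig("combined_prod", {"intrinsic": 1, "interactive": 1})
        means = []
        for sa in (1.0, 2.0, 4.0):
            land = make_uniform_landscape(6, sa=sa, ss=1.0, e=1.0)
            g = build_lattice(land, config, top_k=6)
            report = enumerate_trajectories(g, threshold=8.0)
            means.append(report.mean_terminal_drivers)
        assert means[0] > means[1] > means[2]
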