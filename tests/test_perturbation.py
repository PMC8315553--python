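"""Perturbational score, sweeps, transition graphs and rankings."""

import numpy as np
import pytest

from hopfbrain.errors import ConfigurationError, DegenerateTransitionError
from hopfbrain.perturbation import (
    DEFAULT_AMPLITUDES,
    SweepConfig,
    SweepResult,
    build_transition_graph,
    delta_gof,
    instability_index,
    perturbational_distance,
    rank_perturbation_targets,
    state_diagram,
)
from hopfbrain.io import enumerate_homotopic_pairs


class TestDeltaGoF:
    def test_no_movement_scores_one(self):
        assert delta_gof(0.9, 0.5, 0.5) == pytest.approx(1.0)

    def test_reaching_target_fit_scores_zero(self):
        assert delta_gof(0.9, 0.5, 0.9) == pytest.approx(0.0)

    def test_halfway(self):
        assert delta_gof(0.9, 0.5, 0.7) == pytest.approx(0.5)

    def test_overshoot_goes_negative(self):
        assert delta_gof(0.9, 0.5, 0.95) < 0

    def test_degenerate_denominator_raises(self):
        with pytest.raises(DegenerateTransitionError, match="exclude"):
            delta_gof(0.7, 0.7, 0.6)


def make_sweep(rng, pairs=None, amps=None, grid=None):
    pairs = pairs if pairs is not None else [(0, 1), (2, 3), (4, 5)]
    amps = np.asarray(amps if amps is not None else [0.0, 0.5, 1.0])
    if grid is None:
        grid = np.column_stack(
            [np.ones(len(pairs)), rng.uniform(-0.2, 1.2, (len(pairs), len(amps) - 1))]
        )
    return SweepResult(
        initial_state="A", target_state="B", pairs=pairs, amplitudes=amps,
        delta_gof=grid, gof_target_fit=0.9, gof_initial=0.5,
    )


class TestSweepStructure:
    def test_default_grid_is_45_by_21_for_aal(self, aal90):
        pairs = enumerate_homotopic_pairs(aal90)
        cfg = SweepConfig()
        assert len(pairs) == 45
        assert len(cfg.amplitudes) == 21
        assert cfg.amplitudes[0] == 0.0
        assert cfg.amplitudes[-1] == pytest.approx(2.0)
        assert np.allclose(np.diff(cfg.amplitudes), 0.1)

    def test_amplitudes_must_start_at_zero_increasing(self):
        with pytest.raises(ConfigurationError):
            SweepConfig(amplitudes=(0.1, 0.2))
        with pytest.raises(ConfigurationError):
            SweepConfig(amplitudes=(0.0, 0.2, 0.1))

    def test_perturbational_distance_is_grid_minimum(self, rng):
        sweep = make_sweep(rng)
        assert perturbational_distance(sweep) == sweep.delta_gof.min()
        grid = np.ones((3, 3))
        grid[1, 2] = 0.2
        assert perturbational_distance(make_sweep(rng, grid=grid)) == pytest.approx(0.2)
        assert perturbational_distance(
            make_sweep(rng, grid=np.ones((3, 3)))
        ) == pytest.approx(1.0)

    def test_distance_non_increasing_under_grid_enlargement(self, rng):
        full = make_sweep(rng, pairs=[(0, 1), (2, 3), (4, 5), (6, 7)],
                          amps=[0.0, 0.5, 1.0, 1.5])
        sub_pairs = make_sweep(rng, grid=full.delta_gof[:3])
        assert full.global_best <= sub_pairs.global_best
        sub_amps = SweepResult(
            initial_state="A", target_state="B", pairs=full.pairs,
            amplitudes=full.amplitudes[:3], delta_gof=full.delta_gof[:, :3],
            gof_target_fit=0.9, gof_initial=0.5,
        )
        assert full.global_best <= sub_amps.global_best


class TestTransitionGraph:
    def test_all_above_threshold_gives_empty_graph(self):
        d = np.full((3, 3), 0.5)
        g = build_transition_graph(d, ["a", "b", "c"], 0.3)
        assert g.edges == []

    def test_threshold_is_inclusive(self):
        d = np.ones((2, 2))
        d[0, 1] = 0.3
        g = build_transition_graph(d, ["a", "b"], 0.3)
        assert g.edges == [("a", "b")]

    def test_matches_elementwise_oracle_on_random_matrices(self, rng):
        states = [f"s{i}" for i in range(6)]
        for _ in range(100):
            d = rng.uniform(0, 1, (6, 6))
            thr = rng.uniform(0.2, 0.8)
            g = build_transition_graph(d, states, thr)
            expected = {
                (states[i], states[j])
                for i in range(6) for j in range(6)
                if i != j and d[i, j] <= thr
            }
            assert set(g.edges) == expected
            deg = instability_index(g)
            for i, s in enumerate(states):
                row = sum(1 for j in range(6) if j != i and d[i, j] <= thr)
                assert deg[s] == row

    def test_star_graph_out_degrees(self):
        d = np.ones((4, 4))
        d[0, 1:] = 0.1
        g = build_transition_graph(d, list("wxyz"), 0.3)
        assert instability_index(g) == {"w": 3, "x": 0, "y": 0, "z": 0}

    def test_non_square_rejected(self):
        with pytest.raises(ConfigurationError):
            build_transition_graph(np.ones((2, 3)), ["a", "b"])


class TestRankPerturbationTargets:
    def test_single_transition_equals_its_own_ranks(self, rng):
        sweep = make_sweep(rng)
        res = rank_perturbation_targets([sweep], {("A", "B"): "increase"})
        from scipy.stats import rankdata

        assert np.allclose(res["increase"]["average_rank"],
                           rankdata(sweep.best_per_pair))

    def test_reversed_rankings_average_to_midpoint(self):
        pairs = [(0, 1), (2, 3), (4, 5), (6, 7)]
        amps = [0.0, 1.0]
        up = np.column_stack([np.ones(4), np.array([0.1, 0.2, 0.3, 0.4])])
        down = np.column_stack([np.ones(4), np.array([0.4, 0.3, 0.2, 0.1])])
        s1 = SweepResult("A", "B", pairs, np.asarray(amps), up, 0.9, 0.5)
        s2 = SweepResult("B", "A", pairs, np.asarray(amps), down, 0.9, 0.5)
        res = rank_perturbation_targets(
            [s1, s2], {("A", "B"): "increase", ("B", "A"): "increase"}
        )
        assert np.allclose(res["increase"]["average_rank"], 2.5)

    def test_matches_rank_then_mean_oracle_with_ties(self, rng):
        from scipy.stats import rankdata

        pairs = [(2 * i, 2 * i + 1) for i in range(5)]
        amps = np.array([0.0, 1.0])
        for _ in range(100):
            sweeps = []
            for k in range(3):
                best = rng.choice([0.1, 0.2, 0.3, 0.4], size=5)  # ties likely
                grid = np.column_stack([np.ones(5), best])
                sweeps.append(SweepResult("A", f"T{k}", pairs, amps, grid, 0.9, 0.5))
            grouping = {("A", f"T{k}"): "decrease" for k in range(3)}
            res = rank_perturbation_targets(sweeps, grouping, top_fraction=0.4)
            expected = np.mean([rankdata(s.best_per_pair) for s in sweeps], axis=0)
            assert np.allclose(res["decrease"]["average_rank"], expected)
            order = sorted(range(5), key=lambda i: (expected[i], i))
            assert res["decrease"]["top_pairs"] == [pairs[i] for i in order[:2]]

    def test_mismatched_pair_lists_rejected(self, rng):
        s1 = make_sweep(rng)
        s2 = make_sweep(rng, pairs=[(0, 1), (2, 3)],
                        grid=np.ones((2, 3)))
        with pytest.raises(ConfigurationError, match="pair list"):
            rank_perturbation_targets(
                [s1, s2], {("A", "B"): "increase"}
            )


class TestStateDiagram:
    def test_levels_and_instability_from_fits_and_graph(self):
        from hopfbrain.fitting import FitResult

        a = {
            "W": np.zeros(4),
            "X": np.array([3.0, 4.0, 0.0, 0.0]),
            "Y": np.array([3.0, 4.0, 0.0, 0.0]),
        }
        fits = {
            s: FitResult(g_best=np.zeros(2), a_best=v, gof_best=0.9,
                         run_history=[], config={}, state_name=s)
            for s, v in a.items()
        }
        d = np.ones((3, 3))
        d[1, 0] = 0.1  # X -> W allowed
        graph = build_transition_graph(d, ["W", "X", "Y"], 0.3)
        points = {p.state: p for p in state_diagram(fits, graph,
                                                    {"X": "W", "Y": "W", "W": "W"})}
        assert points["W"].level == 0.0
        assert points["X"].level == pytest.approx(5.0)
        assert points["Y"].level == points["X"].level
        assert points["X"].instability == 1
        assert points["W"].instability == 0

    def test_missing_baseline_fit_rejected(self):
        from hopfbrain.fitting import FitResult

        fits = {"X": FitResult(np.zeros(2), np.zeros(4), 0.9, [], {}, "X")}
        graph = build_transition_graph(np.ones((1, 1)) * 0, ["X"], 0.3)
        with pytest.raises(ConfigurationError, match="baseline"):
            state_diagram(fits, graph, {"X": "W"})
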