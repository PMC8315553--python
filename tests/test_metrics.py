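"""Descriptive distance metrics and distance-matrix post-processing."""

import numpy as np
import pytest

from hopfbrain.core import FCMatrix, StateDataset
from hopfbrain.errors import ConfigurationError
from hopfbrain.metrics import (
    DistanceMatrix,
    RandomForestConfig,
    classification_distance,
    connectivity_correlation_distance,
    difference_correlation,
    fc_difference,
    model_parameter_distance,
    top_fraction_graph,
    zscore_distance_matrix,
)
from tests_support import random_fc_matrix


class TestFCDifference:
    def test_identical_inputs_give_zero_difference(self, rng):
        fc = FCMatrix(random_fc_matrix(rng, 10))
        diff, top, bottom = fc_difference(fc, fc, extreme_fraction=0.1)
        assert np.allclose(diff.values, 0)
        # all-tied edges: deterministic index tie-break
        assert top[0] == (0, 1)
        assert bottom[0] == (0, 1)

    def test_raised_edge_heads_top_list(self, rng):
        base = random_fc_matrix(rng, 10)
        mod = base.copy()
        mod[2, 7] = mod[7, 2] = np.clip(mod[2, 7] + 0.5, -1, 1)
        diff, top, _ = fc_difference(FCMatrix(mod), FCMatrix(base))
        assert top[0] == (2, 7)

    def test_counts_and_order_match_sort_oracle(self, rng):
        a, b = random_fc_matrix(rng, 90), random_fc_matrix(rng, 90)
        diff, top, bottom = fc_difference(FCMatrix(a), FCMatrix(b), 0.05)
        assert len(top) == len(bottom) == 200  # floor(0.05 * 4005)
        iu, ju = np.triu_indices(90, k=1)
        vals = diff.values[iu, ju]
        order = np.argsort(-vals, kind="stable")
        expected_top = {(int(iu[e]), int(ju[e])) for e in order[:200]}
        assert set(top) == expected_top


class TestDifferenceCorrelation:
    def test_self_is_one_negation_is_minus_one(self, rng):
        d = FCMatrix(random_fc_matrix(rng, 12) - np.eye(12), kind="difference")
        neg = FCMatrix(-d.values, kind="difference")
        assert difference_correlation(d, d) == pytest.approx(1.0)
        assert difference_correlation(d, neg) == pytest.approx(-1.0)

    def test_matches_flattened_pearson_oracle(self, rng):
        a = FCMatrix(random_fc_matrix(rng, 15) - np.eye(15), kind="difference")
        b = FCMatrix(random_fc_matrix(rng, 15) - np.eye(15), kind="difference")
        iu, ju = np.triu_indices(15, k=1)
        expected = np.corrcoef(a.values[iu, ju], b.values[iu, ju])[0, 1]
        assert difference_correlation(a, b) == pytest.approx(expected, abs=1e-10)


class TestConnectivityCorrelationDistance:
    def test_identical_changes_give_zero_distance(self, rng):
        wake = FCMatrix(random_fc_matrix(rng, 12))
        state = FCMatrix(random_fc_matrix(rng, 12))
        d, indicator, r, _ = connectivity_correlation_distance(state, wake, state, wake)
        assert d == 0.0
        assert indicator.all()
        assert np.allclose(r, 1.0)

    def test_negated_changes_also_give_zero_distance(self, rng):
        """The indicator uses |R|, so perfectly anti-correlated profiles
        count as similar."""
        wake = FCMatrix(random_fc_matrix(rng, 12))
        state = FCMatrix(random_fc_matrix(rng, 12))
        # construct fc_2 - wake_2 = -(fc_1 - wake_1) via difference matrices
        d, _, r, _ = connectivity_correlation_distance(
            FCMatrix(state.values - wake.values, kind="difference"),
            FCMatrix(np.zeros((12, 12)), kind="difference"),
            FCMatrix(wake.values - state.values, kind="difference"),
            FCMatrix(np.zeros((12, 12)), kind="difference"),
        )
        assert d == 0.0
        assert np.allclose(r, -1.0)

    def test_independent_random_states_are_distant(self, rng):
        d, *_ = connectivity_correlation_distance(
            FCMatrix(random_fc_matrix(rng, 90)), FCMatrix(random_fc_matrix(rng, 90)),
            FCMatrix(random_fc_matrix(rng, 90)), FCMatrix(random_fc_matrix(rng, 90)),
        )
        assert d >= 0.9

    def test_distance_in_unit_interval_and_symmetric(self, rng):
        mats = [FCMatrix(random_fc_matrix(rng, 12)) for _ in range(4)]
        d12, *_ = connectivity_correlation_distance(mats[0], mats[1], mats[2], mats[3])
        d21, *_ = connectivity_correlation_distance(mats[2], mats[3], mats[0], mats[1])
        assert 0.0 <= d12 <= 1.0
        assert d12 == d21


def _fc_cohorts(rng, n_subjects=12, n=20, shift=0.0, name="state"):
    """Wake/state cohorts of per-subject FC; the state class adds ``shift``
    to a fixed 10% subset of edges."""
    iu, ju = np.triu_indices(n, k=1)
    n_edges = len(iu)
    edge_rng = np.random.default_rng(999)
    idx = edge_rng.choice(n_edges, size=n_edges // 10, replace=False)
    wake_subjects, state_subjects = [], []
    for _ in range(n_subjects):
        wake_subjects.append(FCMatrix(random_fc_matrix(rng, n)))
        base = random_fc_matrix(rng, n)
        vals = base[iu, ju].copy()
        vals[idx] = np.clip(vals[idx] + shift, -1, 1)
        mod = np.eye(n)
        mod[iu, ju] = vals
        mod[ju, iu] = vals
        state_subjects.append(FCMatrix(mod))
    wake = StateDataset("W", wake_subjects)
    state = StateDataset(name, state_subjects, wake_baseline=wake)
    return state


@pytest.fixture(scope="module")
def rf_small():
    return RandomForestConfig(n_estimators=60)


class TestClassificationDistance:
    def test_separable_cohorts_classify_well(self, rf_small):
        rng = np.random.default_rng(4)
        cohort = _fc_cohorts(rng, shift=0.8)
        rep = classification_distance(cohort, rf_config=rf_small,
                                      n_permutations=0, seed=1, band=None)
        assert rep.auc_mean >= 0.95
        assert rep.distance <= 0.05

    def test_transfer_to_same_pattern_matches_self(self, rf_small):
        rng = np.random.default_rng(5)
        train = _fc_cohorts(rng, shift=0.8, name="A")
        evalc = _fc_cohorts(rng, shift=0.8, name="B")
        rep_self = classification_distance(train, rf_config=rf_small,
                                           n_permutations=0, seed=2, band=None)
        rep_tr = classification_distance(train, evalc, rf_config=rf_small,
                                         n_permutations=0, seed=2, n_repeats=3,
                                         band=None)
        assert abs(rep_tr.auc_mean - rep_self.auc_mean) <= 0.1

    def test_permutation_null_centers_on_chance(self, rf_small):
        rng = np.random.default_rng(6)
        train = _fc_cohorts(rng, shift=0.8, name="A")
        evalc = _fc_cohorts(rng, shift=0.8, name="B")
        rep = classification_distance(train, evalc, rf_config=rf_small,
                                      n_permutations=30, seed=3, n_repeats=2,
                                      band=None)
        lo, hi = np.percentile(rep.null_aucs, [2.5, 97.5])
        assert lo <= 0.5 <= hi
        assert 0 < rep.p_value <= 1
        assert rep.p_value < 0.2  # real signal beats the null

    def test_too_few_subjects_rejected(self, rng, rf_small):
        cohort = _fc_cohorts(rng, n_subjects=3)
        with pytest.raises(ConfigurationError, match="5 subjects"):
            classification_distance(cohort, rf_config=rf_small, band=None)

    def test_missing_baseline_rejected(self, rng, rf_small):
        ds = StateDataset("X", [FCMatrix(random_fc_matrix(rng, 8))])
        with pytest.raises(ConfigurationError, match="baseline"):
            classification_distance(ds, rf_config=rf_small, band=None)


class TestModelParameterDistance:
    def test_identity_and_pythagoras(self):
        assert model_parameter_distance(np.ones(5), np.ones(5)) == 0.0
        assert model_parameter_distance(np.zeros(2), np.array([3.0, 4.0])) == 5.0

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(50):
            a, b, c = rng.standard_normal((3, 8))
            dab = model_parameter_distance(a, b)
            assert dab == model_parameter_distance(b, a)
            assert dab >= 0
            assert dab <= model_parameter_distance(a, c) + model_parameter_distance(c, b) + 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            model_parameter_distance(np.zeros(3), np.zeros(4))


class TestZscoreDistanceMatrix:
    def test_simple_population_zscores(self):
        v = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        dm = DistanceMatrix(["a", "b", "c"], v, "model_parameter")
        z = zscore_distance_matrix(dm)
        expected = (np.array([1.0, 2.0, 3.0]) - 2.0) / np.std([1, 2, 3])
        iu, ju = np.triu_indices(3, k=1)
        assert np.allclose(z.values[iu, ju], expected)
        assert np.allclose(np.diag(z.values), 0.0)

    def test_location_invariance(self, rng):
        from tests_support import random_distance_matrix

        states = list("abcd")
        v = random_distance_matrix(rng, states)
        dm = DistanceMatrix(states, v, "correlation")
        shifted = v + 5.0
        np.fill_diagonal(shifted, 0.0)
        z1 = zscore_distance_matrix(dm).values
        z2 = zscore_distance_matrix(DistanceMatrix(states, shifted, "correlation")).values
        iu, ju = np.triu_indices(4, k=1)
        assert np.allclose(z1[iu, ju], z2[iu, ju], atol=1e-10)

    def test_matches_mean_sd_oracle_symmetric_and_asymmetric(self, rng):
        from tests_support import random_distance_matrix

        states = list("abcde")
        for symmetric in (True, False):
            for _ in range(100):
                v = random_distance_matrix(rng, states, symmetric=symmetric)
                dm = DistanceMatrix(states, v, "classification", symmetric=symmetric)
                z = zscore_distance_matrix(dm)
                if symmetric:
                    idx = np.triu_indices(5, k=1)
                else:
                    idx = np.nonzero(~np.eye(5, dtype=bool))
                vals = v[idx]
                assert np.allclose(z.values[idx], (vals - vals.mean()) / vals.std())
                assert abs(z.values[idx].mean()) < 1e-10
                assert z.values[idx].std() == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        v = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ConfigurationError, match="variance"):
            zscore_distance_matrix(DistanceMatrix(list("abc"), v, "correlation"))


class TestTopFractionGraph:
    def test_quarter_of_eight_pairs_is_two_edges(self, rng):
        from tests_support import random_distance_matrix

        # 8 unique pairs need a non-square count; use asymmetric 3x3 (6 pairs)
        states = list("abcd")  # 6 unique pairs, fraction 1/3 -> 2 edges
        v = random_distance_matrix(rng, states)
        dm = DistanceMatrix(states, v, "correlation")
        edges = top_fraction_graph(dm, fraction=1 / 3)
        assert len(edges) == 2

    def test_fraction_one_returns_complete_graph(self, rng):
        from tests_support import random_distance_matrix

        states = list("abcd")
        dm = DistanceMatrix(states, random_distance_matrix(rng, states), "correlation")
        assert len(top_fraction_graph(dm, 1.0)) == 6

    def test_matches_sort_and_cut_oracle(self, rng):
        from tests_support import random_distance_matrix

        states = list("abcdef")
        for _ in range(100):
            v = random_distance_matrix(rng, states)
            dm = DistanceMatrix(states, v, "model_parameter")
            edges = top_fraction_graph(dm, 0.25)
            iu, ju = np.triu_indices(6, k=1)
            order = sorted(range(len(iu)), key=lambda e: (v[iu[e], ju[e]], iu[e], ju[e]))
            expected = [(states[iu[e]], states[ju[e]]) for e in order[: int(0.25 * len(iu))]]
            assert edges == expected
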