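import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apneafuse.base_models import TrainingContract
from apneafuse.fusion import (
    FusionResult,
    FuzzyMeasure,
    MlpStacker,
    choquet_fuse,
    entropy,
    majority_vote,
    measure_of_subset,
    singleton_measures,
    solve_lambda,
    sum_rule,
)
from apneafuse.synthetic import generate_score_matrices


def choquet_brute_force(scores: np.ndarray, normalize: bool) -> np.ndarray:
    """Independent oracle: Choquet as the level-set integral ∫ g({s ≥ t}) dt,
    with subset measures from explicit power-set enumeration."""
    l, k = scores.shape
    g = singleton_measures(scores, normalize=normalize)
    lam = solve_lambda(g)
    meas = {
        frozenset(sub): measure_of_subset(sub, g, lam)
        for r in range(l + 1)
        for sub in itertools.combinations(range(l), r)
    }
    out = np.zeros(k)
    for i in range(k):
        s = scores[:, i]
        thresholds = np.concatenate([[0.0], np.sort(s)])
        total = 0.0
        for a, b in zip(thresholds[:-1], thresholds[1:]):
            level_set = frozenset(np.nonzero(s >= b - 1e-15)[0].tolist())
            total += (b - a) * meas[level_set]
        out[i] = total
    return out


class TestEntropy:
    def test_uniform_two_class_vector_attains_maximum_one(self):
        assert entropy([0.5, 0.5]) == 1.0

    def test_one_hot_has_zero_entropy(self):
        assert entropy([1.0, 0.0]) == 0.0

    def test_skewed_vector_value(self):
        # -0.9*log2(0.9) - 0.1*log2(0.1), evaluated independently
        assert entropy([0.9, 0.1]) == pytest.approx(0.4690, abs=1e-4)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            entropy([1.1, -0.1])


class TestSingletonMeasures:
    def test_confident_and_uncertain_mix(self):
        scores = np.array([[1, 0], [1, 0], [0.5, 0.5]], dtype=float)
        np.testing.assert_allclose(
            singleton_measures(scores, normalize=True), [0.5, 0.5, 0.0]
        )
        np.testing.assert_allclose(
            singleton_measures(scores, normalize=False), [1.0, 1.0, 0.0]
        )

    def test_all_uniform_rows_fall_back_to_equal_weights(self):
        scores = np.full((3, 2), 0.5)
        np.testing.assert_allclose(singleton_measures(scores), [1 / 3] * 3)

    def test_normalized_densities_sum_to_one(self, rng):
        scores = rng.dirichlet([1, 1], size=4)
        assert singleton_measures(scores).sum() == pytest.approx(1.0)


class TestLambdaSolver:
    def test_densities_summing_to_one_give_additive_measure(self):
        assert solve_lambda([0.5, 0.5]) == 0.0
        assert solve_lambda([0.2, 0.3, 0.5]) == 0.0

    def test_subadditive_densities_closed_form(self):
        # product form reduces to 0.09λ² - 0.4λ = 0 → λ = 0.4/0.09
        assert solve_lambda([0.3, 0.3]) == pytest.approx(4.4444, abs=1e-3)

    def test_superadditive_densities_closed_form(self):
        # 0.36λ² + 0.2λ = 0 → λ = -0.2/0.36
        assert solve_lambda([0.6, 0.6]) == pytest.approx(-0.5556, abs=1e-3)

    def test_out_of_range_density_rejected(self):
        with pytest.raises(ValueError):
            solve_lambda([0.5, 1.2])

    @pytest.mark.parametrize("g", [[0.3, 0.3], [0.6, 0.6], [0.1, 0.2, 0.3], [0.5, 0.4, 0.7]])
    def test_full_set_measure_is_one(self, g):
        lam = solve_lambda(g)
        assert lam > -1
        assert measure_of_subset(range(len(g)), g, lam) == pytest.approx(1.0, abs=1e-8)


class TestSubsetMeasure:
    def test_pair_measure_hand_evaluation(self):
        lam = solve_lambda([0.3, 0.3])
        got = measure_of_subset([0, 1], [0.3, 0.3], lam)
        assert got == pytest.approx(0.3 + 0.3 + lam * 0.09, abs=1e-9)
        assert got == pytest.approx(1.0, abs=1e-3)

    def test_empty_set_and_singletons(self):
        g = [0.2, 0.5]
        lam = solve_lambda(g)
        assert measure_of_subset([], g, lam) == 0.0
        assert measure_of_subset([0], g, lam) == pytest.approx(0.2)
        assert measure_of_subset([1], g, lam) == pytest.approx(0.5)

    def test_order_independence(self):
        g = [0.2, 0.3, 0.4]
        lam = solve_lambda(g)
        values = {
            round(measure_of_subset(perm, g, lam), 12)
            for perm in itertools.permutations([0, 1, 2])
        }
        assert len(values) == 1

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            measure_of_subset([0, 5], [0.2, 0.3], 0.0)

    def test_monotone_under_subset_inclusion_enumerated(self, rng):
        """g(A) ≤ g(B) whenever A ⊆ B, enumerated for up to 4 classifiers."""
        for l in (2, 3, 4):
            for _ in range(25):
                g = rng.uniform(0.05, 0.95, size=l)
                lam = solve_lambda(g)
                meas = {
                    frozenset(sub): measure_of_subset(sub, g, lam)
                    for r in range(l + 1)
                    for sub in itertools.combinations(range(l), r)
                }
                for a, va in meas.items():
                    for b, vb in meas.items():
                        if a <= b:
                            assert va <= vb + 1e-10

    def test_fuzzy_measure_object_boundary_conditions(self):
        fm = FuzzyMeasure(densities=np.array([0.3, 0.3, 0.3]))
        assert fm([]) == 0.0
        assert fm([0, 1, 2]) == pytest.approx(1.0, abs=1e-8)


class TestChoquet:
    def test_additive_case_equals_weighted_mean(self):
        # λ = 0 (densities sum to 1): Choquet is the plain weighted mean
        g = np.array([0.5, 0.3, 0.2])
        lam = 0.0
        s = np.array([0.9, 0.6, 0.2])
        order = np.argsort(-s)
        prev, total, acc = 0.0, 0.0, 0.0
        for j in order:
            acc = acc + g[j] + lam * acc * g[j]
            total += s[j] * (acc - prev)
            prev = acc
        assert total == pytest.approx(0.9 * 0.5 + 0.6 * 0.3 + 0.2 * 0.2, abs=1e-12)

    def test_idempotence_when_all_classifiers_agree(self):
        row = np.array([0.7, 0.3])
        scores = np.tile(row, (3, 1))
        for normalize in (True, False):
            fused = choquet_fuse(scores, normalize=normalize).scores[0]
            np.testing.assert_allclose(fused, row, atol=1e-9)

    def test_betweenness_bounds(self, rng):
        for _ in range(50):
            scores = rng.dirichlet([1, 1], size=3)
            fused = choquet_fuse(scores, normalize=False).scores[0]
            for i in range(2):
                assert scores[:, i].min() - 1e-12 <= fused[i] <= scores[:, i].max() + 1e-12

    @pytest.mark.parametrize("normalize", [True, False])
    def test_matches_brute_force_enumeration(self, rng, normalize):
        for l in (2, 3, 4):
            for _ in range(100):
                scores = rng.dirichlet(np.ones(2) * rng.uniform(0.3, 5.0), size=l)
                fast = choquet_fuse(scores, normalize=normalize).scores[0]
                slow = choquet_brute_force(scores, normalize)
                np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_normalized_path_equals_entropy_weighted_mean(self, rng):
        """With density normalisation, λ = 0 and the integral is a weighted mean."""
        scores = rng.dirichlet([2, 1], size=3)
        g = singleton_measures(scores, normalize=True)
        expected = g @ scores
        np.testing.assert_allclose(choquet_fuse(scores).scores[0], expected, atol=1e-12)

    def test_equal_entropies_rank_like_sum_rule(self):
        # every classifier equally confident -> same ranking as the sum rule
        scores = np.array([[0.8, 0.2], [0.2, 0.8], [0.8, 0.2]])
        assert (
            choquet_fuse(scores).predictions[0]
            == sum_rule(scores).predictions[0]
        )


class TestDecisionRules:
    def test_majority_simple_cases(self):
        a = np.array([[0.9, 0.1], [0.8, 0.2], [0.2, 0.8]])  # A, A, N -> A (idx 0)
        assert majority_vote(a).predictions[0] == 0
        n = np.array([[0.1, 0.9], [0.2, 0.8], [0.4, 0.6]])
        assert majority_vote(n).predictions[0] == 1

    def test_majority_tie_broken_by_sum_rule(self):
        # 2-2 vote; summed scores favour class 1
        scores = np.array([[0.6, 0.4], [0.55, 0.45], [0.1, 0.9], [0.2, 0.8]])
        assert majority_vote(scores).predictions[0] == 1
        assert sum_rule(scores).predictions[0] == 1

    def test_sum_rule_hand_example(self):
        scores = np.array([[0.6, 0.4], [0.55, 0.45], [0.2, 0.8]])
        result = sum_rule(scores)
        np.testing.assert_allclose(result.scores[0], [1.35, 1.65])
        assert result.predictions[0] == 1

    def test_sum_rule_identical_one_hot_rows(self):
        scores = np.tile([0.0, 1.0], (3, 1))
        assert sum_rule(scores).predictions[0] == 1

    def test_sum_rule_uniform_tie_goes_to_lowest_class_index(self):
        scores = np.full((3, 2), 0.5)
        assert sum_rule(scores).predictions[0] == 0

    def test_non_finite_scores_rejected(self):
        scores = np.array([[np.nan, 1.0]])
        with pytest.raises(ValueError):
            sum_rule(scores)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(np.zeros((0, 0, 2)))


class TestMlpStacker:
    def test_predict_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            MlpStacker().predict(np.full((1, 3, 2), 0.5))

    def test_feature_dimension_mismatch_rejected(self, rng):
        stacker = MlpStacker()
        probs, labels = generate_score_matrices(100, 3, 2, [0.9] * 3, seed=0)
        stacker.fit(probs, labels, TrainingContract(epochs=1, seed=0))
        with pytest.raises(ValueError):
            stacker.predict(np.full((5, 2, 2), 0.5))

    def test_xor_score_pattern_needs_hidden_layer(self, rng):
        """Class = agreement parity of two classifiers: linearly inseparable,
        solvable through the 16-unit hidden layer."""
        n = 2000
        bits = rng.integers(0, 2, size=(n, 2))
        labels = bits[:, 0] ^ bits[:, 1]
        conf = 0.9
        probs = np.empty((n, 2, 2))
        for j in range(2):
            probs[:, j, 0] = np.where(bits[:, j] == 1, conf, 1 - conf)
            probs[:, j, 1] = 1 - probs[:, j, 0]
        stacker = MlpStacker()
        stacker.fit(probs[:1000], labels[:1000], TrainingContract(epochs=60, seed=3))
        acc = (stacker.predict(probs[1000:]).predictions == labels[1000:]).mean()
        assert acc >= 0.9


class TestFusionBeatsBestBase:
    def test_each_rule_at_least_matches_best_classifier(self):
        """Fusing 0.75/0.80/0.85-accurate classifiers should not fall more
        than one point below the best of them."""
        probs, labels = generate_score_matrices(
            20000, 3, 2, [0.75, 0.80, 0.85], sharpness=12, seed=7
        )
        best_base = max(
            (probs[:, j].argmax(axis=1) == labels).mean() for j in range(3)
        )
        results = {
            "majority": majority_vote(probs),
            "sum": sum_rule(probs),
            "choquet": choquet_fuse(probs),
        }
        stacker = MlpStacker()
        stacker.fit(probs[:10000], labels[:10000], TrainingContract(epochs=10, seed=0))
        accs = {name: (r.predictions == labels).mean() for name, r in results.items()}
        accs["mlp"] = (stacker.predict(probs[10000:]).predictions == labels[10000:]).mean()
        for name, acc in accs.items():
            assert acc >= best_base - 0.01, (name, acc, best_base)


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=1.0)),
        min_size=2,
        max_size=4,
    )
)
def test_lambda_solution_always_normalises_the_measure(densities):
    """For any admissible densities the solved λ makes g(X) = 1 (or the
    measure is degenerate with at most one active classifier)."""
    lam = solve_lambda(densities)
    assert lam > -1
    active = [d for d in densities if d > 0]
    if len(active) > 1:
        full = measure_of_subset(range(len(densities)), densities, lam)
        assert full == pytest.approx(1.0, abs=1e-8)
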