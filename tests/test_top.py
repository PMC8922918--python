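import numpy as np
import pytest

from topsel import PredictionSet, TraitWeights
from topsel.top import (
    TOPModel,
    learn_weights,
    rank_candidates,
    similarity_scores,
    top_negative_log_likelihood,
    weighted_l1_distance,
)


def _random_prediction_set(rng, n=12, d=4, noise=0.3):
    obs = rng.standard_normal((n, d))
    pred = obs + noise * rng.standard_normal((n, d))
    return PredictionSet([f"h{i:03d}" for i in range(n)],
                         [f"t{j}" for j in range(d)], obs, pred)


class TestDistance:
    def test_hand_case(self):
        assert weighted_l1_distance([1, 2], [0, 0], [1, 2]) == pytest.approx(5.0)

    def test_zero_at_equality(self, rng):
        y = rng.standard_normal(6)
        assert weighted_l1_distance(y, y, rng.standard_normal(6)) == 0.0

    def test_matches_loop_oracle(self, rng):
        y, yhat, w = (rng.standard_normal(6) for _ in range(3))
        oracle = sum(w[i] * abs(y[i] - yhat[i]) for i in range(6))
        assert weighted_l1_distance(y, yhat, w) == pytest.approx(oracle, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            weighted_l1_distance([1.0], [1.0, 2.0], [1.0, 1.0])


class TestSimilarity:
    def test_two_candidate_closed_form(self):
        # distances 0 and ln 3 give scores 0.75 / 0.25
        target = np.array([0.0])
        preds = np.array([[0.0], [np.log(3.0)]])
        scores = similarity_scores(target, preds, np.array([1.0]))
        np.testing.assert_allclose(scores, [0.75, 0.25], rtol=1e-12)

    def test_zero_weights_uniform(self, rng):
        scores = similarity_scores(rng.standard_normal(3),
                                   rng.standard_normal((7, 3)), np.zeros(3))
        np.testing.assert_allclose(scores, np.full(7, 1 / 7), rtol=1e-12)

    def test_sums_to_one_and_permutation_equivariant(self, rng):
        target = rng.standard_normal(4)
        preds = rng.standard_normal((9, 4))
        w = np.abs(rng.standard_normal(4))
        s = similarity_scores(target, preds, w)
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        perm = rng.permutation(9)
        np.testing.assert_allclose(similarity_scores(target, preds[perm], w), s[perm])

    def test_overflow_safe(self):
        s = similarity_scores(np.array([0.0]), np.array([[0.0], [1e6]]), np.array([1.0]))
        assert np.isfinite(s).all() and s[0] == pytest.approx(1.0)


class TestLikelihood:
    def test_identical_rows_give_uniform(self, rng):
        n, d = 8, 3
        row = rng.standard_normal(d)
        ps = (np.tile(row, (n, 1)), np.tile(row, (n, 1)))
        value, grad = top_negative_log_likelihood(np.ones(d), ps)
        assert value == pytest.approx(n * np.log(n), rel=1e-12)

    def test_zero_weights_give_uniform(self, rng):
        ps = _random_prediction_set(rng)
        value, _ = top_negative_log_likelihood(np.zeros(4), ps)
        assert value == pytest.approx(12 * np.log(12), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        ps = _random_prediction_set(rng, n=8, d=4)
        w = rng.standard_normal(4) * 0.5 + 1.0
        value, grad = top_negative_log_likelihood(w, ps)
        fd = np.empty(4)
        h = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            fp, _ = top_negative_log_likelihood(w + e, ps)
            fm, _ = top_negative_log_likelihood(w - e, ps)
            fd[j] = (fp - fm) / (2 * h)
        np.testing.assert_allclose(grad, fd, rtol=1e-5, atol=1e-7)

    def test_rescaling_invariance(self, rng):
        # scaling all traits by c and weights by 1/c leaves the nll unchanged
        ps = _random_prediction_set(rng)
        w = np.abs(rng.standard_normal(4)) + 0.1
        c = 3.7
        scaled = PredictionSet(ps.individual_ids, ps.trait_names,
                               c * ps.observed, c * ps.predicted)
        v1, _ = top_negative_log_likelihood(w, ps)
        v2, _ = top_negative_log_likelihood(w / c, scaled)
        assert v1 == pytest.approx(v2, rel=1e-10)

    def test_single_individual_rejected(self, rng):
        ps = (rng.standard_normal((1, 3)), rng.standard_normal((1, 3)))
        with pytest.raises(ValueError):
            top_negative_log_likelihood(np.ones(3), ps)


class TestLearning:
    def test_final_nll_not_worse_than_start(self, small_prediction_set):
        results = TOPModel(small_prediction_set).fit()
        v0, _ = top_negative_log_likelihood(
            np.ones(small_prediction_set.n_traits), small_prediction_set
        )
        assert results.nll <= v0 + 1e-9
        assert results.converged

    def test_informative_trait_gets_larger_weight(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            n = 40
            obs = rng.standard_normal((n, 2))
            pred = np.column_stack([
                obs[:, 0] + 0.05 * rng.standard_normal(n),  # near-perfect
                rng.standard_normal(n),  # pure noise
            ])
            ps = PredictionSet([str(i) for i in range(n)], ["good", "noise"], obs, pred)
            w = learn_weights(ps)
            wins += w.w[0] > w.w[1]
        assert wins >= 15

    def test_duplicated_trait_ranking_equivalence(self, rng):
        # splitting one trait's weight across two identical columns leaves
        # every distance, hence every ranking, unchanged
        ps = _random_prediction_set(rng, n=10, d=3)
        w = learn_weights(ps)
        target = rng.standard_normal(3)
        base = rank_candidates(target, ps.predicted, w, ps.individual_ids)
        dup_pred = np.column_stack([ps.predicted, ps.predicted[:, 0]])
        dup_target = np.append(target, target[0])
        for split in (0.0, 0.4, 1.0):
            w_dup = TraitWeights(
                ["t0", "t1", "t2", "t0b"],
                [w.w[0] * (1 - split), w.w[1], w.w[2], w.w[0] * split],
            )
            dup = rank_candidates(dup_target, dup_pred, w_dup, ps.individual_ids)
            assert dup.candidate_ids == base.candidate_ids

    def test_summary_mentions_traits_and_convergence(self, small_prediction_set):
        text = TOPModel(small_prediction_set).fit().summary()
        assert "trait01" in text and "converged" in text

    def test_standardized_fit_gives_equivalent_ranking(self, small_prediction_set):
        rng = np.random.default_rng(5)
        target = small_prediction_set.observed[3]
        w_std = TOPModel(small_prediction_set, standardize=True).fit().weights
        # returned weights are on the raw trait scale
        r = rank_candidates(target, small_prediction_set.predicted, w_std,
                            small_prediction_set.individual_ids)
        assert len(r) == small_prediction_set.n_individuals


class TestRanking:
    def test_exact_match_ranks_first(self, rng):
        preds = rng.standard_normal((8, 3))
        w = np.abs(rng.standard_normal(3)) + 0.1
        r = rank_candidates(preds[4], preds, w, [f"c{i}" for i in range(8)])
        assert r.candidate_ids[0] == "c4"
        assert np.all(np.diff(r.scores) <= 0)

    def test_argmax_is_argmin_distance(self, rng):
        target = rng.standard_normal(5)
        preds = rng.standard_normal((20, 5))
        w = np.abs(rng.standard_normal(5)) + 0.01
        scores = similarity_scores(target, preds, w)
        D = np.array([weighted_l1_distance(target, p, w) for p in preds])
        assert scores.argmax() == D.argmin()

    def test_appending_candidate_preserves_pairwise_order(self, rng):
        target = rng.standard_normal(3)
        preds = rng.standard_normal((6, 3))
        w = np.abs(rng.standard_normal(3)) + 0.1
        ids = [f"c{i}" for i in range(6)]
        r1 = rank_candidates(target, preds, w, ids)
        r2 = rank_candidates(target, np.vstack([preds, rng.standard_normal(3)]),
                             w, ids + ["extra"])
        order2 = [c for c in r2.candidate_ids if c != "extra"]
        assert order2 == r1.candidate_ids

    def test_unit_rescaling_invariance(self, rng):
        target = rng.standard_normal(3)
        preds = rng.standard_normal((10, 3))
        w = np.abs(rng.standard_normal(3)) + 0.1
        ids = [f"c{i}" for i in range(10)]
        c = 4.2
        target2, preds2, w2 = target.copy(), preds.copy(), w.copy()
        target2[1] *= c
        preds2[:, 1] *= c
        w2[1] /= c
        r1 = rank_candidates(target, preds, w, ids)
        r2 = rank_candidates(target2, preds2, w2, ids)
        assert r1.candidate_ids == r2.candidate_ids

    def test_trait_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_candidates(rng.standard_normal(2), rng.standard_normal((4, 3)),
                            np.ones(3), list("abcd"))


def test_perfect_predictions_identify_everyone(rng):
    """With predicted == observed and distinct rows, learned weights push the
    self-identification rate to one."""
    from topsel import identification_rate

    n, d = 25, 3
    obs = rng.standard_normal((n, d))
    ps = PredictionSet([f"h{i}" for i in range(n)], list("abc"), obs, obs.copy())
    w = learn_weights(ps, max_iter=200)
    rate = identification_rate(ps.observed, ps.predicted, w, pool_size=n,
                               n_pools=1, seed=0, ids=ps.individual_ids)
    assert rate == 1.0
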