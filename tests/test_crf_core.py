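import itertools
import math

import numpy as np
import pytest

import chromcrf as cc
from chromcrf import crf_core
from chromcrf.feature_templates import FeatureSet, FeatureTemplate, PWM_STATE
from helpers import enumerate_posteriors, pairwise_auc, random_chain


def tiny_dataset(rng, n_chains=2, n_bins=8, n_binary=2):
    chains = []
    for _ in range(n_chains):
        chains.append(random_chain(rng, n_bins, n_binary))
    return chains


class TestForwardBackward:
    def test_uniform_model_single_bin(self, rng):
        X, _ = random_chain(rng, n_bins=1, n_binary=1)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, np.zeros(fs.k))
        post = cc.log_partition_and_posteriors(X, model)
        assert post.log_Z == pytest.approx(math.log(2))
        np.testing.assert_allclose(post.node_marginals, [[0.5, 0.5]])

    def test_uniform_model_three_bins(self, rng):
        X, _ = random_chain(rng, n_bins=3, n_binary=1)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, np.zeros(fs.k))
        post = cc.log_partition_and_posteriors(X, model)
        assert post.log_Z == pytest.approx(3 * math.log(2))
        np.testing.assert_allclose(post.node_marginals, 0.5)

    def test_single_pwm_feature_logistic(self):
        bins = cc.BinnedChromosome("c", 10, 10)
        X = cc.assemble_feature_matrix(bins, np.array([2.0]), {})
        fs = FeatureSet([FeatureTemplate(PWM_STATE, 1, i=1)], ("PWM",))
        model = cc.CRFModel(fs, np.array([1.0]))
        post = cc.log_partition_and_posteriors(X, model)
        assert post.log_Z == pytest.approx(math.log(1 + math.e**2))
        assert post.node_marginals[0, 1] == pytest.approx(
            math.e**2 / (1 + math.e**2)
        )

    def test_matches_enumeration_on_random_chains(self, rng):
        for _ in range(20):
            L = int(rng.integers(1, 11))
            X, _ = random_chain(rng, n_bins=L, n_binary=2)
            fs = cc.build_default_feature_set(X.row_names)
            w = rng.normal(size=fs.k)
            model = cc.CRFModel(fs, w)
            post = cc.log_partition_and_posteriors(X, model)
            log_z, node1 = enumerate_posteriors(X, fs, w)
            assert post.log_Z == pytest.approx(log_z, abs=1e-8)
            np.testing.assert_allclose(
                post.node_marginals[:, 1], node1, atol=1e-8
            )

    def test_posterior_normalisation_invariants(self, rng):
        X, _ = random_chain(rng, n_bins=30, n_binary=2)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, rng.normal(size=fs.k))
        post = cc.log_partition_and_posteriors(X, model)
        np.testing.assert_allclose(post.node_marginals.sum(1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            post.edge_marginals.sum((1, 2)), 1.0, atol=1e-10
        )
        # marginalising each edge reproduces the adjacent node marginals
        np.testing.assert_allclose(
            post.edge_marginals.sum(2), post.node_marginals[:-1], atol=1e-8
        )
        np.testing.assert_allclose(
            post.edge_marginals.sum(1), post.node_marginals[1:], atol=1e-8
        )
        assert post.log_Z == pytest.approx(post.log_Z_backward, abs=1e-8)

    def test_shift_invariance(self, rng):
        from chromcrf.feature_templates import compile_features

        X, _ = random_chain(rng, n_bins=15, n_binary=1)
        fs = cc.build_default_feature_set(X.row_names)
        w = rng.normal(size=fs.k)
        clique = compile_features(X, fs).clique_scores(w)
        base = crf_core._posteriors_from_clique(clique)
        shifted = crf_core._posteriors_from_clique(clique + 0.37)
        assert shifted.log_Z == pytest.approx(base.log_Z + 15 * 0.37)
        np.testing.assert_allclose(
            shifted.node_marginals, base.node_marginals, atol=1e-10
        )

    def test_non_finite_clique_rejected(self, rng):
        X, _ = random_chain(rng, n_bins=4, n_binary=1)
        fs = cc.build_default_feature_set(X.row_names)
        with pytest.raises(ValueError, match="finite"):
            cc.CRFModel(fs, np.full(fs.k, np.nan))


class TestSequenceScore:
    def test_zero_weights(self, rng):
        X, y = random_chain(rng, n_bins=6)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, np.zeros(fs.k))
        assert cc.sequence_score(X, y, model) == 0.0

    def test_exp_scores_sum_to_partition(self, rng):
        X, _ = random_chain(rng, n_bins=2)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, rng.normal(size=fs.k))
        total = sum(
            math.exp(
                cc.sequence_score(X, cc.LabelSequence("chrT", list(y)), model)
            )
            for y in itertools.product((0, 1), repeat=2)
        )
        post = cc.log_partition_and_posteriors(X, model)
        assert math.log(total) == pytest.approx(post.log_Z, abs=1e-10)

    def test_linear_in_weights(self, rng):
        X, y = random_chain(rng, n_bins=7)
        fs = cc.build_default_feature_set(X.row_names)
        w = rng.normal(size=fs.k)
        s1 = cc.sequence_score(X, y, cc.CRFModel(fs, w))
        s2 = cc.sequence_score(X, y, cc.CRFModel(fs, 2 * w))
        assert s2 == pytest.approx(2 * s1, rel=1e-12)


class TestObjective:
    def test_zero_weights_value(self, rng):
        X, y = random_chain(rng, n_bins=9)
        fs = cc.build_default_feature_set(X.row_names)
        value = cc.regularized_cll([(X, y)], fs, np.zeros(fs.k))
        assert value == pytest.approx(-9 * math.log(2))

    def test_penalty_applied_once(self, rng):
        chains = tiny_dataset(rng, n_chains=3, n_bins=5)
        fs = cc.build_default_feature_set(chains[0][0].row_names)
        w = np.zeros(fs.k)
        w[0], w[1] = 3.0, 4.0
        with_pen = cc.regularized_cll(chains, fs, w, sigma2=1.0)
        no_pen = cc.regularized_cll(chains, fs, w, sigma2=1e12)
        assert with_pen - no_pen == pytest.approx(-25.0 / 2.0, abs=1e-6)

    def test_empty_dataset(self, rng):
        fs = cc.build_default_feature_set(["PWM"])
        with pytest.raises(ValueError, match="empty"):
            cc.regularized_cll([], fs, np.zeros(fs.k))

    def test_concavity_along_random_segments(self, rng):
        chains = tiny_dataset(rng, n_chains=2, n_bins=10)
        fs = cc.build_default_feature_set(chains[0][0].row_names)
        for _ in range(5):
            w1 = rng.normal(size=fs.k)
            w2 = rng.normal(size=fs.k)
            f1 = cc.regularized_cll(chains, fs, w1)
            f2 = cc.regularized_cll(chains, fs, w2)
            mid = cc.regularized_cll(chains, fs, (w1 + w2) / 2)
            assert mid >= (f1 + f2) / 2 - 1e-9


class TestGradient:
    def test_matches_finite_differences(self, rng):
        chains = tiny_dataset(rng, n_chains=2, n_bins=8)
        fs = cc.build_default_feature_set(chains[0][0].row_names)
        w = rng.normal(size=fs.k) * 0.5
        grad = cc.cll_gradient(chains, fs, w)
        h = 1e-5
        for k in rng.choice(fs.k, size=12, replace=False):
            e = np.zeros(fs.k)
            e[k] = h
            fd = (
                cc.regularized_cll(chains, fs, w + e)
                - cc.regularized_cll(chains, fs, w - e)
            ) / (2 * h)
            assert grad[k] == pytest.approx(fd, abs=1e-6 * max(1, abs(fd)))

    def test_uniform_model_closed_form(self, rng):
        # all-zero x rows, zero weights: transition expectations are L/4
        # except the boundary clique, which is uniform over v only
        bins = cc.BinnedChromosome("c", 80, 10)
        X = cc.assemble_feature_matrix(
            bins, np.zeros(8), {"M1": np.zeros(8, dtype=int)}
        )
        y = cc.LabelSequence("c", [0, 1, 0, 0, 1, 0, 0, 0])
        fs = cc.build_default_feature_set(X.row_names)
        grad = cc.cll_gradient([(X, y)], fs, np.zeros(fs.k), sigma2=1e12)
        from chromcrf.feature_templates import TRANSITION, compile_features

        compiled = compile_features(X, fs)
        emp = compiled.empirical_counts(y.labels)
        for k, t in enumerate(fs.templates):
            if t.family != TRANSITION:
                continue
            expected_count = (8 - 1) / 4 + (0.5 if t.u == 0 else 0.0)
            assert grad[k] == pytest.approx(emp[k] - expected_count, abs=1e-10)


class TestTraining:
    def test_objective_improves_over_zero(self, rng):
        chains = tiny_dataset(rng, n_chains=3, n_bins=20)
        fs = cc.build_default_feature_set(chains[0][0].row_names)
        model = cc.train(chains, fs, max_iter=50)
        assert cc.regularized_cll(chains, fs, model.weights) >= cc.regularized_cll(
            chains, fs, np.zeros(fs.k)
        )

    def test_strong_regularization_shrinks_weights(self, rng):
        chains = tiny_dataset(rng, n_chains=2, n_bins=15)
        fs = cc.build_default_feature_set(chains[0][0].row_names)
        model = cc.train(chains, fs, sigma2=1e-6, max_iter=100)
        assert np.linalg.norm(model.weights) < 0.01

    def test_single_class_data_rejected(self, rng):
        X, _ = random_chain(rng, n_bins=10)
        y = cc.LabelSequence("chrT", np.zeros(10, dtype=int))
        fs = cc.build_default_feature_set(X.row_names)
        with pytest.raises(ValueError, match="single label class"):
            cc.train([(X, y)], fs)

    def test_training_is_deterministic(self, rng):
        chains = tiny_dataset(rng, n_chains=2, n_bins=25)
        fs = cc.build_default_feature_set(chains[0][0].row_names)
        m1 = cc.train(chains, fs, max_iter=60)
        m2 = cc.train(chains, fs, max_iter=60)
        np.testing.assert_array_equal(m1.weights, m2.weights)


class TestPrediction:
    def test_zero_weight_model_scores_half(self, rng):
        X, _ = random_chain(rng, n_bins=12)
        fs = cc.build_default_feature_set(X.row_names)
        scored = cc.predict(X, cc.CRFModel(fs, np.zeros(fs.k)))
        np.testing.assert_allclose(scored.scores, 0.5)

    def test_marginals_match_enumeration(self, rng):
        X, _ = random_chain(rng, n_bins=9)
        fs = cc.build_default_feature_set(X.row_names)
        w = rng.normal(size=fs.k)
        scored = cc.predict(X, cc.CRFModel(fs, w))
        _, node1 = enumerate_posteriors(X, fs, w)
        np.testing.assert_allclose(scored.scores, node1, atol=1e-8)

    def test_threshold_is_strict(self, rng):
        X, _ = random_chain(rng, n_bins=5)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, np.zeros(fs.k))
        assert cc.predict(X, model, threshold=1.0).calls.sum() == 0
        assert cc.predict(X, model, threshold=0.0).calls.sum() == 5
        assert cc.predict(X, model, threshold=0.5).calls.sum() == 0  # strict

    def test_sampler_frequencies_match_marginals(self, rng):
        X, _ = random_chain(rng, n_bins=6, n_binary=1)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, rng.normal(size=fs.k))
        marg = cc.predict(X, model).scores
        draws = np.array(
            [cc.sample_labels(X, model, rng).labels for _ in range(4000)]
        )
        np.testing.assert_allclose(draws.mean(0), marg, atol=0.04)


class TestModelIO:
    def test_round_trip(self, tmp_path, rng):
        X, y = random_chain(rng, n_bins=10)
        fs = cc.build_default_feature_set(X.row_names)
        model = cc.CRFModel(fs, rng.normal(size=fs.k), sigma2=3.0)
        path = tmp_path / "model.json"
        cc.save_model(model, path)
        back = cc.load_model(path)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.feature_set.templates == model.feature_set.templates
        assert back.sigma2 == 3.0
        # round-tripped model predicts identically
        np.testing.assert_array_equal(
            cc.predict(X, model).scores, cc.predict(X, back).scores
        )


class TestParameterRecoverySmall:
    def test_recovers_signs_and_separates_classes(self, rng):
        """Data sampled from a known CRF: training recovers the informative
        weight signs and the refit model ranks held-out site bins highly."""
        names = ("PWM", "M1")
        fs = cc.build_default_feature_set(names)
        true_w = np.zeros(fs.k)
        for k, t in enumerate(fs.templates):
            if t.family == PWM_STATE:
                true_w[k] = 1.2 if t.u == 1 else -1.2
            elif t.family == "TRANSITION":
                true_w[k] = 0.8 if t.u == t.v else -0.8
            elif t.family == "OCCURRENCE" and t.i == 2:
                true_w[k] = 1.0 if t.v == 1 else -1.0
        gen = cc.CRFModel(fs, true_w)
        chains = []
        for _ in range(30):
            X, _ = random_chain(rng, n_bins=60, n_binary=1, row_names=list(names))
            chains.append((X, cc.sample_labels(X, gen, rng)))
        model = cc.train(chains[:25], fs, max_iter=150)
        informative = np.abs(true_w) >= 0.5
        assert (np.sign(model.weights[informative]) == np.sign(true_w[informative])).all()
        scores = np.concatenate([cc.predict(X, model).scores for X, _ in chains[25:]])
        labels = np.concatenate([y.labels for _, y in chains[25:]])
        assert pairwise_auc(scores, labels) > 0.8
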