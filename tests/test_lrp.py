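"""Relevance propagation (z+ rule), confidence weighting, normalization."""

import numpy as np
import pytest

from strokexplain.interpretability import (
    confidence_weighted_rating,
    lrp_deep_taylor,
    normalize_importance,
)
from strokexplain.models.mlp import MLPParams


def _positive_net(rng, d=4, M=8):
    """Random rectifier network with positive weights and zero biases, so
    every activation and propagation denominator is strictly positive on
    positive inputs."""
    return MLPParams(
        W1=np.abs(rng.normal(size=(d, M))) + 0.05,
        b1=np.zeros(M),
        W2=np.abs(rng.normal(size=(M, 2))) + 0.05,
        b2=np.zeros(2),
        dropout_rate=0.0,
    )


class TestPropagation:
    def test_conservation_on_positive_weight_networks(self, rng):
        for _ in range(20):
            mlp = _positive_net(rng)
            x = np.abs(rng.normal(size=4)) + 0.01
            rel = lrp_deep_taylor(mlp, x)
            assert rel.input_relevance.sum() == pytest.approx(rel.output_relevance, abs=1e-9)
            assert rel.hidden_relevance.sum() == pytest.approx(rel.output_relevance, abs=1e-9)
            assert (rel.input_relevance >= 0).all()

    def test_single_hidden_neuron_splits_by_activation_share(self):
        """Two inputs a = (1, 3) with unit positive weights receive 1/4 and
        3/4 of the relevance — the printed rule applied directly."""
        mlp = MLPParams(
            W1=np.array([[1.0], [1.0]]),
            b1=np.zeros(1),
            W2=np.array([[0.0, 1.0]]),  # hidden -> bad-outcome neuron
            b2=np.zeros(2),
            dropout_rate=0.0,
        )
        rel = lrp_deep_taylor(mlp, np.array([1.0, 3.0]))
        np.testing.assert_allclose(
            rel.input_relevance, [0.25 * rel.output_relevance, 0.75 * rel.output_relevance],
            atol=1e-12,
        )

    def test_identity_hidden_layer_routes_all_relevance_to_one_input(self):
        """A hidden layer that copies input 1 assigns input 1 the whole
        relevance; the other inputs contribute nothing."""
        W1 = np.zeros((3, 2))
        W1[1, 0] = 1.0  # hidden unit 0 is exactly input 1
        mlp = MLPParams(
            W1=W1, b1=np.zeros(2),
            W2=np.array([[1.0, 2.0], [0.0, 0.0]]),
            b2=np.zeros(2), dropout_rate=0.0,
        )
        rel = lrp_deep_taylor(mlp, np.array([5.0, 2.0, 7.0]))
        assert rel.input_relevance[1] == pytest.approx(rel.output_relevance, abs=1e-12)
        assert rel.input_relevance[[0, 2]] == pytest.approx(0.0, abs=1e-12)

    def test_zero_denominator_neurons_propagate_nothing(self):
        """If every weight into the seeded output is negative, the z+ rule
        finds no positive path and all relevance is dropped."""
        mlp = MLPParams(
            W1=np.array([[1.0, 1.0]]), b1=np.zeros(2),
            W2=np.array([[-1.0, -2.0], [-1.0, -0.5]]),
            b2=np.zeros(2), dropout_rate=0.0,
        )
        rel = lrp_deep_taylor(mlp, np.array([2.0]), seed_output="bad")
        assert rel.input_relevance.sum() == 0.0

    def test_predicted_class_seeding_option(self, rng):
        mlp = _positive_net(rng)
        x = np.abs(rng.normal(size=4)) + 0.01
        probs = mlp.predict_proba_2(x)[0]
        rel = lrp_deep_taylor(mlp, x, seed_output="predicted")
        assert rel.output_relevance == pytest.approx(probs.max())

    def test_non_finite_activations_rejected(self):
        mlp = MLPParams(
            W1=np.array([[np.inf]]), b1=np.zeros(1),
            W2=np.ones((1, 2)), b2=np.zeros(2), dropout_rate=0.0,
        )
        with pytest.raises(ValueError, match="finite"):
            lrp_deep_taylor(mlp, np.array([1.0]))


class TestConfidenceWeighting:
    def test_theta_arithmetic(self):
        """theta = 0.9 for a correct confident positive, 0.1 for a wrong
        confident negative call."""
        rel = np.array([[1.0], [1.0]])
        out = confidence_weighted_rating(rel, np.array([0.9, 0.9]), np.array([1, 0]))
        # mean of theta * r = (0.9*1 + 0.1*1)/2
        assert out.scores[0] == pytest.approx(0.5)

    def test_unit_confidence_reduces_to_plain_average(self, rng):
        rel = rng.normal(size=(6, 3))
        y = np.array([1, 1, 1, 0, 0, 0])
        P = y.astype(float)  # theta = 1 everywhere
        out = confidence_weighted_rating(rel, P, y)
        np.testing.assert_allclose(out.scores, rel.mean(axis=0), atol=1e-12)

    def test_matches_hand_computed_weighted_mean(self, rng):
        rel = rng.normal(size=(10, 4))
        P = rng.random(10)
        y = rng.integers(0, 2, 10)
        theta = y * P + (1 - y) * (1 - P)
        expected = (theta[:, None] * rel).mean(axis=0)
        out = confidence_weighted_rating(rel, P, y)
        np.testing.assert_allclose(out.scores, expected, atol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confidence_weighted_rating(np.ones((3, 2)), np.ones(2), np.ones(3))


class TestNormalization:
    def test_unit_sum_example(self):
        out = normalize_importance([np.array([2.0, 1.0, 1.0])])
        np.testing.assert_allclose(out["mean"], [0.5, 0.25, 0.25])

    def test_absolute_values_taken_first(self):
        out = normalize_importance([np.array([-3.0, 1.0])])
        np.testing.assert_allclose(out["mean"], [0.75, 0.25])

    def test_identical_vectors_have_zero_sd(self):
        out = normalize_importance([np.array([2.0, 1.0, 1.0])] * 50)
        np.testing.assert_allclose(out["sd"], 0.0, atol=1e-15)
        assert out["n_used"] == 50

    def test_scale_coherence(self, rng):
        """Multiplying raw importances by a positive constant leaves the
        normalized ratings unchanged."""
        raw = rng.normal(size=7)
        a = normalize_importance([raw])
        b = normalize_importance([raw * 17.3])
        np.testing.assert_allclose(a["mean"], b["mean"], atol=1e-12)

    def test_all_zero_vector_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize_importance([np.zeros(3), np.array([1.0, 1.0, 0.0])])
        assert out["n_used"] == 1

    def test_every_vector_zero_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                normalize_importance([np.zeros(3)])
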