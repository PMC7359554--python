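"""F-MLP core: activations, ambiguity, fuzzy gradient descent, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmlp import (
    FcmConfig,
    FuzzyNetwork,
    TypeIISigmoid,
    ValidationError,
    decide,
    forward,
    fuzzy_gd_step,
    layer_ambiguity,
    load_model,
    save_model,
    select_variant,
    sigmoid,
    train,
    type2_sigmoid,
)
from fmlp.network import ambiguity_from_memberships, predict_proba


class TestSigmoids:
    def test_base_sigmoid_symmetry(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(2.0) + sigmoid(-2.0) == pytest.approx(1.0, abs=1e-12)
        assert sigmoid(500.0) == pytest.approx(1.0, abs=1e-12)

    def test_type2_values_at_zero(self):
        assert type2_sigmoid(0.0, TypeIISigmoid(2.0, "lower")) == pytest.approx(0.25)
        assert type2_sigmoid(0.0, TypeIISigmoid(2.0, "upper")) == pytest.approx(
            0.5**0.5
        )
        assert type2_sigmoid(0.0, TypeIISigmoid(2.0, "standard")) == 0.5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(x=st.floats(-30, 30, allow_nan=False))
    def test_lower_below_standard_below_upper(self, x):
        """The type-II pair brackets the base sigmoid for alpha > 1."""
        lo = type2_sigmoid(x, TypeIISigmoid(2.0, "lower"))
        mid = sigmoid(x)
        up = type2_sigmoid(x, TypeIISigmoid(2.0, "upper"))
        assert lo <= mid <= up
        assert 0.0 <= lo and up <= 1.0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            TypeIISigmoid(alpha=-1.0, variant="standard")
        with pytest.raises(ValidationError):
            TypeIISigmoid(alpha=1.0, variant="lower")

    def test_derivative_matches_finite_differences(self):
        xs = np.linspace(-4, 4, 17)
        h = 1e-6
        for variant in ("lower", "upper", "standard"):
            act = TypeIISigmoid(2.0, variant)
            num = (act(xs + h) - act(xs - h)) / (2 * h)
            assert np.allclose(act.derivative(xs), num, atol=1e-7)


class TestLayerAmbiguity:
    def test_crisp_and_ambiguous_limits(self):
        assert ambiguity_from_memberships(np.array([[0.5, 0.5]] * 4)) == 0.0
        assert ambiguity_from_memberships(np.array([[1.0, 0.0]] * 4)) == 1.0

    def test_mixed_memberships_mean_square(self):
        u = np.array([[0.9, 0.1], [0.6, 0.4]])
        assert ambiguity_from_memberships(u) == pytest.approx(0.34)

    def test_two_tight_clusters_yield_high_ambiguity_factor(self):
        acts = np.vstack([np.full((10, 3), 0.1), np.full((10, 3), 0.9)])
        acts += np.random.default_rng(0).normal(0, 1e-3, acts.shape)
        amb = layer_ambiguity(acts, FcmConfig(c=2, seed=0))
        assert amb.value > 0.9

    def test_identical_rows_warn_and_return_zero(self):
        with pytest.warns(UserWarning):
            amb = layer_ambiguity(np.ones((5, 3)))
        assert amb.value == 0.0


class TestFuzzyGdStep:
    def test_zero_ambiguity_freezes_weights(self):
        w = np.array([[1.0, -2.0]])
        out = fuzzy_gd_step(w, np.array([[5.0, 5.0]]), eta=0.1, a=0.0)
        assert np.array_equal(out, w)

    def test_full_ambiguity_is_plain_gradient_descent(self):
        w = np.array([1.0])
        assert fuzzy_gd_step(w, np.array([0.5]), eta=0.001, a=1.0) == pytest.approx(
            w - 0.001 * 0.5
        )

    def test_worked_scalar_update(self):
        out = fuzzy_gd_step(np.array([1.0]), np.array([0.5]), eta=0.001, a=0.34)
        assert out[0] == pytest.approx(0.99983, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            fuzzy_gd_step(np.ones((2, 2)), np.ones((2, 3)), eta=0.1, a=0.5)


class TestForward:
    def test_all_zero_weights_force_activation_of_zero(self):
        net = FuzzyNetwork(
            layer_sizes=(2, 2, 1),
            weights=[np.zeros((2, 2)), np.zeros((2, 1))],
            biases=[np.zeros(2), np.zeros(1)],
            activation=TypeIISigmoid(2.0, "lower"),
        )
        p, _ = forward(net, np.array([3.0, -1.0]))
        assert p == pytest.approx(0.25)  # lower sigmoid at 0 = 0.5^2

    def test_matches_hand_computed_chain(self):
        """2-2-1 net evaluated against an explicit hand chain."""
        W1 = np.array([[0.2, -0.3], [0.4, 0.1]])
        b1 = np.array([0.05, -0.05])
        W2 = np.array([[0.5], [-0.25]])
        b2 = np.array([0.1])
        net = FuzzyNetwork(
            layer_sizes=(2, 2, 1), weights=[W1, W2], biases=[b1, b2]
        )
        x = np.array([1.0, 2.0])
        h = 1.0 / (1.0 + np.exp(-(x @ W1 + b1)))
        expected = 1.0 / (1.0 + np.exp(-(h @ W2 + b2)))
        p, acts = forward(net, x)
        assert p == pytest.approx(float(expected[0]), abs=1e-12)
        assert np.allclose(acts[1], h, atol=1e-12)

    def test_forward_is_deterministic(self):
        net = FuzzyNetwork.initialize(seed=11)
        x = np.array([0.3, 0.7])
        assert forward(net, x)[0] == forward(net, x)[0]

    def test_nonfinite_features_rejected(self):
        net = FuzzyNetwork.initialize(seed=0)
        with pytest.raises(ValidationError):
            forward(net, np.array([np.nan, 1.0]))


class TestTraining:
    def test_zero_forced_ambiguity_leaves_weights_bit_identical(
        self, separable_features
    ):
        X, y = separable_features
        net = FuzzyNetwork.initialize(seed=4, epochs=3)
        trained = train(net, X, y, mode="fuzzy", force_ambiguity=0.0)
        for w0, w1 in zip(net.weights, trained.weights):
            assert np.array_equal(w0, w1)
        for b0, b1 in zip(net.biases, trained.biases):
            assert np.array_equal(b0, b1)

    def test_fuzzy_with_unit_ambiguity_reproduces_standard_trajectory(
        self, separable_features
    ):
        """Forcing a=1 with the plain sigmoid collapses fuzzy training onto
        ordinary backpropagation, weight for weight."""
        X, y = separable_features
        net = FuzzyNetwork.initialize(seed=4, epochs=7, eta=0.05)
        standard = train(net, X, y, mode="standard")
        reduced = train(net, X, y, mode="fuzzy", force_ambiguity=1.0)
        for w_s, w_r in zip(standard.weights, reduced.weights):
            assert np.allclose(w_s, w_r, atol=1e-12)

    def test_training_reaches_high_accuracy_on_separable_data(
        self, separable_features
    ):
        X, y = separable_features
        mu, sd = X.mean(axis=0), X.std(axis=0)
        Xz = (X - mu) / sd
        for mode in ("standard", "fuzzy"):
            net = FuzzyNetwork.initialize(seed=1, epochs=300, eta=1.0)
            trained = train(net, Xz, y, mode=mode)
            probs = predict_proba(trained, Xz)
            acc = np.mean(decide(probs).decisions == y)
            assert acc >= 0.9, f"{mode} training accuracy {acc}"

    def test_seeded_training_is_deterministic(self, separable_features):
        X, y = separable_features
        runs = []
        for _ in range(2):
            net = FuzzyNetwork.initialize(seed=9, epochs=3, eta=0.5)
            runs.append(train(net, X, y, mode="fuzzy"))
        for w0, w1 in zip(runs[0].weights, runs[1].weights):
            assert np.array_equal(w0, w1)

    def test_single_class_labels_rejected(self):
        net = FuzzyNetwork.initialize(seed=0)
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValidationError):
            train(net, X, np.ones(6))


class TestDecide:
    def test_mean_threshold_and_strict_rule(self):
        ps = decide([0.9, 0.5, 0.1])
        assert ps.threshold == pytest.approx(0.5)
        # boundary p == threshold goes to irregular
        assert ps.decisions.tolist() == [1, 0, 0]
        assert ps.labels == ["regular", "irregular", "irregular"]

    def test_all_equal_probabilities_are_all_irregular(self):
        assert decide([0.7, 0.7, 0.7]).decisions.tolist() == [0, 0, 0]

    def test_single_sample_is_irregular(self):
        ps = decide([0.8])
        assert ps.threshold == 0.8
        assert ps.decisions.tolist() == [0]

    def test_empty_or_invalid_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            decide([])
        with pytest.raises(ValidationError):
            decide([0.5, 1.2])


class TestSelectVariant:
    @pytest.mark.parametrize(
        "lo,up,tag,acc",
        [(95.2, 90.3, "lower", 95.2), (50, 50, "lower", 50), (10, 90, "upper", 90)],
    )
    def test_max_accuracy_selection_with_lower_tie_break(self, lo, up, tag, acc):
        assert select_variant(lo, up) == (tag, acc)

    def test_out_of_range_accuracy_rejected(self):
        with pytest.raises(ValidationError):
            select_variant(101, 50)


def test_model_json_roundtrip(tmp_path):
    net = FuzzyNetwork.initialize(
        seed=2, activation=TypeIISigmoid(2.0, "upper"), eta=0.01, epochs=5
    )
    path = tmp_path / "model.json"
    save_model(net, path)
    loaded = load_model(path)
    assert loaded.layer_sizes == net.layer_sizes
    assert loaded.activation == net.activation
    assert all(np.array_equal(a, b) for a, b in zip(net.weights, loaded.weights))


def test_trained_variant_envelope_on_equal_preactivations():
    """At identical pre-activations the lower activation never exceeds the
    standard one, nor the standard the upper."""
    zs = np.linspace(-5, 5, 101)
    lo = TypeIISigmoid(2.0, "lower")(zs)
    mid = TypeIISigmoid(2.0, "standard")(zs)
    up = TypeIISigmoid(2.0, "upper")(zs)
    assert np.all(lo <= mid) and np.all(mid <= up)
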