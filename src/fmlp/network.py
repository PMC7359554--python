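"""The fuzzy multilayer perceptron (F-MLP) and its standard counterpart.

Two ideas distinguish the F-MLP from an ordinary sigmoid MLP:

* a *type-II fuzzy sigmoid* activation pair.  From the base sigmoid
  sig(x) = 1/(1+e^-x) a lower and an upper activation are built as
  sig(x)^alpha and sig(x)^(1/alpha) with alpha > 1; together they bound
  the footprint of uncertainty of the activation, and training the network
  once with each bound brackets the attainable performance.

* *fuzzy gradient descent*.  Before each weight update, every non-output
  layer's activations are clustered into two fuzzy groups with fuzzy
  c-means; the layer's ambiguity factor a = mean((u1 - u2)^2) is 0 when
  memberships are maximally ambiguous (0.5/0.5) and 1 when crisp.  The
  usual step w <- w - eta * g becomes w <- w - a * eta * g, so updates
  driven by ambiguous representations are damped and, in the limit a = 0,
  suppressed entirely.

Final class decisions use a data-derived threshold: the mean of the
predicted probabilities, with "regular" assigned only to strictly larger
probabilities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .exceptions import ValidationError
from .fcm import FcmConfig, fcm_cluster

__all__ = [
    "sigmoid",
    "TypeIISigmoid",
    "type2_sigmoid",
    "FuzzyNetwork",
    "LayerAmbiguity",
    "layer_ambiguity",
    "fuzzy_gd_step",
    "forward",
    "train",
    "PredictionSet",
    "decide",
    "select_variant",
    "save_model",
    "load_model",
]

Variant = Literal["lower", "upper", "standard"]
VARIANTS = ("lower", "upper", "standard")


def sigmoid(x):
    """Logistic function sig(x) = 1 / (1 + e^-x), saturating at 0 and 1."""
    return expit(x)


@dataclass(frozen=True)
class TypeIISigmoid:
    """Type-II sigmoid activation.

    variant selects the lower bound sig(x)^alpha, the upper bound
    sig(x)^(1/alpha) or the plain sigmoid.  For alpha > 1 the three are
    ordered lower <= standard <= upper everywhere.
    """

    alpha: float = 2.0
    variant: Variant = "standard"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if self.variant in ("lower", "upper") and self.alpha <= 1:
            raise ValidationError("lower/upper variants require alpha > 1")

    @property
    def exponent(self) -> float:
        if self.variant == "lower":
            return self.alpha
        if self.variant == "upper":
            return 1.0 / self.alpha
        return 1.0

    def __call__(self, x):
        s = expit(np.asarray(x, dtype=float))
        e = self.exponent
        return s if e == 1.0 else s**e

    def derivative(self, x):
        """d/dx sig(x)^e = e * sig(x)^(e-1) * sig(x) * (1 - sig(x))."""
        s = expit(np.asarray(x, dtype=float))
        e = self.exponent
        base = s * (1.0 - s)
        return base if e == 1.0 else e * s ** (e - 1.0) * base


def type2_sigmoid(x, s: TypeIISigmoid):
    """Evaluate the activation s at x (vectorized)."""
    return s(x)


@dataclass
class FuzzyNetwork:
    """Feed-forward network state.

    weights[l] maps layer l to layer l+1 (shape in_size x out_size);
    biases[l] is the layer l+1 bias vector.  The reference architecture
    is 2-4-2-1 with learning rate 0.001 and a single training epoch.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    eta: float = 0.001
    activation: TypeIISigmoid = field(default_factory=TypeIISigmoid)
    epochs: int = 1
    init_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValidationError("need at least an input and an output layer")
        if self.layer_sizes[-1] != 1:
            raise ValidationError("output layer must have exactly one neuron")
        expected = list(zip(self.layer_sizes[:-1], self.layer_sizes[1:]))
        got = [w.shape for w in self.weights]
        if got != expected:
            raise ValidationError(f"weight shapes {got} != layer plan {expected}")
        if self.eta <= 0:
            raise ValidationError("learning rate eta must be > 0")

    @classmethod
    def initialize(
        cls,
        layer_sizes: Sequence[int] = (2, 4, 2, 1),
        *,
        eta: float = 0.001,
        activation: TypeIISigmoid | None = None,
        epochs: int = 1,
        seed: int = 0,
    ) -> "FuzzyNetwork":
        """Seeded init: weights uniform on (-0.5, 0.5), biases zero."""
        rng = np.random.default_rng(seed)
        sizes = tuple(int(s) for s in layer_sizes)
        weights = [
            rng.uniform(-0.5, 0.5, size=(a, b))
            for a, b in zip(sizes[:-1], sizes[1:])
        ]
        biases = [np.zeros(b) for b in sizes[1:]]
        return cls(
            layer_sizes=sizes,
            weights=weights,
            biases=biases,
            eta=eta,
            activation=activation or TypeIISigmoid(),
            epochs=epochs,
            init_seed=seed,
        )

    def copy(self) -> "FuzzyNetwork":
        return replace(
            self,
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
        )


@dataclass
class LayerAmbiguity:
    """Per-layer ambiguity scalar a = mean_j (u1j - u2j)^2 in [0, 1]."""

    value: float
    memberships: np.ndarray | None = None


def layer_ambiguity(
    activations: np.ndarray, cfg: FcmConfig | None = None
) -> LayerAmbiguity:
    """Cluster a layer's activation table into two fuzzy groups and reduce
    the memberships to a single ambiguity scalar.

    Rows are the clustered objects (by default one per training sample);
    a = 0 means every object sits exactly between the two clusters, a = 1
    means every object belongs crisply to one of them.  If all rows are
    identical the clusters are indistinct and a = 0 is returned with a
    warning.
    """
    A = np.asarray(activations, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.shape[0] < 2:
        raise ValidationError("need at least 2 objects to measure ambiguity")
    cfg = cfg or FcmConfig(c=2)
    if cfg.c != 2:
        raise ValidationError("layer ambiguity is defined for c = 2 clusters")
    if np.unique(A, axis=0).shape[0] < 2:
        warnings.warn(
            "all activation rows identical; clusters indistinct, ambiguity = 0",
            stacklevel=2,
        )
        return LayerAmbiguity(value=0.0, memberships=None)
    result = fcm_cluster(A, cfg)
    u = result.u
    value = float(np.mean((u[:, 0] - u[:, 1]) ** 2))
    return LayerAmbiguity(value=value, memberships=u)


def ambiguity_from_memberships(u: np.ndarray) -> float:
    """mean((u1 - u2)^2) straight from a two-column membership matrix."""
    u = np.asarray(u, dtype=float)
    return float(np.mean((u[:, 0] - u[:, 1]) ** 2))


def fuzzy_gd_step(
    weights: np.ndarray, gradients: np.ndarray, eta: float, a: float
) -> np.ndarray:
    """One fuzzy gradient-descent update: w' = w - a * eta * g.

    a is the ambiguity factor in [0, 1]; a = 1 recovers plain gradient
    descent and a = 0 leaves the weights untouched.
    """
    w = np.asarray(weights, dtype=float)
    g = np.asarray(gradients, dtype=float)
    if w.shape != g.shape:
        raise ValidationError(f"shape mismatch: weights {w.shape}, grads {g.shape}")
    if not (0.0 <= a <= 1.0):
        raise ValidationError("ambiguity factor must lie in [0, 1]")
    if eta <= 0:
        raise ValidationError("eta must be > 0")
    return w - a * eta * g


def _forward_pass(net: FuzzyNetwork, X: np.ndarray, act: TypeIISigmoid):
    """Batch forward pass; returns activations per layer and pre-activations."""
    activations = [X]
    zs = []
    a = X
    for W, b in zip(net.weights, net.biases):
        z = a @ W + b
        zs.append(z)
        a = act(z)
        activations.append(a)
    return activations, zs


def forward(net: FuzzyNetwork, x: np.ndarray):
    """Propagate features through the network.

    Accepts one feature vector or a batch (n, d); returns the predicted
    probability (scalar or vector) and the cached per-layer activations.
    """
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != net.layer_sizes[0]:
        raise ValidationError(
            f"feature count {X.shape[1]} != input layer size {net.layer_sizes[0]}"
        )
    if not np.isfinite(X).all():
        raise ValidationError("features contain non-finite values")
    activations, _ = _forward_pass(net, X, net.activation)
    p = activations[-1][:, 0]
    if single:
        return float(p[0]), [a[0] for a in activations]
    return p, activations


def predict_proba(net: FuzzyNetwork, X: np.ndarray) -> np.ndarray:
    """Predicted probabilities for a feature batch."""
    p, _ = forward(net, np.atleast_2d(np.asarray(X, dtype=float)))
    return p


def train(
    net: FuzzyNetwork,
    X: np.ndarray,
    y: np.ndarray,
    mode: Literal["fuzzy", "standard"] = "fuzzy",
    *,
    ambiguity_mode: Literal["per_layer", "global"] = "per_layer",
    orientation: Literal["samples", "neurons"] = "samples",
    fcm_cfg: FcmConfig | None = None,
    force_ambiguity: float | None = None,
) -> FuzzyNetwork:
    """Full-batch training with fuzzy (ambiguity-scaled) gradient descent.

    Each epoch: (i) forward pass caching every layer's activations;
    (ii) in fuzzy mode, fuzzy-c-means the input layer and each hidden
    layer (never the output layer) into two clusters and form the layer's
    ambiguity scalar; (iii) backpropagate the error delta
    (true - pred) * phi'(z); (iv) scale each weight matrix's update by the
    ambiguity of its source layer.  Standard mode fixes the ambiguity at 1
    and uses the plain sigmoid.

    ambiguity_mode="global" averages the per-layer scalars into one factor
    applied everywhere; orientation="neurons" clusters the transposed
    activation table (objects = neurons) instead of samples;
    force_ambiguity pins every layer's scalar to a constant (bypassing the
    clustering), which with the plain-sigmoid activation and a = 1 makes
    fuzzy training coincide with the standard trajectory.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValidationError("X and y length mismatch")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValidationError("labels must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValidationError("training requires both classes present")
    for cls_label in (0.0, 1.0):
        if np.sum(y == cls_label) < 2:
            raise ValidationError("need at least 2 samples per class")
    if mode not in ("fuzzy", "standard"):
        raise ValidationError(f"unknown training mode {mode!r}")

    act = TypeIISigmoid() if mode == "standard" else net.activation
    trained = net.copy()
    if mode == "standard":
        trained.activation = act
    n_layers = len(trained.layer_sizes)
    n = X.shape[0]

    for epoch in range(trained.epochs):
        activations, zs = _forward_pass(trained, X, act)

        if mode == "fuzzy" and force_ambiguity is not None:
            if not (0.0 <= force_ambiguity <= 1.0):
                raise ValidationError("force_ambiguity must lie in [0, 1]")
            ambiguities = [float(force_ambiguity)] * (n_layers - 1)
        elif mode == "fuzzy":
            ambiguities = []
            for l in range(n_layers - 1):  # input + hidden layers only
                table = activations[l]
                if orientation == "neurons":
                    table = table.T
                cfg = fcm_cfg or FcmConfig(c=2, seed=trained.init_seed + l)
                try:
                    amb = layer_ambiguity(table, cfg)
                    ambiguities.append(amb.value)
                except ValidationError:
                    ambiguities.append(0.0)
            if ambiguity_mode == "global":
                g_amb = float(np.mean(ambiguities))
                ambiguities = [g_amb] * (n_layers - 1)
        else:
            ambiguities = [1.0] * (n_layers - 1)

        # backprop of the (true - pred) error through phi'
        p = activations[-1][:, 0]
        delta = -((y - p) * act.derivative(zs[-1][:, 0]))[:, None] / n
        deltas = [delta]
        for l in range(n_layers - 2, 0, -1):
            delta = (deltas[0] @ trained.weights[l].T) * act.derivative(zs[l - 1])
            deltas.insert(0, delta)

        for l in range(n_layers - 1):
            grad_w = activations[l].T @ deltas[l]
            grad_b = deltas[l].sum(axis=0)
            a_l = ambiguities[l]
            trained.weights[l] = fuzzy_gd_step(
                trained.weights[l], grad_w, trained.eta, a_l
            )
            trained.biases[l] = fuzzy_gd_step(
                trained.biases[l], grad_b, trained.eta, a_l
            )
    return trained


@dataclass
class PredictionSet:
    """Probabilities with the mean-probability decision rule applied.

    threshold = mean(p_i); decision is regular (1) only when p_i is
    strictly greater than the threshold, otherwise irregular (0).
    """

    probabilities: np.ndarray
    threshold: float
    decisions: np.ndarray

    @property
    def labels(self) -> list[str]:
        return ["regular" if d == 1 else "irregular" for d in self.decisions]


def decide(probs: Sequence[float]) -> PredictionSet:
    """Apply the mean-probability threshold rule to a probability batch."""
    p = np.asarray(probs, dtype=float).ravel()
    if p.size == 0:
        raise ValidationError("decide() requires at least one probability")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("probabilities must lie in [0, 1]")
    threshold = float(np.mean(p))
    # strict inequality with a float-noise guard so that "all equal"
    # batches decide irregular even when the mean rounds a ulp low
    decisions = (p - threshold > 1e-12).astype(int)
    return PredictionSet(probabilities=p, threshold=threshold, decisions=decisions)


def select_variant(acc_lower: float, acc_upper: float) -> tuple[str, float]:
    """Pick the better-performing half of the type-II pair.

    Returns (variant tag, accuracy); ties resolve to "lower" so the
    selection is deterministic.
    """
    for acc in (acc_lower, acc_upper):
        if not (0.0 <= acc <= 100.0):
            raise ValidationError("accuracies must lie in [0, 100]")
    if acc_upper > acc_lower:
        return "upper", float(acc_upper)
    return "lower", float(acc_lower)


def save_model(net: FuzzyNetwork, path: str | Path) -> None:
    payload = {
        "layer_sizes": list(net.layer_sizes),
        "weights": [w.tolist() for w in net.weights],
        "biases": [b.tolist() for b in net.biases],
        "eta": net.eta,
        "alpha": net.activation.alpha,
        "variant": net.activation.variant,
        "epochs": net.epochs,
        "init_seed": net.init_seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> FuzzyNetwork:
    payload = json.loads(Path(path).read_text())
    return FuzzyNetwork(
        layer_sizes=tuple(payload["layer_sizes"]),
        weights=[np.asarray(w, dtype=float) for w in payload["weights"]],
        biases=[np.asarray(b, dtype=float) for b in payload["biases"]],
        eta=payload["eta"],
        activation=TypeIISigmoid(alpha=payload["alpha"], variant=payload["variant"]),
        epochs=payload["epochs"],
        init_seed=payload["init_seed"],
    )
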