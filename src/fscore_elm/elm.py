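"""Extreme learning machine: random hidden layer, analytic output weights.

A single-hidden-layer feedforward network whose K hidden nodes have input
weights wᵢ and biases bᵢ drawn at random (uniform on [−1, 1]) and never
trained.  With a sigmoid activation g, the hidden-layer output matrix over N
samples is

    H[j, i] = g(wᵢ · xⱼ + bᵢ),            H ∈ ℝ^{N×K},

and training reduces to the linear least-squares problem min‖Hβ − T‖.  The
output weights are taken as β = H⁺T with H⁺ the Moore–Penrose pseudoinverse,
i.e. the least-squares solution of smallest Euclidean norm — the property
linked to the ELM's generalization behaviour.  For K = N and invertible H
the network interpolates the training data exactly.

Binary targets are encoded as a single output node with T ∈ {−1, +1}; the
predicted label is the sign of the network output, with a score of exactly 0
mapping to +1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy.linalg import lstsq
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "hidden_matrix",
    "solve_output_weights",
    "ELMClassifier",
    "elm_train",
    "elm_predict",
]


def hidden_matrix(X: np.ndarray, weights: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Sigmoid hidden-layer output matrix H[j, i] = σ(wᵢ·xⱼ + bᵢ).

    ``X`` is N×n, ``weights`` K×n, ``biases`` length K; column i of the
    result is the output of the i-th hidden node on all samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    biases = np.asarray(biases, dtype=float).ravel()
    if X.shape[1] != weights.shape[1]:
        raise ValueError(
            f"input dim mismatch: X has {X.shape[1]} columns, weights expect {weights.shape[1]}"
        )
    if biases.size != weights.shape[0]:
        raise ValueError("one bias per hidden node required")
    return expit(X @ weights.T + biases)


def solve_output_weights(H: np.ndarray, T: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """Minimal-norm least-squares output weights β = H⁺T.

    SVD-based; singular values below ``rcond`` times the largest are treated
    as zero.
    """
    beta, *_ = lstsq(H, T, cond=rcond, lapack_driver="gelsd")
    return beta


class ELMClassifier(BaseEstimator, ClassifierMixin):
    """Binary extreme learning machine with ±1 labels.

    Parameters
    ----------
    n_hidden : int
        Hidden-node count K.
    rcond : float
        Relative singular-value cutoff for the pseudoinverse.
    random_state : int, Generator or None
        Seeds the hidden-layer draw; a fixed seed gives an identical model.

    Attributes
    ----------
    input_weights_ : ndarray (K, n); biases_ : ndarray (K,)
        The random, untrained hidden layer.
    output_weights_ : ndarray (K,)
        Minimal-norm least-squares solution for the single output node.
    """

    def __init__(self, n_hidden: int = 20, rcond: float = 1e-10, random_state=None):
        self.n_hidden = n_hidden
        self.rcond = rcond
        self.random_state = random_state

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y lengths differ")
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("targets must be +1/-1")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        n = X.shape[1]
        self.input_weights_ = rng.uniform(-1.0, 1.0, size=(self.n_hidden, n))
        self.biases_ = rng.uniform(-1.0, 1.0, size=self.n_hidden)
        H = hidden_matrix(X, self.input_weights_, self.biases_)
        self.output_weights_ = solve_output_weights(H, y, rcond=self.rcond)
        self.classes_ = np.array([-1.0, 1.0])
        self.n_features_in_ = n
        return self

    def decision_function(self, X):
        check_is_fitted(self, "output_weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fit on {self.n_features_in_}"
            )
        H = hidden_matrix(X, self.input_weights_, self.biases_)
        return H @ self.output_weights_

    def predict(self, X):
        # tie rule: a score of exactly 0 is classed +1
        return np.where(self.decision_function(X) >= 0, 1.0, -1.0)

    def to_json(self, path=None) -> dict:
        check_is_fitted(self, "output_weights_")
        obj = {
            "activation": "sigmoid",
            "n_hidden": int(self.n_hidden),
            "n_inputs": int(self.n_features_in_),
            "n_outputs": 1,
            "rcond": self.rcond,
            "input_weights": self.input_weights_.tolist(),
            "biases": self.biases_.tolist(),
            "output_weights": self.output_weights_.tolist(),
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2) + "\n")
        return obj

    @classmethod
    def from_json(cls, obj_or_path) -> "ELMClassifier":
        obj = (
            obj_or_path
            if isinstance(obj_or_path, dict)
            else json.loads(Path(obj_or_path).read_text())
        )
        model = cls(n_hidden=obj["n_hidden"], rcond=obj.get("rcond", 1e-10))
        model.input_weights_ = np.asarray(obj["input_weights"], dtype=float)
        model.biases_ = np.asarray(obj["biases"], dtype=float)
        model.output_weights_ = np.asarray(obj["output_weights"], dtype=float)
        model.classes_ = np.array([-1.0, 1.0])
        model.n_features_in_ = obj["n_inputs"]
        return model


def elm_train(X, T, K: int, seed=None, rcond: float = 1e-10) -> ELMClassifier:
    """Train a K-hidden-node ELM on (X, T) with a seeded hidden layer."""
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
        raise ValueError("non-finite training inputs")
    return ELMClassifier(n_hidden=K, rcond=rcond, random_state=seed).fit(X, T)


def elm_predict(model: ELMClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Network scores Hβ and the ±1 labels (score ≥ 0 → +1)."""
    scores = model.decision_function(X)
    return scores, np.where(scores >= 0, 1.0, -1.0)
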