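"""Single-hidden-layer feed-forward networks: forward pass and derivatives.

The prediction for individual i with input row p_i is

    t̂_i = b + Σ_k w_k · g(b_k + p_i' u[k]),        k = 1..S,

with S hidden neurons, input-to-hidden strengths u[k], hidden biases b_k,
hidden-to-output weights w_k and a hyperbolic-tangent (or identity) hidden
activation g.  The outer activation is linear and its regression coefficient
is fixed at 1: with a linear output, an outer coefficient c and the w_k are
not jointly identifiable, so c is folded into the w_k.  The outer bias b is
removed by centering the targets (it can be made trainable via the
architecture flag).

The "linear" architecture — one neuron with identity activations throughout,
which turns the network into a random regression t̂_i = p_i'u — is
represented exactly in that reduced form (m = q free weights), so that
training coincides with empirical-Bayes ridge regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "Architecture",
    "WeightVector",
    "Dataset",
    "tanh_activation",
    "forward",
    "residual_jacobian",
]

FLATTEN_ORDER_VERSION = 1  # [row-major u, hidden biases, output weights, (outer bias)]


def tanh_activation(x):
    """Hyperbolic tangent g(x) = (e^x − e^−x)/(e^x + e^−x), saturation-safe."""
    return np.tanh(x)


def _dtanh(x):
    t = np.tanh(x)
    return 1.0 - t * t


@dataclass(frozen=True)
class Architecture:
    """Network shape: q inputs, S hidden neurons, activation choices."""

    n_inputs: int
    n_neurons: int = 1
    hidden_activation: Literal["tanh", "identity"] = "tanh"
    linear: bool = False  # reduced random-regression form (see module docstring)
    outer_bias_trainable: bool = False

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if self.linear and (
            self.n_neurons != 1 or self.hidden_activation != "identity"
        ):
            raise ValueError(
                "linear architecture means one neuron with identity activation"
            )

    @classmethod
    def make_linear(cls, n_inputs: int) -> "Architecture":
        """The benchmark linear net: random regression on the inputs."""
        return cls(n_inputs, 1, "identity", linear=True)

    @property
    def n_weights(self) -> int:
        """m, the number of trainable connection strengths and biases."""
        if self.linear:
            m = self.n_inputs
        else:
            m = self.n_neurons * self.n_inputs + 2 * self.n_neurons
        return m + (1 if self.outer_bias_trainable else 0)

    def activation(self, x):
        if self.hidden_activation == "tanh":
            return np.tanh(x)
        return x

    def activation_deriv(self, x):
        if self.hidden_activation == "tanh":
            return _dtanh(x)
        return np.ones_like(x)


@dataclass
class WeightVector:
    """Structured view of the flattened weight vector.

    Flattening order (version 1): row-major input-to-hidden block (S×q),
    hidden biases (S), hidden-to-output weights (S), then the outer bias if
    trainable.  For the linear architecture only the q input strengths are
    free; the hidden bias is fixed at 0 and the output weight at 1.
    """

    arch: Architecture
    input_to_hidden: np.ndarray  # S×q
    hidden_biases: np.ndarray  # S
    hidden_to_output: np.ndarray  # S
    outer_bias: float = 0.0

    def flatten(self) -> np.ndarray:
        if self.arch.linear:
            parts = [self.input_to_hidden.ravel()]
        else:
            parts = [
                self.input_to_hidden.ravel(),
                self.hidden_biases,
                self.hidden_to_output,
            ]
        if self.arch.outer_bias_trainable:
            parts.append(np.array([self.outer_bias]))
        return np.concatenate(parts)

    @classmethod
    def from_flat(cls, arch: Architecture, w: np.ndarray) -> "WeightVector":
        w = np.asarray(w, dtype=float)
        if w.shape != (arch.n_weights,):
            raise ValueError(
                f"weight vector has length {w.size}, architecture requires "
                f"{arch.n_weights}"
            )
        s, q = arch.n_neurons, arch.n_inputs
        outer = float(w[-1]) if arch.outer_bias_trainable else 0.0
        if arch.linear:
            return cls(
                arch,
                input_to_hidden=w[:q].reshape(1, q),
                hidden_biases=np.zeros(1),
                hidden_to_output=np.ones(1),
                outer_bias=outer,
            )
        u = w[: s * q].reshape(s, q)
        b = w[s * q : s * q + s]
        wo = w[s * q + s : s * q + 2 * s]
        return cls(arch, u.copy(), b.copy(), wo.copy(), outer)


@dataclass
class Dataset:
    """Paired network inputs P (rows p_i) and phenotypic targets t."""

    inputs: np.ndarray
    targets: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        self.targets = np.asarray(self.targets, dtype=float).ravel()
        if self.inputs.shape[0] != self.targets.shape[0]:
            raise ValueError(
                f"{self.inputs.shape[0]} input rows but "
                f"{self.targets.shape[0]} targets"
            )
        if not self.ids:
            self.ids = [f"obs{i}" for i in range(self.targets.size)]

    @property
    def n(self) -> int:
        return self.targets.size


def _pre_activations(arch: Architecture, wv: WeightVector, p: np.ndarray):
    return p @ wv.input_to_hidden.T + wv.hidden_biases[None, :]


def forward(arch: Architecture, w: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Network predictions t̂ for input rows p (n×q)."""
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if p.shape[1] != arch.n_inputs:
        raise ValueError(
            f"inputs have {p.shape[1]} columns, architecture expects "
            f"{arch.n_inputs}"
        )
    wv = w if isinstance(w, WeightVector) else WeightVector.from_flat(arch, w)
    a = _pre_activations(arch, wv, p)
    hidden = arch.activation(a)
    return hidden @ wv.hidden_to_output + wv.outer_bias


def residual_jacobian(
    arch: Architecture, w: np.ndarray, data: Dataset
) -> np.ndarray:
    """n×m Jacobian of the residuals e_i = t_i − t̂_i with respect to w.

    Analytic back-propagated derivatives; the tanh derivative is
    g'(x) = 1 − tanh²(x) (identically 4P(1−P) for P = logistic(−2x)).
    """
    wv = w if isinstance(w, WeightVector) else WeightVector.from_flat(arch, w)
    p = data.inputs
    n = data.n
    a = _pre_activations(arch, wv, p)  # n×S
    gp = arch.activation_deriv(a)  # n×S

    if arch.linear:
        blocks = [-p]
    else:
        d = gp * wv.hidden_to_output[None, :]  # n×S
        ju = -(d[:, :, None] * p[:, None, :]).reshape(n, -1)  # u, row-major
        jb = -d  # hidden biases
        jw = -arch.activation(a)  # output weights
        blocks = [ju, jb, jw]
    if arch.outer_bias_trainable:
        blocks.append(-np.ones((n, 1)))
    return np.concatenate(blocks, axis=1)
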