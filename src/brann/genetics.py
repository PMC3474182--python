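"""Quantitative-genetics interpretation of a trained network.

The network generalizes the "marked breeding value" x'β of a linear marker
regression: the breeding value of individual i is the input-weighted
gradient of the fitted genotype-to-phenotype map at that individual's
inputs,

    BV_i = p_i' ∂t̂_i/∂p_i
         = p_i' Σ_k w_k · g'(b_k + p_i'u[k]) · u[k]

for a tanh hidden layer with linear output (g' = 1 − tanh² = 4P(1−P)).
For an identity-activation network this collapses to p_i'u, the classical
linear marked breeding value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .network import Architecture, WeightVector
from .regularize import TrainedNetwork

__all__ = [
    "BreedingValueReport",
    "breeding_value",
    "breeding_values",
    "input_gradient",
    "input_importance",
    "weight_distribution_summary",
]


@dataclass
class BreedingValueReport:
    """Per-individual breeding values plus per-input importance shares."""

    ids: list[str]
    bv_scaled: np.ndarray
    bv_trait_units: np.ndarray
    importance: np.ndarray


def _weights(net: TrainedNetwork | WeightVector) -> tuple[Architecture, WeightVector]:
    if isinstance(net, TrainedNetwork):
        return net.arch, net.weights
    return net.arch, net


def input_gradient(net: TrainedNetwork | WeightVector, p: np.ndarray) -> np.ndarray:
    """∂t̂/∂p at each input row: n×q matrix of analytic partial derivatives."""
    arch, wv = _weights(net)
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if p.shape[1] != arch.n_inputs:
        raise ValueError(
            f"input rows have {p.shape[1]} entries, architecture expects "
            f"{arch.n_inputs}"
        )
    a = p @ wv.input_to_hidden.T + wv.hidden_biases[None, :]  # n×S
    d = arch.activation_deriv(a) * wv.hidden_to_output[None, :]  # n×S
    return d @ wv.input_to_hidden  # n×q


def breeding_value(net: TrainedNetwork | WeightVector, p_i: np.ndarray) -> float:
    """BV_i = p_i' ∂t̂_i/∂p_i for a single input vector."""
    p_i = np.asarray(p_i, dtype=float).ravel()
    grad = input_gradient(net, p_i[None, :])[0]
    return float(p_i @ grad)


def breeding_values(
    net: TrainedNetwork, p: np.ndarray, ids: list[str] | None = None
) -> BreedingValueReport:
    """Breeding values for all rows of p, on both scaled and trait scales.

    Trait-unit values multiply by the slope of the target scale record
    (gradients are unaffected by the additive centering constant).
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    grad = input_gradient(net, p)
    bv = np.einsum("ij,ij->i", p, grad)
    slope = 1.0
    if net.target_scale_record is not None:
        slope = net.target_scale_record.slope
    report_ids = ids if ids is not None else [f"ind{i}" for i in range(p.shape[0])]
    return BreedingValueReport(
        ids=list(report_ids),
        bv_scaled=bv,
        bv_trait_units=bv * slope,
        importance=input_importance(net),
    )


def input_importance(
    net: TrainedNetwork | WeightVector, include_output_weights: bool = False
) -> np.ndarray:
    """Relative importance of each input: its share of absolute connection strength.

    share_j = Σ_k |u_j[k]| / Σ_{j',k} |u_j'[k]| over the input-to-hidden
    strengths (biases and output weights excluded by default; with
    ``include_output_weights`` each neuron's strengths are weighted by
    |w_k| before pooling).
    """
    _, wv = _weights(net)
    u = np.abs(wv.input_to_hidden)  # S×q
    if include_output_weights:
        u = u * np.abs(wv.hidden_to_output)[:, None]
    per_input = u.sum(axis=0)
    total = per_input.sum()
    if total == 0:
        warnings.warn("all input weights are zero; importance is uniform")
        return np.full(per_input.size, 1.0 / per_input.size)
    return per_input / total


def weight_distribution_summary(
    net: TrainedNetwork | WeightVector, bins: int = 20
) -> dict:
    """Shrinkage diagnostics: sum of squares of weights, counts, histogram."""
    arch, wv = _weights(net)
    flat = wv.flatten()
    if arch.outer_bias_trainable:
        flat = flat[:-1]
    hist, edges = np.histogram(wv.input_to_hidden.ravel(), bins=bins)
    return {
        "sum_of_squares": float(flat @ flat),
        "n_weights": int(flat.size),
        "blocks": {
            "input_to_hidden_ss": float(np.sum(wv.input_to_hidden**2)),
            "hidden_biases_ss": 0.0 if arch.linear else float(
                np.sum(wv.hidden_biases**2)
            ),
            "hidden_to_output_ss": 0.0 if arch.linear else float(
                np.sum(wv.hidden_to_output**2)
            ),
        },
        "histogram_counts": hist.tolist(),
        "histogram_edges": edges.tolist(),
    }
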