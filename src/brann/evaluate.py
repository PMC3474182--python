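"""Repeated random cross-validation and predictive-performance summaries.

Two partition designs are supported, matching the two case-study layouts:
60/20/20 train/validation/test fractions (validation used for early
stopping) and fixed-count train/test splits such as 480/119.  Networks are
retrained from scratch on every repeat with fresh random partitions and
initial weights; summaries report the mean and standard error over repeats
of the testing-set Pearson correlation, mean squared error, the effective
number of parameters γ and the weight sum of squares E_W.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .network import Architecture, Dataset
from .preprocess import (
    apply_scale_matrix,
    center_targets,
    minmax_scale,
    minmax_unscale,
    scale_matrix,
)
from .regularize import TrainConfig, TrainingError, train

__all__ = [
    "PartitionScheme",
    "RunSummary",
    "partition",
    "metrics",
    "repeated_cv",
    "make_architecture",
    "summary_table",
]

logger = logging.getLogger(__name__)


@dataclass
class PartitionScheme:
    """Random-partition design for repeated cross-validation."""

    kind: Literal["train_val_test", "train_test"] = "train_val_test"
    fractions: tuple[float, ...] | None = (0.6, 0.2, 0.2)
    counts: tuple[int, ...] | None = None
    n_repeats: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.counts is not None:
            self.fractions = None
            expected = 3 if self.kind == "train_val_test" else 2
            if len(self.counts) != expected:
                raise ValueError(
                    f"{self.kind} scheme needs {expected} counts"
                )
        elif self.fractions is not None:
            expected = 3 if self.kind == "train_val_test" else 2
            if len(self.fractions) != expected:
                raise ValueError(
                    f"{self.kind} scheme needs {expected} fractions"
                )
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("partition fractions must sum to 1")
        else:
            raise ValueError("either fractions or counts must be given")


def partition(
    n: int, scheme: PartitionScheme, repeat_index: int
) -> tuple[np.ndarray, ...]:
    """Disjoint index sets covering 0..n-1; deterministic in (seed, repeat)."""
    if scheme.counts is not None:
        sizes = list(scheme.counts)
        if sum(sizes) != n:
            raise ValueError(
                f"partition counts {sizes} do not sum to n={n}"
            )
    else:
        fracs = scheme.fractions
        sizes = [int(round(f * n)) for f in fracs[:-1]]
        sizes.append(n - sum(sizes))
    if any(s <= 0 for s in sizes):
        raise ValueError(f"infeasible partition sizes {sizes} for n={n}")
    rng = np.random.default_rng([scheme.base_seed, repeat_index])
    perm = rng.permutation(n)
    parts, start = [], 0
    for s in sizes:
        parts.append(np.sort(perm[start : start + s]))
        start += s
    return tuple(parts)


def metrics(predictions: np.ndarray, observations: np.ndarray) -> tuple[float, float]:
    """(Pearson r, mean squared error); r is NaN if predictions are constant."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    observations = np.asarray(observations, dtype=float).ravel()
    if predictions.shape != observations.shape:
        raise ValueError("predictions and observations differ in length")
    mse = float(np.mean((predictions - observations) ** 2))
    if predictions.size < 3 or np.std(predictions) == 0 or np.std(observations) == 0:
        warnings.warn("Pearson r undefined (constant vector); reported as NaN")
        return np.nan, mse
    r = float(np.corrcoef(predictions, observations)[0, 1])
    return r, mse


def make_architecture(spec: int | str | Architecture, n_inputs: int) -> Architecture:
    """'linear' or a neuron count (1..6) into an Architecture for q inputs."""
    if isinstance(spec, Architecture):
        return spec
    if isinstance(spec, str) and spec.lower() == "linear":
        return Architecture.make_linear(n_inputs)
    return Architecture(n_inputs=n_inputs, n_neurons=int(spec), hidden_activation="tanh")


def _arch_label(spec: int | str | Architecture) -> str:
    if isinstance(spec, Architecture):
        if spec.linear:
            return "linear"
        return f"{spec.n_neurons}_neurons"
    if isinstance(spec, str) and spec.lower() == "linear":
        return "linear"
    return f"{int(spec)}_neurons"


@dataclass
class RunSummary:
    """Per-run records and aggregate mean ± SE for one architecture."""

    architecture: str
    runs: list[dict] = field(default_factory=list)
    n_failed: int = 0

    def aggregate(self) -> dict:
        out = {"architecture": self.architecture, "n_runs": len(self.runs),
               "n_failed": self.n_failed}
        if not self.runs:
            return out
        frame = pd.DataFrame(self.runs)
        for col in ("r", "mse", "mse_scaled", "gamma", "e_w"):
            vals = frame[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            out[f"mean_{col}"] = float(np.mean(vals)) if vals.size else np.nan
            out[f"se_{col}"] = (
                float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                if vals.size > 1
                else np.nan
            )
        return out


def repeated_cv(
    inputs: np.ndarray,
    targets: np.ndarray,
    arch_specs: Sequence[int | str | Architecture],
    scheme: PartitionScheme,
    config: TrainConfig | None = None,
    scale_inputs: bool = True,
) -> dict[str, RunSummary]:
    """Train every architecture on every random repeat and summarize.

    Per repeat: partition → min-max scale inputs and target on the training
    rows only → center the target → train (with validation early stopping
    when the scheme has a validation part and the config enables it) →
    predict the test rows → Pearson r and MSE on the original trait scale
    (MSE on the scaled scale is reported alongside).
    """
    cfg = config or TrainConfig()
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    targets = np.asarray(targets, dtype=float).ravel()
    n = targets.size
    results = {
        _arch_label(spec): RunSummary(architecture=_arch_label(spec))
        for spec in arch_specs
    }

    for rep in range(scheme.n_repeats):
        parts = partition(n, scheme, rep)
        if scheme.kind == "train_val_test":
            tr_idx, val_idx, te_idx = parts
        else:
            tr_idx, te_idx = parts
            val_idx = None

        if scale_inputs:
            x_tr, in_recs = scale_matrix(inputs[tr_idx])
            x_te = apply_scale_matrix(inputs[te_idx], in_recs)
            x_val = apply_scale_matrix(inputs[val_idx], in_recs) if val_idx is not None else None
        else:
            x_tr, x_te = inputs[tr_idx], inputs[te_idx]
            x_val = inputs[val_idx] if val_idx is not None else None

        t_tr_scaled, t_rec = minmax_scale(targets[tr_idx])
        t_tr, t_mean = center_targets(t_tr_scaled)
        train_data = Dataset(x_tr, t_tr)
        val_data = None
        if x_val is not None:
            val_data = Dataset(x_val, t_rec.scale(targets[val_idx]) - t_mean)

        for spec in arch_specs:
            label = _arch_label(spec)
            arch = make_architecture(spec, inputs.shape[1])
            run_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * rep})
            try:
                net = train(arch, train_data, run_cfg, validation=val_data)
            except TrainingError as err:
                logger.warning("run %d (%s) failed: %s", rep, label, err)
                results[label].n_failed += 1
                continue
            pred_scaled = net.predict(x_te) + t_mean - net.target_mean
            pred = minmax_unscale(pred_scaled, t_rec)
            r, mse = metrics(pred, targets[te_idx])
            _, mse_scaled = metrics(pred_scaled, t_rec.scale(targets[te_idx]))
            results[label].runs.append(
                {
                    "repeat": rep,
                    "r": r,
                    "mse": mse,
                    "mse_scaled": mse_scaled,
                    "gamma": net.state.gamma,
                    "e_w": net.state.e_w,
                    "epochs": net.n_epochs,
                    "status": net.status,
                }
            )
    return results


def summary_table(results: dict[str, RunSummary]) -> pd.DataFrame:
    """Table-shaped aggregate: one row per architecture, mean ± SE columns."""
    return pd.DataFrame([rs.aggregate() for rs in results.values()])
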