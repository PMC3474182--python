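"""Model/results front end for Bayesian-regularized network regression.

`BayesRegNet` is constructed from a phenotype vector and an input matrix
(marker codes, relationship-matrix rows, or any covariates); `fit()` runs
the Levenberg-Marquardt / evidence-framework loop and returns a
`BayesRegNetResults` holding the MAP weights, the tuned precisions (α, β),
the effective number of parameters γ, and convenience methods for
prediction, breeding values, and a text summary.

Example
-------
>>> model = BayesRegNet(t, Z, n_neurons=2)
>>> res = model.fit(seed=1)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .evaluate import metrics
from .genetics import breeding_values, input_importance
from .network import Architecture, Dataset
from .preprocess import apply_scale_matrix, center_targets, scale_matrix
from .regularize import TrainConfig, TrainedNetwork, heritability, train

__all__ = ["BayesRegNet", "BayesRegNetResults"]


class BayesRegNet:
    """Feed-forward network with Gaussian weight priors, evidence-tuned.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Phenotypes (targets).  Centered internally; predictions are
        returned on the original scale.
    exog : array-like, shape (n, q)
        Input rows p_i: relationship-matrix rows, centered marker codes,
        or arbitrary covariates.
    n_neurons : int
        Hidden-layer size S (typically 1-6 for genomic prediction).
    activation : {"tanh", "linear"}
        "tanh" gives the nonlinear network; "linear" gives the benchmark
        random regression (empirical-Bayes ridge).
    scale_inputs : bool
        Min-max scale each input column into [-1, 1] before training.
    """

    def __init__(
        self,
        endog,
        exog,
        n_neurons: int = 1,
        activation: str = "tanh",
        scale_inputs: bool = True,
        ids: Sequence[str] | None = None,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.size:
            raise ValueError("endog and exog disagree on the number of rows")
        if activation not in ("tanh", "linear"):
            raise ValueError("activation must be 'tanh' or 'linear'")
        if activation == "linear":
            self.arch = Architecture.make_linear(self.exog.shape[1])
        else:
            self.arch = Architecture(
                n_inputs=self.exog.shape[1],
                n_neurons=n_neurons,
                hidden_activation="tanh",
            )
        self.scale_inputs = scale_inputs
        self.ids = list(ids) if ids is not None else [
            f"ind{i}" for i in range(self.endog.size)
        ]

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        target: str,
        features: Sequence[str] | None = None,
        **kwargs,
    ) -> "BayesRegNet":
        """Build from a DataFrame: one target column, the rest as inputs."""
        features = (
            list(features)
            if features is not None
            else [c for c in frame.columns if c != target]
        )
        return cls(
            frame[target].to_numpy(),
            frame[features].to_numpy(),
            ids=[str(i) for i in frame.index],
            **kwargs,
        )

    def fit(
        self,
        config: TrainConfig | None = None,
        validation_idx: np.ndarray | None = None,
        seed: int | None = None,
        **config_kwargs,
    ) -> "BayesRegNetResults":
        """Train to the MAP weights with evidence-tuned (α, β)."""
        if config is None:
            if seed is not None:
                config_kwargs.setdefault("seed", seed)
            config = TrainConfig(**config_kwargs)
        elif seed is not None or config_kwargs:
            raise ValueError("pass either a TrainConfig or keyword overrides")

        mask = np.ones(self.endog.size, dtype=bool)
        if validation_idx is not None:
            mask[np.asarray(validation_idx)] = False

        x = self.exog
        if self.scale_inputs:
            x_tr, in_recs = scale_matrix(x[mask])
            x_all = apply_scale_matrix(x, in_recs)
        else:
            in_recs = None
            x_tr, x_all = x[mask], x
        t_tr, t_mean = center_targets(self.endog[mask])
        data = Dataset(x_tr, t_tr)
        val = None
        if validation_idx is not None:
            val = Dataset(x_all[~mask], self.endog[~mask] - t_mean)
        net = train(self.arch, data, config, validation=val)
        net.target_mean = t_mean
        net.input_scale_records = in_recs
        return BayesRegNetResults(self, net)


class BayesRegNetResults:
    """Fitted network: MAP weights, tuned hyperparameters, diagnostics."""

    def __init__(self, model: BayesRegNet, net: TrainedNetwork) -> None:
        self.model = model
        self.net = net
        self.state = net.state

    # -- point estimates ------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        """Flattened MAP connection strengths and biases."""
        return self.net.weights.flatten()

    @property
    def alpha(self) -> float:
        return self.state.alpha

    @property
    def beta(self) -> float:
        return self.state.beta

    @property
    def gamma(self) -> float:
        """Effective number of parameters m − 2α·tr(H⁻¹)."""
        return self.state.gamma

    @property
    def heritability(self) -> float:
        """h² = β/(α+β) (meaningful for the linear infinitesimal representation)."""
        return heritability(self.alpha, self.beta)

    @property
    def sigma2(self) -> float:
        """Residual variance 1/(2β) on the training target scale."""
        return 1.0 / (2.0 * self.beta)

    @property
    def sigma2_w(self) -> float:
        """Prior weight variance 1/(2α)."""
        return 1.0 / (2.0 * self.alpha)

    # -- predictions ----------------------------------------------------
    def _transform(self, exog: np.ndarray | None) -> np.ndarray:
        x = self.model.exog if exog is None else np.atleast_2d(
            np.asarray(exog, dtype=float)
        )
        if self.net.input_scale_records is not None:
            x = apply_scale_matrix(x, self.net.input_scale_records)
        return x

    def predict(self, exog: np.ndarray | None = None) -> np.ndarray:
        """Predicted phenotypes on the original target scale."""
        return self.net.predict(self._transform(exog))

    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def breeding_values(self, exog: np.ndarray | None = None):
        """Derivative-based breeding values for the (scaled) input rows."""
        return breeding_values(self.net, self._transform(exog), ids=self.model.ids)

    def input_importance(self) -> np.ndarray:
        return input_importance(self.net)

    def history(self) -> pd.DataFrame:
        return self.net.history_frame()

    def plot_history(self, ax=None):
        """Objective and γ across epochs (requires matplotlib)."""
        import matplotlib.pyplot as plt

        frame = self.history()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(frame["epoch"], frame["F"], label="F = βE_D + αE_W")
        ax.set_xlabel("epoch")
        ax.set_ylabel("penalized objective")
        twin = ax.twinx()
        twin.plot(frame["epoch"], frame["gamma"], color="C1", label="γ")
        twin.set_ylabel("effective parameters γ")
        ax.legend(loc="upper right")
        return ax

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        arch = self.net.arch
        kind = "linear (random regression)" if arch.linear else (
            f"{arch.n_neurons}-neuron {arch.hidden_activation}"
        )
        r, mse = metrics(self.predict(), self.model.endog)
        lines = [
            "Bayesian-regularized network regression",
            "=" * 55,
            f"architecture:        {kind}",
            f"inputs (q):          {arch.n_inputs}",
            f"weights (m):         {arch.n_weights}",
            f"observations (n):    {self.model.endog.size}",
            f"epochs run:          {self.net.n_epochs} ({self.net.status})",
            "-" * 55,
            f"alpha (=1/2sigma2_w): {self.alpha:.6g}",
            f"beta  (=1/2sigma2):   {self.beta:.6g}",
            f"effective params γ:  {self.gamma:.2f}",
            f"h2 = beta/(alpha+beta): {self.heritability:.4f}",
            f"E_D (resid SS):      {self.state.e_d:.6g}",
            f"E_W (weight SS):     {self.state.e_w:.6g}",
            f"training fit: r = {r:.4f}, MSE = {mse:.6g}",
            "=" * 55,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<BayesRegNetResults gamma={self.gamma:.2f} h2={self.heritability:.3f}>"
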