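"""Bayesian regularization by the evidence framework with Levenberg-Marquardt.

Weights get independent Gaussian priors N(0, σ²_w) and residuals are
Gaussian N(0, σ²).  With the precision-style parameters α = 1/(2σ²_w) and
β = 1/(2σ²), the conditional posterior mode of the weights minimizes the
penalized sum of squares

    F(α, β) = β·E_D + α·E_W,   E_D = Σ(t_i − t̂_i)²,   E_W = w'w.

α and β are tuned by maximizing the Laplace approximation to the marginal
likelihood ("evidence"),

    log p(D|α, β) ≈ K + n/2·log β + m/2·log α − F − ½·log|H|,

with H = 2βJ'J + 2αI the Gauss-Newton Hessian of F.  The re-estimation
iteration is

    α_new = m / (2(w'w + tr H⁻¹)),      β_new = (n − γ) / (2·E_D),

where γ = m − 2α·tr H⁻¹ is the effective number of parameters — the count
of weights determined by the data rather than by the prior.  Training
alternates one damped Gauss-Newton (Levenberg-Marquardt) step on F with one
(α, β) update until convergence.

In the single-neuron linear representation of the additive infinitesimal
model, heritability is h² = σ²_w/(σ²_w + σ²) = β/(α + β).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import scipy.linalg

from .network import Architecture, Dataset, WeightVector, forward, residual_jacobian
from .preprocess import ScaleRecord

__all__ = [
    "RegularizationState",
    "TrainConfig",
    "TrainedNetwork",
    "TrainingError",
    "objective",
    "gradient",
    "gauss_newton_hessian",
    "lm_step",
    "effective_parameters",
    "update_alpha_beta",
    "log_evidence",
    "heritability",
    "train",
]

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    """Numerical failure during training (divergence, singular Hessian, ...)."""


@dataclass
class RegularizationState:
    """Evidence-framework bookkeeping at the current weights."""

    alpha: float
    beta: float
    gamma: float
    e_d: float
    e_w: float
    hessian_logdet: float = np.nan
    trace_hinv: float = np.nan

    @property
    def objective_value(self) -> float:
        return self.beta * self.e_d + self.alpha * self.e_w

    @property
    def heritability(self) -> float:
        return heritability(self.alpha, self.beta)


@dataclass
class TrainConfig:
    """Knobs of the LM / evidence training loop.

    Defaults mirror common Levenberg-Marquardt practice: damping starts at
    1e-3, is divided by 10 after an accepted step and multiplied by 10
    after a rejection, capped at 1e10.  The epoch cap is 1000.
    """

    max_epochs: int = 1000
    lm_damping: float = 1e-3
    damping_increase: float = 10.0
    damping_decrease: float = 0.1
    damping_min: float = 1e-12
    damping_max: float = 1e10
    gradient_tol: float = 1e-7
    f_rel_tol: float = 1e-8
    f_rel_patience: int = 5
    hyper_rel_tol: float = 1e-9  # (α, β) relative change deemed converged
    update_cadence: int = 1  # evidence update every k-th accepted step; 0 = never
    # near-zero prior precision and unit noise precision at the start: the
    # first LM steps fit the data essentially unregularized, then the
    # evidence updates take over (the MATLAB trainbr convention)
    alpha_init: float = 1e-6
    beta_init: float | None = 1.0
    alpha_update: Literal["paper", "mackay"] = "paper"
    init_scale: float = 0.1
    early_stopping: bool = False
    patience: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.lm_damping <= 0:
            raise ValueError("initial LM damping must be > 0")


@dataclass
class TrainedNetwork:
    """A fitted network: MAP weights plus the final regularization state."""

    arch: Architecture
    weights: WeightVector
    state: RegularizationState
    history: list[dict] = field(default_factory=list)
    status: str = "max_epochs"
    n_epochs: int = 0
    config: TrainConfig | None = None
    target_mean: float = 0.0
    input_scale_records: list[ScaleRecord] | None = None
    target_scale_record: ScaleRecord | None = None

    def predict(self, p: np.ndarray, original_scale: bool = False) -> np.ndarray:
        """Predictions on the training (scaled/centered) scale by default."""
        that = forward(self.arch, self.weights, p) + 0.0
        that = that + self.target_mean
        if original_scale and self.target_scale_record is not None:
            that = self.target_scale_record.unscale(that)
        return that

    def history_frame(self):
        import pandas as pd

        return pd.DataFrame(self.history)


def _reg_mask(arch: Architecture) -> np.ndarray:
    """1 for weights under the Gaussian prior; the outer bias is exempt."""
    mask = np.ones(arch.n_weights)
    if arch.outer_bias_trainable:
        mask[-1] = 0.0
    return mask


def objective(
    arch: Architecture,
    w: np.ndarray,
    data: Dataset,
    alpha: float,
    beta: float,
) -> tuple[float, float, float]:
    """Penalized sum of squares: returns (F, E_D, E_W)."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be non-negative")
    w = np.asarray(w, dtype=float)
    e = data.targets - forward(arch, w, data.inputs)
    e_d = float(e @ e)
    wr = w * _reg_mask(arch)
    e_w = float(wr @ wr)
    return beta * e_d + alpha * e_w, e_d, e_w


def gradient(
    arch: Architecture,
    w: np.ndarray,
    data: Dataset,
    alpha: float,
    beta: float,
    jac: np.ndarray | None = None,
) -> np.ndarray:
    """∇F = 2β·J'e + 2α·w with J = ∂e/∂w."""
    w = np.asarray(w, dtype=float)
    if jac is None:
        jac = residual_jacobian(arch, w, data)
    e = data.targets - forward(arch, w, data.inputs)
    return 2.0 * beta * (jac.T @ e) + 2.0 * alpha * (w * _reg_mask(arch))


def gauss_newton_hessian(
    jac: np.ndarray, alpha: float, beta: float, reg_mask: np.ndarray | None = None
) -> np.ndarray:
    """H ≈ 2β·J'J + 2α·I (exact for models linear in the weights)."""
    jac = np.asarray(jac, dtype=float)
    if not np.all(np.isfinite(jac)):
        raise TrainingError("non-finite entries in the residual Jacobian")
    m = jac.shape[1]
    diag = np.ones(m) if reg_mask is None else np.asarray(reg_mask, dtype=float)
    return 2.0 * beta * (jac.T @ jac) + 2.0 * alpha * np.diag(diag)


def _chol_summaries(h: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(log det H, tr H⁻¹, H⁻¹) via Cholesky; eigenvalue fallback with clipping."""
    try:
        c, low = scipy.linalg.cho_factor(h, lower=True)
        hinv = scipy.linalg.cho_solve((c, low), np.eye(h.shape[0]))
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    except scipy.linalg.LinAlgError:
        eigval, eigvec = scipy.linalg.eigh(h)
        eigval = np.clip(eigval, 1e-12, None)
        hinv = (eigvec / eigval) @ eigvec.T
        logdet = float(np.sum(np.log(eigval)))
    return logdet, float(np.trace(hinv)), hinv


def effective_parameters(alpha: float, h: np.ndarray) -> float:
    """γ = m − 2α·tr(H⁻¹): weights effectively determined by the data."""
    m = h.shape[0]
    try:
        c, low = scipy.linalg.cho_factor(h, lower=True)
    except scipy.linalg.LinAlgError as err:
        raise TrainingError(f"Hessian is singular or indefinite: {err}") from None
    hinv = scipy.linalg.cho_solve((c, low), np.eye(m))
    return m - 2.0 * alpha * float(np.trace(hinv))


def update_alpha_beta(
    state: RegularizationState,
    w_map: np.ndarray,
    n: int,
    m: int,
    rule: Literal["paper", "mackay"] = "paper",
) -> tuple[float, float]:
    """Evidence-framework re-estimation of (α, β) at the current MAP weights.

    ``paper`` uses α_new = m/(2(w'w + tr H⁻¹)); ``mackay`` uses the classic
    α_new = γ/(2·E_W).  The two agree at the fixed point.  β_new =
    (n − m + 2α·tr H⁻¹)/(2·E_D) = (n − γ)/(2·E_D) in both cases.
    """
    w_map = np.asarray(w_map, dtype=float)
    ww = float(w_map @ w_map)
    gamma = m - 2.0 * state.alpha * state.trace_hinv
    if n <= gamma:
        raise TrainingError(
            f"effective parameters exceed sample size (gamma={gamma:.2f}, "
            f"n={n}): over-fitting"
        )
    if state.e_d <= 0:
        raise TrainingError("perfect fit (E_D = 0): beta update undefined")
    if rule == "paper":
        denom = ww + state.trace_hinv
        if denom <= 0:
            raise TrainingError("degenerate alpha update (w'w + trH⁻¹ <= 0)")
        alpha_new = m / (2.0 * denom)
    elif rule == "mackay":
        if ww <= 0:
            raise TrainingError("degenerate alpha update (E_W = 0)")
        alpha_new = gamma / (2.0 * ww)
    else:
        raise ValueError(f"unknown alpha update rule {rule!r}")
    beta_new = (n - gamma) / (2.0 * state.e_d)
    return float(alpha_new), float(beta_new)


def log_evidence(
    state: RegularizationState, n: int, m: int
) -> float:
    """Laplace log-evidence n/2·log β + m/2·log α − F − ½·log|H| (constant omitted)."""
    if not np.isfinite(state.hessian_logdet):
        raise TrainingError("Hessian log-determinant unavailable")
    return (
        0.5 * n * np.log(state.beta)
        + 0.5 * m * np.log(state.alpha)
        - state.objective_value
        - 0.5 * state.hessian_logdet
    )


def heritability(alpha: float, beta: float) -> float:
    """h² = β/(α+β), i.e. σ²_w/(σ²_w + σ²) in the linear representation."""
    if alpha + beta <= 0:
        raise ValueError("alpha + beta must be positive")
    return beta / (alpha + beta)


def lm_step(
    arch: Architecture,
    w: np.ndarray,
    data: Dataset,
    alpha: float,
    beta: float,
    damping: float,
    config: TrainConfig | None = None,
    jac: np.ndarray | None = None,
) -> tuple[np.ndarray, bool, float]:
    """One damped Gauss-Newton step on F; returns (w_new, accepted, damping).

    Solves (2βJ'J + 2αI + λI)Δw = −∇F, accepts iff F does not increase,
    otherwise raises λ and retries until the damping cap.
    """
    cfg = config or TrainConfig()
    if damping <= 0:
        raise ValueError("damping must be positive")
    w = np.asarray(w, dtype=float)
    f0, _, _ = objective(arch, w, data, alpha, beta)
    if jac is None:
        jac = residual_jacobian(arch, w, data)
    grad = gradient(arch, w, data, alpha, beta, jac=jac)
    h = gauss_newton_hessian(jac, alpha, beta, reg_mask=_reg_mask(arch))
    m = h.shape[0]
    lam = damping
    while lam <= cfg.damping_max:
        try:
            delta = np.linalg.solve(h + lam * np.eye(m), -grad)
        except np.linalg.LinAlgError:
            lam *= cfg.damping_increase
            continue
        w_new = w + delta
        f_new, _, _ = objective(arch, w_new, data, alpha, beta)
        if np.isfinite(f_new) and f_new <= f0:
            lam_next = max(lam * cfg.damping_decrease, cfg.damping_min)
            return w_new, True, lam_next
        lam *= cfg.damping_increase
    return w, False, lam


def _state_at(
    arch: Architecture,
    w: np.ndarray,
    data: Dataset,
    alpha: float,
    beta: float,
) -> tuple[RegularizationState, np.ndarray]:
    """Regularization state (γ, E_D, E_W, Hessian summaries) at weights w."""
    jac = residual_jacobian(arch, w, data)
    h = gauss_newton_hessian(jac, alpha, beta, reg_mask=_reg_mask(arch))
    logdet, tr_hinv, _ = _chol_summaries(h)
    _, e_d, e_w = objective(arch, w, data, alpha, beta)
    m = arch.n_weights
    gamma = m - 2.0 * alpha * tr_hinv
    state = RegularizationState(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        e_d=e_d,
        e_w=e_w,
        hessian_logdet=logdet,
        trace_hinv=tr_hinv,
    )
    return state, jac


def initialize_weights(arch: Architecture, config: TrainConfig) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    return rng.normal(0.0, config.init_scale, size=arch.n_weights)


def train(
    arch: Architecture,
    data: Dataset,
    config: TrainConfig | None = None,
    validation: Dataset | None = None,
) -> TrainedNetwork:
    """Full training loop: LM step → γ → (α, β) update, iterated to convergence.

    Stops on the epoch cap, a small gradient, a stalled objective, the
    damping cap, or (optionally) rising validation mean squared error.
    Deterministic for a fixed seed and configuration.
    """
    cfg = config or TrainConfig()
    n, m = data.n, arch.n_weights
    w = initialize_weights(arch, cfg)
    alpha = cfg.alpha_init
    var_t = float(np.var(data.targets))
    beta = cfg.beta_init if cfg.beta_init is not None else 1.0 / (
        2.0 * max(var_t, 1e-12)
    )

    history: list[dict] = []
    status = "max_epochs"
    damping = cfg.lm_damping
    stall_count = 0
    f_prev = None
    best_val = np.inf
    best_w = w.copy()
    fails = 0
    accepted_steps = 0
    epoch = 0

    jac_cur: np.ndarray | None = None
    for epoch in range(1, cfg.max_epochs + 1):
        w_new, accepted, damping = lm_step(
            arch, w, data, alpha, beta, damping, cfg, jac=jac_cur
        )
        if not accepted:
            status = "damping_cap"
            break
        w = w_new
        accepted_steps += 1

        state, jac = _state_at(arch, w, data, alpha, beta)
        jac_cur = jac  # Jacobian at the accepted w; reused by the next LM step
        f_val = state.objective_value
        if not np.isfinite(f_val):
            raise TrainingError(
                f"objective diverged at epoch {epoch} "
                f"(F={f_val}, alpha={alpha:.3e}, beta={beta:.3e})"
            )

        val_mse = np.nan
        if validation is not None:
            val_pred = forward(arch, w, validation.inputs)
            val_mse = float(np.mean((validation.targets - val_pred) ** 2))
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_w = w.copy()
                fails = 0
            else:
                fails += 1

        history.append(
            {
                "epoch": epoch,
                "F": f_val,
                "E_D": state.e_d,
                "E_W": state.e_w,
                "alpha": alpha,
                "beta": beta,
                "gamma": state.gamma,
                "val_mse": val_mse,
                "damping": damping,
            }
        )
        logger.info(
            "epoch %d: F=%.6g E_D=%.6g E_W=%.6g gamma=%.3f alpha=%.3e beta=%.3e",
            epoch, f_val, state.e_d, state.e_w, state.gamma, alpha, beta,
        )

        if validation is not None and cfg.early_stopping and fails >= cfg.patience:
            status = "early_stopping"
            break

        # weights converged at the current (alpha, beta)?
        grad_inf = float(np.max(np.abs(gradient(arch, w, data, alpha, beta, jac=jac))))
        weights_done = grad_inf < cfg.gradient_tol
        if not weights_done and f_prev is not None:
            rel = abs(f_prev - f_val) / max(abs(f_prev), 1e-300)
            stall_count = stall_count + 1 if rel < cfg.f_rel_tol else 0
            weights_done = stall_count >= cfg.f_rel_patience
            if weights_done:
                status = "objective_stalled"
        else:
            if weights_done:
                status = "gradient_tol"
        f_prev = f_val

        updates_active = bool(cfg.update_cadence)
        hyper_done = not updates_active
        if updates_active and accepted_steps % cfg.update_cadence == 0:
            try:
                alpha_new, beta_new = update_alpha_beta(
                    state, w, n, m, rule=cfg.alpha_update
                )
            except TrainingError as err:
                logger.warning("stopping evidence updates: %s", err)
                status = "update_failed"
                break
            hyper_rel = max(
                abs(alpha_new - alpha) / max(alpha, 1e-300),
                abs(beta_new - beta) / max(beta, 1e-300),
            )
            hyper_done = hyper_rel < cfg.hyper_rel_tol
            alpha, beta = alpha_new, beta_new
            # objective changed scale with the new (alpha, beta)
            f_prev, _, _ = objective(arch, w, data, alpha, beta)
            stall_count = 0

        if weights_done and hyper_done:
            break
        status = "max_epochs"

    early_active = validation is not None and cfg.early_stopping
    if early_active and np.isfinite(best_val):
        w = best_w

    if not early_active and cfg.max_epochs > 0 and status in (
        "gradient_tol", "objective_stalled", "max_epochs", "update_failed",
    ):
        # one polishing LM solve at the final (alpha, beta) so the reported
        # weights are the MAP for the reported hyperparameters
        w_fin, accepted, damping = lm_step(
            arch, w, data, alpha, beta, cfg.damping_min, cfg
        )
        if accepted:
            w = w_fin

    state, _ = _state_at(arch, w, data, alpha, beta)
    wv = WeightVector.from_flat(arch, w)
    return TrainedNetwork(
        arch=arch,
        weights=wv,
        state=state,
        history=history,
        status=status,
        n_epochs=epoch if cfg.max_epochs > 0 else 0,
        config=cfg,
    )
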