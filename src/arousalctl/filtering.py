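"""Recursive Bayesian filters for the augmented arousal dynamics.

The augmented state stacks the latent arousal ``x`` with either a
time-varying transition gain ``rho`` (adaptive track) or an additive
disturbance ``d`` (robust track).  Prediction linearizes the transition at
the incoming posterior mean (extended-Kalman style); the measurement update
folds the mixed Bernoulli + Gaussian observation in through its score ``g``
and curvature ``-h`` evaluated at the predicted state:

    Sigma_post = (Sigma_pred^{-1} + diag(h, 0))^{-1}
    mean_post  = mean_pred + Sigma_post @ (g, 0)'

i.e. posterior precision = prior precision + observed information.  The
update is computed as a rank-1 Sherman-Morrison downdate of the predicted
covariance, which remains valid when the auxiliary component has zero
variance.  Only the first (state) component receives direct observational
information; the gain/disturbance component learns purely through the
off-diagonal covariance coupling built up by prediction.

A 1-D nominal filter (random-walk-plus-control transition, same observation
update) serves the static-controller baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import (
    Observation,
    ObservationParams,
    StateNoiseParams,
    loglik_gradient,
    loglik_hessian,
)

__all__ = [
    "AugmentedBelief",
    "ProcessModel2D",
    "adaptive_model",
    "robust_model",
    "predict",
    "update",
    "FilterTrace",
    "filter_series",
    "NominalTrace",
    "filter_nominal",
]

_PSD_TOL = 1e-10


class FilterDivergence(RuntimeError):
    """Raised when a belief becomes non-finite or numerically unusable."""


@dataclass(frozen=True)
class AugmentedBelief:
    """Gaussian belief over the 2-D augmented state.

    ``mean[0]`` is the latent arousal state; ``mean[1]`` is the gain
    (adaptive track) or disturbance (robust track).  The covariance is kept
    symmetric positive semidefinite; the auxiliary variance may be zero
    (a point-mass prior), the state variance must be positive.
    """

    mean: np.ndarray
    cov: np.ndarray
    track: str

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(2)
        cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if self.track not in ("adaptive", "robust"):
            raise ValueError(f"track must be 'adaptive' or 'robust', got {self.track!r}")
        if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(cov)):
            raise FilterDivergence("non-finite belief")
        if abs(cov[0, 1] - cov[1, 0]) > _PSD_TOL:
            raise ValueError("covariance must be symmetric")
        if cov[0, 0] <= 0.0 or cov[1, 1] < 0.0:
            raise ValueError("state variance must be > 0 and auxiliary variance >= 0")
        if np.linalg.det(cov) < -_PSD_TOL:
            raise ValueError("covariance must be positive semidefinite")


@dataclass(frozen=True)
class ProcessModel2D:
    """Transition map, Jacobian and process covariance of one augmented track."""

    track: str
    transition: Callable[[np.ndarray, float], np.ndarray]
    jacobian: Callable[[np.ndarray], np.ndarray]
    process_cov: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.process_cov, dtype=float).reshape(2, 2)
        object.__setattr__(self, "process_cov", K)
        if K[0, 1] != 0.0 or K[1, 0] != 0.0:
            raise ValueError("process covariance must be diagonal")
        if K[0, 0] <= 0.0 or K[1, 1] < 0.0:
            raise ValueError("process variances must be (>0, >=0)")


def adaptive_model(noise: StateNoiseParams) -> ProcessModel2D:
    """Augmented model for the time-varying-gain track: f(x, rho) = (rho*x + u, rho)."""

    def transition(mean: np.ndarray, u: float) -> np.ndarray:
        x, rho = mean
        return np.array([rho * x + u, rho])

    def jacobian(mean: np.ndarray) -> np.ndarray:
        x, rho = mean
        return np.array([[rho, x], [0.0, 1.0]])

    return ProcessModel2D(
        track="adaptive",
        transition=transition,
        jacobian=jacobian,
        process_cov=np.diag([noise.process_var, noise.gain_walk_var]),
    )


def robust_model(noise: StateNoiseParams) -> ProcessModel2D:
    """Augmented model for the disturbance track: f(x, d) = (x + d + u, d)."""

    def transition(mean: np.ndarray, u: float) -> np.ndarray:
        x, d = mean
        return np.array([x + d + u, d])

    def jacobian(mean: np.ndarray) -> np.ndarray:
        return np.array([[1.0, 1.0], [0.0, 1.0]])

    return ProcessModel2D(
        track="robust",
        transition=transition,
        jacobian=jacobian,
        process_cov=np.diag([noise.process_var, noise.disturbance_walk_var]),
    )


def predict(
    belief: AugmentedBelief, control: float, model: ProcessModel2D
) -> AugmentedBelief:
    """One prediction step: propagate the mean, linearize the covariance.

    The Jacobian is evaluated at the incoming posterior mean; the
    environmental stimulus is deliberately absent (the estimator never sees
    it, matching the control design's ignorance of the stimulus schedule).
    """
    if belief.track != model.track:
        raise ValueError(f"belief track {belief.track!r} != model track {model.track!r}")
    if not np.all(np.isfinite(belief.mean)):
        raise FilterDivergence("non-finite belief mean entering predict")
    mean = model.transition(belief.mean, control)
    F = model.jacobian(belief.mean)
    cov = F @ belief.cov @ F.T + model.process_cov
    cov = 0.5 * (cov + cov.T)
    return AugmentedBelief(mean=mean, cov=cov, track=belief.track)


def _information_update(
    mean: np.ndarray, cov: np.ndarray, g: float, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-1 information update with observed information c = -h on component 0."""
    c = -h
    sigma_col = cov[:, 0]
    denom = 1.0 + c * cov[0, 0]
    if denom <= 0.0 or not np.isfinite(denom):
        raise FilterDivergence(
            f"singular posterior covariance (denominator {denom}, curvature {h})"
        )
    cov_post = cov - (c / denom) * np.outer(sigma_col, sigma_col)
    cov_post = 0.5 * (cov_post + cov_post.T)
    mean_post = mean + g * cov_post[:, 0]
    if not np.all(np.isfinite(mean_post)) or cov_post[0, 0] <= 0.0:
        raise FilterDivergence(
            f"numerical failure in measurement update: mean {mean_post}, "
            f"state variance {cov_post[0, 0]} (score {g}, curvature {h})"
        )
    return mean_post, cov_post


def update(
    belief_pred: AugmentedBelief,
    obs: Observation,
    params: ObservationParams,
    *,
    binary_channel: bool = True,
    tonic_channel: bool = True,
    iterate: bool = False,
    max_iter: int = 20,
    tol: float = 1e-10,
) -> AugmentedBelief:
    """Measurement update of the predicted belief.

    Default is the single Newton-style step: score and curvature evaluated
    at the predicted state mean.  With ``iterate=True`` the update is
    repeated to convergence on the posterior mode (Laplace covariance at the
    final iterate), used by the mode-consistency cross-checks.
    """
    x_eval = float(belief_pred.mean[0])
    g = loglik_gradient(
        obs, x_eval, params, binary_channel=binary_channel, tonic_channel=tonic_channel
    )
    h = loglik_hessian(
        obs, x_eval, params, binary_channel=binary_channel, tonic_channel=tonic_channel
    )
    mean_post, cov_post = _information_update(belief_pred.mean, belief_pred.cov, g, h)

    if iterate:
        # Newton iterations on the joint log-posterior; prior precision from
        # the predicted covariance (requires it to be nonsingular).
        prior_prec = np.linalg.inv(belief_pred.cov)
        mean = mean_post.copy()
        for _ in range(max_iter):
            x_i = float(mean[0])
            g_i = loglik_gradient(
                obs, x_i, params, binary_channel=binary_channel, tonic_channel=tonic_channel
            )
            h_i = loglik_hessian(
                obs, x_i, params, binary_channel=binary_channel, tonic_channel=tonic_channel
            )
            grad = -prior_prec @ (mean - belief_pred.mean) + np.array([g_i, 0.0])
            hess = -prior_prec + np.array([[h_i, 0.0], [0.0, 0.0]])
            step = np.linalg.solve(hess, grad)
            mean = mean - step
            if np.max(np.abs(step)) < tol:
                break
        x_f = float(mean[0])
        h_f = loglik_hessian(
            obs, x_f, params, binary_channel=binary_channel, tonic_channel=tonic_channel
        )
        cov_post = np.linalg.inv(prior_prec + np.array([[-h_f, 0.0], [0.0, 0.0]]))
        cov_post = 0.5 * (cov_post + cov_post.T)
        mean_post = mean

    return AugmentedBelief(mean=mean_post, cov=cov_post, track=belief_pred.track)


@dataclass
class FilterTrace:
    """Predicted and updated beliefs per step of a filtering pass."""

    predicted: list[AugmentedBelief] = field(default_factory=list)
    updated: list[AugmentedBelief] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        rows = []
        for k, (p, u) in enumerate(zip(self.predicted, self.updated)):
            rows.append(
                {
                    "step": k,
                    "x_pred": p.mean[0],
                    "x_post": u.mean[0],
                    "aux_pred": p.mean[1],
                    "aux_post": u.mean[1],
                    "var_x_post": u.cov[0, 0],
                    "var_aux_post": u.cov[1, 1],
                    "cov_post": u.cov[0, 1],
                }
            )
        return pd.DataFrame(rows)


def filter_series(
    observations: Sequence[Observation],
    controls: Sequence[float],
    model: ProcessModel2D,
    params: ObservationParams,
    initial_belief: AugmentedBelief,
) -> FilterTrace:
    """Strictly causal filtering pass over an observation sequence.

    ``controls[k]`` is the input applied between steps k and k+1; the
    predicted belief at step k+1 therefore uses it.  The belief at step k
    depends only on observations up to and including k.  An empty
    observation sequence returns a trace holding only the initial belief as
    its sole prediction.
    """
    if len(observations) != len(controls):
        raise ValueError(
            f"observations ({len(observations)}) and controls ({len(controls)}) "
            "must be aligned"
        )
    trace = FilterTrace()
    belief_pred = initial_belief
    if not observations:
        trace.predicted.append(belief_pred)
        return trace
    for obs, u in zip(observations, controls):
        trace.predicted.append(belief_pred)
        belief_post = update(belief_pred, obs, params)
        trace.updated.append(belief_post)
        belief_pred = predict(belief_post, float(u), model)
    return trace


@dataclass
class NominalTrace:
    """Scalar filter trace: predicted and posterior (mean, variance) per step."""

    mean_pred: np.ndarray
    var_pred: np.ndarray
    mean_post: np.ndarray
    var_post: np.ndarray


def filter_nominal(
    observations: Sequence[Observation],
    controls: Sequence[float],
    params: ObservationParams,
    noise: StateNoiseParams,
    *,
    initial_mean: float = 0.0,
    initial_var: float = 1.0,
    binary_channel: bool = True,
    tonic_channel: bool = True,
) -> NominalTrace:
    """1-D filter under the nominal transition x_{k+1} = x_k + u_k.

    This is the estimator behind the static baseline controller: it carries
    no gain or disturbance component, only the latent state.
    """
    if len(observations) != len(controls):
        raise ValueError("observations and controls must be aligned")
    K = len(observations)
    mp, vp = np.empty(K), np.empty(K)
    mu, vu = np.empty(K), np.empty(K)
    mean, var = float(initial_mean), float(initial_var)
    for k, (obs, u) in enumerate(zip(observations, controls)):
        mp[k], vp[k] = mean, var
        g = loglik_gradient(
            obs, mean, params, binary_channel=binary_channel, tonic_channel=tonic_channel
        )
        h = loglik_hessian(
            obs, mean, params, binary_channel=binary_channel, tonic_channel=tonic_channel
        )
        c = -h
        denom = 1.0 + c * var
        if denom <= 0.0 or not np.isfinite(denom):
            raise FilterDivergence(f"singular nominal update at step {k}")
        var_post = var - (c / denom) * var * var
        mean_post = mean + g * var_post
        mu[k], vu[k] = mean_post, var_post
        mean = mean_post + float(u)
        var = var_post + noise.process_var
    return NominalTrace(mean_pred=mp, var_pred=vp, mean_post=mu, var_post=vu)
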