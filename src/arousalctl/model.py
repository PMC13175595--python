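"""Observation model for latent cognitive arousal inferred from skin conductance.

A scalar latent arousal state ``x`` drives two conditionally independent
observation channels per time step:

* a binary skin-conductance-response (SCR) event ``n`` with Bernoulli
  probability ``q = sigmoid(gamma + x)``, and
* a continuous log-tonic skin-conductance level
  ``r ~ N(rho0 + rho1 * x, sigma_zeta^2)``.

The paper-style symbols ``rho0``/``rho1`` (tonic regression coefficients)
are named ``tonic_intercept``/``tonic_slope`` here so they never collide
with the time-varying state gain (also conventionally written ``rho``)
estimated by the adaptive filter.

This module is the single source of truth for the likelihood, its score
(first derivative in the state) and its curvature (second derivative),
which the recursive Bayesian filters consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ObservationParams",
    "StateNoiseParams",
    "Observation",
    "scr_probability",
    "calibrate_gamma",
    "log_observation_likelihood",
    "loglik_gradient",
    "loglik_hessian",
]

# Probabilities from the sigmoid are clamped into this open interval so the
# Bernoulli log-likelihood and its derivatives stay finite for any float state.
_Q_MIN = 1e-12
_Q_MAX = 1.0 - 1e-12

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ObservationParams:
    """Per-participant observation model parameters.

    Parameters
    ----------
    gamma
        Baseline log-odds offset of the SCR channel (dimensionless).
    tonic_intercept
        Intercept of the linear log-tonic channel (log-conductance units).
    tonic_slope
        Slope of the log-tonic channel (log-conductance per state unit);
        must be nonzero, otherwise the continuous channel carries no
        information about the state.
    tonic_noise_var
        Variance of the log-tonic measurement noise (log-conductance^2).
    """

    gamma: float
    tonic_intercept: float
    tonic_slope: float
    tonic_noise_var: float

    def __post_init__(self) -> None:
        if not self.tonic_noise_var > 0.0:
            raise ValueError(
                f"tonic_noise_var must be > 0, got {self.tonic_noise_var}"
            )
        if self.tonic_slope == 0.0:
            raise ValueError(
                "tonic_slope must be nonzero: a zero slope makes the "
                "continuous channel uninformative about the state"
            )


@dataclass(frozen=True)
class StateNoiseParams:
    """Process-noise variances of the latent dynamics.

    ``process_var`` is the per-step state noise variance; ``gain_walk_var``
    and ``disturbance_walk_var`` drive the random walks of the time-varying
    gain (adaptive track) and the disturbance input (robust track).
    """

    process_var: float
    gain_walk_var: float = 0.0
    disturbance_walk_var: float = 0.0

    def __post_init__(self) -> None:
        # zero is allowed so simulations can be run noise-free; the filters
        # require a strictly positive state-noise variance and enforce it at
        # process-model construction.
        if self.process_var < 0.0:
            raise ValueError(f"process_var must be >= 0, got {self.process_var}")
        if self.gain_walk_var < 0.0:
            raise ValueError("gain_walk_var must be >= 0")
        if self.disturbance_walk_var < 0.0:
            raise ValueError("disturbance_walk_var must be >= 0")


@dataclass(frozen=True)
class Observation:
    """One time step's observation pair (binary SCR event, log-tonic value)."""

    scr_event: int
    log_tonic: float

    def __post_init__(self) -> None:
        if self.scr_event not in (0, 1):
            raise ValueError(f"scr_event must be 0 or 1, got {self.scr_event}")


def scr_probability(state: float, params: ObservationParams) -> float:
    """Probability of an SCR event given the latent state.

    ``q = 1 / (1 + exp(-(gamma + x)))``, evaluated in a branch-stable form
    and clamped strictly inside (0, 1) so extreme states never yield 0 or 1.
    """
    z = params.gamma + state
    if z >= 0.0:
        q = 1.0 / (1.0 + math.exp(-z))
    else:
        ez = math.exp(z)
        q = ez / (1.0 + ez)
    return min(max(q, _Q_MIN), _Q_MAX)


def calibrate_gamma(mean_scr_rate: float) -> float:
    """Baseline offset gamma from the average SCR event probability.

    Assumes the state sits near zero on average, so the base rate pins the
    sigmoid offset: ``gamma = logit(mean_scr_rate)``.
    """
    if not 0.0 < mean_scr_rate < 1.0:
        raise ValueError(
            f"mean_scr_rate must lie strictly in (0, 1), got {mean_scr_rate}"
        )
    return math.log(mean_scr_rate / (1.0 - mean_scr_rate))


def _tonic_residual(obs: Observation, state: float, params: ObservationParams) -> float:
    return obs.log_tonic - params.tonic_intercept - params.tonic_slope * state


def log_observation_likelihood(
    obs: Observation,
    state: float,
    params: ObservationParams,
    *,
    binary_channel: bool = True,
    tonic_channel: bool = True,
) -> float:
    """Joint log-likelihood of one observation given the state.

    The two channels are conditionally independent given the state, so the
    log-likelihood is the Bernoulli term plus the Gaussian log-density of
    the log-tonic value.  Either channel can be switched off (used by the
    filter-reduction cross-checks).
    """
    total = 0.0
    if binary_channel:
        q = scr_probability(state, params)
        total += obs.scr_event * math.log(q) + (1 - obs.scr_event) * math.log(1.0 - q)
    if tonic_channel:
        resid = _tonic_residual(obs, state, params)
        v = params.tonic_noise_var
        total += -0.5 * (_LOG_2PI + math.log(v)) - 0.5 * resid * resid / v
    return total


def loglik_gradient(
    obs: Observation,
    state: float,
    params: ObservationParams,
    *,
    binary_channel: bool = True,
    tonic_channel: bool = True,
) -> float:
    """Score of the observation log-likelihood in the state.

    ``g = (n - q) + rho1 * (r - rho0 - rho1*x) / sigma_zeta^2``.
    """
    g = 0.0
    if binary_channel:
        g += obs.scr_event - scr_probability(state, params)
    if tonic_channel:
        g += params.tonic_slope * _tonic_residual(obs, state, params) / params.tonic_noise_var
    return g


def loglik_hessian(
    obs: Observation,
    state: float,
    params: ObservationParams,
    *,
    binary_channel: bool = True,
    tonic_channel: bool = True,
) -> float:
    """Curvature of the observation log-likelihood in the state.

    ``-q(1-q) - rho1^2 / sigma_zeta^2``; strictly negative whenever the
    tonic channel is on, and never positive.  Does not depend on the
    observed values, only on the evaluation state.
    """
    h = 0.0
    if binary_channel:
        q = scr_probability(state, params)
        h -= q * (1.0 - q)
    if tonic_channel:
        h -= params.tonic_slope**2 / params.tonic_noise_var
    return h
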