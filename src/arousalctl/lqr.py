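"""Scalar LQR machinery: discrete algebraic Riccati equation, feedback gains,
and set-point (equilibrium) inputs for the adaptive and robust designs.

For the scalar system x_{k+1} = a x_k + u_k with stage cost
Q (x - x*)^2 + R (u - u*)^2, the infinite-horizon value satisfies the
discrete algebraic Riccati equation

    P = Q + a^2 P - a^2 P^2 / (P + R),

whose unique positive root is the positive solution of
P^2 + (R - Q - a^2 R) P - Q R = 0.  The optimal feedback gain is
l = a P / (P + R), applied around the set point: u = u* - l (x - x*).

The equilibrium input u* absorbs the estimated model deviation: for the
adaptive track (transition gain rho) steady state at x* needs
u* = x* (1 - rho); for the robust track (additive disturbance d) it needs
u* = -d, exact disturbance cancellation.  The static baseline freezes the
auxiliary quantity at its nominal value (rho = 1, d = 0), so its u* is
always zero and only the feedback term acts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ControlWeights",
    "ControlLaw",
    "solve_scalar_dare",
    "feedback_gain",
    "equilibrium_input_adaptive",
    "equilibrium_input_robust",
    "control_action",
    "adaptive_law",
    "robust_law",
    "static_law",
]

# Transient filter excursions of the gain estimate are clamped to this range
# before entering the Riccati solve, avoiding pathological feedback gains.
GAIN_ESTIMATE_CLAMP = (-2.0, 2.0)


@dataclass(frozen=True)
class ControlWeights:
    """Quadratic stage-cost weights: state_weight Q and input_weight R, both > 0."""

    state_weight: float = 1.0
    input_weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.state_weight > 0.0:
            raise ValueError(f"state_weight must be > 0, got {self.state_weight}")
        if not self.input_weight > 0.0:
            raise ValueError(f"input_weight must be > 0, got {self.input_weight}")


@dataclass(frozen=True)
class ControlLaw:
    """Frozen-parameter LQR law: u = equilibrium_input - gain * (x - target)."""

    gain: float
    equilibrium_input: float
    target: float
    riccati_value: float

    def __post_init__(self) -> None:
        if not self.riccati_value > 0.0:
            raise ValueError("riccati_value must be > 0")


def solve_scalar_dare(a: float, weights: ControlWeights) -> float:
    """Unique positive root of the scalar discrete algebraic Riccati equation."""
    if not math.isfinite(a):
        raise ValueError(f"transition coefficient must be finite, got {a}")
    Q, R = weights.state_weight, weights.input_weight
    b = R - Q - a * a * R
    # P^2 + b P - Q R = 0; the product of roots is -QR < 0, so exactly one
    # root is positive.
    P = 0.5 * (-b + math.sqrt(b * b + 4.0 * Q * R))
    return P


def feedback_gain(a: float, P: float, weights: ControlWeights) -> float:
    """LQR feedback gain l = a P / (P + R)."""
    if not P > 0.0:
        raise ValueError(f"Riccati value must be > 0, got {P}")
    return a * P / (P + weights.input_weight)


def equilibrium_input_adaptive(target: float, gain_estimate: float) -> float:
    """Steady-state input holding x* under transition gain rho: u* = x* (1 - rho)."""
    return target * (1.0 - gain_estimate)


def equilibrium_input_robust(disturbance_estimate: float) -> float:
    """Steady-state input cancelling the estimated disturbance: u* = -d."""
    return -disturbance_estimate


def control_action(state_estimate: float, law: ControlLaw) -> float:
    """Set-point LQR action u = u* - l (x_hat - x*)."""
    return law.equilibrium_input - law.gain * (state_estimate - law.target)


def adaptive_law(
    target: float,
    gain_estimate: float,
    weights: ControlWeights,
    *,
    clamp: tuple[float, float] = GAIN_ESTIMATE_CLAMP,
) -> ControlLaw:
    """Adaptive LQR law at the current gain estimate (re-solved each step).

    The gain estimate is clamped before the Riccati solve; the equilibrium
    input uses the clamped value so the law is internally consistent.
    """
    rho = min(max(gain_estimate, clamp[0]), clamp[1])
    P = solve_scalar_dare(rho, weights)
    return ControlLaw(
        gain=feedback_gain(rho, P, weights),
        equilibrium_input=equilibrium_input_adaptive(target, rho),
        target=target,
        riccati_value=P,
    )


def robust_law(
    target: float, disturbance_estimate: float, weights: ControlWeights
) -> ControlLaw:
    """Robust LQR law: fixed unit-gain Riccati solution, u* cancels d-hat."""
    P = solve_scalar_dare(1.0, weights)
    return ControlLaw(
        gain=feedback_gain(1.0, P, weights),
        equilibrium_input=equilibrium_input_robust(disturbance_estimate),
        target=target,
        riccati_value=P,
    )


def static_law(target: float, weights: ControlWeights, track: str = "adaptive") -> ControlLaw:
    """Static baseline law: auxiliary quantity frozen at its nominal value.

    Adaptive analogue freezes rho = 1 (so u* = 0); robust analogue freezes
    d = 0 (so u* = 0).  Both reduce to pure feedback around the target with
    the unit-gain Riccati solution.
    """
    if track == "adaptive":
        return adaptive_law(target, 1.0, weights)
    if track == "robust":
        return robust_law(target, 0.0, weights)
    raise ValueError(f"track must be 'adaptive' or 'robust', got {track!r}")
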