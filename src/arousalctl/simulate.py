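"""Ground-truth simulators for the latent arousal dynamics.

Three transition families are supported:

* nominal:       x_{k+1} = x_k + s_k + u_k + nu_k
* time-varying:  x_{k+1} = rho_k x_k + s_k + u_k + nu_k,   rho random walk
* disturbed:     x_{k+1} = x_k + d_k + s_k + u_k + nu_k,   d random walk

One time step is an abstract discrete index; scenario lengths and block
durations are configuration values, not claims about wall-clock seconds.
All randomness flows through a caller-supplied :class:`numpy.random.Generator`
so a run is a pure function of (parameters, schedule, seed).  Within a step
the draw order is fixed (SCR event, tonic noise, process noise, walk noise)
so traces are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import Observation, ObservationParams, StateNoiseParams, scr_probability

__all__ = [
    "StimulusSchedule",
    "TruthTrajectory",
    "make_stimulus_schedule",
    "step_nominal",
    "step_timevarying",
    "step_disturbed",
    "sample_observation",
    "simulate_truth",
]


@dataclass(frozen=True)
class StimulusSchedule:
    """Per-step environmental stimulus values with block labels."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("stimulus schedule must be a nonempty 1-D sequence")
        if len(self.labels) != values.size:
            raise ValueError(
                f"labels ({len(self.labels)}) and values ({values.size}) "
                "must have identical length"
            )

    @property
    def length(self) -> int:
        return int(self.values.size)


def make_stimulus_schedule(
    blocks: Sequence[tuple[str, int, float]],
) -> StimulusSchedule:
    """Build a piecewise-constant stimulus schedule from (tag, duration, amplitude) blocks."""
    if not blocks:
        raise ValueError("block list must be nonempty")
    values: list[float] = []
    labels: list[str] = []
    for tag, duration, amplitude in blocks:
        if not (isinstance(duration, (int, np.integer)) and duration > 0):
            raise ValueError(f"block duration must be a positive integer, got {duration}")
        values.extend([float(amplitude)] * int(duration))
        labels.extend([str(tag)] * int(duration))
    return StimulusSchedule(values=np.array(values), labels=tuple(labels))


def step_nominal(
    state: float,
    stimulus: float,
    control: float,
    noise: StateNoiseParams,
    rng: np.random.Generator,
) -> float:
    """One nominal transition; deterministic when ``process_var`` is zero."""
    nu = rng.normal(0.0, math.sqrt(noise.process_var)) if noise.process_var > 0 else 0.0
    return state + stimulus + control + nu


def step_timevarying(
    state: float,
    gain: float,
    stimulus: float,
    control: float,
    noise: StateNoiseParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Time-varying-gain transition: state uses the CURRENT gain, then the gain walks."""
    nu = rng.normal(0.0, math.sqrt(noise.process_var)) if noise.process_var > 0 else 0.0
    eps = (
        rng.normal(0.0, math.sqrt(noise.gain_walk_var))
        if noise.gain_walk_var > 0
        else 0.0
    )
    return gain * state + stimulus + control + nu, gain + eps


def step_disturbed(
    state: float,
    disturbance: float,
    stimulus: float,
    control: float,
    noise: StateNoiseParams,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Disturbance-input transition: state adds the CURRENT disturbance, then it walks."""
    nu = rng.normal(0.0, math.sqrt(noise.process_var)) if noise.process_var > 0 else 0.0
    omega = (
        rng.normal(0.0, math.sqrt(noise.disturbance_walk_var))
        if noise.disturbance_walk_var > 0
        else 0.0
    )
    return state + disturbance + stimulus + control + nu, disturbance + omega


def sample_observation(
    state: float,
    params: ObservationParams,
    rng: np.random.Generator,
) -> Observation:
    """Draw one (SCR event, log-tonic) observation pair at the given state."""
    q = scr_probability(state, params)
    scr = int(rng.random() < q)
    sigma = math.sqrt(params.tonic_noise_var)
    tonic_mean = params.tonic_intercept + params.tonic_slope * state
    log_tonic = tonic_mean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    return Observation(scr_event=scr, log_tonic=log_tonic)


@dataclass
class TruthTrajectory:
    """Aligned per-step ground-truth record of one simulated run.

    ``state[k]`` is the latent state at step k (before the k -> k+1
    transition); ``gain``/``disturbance`` are the auxiliary truth tracks
    (constant 1 / constant 0 when unused — the two tracks are mutually
    exclusive per run); ``controls[k]`` is the input applied between k and
    k+1.
    """

    state: np.ndarray
    gain: np.ndarray
    disturbance: np.ndarray
    observations: list[Observation]
    controls: np.ndarray
    stimulus: np.ndarray
    labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        n = len(self.state)
        for name in ("gain", "disturbance", "observations", "controls", "stimulus"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from state length {n}")

    def to_frame(self) -> pd.DataFrame:
        labels = self.labels if self.labels else ("",) * len(self.state)
        return pd.DataFrame(
            {
                "step": np.arange(len(self.state)),
                "stimulus": self.stimulus,
                "block_label": labels,
                "x_true": self.state,
                "gain_true": self.gain,
                "disturbance_true": self.disturbance,
                "u_applied": self.controls,
                "scr_event": [o.scr_event for o in self.observations],
                "log_tonic": [o.log_tonic for o in self.observations],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_truth(
    schedule: StimulusSchedule,
    obs_params: ObservationParams,
    noise: StateNoiseParams,
    rng: np.random.Generator,
    *,
    track: str = "nominal",
    controls: np.ndarray | None = None,
    x0: float = 0.0,
    gain0: float = 1.0,
    disturbance0: float = 0.0,
) -> TruthTrajectory:
    """Simulate an open-loop truth trajectory under a fixed control sequence.

    ``track`` selects the transition family: ``nominal``, ``adaptive``
    (time-varying gain) or ``robust`` (disturbance input).  With
    ``controls=None`` the run is uncontrolled (u = 0 throughout).
    """
    if track not in ("nominal", "adaptive", "robust"):
        raise ValueError(f"unknown track {track!r}")
    K = schedule.length
    u = np.zeros(K) if controls is None else np.asarray(controls, dtype=float)
    if u.size != K:
        raise ValueError(f"controls length {u.size} != schedule length {K}")

    states = np.empty(K)
    gains = np.empty(K)
    dists = np.empty(K)
    obs: list[Observation] = []
    x, rho, d = float(x0), float(gain0), float(disturbance0)
    for k in range(K):
        states[k], gains[k], dists[k] = x, rho, d
        obs.append(sample_observation(x, obs_params, rng))
        s = float(schedule.values[k])
        if track == "nominal":
            x = step_nominal(x, s, u[k], noise, rng)
        elif track == "adaptive":
            x, rho = step_timevarying(x, rho, s, u[k], noise, rng)
        else:
            x, d = step_disturbed(x, d, s, u[k], noise, rng)
    return TruthTrajectory(
        state=states,
        gain=gains,
        disturbance=dists,
        observations=obs,
        controls=u,
        stimulus=schedule.values.copy(),
        labels=schedule.labels,
    )
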