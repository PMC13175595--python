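"""Synthetic participant profiles and the canonical evaluation battery.

The original study parameterized its simulations from electrodermal
recordings of six participants; this module stands in for those fitted
models by sampling plausible parameter sets from documented ranges.  The
ranges are declared plausibility ranges for wrist-worn EDA under alternating
cognitive-stress / relaxation blocks, not estimates of any real participant.

A profile bundles the observation model (SCR base rate -> gamma, tonic
regression, noise variances) with truth-path specifications for the two
augmented tracks: a clipped random-walk transition gain (adaptive track) and
a mid-run step disturbance with a small walk (robust track) — conditions
under which joint estimation of the auxiliary quantity is actually needed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .loop import Scenario
from .model import ObservationParams, StateNoiseParams, calibrate_gamma
from .simulate import StimulusSchedule, make_stimulus_schedule

__all__ = [
    "GainPathSpec",
    "DisturbancePathSpec",
    "ParticipantProfile",
    "ReferenceSpec",
    "generate_profile",
    "build_reference",
    "default_battery",
    "PROFILE_SEEDS",
]

# Documented seeds of the canonical six-profile battery.
PROFILE_SEEDS = (101, 102, 103, 104, 105, 106)

# Default scenario geometry: 400 abstract steps per run, 50-step blocks.
SCENARIO_LENGTH = 400
BLOCK_LENGTH = 50


@dataclass(frozen=True)
class GainPathSpec:
    """Truth path of the time-varying transition gain (adaptive track).

    ``constant`` holds the start value; ``walk`` lets it drift with the
    profile's gain_walk_var, clipped to ``clip`` to keep the simulated
    physiology in a plausible mildly-stable-to-mildly-unstable band.
    """

    kind: str = "walk"
    start: float = 0.9
    clip: tuple[float, float] = (0.5, 1.1)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "walk"):
            raise ValueError(f"unknown gain path kind {self.kind!r}")
        if not self.clip[0] <= self.start <= self.clip[1]:
            raise ValueError("gain start must lie inside the clip range")


@dataclass(frozen=True)
class DisturbancePathSpec:
    """Truth path of the disturbance input (robust track).

    ``zero`` means no disturbance; ``step`` adds ``step_size`` at fraction
    ``step_frac`` of the run (plus the profile's disturbance walk);
    ``walk`` is the pure random walk.
    """

    kind: str = "step"
    step_frac: float = 0.5
    step_size: float = 0.4

    def __post_init__(self) -> None:
        if self.kind not in ("zero", "step", "walk"):
            raise ValueError(f"unknown disturbance path kind {self.kind!r}")
        if not 0.0 < self.step_frac < 1.0:
            raise ValueError("step_frac must lie in (0, 1)")


@dataclass(frozen=True)
class ParticipantProfile:
    """One synthetic participant: observation model, noise, truth paths."""

    profile_id: str
    obs_params: ObservationParams
    noise_params: StateNoiseParams
    gain_path: GainPathSpec
    disturbance_path: DisturbancePathSpec
    scr_base_rate: float

    def to_dict(self) -> dict:
        return {
            "profile_id": self.profile_id,
            "scr_base_rate": self.scr_base_rate,
            "obs_params": asdict(self.obs_params),
            "noise_params": asdict(self.noise_params),
            "gain_path": asdict(self.gain_path),
            "disturbance_path": asdict(self.disturbance_path),
            "note": "synthetic profile sampled from plausibility ranges",
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ParticipantProfile":
        gp = dict(d["gain_path"])
        gp["clip"] = tuple(gp["clip"])
        return cls(
            profile_id=d["profile_id"],
            scr_base_rate=d["scr_base_rate"],
            obs_params=ObservationParams(**d["obs_params"]),
            noise_params=StateNoiseParams(**d["noise_params"]),
            gain_path=GainPathSpec(**gp),
            disturbance_path=DisturbancePathSpec(**d["disturbance_path"]),
        )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


# Recording-quality screen: the continuous channel must carry at least this
# much Fisher information about the state (slope^2 / noise var).  Emulates
# the source study's exclusion of noisy / artifact-laden recordings.
TONIC_INFO_FLOOR = 2.0


def generate_profile(seed: int, profile_id: str | None = None) -> ParticipantProfile:
    """Sample one synthetic participant profile; deterministic per seed.

    Ranges: SCR base rate U(0.05, 0.4) -> gamma = logit(rate); tonic slope
    U(0.3, 1.5); tonic intercept U(-1, 1); tonic noise var log-U(0.05, 0.5);
    process var log-U(1e-3, 1e-2); gain walk var log-U(1e-5, 1e-4);
    disturbance walk var log-U(1e-4, 1e-3); disturbance step size
    U(0.25, 0.5) at mid-run.  The time-varying gain starts at the nominal
    value 1.0 and drifts from there (the adaptive track relaxes the nominal
    unit gain into a random walk).

    Draws whose tonic channel falls below ``TONIC_INFO_FLOOR`` are rejected
    and redrawn, mirroring the exclusion of low-quality recordings in the
    kind of wearable study this generator emulates.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    base_rate = float(rng.uniform(0.05, 0.4))
    while True:
        tonic_intercept = float(rng.uniform(-1.0, 1.0))
        tonic_slope = float(rng.uniform(0.3, 1.5))
        tonic_noise_var = _log_uniform(rng, 0.05, 0.5)
        if tonic_slope**2 / tonic_noise_var >= TONIC_INFO_FLOOR:
            break
    obs = ObservationParams(
        gamma=calibrate_gamma(base_rate),
        tonic_intercept=tonic_intercept,
        tonic_slope=tonic_slope,
        tonic_noise_var=tonic_noise_var,
    )
    noise = StateNoiseParams(
        process_var=_log_uniform(rng, 1e-3, 1e-2),
        gain_walk_var=_log_uniform(rng, 1e-5, 1e-4),
        disturbance_walk_var=_log_uniform(rng, 1e-4, 1e-3),
    )
    gain_path = GainPathSpec(kind="walk", start=1.0)
    dist_path = DisturbancePathSpec(
        kind="step", step_frac=0.5, step_size=float(rng.uniform(0.25, 0.5))
    )
    return ParticipantProfile(
        profile_id=profile_id or f"seed{seed}",
        obs_params=obs,
        noise_params=noise,
        gain_path=gain_path,
        disturbance_path=dist_path,
        scr_base_rate=base_rate,
    )


@dataclass(frozen=True)
class ReferenceSpec:
    """Piecewise-constant reference trajectory specification.

    ``binary`` alternates between exactly two distinct target levels;
    ``staircase`` visits at least three distinct levels (multi-step
    tracking).  ``levels`` and ``segment_lengths`` align one-to-one.
    """

    kind: str
    levels: tuple[float, ...]
    segment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "staircase"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if len(self.levels) != len(self.segment_lengths):
            raise ValueError("levels and segment_lengths must align")
        distinct = len(set(self.levels))
        if self.kind == "binary" and distinct != 2:
            raise ValueError(f"binary reference needs exactly 2 distinct levels, got {distinct}")
        if self.kind == "staircase" and distinct < 3:
            raise ValueError(f"staircase reference needs >= 3 distinct levels, got {distinct}")
        if any(n < 1 for n in self.segment_lengths):
            raise ValueError("segment lengths must be positive")


def build_reference(spec: ReferenceSpec, length: int) -> np.ndarray:
    """Render a reference spec into a per-step target sequence of given length."""
    total = int(sum(spec.segment_lengths))
    if total != length:
        raise ValueError(f"segment lengths sum to {total}, expected {length}")
    return np.repeat(np.asarray(spec.levels, dtype=float), spec.segment_lengths)


def _alternating_blocks(
    tag_a: str, amp_a: float, tag_b: str, amp_b: float, n_pairs: int, block: int
) -> list[tuple[str, int, float]]:
    blocks: list[tuple[str, int, float]] = []
    for _ in range(n_pairs):
        blocks.append((tag_a, block, amp_a))
        blocks.append((tag_b, block, amp_b))
    return blocks


def inhibition_scenario(track: str = "adaptive") -> Scenario:
    """Alternating relax/stress stimulation; target low during stress blocks."""
    n_pairs = SCENARIO_LENGTH // (2 * BLOCK_LENGTH)
    stim = make_stimulus_schedule(
        _alternating_blocks("relax", 0.0, "stress", 0.08, n_pairs, BLOCK_LENGTH)
    )
    spec = ReferenceSpec(
        kind="binary",
        levels=(0.5, 0.0) * n_pairs,
        segment_lengths=(BLOCK_LENGTH,) * (2 * n_pairs),
    )
    return Scenario(
        name="inhibition",
        stimulus=stim,
        reference=build_reference(spec, SCENARIO_LENGTH),
        controller_track=track,
    )


def excitation_scenario(track: str = "adaptive") -> Scenario:
    """Alternating neutral/calming stimulation; target high during calm blocks."""
    n_pairs = SCENARIO_LENGTH // (2 * BLOCK_LENGTH)
    stim = make_stimulus_schedule(
        _alternating_blocks("neutral", 0.0, "relax", -0.05, n_pairs, BLOCK_LENGTH)
    )
    spec = ReferenceSpec(
        kind="binary",
        levels=(0.5, 1.5) * n_pairs,
        segment_lengths=(BLOCK_LENGTH,) * (2 * n_pairs),
    )
    return Scenario(
        name="excitation",
        stimulus=stim,
        reference=build_reference(spec, SCENARIO_LENGTH),
        controller_track=track,
    )


def multistep_scenario(track: str = "adaptive") -> Scenario:
    """Staircase reference across three arousal levels with mild stimulation."""
    seg = SCENARIO_LENGTH // 5
    stim = make_stimulus_schedule(
        [
            ("relax", seg, 0.0),
            ("stress", seg, 0.05),
            ("relax", seg, 0.0),
            ("stress", seg, 0.05),
            ("relax", seg, 0.0),
        ]
    )
    spec = ReferenceSpec(
        kind="staircase",
        levels=(0.0, 0.75, 1.5, 0.75, 0.0),
        segment_lengths=(seg,) * 5,
    )
    return Scenario(
        name="multistep",
        stimulus=stim,
        reference=build_reference(spec, SCENARIO_LENGTH),
        controller_track=track,
    )


def default_battery() -> tuple[list[ParticipantProfile], list[Scenario]]:
    """The canonical evaluation battery: six profiles, three scenario shapes.

    Profiles are generated from the documented seeds and labelled P1..P6;
    scenarios default to the adaptive track and are re-targeted per track by
    ``Scenario.with_track``.  Regeneration is bit-identical.
    """
    profiles = [
        generate_profile(seed, profile_id=f"P{i + 1}")
        for i, seed in enumerate(PROFILE_SEEDS)
    ]
    scenarios = [inhibition_scenario(), excitation_scenario(), multistep_scenario()]
    return profiles, scenarios
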