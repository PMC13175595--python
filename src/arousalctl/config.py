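"""Structured run configuration: YAML parsing, validation, provenance hashing.

One flat-sectioned YAML file describes a run: which synthetic profile to use
(generation seed or JSON file), the scenario shape and controller track, the
LQR weights, and the seeds.  Unknown keys are errors, not warnings, so typos
never silently fall back to defaults.  Every output file carries the config
hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .loop import Scenario
from .lqr import ControlWeights
from .profiles import (
    ParticipantProfile,
    excitation_scenario,
    generate_profile,
    inhibition_scenario,
    multistep_scenario,
)

__all__ = ["RunConfig", "load_config", "config_hash"]

_SCENARIO_BUILDERS = {
    "inhibition": inhibition_scenario,
    "excitation": excitation_scenario,
    "multistep": multistep_scenario,
}

_SECTION_KEYS = {
    "profile": {"seed", "file"},
    "scenario": {"name", "track", "sign_clamp"},
    "weights": {"Q_a", "R_a", "Q_r", "R_r"},
    "run": {"seed", "n_seeds"},
}


@dataclass
class RunConfig:
    """Validated configuration for simulate/run/battery commands."""

    profile_seed: int | None = 101
    profile_file: str | None = None
    scenario_name: str = "inhibition"
    track: str = "adaptive"
    sign_clamp: str | None = None
    weights_adaptive: ControlWeights = field(default_factory=ControlWeights)
    weights_robust: ControlWeights = field(default_factory=ControlWeights)
    seed: int = 1
    n_seeds: int = 20
    raw: dict = field(default_factory=dict)

    def build_profile(self) -> ParticipantProfile:
        if self.profile_file is not None:
            data = json.loads(Path(self.profile_file).read_text())
            return ParticipantProfile.from_dict(data)
        return generate_profile(self.profile_seed)

    def build_scenario(self) -> Scenario:
        scenario = _SCENARIO_BUILDERS[self.scenario_name](self.track)
        if self.sign_clamp is not None:
            scenario = Scenario(
                name=scenario.name,
                stimulus=scenario.stimulus,
                reference=scenario.reference,
                controller_track=scenario.controller_track,
                sign_clamp=self.sign_clamp,
            )
        return scenario

    def weights_for(self, track: str) -> ControlWeights:
        return self.weights_adaptive if track == "adaptive" else self.weights_robust


def _check_keys(section: str, mapping: dict) -> None:
    unknown = set(mapping) - _SECTION_KEYS[section]
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {sorted(unknown)}")


def load_config(path: str | Path | None) -> RunConfig:
    """Parse and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping of sections")
    unknown_sections = set(data) - set(_SECTION_KEYS)
    if unknown_sections:
        raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
    cfg = RunConfig(raw=data)

    prof = data.get("profile", {})
    _check_keys("profile", prof)
    if "file" in prof:
        cfg.profile_file = str(prof["file"])
        cfg.profile_seed = None
    elif "seed" in prof:
        cfg.profile_seed = int(prof["seed"])

    scen = data.get("scenario", {})
    _check_keys("scenario", scen)
    cfg.scenario_name = scen.get("name", cfg.scenario_name)
    if cfg.scenario_name not in _SCENARIO_BUILDERS:
        raise ValueError(f"unknown scenario name {cfg.scenario_name!r}")
    cfg.track = scen.get("track", cfg.track)
    if cfg.track not in ("adaptive", "robust"):
        raise ValueError(f"unknown track {cfg.track!r}")
    cfg.sign_clamp = scen.get("sign_clamp", None)

    w = data.get("weights", {})
    _check_keys("weights", w)
    cfg.weights_adaptive = ControlWeights(
        state_weight=float(w.get("Q_a", 1.0)), input_weight=float(w.get("R_a", 1.0))
    )
    cfg.weights_robust = ControlWeights(
        state_weight=float(w.get("Q_r", 1.0)), input_weight=float(w.get("R_r", 1.0))
    )

    run = data.get("run", {})
    _check_keys("run", run)
    cfg.seed = int(run.get("seed", cfg.seed))
    cfg.n_seeds = int(run.get("n_seeds", cfg.n_seeds))
    if cfg.n_seeds < 1:
        raise ValueError("run.n_seeds must be >= 1")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    payload = {
        "profile_seed": cfg.profile_seed,
        "profile_file": cfg.profile_file,
        "scenario": cfg.scenario_name,
        "track": cfg.track,
        "sign_clamp": cfg.sign_clamp,
        "Q_a": cfg.weights_adaptive.state_weight,
        "R_a": cfg.weights_adaptive.input_weight,
        "Q_r": cfg.weights_robust.state_weight,
        "R_r": cfg.weights_robust.input_weight,
        "seed": cfg.seed,
        "n_seeds": cfg.n_seeds,
    }
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
    return digest.hexdigest()[:16]
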