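"""Run configuration: every tunable constant of the simulator in one place.

A :class:`RunConfig` loads from YAML or JSON with strict validation —
unknown keys are rejected by name, ranges are checked on construction — and
round-trips losslessly, so identical configs plus identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .esgp import ReservoirSpec


@dataclass(frozen=True)
class RunConfig:
    # scene / clock
    grid: int = 16                     # coarse sensor grid (16 x 16)
    full_res: int = 128                # full-resolution map size
    n_frames: int = 6                  # movie frames = saccade epochs
    iterations_per_saccade: int = 16
    ms_per_iteration: int = 12
    # salience
    rho_sd: float = 1.0 / 16.0         # component-bump sd, image units
    decay_a: float = 0.5               # fading weight of previous maps
    fovea_sd: float = 0.05
    bg_floor: float = 0.2
    shape_softmax_sd: float = 15.0
    sigma_obj_min: float = 0.12
    sigma_obj_max: float = 0.9
    # oculomotor
    decision_radius: float = 0.06
    hand_radius: float = 0.10
    gain: float = 0.35
    # inference
    prior_mode: str = "uniform"        # "uniform" | "biased"
    prior_big: float = 0.5
    mix_rest: float = 0.5
    beta: float = 1.0
    obs_angle_noise: float = 8.0       # deg; visual read-out noise on angles
    obs_pos_noise: float = 0.02        # visual read-out noise on hand position
    # generator
    noise_sd: float = 2.5              # deg, per joint-angle channel
    pos_noise: float = 0.015
    actor_angle_sd: float = 6.0
    actor_via_sd: float = 0.03
    n_actors: int = 6
    n_moves_per_actor: int = 50
    # reservoir / readout
    n_units: int = 100
    spectral_radius: float = 0.9
    leak_rate: float = 0.5
    input_scaling: float = 0.5
    ridge_lam: float = 1.0
    washout: int = 1                   # frames of position evidence discarded
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (self.grid > 0, "grid must be positive"),
            (self.full_res % self.grid == 0,
             "full_res must be divisible by grid"),
            (self.n_frames >= 1, "n_frames must be >= 1"),
            (0.0 <= self.decay_a < 1.0, "decay_a must lie in [0, 1)"),
            (self.rho_sd > 0, "rho_sd must be positive"),
            (self.fovea_sd > 0, "fovea_sd must be positive"),
            (0 < self.sigma_obj_min <= self.sigma_obj_max,
             "sigma_obj bounds must satisfy 0 < min <= max"),
            (self.decision_radius > 0, "decision_radius must be positive"),
            (0.0 < self.gain < 1.0, "gain must lie in (0, 1)"),
            (self.prior_mode in ("uniform", "biased"),
             "prior_mode must be 'uniform' or 'biased'"),
            (0.0 < self.prior_big < 1.0, "prior_big must lie in (0, 1)"),
            (0.0 <= self.mix_rest < 1.0, "mix_rest must lie in [0, 1)"),
            (self.beta > 0, "beta must be positive"),
            (self.noise_sd >= 0, "noise_sd must be non-negative"),
            (self.obs_angle_noise >= 0 and self.obs_pos_noise >= 0,
             "observation noise must be non-negative"),
            (self.n_actors >= 1 and self.n_moves_per_actor >= 1,
             "actor and movement counts must be positive"),
            (0.0 <= self.spectral_radius < 1.0,
             "spectral_radius must lie in [0, 1)"),
            (0.0 < self.leak_rate <= 1.0, "leak_rate must lie in (0, 1]"),
            (self.ridge_lam > 0, "ridge_lam must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @property
    def saccade_duration_ms(self) -> int:
        return self.iterations_per_saccade * self.ms_per_iteration

    @property
    def trial_duration_ms(self) -> int:
        return self.n_frames * self.saccade_duration_ms

    def reservoir_spec(self, seed: int) -> ReservoirSpec:
        return ReservoirSpec(
            n_units=self.n_units,
            spectral_radius=self.spectral_radius,
            leak_rate=self.leak_rate,
            input_scaling=self.input_scaling,
            seed=seed,
        )

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML/JSON file (defaults applied).

    An empty or missing file yields all defaults; unknown keys raise with
    the offending field named.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            data = json.loads(text) if text.strip() else {}
        else:
            data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data)}")
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config field(s): {', '.join(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=True))
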