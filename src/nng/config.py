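"""Game configuration.

The Nested Neuron Game is parameterised by the world geometry (start-target
distance, target radius), the per-press step sizes of the three couplings
(actor press -> sensor cursor, actor press -> actor cursor, sensor press ->
actor target) and the trial/batch structure. Step sizes default to 8 length
units per press, which at the 840-unit start distance yields trial lengths of
a few hundred steps for a trained ensemble.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class GameConfig:
    """World and schedule parameters of one Nested Neuron Game.

    Parameters
    ----------
    n_sensors, n_actors
        Units per group (the experiment uses 4 + 4).
    step_sensor_screen
        Displacement of the sensor-screen cursor per actor press (alpha).
    step_actor_screen
        Displacement of the actor-screen cursor per actor press (beta).
    step_target
        Displacement of the actor-screen target per sensor press (gamma).
    start_target_distance
        Distance between sensor cursor start and sensor target (840 units).
    target_radius
        Radius of the circular target area; reaching it (boundary inclusive)
        ends a trial successfully.
    trials_per_batch
        Trials played with one direction assignment before re-randomising.
    decision_availability
        Probability per step per unit of being granted a decision slot
        (~0.80, fitted to the sparse pressing of the human players).
    target_hidden_steps
        Number of initial steps during which the actor target is invisible;
        actor units receive a degenerate stimulus until then.
    """

    n_sensors: int = 4
    n_actors: int = 4
    step_sensor_screen: float = 8.0
    step_actor_screen: float = 8.0
    step_target: float = 8.0
    start_target_distance: float = 840.0
    target_radius: float = 40.0
    trials_per_batch: int = 6
    batches: int = 35
    max_steps_per_trial: int = 5000
    decision_availability: float = 0.80
    target_hidden_steps: int = 5
    windrose_jitter: float = 0.0872664625997165  # 5 degrees
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("step_sensor_screen", "step_actor_screen", "step_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.decision_availability <= 1:
            raise ValueError("decision_availability must be in (0, 1]")
        if self.trials_per_batch < 1:
            raise ValueError("trials_per_batch must be >= 1")
        if not 0 <= self.target_radius < self.start_target_distance:
            raise ValueError("target_radius must lie in [0, start_target_distance)")
        if self.max_steps_per_trial < 1:
            raise ValueError("max_steps_per_trial must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GameConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})


def load_config(path) -> dict:
    """Read a YAML config file with a flat ``game:`` block plus optional
    ``thompson:``, ``br:``, ``rl:`` and ``evolution:`` blocks.

    Returns the raw section dict; use :meth:`GameConfig.from_dict` on
    ``sections.get("game", {})``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return data


def save_config(path, sections: dict) -> None:
    Path(path).write_text(yaml.safe_dump(sections, sort_keys=True))


def dump_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))


def _json_default(obj):
    import numpy as np

    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
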