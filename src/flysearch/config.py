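"""Run configuration: defaults, config-file loading, flag overrides.

Every analysis default mirrors the experimental protocol it implements:
1 cm occupancy bins, 0.1 s time-downsampling, 1 mm distance-downsampling,
a 100 s test window, a 5 s initial-direction window, 2.5 mm overlap
proximity inside a 2 cm window for the intersection score, and a 5 min
initial exclusion for the pheromone test stage.  The effective
configuration is echoed verbatim into every report so runs are
reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    bin_size_cm: float = 1.0
    time_step_s: float = 0.1
    distance_step_cm: float = 0.1
    test_window_s: float = 100.0
    direction_window_s: float = 5.0
    intersection_prox_cm: float = 0.25
    intersection_window_cm: float = 2.0
    exclude_initial_s: float = 300.0
    pheromone_rate_hz: float = 10.0
    max_speed_cm_s: float = 50.0
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML/JSON file + overrides.

    Flags (non-None ``overrides``) take precedence over file values, which
    take precedence over defaults.  Unknown keys in the file are rejected.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)
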