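"""Analysis configuration: every tunable of the pipeline in one place.

Defaults reproduce the reference protocol: 60 s rectangular window on a
2.5 s TR (24 volumes), step 1 TR, 40% proportional density, k chosen from
2..10 by the elbow rule, correlation distance, 1000 rich-club nulls,
mean + 1 SD hub threshold, 0.3 mm FD censoring with a 200-volume floor.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml


@dataclasses.dataclass
class AnalysisConfig:
    window_length_s: float = 60.0
    window_step_volumes: int = 1
    tr_s: float = 2.5
    density: float = 0.40
    k_range: tuple[int, int] = (2, 10)
    k_fixed: int | None = None
    distance: str = "correlation"
    n_null: int = 1000
    hub_sd_multiplier: float = 1.0
    fd_threshold_mm: float = 0.3
    min_volumes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_range = tuple(self.k_range)  # type: ignore[assignment]
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        width = self.window_width_volumes
        if abs(self.window_length_s / self.tr_s - width) > 1e-9:
            raise ValueError(
                f"window_length_s={self.window_length_s} is not an integer "
                f"number of volumes at tr_s={self.tr_s}"
            )
        if width < 2:
            raise ValueError("window must span at least 2 volumes")
        if not (0.0 < self.density <= 1.0):
            raise ValueError("density must lie in (0, 1]")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.window_step_volumes < 1:
            raise ValueError("window_step_volumes must be >= 1")
        if len(self.k_range) != 2 or self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValueError("k_range must be (lo, hi) with 2 <= lo <= hi")
        if self.k_fixed is not None and self.k_fixed < 1:
            raise ValueError("k_fixed must be >= 1")
        if self.distance != "correlation":
            raise ValueError(f"unsupported distance '{self.distance}'")

    @property
    def window_width_volumes(self) -> int:
        return int(round(self.window_length_s / self.tr_s))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")
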