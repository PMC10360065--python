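"""Assay configuration.

All tunables of the screen live in one validated object so that a whole
analysis (thresholds, timing, mass tolerance) is reproducible from a single
JSON/YAML file.  Defaults encode the screening conditions: 37 degC, a 4 h
monitoring window read from a ~3 min instrument dead time, the 0.1 / 0.2
relative-absorbance-difference cut points, and a 5 ppm mass tolerance.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, model_validator


class AssayConfig(BaseModel):
    """Validated bundle of assay parameters.

    Parameters
    ----------
    temperature : float
        Assay temperature in degC.  Metadata only; no rate correction is
        applied.
    duration : float
        Monitoring window in seconds (default 4 h).
    stable_threshold, unstable_threshold : float
        Cut points on the relative absorbance difference separating
        stable / intermediate / unstable compounds.
    reactivity_threshold : float
        Relative absorbance difference (vs blank) above which a
        compound-reagent pair is flagged reactive.
    min_first_absorbance : float
        First-read absorbance (AU) below which results carry a low-signal
        flag: the relative statistic becomes unreliable when its
        denominator approaches the noise floor.
    dead_time : float
        Seconds between mixing and the first read.
    ppm_tolerance : float
        Mass-matching tolerance for adduct assignment, in ppm.
    """

    temperature: float = 37.0
    duration: float = 14400.0
    stable_threshold: float = 0.1
    unstable_threshold: float = 0.2
    reactivity_threshold: float = 0.2
    min_first_absorbance: float = 0.05
    dead_time: float = 180.0
    ppm_tolerance: float = 5.0

    @model_validator(mode="after")
    def _check(self) -> "AssayConfig":
        if not (0 < self.stable_threshold < self.unstable_threshold):
            raise ValueError("need 0 < stable_threshold < unstable_threshold")
        for name in ("reactivity_threshold", "min_first_absorbance",
                     "ppm_tolerance", "duration", "temperature"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dead_time < 0:
            raise ValueError("dead_time must be nonnegative")
        if self.duration <= self.dead_time:
            raise ValueError("duration must exceed dead_time")
        return self

    @classmethod
    def from_file(cls, path: str | Path) -> "AssayConfig":
        """Load a config from a JSON or YAML file (by extension)."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in {".yaml", ".yml"}:
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**(data or {}))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2), encoding="utf-8")


DEFAULT_CONFIG = AssayConfig()
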