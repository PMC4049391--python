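"""Run configuration: validated key=value files shared by CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .errors import ConfigError


@dataclass
class RunConfig:
    seed: int = 0
    tolerance: float = 0.02  # band co-migration, relative length
    alpha: float = 0.05
    correction: str = "bonferroni"
    threshold_um: float = 100.0  # high/low affinity boundary
    mode: str = "diagnostic"  # gel quantification mode
    verbosity: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tolerance <= 0.2:
            raise ConfigError(f"tolerance {self.tolerance} outside [0, 0.2]")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.correction not in ("bonferroni", "none"):
            raise ConfigError(f"unknown correction {self.correction!r}")
        if self.mode not in ("diagnostic", "least_squares"):
            raise ConfigError(f"unknown quantification mode {self.mode!r}")
        if self.threshold_um <= 0:
            raise ConfigError("threshold_um must be positive")


_CASTS = {f.name: f.type for f in fields(RunConfig)}


def load_config(path, **overrides) -> RunConfig:
    """Parse a key=value config file; unknown keys are rejected by name."""
    values: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in _CASTS:
                raise ConfigError(f"{path}:{lineno}: unknown configuration key {key!r}")
            values[key] = raw
    values.update({k: v for k, v in overrides.items() if v is not None})
    kwargs = {}
    for key, raw in values.items():
        target = {"seed": int, "verbosity": int, "tolerance": float,
                  "alpha": float, "threshold_um": float}.get(key, str)
        try:
            kwargs[key] = target(raw) if isinstance(raw, str) else raw
        except ValueError as exc:
            raise ConfigError(f"configuration key {key!r}: bad value {raw!r}") from exc
    return RunConfig(**kwargs)
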