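"""Run configuration shared by the CLI subcommands.

Holds the fixed analysis constants — 1 s averaging window with ~300 ms
edge windows, 16/20 µm neck annulus diameters, the expected cell area for
the target-area threshold — plus acquisition metadata that plain TIFFs do
not carry (fps, pixel size).  Values can be loaded from a TOML file and
overridden by CLI flags.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ParameterError


@dataclass
class RunConfig:
    pixel_size_um: float = 1.0
    fps: float = 200.0
    expected_area_um2: float = 350.0
    window_s: float = 1.0
    edge_window_s: float = 0.3
    annulus_inner_d_um: float = 16.0
    annulus_outer_d_um: float = 20.0
    min_trace_length_um: float = 20.0
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "fps", "expected_area_um2", "window_s",
                     "edge_window_s", "annulus_inner_d_um",
                     "annulus_outer_d_um", "min_trace_length_um"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.annulus_outer_d_um <= self.annulus_inner_d_um:
            raise ParameterError("annulus outer diameter must exceed inner")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
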