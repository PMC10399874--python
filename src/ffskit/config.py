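"""Run configuration: the single source of truth for every analysis constant.

All tunable constants of the pipeline live in :class:`RunConfig`.  Analysis
functions take their parameters explicitly; the CLI builds a ``RunConfig``
from a YAML file plus command-line overrides and passes the values down, so
that any output can be reproduced from the echoed configuration alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("ffskit")


@dataclass
class RunConfig:
    """Pipeline constants with their acquisition-anchored defaults.

    Defaults mirror a typical confocal photon-counting setup: 50 us pixel
    dwell and 400 nm pixels for raster (N&B) stacks, 472.73 us line time and
    ~80 nm pixels for membrane line scans.
    """

    # acquisition metadata defaults (overridable per file via sidecar/flags)
    pixel_dwell_time_s: float = 50e-6
    pixel_size_um: float = 0.4
    line_time_s: float = 472.73e-6
    line_pixel_size_um: float = 0.08

    # N&B analysis
    boxcar_window_frames: int = 8
    saturation_rate_hz: float = 1e6
    bleach_endpoint_fraction: float = 0.05

    # sFCS analysis
    block_size_lines: int = 1000
    trace_halfwidth_sigmas: float = 2.5
    background_exclusion_windows: float = 2.0
    multitau_points_per_octave: int = 16
    acf_segments: int = 8
    segment_rejection_sd: float = 3.0

    # fitting
    structure_parameter: float | None = None  # fixed S for sFCS fits (None = free)
    fit_weights: bool = True

    # calibration
    s_plausibility_band: tuple[float, float] = (3.0, 15.0)

    # provenance
    seed: int = 0
    output_dir: str = "."

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["s_plausibility_band"] = list(self.s_plausibility_band)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the configuration, embedded in outputs."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "s_plausibility_band" in data:
            data["s_plausibility_band"] = tuple(data["s_plausibility_band"])
        return cls(**data)

    def log_constants(self) -> None:
        for key, value in sorted(self.to_dict().items()):
            logger.info("config %s = %r", key, value)
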