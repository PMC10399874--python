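"""File formats: multi-page TIFF + JSON sidecar, CSV traces/curves, JSON fits.

Photon-count arrays travel as 16-bit unsigned multi-page TIFF, one page per
frame (stacks) or per line block (kymographs).  Acquisition metadata never
lives in vendor-specific TIFF tags: a JSON sidecar next to the image (same
stem, ``.json``) is the canonical channel, and missing metadata is an error
rather than a silent default.  Traces and correlation curves are plain CSV;
fits and calibrations are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import numpy as np
import tifffile

from .fcs_models import CorrelationCurve, FitResult
from .pointfcs import CalibrationResult
from .simulate import ImageStack, IntensityTrace, Kymograph

__all__ = [
    "write_stack", "read_stack",
    "write_kymograph", "read_kymograph",
    "write_trace", "read_trace",
    "write_curve", "read_curve",
    "write_fit", "write_calibration",
    "sidecar_path",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def _write_sidecar(path: str | Path, payload: dict[str, Any]) -> None:
    with open(sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _read_sidecar(path: str | Path) -> dict[str, Any]:
    sc = sidecar_path(path)
    if not sc.exists():
        return {}
    with open(sc) as fh:
        return json.load(fh)


def _as_uint16(counts: np.ndarray) -> np.ndarray:
    if counts.min(initial=0) < 0:
        raise ValueError("negative counts cannot be written")
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed the uint16 range")
    return counts.astype(np.uint16)


def _require(meta: dict[str, Any], key: str, override: Optional[float], path) -> float:
    if override is not None:
        return float(override)
    if key not in meta:
        raise ValueError(f"missing metadata '{key}' for {path}: no sidecar value "
                         "and no override given")
    return float(meta[key])


# ---------------------------------------------------------------------------
# image stacks

def write_stack(stack: ImageStack, path: str | Path,
                meta: Optional[dict[str, Any]] = None) -> None:
    """Write a stack as uint16 multi-page TIFF plus its JSON sidecar."""
    tifffile.imwrite(path, _as_uint16(stack.counts), photometric="minisblack")
    payload = {
        "kind": "image_stack",
        "pixel_dwell_time_s": stack.pixel_dwell_time,
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "laser_power_label": stack.laser_power_label,
    }
    payload.update(meta or {})
    _write_sidecar(path, payload)


def read_stack(path: str | Path,
               pixel_dwell_time: Optional[float] = None,
               pixel_size: Optional[float] = None,
               frame_interval: Optional[float] = None,
               allow_float: bool = False) -> ImageStack:
    """Read a multi-page TIFF stack; counts are preserved bit-exactly."""
    counts = tifffile.imread(path)
    if counts.ndim == 2:
        counts = counts[None]
    if not np.issubdtype(counts.dtype, np.integer):
        if not allow_float:
            raise ValueError(f"{path} has float pixels; pass allow_float=True "
                             "to round to integer counts")
        counts = np.rint(counts).astype(np.int64)
    meta = _read_sidecar(path)
    return ImageStack(
        counts=counts.astype(np.int64),
        pixel_dwell_time=_require(meta, "pixel_dwell_time_s", pixel_dwell_time, path),
        pixel_size=_require(meta, "pixel_size_um", pixel_size, path),
        frame_interval=_require(meta, "frame_interval_s", frame_interval, path),
        laser_power_label=str(meta.get("laser_power_label", "")),
    )


# ---------------------------------------------------------------------------
# kymographs

def write_kymograph(kymo: Kymograph, path: str | Path,
                    meta: Optional[dict[str, Any]] = None,
                    lines_per_page: int = 4096) -> None:
    """Write a kymograph as uint16 TIFF (line blocks as pages) + sidecar."""
    counts = _as_uint16(kymo.counts)
    with tifffile.TiffWriter(path) as writer:
        for i in range(0, counts.shape[0], lines_per_page):
            writer.write(counts[i:i + lines_per_page],
                         photometric="minisblack", contiguous=False)
    payload = {
        "kind": "kymograph",
        "line_time_s": kymo.line_time,
        "pixel_size_um": kymo.pixel_size,
        "n_lines": int(kymo.n_lines),
    }
    payload.update(meta or {})
    _write_sidecar(path, payload)


def read_kymograph(path: str | Path,
                   line_time: Optional[float] = None,
                   pixel_size: Optional[float] = None) -> Kymograph:
    with tifffile.TiffFile(path) as tif:
        counts = np.vstack([np.atleast_2d(page.asarray()) for page in tif.pages])
    if not np.issubdtype(counts.dtype, np.integer):
        raise ValueError(f"{path} has non-integer pixels")
    meta = _read_sidecar(path)
    n_lines = meta.get("n_lines")
    if n_lines is not None:
        counts = counts[: int(n_lines)]
    return Kymograph(
        counts=counts.astype(np.int64),
        line_time=_require(meta, "line_time_s", line_time, path),
        pixel_size=_require(meta, "pixel_size_um", pixel_size, path),
    )


def write_brightness_map(bmap, path: str | Path,
                         meta: Optional[dict[str, Any]] = None) -> None:
    """Write a BrightnessMap as a 3-channel float32 TIFF (epsilon, n, mask).

    Channel 0: brightness in counts/s/molecule (0 where invalid);
    channel 1: particle number (NaN where invalid); channel 2: valid mask.
    """
    stack = np.stack([
        bmap.epsilon.astype(np.float32),
        bmap.number.astype(np.float32),
        bmap.valid_mask.astype(np.float32),
    ])
    tifffile.imwrite(path, stack, photometric="minisblack")
    payload = {
        "kind": "brightness_map",
        "channels": ["epsilon_cps", "number", "valid_mask"],
        "pixel_dwell_time_s": bmap.pixel_dwell_time,
    }
    payload.update(meta or {})
    _write_sidecar(path, payload)


# ---------------------------------------------------------------------------
# traces and curves

def write_trace(trace: IntensityTrace, path: str | Path) -> None:
    t = np.arange(trace.counts.size) * trace.dt
    data = np.column_stack([t, trace.counts])
    np.savetxt(path, data, delimiter=",", header="time_s,counts", comments="",
               fmt=["%.9e", "%.6f"])


def read_trace(path: str | Path) -> IntensityTrace:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError(f"{path}: expected columns time_s,counts")
    t, counts = data[:, 0], data[:, 1]
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValueError(f"{path}: time column is not increasing")
    return IntensityTrace(counts=counts, dt=dt)


def write_curve(curve: CorrelationCurve, path: str | Path) -> None:
    cols = [curve.lags, curve.G]
    header = "lag_s,G"
    if curve.sd_G is not None:
        cols.append(curve.sd_G)
        header += ",sd_G"
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
               comments="", fmt="%.12e")


def read_curve(path: str | Path) -> CorrelationCurve:
    with open(path) as fh:
        header = fh.readline().strip().split(",")
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    sd = data[:, 2] if "sd_G" in header and data.shape[1] > 2 else None
    return CorrelationCurve(lags=data[:, 0], G=data[:, 1], sd_G=sd)


# ---------------------------------------------------------------------------
# fit / calibration reports

def write_fit(fit: FitResult, path: str | Path,
              meta: Optional[dict[str, Any]] = None) -> None:
    payload = dataclasses.asdict(fit)
    payload.update(meta or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_calibration(result: CalibrationResult, path: str | Path,
                      meta: Optional[dict[str, Any]] = None) -> None:
    payload = {
        "combined": dataclasses.asdict(result.combined),
        "pooled": {k: {"mean": v[0], "sd": v[1]} for k, v in result.pooled.items()},
        "n_measurements": result.n_measurements,
        "n_converged": result.n_converged,
        "dye_diffusion_um2_s": result.dye_diffusion,
        "waist_w0_um": result.waist_w0,
        "effective_volume_um3": result.effective_volume,
        "per_measurement": [dataclasses.asdict(f) for f in result.per_measurement],
    }
    payload.update(meta or {})
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_calibration_s(path: str | Path) -> float:
    """Structure parameter from a calibration JSON (for fixing S in sFCS)."""
    with open(path) as fh:
        payload = json.load(fh)
    return float(payload["combined"]["params"]["S"])
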