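"""Synthetic confocal photon-count data with the statistics FFS analysis assumes.

Three generators cover the three acquisition modalities:

* :func:`simulate_nb_stack` — raster image time-stacks for Number & Brightness.
  A fast compound-Poisson path: the frame interval (~0.8 s for a 128x128 image
  at 50 us dwell) far exceeds cytosolic diffusion times, so successive frames
  are statistically independent and each pixel-frame can be drawn directly
  from the stationary occupancy distribution.
* :func:`simulate_membrane_trace` / :func:`simulate_kymograph` — 2D Brownian
  dynamics of membrane-bound emitters under a Gaussian detection profile,
  rendered into a line-scan kymograph for scanning FCS.
* :func:`simulate_point_trace` — 3D Brownian dynamics in an elongated Gaussian
  detection volume (structure parameter S = axial/lateral waist ratio), for
  point-FCS calibration.

Oligomers carry ``subunits`` fluorophores, each independently fluorescent
with probability ``fluorescence_probability``; the number of bright subunits
per emitter is a fixed Binomial draw.  For the raster path this yields an
apparent molecular brightness of ``lambda * (1 + (s - 1) * p)`` counts per
dwell (``lambda`` = per-fluorophore counts/dwell), the closed form the
brightness-ratio (pf) analysis relies on.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``: identical config => bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numba
import numpy as np

__all__ = [
    "SimConfig",
    "ImageStack",
    "Kymograph",
    "IntensityTrace",
    "simulate_nb_stack",
    "simulate_membrane_trace",
    "simulate_kymograph",
    "simulate_point_trace",
]

_GEOMETRIES = ("raster3d", "membrane2d", "point3d")


# ---------------------------------------------------------------------------
# carriers

@dataclass
class ImageStack:
    """Photon-count image time-stack: ``counts[frame, row, col]``."""

    counts: np.ndarray
    pixel_dwell_time: float  # seconds
    pixel_size: float  # micrometres
    frame_interval: float  # seconds
    laser_power_label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be frames x height x width")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be an integer array")
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if self.pixel_dwell_time <= 0:
            raise ValueError("pixel_dwell_time must be positive")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]


@dataclass
class Kymograph:
    """Repeated line scans: ``counts[line, pixel]``."""

    counts: np.ndarray
    line_time: float  # seconds
    pixel_size: float  # micrometres

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be lines x pixels")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be an integer array")
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if self.line_time <= 0:
            raise ValueError("line_time must be positive")

    @property
    def n_lines(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.counts.shape[1]


@dataclass
class IntensityTrace:
    """Binned photon-count time series with bin width ``dt`` seconds."""

    counts: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 2:
            raise ValueError("counts must be a 1D array of length >= 2")
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return self.counts.size * self.dt

    @property
    def mean_rate(self) -> float:
        """Mean count rate in counts/second."""
        return float(self.counts.mean()) / self.dt


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimConfig:
    """Ground-truth parameters for the synthetic photon-count generators.

    Lengths are micrometres, times seconds, rates per second.
    ``n_particles_mean`` is the mean occupancy of the effective detection
    area (``pi*w0**2``, membrane) or volume (``pi**1.5 * w0**3 * S``, 3D);
    for the raster path it is simply the Poisson mean per pixel-frame.
    ``molecular_brightness`` is the peak detected count rate per bright
    fluorophore.
    """

    seed: int = 0
    geometry: str = "raster3d"
    diffusion_coefficient: float = 1.0  # um^2/s
    n_particles_mean: float = 5.0
    molecular_brightness: float = 10_000.0  # counts/s per bright fluorophore
    subunits: int = 1
    fluorescence_probability: float = 1.0
    bleach_rate: float = 0.0  # 1/s, irreversible
    background_rate: float = 0.0  # counts/s per pixel (raster) or per line (scan)
    waist_w0: float = 0.2  # um, lateral 1/e^2 radius
    structure_parameter: float = 5.0  # axial/lateral waist ratio

    # raster (N&B) modality
    n_frames: int = 100
    height: int = 128
    width: int = 128
    pixel_dwell_time: float = 50e-6  # s
    pixel_size: float = 0.4  # um
    frame_interval: Optional[float] = None  # s; default height*width*dwell

    # line-scan modality
    line_time: float = 472.73e-6  # s
    scan_pixels: int = 256
    scan_pixel_size: float = 0.08  # um

    # Brownian-dynamics boxes (periodic)
    box_factor: float = 20.0  # membrane box side, units of w0
    point_box_lateral: float = 20.0  # units of w0
    point_box_axial: float = 4.0  # units of S*w0

    # optional triplet-like blinking (telegraph), point modality only
    blink_off_rate: float = 0.0  # bright->dark, 1/s
    blink_on_rate: float = 0.0  # dark->bright, 1/s

    def __post_init__(self) -> None:
        if self.geometry not in _GEOMETRIES:
            raise ValueError(f"geometry must be one of {_GEOMETRIES}")
        if not 0.0 <= self.fluorescence_probability <= 1.0:
            raise ValueError("fluorescence_probability must be in [0, 1]")
        if self.subunits < 1:
            raise ValueError("subunits must be >= 1")
        for name in ("diffusion_coefficient", "n_particles_mean",
                     "molecular_brightness", "bleach_rate", "background_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.waist_w0 <= 0 or self.structure_parameter <= 0:
            raise ValueError("waist_w0 and structure_parameter must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def tau_d_2d(self) -> float:
        """Lateral diffusion time w0^2 / (4 D)."""
        return self.waist_w0**2 / (4.0 * self.diffusion_coefficient)

    @property
    def counts_per_dwell(self) -> float:
        """Per-fluorophore mean counts in one raster dwell (lambda)."""
        return self.molecular_brightness * self.pixel_dwell_time

    @property
    def apparent_brightness_per_dwell(self) -> float:
        """Closed-form apparent brightness of the raster path, counts/dwell.

        epsilon = lambda * E[q^2]/E[q] with q ~ Binomial(subunits, p),
        which reduces to lambda * (1 + (subunits - 1) * p).
        """
        s, p = self.subunits, self.fluorescence_probability
        return self.counts_per_dwell * (1.0 + (s - 1) * p)

    @property
    def raster_frame_interval(self) -> float:
        if self.frame_interval is not None:
            return self.frame_interval
        return self.height * self.width * self.pixel_dwell_time


# ---------------------------------------------------------------------------
# raster (N&B) path

def simulate_nb_stack(config: SimConfig) -> ImageStack:
    """Draw a raster photon-count stack from the stationary compound process.

    Per pixel and frame: occupancy ``m ~ Poisson(n * survival(t))`` with
    ``survival(t) = exp(-bleach_rate * t_frame)``; the total number of bright
    fluorophores among the ``m`` occupants is ``Binomial(m * subunits, p)``;
    detected counts are Poisson with mean ``(bright fluorophores) * lambda``
    plus Poisson background.  Valid when frames are temporally decorrelated
    (frame interval >> diffusion time), which holds for raster N&B stacks.
    """
    if config.geometry != "raster3d":
        raise ValueError("simulate_nb_stack requires geometry='raster3d'")
    if config.pixel_dwell_time <= 0:
        raise ValueError("pixel dwell time must be positive")

    rng = config.rng()
    frames, h, w = config.n_frames, config.height, config.width
    lam = config.counts_per_dwell
    t_frame = np.arange(frames) * config.raster_frame_interval
    survival = np.exp(-config.bleach_rate * t_frame)[:, None, None]

    occupancy = rng.poisson(config.n_particles_mean * survival, size=(frames, h, w))
    bright = rng.binomial(occupancy * config.subunits, config.fluorescence_probability)
    mean_counts = bright * lam + config.background_rate * config.pixel_dwell_time
    counts = rng.poisson(mean_counts).astype(np.int64)

    return ImageStack(
        counts=counts,
        pixel_dwell_time=config.pixel_dwell_time,
        pixel_size=config.pixel_size,
        frame_interval=config.raster_frame_interval,
        laser_power_label=f"synthetic seed={config.seed}",
    )


# ---------------------------------------------------------------------------
# Brownian-dynamics paths

def _subunit_counts(rng: np.random.Generator, config: SimConfig, m: int) -> np.ndarray:
    return rng.binomial(config.subunits, config.fluorescence_probability, size=m)


@numba.njit(fastmath=True)
def _bd_walk(rng, pos, q, n_steps, step_std, box, inv_width_sq, centre,
             scale, bleach_hazard, out):  # pragma: no cover - jitted
    """Fused Brownian walk + Gaussian detection weighting (see wrapper)."""
    m, ndim = pos.shape
    for t in range(n_steps):
        tot = 0.0
        for i in range(m):
            d2 = 0.0
            for a in range(ndim):
                x = pos[i, a] + step_std * rng.standard_normal()
                if x < 0.0:
                    x += box[a]
                elif x >= box[a]:
                    x -= box[a]
                pos[i, a] = x
                dx = x - centre[a]
                d2 += dx * dx * inv_width_sq[a]
            # weights below exp(-25) are negligible: skip the exp and let
            # bleaching act only where there is appreciable excitation
            if d2 < 25.0:
                w = np.exp(-d2)
                qi = q[i]
                if bleach_hazard > 0.0 and qi > 0:
                    p = bleach_hazard * w
                    lost = 0
                    for _ in range(qi):
                        if rng.random() < p:
                            lost += 1
                    if lost:
                        q[i] = qi - lost
                        qi = q[i]
                tot += qi * w
        out[t] = scale * tot


def _brownian_intensity(
    rng: np.random.Generator,
    n_steps: int,
    dt: float,
    box: np.ndarray,
    inv_width_sq: np.ndarray,
    q: np.ndarray,
    diffusion: float,
    rate_per_fluor: float,
    bleach_rate: float,
) -> np.ndarray:
    """Expected counts per bin for Brownian emitters in a periodic box.

    ``box`` gives the side length per axis, ``inv_width_sq[a]`` the factor
    ``2 / w_a^2`` of the Gaussian detection weight along axis ``a``; the
    detection centre sits at the box centre.  ``q`` holds the number of
    bright fluorophores per particle.  Optional irreversible bleaching darkens
    a fluorophore within a step with probability ``bleach_rate*dt*weight``
    (excitation-proportional).
    """
    pos = rng.uniform(0.0, 1.0, size=(q.size, box.size)) * box
    out = np.empty(n_steps)
    _bd_walk(
        rng,
        pos,
        q.astype(np.int64).copy(),
        n_steps,
        math.sqrt(2.0 * diffusion * dt),
        box.astype(np.float64),
        inv_width_sq.astype(np.float64),
        box / 2.0,
        rate_per_fluor * dt,
        bleach_rate * dt,
        out,
    )
    return out


def simulate_membrane_trace(config: SimConfig, duration: float) -> IntensityTrace:
    """Fluorescence trace of 2D Brownian emitters under a Gaussian spot.

    Particles diffuse in a periodic square box of side ``box_factor * w0``;
    expected counts per bin are ``sum_i q_i * brightness * dt *
    exp(-2 r_i^2 / w0^2)`` and detected counts are Poisson.  The bin width is
    ``config.line_time`` (one bin per line scan).
    """
    if config.geometry != "membrane2d":
        raise ValueError("simulate_membrane_trace requires geometry='membrane2d'")
    if config.line_time <= 0:
        raise ValueError("line_time must be positive")
    if config.box_factor < 10.0:
        raise ValueError("box side must be at least 10 * w0 for usable statistics")

    rng = config.rng()
    dt = config.line_time
    n_steps = int(round(duration / dt))
    if n_steps < 2:
        raise ValueError("duration must cover at least 2 bins")

    w0 = config.waist_w0
    side = config.box_factor * w0
    area_eff = math.pi * w0**2
    m = max(1, int(round(config.n_particles_mean * side**2 / area_eff)))
    q = _subunit_counts(rng, config, m)

    expected = _brownian_intensity(
        rng,
        n_steps,
        dt,
        box=np.array([side, side]),
        inv_width_sq=np.array([2.0 / w0**2, 2.0 / w0**2]),
        q=q,
        diffusion=config.diffusion_coefficient,
        rate_per_fluor=config.molecular_brightness,
        bleach_rate=config.bleach_rate,
    )
    counts = rng.poisson(expected).astype(np.int64)
    return IntensityTrace(counts=counts, dt=dt)


def simulate_point_trace(config: SimConfig, duration: float, dt: float) -> IntensityTrace:
    """Point-detection trace of 3D Brownian emitters in a Gaussian volume.

    Detection weight ``exp(-2(x^2+y^2)/w0^2 - 2 z^2/(S*w0)^2)``; counts per
    bin are Poisson around the instantaneous expected intensity.  Optional
    two-state blinking (telegraph with ``blink_off_rate``/``blink_on_rate``)
    modulates each particle between bright and dark.
    """
    if config.geometry != "point3d":
        raise ValueError("simulate_point_trace requires geometry='point3d'")
    if dt <= 0:
        raise ValueError("dt must be positive")

    rng = config.rng()
    n_steps = int(round(duration / dt))
    if n_steps < 2:
        raise ValueError("duration must cover at least 2 bins")

    w0 = config.waist_w0
    wz = config.structure_parameter * w0
    side_xy = config.point_box_lateral * w0
    side_z = config.point_box_axial * wz
    vol_eff = math.pi**1.5 * w0**3 * config.structure_parameter
    vol_box = side_xy**2 * side_z
    m = max(1, int(round(config.n_particles_mean * vol_box / vol_eff)))
    q = _subunit_counts(rng, config, m)

    blinking = config.blink_off_rate > 0.0 and config.blink_on_rate > 0.0
    expected = _brownian_intensity(
        rng,
        n_steps,
        dt,
        box=np.array([side_xy, side_xy, side_z]),
        inv_width_sq=np.array([2.0 / w0**2, 2.0 / w0**2, 2.0 / wz**2]),
        q=q if not blinking else np.ones(m, dtype=np.int64),
        diffusion=config.diffusion_coefficient,
        rate_per_fluor=config.molecular_brightness,
        bleach_rate=config.bleach_rate,
    )

    if blinking:
        # telegraph modulation drawn independently of positions; multiply the
        # per-particle weights in a second pass would require trajectories, so
        # blinking is modelled as a global multiplicative telegraph per
        # particle applied to an occupancy-resolved intensity.  For the small
        # particle numbers of point FCS this uses a per-step loop.
        expected = expected * _telegraph_factor(
            rng, n_steps, dt, m, q, config.blink_off_rate, config.blink_on_rate
        )

    expected = expected + config.background_rate * dt
    counts = rng.poisson(expected).astype(np.int64)
    return IntensityTrace(counts=counts, dt=dt)


def _telegraph_factor(
    rng: np.random.Generator,
    n_steps: int,
    dt: float,
    m: int,
    q: np.ndarray,
    k_off: float,
    k_on: float,
) -> np.ndarray:
    """Mean bright fraction per step from independent two-state switching."""
    p_eq = k_on / (k_on + k_off)
    state = rng.random(m) < p_eq
    p_off = min(1.0, k_off * dt)
    p_on = min(1.0, k_on * dt)
    total_q = max(1.0, float(q.sum()))
    factor = np.empty(n_steps)
    for i in range(n_steps):
        flips_off = rng.random(m) < p_off
        flips_on = rng.random(m) < p_on
        state = np.where(state, ~flips_off, flips_on)
        factor[i] = float(q[state].sum()) / total_q
    return factor


def simulate_kymograph(
    trace: IntensityTrace,
    config: SimConfig,
    membrane_center: float = 128.0,
    profile_sigma: float = 3.0,
    drift: float = 0.0,
) -> Kymograph:
    """Render a membrane trace into a line-scan kymograph.

    Each line's membrane counts are distributed across pixels by drawing one
    Gaussian-distributed position per photon (centre ``membrane_center +
    drift * line``, width ``profile_sigma``), which realises a multinomial
    split with the pixel-integrated Gaussian profile; per-line totals are
    conserved exactly.  Independent Poisson background (``background_rate``
    counts/s per line, spread uniformly over pixels) is added afterwards.
    """
    n_pixels = config.scan_pixels
    n_lines = trace.counts.size
    last_center = membrane_center + drift * (n_lines - 1)
    for c in (membrane_center, last_center):
        if not (3.0 * profile_sigma <= c <= n_pixels - 1 - 3.0 * profile_sigma):
            raise ValueError(
                "membrane centre +- 3 sigma leaves the pixel range "
                f"(centre {c:.2f} of {n_pixels} pixels)"
            )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x6B796D6F]))
    counts = np.asarray(trace.counts, dtype=np.int64)
    total = int(counts.sum())

    kymo = np.zeros((n_lines, n_pixels), dtype=np.int64)
    if total:
        line_idx = np.repeat(np.arange(n_lines), counts)
        centres = membrane_center + drift * line_idx
        pos = rng.normal(centres, profile_sigma)
        pix = np.clip(np.floor(pos + 0.5).astype(np.int64), 0, n_pixels - 1)
        np.add.at(kymo, (line_idx, pix), 1)

    if config.background_rate > 0.0:
        bg_mean = config.background_rate * trace.dt / n_pixels
        kymo += rng.poisson(bg_mean, size=kymo.shape)

    return Kymograph(counts=kymo, line_time=trace.dt, pixel_size=config.scan_pixel_size)
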