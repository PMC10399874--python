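"""Scanning FCS of membrane line scans.

A kymograph (repeated line scans perpendicular to a membrane) is reduced to
a membrane fluorescence time series, autocorrelated with a multi-tau scheme
and fitted with the 2D diffusion model; molecular brightness is the mean
count rate divided by the fitted particle number, B = <I> / N.

Processing stages:

1. :func:`detect_membrane` — block-averaged line profiles fitted with a
   Gaussian plus constant background give the membrane position over time.
2. :func:`align_lines` — integer-pixel shifts (interpolated between blocks)
   remove lateral drift; photon counts are never resampled, so the Poisson
   statistics and per-line totals are preserved exactly.
3. :func:`membrane_trace` — counts within +-halfwidth_sigmas * sigma of the
   aligned centre are summed per line; background estimated from pixels far
   outside the window is subtracted.
4. :func:`compute_acf` — multi-tau autocorrelation
   G(tau) = <F(t) F(t+tau)> / <F>^2 - 1 with symmetric normalisation and
   optional segment-wise averaging for per-lag uncertainties.
5. :func:`fit <ffskit.fcs_models.fit_acf>` + :func:`sfcs_brightness`.

:func:`run_sfcs` composes the stages and keeps every diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .fcs_models import CorrelationCurve, FitResult, fit_acf
from .nandb import BleachedFraction, bleached_fraction
from .simulate import IntensityTrace, Kymograph

__all__ = [
    "MembraneLocalization",
    "AlignmentResult",
    "TraceExtraction",
    "CorrelationCurve",
    "SfcsResult",
    "StageError",
    "detect_membrane",
    "align_lines",
    "membrane_trace",
    "compute_acf",
    "multitau_lags",
    "direct_acf",
    "sfcs_brightness",
    "run_sfcs",
]


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that raised it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class MembraneLocalization:
    """Per-block Gaussian membrane position along the scan axis."""

    block_size: int  # lines per block
    block_mid_lines: np.ndarray  # line index at block centre
    centers: np.ndarray  # pixels, sub-pixel
    sigmas: np.ndarray  # pixels
    amplitudes: np.ndarray  # counts/pixel/line at peak
    backgrounds: np.ndarray  # counts/pixel/line
    ok: np.ndarray  # bool per block

    @property
    def n_blocks(self) -> int:
        return self.centers.size


@dataclass
class AlignmentResult:
    kymograph: Kymograph
    shifts: np.ndarray  # integer pixels applied per line
    fractional_residual: np.ndarray  # sub-pixel remainder per line
    reference_center: float  # pixels


@dataclass
class TraceExtraction:
    trace: IntensityTrace
    center: float  # pixels, from the aligned pooled profile
    sigma: float  # pixels
    window: tuple[int, int]  # inclusive pixel bounds summed per line
    background_per_pixel: float  # counts/pixel/line
    n_clamped: int  # bins clamped to zero after background subtraction


@dataclass
class SfcsResult:
    """Full record of one scanning-FCS measurement."""

    localization: MembraneLocalization
    alignment: AlignmentResult
    extraction: TraceExtraction
    curve: CorrelationCurve
    fit: FitResult
    brightness: float  # counts/s/molecule
    bleach: BleachedFraction


def _gauss_const(x: np.ndarray, amp: float, center: float, sigma: float, bg: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((x - center) / sigma) ** 2) + bg


def _fit_profile(profile: np.ndarray) -> tuple[float, float, float, float]:
    """Gaussian + constant fit of a line profile; raises on failure."""
    x = np.arange(profile.size, dtype=np.float64)
    bg0 = float(np.median(profile))
    amp0 = float(profile.max() - bg0)
    c0 = float(profile.argmax())
    noise = float(profile.std())
    if amp0 <= 0 or amp0 < 2.0 * noise:
        raise ValueError("no peak contrast above background")
    # sigma floor 0.8 px: a diffraction-limited membrane profile spans several
    # pixels, and the floor keeps flat-noise profiles from being fitted as
    # single-pixel spikes
    p0 = [amp0, c0, 2.0, max(bg0, 0.0)]
    bounds = ([0.0, 0.0, 0.8, 0.0],
              [np.inf, profile.size - 1.0, profile.size / 4.0, np.inf])
    popt, _ = curve_fit(_gauss_const, x, profile, p0=p0, bounds=bounds, maxfev=10000)
    amp, center, sigma, bg = map(float, popt)
    resid_sd = float(np.std(profile - _gauss_const(x, *popt)))
    if amp < 4.0 * resid_sd:
        raise ValueError("fitted peak not significant against residual noise")
    return amp, center, sigma, bg


def detect_membrane(kymo: Kymograph, block_size: int = 1000) -> MembraneLocalization:
    """Locate the membrane per block of lines via Gaussian profile fits."""
    n_blocks = kymo.n_lines // block_size
    if n_blocks < 2:
        raise ValueError(
            f"need >= 2 blocks of {block_size} lines, got {kymo.n_lines} lines"
        )
    centers = np.full(n_blocks, np.nan)
    sigmas = np.full(n_blocks, np.nan)
    amps = np.full(n_blocks, np.nan)
    bgs = np.full(n_blocks, np.nan)
    ok = np.zeros(n_blocks, dtype=bool)
    mids = (np.arange(n_blocks) + 0.5) * block_size - 0.5

    for ib in range(n_blocks):
        profile = kymo.counts[ib * block_size:(ib + 1) * block_size].mean(axis=0)
        try:
            amps[ib], centers[ib], sigmas[ib], bgs[ib] = _fit_profile(profile)
            ok[ib] = True
        except (ValueError, RuntimeError):
            continue

    if not ok.any():
        raise ValueError("no block yielded a convergent membrane peak fit")
    return MembraneLocalization(
        block_size=block_size,
        block_mid_lines=mids,
        centers=centers,
        sigmas=sigmas,
        amplitudes=amps,
        backgrounds=bgs,
        ok=ok,
    )


def align_lines(kymo: Kymograph, loc: MembraneLocalization) -> AlignmentResult:
    """Shift each line by the negated drift of the membrane centre.

    Block centres are linearly interpolated to per-line positions; each line
    is shifted by the nearest integer offset (circularly, so per-line counts
    are exactly conserved) and the sub-pixel remainder is recorded.
    """
    if not loc.ok.any():
        raise ValueError("localization contains no valid blocks")
    mids = loc.block_mid_lines[loc.ok]
    centers = loc.centers[loc.ok]
    line_idx = np.arange(kymo.n_lines, dtype=np.float64)
    per_line_center = np.interp(line_idx, mids, centers)

    reference = float(centers.mean())
    offset = reference - per_line_center
    shifts = np.round(offset).astype(np.int64)
    residual = offset - shifts

    if np.abs(shifts).max(initial=0) > 0.1 * kymo.n_pixels:
        raise ValueError("alignment shift would displace > 10% of the profile")

    n_pix = kymo.n_pixels
    cols = (np.arange(n_pix)[None, :] - shifts[:, None]) % n_pix
    aligned = kymo.counts[np.arange(kymo.n_lines)[:, None], cols]
    out = Kymograph(counts=aligned, line_time=kymo.line_time, pixel_size=kymo.pixel_size)
    return AlignmentResult(
        kymograph=out,
        shifts=shifts,
        fractional_residual=residual,
        reference_center=reference,
    )


def membrane_trace(
    aligned: Kymograph,
    loc: MembraneLocalization,
    halfwidth_sigmas: float = 2.5,
    background_exclusion: float = 2.0,
) -> TraceExtraction:
    """Sum membrane counts per line and subtract the off-membrane background.

    The window is +-``halfwidth_sigmas * sigma`` around the centre of the
    pooled (all-lines) profile of the aligned kymograph; the background per
    pixel per line is estimated from pixels farther than
    ``background_exclusion`` times the window half-width from the centre.
    """
    profile = aligned.counts.mean(axis=0)
    try:
        _, center, sigma, _ = _fit_profile(profile)
    except (ValueError, RuntimeError) as exc:
        raise ValueError(f"pooled profile fit failed: {exc}") from exc

    half = halfwidth_sigmas * sigma
    lo = int(np.ceil(center - half))
    hi = int(np.floor(center + half))
    if lo < 0 or hi > aligned.n_pixels - 1 or hi < lo:
        raise ValueError("summation window collides with the image edge")

    pix = np.arange(aligned.n_pixels)
    bg_sel = np.abs(pix - center) > background_exclusion * half
    background = float(aligned.counts[:, bg_sel].mean()) if bg_sel.any() else 0.0

    window_width = hi - lo + 1
    raw = aligned.counts[:, lo:hi + 1].sum(axis=1).astype(np.float64)
    corrected = raw - background * window_width
    n_clamped = int((corrected < 0).sum())
    corrected = np.clip(corrected, 0.0, None)

    trace = IntensityTrace(counts=corrected, dt=aligned.line_time)
    return TraceExtraction(
        trace=trace,
        center=center,
        sigma=sigma,
        window=(lo, hi),
        background_per_pixel=background,
        n_clamped=n_clamped,
    )


# ---------------------------------------------------------------------------
# autocorrelation

def _acf_at_lags(series: np.ndarray, lags_bins: np.ndarray) -> np.ndarray:
    """Symmetrically normalised correlator at integer lags (in bins).

    G(k) = mean(F_t F_{t+k}) / (mean(F_t) mean(F_{t+k})) - 1 with both means
    taken over the overlapping range; invariant under rescaling of F, so it
    applies unchanged to the pairwise-summed series of higher octaves.
    """
    out = np.empty(lags_bins.size)
    for i, k in enumerate(lags_bins):
        a = series[:-k]
        b = series[k:]
        denom = a.mean() * b.mean()
        out[i] = (a * b).mean() / denom - 1.0 if denom > 0 else 0.0
    return out


def multitau_lags(n_bins: int, m: int = 16, min_avg: int = 16) -> list[tuple[int, np.ndarray]]:
    """Lag layout of the multi-tau scheme: (binning level, lags in bins)."""
    levels: list[tuple[int, np.ndarray]] = []
    length = n_bins
    level = 0
    while True:
        if level == 0:
            ks = np.arange(1, 2 * m + 1)
        else:
            ks = np.arange(m + 1, 2 * m + 1)
        ks = ks[ks < length - min_avg]
        if ks.size == 0:
            break
        levels.append((level, ks))
        length //= 2
        level += 1
        if length < 2 * m + min_avg:
            break
    return levels


def _multitau(series: np.ndarray, dt: float, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Multi-tau ACF of one segment: quasi-log lags (s) and G values."""
    layout = multitau_lags(series.size, m)
    if not layout:
        raise ValueError("trace too short for the multi-tau scheme")
    lags_all: list[np.ndarray] = []
    g_all: list[np.ndarray] = []
    s = series.astype(np.float64)
    current_level = 0
    for level, ks in layout:
        while current_level < level:
            n_even = (s.size // 2) * 2
            s = s[:n_even:2] + s[1:n_even:2]
            current_level += 1
        lags_all.append(ks * (dt * 2**level))
        g_all.append(_acf_at_lags(s, ks))
    return np.concatenate(lags_all), np.concatenate(g_all)


def direct_acf(trace: IntensityTrace, max_lag_bins: int) -> CorrelationCurve:
    """Brute-force correlator at every integer lag up to ``max_lag_bins``.

    Reference implementation used to validate the multi-tau estimator; the
    normalisation is identical, so values agree at unbinned lags to
    floating-point precision.
    """
    series = np.asarray(trace.counts, dtype=np.float64)
    ks = np.arange(1, max_lag_bins + 1)
    if ks.size == 0 or max_lag_bins >= series.size:
        raise ValueError("invalid maximum lag")
    g = _acf_at_lags(series, ks)
    return CorrelationCurve(lags=ks * trace.dt, G=g)


def compute_acf(
    trace: IntensityTrace,
    m: int = 16,
    n_segments: int = 8,
    reject_sd: float = 3.0,
    min_length: int = 1024,
) -> CorrelationCurve:
    """Multi-tau autocorrelation with segment-wise error estimation.

    The trace is cut into ``n_segments`` equal parts; segments whose mean
    intensity deviates more than ``reject_sd`` standard deviations from the
    across-segment mean are discarded (distorted passages, e.g. membrane
    detachment).  The curve is the across-segment mean, ``sd_G`` the
    standard error of that mean.  With ``n_segments=1`` the estimator is the
    plain multi-tau correlator of the full trace.
    """
    series = np.asarray(trace.counts, dtype=np.float64)
    if series.size < min_length:
        raise ValueError(f"trace must have at least {min_length} bins")
    if series.mean() <= 0:
        raise ValueError("zero-mean trace cannot be normalised")
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")

    if n_segments == 1:
        lags, g = _multitau(series, trace.dt, m)
        return CorrelationCurve(lags=lags, G=g, sd_G=None, n_segments=1)

    seg_len = series.size // n_segments
    segments = [series[i * seg_len:(i + 1) * seg_len] for i in range(n_segments)]
    means = np.array([s.mean() for s in segments])
    sd = means.std(ddof=1)
    keep = (np.abs(means - means.mean()) <= reject_sd * sd) if sd > 0 else np.ones(
        n_segments, dtype=bool)
    kept = [s for s, k in zip(segments, keep) if k]
    n_rejected = int(n_segments - len(kept))
    if not kept:
        raise ValueError("all segments rejected")

    curves = [_multitau(s, trace.dt, m) for s in kept]
    lags = curves[0][0]
    g_stack = np.vstack([g for _, g in curves])
    g_mean = g_stack.mean(axis=0)
    if len(kept) > 1:
        sd_g = g_stack.std(axis=0, ddof=1) / np.sqrt(len(kept))
    else:
        sd_g = None
    return CorrelationCurve(
        lags=lags, G=g_mean, sd_G=sd_g,
        n_segments=len(kept), n_rejected=n_rejected,
    )


def sfcs_brightness(trace: IntensityTrace, fit: FitResult) -> float:
    """Molecular brightness B = <I> / N in counts/s/molecule."""
    if not fit.converged:
        raise ValueError("fit did not converge; brightness undefined")
    n = fit.params.get("N", 0.0)
    if n <= 0:
        raise ValueError("fitted N must be positive")
    return trace.mean_rate / n


def run_sfcs(
    kymo: Kymograph,
    s_fixed: Optional[float] = 1.0,
    block_size: int = 1000,
    halfwidth_sigmas: float = 2.5,
    background_exclusion: float = 2.0,
    m: int = 16,
    n_segments: int = 8,
) -> SfcsResult:
    """Full scanning-FCS analysis of one kymograph.

    ``s_fixed`` pins the structure parameter during the 2D fit (pass the
    daily calibration value, or ``None`` to float it).  Any stage failure is
    re-raised as :class:`StageError` naming the stage.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except (ValueError, RuntimeError) as exc:
            if isinstance(exc, StageError):
                raise
            raise StageError(name, str(exc)) from exc

    loc = stage("detect_membrane", detect_membrane, kymo, block_size)
    alignment = stage("align_lines", align_lines, kymo, loc)
    extraction = stage(
        "membrane_trace", membrane_trace, alignment.kymograph, loc,
        halfwidth_sigmas, background_exclusion,
    )
    curve = stage("compute_acf", compute_acf, extraction.trace, m, n_segments)
    fixed = {"S": s_fixed} if s_fixed is not None else None
    fit = stage("fit_acf", fit_acf, curve, "2d", None, None, fixed)
    if not fit.converged:
        raise StageError("fit_acf", f"fit did not converge: {fit.message}")
    brightness = stage("sfcs_brightness", sfcs_brightness, extraction.trace, fit)
    bleach = stage("bleached_fraction", bleached_fraction, extraction.trace)
    return SfcsResult(
        localization=loc,
        alignment=alignment,
        extraction=extraction,
        curve=curve,
        fit=fit,
        brightness=brightness,
        bleach=bleach,
    )
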