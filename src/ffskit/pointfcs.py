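"""Point-FCS calibration of the confocal detection volume.

A freely diffusing dye of known diffusion coefficient is measured at the
focus; acquisition autocorrelations are averaged and fitted with the 3D
diffusion + triplet model.  The day constants come from the fit of the
grand-average ACF over all acquisitions (the best-conditioned estimate of
the weakly constrained axial ratio), while per-measurement fits report the
between-measurement spread.  The diffusion time and structure parameter
define the detection geometry:

    w0 = sqrt(4 * D_dye * tau_d),    V_eff = pi**1.5 * w0**3 * S

The resulting structure parameter is what membrane scanning-FCS fits hold
fixed for the rest of the session (:func:`fixed_s_for_day`).

The dye diffusion coefficient is always a user input: it depends on
temperature and the dye lot, so baking in a literature constant would make
the calibration untraceable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .fcs_models import CorrelationCurve, FitResult, fit_acf
from .scanfcs import compute_acf
from .simulate import IntensityTrace

__all__ = ["CalibrationResult", "calibrate", "fixed_s_for_day",
           "waist_from_diffusion", "effective_volume"]


def waist_from_diffusion(dye_D: float, tau_d: float) -> float:
    """Lateral 1/e^2 waist from a known diffusion coefficient: sqrt(4 D tau_d)."""
    if dye_D <= 0 or tau_d <= 0:
        raise ValueError("dye_D and tau_d must be positive")
    return math.sqrt(4.0 * dye_D * tau_d)


def effective_volume(w0: float, S: float) -> float:
    """Effective confocal detection volume pi**1.5 * w0**3 * S."""
    return math.pi**1.5 * w0**3 * S


@dataclass
class CalibrationResult:
    """Detection-volume calibration from dye point-FCS.

    ``combined`` is the fit of the grand-average ACF over every acquisition
    of the day and provides the day constants (tau_d, S, N); ``pooled``
    holds mean +- SD of the per-measurement fits and quantifies their
    spread.
    """

    combined: FitResult
    per_measurement: list[FitResult]
    pooled: dict[str, tuple[float, float]]  # name -> (mean, SD across measurements)
    n_measurements: int
    n_converged: int
    dye_diffusion: Optional[float] = None  # um^2/s, user-supplied
    waist_w0: Optional[float] = None  # um
    effective_volume: Optional[float] = None  # um^3
    curves: list[CorrelationCurve] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.combined.converged

    @property
    def tau_d(self) -> float:
        return self.combined.params["tau_d"]

    @property
    def S(self) -> float:
        return self.combined.params["S"]

    @property
    def N(self) -> float:
        return self.combined.params["N"]


def _average_curves(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Mean ACF across acquisitions with propagated per-lag uncertainty.

    When the acquisition curves carry segment-based ``sd_G``, those standard
    errors are pooled (quadrature mean / sqrt(k)); otherwise the
    across-acquisition scatter is used.
    """
    lags = curves[0].lags
    stack = np.vstack([c.G for c in curves])
    k = len(curves)
    if all(c.sd_G is not None for c in curves) and k >= 1:
        sd_stack = np.vstack([c.sd_G for c in curves])
        sd = np.sqrt((sd_stack**2).mean(axis=0) / k)
    elif k > 1:
        sd = stack.std(axis=0, ddof=1) / math.sqrt(k)
    else:
        sd = None
    return CorrelationCurve(lags=lags, G=stack.mean(axis=0), sd_G=sd,
                            n_segments=k)


def calibrate(
    traces: Sequence[IntensityTrace],
    dye_D: Optional[float] = None,
    acquisitions_per_measurement: Optional[int] = None,
    m: int = 16,
    acquisition_segments: int = 8,
    fix_S: Optional[float] = None,
    fit_each_acquisition: bool = False,
    fit_max_lag: Optional[float] = 5e-3,
    use_weights: bool = False,
) -> CalibrationResult:
    """Fit dye point-FCS acquisitions and pool the detection-volume geometry.

    ``traces`` are the individual acquisitions, grouped consecutively into
    measurements of ``acquisitions_per_measurement`` each (default: all in
    one measurement).  The day constants come from fitting the grand-average
    ACF over all acquisitions; per-measurement average ACFs are fitted as
    well to report the between-measurement spread (``fit_each_acquisition``
    fits every acquisition separately instead).  ``dye_D`` (um^2/s) unlocks
    the waist and effective volume; without it only fit parameters are
    reported.

    Fits are restricted to lags <= ``fit_max_lag`` (the diffusion and
    dark-state information is exhausted within ~100 diffusion times; the
    pure-baseline region only dilutes the weak axial-ratio signal) and are
    unweighted by default: per-lag SDs estimated from a handful of segments
    are too noisy to serve as chi-square weights at calibration statistics.
    """
    if not traces:
        raise ValueError("at least one acquisition is required")
    n_per = acquisitions_per_measurement or len(traces)
    if n_per < 1:
        raise ValueError("acquisitions_per_measurement must be >= 1")

    # a shared lag grid needs equal-length acquisitions
    min_len = min(t.counts.size for t in traces)
    dt = traces[0].dt
    if any(abs(t.dt - dt) > 1e-15 for t in traces):
        raise ValueError("all acquisitions must share the same bin width")

    acq_curves = [
        compute_acf(IntensityTrace(t.counts[:min_len], t.dt), m=m,
                    n_segments=acquisition_segments)
        for t in traces
    ]

    groups: list[list[CorrelationCurve]] = [
        acq_curves[i:i + n_per] for i in range(0, len(acq_curves), n_per)
    ]
    fixed = {"S": fix_S} if fix_S is not None else None

    def windowed(curve: CorrelationCurve) -> CorrelationCurve:
        if fit_max_lag is None:
            return curve
        sel = curve.lags <= fit_max_lag
        return CorrelationCurve(curve.lags[sel], curve.G[sel],
                                None if curve.sd_G is None else curve.sd_G[sel],
                                curve.n_segments)

    def fit_one(curve: CorrelationCurve) -> Optional[FitResult]:
        try:
            return fit_acf(windowed(curve), model="3d_triplet", fixed=fixed,
                           use_weights=use_weights)
        except ValueError:
            return None

    combined = fit_one(_average_curves(acq_curves))
    if combined is None or not combined.converged:
        raise ValueError("all calibration fits failed to converge")

    fits: list[FitResult] = []
    curves: list[CorrelationCurve] = []
    for group in groups:
        units = [_average_curves(group)] if not fit_each_acquisition else group
        for curve in units:
            curves.append(curve)
            fit = fit_one(curve)
            if fit is not None:
                fits.append(fit)

    good = [f for f in fits if f.converged]
    names = combined.params.keys()
    pooled = {}
    for name in names:
        vals = np.array([f.params[name] for f in good]) if good else np.array([])
        if vals.size:
            pooled[name] = (float(vals.mean()),
                            float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
        else:
            pooled[name] = (float("nan"), float("nan"))

    w0 = veff = None
    if dye_D is not None:
        w0 = waist_from_diffusion(dye_D, combined.params["tau_d"])
        veff = effective_volume(w0, combined.params["S"])

    return CalibrationResult(
        combined=combined,
        per_measurement=fits,
        pooled=pooled,
        n_measurements=len(groups),
        n_converged=len(good),
        dye_diffusion=dye_D,
        waist_w0=w0,
        effective_volume=veff,
        curves=curves,
    )


def fixed_s_for_day(
    result: CalibrationResult,
    band: tuple[float, float] = (3.0, 15.0),
) -> tuple[float, bool]:
    """Pooled structure parameter for today's sFCS fits, with a sanity flag.

    Returns ``(S, in_band)``; ``in_band`` is False when S falls outside the
    plausibility band (default [3, 15], bracketing typical confocal values).
    """
    if not result.converged:
        raise ValueError("calibration did not converge; no S available")
    s = result.S
    return s, bool(band[0] <= s <= band[1])
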