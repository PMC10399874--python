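"""Closed-form FCS correlation models and the shared least-squares fit engine.

Two detection geometries are covered:

* 2D diffusion in a Gaussian detection area (membrane scanning FCS),

      G(tau) = offset + (1/N) (1 + tau/tau_d)^(-1/2) (1 + tau/(tau_d S^2))^(-1/2)

* 3D diffusion in a prolate Gaussian volume with a fast reversible dark
  state ("triplet") multiplying the diffusive part,

      G(tau) = offset + (1 + T e^(-tau/tau_T) / (1 - T))
               * (1/N) (1 + tau/tau_d)^(-1) (1 + tau/(tau_d S^2))^(-1/2)

``N`` is the mean particle number in the effective detection area/volume,
``tau_d`` the diffusion time, ``S`` the structure parameter (axial/lateral
waist ratio), ``T`` the dark-state fraction and ``tau_T`` its relaxation
time.  Fitting is nonlinear least squares (Levenberg-Marquardt via lmfit)
with optional per-lag standard-deviation weights and the ability to fix any
parameter, e.g. ``S`` to the daily dye calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import lmfit
import numpy as np

__all__ = [
    "Acf2DParams",
    "Acf3DTripletParams",
    "CorrelationCurve",
    "FitResult",
    "acf_2d",
    "acf_3d_triplet",
    "initial_guess",
    "fit_acf",
    "DEFAULT_BOUNDS",
]

# bounds preventing parameter-exchange degeneracy during fits
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "N": (1e-3, 1e6),
    "tau_d": (1e-6, 10.0),
    # S >= 1 (axial >= lateral) excludes the exact (tau_d, S) -> (tau_d*S^2, 1/S)
    # mirror solution of the diffusion models
    "S": (1.0, 1e3),
    "offset": (-1.0, 1.0),
    "T": (0.0, 0.5),
    "tau_T": (1e-7, 1e-5),
}


@dataclass
class Acf2DParams:
    N: float
    tau_d: float  # seconds
    S: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.N <= 0 or self.tau_d <= 0 or self.S <= 0:
            raise ValueError("N, tau_d and S must be positive")


@dataclass
class Acf3DTripletParams:
    N: float
    tau_d: float  # seconds
    S: float = 5.0
    T: float = 0.0
    tau_T: float = 5e-6  # seconds
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.N <= 0 or self.tau_d <= 0 or self.S <= 0:
            raise ValueError("N, tau_d and S must be positive")
        if not 0.0 <= self.T < 1.0:
            raise ValueError("triplet fraction T must be in [0, 1)")
        if self.tau_T <= 0:
            raise ValueError("tau_T must be positive")


@dataclass
class CorrelationCurve:
    """Autocorrelation amplitudes on a (quasi-logarithmic) lag grid."""

    lags: np.ndarray  # seconds, strictly increasing, first lag > 0
    G: np.ndarray
    sd_G: Optional[np.ndarray] = None  # per-lag SD from segment averaging
    n_segments: int = 1
    n_rejected: int = 0  # segments discarded as intensity outliers

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=np.float64)
        self.G = np.asarray(self.G, dtype=np.float64)
        if self.lags.ndim != 1 or self.lags.shape != self.G.shape:
            raise ValueError("lags and G must be matching 1D arrays")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.lags.size and self.lags[0] <= 0:
            raise ValueError("first lag must be positive")
        if self.sd_G is not None:
            self.sd_G = np.asarray(self.sd_G, dtype=np.float64)
            if self.sd_G.shape != self.G.shape:
                raise ValueError("sd_G must match G")


@dataclass
class FitResult:
    """Converged parameter estimates with uncertainties and diagnostics."""

    model: str
    params: dict[str, float]
    stderr: dict[str, Optional[float]]
    redchi: float
    converged: bool
    fixed: dict[str, float] = field(default_factory=dict)
    init: dict[str, float] = field(default_factory=dict)
    nfev: int = 0
    message: str = ""

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def acf_2d(tau: np.ndarray | float, params: Acf2DParams) -> np.ndarray | float:
    """2D Brownian-diffusion autocorrelation model."""
    tau = np.asarray(tau, dtype=np.float64)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    x = tau / params.tau_d
    g = params.offset + (1.0 / params.N) / np.sqrt((1.0 + x) * (1.0 + x / params.S**2))
    return g if g.ndim else float(g)


def acf_3d_triplet(tau: np.ndarray | float, params: Acf3DTripletParams) -> np.ndarray | float:
    """3D diffusion autocorrelation with a multiplicative triplet term."""
    tau = np.asarray(tau, dtype=np.float64)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    x = tau / params.tau_d
    diff = (1.0 / params.N) / ((1.0 + x) * np.sqrt(1.0 + x / params.S**2))
    trip = 1.0 + params.T / (1.0 - params.T) * np.exp(-tau / params.tau_T)
    g = params.offset + trip * diff
    return g if g.ndim else float(g)


_MODEL_PARAMS = {
    "2d": ("N", "tau_d", "S", "offset"),
    "3d_triplet": ("N", "tau_d", "S", "T", "tau_T", "offset"),
}


def _model_eval(model: str, tau: np.ndarray, values: Mapping[str, float]) -> np.ndarray:
    if model == "2d":
        return acf_2d(tau, Acf2DParams(values["N"], values["tau_d"],
                                       values["S"], values["offset"]))
    return acf_3d_triplet(tau, Acf3DTripletParams(
        values["N"], values["tau_d"], values["S"],
        values["T"], values["tau_T"], values["offset"]))


def initial_guess(curve: CorrelationCurve, model: str = "2d") -> dict[str, float]:
    """Moment-based starting values: N from the early-lag plateau, tau_d
    from the half-decay lag."""
    if curve.G.size < 4:
        raise ValueError("curve too short for an initial guess")
    if np.all(np.diff(curve.G) > 0):
        raise ValueError("monotonically increasing curve is not a valid ACF")
    plateau = float(curve.G[:3].mean())
    if plateau <= 0:
        raise ValueError("non-positive early-lag plateau")
    below = np.nonzero(curve.G < 0.5 * plateau)[0]
    tau_half = float(curve.lags[below[0]]) if below.size else float(curve.lags[-1])
    guess = {
        "N": 1.0 / plateau,
        "tau_d": tau_half,
        "S": 5.0 if model == "3d_triplet" else 2.0,
        "offset": 0.0,
    }
    if model == "3d_triplet":
        guess["T"] = 0.0
        guess["tau_T"] = max(float(curve.lags[0]), 1e-6)
    return guess


def fit_acf(
    curve: CorrelationCurve,
    model: str = "2d",
    init: Optional[Mapping[str, float]] = None,
    bounds: Optional[Mapping[str, tuple[float, float]]] = None,
    fixed: Optional[Mapping[str, float]] = None,
    use_weights: bool = True,
) -> FitResult:
    """Weighted nonlinear least-squares fit of an ACF model to a curve.

    ``fixed`` maps parameter names to values held constant (e.g. ``S`` from
    calibration).  Per-lag weights ``1/sd_G`` are applied when the curve
    carries them and ``use_weights`` is true.  Non-convergence is flagged on
    the result, never silently replaced by defaults.
    """
    if model not in _MODEL_PARAMS:
        raise ValueError(f"model must be one of {sorted(_MODEL_PARAMS)}")
    if curve.G.size < 8:
        raise ValueError("fit requires at least 8 lag points")
    if np.ptp(curve.G) == 0:
        raise ValueError("degenerate curve: all correlation values equal")

    names = _MODEL_PARAMS[model]
    fixed = dict(fixed or {})
    guess = initial_guess(curve, model)
    if init:
        guess.update(init)
    guess.update(fixed)
    lims = dict(DEFAULT_BOUNDS)
    if bounds:
        lims.update(bounds)

    # a dark state faster than the lag sampling cannot be resolved; without
    # this floor the triplet term degenerates into a one-lag amplitude knob
    if "tau_T" in names and "tau_T" not in fixed:
        lo, hi = lims["tau_T"]
        floor = max(lo, float(curve.lags[0]))
        if floor >= hi:
            # sampling coarser than any allowed dark-state time: drop the term
            fixed.setdefault("T", 0.0)
            guess["T"] = 0.0
            fixed.setdefault("tau_T", float(guess["tau_T"]))
        else:
            lims["tau_T"] = (floor, hi)

    pars = lmfit.Parameters()
    for name in names:
        lo, hi = lims[name]
        if lo >= hi:
            raise ValueError(f"empty bounds for parameter '{name}'")
        value = float(np.clip(guess[name], lo, hi))
        pars.add(name, value=value, min=lo, max=hi, vary=name not in fixed)

    weights = None
    if use_weights and curve.sd_G is not None:
        sd = np.asarray(curve.sd_G, dtype=np.float64)
        positive = sd[sd > 0]
        floor = positive.min() if positive.size else 1.0
        weights = 1.0 / np.maximum(sd, floor)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        vals = {name: p[name].value for name in names}
        res = _model_eval(model, curve.lags, vals) - curve.G
        return res * weights if weights is not None else res

    out = lmfit.minimize(residual, pars, method="leastsq",
                         xtol=1e-12, ftol=1e-12)
    estimates = {name: float(out.params[name].value) for name in names}
    stderr = {name: (float(out.params[name].stderr)
                     if out.params[name].stderr is not None else None)
              for name in names}
    return FitResult(
        model=model,
        params=estimates,
        stderr=stderr,
        redchi=float(out.redchi),
        converged=bool(out.success),
        fixed=fixed,
        init={name: float(guess[name]) for name in names},
        nfev=int(out.nfev),
        message=str(out.message),
    )
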