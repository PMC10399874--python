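# Methods

`ffskit` implements the analysis stack used to quantify fluorescent-protein
oligomerization from fluorescence fluctuations: Number & Brightness (N&B)
moment analysis of raster image time-stacks, scanning fluorescence
correlation spectroscopy (sFCS) of membrane line scans, point-FCS
calibration of the confocal detection volume, and the fluorescence
probability (pf) derived from monomer/dimer brightness ratios.  Because the
quantities of interest are statistical functionals of photon-count
fluctuations, every stage is validated against a synthetic confocal
simulator whose ground truth is known exactly.

## Models and estimators

**N&B.** Each pixel's photon counts over frames have temporal mean `k` and
unbiased variance `s2`.  In photon-counting detection, shot noise
contributes `k` to the variance, so the molecular (apparent) brightness and
particle number are

    epsilon = (s2 - k) / k      [counts/dwell; divided by the dwell time
                                 for counts/s/molecule]
    n       = k^2 / (s2 - k)

Pixels with `s2 <= k` carry no resolvable number fluctuation; they are
flagged invalid for `n` and exported with `epsilon = 0`, while the raw
(possibly negative) estimator is retained for diagnostics — the image
median of the raw values is the package's shot-noise null check.

**ROI pooling.** Two pooling modes exist, and the difference matters.  The
per-pixel ratio `s2/k` is biased by `O(1/F)` for `F` frames per window; a
delta-method expansion for the compound-Poisson pixel process gives a
relative bias near −7% at `F = 8`, which would propagate directly into pf.
The default ROI summary therefore pools moments first,
`sum(s2 - k) / sum(k)` over ROI pixels, which is unbiased to leading order
for a homogeneous ROI; per-pixel averaging remains available
(`pooling="pixel"`) for maps and heterogeneous regions.

**Boxcar bleaching correction.** The stack is cut into consecutive
non-overlapping 8-frame windows (remainder dropped).  Within a window the
slow intensity trend from photobleaching or cell movement is negligible, so
the window-wise brightness is nearly unbiased; the window series is then
extrapolated with an ordinary least-squares line to the temporal midpoint
of the first frame.  Saturated pixels (photon rate above 1 MHz in any
frame, i.e. >50 counts per 50 µs dwell) are excluded before pooling.  The
bleached fraction is `1 − mean(last 5% of frame totals)/mean(first 5%)`;
for an exponential decay with `k·T = ln 2` the 5% endpoint averages sit at
0.025 T and 0.975 T, so the expected readout is `1 − 2^(−0.95) ≈ 0.483`,
the value the tests assert.

**FCS models.**  2D diffusion in a Gaussian detection area and 3D diffusion
in a prolate Gaussian volume with a multiplicative dark-state ("triplet")
term:

    G_2D(tau) = offset + (1/N) (1+tau/tau_d)^(-1/2) (1+tau/(tau_d S^2))^(-1/2)
    G_3D(tau) = offset + (1 + T e^(-tau/tau_T)/(1-T))
                (1/N) (1+tau/tau_d)^(-1) (1+tau/(tau_d S^2))^(-1/2)

with `tau_d = w0^2/(4D)` and structure parameter `S` (axial/lateral waist
ratio).  The exact functional form of the triplet factor follows the
standard confocal convention.  Both models are invariant under
`(tau_d, S) → (tau_d S^2, 1/S)`; fits therefore constrain `S ≥ 1` (the
physical branch).  `tau_T` is bounded to [0.1 µs, 10 µs] — the range of
dye/FP dark-state lifetimes — and additionally floored at the first lag of
the curve being fitted, because a dark state faster than the sampling
interval is unresolvable and would otherwise act as a one-lag amplitude
knob.

**Multi-tau correlator.**  `G(tau) = <F(t)F(t+tau)>/<F>^2 − 1` with
symmetric normalisation (both means over the overlapping range), 16 lags
per octave, pairwise binning between octaves.  The estimator is
scale-invariant, so it applies unchanged to the summed series of higher
octaves, and at unbinned (level-0) lags it is arithmetically identical to
the brute-force direct estimator — the equality test runs at 1e-12
relative tolerance.  Traces are split into 8 segments by default; segments
whose mean deviates more than 3 SD are rejected, the curve is the segment
mean and `sd_G` its standard error.

**sFCS pipeline.**  Membrane localization fits a Gaussian + constant to
1000-line block-averaged profiles (`sigma ≥ 0.8 px`, so flat noise cannot
pose as a membrane); lines are realigned with integer-pixel shifts
interpolated between blocks (no photon resampling, exact count
conservation); the membrane trace sums a ±2.5 sigma window with background
estimated beyond twice the window half-width; the ACF is fitted with the 2D
model, by default with `S` fixed to the calibration value (S = 1 for the
isotropic synthetic geometry), and brightness is `B = <I>/N`.

**Point-FCS calibration.**  Acquisition ACFs are computed per acquisition
(8 segments each).  The day constants (`tau_d`, `S`, `N`) come from fitting
the grand-average ACF over *all* acquisitions; per-measurement average-ACF
fits are also reported as mean ± SD to quantify spread.  This ordering was
a genuinely open choice; the grand fit was adopted because the axial ratio
S is weakly identified, and at desk-scale statistics per-measurement fits
scatter by ±30% in S while the grand fit recovered S within 20% and tau_d
within 2% across independent replicate runs.  Calibration fits are
restricted to lags ≤ 5 ms (≈150 tau_d; beyond that only the baseline
remains, and the finite-segment normalisation bias there distorts the weak
axial tail) and are unweighted: per-lag SDs estimated from a handful of
segments proved far too noisy to serve as chi-square weights (weighted fits
showed tau_d errors up to 70% where unweighted fits were within 6%).
Supplying the dye diffusion coefficient (a required user input — it depends
on temperature and dye lot) converts `tau_d` to `w0 = sqrt(4 D tau_d)` and
`V_eff = pi^1.5 w0^3 S`.

**pf.**  For a tandem dimer whose subunits are independently fluorescent
with probability `pf`, enumeration over the binomial subunit states gives
`B_dimer = (1 + pf) · B_monomer`, hence `pf = B_dimer/B_monomer − 1`.  The
monomer reference is the mean over that day's (and condition's and
method's) monomer cells — mixing days in one reference is a hard error —
and only per-cell pf values are pooled across days (mean ± SEM).  Per-cell
values outside [0, 1] are kept and counted: they arise from noise, and
excluding them would bias the mean.

## The synthetic generators

The simulator emulates the statistics the analyses assume, not the optics:
a 3D Gaussian detection weight stands in for the full PSF, and detector
afterpulsing/dead time, chromophore maturation kinetics and protonation
chemistry are out of scope.  Oligomers carry `s` subunits, each
independently bright with probability `p` (fixed per emitter), giving the
closed-form apparent brightness `lambda (1 + (s−1)p)` used as ground truth.

*Raster (N&B) path.*  At 128×128 px and 50 µs dwell the frame interval
(0.819 s) exceeds cytosolic diffusion times by orders of magnitude, so
frames are drawn independently from the stationary compound process:
occupancy `m ~ Poisson(n·exp(−k_bleach·t))`, bright subunits
`Binomial(m·s, p)`, counts Poisson around brightness × dwell plus
background.  Irreversible bleaching reduces occupancy, not per-emitter
brightness.

*Brownian-dynamics paths.*  Membrane (2D) and point (3D) traces integrate
Brownian particles in a periodic box with Gaussian detection weights,
Poisson counts per bin; the kernel is numba-jitted.  Positions at the bin
instants are exactly Brownian-distributed, so the ACF at lags ≥ dt matches
the continuous models.  Box sizes: 20 w0 (membrane, per the ≥10 w0 guard)
and 20 w0 lateral / 4 S·w0 axial (point).  The point box must be this
large: with a 10–14 w0 box the lowest diffusive modes are missing at the
axial-transition lags `tau_d S^2`, which measurably suppresses the ACF tail
and biases S low.  For a Gaussian spot the fitted `N` is `c·π w0^2`
(membrane) or `c·π^1.5 w0^3 S` (point) while the mean rate per fitted
particle is `lambda/2` (beam-shape factor); recovery tests compare against
these, not against the peak rate.

*Kymograph synthesis.*  Each line's membrane photons are placed by drawing
one Gaussian position per photon (equivalent to a multinomial split over
pixel-integrated profile weights), conserving per-line totals exactly, plus
independent Poisson background per pixel.

## Default parameters

| parameter | default | why |
|---|---|---|
| pixel dwell / size (N&B) | 50 µs / 400 nm | standard photon-counting raster settings for 128×128 stacks of 100 frames |
| boxcar window | 8 frames | short enough that bleaching within a window is negligible |
| saturation threshold | 1 MHz | photon-counting detector linearity limit |
| line time / pixels (sFCS) | 472.73 µs / 256 px × 80 nm | typical membrane line-scan raster |
| multi-tau | m = 16, 8 segments, 3 SD rejection | standard correlator layout |
| trace window / background | ±2.5 σ / beyond 2× window | captures >98% of the profile; background region untouched by signal |
| simulator brightness | 10 kcps (FP), 100 kcps (dye) | realistic per-molecule count rates at imaging powers |
| occupancy | n = 5 (raster), N = 10 (membrane), N = 1.5 (point) | single-molecule fluctuation regime |
| diffusion | D = 1 µm²/s (membrane), 333 µm²/s (dye) | membrane protein vs small free dye; tau_d = 10 ms / 30 µs at w0 = 0.2 µm |
| S | 5 | mid-range confocal axial ratio; plausibility band [3, 15] |

## Problem sizes

The validation runs use 128×128×100 stacks (20 + 20 cells per pf
condition), 20 kymographs of 1e5 lines (≈47 s of membrane signal each),
and a calibration day of 5 measurements × 3 acquisitions of 1 s at 1 µs
bins.  The acceptance script uses the same sizes with 8 kymographs.  These
sizes were chosen so each stage has enough statistics for its stated
tolerance while the whole suite stays desk-scale.

## What passing tests do and do not show

The generators share the analyses' own statistical assumptions (Poisson
photons, Gaussian detection, ideal detectors, homogeneous ROIs, a single
diffusing species).  Passing tests therefore demonstrate the correctness of
the estimators and fits under those assumptions; they do not validate
robustness to PSF aberrations, detector artefacts, spatially heterogeneous
expression, membrane undulations, or multi-component diffusion, all of
which real measurements contain.

## Numerical choices and limitations

- Variance uses the unbiased (F−1) estimator; at 8-frame windows the bias
  of the biased form would be material.
- Extrapolation target is the temporal midpoint of the first frame —
  unbiased for a linear trend.
- Integer-pixel alignment shifts preserve Poisson statistics; the
  sub-pixel residual (≤0.5 px) is recorded, not resampled.
- Fits are Levenberg–Marquardt (lmfit) with `xtol = ftol = 1e-12`;
  refitting from a solution reproduces it to better than 1e-8.
- Degenerate inputs fail loudly: single-frame stacks, zero-mean traces,
  all-equal curves, empty ROIs after masking, membrane-less kymographs.
- Triplet/axial identifiability is limited by the µs bin width of the
  synthetic traces (hardware correlators reach ns lags): at tau_d ≈ 30 µs
  the fitted dark-state fraction on triplet-free data can fluctuate up to
  ≈0.06 across seeds, and S is determined only at the ±20–25% level.
- The fitted `S` of the isotropic membrane simulation is 1 by
  construction; real sFCS fixes S from the daily dye calibration instead.
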