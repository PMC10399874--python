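# ffskit

Fluorescence fluctuation spectroscopy (FFS) toolkit for quantifying the
brightness, photostability and oligomeric state of fluorescently tagged
proteins in live-cell measurements — and for validating every step of that
analysis on synthetic photon-count data with known ground truth.

The package is aimed at quantitative microscopists who acquire
photon-counting confocal data and need the full analysis chain:

- **Number & Brightness (N&B)** — per-pixel molecular brightness
  `epsilon = (sigma^2 - k)/k` and particle number `n = k^2/(sigma^2 - k)`
  from image time-stacks, with detector-saturation masking (1 MHz rule),
  boxcar photobleaching correction (8-frame windows, linear extrapolation
  to the acquisition start) and bleached-fraction readout.
- **Scanning FCS (sFCS)** — membrane line-scan kymographs reduced to a
  membrane intensity trace (Gaussian localization, drift alignment,
  windowed extraction), multi-tau autocorrelation, 2D diffusion-model fit
  `G(tau) = (1/N)(1+tau/tau_d)^(-1/2)(1+tau/(tau_d S^2))^(-1/2)`, and
  molecular brightness `B = <I>/N`.
- **Point-FCS calibration** — dye measurements fitted with the 3D
  diffusion + triplet model to obtain the diffusion time `tau_d`, the
  structure parameter `S` (fixed in later sFCS fits) and, given the dye's
  diffusion coefficient, the beam waist `w0 = sqrt(4 D tau_d)` and
  effective detection volume.
- **Fluorescence probability (pf)** — not every fluorescent-protein
  subunit emits (maturation, dark states, bleaching). From per-day
  monomer-referenced dimer brightness, `pf = B_dimer/B_monomer - 1`,
  pooled across cells and sessions with mean ± SEM, plus the descriptive
  group summaries (mean, median, IQR, n).
- **Synthetic data** — compound-Poisson raster stacks and Brownian-dynamics
  membrane/point traces with Gaussian detection, binomial subunit
  labelling, photobleaching and background, so that every estimator above
  can be tested against exact closed forms.

## Worked example

Simulate one experiment day — six monomer and six dimer cells whose
subunits are fluorescent with probability 0.7 — run the N&B pipeline on
each stack, and estimate pf:

```python
import numpy as np
from ffskit import (
    SimConfig, simulate_nb_stack, boxcar_brightness,
    BrightnessRecord, pf_from_records,
)

records = []
for i in range(6):
    for construct, subunits, base in (("monomer", 1, 100), ("dimer", 2, 200)):
        cfg = SimConfig(seed=base + i, subunits=subunits,
                        fluorescence_probability=0.7)
        stack = simulate_nb_stack(cfg)              # 100 frames, 128x128 px
        _, series = boxcar_brightness(stack, window=8)
        records.append(BrightnessRecord(
            cell_id=f"{construct}{i}", construct=construct, day="day1",
            brightness=series.extrapolated_epsilon))

mono = [r.brightness for r in records if r.construct == "monomer"]
est = pf_from_records(records)
print(f"monomer brightness: {np.mean(mono):,.0f} counts/s/molecule")
print(f"pf = {est.mean:.3f} +- {est.sem:.3f}  (n = {est.n} dimer cells)")
```

Output:

```
monomer brightness: 10,020 counts/s/molecule
pf = 0.699 +- 0.005  (n = 6 dimer cells)
```

The monomer brightness recovers the generator's 10,000 counts/s/molecule;
the dimer/monomer ratio minus one recovers the per-subunit fluorescence
probability (closed form `B_dimer = (1 + pf) B_monomer`), so `pf ≈ 0.7`.

The same pipeline is available from the shell:

```bash
ffskit simulate --preset nb-dimer --seed 1 --out data/
ffskit nandb data/*.tif --out nandb.csv
ffskit sfcs kymo.tif --structure-parameter 1.0 --out sfcs.csv
ffskit calibrate day1/*.csv --dye-d 400 --out calibration.json
ffskit pf records.csv --out pf.csv
```

Images travel as uint16 multi-page TIFF with a JSON sidecar for
acquisition metadata (dwell time, pixel size, line time); traces and
curves as CSV; fits and calibrations as JSON. Every output embeds the seed
and configuration, and re-running any command with the same seed
reproduces its outputs byte-for-byte.

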