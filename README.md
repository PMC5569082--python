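# ptoct — photothermal OCT processing

Photothermal optical coherence tomography (PT-OCT) detects absorbers —
melanin in the retinal pigment epithelium (RPE), systemically injected gold
nanorods accumulating in choroidal neovascular lesions — by driving them
with an amplitude-modulated heating laser and reading the resulting
oscillation of OCT phase. The change in phase relates to the change in
optical path length around the absorber as

```
ΔΦ(z) = 4π n ΔOPL(z) / λ0
```

with `n` the tissue refractive index and `λ0` the OCT center wavelength, so
a lock-in on the phase at the modulation frequency `f0` yields a
depth-resolved absorber map in nanometers of optical path length, linear in
heating-laser power and absorber concentration.

This package implements the full processing chain for spectral-domain
PT-OCT M-scans, plus a forward simulator with known ground truth:

- **`ptoct.simulate`** — phantoms (pigmented/albino retina, nanorod lesion
  with saline control, single calibration reflector) rendered as raw
  spectrometer interferograms with square-wave thermal drive, phase and
  detector noise, breathing motion and corrupted A-scans.
- **`ptoct.reconstruction`** — wavelength→wavenumber resampling (cubic),
  background subtraction, automatic dispersion compensation (sharpness
  optimization of a phase polynomial in k), Chirp-Z transform to an
  arbitrary zoomed depth window.
- **`ptoct.signal`** — phase time series per depth pixel, wrapped first
  temporal derivative, Fourier lock-in at `f0` with transfer-function
  compensation, spectral noise-floor estimation and subtraction, conversion
  to nm.
- **`ptoct.motion`** — per-A-scan axial registration to a motion-free
  reference volume (upsampled phase cross-correlation), identical shifts
  applied to the PT-OCT image, corrupted-column detection and 1-D linear
  interpolation.
- **`ptoct.roi`** — axial profiles, RPE peak with half-maximum band and
  FWHM, background and peak-to-background metrics, lesion-ROI means with an
  area-based inclusion filter, en-face projections.
- **`ptoct.stats`** — exact two-tailed Mann-Whitney U (full enumeration at
  small n), through-origin linear regression with R² and 95% CI, cohort
  comparisons and power-series analysis with detection-limit flags.
- **`ptoct.experiments`** — study-level drivers that run the above end to
  end on simulated cohorts.

## Worked example

Recover a known 5 nm photothermal drive from raw simulated spectra:

```python
import numpy as np
from ptoct import AcquisitionConfig, make_phantom, simulate_mscan, process_mscan

cfg = AcquisitionConfig(n_spectrometer_pixels=512, pt_power_mw=1.0)
truth = make_phantom("single_reflector", depth_um=200.0,
                     absorber_units=5.0 / 1.56,   # kappa * P * C = 5 nm
                     thermal_mode="pure_sine", phase_model="local")
raw = simulate_mscan(truth, cfg, power_mw=1.0, noiseless=True)
profile = process_mscan(raw, window_um=(150.0, 250.0), n_out=101)
i = np.argmax(profile.opl_amplitude_nm)
print(f"peak {profile.opl_amplitude_nm[i]:.3f} nm at {profile.depth_grid_um[i]:.0f} um")
```

prints

```
peak 5.016 nm at 193 um
```

— the 5 nm drive is recovered to 0.3% at the reflector's point-spread
function (the value at the exact reflector pixel, 200 µm, is 5.000 nm).
A pigmented-retina phantom processed the same way yields an axial profile
peaking at the RPE band; `ptoct.experiments.run_power_series` repeats that
over laser powers and eyes, reproducing the study-level behaviour (peak
amplitude linear in power, band width invariant, background rising with
power while peak-to-background falls).

The same pipeline is scriptable from the shell:

```
ptoct run-all --kind pigmented_retina --power 8 --seed 1 --workdir out/
```

writes the raw HDF5 container, OCT/PT-OCT image volumes, TIFF overlays and
a per-B-scan metrics CSV.

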