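# Methods

## Signal model

A spectral-domain OCT system records, for each lateral position, repeated
spectra (an M-scan) while a heating laser is amplitude-modulated at
`f0 = 500 Hz` (square wave, 50% duty). Absorbed light periodically heats
the tissue around the absorber; the refractive-index change and
thermoelastic expansion modulate the optical path length to every
scatterer whose beam path crosses the heated region. The OCT phase at
depth z then oscillates with amplitude

    ΔΦ(z) = 4π n ΔOPL(z) / λ0

(`n` = 1.38, `λ0` = 860 nm by default). The pipeline reports
ΔOPL = λ0·ΔΦ/(4πn) in nanometers.

The simulator renders the raw interferogram of reflector j at depth z_j as

    S(k_i, t) = G(k_i)·[D + Σ_j a_j cos(2 k_i n z_j + φ_j(t) + θ(k_i))] + ε

with G the Gaussian source envelope (λ0 ± Δλ), θ(k) = a2·x² + a3·x³ a
dispersion phase on the normalized wavenumber axis x ∈ [−1, 1], ε additive
detector noise, and φ_j(t) = (4πn/λ0)·A_j·g(t) + b(t) the photothermal
drive plus common-mode phase jitter b(t). Spectra are sampled on a
wavelength grid linear in spectrometer pixel spanning λ0 ± 1.5Δλ.

**Amplitude convention.** `g(t)` is the thermal response waveform (a
first-order low-pass response to the square drive, time constant τ)
rescaled so that its Fourier component at f0 has unit amplitude. The truth
amplitude `A = κ·P·C` is therefore exactly the sinusoidal-equivalent
oscillation a Fourier lock-in at f0 reads back, for any drive waveform —
what the analysis reports is what the ground truth stores. A `pure_sine`
mode (g = 1 + sin 2πf0t) exists for closed-form validation.

**Absorber-to-amplitude model.** Optical path change accumulates through
the heated region: the default model convolves the absorber concentration
profile with a one-sided-weighted exponential kernel of length
`decay_length_um = 10 µm` — the thermal diffusion length √(D/πf0) for
tissue (D ≈ 1.4×10⁻⁷ m²/s) at 500 Hz — with full weight for scatterers
below the absorber (the beam traverses the heated layer) and half weight
above (expansion-driven displacement only). Pure `cumulative` (unweighted
running sum) and `local` (A ∝ C at the scatterer) modes are switchable for
unit testing. The model is linear in laser power and concentration by
construction.

## Reconstruction

Spectra are resampled to a uniform k = 2π/λ grid with cubic splines
(endpoints preserved), optionally background-subtracted, multiplied by
e^(−iθ̂(k)) for dispersion compensation, and transformed to depth with a
Chirp-Z transform, which evaluates the transform on an arbitrary zoomed
window instead of the fixed FFT grid. With the window set to the full
sampling range the CZT reproduces the FFT bin for bin (relative error
~1e-10 at 512 spectral pixels, growing roughly with the square of the
pixel count through accumulated chirp-phase rounding).

Dispersion coefficients (a2, a3) are estimated by maximizing the peak
intensity of the reconstructed mean A-scan: the probe spectrum is
high-pass filtered along k (the smooth source envelope would otherwise be
chirp-focused by trial coefficients and dominate the metric), a coarse
grid search seeds a Nelder-Mead refinement, and the metric is evaluated on
a finely sampled window zoomed around the dominant reflector to avoid
grid scalloping. Flat or noise-only input returns the identity model with
a warning. Both coefficients recover within 5% at the full 2048-pixel
spectrometer sampling; at heavily reduced samplings the odd-order term is
weakly identified (interpolation phase error concentrates at the band
edges), though peak restoration stays within 1% of dispersion-free.

**Background subtraction and phase.** The temporal-mean background
estimator removes the DC/source term and fixed-pattern noise and is used
for intensity imaging. It is *not* applied before phase extraction:
subtracting the temporal mean also removes the J0(ΔΦ)-scaled static
fringe, leaving a residual whose argument flips by ±π/2 with the drive
rather than following it — phase demodulation after mean subtraction
over-reads the amplitude severalfold. The phase-carrying reconstruction
therefore keeps the raw spectrum; the unmodulated source term lands at
zero delay, outside the imaging window, where its Gaussian leakage decays
within a few coherence lengths.

## Photothermal demodulation

Per depth pixel: phase of the complex field over time → first difference
with each increment re-wrapped to (−π, π] (removes bulk drift; linear
drift becomes DC) → single-sided magnitude spectrum (2/M scaling) → peak
at the bin nearest f0, divided by the first-difference transfer function
2·sin(πf0/fs) so the reported quantity is the phase amplitude itself.
When fs/f0 is an integer the record is truncated to a whole number of
modulation periods (700 samples → 680 at the defaults), making the f0 bin
exact; a pure sine is then recovered to machine precision. The noise
floor is the median bin magnitude excluding DC±2, f0±2 and 2f0±2 bins
(median for robustness to harmonic leakage of the square drive), converted
identically and subtracted; negative results clip to zero.

Pixels with OCT intensity less than 5 dB above the shot floor
(20th-percentile image intensity) or more than 40 dB below the brightest
reflector are masked: at such pixels the fringe is too weak for its phase
to mean anything, and interference with static leakage can amplify the
apparent oscillation arbitrarily. Both thresholds are configurable.

## Motion correction

Each OCT A-scan is registered axially (1-D) against the same column of a
fast, motion-free reference volume using phase cross-correlation with
optional subpixel upsampling; integer offsets by default so that the
PT-OCT column can be shifted identically without resampling the nm image.
Shifts are zero-filled, never circular, and vacated pixels are excluded
from statistics via a validity mask. Columns whose normalized correlation
falls below 0.5 (or that are all zero) are flagged corrupted, left in
place, and rebuilt per depth pixel by linear interpolation between the
nearest valid lateral neighbours (nearest-neighbour extension at edges).

## Quantification

Axial profiles average the PT-OCT B-scan over valid A-scans per depth. The
peak band is the contiguous interval around the global maximum where the
profile stays above half the peak, with sub-pixel linear interpolation of
the crossings (plateau maxima use the plateau center; a side with no
crossing truncates at the profile edge with a flag). Background statistics
exclude the band dilated by a 1-pixel margin; a zero background leaves the
peak-to-background ratio undefined rather than infinite. Lesion means
average PT-OCT voxels inside a frozen boolean ROI mask; the inclusion
filter requires total mask area (summed over B-scans) strictly above
40 000 pixels. En-face projections are depth means, composited with PT-OCT
in the green channel over a display range recorded in the image metadata
(default [0, 99th percentile]).

For power-series band metrics the per-A-scan signal and floor profiles
are averaged *before* subtraction: subtracting and clipping per pixel
first would bias the band edges (narrowing them at low power where the
signal approaches the floor).

## Statistics

The exact two-tailed Mann-Whitney U enumerates all C(n1+n2, n1) labelings
when both groups have ≤ 8 members and no ties (cost ≤ 12 870), counting
the labelings at least as extreme in either tail (equivalent to doubling
the smaller tail); with ties or larger groups it falls back to the normal
approximation with continuity and tie corrections. Fully separated groups
of six give p = 2/924 ≈ 0.0022. Through-origin regression uses
slope = Σxy/Σx² with R² against the centered total sum of squares (the
uncentered variant is available behind a warning) and a t-based 95% CI
with n−1 degrees of freedom. The power-series fit weights per-power means
by 1/P²: between-eye scatter grows in proportion to power (the signal is
multiplicative in absorber content), and proportional-variance weighting
keeps the nominal CI honest — coverage is ~95% in Monte-Carlo at 20%
proportional noise. Powers whose per-eye signals do not differ from the
laser-off group by exact MWU are flagged as below the detection limit. No
multiple-testing correction is applied; the number of comparisons is
reported.

## Simulated study conditions

Defaults emulate the acquisitions the analyses were designed for: 2048
spectrometer pixels (tests subsample to 256–512 for speed; the physics is
unchanged), 700 repeats at 10 kHz (35 modulation periods), 400 A-scans per
B-scan (32–64 in tests), τ = 0.2 ms thermal time constant, κ chosen so
unit concentration at 1 mW yields 1.56 nm. The pigmented phantom carries a
Gaussian RPE absorber band (FWHM 12 µm at 185 µm depth) over a weak
uniform choroid band; its melanin content is set so the RPE peak is
clearly resolved above the detection floor at 1 mW (~2.3 nm, ~19 nm at
8 mW), consistent with 1 mW being sufficient for melanin imaging. Phase
jitter of 0.01 rad/sample — the shot-noise-limited phase stability at
~40 dB SNR — gives a ~0.15 nm lock-in floor and a ~0.5 nm (3σ) detection
limit; detector noise is sized for a ~50 dB image dynamic range. Breathing
is a 1–2 Hz sinusoid plus drift, 5 px amplitude by default; corrupted
A-scans are decorrelated noise. Cohort-level generators add between-eye
variability (band depth/width, melanin content, thermal spread) on top of
speckle, which decorrelates laterally (independent reflectivity draws per
A-scan).

What the simulator does **not** model: rigorous bioheat transport (the
exponential kernel is a one-parameter surrogate), speckle statistics of
real tissue (uniform reflectivity jitter, not fully developed speckle),
eye optics and aberrations, lateral motion, and vascular structure.
Passing tests therefore demonstrate correctness of the *processing* under
a faithful signal model, not performance on real eyes.

## Numerical choices and limitations

- Depth index 0 is zero optical delay, increasing toward the choroid; the
  default imaging window is the positive half-range, excluding the
  complex-conjugate image (full-range reconstruction is out of scope).
- Lock-in truncation to whole modulation periods assumes fs/f0 near an
  integer; otherwise the nearest bin is used with a warning and the
  scalloping loss (<0.5% at half-bin offset) is accepted.
- The 1/√N_t sensitivity scaling holds approximately: coherent truncation
  quantizes the effective record length, so measured ratios deviate by
  ~10–20% from the ideal square-root law.
- Exact-MWU enumeration is limited to groups of ≤ 8; the designs analysed
  here use 6 or 7 eyes.
- Cohort summary generators (`cohort_table`, `power_series_table`) work at
  the per-eye level with emulated means and scatter; they exist so that
  statistical procedures can be exercised over hundreds of replicates at
  negligible cost, and their magnitudes mirror the full pipeline's output
  on the corresponding phantoms.
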