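"""Forward model: raw spectral-domain PT-OCT data with known ground truth.

The simulator emulates the study geometry: a melanin-bearing retina phantom
(absorbing RPE band over a weakly absorbing choroid), an albino phantom with
no absorber, and a laser-induced choroidal neovascularization (LCNV) lesion
phantom with or without gold-nanorod absorber inside the lesion dome.

Signal model for one reflector j at depth ``z_j`` with reflectivity ``a_j``::

    S(k_i, t) = G(k_i) * [D + sum_j a_j cos(2 k_i n z_j + phi_j(t) + theta(k_i))] + eps

where ``G`` is the Gaussian source envelope, ``theta(k)`` a dispersion phase
polynomial, and ``phi_j(t) = (4 pi n / lambda0) * A_j * g(t) + b(t)`` the
photothermal phase drive plus bulk phase noise. ``g(t)`` is the thermal
response to the square-wave modulation, normalized so that its Fourier
component at the modulation frequency f0 has unit amplitude; the truth
amplitude ``A_j`` (nm) is therefore exactly the sinusoidal-equivalent optical
path length oscillation that an f0 lock-in recovers. ``A_j`` is linear in
laser power and absorber concentration: ``A = kappa * P * C_eff``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import AcquisitionConfig
from .containers import RawSpectralMScan
from .errors import ParameterError

__all__ = [
    "PhantomTruth",
    "RawVolume",
    "make_phantom",
    "modulation_waveform",
    "normalized_drive",
    "make_wavelength_grid",
    "unambiguous_depth_um",
    "simulate_mscan",
    "simulate_volume",
    "make_breathing_trace",
    "cohort_table",
    "power_series_table",
]

PHANTOM_KINDS = (
    "pigmented_retina",
    "albino_retina",
    "lcnv_lesion",
    "lcnv_control",
    "single_reflector",
)

THERMAL_MODES = ("square_lowpass", "pure_sine")
PHASE_MODELS = ("local", "cumulative", "cumulative_decay")


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------
@dataclass
class PhantomTruth:
    """Complete simulator ground truth for one phantom.

    ``reflector_depths_um`` is shared across lateral positions; reflectivity
    and absorber concentration are per reflector and lateral/B-scan position
    (shape ``(n_ref, n_lat, n_bscan)``). ``kappa_nm_per_mw_unit`` converts
    power × concentration to the true photothermal amplitude in nm.
    """

    kind: str
    reflector_depths_um: np.ndarray
    reflector_amplitudes: np.ndarray
    absorber_map: np.ndarray
    kappa_nm_per_mw_unit: float = 1.56
    thermal_time_constant_ms: float = 0.2
    thermal_mode: str = "square_lowpass"
    phase_model: str = "cumulative_decay"
    # thermal diffusion length sqrt(D/(pi f0)) ~ 10 um for tissue at 500 Hz
    decay_length_um: float = 10.0
    # heat spreads outward in both directions; path-length accumulation acts
    # fully on scatterers below the absorber, partially (expansion) above
    upward_fraction: float = 0.5
    delta_t_scale_c: float = 2.0
    # shot-noise-limited phase stability ~1/sqrt(SNR): 0.01 rad at 40 dB,
    # giving a ~0.15 nm lock-in floor and a ~0.5 nm (3 sigma) detection limit
    phase_noise_rad: float = 0.01
    # detector noise sized for a ~50 dB image dynamic range (research SD-OCT)
    spectral_noise: float = 0.01
    motion_trace_px: np.ndarray | None = None
    dropout_columns: list = field(default_factory=list)
    seed: int = 0
    pixel_size_z_um: float = 1.0
    depth_window_um: tuple = (20.0, 270.0)
    rpe_band_um: tuple | None = None
    lesion_center_lat: int | None = None
    lesion_radius_lat: float | None = None
    lesion_depth_band_um: tuple | None = None

    def __post_init__(self) -> None:
        self.reflector_depths_um = np.atleast_1d(
            np.asarray(self.reflector_depths_um, dtype=float)
        )
        amp = np.asarray(self.reflector_amplitudes, dtype=float)
        conc = np.asarray(self.absorber_map, dtype=float)
        if amp.ndim == 1:
            amp = amp[:, None, None]
        if conc.ndim == 1:
            conc = conc[:, None, None]
        self.reflector_amplitudes = amp
        self.absorber_map = conc
        if amp.shape != conc.shape or amp.shape[0] != self.reflector_depths_um.size:
            raise ParameterError("reflector arrays must share shape (n_ref, n_lat, n_b)")
        if np.any(conc < 0):
            raise ParameterError("absorber concentrations must be >= 0")
        if self.thermal_time_constant_ms <= 0:
            raise ParameterError("thermal_time_constant_ms must be > 0")
        if self.thermal_mode not in THERMAL_MODES:
            raise ParameterError(f"thermal_mode must be one of {THERMAL_MODES}")
        if self.phase_model not in PHASE_MODELS:
            raise ParameterError(f"phase_model must be one of {PHASE_MODELS}")
        if self.phase_noise_rad < 0 or self.spectral_noise < 0:
            raise ParameterError("noise levels must be >= 0")
        order = np.argsort(self.reflector_depths_um)
        self.reflector_depths_um = self.reflector_depths_um[order]
        self.reflector_amplitudes = self.reflector_amplitudes[order]
        self.absorber_map = self.absorber_map[order]

    # -- derived quantities ------------------------------------------------
    @property
    def n_lateral(self) -> int:
        return self.reflector_amplitudes.shape[1]

    @property
    def n_bscans(self) -> int:
        return self.reflector_amplitudes.shape[2]

    def effective_concentration(self) -> np.ndarray:
        """Absorber concentration driving each reflector's phase.

        ``local``: the reflector's own concentration. ``cumulative``: all
        absorber at or above it (optical path change accumulates through the
        heated region). ``cumulative_decay``: cumulative with an exponential
        decay over ``decay_length_um``, modelling the finite spatial extent
        of the temperature rise around the absorber.
        """
        C = self.absorber_map
        if self.phase_model == "local":
            return C
        z = self.reflector_depths_um
        if self.phase_model == "cumulative":
            return np.cumsum(C, axis=0)
        # exponential thermal-spread kernel: full weight for scatterers below
        # the absorber (beam path crosses the heated region), reduced weight
        # above (thermoelastic displacement only)
        dz = z[:, None] - z[None, :]  # (target, source)
        w = np.exp(-np.abs(dz) / self.decay_length_um)
        w[dz < 0] *= self.upward_fraction
        return np.einsum("ts,sij->tij", w, C)

    def amplitude_nm(self, power_mw: float) -> np.ndarray:
        """True photothermal amplitude A (nm) per reflector at this power."""
        if power_mw < 0:
            raise ParameterError("power must be >= 0")
        return self.kappa_nm_per_mw_unit * power_mw * self.effective_concentration()

    def expected_peak_nm(self, power_mw: float, lateral: int = 0, bscan: int = 0) -> float:
        return float(self.amplitude_nm(power_mw)[:, lateral, bscan].max(initial=0.0))

    def absorber_band_fwhm_um(self, lateral: int = 0, bscan: int = 0) -> float:
        """FWHM of the (local) absorber concentration profile in depth."""
        c = self.absorber_map[:, lateral, bscan]
        if c.max() <= 0:
            return 0.0
        z = self.reflector_depths_um
        half = c.max() / 2.0
        above = np.nonzero(c >= half)[0]
        lo, hi = above[0], above[-1]
        zlo = z[lo]
        if lo > 0:
            zlo = np.interp(half, [c[lo - 1], c[lo]], [z[lo - 1], z[lo]])
        zhi = z[hi]
        if hi < c.size - 1:
            zhi = np.interp(half, [c[hi + 1], c[hi]], [z[hi + 1], z[hi]])
        return float(zhi - zlo)

    def lesion_mask(self, n_depth: int, depth_grid_um: np.ndarray) -> np.ndarray:
        """Boolean (depth, lateral, bscan) mask of the lesion dome on a grid."""
        if self.lesion_center_lat is None:
            raise ParameterError("phantom has no lesion geometry")
        mask = np.zeros((n_depth, self.n_lateral, self.n_bscans), dtype=bool)
        zlo, zhi = self.lesion_depth_band_um
        for b in range(self.n_bscans):
            for j in range(self.n_lateral):
                r = abs(j - self.lesion_center_lat) / self.lesion_radius_lat
                if r >= 1.0:
                    continue
                depth_extent = np.sqrt(1.0 - r**2)
                top = zhi - (zhi - zlo) * depth_extent
                sel = (depth_grid_um >= top) & (depth_grid_um <= zhi)
                mask[sel, j, b] = True
        return mask


@dataclass
class RawVolume:
    """Raw spectra for a full scan: [bscan, lateral, spectrometer px, time]."""

    spectra: np.ndarray
    wavelength_grid_nm: np.ndarray
    config: AcquisitionConfig
    truth: PhantomTruth | None = None

    @property
    def n_bscans(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.spectra.shape[1]

    def mscan(self, bscan: int, lateral: int) -> RawSpectralMScan:
        return RawSpectralMScan(
            spectra=np.asarray(self.spectra[bscan, lateral], dtype=float),
            wavelength_grid_nm=self.wavelength_grid_nm,
            config=self.config,
        )


# ---------------------------------------------------------------------------
# modulation waveform
# ---------------------------------------------------------------------------
def modulation_waveform(
    t: np.ndarray,
    f0: float,
    duty: float = 0.5,
    mode: str = "square_lowpass",
    tau_ms: float = 0.2,
) -> np.ndarray:
    """Unit-amplitude photothermal ΔOPL time course m(t) ∈ [0, 1].

    ``pure_sine`` returns ½(1 + sin 2πf0t) and ignores ``tau_ms``.
    ``square_lowpass`` returns the steady-state first-order (exponential
    rise/decay, time constant τ) response to the 0/1 square drive,
    normalized to peak 1.
    """
    t = np.asarray(t, dtype=float)
    if mode == "pure_sine":
        return 0.5 * (1.0 + np.sin(2.0 * np.pi * f0 * t))
    if mode != "square_lowpass":
        raise ParameterError(f"unknown thermal mode {mode!r}")
    tau = tau_ms * 1e-3
    if tau <= 0:
        raise ParameterError("tau must be > 0")
    if not 0 < duty < 1:
        raise ParameterError("duty must be in (0, 1)")
    T = 1.0 / f0
    ton = duty * T
    toff = T - ton
    # steady-state cyclic boundary values of the first-order response
    e_on = np.exp(-ton / tau)
    e_off = np.exp(-toff / tau)
    m_start = (1.0 - e_on) * e_off / (1.0 - e_on * e_off)  # value at drive turn-on
    m_peak = 1.0 - (1.0 - m_start) * e_on  # value at drive turn-off
    tp = np.mod(t, T)
    on = tp < ton
    m = np.empty_like(tp)
    m[on] = 1.0 - (1.0 - m_start) * np.exp(-tp[on] / tau)
    m[~on] = m_peak * np.exp(-(tp[~on] - ton) / tau)
    return m / m_peak


def _fundamental_amplitude(f0: float, duty: float, mode: str, tau_ms: float) -> float:
    """Amplitude of the f0 Fourier component of the unit modulation waveform."""
    if mode == "pure_sine":
        return 0.5
    n_fine = 4096
    t = np.arange(n_fine) / (n_fine * f0)  # exactly one period
    m = modulation_waveform(t, f0, duty, mode, tau_ms)
    return 2.0 * np.abs(np.mean(m * np.exp(-2j * np.pi * f0 * t)))


def normalized_drive(
    t: np.ndarray,
    f0: float,
    duty: float = 0.5,
    mode: str = "square_lowpass",
    tau_ms: float = 0.2,
) -> np.ndarray:
    """Modulation waveform rescaled so its f0 Fourier component is 1.

    Multiplying this drive by the truth amplitude A makes A exactly the
    sinusoidal-equivalent amplitude a Fourier lock-in at f0 reads back.
    The component is measured on the sampling grid itself (over a whole
    number of periods when possible), so harmonic aliasing at coarse
    sampling rates is normalized away rather than left as a bias.
    """
    t = np.asarray(t, dtype=float)
    m = modulation_waveform(t, f0, duty, mode, tau_ms)
    c = None
    if t.size >= 2:
        dt = t[1] - t[0]
        per = 1.0 / (f0 * dt)
        per_round = round(per)
        if per_round >= 2 and abs(per - per_round) < 1e-9 * per and t.size >= per_round:
            n_whole = (t.size // per_round) * per_round
            c = 2.0 * np.abs(
                np.mean(m[:n_whole] * np.exp(-2j * np.pi * f0 * t[:n_whole]))
            )
    if c is None or c == 0.0:
        c = _fundamental_amplitude(f0, duty, mode, tau_ms)
    return m / c


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------
def _band(z0: float, z1: float, spacing: float) -> np.ndarray:
    n = max(int(round((z1 - z0) / spacing)) + 1, 2)
    return np.linspace(z0, z1, n)


def make_phantom(
    kind: str,
    n_lateral: int = 1,
    n_bscans: int = 1,
    seed: int = 0,
    *,
    depth_um: float = 200.0,
    amplitude: float = 1.0,
    absorber_units: float = 0.0,
    rpe_depth_um: float = 185.0,
    rpe_fwhm_um: float = 12.0,
    rpe_total_absorber: float = 3.0,
    choroid_band_um: tuple = (197.0, 240.0),
    choroid_total_absorber: float = 0.5,
    retina_band_um: tuple = (60.0, 170.0),
    lesion_total_absorber: float = 0.35,
    lesion_radius_lat: float | None = None,
    depth_window_um: tuple = (20.0, 270.0),
    speckle: bool = True,
    **truth_kwargs,
) -> PhantomTruth:
    """Build a ground-truth phantom of the requested kind.

    Kinds: ``pigmented_retina`` (absorbing RPE band over a weak choroid),
    ``albino_retina`` (same scattering structure, zero absorber),
    ``lcnv_lesion`` (dome-shaped lesion with uniform absorber over an RPE
    band), ``lcnv_control`` (same geometry, no absorber in the lesion),
    ``single_reflector`` (one mirror, optionally absorbing).
    """
    if kind not in PHANTOM_KINDS:
        raise ParameterError(f"unknown phantom kind {kind!r}; expected one of {PHANTOM_KINDS}")
    rng = np.random.default_rng(seed)
    zlo_w, zhi_w = depth_window_um

    if kind == "single_reflector":
        if not zlo_w < depth_um < zhi_w:
            raise ParameterError("reflector depth outside the depth window")
        return PhantomTruth(
            kind=kind,
            reflector_depths_um=np.array([depth_um]),
            reflector_amplitudes=np.full((1, n_lateral, n_bscans), amplitude),
            absorber_map=np.full((1, n_lateral, n_bscans), absorber_units),
            seed=seed,
            depth_window_um=depth_window_um,
            **truth_kwargs,
        )

    rpe_half = max(2.0 * rpe_fwhm_um, 10.0) / 2.0
    rpe_band = (rpe_depth_um - rpe_half, rpe_depth_um + rpe_half)
    if kind in ("pigmented_retina", "albino_retina"):
        bands = [retina_band_um, rpe_band, choroid_band_um]
    else:
        bands = [retina_band_um, rpe_band]
    span = sum(b[1] - b[0] for b in bands)
    if span >= (zhi_w - zlo_w):
        raise ParameterError("tissue bands leave no background region in the depth window")
    for b in bands:
        if b[0] < zlo_w or b[1] > zhi_w:
            raise ParameterError(f"band {b} outside depth window {depth_window_um}")

    depths, amps, concs = [], [], []

    def add_band(z0, z1, spacing, refl, conc_profile):
        z = _band(z0, z1, spacing)
        depths.append(z)
        a = np.full((z.size, n_lateral, n_bscans), refl)
        if speckle:
            # speckle decorrelates laterally: independent draw per column
            a = a * rng.uniform(0.6, 1.4, size=a.shape)
        amps.append(a)
        concs.append(conc_profile(z))

    # neural retina: scattering, non-absorbing
    add_band(*retina_band_um, 4.0, 0.25, lambda z: np.zeros(z.size))

    # RPE: strong scattering, Gaussian absorber profile of requested FWHM
    sigma = rpe_fwhm_um / 2.3548200450309493
    rpe_absorbing = kind in ("pigmented_retina", "lcnv_lesion", "lcnv_control")

    def rpe_conc(z):
        prof = np.exp(-0.5 * ((z - rpe_depth_um) / sigma) ** 2)
        prof /= prof.sum()
        return rpe_total_absorber * prof if rpe_absorbing else np.zeros(z.size)

    add_band(rpe_band[0], rpe_band[1], 2.0, 1.0, rpe_conc)

    if kind in ("pigmented_retina", "albino_retina"):
        total = choroid_total_absorber if kind == "pigmented_retina" else 0.0

        def cho_conc(z):
            return np.full(z.size, total / z.size)

        # choroid scatters strongly (dense vasculature + melanin)
        add_band(*choroid_band_um, 4.0, 0.6, cho_conc)

    z_all = np.concatenate(depths)
    amp_map = np.concatenate(amps, axis=0)
    conc_map = np.tile(np.concatenate(concs)[:, None, None], (1, n_lateral, n_bscans))

    lesion_geom: dict = {}
    if kind in ("lcnv_lesion", "lcnv_control"):
        if lesion_radius_lat is None:
            lesion_radius_lat = max(n_lateral / 3.0, 2.0)
        center = n_lateral // 2
        lesion_band = (rpe_band[0] - 60.0, rpe_band[0] - 4.0)
        z_les = _band(lesion_band[0], lesion_band[1], 4.0)
        les_amp = np.zeros((z_les.size, n_lateral, n_bscans))
        les_conc = np.zeros_like(les_amp)
        for b in range(n_bscans):
            for j in range(n_lateral):
                r = abs(j - center) / lesion_radius_lat
                if r >= 1.0:
                    continue
                extent = np.sqrt(1.0 - r**2)
                top = lesion_band[1] - (lesion_band[1] - lesion_band[0]) * extent
                inside = z_les >= top
                n_in = int(inside.sum())
                if n_in == 0:
                    continue
                a = np.full(n_in, 0.5)
                if speckle:
                    a = a * rng.uniform(0.6, 1.4, size=n_in)
                les_amp[inside, j, b] = a
                if kind == "lcnv_lesion":
                    les_conc[inside, j, b] = lesion_total_absorber / n_in
        z_all = np.concatenate([z_all, z_les])
        amp_map = np.concatenate([amp_map, les_amp], axis=0)
        conc_map = np.concatenate([conc_map, les_conc], axis=0)
        lesion_geom = dict(
            lesion_center_lat=center,
            lesion_radius_lat=float(lesion_radius_lat),
            lesion_depth_band_um=lesion_band,
        )

    return PhantomTruth(
        kind=kind,
        reflector_depths_um=z_all,
        reflector_amplitudes=amp_map,
        absorber_map=conc_map,
        seed=seed,
        depth_window_um=depth_window_um,
        rpe_band_um=rpe_band,
        **lesion_geom,
        **truth_kwargs,
    )


# ---------------------------------------------------------------------------
# raw spectrum synthesis
# ---------------------------------------------------------------------------
def make_wavelength_grid(config: AcquisitionConfig) -> np.ndarray:
    """Spectrometer wavelength calibration: linear in pixel, λ0 ± 1.5 Δλ."""
    lam0, dlam = config.center_wavelength_nm, config.bandwidth_nm
    return np.linspace(lam0 - 1.5 * dlam, lam0 + 1.5 * dlam, config.n_spectrometer_pixels)


def unambiguous_depth_um(config: AcquisitionConfig) -> float:
    """Nyquist depth of the spectral sampling (µm)."""
    lam = make_wavelength_grid(config)
    k = 2.0 * np.pi / lam
    dk = (k.max() - k.min()) / (k.size - 1)
    return float(np.pi / (2.0 * config.refractive_index * dk) / 1000.0)


def _source_envelope(k: np.ndarray, config: AcquisitionConfig) -> np.ndarray:
    k0 = 2.0 * np.pi / config.center_wavelength_nm
    dk_fwhm = 2.0 * np.pi * config.bandwidth_nm / config.center_wavelength_nm**2
    return np.exp(-4.0 * np.log(2.0) * ((k - k0) / dk_fwhm) ** 2)


def dispersion_phase(k: np.ndarray, a2: float, a3: float) -> np.ndarray:
    """Dispersion phase polynomial θ(k) = a2·x² + a3·x³ on x = normalized k."""
    kc = 0.5 * (k.max() + k.min())
    x = (k - kc) / (0.5 * (k.max() - k.min()))
    return a2 * x**2 + a3 * x**3


def simulate_mscan(
    truth: PhantomTruth,
    config: AcquisitionConfig,
    lateral: int = 0,
    bscan: int = 0,
    power_mw: float | None = None,
    dispersion: tuple = (0.0, 0.0),
    seed: int | None = None,
    motion_offset_px: float = 0.0,
    noiseless: bool = False,
) -> RawSpectralMScan:
    """Synthesize one raw spectral M-scan for a phantom column.

    ``motion_offset_px`` shifts every reflector axially by that many
    canonical depth pixels (breathing surrogate). Noise (bulk phase jitter
    and additive spectral noise) follows the truth's levels unless
    ``noiseless``.
    """
    if power_mw is None:
        power_mw = config.pt_power_mw
    if power_mw < 0:
        raise ParameterError("power must be >= 0")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    lam = make_wavelength_grid(config)
    k = 2.0 * np.pi / lam  # rad/nm, decreasing with pixel index
    n = config.refractive_index
    z_um = truth.reflector_depths_um + motion_offset_px * truth.pixel_size_z_um
    if np.any(z_um <= 0) or z_um.max() >= unambiguous_depth_um(config):
        raise ParameterError("reflector beyond the unambiguous depth range")
    z_nm = z_um * 1000.0
    a = truth.reflector_amplitudes[:, lateral, bscan]
    A = truth.amplitude_nm(power_mw)[:, lateral, bscan]  # nm

    t = np.arange(config.n_repeats) / config.line_rate_hz
    g = normalized_drive(
        t,
        config.mod_frequency_hz,
        config.mod_duty,
        truth.thermal_mode,
        truth.thermal_time_constant_ms,
    )
    dphi = 4.0 * np.pi * n / config.center_wavelength_nm * A  # rad per unit drive
    phases = dphi[:, None] * g[None, :]
    if not noiseless and truth.phase_noise_rad > 0:
        phases = phases + rng.normal(0.0, truth.phase_noise_rad, size=t.size)[None, :]

    theta = dispersion_phase(k, *dispersion)
    carrier = np.exp(1j * (2.0 * k[:, None] * n * z_nm[None, :] + theta[:, None]))
    fringes = np.real((carrier * a[None, :]) @ np.exp(1j * phases))

    G = _source_envelope(k, config)
    dc = float(np.sum(np.abs(a))) + 1.0
    spectra = G[:, None] * (dc + fringes)
    if not noiseless and truth.spectral_noise > 0:
        spectra = spectra + rng.normal(0.0, truth.spectral_noise, size=spectra.shape)
        spectra += 6.0 * truth.spectral_noise  # dark offset keeps counts positive
    spectra = np.maximum(spectra, 0.0)
    return RawSpectralMScan(spectra=spectra, wavelength_grid_nm=lam, config=config)


# ---------------------------------------------------------------------------
# volumes and motion
# ---------------------------------------------------------------------------
def make_breathing_trace(
    n_ascans: int,
    dwell_s: float,
    amplitude_px: float = 5.0,
    freq_hz: float = 1.5,
    drift_px_per_s: float = 1.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Slow smooth axial displacement per A-scan: sinusoid plus linear drift."""
    t = np.arange(n_ascans) * dwell_s
    return amplitude_px * np.sin(2.0 * np.pi * freq_hz * t + phase) + drift_px_per_s * t


def simulate_volume(
    truth: PhantomTruth,
    config: AcquisitionConfig,
    seed: int = 0,
    motion_amplitude_px: float = 5.0,
    motion_freq_hz: float = 1.5,
    dropout_fraction: float = 0.0,
    dispersion: tuple = (0.0, 0.0),
    power_mw: float | None = None,
) -> tuple["RawVolume", "RawVolume"]:
    """Simulate a raw M-scan volume plus a motion-free single-shot reference.

    Returns ``(raw, reference)``; the reference has the same geometry with no
    motion, no dropout and no photothermal drive, with a short time axis
    (two repeats) standing in for a fast standard OCT volume scan.
    The applied motion trace and dropout column indices are recorded on the
    returned raw volume's truth.
    """
    rng = np.random.default_rng(seed)
    n_lat, n_b = truth.n_lateral, truth.n_bscans
    if power_mw is None:
        power_mw = config.pt_power_mw

    dwell = config.n_repeats / config.line_rate_hz
    depth_extent = truth.depth_window_um[1] - truth.depth_window_um[0]
    if motion_amplitude_px * truth.pixel_size_z_um >= depth_extent:
        raise ParameterError("motion amplitude exceeds the depth window")
    trace = np.stack(
        [
            make_breathing_trace(
                n_lat, dwell, motion_amplitude_px, motion_freq_hz,
                phase=float(rng.uniform(0, 2 * np.pi)),
            )
            for _ in range(n_b)
        ],
        axis=1,
    )  # (n_lat, n_b)

    dropout: list = []
    if dropout_fraction > 0:
        n_drop = int(round(dropout_fraction * n_lat))
        for b in range(n_b):
            cols = rng.choice(n_lat, size=n_drop, replace=False)
            dropout.extend((b, int(c)) for c in sorted(cols))

    lam = make_wavelength_grid(config)
    G = _source_envelope(2.0 * np.pi / lam, config)
    raw = np.empty(
        (n_b, n_lat, config.n_spectrometer_pixels, config.n_repeats), dtype=np.float32
    )
    for b in range(n_b):
        for j in range(n_lat):
            if (b, j) in dropout:
                # corrupted A-scan: decorrelated noise, no structure
                noise = rng.normal(0.0, 1.0, size=(config.n_spectrometer_pixels, config.n_repeats))
                raw[b, j] = np.maximum(G[:, None] * 2.0 + noise + 6.0, 0.0)
                continue
            m = simulate_mscan(
                truth, config, lateral=j, bscan=b, power_mw=power_mw,
                dispersion=dispersion, seed=int(rng.integers(0, 2**31 - 1)),
                motion_offset_px=float(trace[j, b]),
            )
            raw[b, j] = m.spectra

    truth_moving = replace(
        truth, motion_trace_px=trace, dropout_columns=dropout, seed=seed
    )
    raw_vol = RawVolume(raw, lam, config, truth_moving)

    # single-shot reference: no drive, no motion, 2 repeats
    ref_cfg = replace(config, n_repeats=2, pt_power_mw=0.0)
    ref = np.empty((n_b, n_lat, config.n_spectrometer_pixels, 2), dtype=np.float32)
    for b in range(n_b):
        for j in range(n_lat):
            m = simulate_mscan(
                truth, ref_cfg, lateral=j, bscan=b, power_mw=0.0,
                dispersion=dispersion, seed=int(rng.integers(0, 2**31 - 1)),
            )
            ref[b, j] = m.spectra
    ref_vol = RawVolume(ref, lam, ref_cfg, replace(truth, motion_trace_px=None, seed=seed))
    return raw_vol, ref_vol


# ---------------------------------------------------------------------------
# cohort-level generators (per-eye summary values)
# ---------------------------------------------------------------------------
#: Per-eye mean PT-OCT signal (nm) emulating the study cohorts at 8 mW:
#: pigmented retina-band mean, albino near-floor, gold-nanorod lesion mean
#: above the melanin-driven background of the saline control.
COHORT_PARAMS = {
    "pigmented": (5.0, 1.5),
    "albino": (0.2, 0.15),
    "gnr": (7.0, 1.5),
    "control": (3.4, 1.0),
}


def cohort_table(groups: dict | None = None, seed: int = 0):
    """Per-eye summary table for group comparisons.

    ``groups`` maps group label -> number of eyes; values are drawn from the
    group's emulated (mean, sd) in :data:`COHORT_PARAMS`, floored at zero.
    Returns a pandas DataFrame with columns eye_id, group, value_nm.
    """
    import pandas as pd

    if groups is None:
        groups = {"pigmented": 6, "albino": 6}
    rng = np.random.default_rng(seed)
    rows = []
    for label, n_eyes in groups.items():
        mu, sd = COHORT_PARAMS[label]
        vals = np.maximum(rng.normal(mu, sd, size=n_eyes), 0.0)
        for i, v in enumerate(vals):
            rows.append({"eye_id": f"{label}_{i}", "group": label, "value_nm": float(v)})
    return pd.DataFrame(rows)


def power_series_table(
    powers_mw=(0.0, 0.4, 1.0, 2.0, 4.0, 8.0, 10.0),
    n_eyes: int = 6,
    slope_nm_per_mw: float = 1.56,
    noise_fraction: float = 0.2,
    detection_floor_nm: float = 0.0,
    floor_noise_nm: float = 0.15,
    seed: int = 0,
):
    """Per-eye, per-power PT-OCT signal table emulating the power series.

    The measured value is ``max(0, slope·P·(1 + ε) − floor + η)``. With a
    nonzero ``detection_floor_nm`` (~0.5 nm) no signal registers below the
    detection limit near 0.5 mW, emulating the noise-floor subtraction; the
    default of 0 keeps the series linear for slope-recovery studies.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for p in powers_mw:
        true = slope_nm_per_mw * p
        vals = true * (1.0 + noise_fraction * rng.standard_normal(n_eyes))
        if detection_floor_nm > 0:
            vals = vals - detection_floor_nm + floor_noise_nm * rng.standard_normal(n_eyes)
        measured = np.maximum(vals, 0.0)
        for i in range(n_eyes):
            rows.append(
                {
                    "eye_id": f"eye_{i}",
                    "power_mw": float(p),
                    "value_nm": float(measured[i]),
                    "true_nm": float(true),
                }
            )
    return pd.DataFrame(rows)
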