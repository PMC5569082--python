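"""Spectral reconstruction: resampling, background, dispersion, Chirp-Z."""

import warnings

import numpy as np
import pytest

from ptoct import AcquisitionConfig
from ptoct.containers import RawSpectralMScan
from ptoct.errors import ParameterError, ValidationError
from ptoct.reconstruction import (
    DispersionModel,
    apply_dispersion,
    chirpz_to_depth,
    estimate_dispersion,
    nyquist_depth_um,
    resample_to_wavenumber,
    subtract_background,
)
from ptoct.simulate import make_phantom, simulate_mscan


def _uniform_k_grid(n=256):
    return np.linspace(2 * np.pi / 920.0, 2 * np.pi / 800.0, n)


class TestResample:
    def test_constant_spectrum_stays_constant(self):
        lam = np.linspace(800.0, 920.0, 256)
        cfg = AcquisitionConfig(n_spectrometer_pixels=256, n_repeats=2)
        raw = RawSpectralMScan(np.full((256, 2), 3.0), lam, cfg)
        sk, kg = resample_to_wavenumber(raw)
        assert np.allclose(sk, 3.0, atol=1e-10)
        dk = np.diff(kg)
        assert np.allclose(dk, dk[0])

    def test_uniform_in_k_input_is_identity(self):
        k = _uniform_k_grid()  # ascending
        lam = 2 * np.pi / k  # descending wavelength grid -> k ascending with pixel
        cfg = AcquisitionConfig(n_spectrometer_pixels=256, n_repeats=2)
        data = np.cos(np.outer(k, [1e5, 1e5])) + 2.0
        raw = RawSpectralMScan(data, lam, cfg)
        sk, kg = resample_to_wavenumber(raw)
        assert np.allclose(kg, k, atol=1e-14)
        assert np.allclose(sk, data, atol=1e-10)

    def test_resampling_sharpens_deep_fringe(self):
        # a fixed-depth fringe is chirped on the wavelength grid: its depth
        # peak is broadened if transformed without k-resampling
        cfg = AcquisitionConfig(n_spectrometer_pixels=512, n_repeats=2)
        truth = make_phantom("single_reflector", depth_um=400.0, phase_model="local",
                             depth_window_um=(20.0, 550.0))
        raw = simulate_mscan(truth, cfg, power_mw=0.0, noiseless=True)
        sk, kg = resample_to_wavenumber(raw)

        def peak_width(spec):
            mag = np.abs(np.fft.rfft(spec - spec.mean(), n=8192))
            mag[:1024] = 0.0  # exclude the smooth source-envelope term
            pk = mag.argmax()
            half = mag[pk] / 2
            above = np.nonzero(mag >= half)[0]
            return above.max() - above.min() + 1

        w_resampled = peak_width(sk[:, 0])
        w_raw = peak_width(raw.spectra[:, 0])
        assert w_raw / w_resampled > 1.5


class TestSubtractBackground:
    def test_identical_spectra_cancel(self):
        block = np.tile(np.arange(32.0)[:, None], (1, 5))
        assert np.allclose(subtract_background(block), 0.0)

    def test_dc_removed_fringe_kept(self):
        k = _uniform_k_grid(128)
        t = np.arange(6)
        fringe = np.cos(np.outer(k, np.full(6, 2e5)) + 0.0)
        block = fringe + 100.0
        out = subtract_background(block)
        assert abs(out.mean()) < 1e-12
        # static fringe is its own temporal mean: removed entirely
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_time_varying_fringe_attenuated_by_phase_mean(self):
        k = _uniform_k_grid(128)
        phi0 = 0.4
        t = np.arange(64)
        phases = phi0 * np.sin(2 * np.pi * t / 16.0)
        block = np.cos(2e5 * k[:, None] + phases[None, :])
        out = subtract_background(block)
        # subtracted mean equals Re{e^{ikz}·mean(e^{iφ})}: per-sample residual
        from scipy.special import j0

        expected = block - np.real(
            np.exp(1j * 2e5 * k)[:, None] * np.mean(np.exp(1j * phases))
        )
        assert np.allclose(out, expected, atol=1e-10)
        assert abs(np.mean(np.exp(1j * phases))) == pytest.approx(j0(phi0), abs=1e-3)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            subtract_background(np.ones((8, 1)))


class TestChirpZ:
    def test_full_range_matches_fft_bin_for_bin(self):
        rng = np.random.default_rng(0)
        n = 512
        k = _uniform_k_grid(n)
        cfg = AcquisitionConfig(n_spectrometer_pixels=n)
        x = rng.normal(size=n) + 1j * rng.normal(size=n)
        dk = (k[-1] - k[0]) / (n - 1)
        z_nyq_nm = np.pi / (2 * cfg.refractive_index * dk)
        dz_um = 2 * z_nyq_nm / n / 1000.0
        cm = chirpz_to_depth(x[:, None], k, cfg, (0.0, dz_um * (n - 1)), n)
        carrier = np.exp(-2j * k[0] * cfg.refractive_index * cm.depth_grid_um * 1000.0)
        fft = np.fft.fft(x) * carrier
        err = np.abs(cm.field[:, 0] - fft).max() / np.abs(fft).max()
        assert err < 1e-9

    def test_delta_spectrum_is_flat_in_depth(self):
        n = 256
        k = _uniform_k_grid(n)
        cfg = AcquisitionConfig(n_spectrometer_pixels=n)
        x = np.zeros(n, complex)
        x[n // 2] = 1.0
        cm = chirpz_to_depth(x[:, None], k, cfg, (50.0, 400.0), 64)
        mag = np.abs(cm.field[:, 0])
        assert mag.max() == pytest.approx(mag.min(), rel=1e-9)

    def test_zoomed_window_localizes_reflector(self):
        n = 512
        k = _uniform_k_grid(n)
        cfg = AcquisitionConfig(n_spectrometer_pixels=n)
        x = np.cos(2 * k * cfg.refractive_index * 200_000.0)
        cm = chirpz_to_depth(x[:, None].astype(complex), k, cfg, (150.0, 250.0), 101)
        z_pk = cm.depth_grid_um[np.argmax(np.abs(cm.field[:, 0]))]
        assert abs(z_pk - 200.0) <= cm.pixel_size_z_um / 2

    def test_window_beyond_range_rejected(self):
        n = 128
        k = _uniform_k_grid(n)
        cfg = AcquisitionConfig(n_spectrometer_pixels=n)
        z_nyq = nyquist_depth_um(k, cfg.refractive_index)
        with pytest.raises(ParameterError):
            chirpz_to_depth(np.ones((n, 1), complex), k, cfg, (0.0, 3.0 * z_nyq), 64)

    def test_linearity_over_reflectors(self):
        n = 256
        k = _uniform_k_grid(n)
        cfg = AcquisitionConfig(n_spectrometer_pixels=n)
        s1 = np.cos(2 * k * cfg.refractive_index * 150_000.0)
        s2 = 0.5 * np.cos(2 * k * cfg.refractive_index * 220_000.0)
        win, m = (100.0, 260.0), 161
        f1 = chirpz_to_depth(s1[:, None].astype(complex), k, cfg, win, m).field
        f2 = chirpz_to_depth(s2[:, None].astype(complex), k, cfg, win, m).field
        f12 = chirpz_to_depth((s1 + s2)[:, None].astype(complex), k, cfg, win, m).field
        assert np.allclose(f12, f1 + f2, atol=1e-9 * np.abs(f1).max())

    def test_parseval_energy_preserved_on_full_range(self):
        rng = np.random.default_rng(1)
        n = 256
        k = _uniform_k_grid(n)
        cfg = AcquisitionConfig(n_spectrometer_pixels=n)
        x = rng.normal(size=n) + 1j * rng.normal(size=n)
        dk = (k[-1] - k[0]) / (n - 1)
        z_nyq_nm = np.pi / (2 * cfg.refractive_index * dk)
        dz_um = 2 * z_nyq_nm / n / 1000.0
        cm = chirpz_to_depth(x[:, None], k, cfg, (0.0, dz_um * (n - 1)), n)
        assert np.sum(np.abs(cm.field) ** 2) / n == pytest.approx(
            np.sum(np.abs(x) ** 2), rel=1e-9
        )


@pytest.fixture(scope="module")
def dispersed():
    cfg = AcquisitionConfig(n_repeats=8)  # full 2048-pixel spectrometer
    truth = make_phantom("single_reflector", depth_um=200.0, phase_model="local")
    raw = simulate_mscan(truth, cfg, power_mw=0.0, dispersion=(10.0, 4.0), noiseless=True)
    sk, kg = resample_to_wavenumber(raw)
    return cfg, truth, sk, kg


class TestDispersion:

    def test_known_coefficients_recovered(self, dispersed):
        cfg, truth, sk, kg = dispersed
        model = estimate_dispersion(sk, kg, cfg)
        assert model.a2 == pytest.approx(10.0, rel=0.05)
        assert model.a3 == pytest.approx(4.0, rel=0.05)

    def test_corrected_peak_height_matches_dispersion_free(self, dispersed):
        cfg, truth, sk, kg = dispersed
        model = estimate_dispersion(sk, kg, cfg)
        raw0 = simulate_mscan(truth, cfg, power_mw=0.0, dispersion=(0.0, 0.0), noiseless=True)
        sk0, _ = resample_to_wavenumber(raw0)
        pk_free = np.abs(
            chirpz_to_depth(sk0.astype(complex), kg, cfg, (150, 250), 201).field
        ).max()
        pk_corr = np.abs(
            chirpz_to_depth(apply_dispersion(sk.astype(complex), kg, model), kg, cfg, (150, 250), 201).field
        ).max()
        assert pk_corr == pytest.approx(pk_free, rel=0.01)

    def test_dispersion_free_input_gives_near_zero_a2(self):
        cfg = AcquisitionConfig(n_repeats=8)
        truth = make_phantom("single_reflector", depth_um=200.0, phase_model="local")
        raw = simulate_mscan(truth, cfg, power_mw=0.0, noiseless=True)
        sk, kg = resample_to_wavenumber(raw)
        model = estimate_dispersion(sk, kg, cfg)
        assert abs(model.a2) < 0.5

    def test_sharpness_is_locally_maximal_at_truth(self, dispersed):
        cfg, truth, sk, kg = dispersed
        from ptoct.reconstruction import _sharpness

        win = (170.0, 230.0)
        at_truth = _sharpness(sk.mean(axis=1, keepdims=True), kg, cfg, 10.0, 4.0, win, 301)
        for da in (-3.0, 3.0):
            perturbed = _sharpness(
                sk.mean(axis=1, keepdims=True), kg, cfg, 10.0 + da, 4.0, win, 301
            )
            assert at_truth >= perturbed

    def test_noise_only_input_warns_and_returns_identity(self):
        cfg = AcquisitionConfig(n_spectrometer_pixels=256, n_repeats=4)
        kg = _uniform_k_grid(256)
        rng = np.random.default_rng(0)
        noise = rng.normal(5.0, 0.1, size=(256, 4))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = estimate_dispersion(noise, kg, cfg)
        assert (model.a2, model.a3) == (0.0, 0.0)
        assert any("dominant" in str(w.message) for w in caught)


def test_phase_modulation_survives_reconstruction(small_config):
    """A pure-sine phase drive appears at the reconstructed peak with the
    driven amplitude (phase fidelity of the full transform chain)."""
    truth = make_phantom(
        "single_reflector", depth_um=200.0, absorber_units=1.0,
        thermal_mode="pure_sine", phase_model="local",
    )
    from ptoct.reconstruction import reconstruct_mscan

    raw = simulate_mscan(truth, small_config, power_mw=2.0, noiseless=True)
    cm = reconstruct_mscan(raw, window_um=(150.0, 250.0), n_out=101)
    ipk = np.argmax(np.abs(cm.field).mean(axis=1))
    phase = np.unwrap(np.angle(cm.field[ipk]))
    # drive amplitude in rad: (4 pi n / lambda0) * A, with A = 1.56*2 nm and
    # the normalized sine drive 1 + sin
    a_nm = 1.56 * 2.0
    dphi = 4 * np.pi * small_config.refractive_index / small_config.center_wavelength_nm * a_nm
    swing = (phase.max() - phase.min()) / 2.0
    assert swing == pytest.approx(dphi, rel=0.01)
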