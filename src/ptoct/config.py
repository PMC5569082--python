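"""Acquisition and analysis configuration.

The defaults describe a spectral-domain OCT system modified for photothermal
imaging: an 860 nm / 40 nm-bandwidth source read out on a 2048-pixel
spectrometer at a 10 kHz line rate, with the photothermal laser
amplitude-modulated by a 500 Hz square wave at 50% duty cycle and 700
repeated A-scans (M-mode) recorded per lateral position.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError, ValidationError

__all__ = ["AcquisitionConfig", "AnalysisConfig", "load_yaml_config", "save_yaml_config"]


@dataclass
class AcquisitionConfig:
    """Instrument settings for one PT-OCT acquisition.

    Parameters
    ----------
    center_wavelength_nm : float
        Center wavelength λ0 of the OCT source (nm).
    bandwidth_nm : float
        FWHM spectral bandwidth Δλ of the source (nm).
    line_rate_hz : float
        A-scan (spectrum) acquisition rate fs (Hz).
    mod_frequency_hz : float
        Photothermal amplitude-modulation frequency f0 (Hz). Must be below
        the Nyquist rate fs/2 to be resolvable by the temporal lock-in.
    mod_duty : float
        Duty cycle of the square-wave drive, in (0, 1).
    n_repeats : int
        Number of repeated temporal A-scans per M-scan, N_t.
    refractive_index : float
        Bulk refractive index n used to convert phase to optical path length.
    pt_power_mw : float
        Photothermal laser power at the sample (mW). Zero disables the drive.
    n_spectrometer_pixels : int
        Number of spectrometer (CCD) pixels.
    n_ascans_per_bscan : int
        Lateral A-scan count per B-scan.
    """

    center_wavelength_nm: float = 860.0
    bandwidth_nm: float = 40.0
    line_rate_hz: float = 10_000.0
    mod_frequency_hz: float = 500.0
    mod_duty: float = 0.5
    n_repeats: int = 700
    refractive_index: float = 1.38
    pt_power_mw: float = 8.0
    n_spectrometer_pixels: int = 2048
    n_ascans_per_bscan: int = 400

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = (
            ("center_wavelength_nm", self.center_wavelength_nm),
            ("bandwidth_nm", self.bandwidth_nm),
            ("line_rate_hz", self.line_rate_hz),
            ("mod_frequency_hz", self.mod_frequency_hz),
            ("refractive_index", self.refractive_index),
        )
        for name, value in positive:
            if not value > 0:
                raise ValidationError(f"{name} must be > 0, got {value!r}")
        if self.pt_power_mw < 0:
            raise ValidationError("pt_power_mw must be >= 0")
        if not 0 < self.mod_duty < 1:
            raise ValidationError(f"mod_duty must be in (0, 1), got {self.mod_duty!r}")
        if self.n_repeats < 2:
            raise ValidationError("n_repeats must be >= 2")
        if not self.mod_frequency_hz < self.line_rate_hz / 2:
            raise ValidationError(
                "mod_frequency_hz must be below the Nyquist rate line_rate_hz/2"
            )
        if self.n_spectrometer_pixels < 2 or self.n_ascans_per_bscan < 1:
            raise ValidationError("spectrometer and A-scan counts must be positive")

    # -- convenience -------------------------------------------------------
    @property
    def duration_s(self) -> float:
        """Length of one M-scan record in seconds."""
        return self.n_repeats / self.line_rate_hz

    @property
    def n_modulation_periods(self) -> float:
        """Number of photothermal modulation periods captured per M-scan."""
        return self.duration_s * self.mod_frequency_hz

    def axial_resolution_um(self, in_tissue: bool = False) -> float:
        """Gaussian coherence-length axial resolution (2 ln2/π)·λ0²/Δλ, in µm."""
        res_nm = (2.0 * 0.6931471805599453 / 3.141592653589793) * (
            self.center_wavelength_nm**2 / self.bandwidth_nm
        )
        if in_tissue:
            res_nm /= self.refractive_index
        return res_nm / 1000.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown AcquisitionConfig fields: {sorted(unknown)}")
        return cls(**d)


@dataclass
class AnalysisConfig:
    """Settings for ROI quantification and group statistics.

    ``area_threshold_px`` implements the lesion-inclusion rule: lesions whose
    total mask area (summed over B-scans) does not exceed the threshold are
    excluded from group comparisons. ``background_margin_px`` widens the
    half-maximum band before computing background statistics.
    """

    area_threshold_px: int = 40_000
    background_margin_px: int = 1
    power_levels_mw: list = field(default_factory=lambda: [0.4, 1.0, 2.0, 4.0, 8.0, 10.0])

    def __post_init__(self) -> None:
        if self.area_threshold_px <= 0:
            raise ValidationError("area_threshold_px must be > 0")
        if self.background_margin_px < 0:
            raise ValidationError("background_margin_px must be >= 0")


def load_yaml_config(path) -> dict:
    """Load a YAML run configuration.

    Returns a dict with keys ``acquisition`` (AcquisitionConfig) and
    ``analysis`` (AnalysisConfig); missing sections get defaults. Extra
    top-level sections are passed through untouched for stage parameters.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    out["acquisition"] = AcquisitionConfig.from_dict(raw.get("acquisition", {}) or {})
    analysis = raw.get("analysis", {}) or {}
    out["analysis"] = AnalysisConfig(**analysis)
    return out


def save_yaml_config(path, acquisition: AcquisitionConfig, analysis: AnalysisConfig | None = None, **extra) -> None:
    doc = {"acquisition": acquisition.to_dict()}
    if analysis is not None:
        doc["analysis"] = dataclasses.asdict(analysis)
    doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
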