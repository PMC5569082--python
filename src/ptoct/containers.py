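"""Core in-memory data containers shared by all pipeline stages.

Depth-axis convention: index 0 is zero optical delay, depth increases
downward (toward the choroid in retinal data). All optical-path-length
images are in nanometers; OCT structural images are log-intensity (dB,
arbitrary reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AcquisitionConfig
from .errors import DimensionError, ValidationError

__all__ = ["RawSpectralMScan", "ImageVolume", "ROIMask"]

IMAGE_KINDS = ("oct_log_intensity", "ptoct_nm")


@dataclass
class RawSpectralMScan:
    """One M-scan: repeated raw spectra at a fixed lateral position.

    ``spectra`` is [spectrometer pixel × time sample], non-negative counts;
    ``wavelength_grid_nm`` maps spectrometer pixel to wavelength and must be
    strictly monotonic.
    """

    spectra: np.ndarray
    wavelength_grid_nm: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelength_grid_nm = np.asarray(self.wavelength_grid_nm, dtype=float)
        if self.spectra.ndim != 2:
            raise ValidationError("spectra must be 2-D [pixel x time]")
        if self.wavelength_grid_nm.shape != (self.spectra.shape[0],):
            raise DimensionError(
                "wavelength_grid length must equal the spectrometer-pixel axis"
            )
        dl = np.diff(self.wavelength_grid_nm)
        if not (np.all(dl > 0) or np.all(dl < 0)):
            raise ValidationError("wavelength_grid must be strictly monotonic")
        if np.any(self.spectra < 0):
            raise ValidationError("raw spectra must be non-negative")
        if self.spectra.shape[1] != self.config.n_repeats:
            raise ValidationError(
                f"time axis length {self.spectra.shape[1]} != config.n_repeats "
                f"{self.config.n_repeats}"
            )

    @property
    def n_pixels(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_time(self) -> int:
        return self.spectra.shape[1]


@dataclass
class ImageVolume:
    """A [depth × lateral × B-scan] image volume with physical depth scale."""

    values: np.ndarray
    pixel_size_z_um: float
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # single B-scan promoted to a 1-deep volume
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValidationError("values must be 3-D [depth x lateral x bscan]")
        if self.kind not in IMAGE_KINDS:
            raise ValidationError(f"kind must be one of {IMAGE_KINDS}, got {self.kind!r}")
        if self.pixel_size_z_um <= 0:
            raise ValidationError("pixel_size_z_um must be > 0")
        if self.kind == "ptoct_nm" and np.any(self.values < -1e-9):
            raise ValidationError("ptoct_nm volumes must be non-negative")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def depth_axis_um(self) -> np.ndarray:
        return np.arange(self.shape[0]) * self.pixel_size_z_um

    def require_congruent(self, other: "ImageVolume") -> None:
        if self.shape != other.shape:
            raise DimensionError(
                f"volumes are not congruent: {self.shape} vs {other.shape}"
            )


@dataclass
class ROIMask:
    """Boolean mask congruent with an :class:`ImageVolume`."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim == 2:
            self.mask = self.mask[:, :, None]
        if self.mask.ndim != 3:
            raise ValidationError("mask must be 3-D [depth x lateral x bscan]")

    def require_congruent(self, volume: ImageVolume) -> None:
        if self.mask.shape != volume.shape:
            raise DimensionError(
                f"mask shape {self.mask.shape} does not match volume {volume.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def area_per_bscan(self) -> np.ndarray:
        """Mask pixel count per B-scan (summed over depth × lateral)."""
        return self.mask.sum(axis=(0, 1))
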