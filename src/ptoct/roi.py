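"""Quantification of PT-OCT images.

Axial (depth) profiles averaged over A-scans; the RPE signal peak with its
full-width-at-half-maximum band; mean background outside that band and the
peak-to-background ratio; per-lesion ROI means with the area-based inclusion
filter; en-face mean projections with PT-OCT rendered in the green channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import AnalysisConfig
from .containers import ImageVolume, ROIMask
from .errors import DimensionError, ParameterError, PTOCTError

__all__ = [
    "LayerMetrics",
    "LesionSummary",
    "axial_profile",
    "find_peak_fwhm",
    "background_stats",
    "lesion_mean",
    "enface_projection",
]


@dataclass
class LayerMetrics:
    """Peak/band/background metrics of one axial PT-OCT profile."""

    peak_depth_um: float
    peak_value_nm: float
    fwhm_um: float
    band_um: tuple
    mean_background_nm: float | None = None
    peak_to_background: float | None = None
    band_truncated: bool = False


@dataclass
class LesionSummary:
    """Per-eye lesion ROI summary feeding the group statistics."""

    eye_id: str
    group: str
    mean_signal_nm: float
    roi_voxels: int
    roi_area_px: int
    included: bool


# ---------------------------------------------------------------------------
def axial_profile(
    pt_bscan: np.ndarray, valid_mask: np.ndarray | None = None
) -> np.ndarray:
    """Mean PT-OCT signal per depth over the A-scans of one B-scan.

    Flagged/zero-filled pixels (``valid_mask`` False) are excluded from the
    mean; depths with no valid pixel yield 0.
    """
    pt_bscan = np.asarray(pt_bscan, dtype=float)
    if pt_bscan.ndim != 2 or pt_bscan.size == 0:
        raise ParameterError("axial_profile expects a non-empty 2-D B-scan")
    if valid_mask is None:
        return pt_bscan.mean(axis=1)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    if valid_mask.shape != pt_bscan.shape:
        raise DimensionError("valid mask must be congruent with the B-scan")
    counts = valid_mask.sum(axis=1)
    sums = np.where(valid_mask, pt_bscan, 0.0).sum(axis=1)
    return np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)


def find_peak_fwhm(
    profile: np.ndarray, depth_grid_um: np.ndarray | None = None
) -> LayerMetrics:
    """Global peak of a profile and its half-maximum band.

    The band is the contiguous interval around the (center-of-plateau)
    global maximum where the profile stays at or above half the peak; edges
    are refined by linear sub-pixel interpolation of the half-max crossing.
    A side with no crossing truncates at the profile edge
    (``band_truncated``).
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 3:
        raise ParameterError("profile too short")
    if depth_grid_um is None:
        depth_grid_um = np.arange(profile.size, dtype=float)
    peak_val = profile.max()
    if peak_val <= 0:
        raise ParameterError("profile has no positive maximum")
    at_max = np.nonzero(profile == peak_val)[0]
    # plateau at the maximum: take its center
    ipk = int(at_max[(at_max.size - 1) // 2]) if at_max.size > 1 else int(at_max[0])
    half = peak_val / 2.0

    truncated = False
    i = ipk
    while i > 0 and profile[i - 1] >= half:
        i -= 1
    if i == 0 and profile[0] >= half:
        lo = depth_grid_um[0]
        truncated = True
    else:
        lo = np.interp(half, [profile[i - 1], profile[i]], [depth_grid_um[i - 1], depth_grid_um[i]])
    j = ipk
    n = profile.size
    while j < n - 1 and profile[j + 1] >= half:
        j += 1
    if j == n - 1 and profile[-1] >= half:
        hi = depth_grid_um[-1]
        truncated = True
    else:
        hi = np.interp(half, [profile[j + 1], profile[j]], [depth_grid_um[j + 1], depth_grid_um[j]])

    return LayerMetrics(
        peak_depth_um=float(depth_grid_um[ipk]),
        peak_value_nm=float(peak_val),
        fwhm_um=float(hi - lo),
        band_um=(float(lo), float(hi)),
        band_truncated=truncated,
    )


def background_stats(
    profile: np.ndarray,
    band_um: tuple,
    depth_grid_um: np.ndarray | None = None,
    margin_px: int = 1,
) -> tuple[float | None, float | None]:
    """Mean background outside the (margin-dilated) band, and the
    peak-to-background ratio (max inside the band over that background).

    Returns ``(mean_background, peak_to_background)``; a zero background
    leaves the ratio undefined (``None``), never infinite.
    """
    profile = np.asarray(profile, dtype=float)
    if depth_grid_um is None:
        depth_grid_um = np.arange(profile.size, dtype=float)
    lo, hi = band_um
    if lo >= hi:
        raise ParameterError("band must satisfy lo < hi")
    dz = depth_grid_um[1] - depth_grid_um[0] if depth_grid_um.size > 1 else 1.0
    in_band = (depth_grid_um >= lo) & (depth_grid_um <= hi)
    dilated = (depth_grid_um >= lo - margin_px * dz) & (depth_grid_um <= hi + margin_px * dz)
    if not np.any(~dilated):
        raise ParameterError("no background pixels outside the dilated band")
    if not np.any(in_band):
        raise ParameterError("band contains no profile samples")
    mean_bg = float(profile[~dilated].mean())
    peak = float(profile[in_band].max())
    if mean_bg <= 0:
        return mean_bg, None
    return mean_bg, peak / mean_bg


# ---------------------------------------------------------------------------
def lesion_mean(
    pt_volume: ImageVolume,
    roi: ROIMask,
    config: AnalysisConfig | None = None,
    eye_id: str = "",
    group: str = "",
) -> LesionSummary:
    """Mean PT-OCT signal per voxel inside a lesion ROI.

    ``included`` applies the area filter: the total mask pixel count summed
    across B-scans must exceed ``config.area_threshold_px``.
    """
    if config is None:
        config = AnalysisConfig()
    roi.require_congruent(pt_volume)
    n_vox = roi.n_voxels
    if n_vox == 0:
        raise PTOCTError("empty ROI mask")
    mean_sig = float(pt_volume.values[roi.mask].mean())
    area = int(roi.area_per_bscan().sum())
    return LesionSummary(
        eye_id=eye_id,
        group=group,
        mean_signal_nm=mean_sig,
        roi_voxels=n_vox,
        roi_area_px=area,
        included=area > config.area_threshold_px,
    )


def enface_projection(
    oct_volume: ImageVolume,
    pt_volume: ImageVolume,
    pt_display_range: tuple | None = None,
) -> dict:
    """Depth-mean en-face projections plus an RGB composite.

    Returns ``{'oct': 2-D, 'ptoct': 2-D, 'composite': (lat, bscan, 3),
    'pt_display_range': (lo, hi)}`` with the OCT projection in gray and the
    PT-OCT projection in the green channel, scaled to the display range
    (default [0, 99th percentile]).
    """
    oct_volume.require_congruent(pt_volume)
    oct_proj = oct_volume.values.mean(axis=0)
    pt_proj = pt_volume.values.mean(axis=0)
    if pt_display_range is None:
        hi = float(np.percentile(pt_proj, 99))
        pt_display_range = (0.0, hi if hi > 0 else 1.0)
    lo, hi = pt_display_range
    o_lo, o_hi = float(oct_proj.min()), float(oct_proj.max())
    gray = (oct_proj - o_lo) / (o_hi - o_lo) if o_hi > o_lo else np.zeros_like(oct_proj)
    green = np.clip((pt_proj - lo) / (hi - lo), 0.0, 1.0) if hi > lo else np.zeros_like(pt_proj)
    composite = np.stack([gray, np.maximum(gray, green), gray], axis=-1)
    return {
        "oct": oct_proj,
        "ptoct": pt_proj,
        "composite": composite,
        "pt_display_range": (float(lo), float(hi)),
    }
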