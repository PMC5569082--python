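"""Breathing-artifact correction.

Each OCT A-scan is registered axially (1-D, depth only) against the same
column of a motion-free reference volume using upsampled phase
cross-correlation; the identical vertical offset is applied to the
corresponding PT-OCT A-scan. Columns whose normalized correlation falls
below a threshold are flagged corrupted and rebuilt by 1-D linear
interpolation between their nearest valid lateral neighbours. Shifts are
zero-filled (never circular) so tissue is not wrapped across the image;
vacated pixels are recorded in a validity mask and excluded from statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import shift as _ndshift
from skimage.registration import phase_cross_correlation

from .containers import ImageVolume
from .errors import DimensionError, PTOCTError

__all__ = [
    "MotionTrace",
    "estimate_shift",
    "correct_bscan",
    "correct_volume",
    "interpolate_missing",
]


@dataclass
class MotionTrace:
    """Per-A-scan axial offsets and corruption flags for one B-scan."""

    offsets_px: np.ndarray
    corrupted: np.ndarray
    correlation: np.ndarray
    reference_id: str = ""
    valid_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.offsets_px = np.asarray(self.offsets_px, dtype=float)
        self.corrupted = np.asarray(self.corrupted, dtype=bool)
        self.correlation = np.asarray(self.correlation, dtype=float)


# ---------------------------------------------------------------------------
def estimate_shift(
    column: np.ndarray, reference: np.ndarray, upsample_factor: int = 1
) -> tuple[float, float]:
    """Axial displacement of ``column`` relative to ``reference``.

    Returns ``(offset, correlation)``: a positive offset means the column's
    content sits ``offset`` pixels deeper than the reference; correcting it
    requires shifting by ``-offset``. The offset is refined to
    ``1/upsample_factor`` pixel; correlation is the normalized
    cross-correlation of the re-aligned column with the reference, in
    [0, 1]. An all-zero column has no defined offset: returns
    ``(nan, 0.0)``.
    """
    col = np.asarray(column, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if col.shape != ref.shape:
        raise DimensionError("column and reference must have equal length")
    if not np.any(col) or not np.any(ref):
        return float("nan"), 0.0
    shift, _, _ = phase_cross_correlation(
        ref, col, upsample_factor=upsample_factor, normalization=None
    )
    offset = -float(shift[0])

    aligned = _shift_zero_fill(col, -round(offset))
    overlap = (aligned != 0) & (ref != 0)
    if overlap.sum() < 3:
        return offset, 0.0
    a, b = aligned[overlap], ref[overlap]
    denom = np.std(a) * np.std(b)
    if denom == 0:
        corr = 1.0 if np.allclose(a, b) else 0.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    return offset, float(np.clip(corr, 0.0, 1.0))


def _shift_zero_fill(col: np.ndarray, s: int) -> np.ndarray:
    """Integer axial shift with zero fill (content moves deeper for s > 0)."""
    out = np.zeros_like(col)
    if s == 0:
        out[:] = col
    elif s > 0:
        out[s:] = col[: col.size - s]
    else:
        out[:s] = col[-s:]
    return out


def _shift_column(col: np.ndarray, s: float, subpixel: bool) -> tuple[np.ndarray, np.ndarray]:
    """Shift a column, returning the shifted values and a validity mask."""
    if not subpixel:
        si = int(round(s))
        out = _shift_zero_fill(col, si)
        valid = _shift_zero_fill(np.ones_like(col), si) > 0
        return out, valid
    out = _ndshift(col, s, order=1, mode="constant", cval=0.0)
    valid = _ndshift(np.ones_like(col), s, order=1, mode="constant", cval=0.0) > 0.5
    return out, valid


# ---------------------------------------------------------------------------
def correct_bscan(
    oct_bscan: np.ndarray,
    pt_bscan: np.ndarray,
    reference_bscan: np.ndarray,
    correlation_threshold: float = 0.5,
    upsample_factor: int = 1,
    subpixel: bool = False,
    reference_id: str = "",
) -> tuple[np.ndarray, np.ndarray, MotionTrace]:
    """Register each OCT A-scan to the reference and co-shift the PT-OCT.

    Offsets are estimated on the OCT columns only (structure is reliable
    there) and applied identically to both images. Columns with correlation
    below ``correlation_threshold`` (or with no defined offset) are flagged
    corrupted, left unshifted, and excluded via the trace's validity mask —
    :func:`interpolate_missing` rebuilds them afterwards.
    """
    oct_bscan = np.asarray(oct_bscan, dtype=float)
    pt_bscan = np.asarray(pt_bscan, dtype=float)
    ref = np.asarray(reference_bscan, dtype=float)
    if oct_bscan.shape != pt_bscan.shape:
        raise DimensionError("OCT and PT-OCT B-scans must be congruent")
    if oct_bscan.shape != ref.shape:
        raise DimensionError("reference B-scan size mismatch")

    n_z, n_lat = oct_bscan.shape
    offsets = np.zeros(n_lat)
    corr = np.zeros(n_lat)
    corrupted = np.zeros(n_lat, dtype=bool)
    oct_out = np.zeros_like(oct_bscan)
    pt_out = np.zeros_like(pt_bscan)
    valid = np.zeros((n_z, n_lat), dtype=bool)

    for j in range(n_lat):
        o, c = estimate_shift(oct_bscan[:, j], ref[:, j], upsample_factor)
        corr[j] = c
        if not np.isfinite(o) or c < correlation_threshold:
            corrupted[j] = True
            offsets[j] = np.nan
            oct_out[:, j] = oct_bscan[:, j]
            pt_out[:, j] = pt_bscan[:, j]
            continue
        if not subpixel:
            o = round(o)
        offsets[j] = o
        oct_out[:, j], v = _shift_column(oct_bscan[:, j], -o, subpixel)
        pt_out[:, j], _ = _shift_column(pt_bscan[:, j], -o, subpixel)
        valid[:, j] = v

    trace = MotionTrace(offsets, corrupted, corr, reference_id, valid_mask=valid)
    return oct_out, pt_out, trace


def interpolate_missing(bscan: np.ndarray, corrupted: np.ndarray) -> np.ndarray:
    """Replace corrupted A-scans by lateral 1-D linear interpolation.

    Each corrupted column is rebuilt per depth pixel from the nearest valid
    columns on either side; runs at the image edge extend the nearest valid
    neighbour. All-corrupted input is unrecoverable.
    """
    bscan = np.asarray(bscan, dtype=float)
    corrupted = np.asarray(corrupted, dtype=bool)
    if corrupted.shape != (bscan.shape[1],):
        raise DimensionError("corrupted mask must have one flag per A-scan")
    if not corrupted.any():
        return bscan.copy()
    if corrupted.all():
        raise PTOCTError("all A-scans corrupted: nothing to interpolate from")
    cols = np.arange(bscan.shape[1])
    good = cols[~corrupted]
    out = bscan.copy()
    out[:, corrupted] = np.stack(
        [np.interp(cols[corrupted], good, row[good]) for row in bscan]
    )
    return out


def correct_volume(
    oct_vol: ImageVolume,
    pt_vol: ImageVolume,
    reference_vol: ImageVolume,
    correlation_threshold: float = 0.5,
    upsample_factor: int = 1,
    subpixel: bool = False,
    interpolate: bool = True,
) -> tuple[ImageVolume, ImageVolume, list[MotionTrace]]:
    """Motion-correct every B-scan of an OCT/PT-OCT volume pair."""
    oct_vol.require_congruent(pt_vol)
    oct_vol.require_congruent(reference_vol)
    n_b = oct_vol.shape[2]
    oct_out = np.empty_like(oct_vol.values)
    pt_out = np.empty_like(pt_vol.values)
    traces = []
    for b in range(n_b):
        oc, pc, tr = correct_bscan(
            oct_vol.values[:, :, b],
            pt_vol.values[:, :, b],
            reference_vol.values[:, :, b],
            correlation_threshold,
            upsample_factor,
            subpixel,
            reference_id=f"bscan_{b}",
        )
        if interpolate and tr.corrupted.any() and not tr.corrupted.all():
            oc = interpolate_missing(oc, tr.corrupted)
            pc = interpolate_missing(pc, tr.corrupted)
        oct_out[:, :, b] = oc
        pt_out[:, :, b] = pc
        traces.append(tr)
    meta = dict(oct_vol.meta, motion_corrected=True)
    return (
        ImageVolume(oct_out, oct_vol.pixel_size_z_um, oct_vol.kind, meta),
        ImageVolume(np.maximum(pt_out, 0.0), pt_vol.pixel_size_z_um, pt_vol.kind, dict(pt_vol.meta)),
        traces,
    )
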