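"""File I/O: the raw-data HDF5 container, TIFF image export, CSV tables.

HDF5 layout::

    /raw/bscan_{i}/mscan_{j}/spectra           [pixel x time]
    /raw/bscan_{i}/mscan_{j}/wavelength_grid   [pixel]
    file attrs                                 AcquisitionConfig fields
    /truth/*                                   optional simulator ground truth
    /images/{oct,ptoct}                        optional processed volumes

All float data round-trips bit-exactly (float64 in HDF5); TIFF export is
float32 for the data channels plus an 8-bit RGB overlay whose display range
is recorded in the image description.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
import tifffile

from .config import AcquisitionConfig
from .containers import ImageVolume, ROIMask, RawSpectralMScan
from .errors import DimensionError, FormatError
from .motion import MotionTrace
from .simulate import PhantomTruth, RawVolume

__all__ = [
    "write_raw",
    "read_raw",
    "write_image_volumes",
    "read_image_volumes",
    "export_images",
    "motion_traces_to_csv",
]

_TRUTH_ARRAYS = (
    "reflector_depths_um",
    "reflector_amplitudes",
    "absorber_map",
    "motion_trace_px",
)
_TRUTH_SCALARS = (
    "kind",
    "kappa_nm_per_mw_unit",
    "thermal_time_constant_ms",
    "thermal_mode",
    "phase_model",
    "decay_length_um",
    "delta_t_scale_c",
    "phase_noise_rad",
    "spectral_noise",
    "seed",
    "pixel_size_z_um",
)
_TRUTH_TUPLES = ("depth_window_um", "rpe_band_um", "lesion_depth_band_um")
_TRUTH_OPTIONAL = ("lesion_center_lat", "lesion_radius_lat")


def write_raw(path, data: RawVolume | RawSpectralMScan) -> None:
    """Write a raw volume (or a single M-scan) to the HDF5 container."""
    if isinstance(data, RawSpectralMScan):
        vol = RawVolume(
            data.spectra[None, None], data.wavelength_grid_nm, data.config, None
        )
    else:
        vol = data
    with h5py.File(path, "w") as fh:
        for key, val in vol.config.to_dict().items():
            fh.attrs[key] = val
        raw = fh.create_group("raw")
        for b in range(vol.n_bscans):
            gb = raw.create_group(f"bscan_{b}")
            for j in range(vol.n_lateral):
                gm = gb.create_group(f"mscan_{j}")
                gm.create_dataset("spectra", data=np.asarray(vol.spectra[b, j], dtype=np.float64))
                gm.create_dataset("wavelength_grid", data=vol.wavelength_grid_nm)
        if vol.truth is not None:
            _write_truth(fh.create_group("truth"), vol.truth)


def _write_truth(g: h5py.Group, truth: PhantomTruth) -> None:
    for name in _TRUTH_ARRAYS:
        arr = getattr(truth, name)
        if arr is not None:
            g.create_dataset(name, data=np.asarray(arr, dtype=np.float64))
    if truth.dropout_columns:
        g.create_dataset("dropout_columns", data=np.asarray(truth.dropout_columns, dtype=np.int64))
    for name in _TRUTH_SCALARS:
        g.attrs[name] = getattr(truth, name)
    for name in _TRUTH_TUPLES + _TRUTH_OPTIONAL:
        val = getattr(truth, name)
        if val is not None:
            g.attrs[name] = val


def _read_truth(g: h5py.Group) -> PhantomTruth:
    kwargs: dict = {}
    for name in _TRUTH_ARRAYS:
        if name in g:
            kwargs[name] = g[name][()]
    if "dropout_columns" in g:
        kwargs["dropout_columns"] = [tuple(int(v) for v in row) for row in g["dropout_columns"][()]]
    for name in _TRUTH_SCALARS:
        val = g.attrs[name]
        kwargs[name] = val.item() if hasattr(val, "item") else val
    for name in _TRUTH_TUPLES:
        if name in g.attrs:
            kwargs[name] = tuple(float(v) for v in g.attrs[name])
    for name in _TRUTH_OPTIONAL:
        if name in g.attrs:
            val = g.attrs[name]
            kwargs[name] = val.item() if hasattr(val, "item") else val
    if "lesion_center_lat" in kwargs:
        kwargs["lesion_center_lat"] = int(kwargs["lesion_center_lat"])
    kwargs["seed"] = int(kwargs["seed"])
    return PhantomTruth(**kwargs)


def read_raw(path) -> RawVolume:
    """Read the HDF5 container back into a :class:`RawVolume`.

    Raises :class:`FormatError` naming the first absent dataset; config
    attributes are re-validated on load.
    """
    with h5py.File(path, "r") as fh:
        cfg_fields = {f.name for f in dataclasses.fields(AcquisitionConfig)}
        attrs = {k: (v.item() if hasattr(v, "item") else v) for k, v in fh.attrs.items() if k in cfg_fields}
        for name in ("n_repeats", "n_spectrometer_pixels", "n_ascans_per_bscan"):
            if name in attrs:
                attrs[name] = int(attrs[name])
        config = AcquisitionConfig.from_dict(attrs)
        if "raw" not in fh:
            raise FormatError(f"{path}: missing group /raw")
        raw = fh["raw"]
        bscans = sorted(raw.keys(), key=lambda s: int(s.split("_")[1]))
        blocks, lam = [], None
        for bname in bscans:
            gb = raw[bname]
            mscans = sorted(gb.keys(), key=lambda s: int(s.split("_")[1]))
            row = []
            for mname in mscans:
                gm = gb[mname]
                for req in ("spectra", "wavelength_grid"):
                    if req not in gm:
                        raise FormatError(f"{path}: missing dataset /raw/{bname}/{mname}/{req}")
                row.append(gm["spectra"][()])
                lam = gm["wavelength_grid"][()]
            blocks.append(np.stack(row))
        spectra = np.stack(blocks)
        truth = _read_truth(fh["truth"]) if "truth" in fh else None
    return RawVolume(spectra, lam, config, truth)


# ---------------------------------------------------------------------------
def write_image_volumes(path, oct_vol: ImageVolume, pt_vol: ImageVolume) -> None:
    oct_vol.require_congruent(pt_vol)
    with h5py.File(path, "w") as fh:
        g = fh.create_group("images")
        for name, vol in (("oct", oct_vol), ("ptoct", pt_vol)):
            d = g.create_dataset(name, data=vol.values)
            d.attrs["pixel_size_z_um"] = vol.pixel_size_z_um
            d.attrs["kind"] = vol.kind
            d.attrs["meta"] = json.dumps(vol.meta, default=str)


def read_image_volumes(path) -> tuple[ImageVolume, ImageVolume]:
    with h5py.File(path, "r") as fh:
        if "images" not in fh:
            raise FormatError(f"{path}: missing group /images")
        out = []
        for name in ("oct", "ptoct"):
            if name not in fh["images"]:
                raise FormatError(f"{path}: missing dataset /images/{name}")
            d = fh["images"][name]
            out.append(
                ImageVolume(
                    d[()],
                    float(d.attrs["pixel_size_z_um"]),
                    str(d.attrs["kind"]),
                    json.loads(d.attrs.get("meta", "{}")),
                )
            )
    return out[0], out[1]


# ---------------------------------------------------------------------------
def export_images(
    oct_vol: ImageVolume,
    pt_vol: ImageVolume,
    path_prefix,
    roi: ROIMask | None = None,
    pt_display_range: tuple | None = None,
) -> dict:
    """Export TIFF stacks: grayscale OCT, PT-OCT, and an RGB overlay.

    The overlay renders PT-OCT in the green channel scaled to
    ``pt_display_range`` (default [0, 99th percentile of the PT volume]);
    the range is recorded in the overlay's image description for
    reproducibility. Returns the written paths and the range used.
    """
    oct_vol.require_congruent(pt_vol)
    if roi is not None:
        roi.require_congruent(pt_vol)
    if pt_display_range is None:
        hi = float(np.percentile(pt_vol.values, 99))
        pt_display_range = (0.0, hi if hi > 0 else 1.0)
    lo, hi = map(float, pt_display_range)
    if not hi > lo:
        raise DimensionError("display range must satisfy lo < hi")

    prefix = str(path_prefix)
    paths = {
        "oct": f"{prefix}_oct.tif",
        "ptoct": f"{prefix}_ptoct.tif",
        "overlay": f"{prefix}_overlay.tif",
    }
    # stacks: pages = B-scans
    oct_stack = np.moveaxis(oct_vol.values, 2, 0).astype(np.float32)
    pt_stack = np.moveaxis(pt_vol.values, 2, 0).astype(np.float32)
    tifffile.imwrite(paths["oct"], oct_stack, photometric="minisblack")
    tifffile.imwrite(paths["ptoct"], pt_stack, photometric="minisblack")

    o = oct_stack
    o_lo, o_hi = float(o.min()), float(o.max())
    gray = (o - o_lo) / (o_hi - o_lo) if o_hi > o_lo else np.zeros_like(o)
    green = np.clip((pt_stack - lo) / (hi - lo), 0.0, 1.0)
    rgb = np.stack([gray, np.maximum(gray, green), gray], axis=-1)
    if roi is not None:
        rgb[np.moveaxis(roi.mask, 2, 0), 2] = 1.0  # ROI outline channel
    meta = {"pt_display_range_nm": [lo, hi], "kind": "oct+ptoct overlay"}
    tifffile.imwrite(
        paths["overlay"], (rgb * 255).astype(np.uint8),
        photometric="rgb", description=json.dumps(meta),
    )
    return {"paths": paths, "pt_display_range": (lo, hi)}


def motion_traces_to_csv(path, traces: list[MotionTrace]) -> None:
    rows = []
    for b, tr in enumerate(traces):
        for j, (o, c, r) in enumerate(zip(tr.offsets_px, tr.corrupted, tr.correlation)):
            rows.append(
                {
                    "bscan": b,
                    "ascan": j,
                    "offset_px": o,
                    "corrupted": bool(c),
                    "correlation": r,
                    "reference_id": tr.reference_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
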