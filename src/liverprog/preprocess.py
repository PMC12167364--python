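"""Standardized CT preprocessing: registered phases -> fixed-size 4D input.

The chain (in the order it runs) is

    resample to isotropic 1 mm  ->  HU clip to [-200, 250]  ->
    rescale to [0, 1]  ->  slice-wise CLAHE  ->  crop to the liver
    bounding box  ->  resize each phase to an E^3 cube and stack (A, V, D)

Registration itself is an interface, not an implementation: synthetic (and
any pre-registered) data pass through a no-op registrar, and an external
registrar can be plugged in via :func:`preprocess_scan`'s ``registrar``
hook.  Every numeric choice (window, CLAHE parameters, padding, edge) is
recorded in the :class:`ModelInput` provenance so the tensor can be
reproduced from the original scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import exposure

from .datatypes import TriphasicScan, PHASES

__all__ = [
    "ModelInput",
    "HU_WINDOW",
    "resample_isotropic",
    "clip_hu",
    "clahe_enhance",
    "crop_to_liver",
    "standardize_input",
    "preprocess_scan",
]

#: Default HU window; values outside carry no liver-relevant information.
HU_WINDOW = (-200.0, 250.0)
DEFAULT_CLAHE_CLIP = 0.01
DEFAULT_CLAHE_TILES = 8


@dataclass
class ModelInput:
    """Fixed-size network input for one patient.

    ``array`` has shape (3, E, E, E) with phases stacked in (A, V, D) order
    and values in [0, 1].  ``tumor_mask`` / ``liver_mask`` are the masks
    resized to the same cube (soft, in [0, 1]) for mask-gated models and
    activation-map comparisons.  ``provenance`` records the crop box in the
    resampled voxel grid plus every normalization parameter.
    """

    patient_id: str
    array: np.ndarray
    tumor_mask: np.ndarray
    liver_mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def edge(self) -> int:
        return int(self.array.shape[-1])

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            array=self.array,
            tumor_mask=self.tumor_mask,
            liver_mask=self.liver_mask,
        )
        path.with_suffix(".json").write_text(
            json.dumps({"patient_id": self.patient_id, "provenance": self.provenance},
                       indent=2, default=str)
        )

    @classmethod
    def load(cls, path) -> "ModelInput":
        import json
        from pathlib import Path

        path = Path(path)
        data = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            patient_id=meta["patient_id"],
            array=data["array"],
            tumor_mask=data["tumor_mask"],
            liver_mask=data["liver_mask"],
            provenance=meta["provenance"],
        )


# ---------------------------------------------------------------------------
# resampling


def _resample_volume(vol: np.ndarray, spacing: tuple, target: tuple,
                     interpolator) -> np.ndarray:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol, dtype=np.float32))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))  # sitk is (x, y, z)
    out_size = [
        int(round(n * s / t))
        for n, s, t in zip(vol.shape[::-1], spacing[::-1], target[::-1])
    ]
    res = sitk.Resample(
        img,
        out_size,
        sitk.Transform(),
        interpolator,
        img.GetOrigin(),
        tuple(float(t) for t in target[::-1]),
        img.GetDirection(),
        0.0,
        sitk.sitkFloat32,
    )
    return sitk.GetArrayFromImage(res)


def resample_isotropic(scan: TriphasicScan, target_spacing=(1.0, 1.0, 1.0)) -> TriphasicScan:
    """Resample phases (cubic B-spline) and masks (nearest neighbor).

    Output voxel size is ``target_spacing`` mm; masks stay strictly binary.
    """
    if np.isscalar(target_spacing):
        target_spacing = (float(target_spacing),) * 3
    if any(t <= 0 for t in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if tuple(scan.spacing) == tuple(target_spacing):
        return scan
    phases = {
        ph: _resample_volume(vol, scan.spacing, target_spacing, sitk.sitkBSpline)
        for ph, vol in scan.phases.items()
    }
    liver = _resample_volume(
        scan.liver_mask.astype(np.float32), scan.spacing, target_spacing,
        sitk.sitkNearestNeighbor,
    ).astype(np.uint8)
    tumor = _resample_volume(
        scan.tumor_mask.astype(np.float32), scan.spacing, target_spacing,
        sitk.sitkNearestNeighbor,
    ).astype(np.uint8)
    return TriphasicScan(
        patient_id=scan.patient_id,
        phases=phases,
        spacing=tuple(float(t) for t in target_spacing),
        liver_mask=liver,
        tumor_mask=tumor,
    )


# ---------------------------------------------------------------------------
# intensity normalization


def clip_hu(volume: np.ndarray, window=HU_WINDOW) -> np.ndarray:
    """Clamp HU values to ``window`` (order-preserving inside the window)."""
    lo, hi = float(window[0]), float(window[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ValueError(f"invalid HU window {window}: need finite lo < hi")
    return np.clip(volume, lo, hi)


def rescale_unit(volume: np.ndarray, window=HU_WINDOW) -> np.ndarray:
    """Map the HU window linearly onto [0, 1]."""
    lo, hi = float(window[0]), float(window[1])
    return (np.clip(volume, lo, hi) - lo) / (hi - lo)


def clahe_enhance(volume: np.ndarray, clip_limit: float = DEFAULT_CLAHE_CLIP,
                  tile_grid: int = DEFAULT_CLAHE_TILES) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, slice by slice.

    CLAHE is 2D-native; the common CT adaptation applies it per axial slice
    (axis 0).  Input must already be rescaled to [0, 1]; constant input is
    returned unchanged.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(vol)):
        raise ValueError("CLAHE input contains non-finite voxels")
    if vol.min() < -1e-9 or vol.max() > 1 + 1e-9:
        raise ValueError("CLAHE input must be rescaled to [0, 1] first")
    out = np.empty_like(vol)
    for z in range(vol.shape[0]):
        sl = vol[z]
        if np.ptp(sl) < 1e-12:
            out[z] = sl  # degenerate slice: histogram is a single bin
            continue
        ny, nx = sl.shape
        kernel = (max(ny // tile_grid, 1), max(nx // tile_grid, 1))
        out[z] = exposure.equalize_adapthist(sl, kernel_size=kernel,
                                             clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# geometry


def liver_bounding_box(mask: np.ndarray, pad: int = 0) -> tuple:
    """Tight axis-aligned bounding box of a nonempty mask, expanded by pad."""
    if not np.any(mask):
        raise ValueError("no liver segmentation: mask is empty")
    slices = []
    for ax in range(mask.ndim):
        proj = np.any(mask, axis=tuple(i for i in range(mask.ndim) if i != ax))
        idx = np.where(proj)[0]
        lo = max(int(idx[0]) - pad, 0)
        hi = min(int(idx[-1]) + 1 + pad, mask.shape[ax])
        slices.append((lo, hi))
    return tuple(slices)


def crop_to_liver(scan: TriphasicScan, pad: int = 0) -> TriphasicScan:
    """Crop all phases and masks to the liver mask's 3D bounding box."""
    box = liver_bounding_box(scan.liver_mask, pad=pad)
    sl = tuple(slice(lo, hi) for lo, hi in box)
    cropped = TriphasicScan(
        patient_id=scan.patient_id,
        phases={ph: vol[sl] for ph, vol in scan.phases.items()},
        spacing=scan.spacing,
        liver_mask=scan.liver_mask[sl],
        tumor_mask=scan.tumor_mask[sl],
    )
    cropped.validate()
    return cropped, box


def _resize(vol: np.ndarray, edge: int, order: int) -> np.ndarray:
    factors = [edge / s for s in vol.shape]
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return vol.astype(np.float32)
    out = ndimage.zoom(vol.astype(np.float64), factors, order=order,
                       mode="nearest", grid_mode=True)
    # grid_mode zoom can land one voxel off for awkward ratios; enforce shape
    out = out[tuple(slice(0, edge) for _ in range(3))]
    if out.shape != (edge, edge, edge):  # pragma: no cover - defensive
        pad = [(0, edge - s) for s in out.shape]
        out = np.pad(out, pad, mode="edge")
    return out.astype(np.float32)


def standardize_input(scan: TriphasicScan, edge: int = 128,
                      window=HU_WINDOW, crop_box=None,
                      already_unit: bool = False) -> ModelInput:
    """Resize each phase to an ``edge``^3 cube and stack in (A, V, D) order.

    Phases are resized with cubic interpolation (anisotropic stretch — the
    network input is a fixed cube), masks with linear interpolation so the
    gating channel stays soft in [0, 1].  If ``already_unit`` the phases are
    assumed rescaled to [0, 1]; otherwise the HU window is applied here.
    """
    if edge < 8:
        raise ValueError(f"edge must be >= 8, got {edge}")
    missing = [ph for ph in PHASES if ph not in scan.phases]
    if missing:
        raise ValueError(f"missing phase {missing[0]!r} in scan {scan.patient_id}")
    stacked = []
    for ph in PHASES:
        vol = scan.phases[ph]
        unit = np.asarray(vol, dtype=np.float64) if already_unit else rescale_unit(vol, window)
        stacked.append(np.clip(_resize(unit, edge, order=3), 0.0, 1.0))
    tumor = np.clip(_resize(scan.tumor_mask.astype(np.float64), edge, order=1), 0, 1)
    liver = np.clip(_resize(scan.liver_mask.astype(np.float64), edge, order=1), 0, 1)
    provenance = {
        "patient_id": scan.patient_id,
        "hu_window": list(window),
        "edge": int(edge),
        "phase_order": list(PHASES),
        "source_shape": list(scan.shape),
        "spacing_mm": list(scan.spacing),
        "crop_box": [list(b) for b in crop_box] if crop_box is not None else None,
    }
    return ModelInput(
        patient_id=scan.patient_id,
        array=np.stack(stacked).astype(np.float32),
        tumor_mask=tumor.astype(np.float32),
        liver_mask=liver.astype(np.float32),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# full chain


def identity_registrar(scan: TriphasicScan) -> TriphasicScan:
    """No-op registrar for data that is already co-registered."""
    return scan


def preprocess_scan(scan: TriphasicScan, edge: int = 128,
                    target_spacing=(1.0, 1.0, 1.0), window=HU_WINDOW,
                    clahe_clip: float = DEFAULT_CLAHE_CLIP,
                    clahe_tiles: int = DEFAULT_CLAHE_TILES,
                    pad: int = 0, apply_clahe: bool = True,
                    registrar: Callable = identity_registrar) -> ModelInput:
    """Run the full deterministic preprocessing chain on one scan."""
    scan = registrar(scan)
    scan = resample_isotropic(scan, target_spacing)
    unit_phases = {}
    for ph, vol in scan.phases.items():
        unit = rescale_unit(clip_hu(vol, window), window)
        if apply_clahe:
            unit = clahe_enhance(unit, clip_limit=clahe_clip, tile_grid=clahe_tiles)
        unit_phases[ph] = unit
    normalized = TriphasicScan(
        patient_id=scan.patient_id,
        phases=unit_phases,
        spacing=scan.spacing,
        liver_mask=scan.liver_mask,
        tumor_mask=scan.tumor_mask,
    )
    cropped, box = crop_to_liver(normalized, pad=pad)
    mi = standardize_input(cropped, edge=edge, window=window, crop_box=box,
                           already_unit=True)
    mi.provenance.update(
        clahe={"applied": bool(apply_clahe), "clip_limit": clahe_clip,
               "tile_grid": clahe_tiles},
        pad=int(pad),
        order=["resample", "clip_hu", "rescale", "clahe", "crop", "resize"],
    )
    return mi
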