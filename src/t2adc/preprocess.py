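"""Volume preprocessing: NIfTI ingestion, resampling to a target spacing,
z-score normalization, prostate-mask-guided cropping, axial slice
extraction for the networks, and the inverse placement of generated slices
back into volume geometry.

Conventions: the slice axis is the third array axis; voxel indexing is
0-based; crop boxes are half-open ``[lo, hi)``; slice images are rescaled
to [-1, 1] with the per-volume min/max recorded for exact inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume", "SliceSample", "load_volume", "save_volume",
    "resample", "zscore", "crop_to_mask", "extract_slices",
    "reinsert_slices", "NETWORK_STRIDE",
]

#: total downsampling stride of the generator; slice sizes are padded to a
#: multiple of this.
NETWORK_STRIDE = 4


@dataclass
class Volume:
    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = None
    role: str = "t2"  # one of {"t2", "adc", "mask"}

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive: {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data contains non-finite values")
        if self.role == "mask" and not np.isin(self.data, (0, 1)).all():
            raise ValueError("mask volumes must be binary (0/1)")
        if self.affine is None:
            self.affine = np.diag([*self.spacing_mm, 1.0])
        self.affine = np.asarray(self.affine, dtype=np.float64)
        norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(norms, self.spacing_mm, atol=1e-6):
            raise ValueError(
                f"affine column norms {norms} inconsistent with spacing "
                f"{self.spacing_mm}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SliceSample:
    image: np.ndarray               # 2D, in [-1, 1], stride-divisible
    domain: str                     # "X" (T2W) or "Y" (ADC)
    subject_id: str
    slice_index: int
    crop_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    pad: tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right
    vmin: float = -1.0              # original intensity range for inversion
    vmax: float = 1.0

    def __post_init__(self):
        h, w = self.image.shape
        if h % NETWORK_STRIDE or w % NETWORK_STRIDE:
            raise ValueError(
                f"slice {h}x{w} not divisible by stride {NETWORK_STRIDE}"
            )


def load_volume(path: str | Path, role: str = "t2") -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing_mm=spacing, affine=np.asarray(img.affine),
                  role=role)


def save_volume(vol: Volume, path: str | Path) -> None:
    path = Path(path)
    try:
        img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
        img.header.set_zooms(vol.spacing_mm)
        nib.save(img, str(path))
    except OSError as e:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed to write NIfTI volume to {path}: {e}") from e


def resample(vol: Volume, target_spacing: tuple[float, float, float]) -> Volume:
    """Resample to ``target_spacing``; trilinear for intensities, nearest
    neighbour for masks.  Output shape is round(shape * spacing / target)."""
    target = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target):
        raise ValueError(f"target spacing must be positive: {target}")
    in_shape = np.array(vol.shape, dtype=float)
    in_sp = np.array(vol.spacing_mm)
    out_shape = np.round(in_shape * in_sp / np.array(target)).astype(int)
    if np.any(out_shape < 1):
        raise ValueError(
            f"degenerate output shape {tuple(out_shape)} for target {target}"
        )
    # corner-aligned sampling grid in input voxel coordinates
    axes = [np.arange(n) * target[i] / in_sp[i] for i, n in enumerate(out_shape)]
    grid = np.meshgrid(*axes, indexing="ij")
    order = 0 if vol.role == "mask" else 1
    out = ndimage.map_coordinates(
        vol.data.astype(np.float64), np.stack(grid), order=order, mode="nearest"
    )
    if vol.role == "mask":
        out = np.rint(out)
    new_affine = vol.affine.copy()
    for i in range(3):
        col = vol.affine[:3, i]
        new_affine[:3, i] = col / np.linalg.norm(col) * target[i]
    return Volume(data=out, spacing_mm=target, affine=new_affine, role=vol.role)


def zscore(vol: Volume) -> Volume:
    """Normalize the whole volume to mean 0, sd 1."""
    sd = vol.data.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant volume (zero variance)")
    data = (vol.data - vol.data.mean()) / sd
    return Volume(data=data, spacing_mm=vol.spacing_mm, affine=vol.affine,
                  role=vol.role)


def crop_to_mask(vol: Volume, mask: Volume, margin_mm=(5.0, 5.0, 0.0)):
    """Crop ``vol`` to the mask bounding box dilated by ``margin_mm``.

    Returns ``(cropped_volume, crop_box)`` with the half-open box in voxel
    coordinates of the input grid, clipped to the volume bounds.
    """
    if mask.role != "mask":
        raise ValueError("second argument must have role='mask'")
    if mask.shape != vol.shape:
        raise ValueError(f"grid mismatch: {vol.shape} vs {mask.shape}")
    if not mask.data.any():
        raise ValueError("empty mask: nothing to crop to")
    if np.isscalar(margin_mm):
        margin_mm = (float(margin_mm),) * 3
    nz = np.nonzero(mask.data)
    box = []
    for ax in range(3):
        m = int(round(float(margin_mm[ax]) / vol.spacing_mm[ax]))
        lo = max(0, int(nz[ax].min()) - m)
        hi = min(vol.shape[ax], int(nz[ax].max()) + 1 + m)
        box.append((lo, hi))
    box = tuple(box)
    sl = tuple(slice(lo, hi) for lo, hi in box)
    out = Volume(data=vol.data[sl].copy(), spacing_mm=vol.spacing_mm,
                 affine=vol.affine, role=vol.role)
    return out, box


def _pad_to_stride(img: np.ndarray, fill: float):
    h, w = img.shape
    ph = (-h) % NETWORK_STRIDE
    pw = (-w) % NETWORK_STRIDE
    top, bottom = ph // 2, ph - ph // 2
    left, right = pw // 2, pw - pw // 2
    padded = np.pad(img, ((top, bottom), (left, right)), constant_values=fill)
    return padded, (top, bottom, left, right)


def extract_slices(t2: Volume, adc: Volume | None, mask: Volume,
                   subject_id: str = "subject",
                   crop_box=None) -> list[SliceSample]:
    """One sample per axial slice with nonzero mask area, per domain.

    Images are rescaled to [-1, 1] using the per-volume min/max and padded
    symmetrically to stride divisibility.  T2/ADC pairing is preserved via
    matching ``slice_index`` when ``adc`` is given.
    """
    if mask.shape != t2.shape or (adc is not None and adc.shape != t2.shape):
        raise ValueError("t2/adc/mask volumes must share the same grid")
    keep = [k for k in range(t2.shape[2]) if mask.data[:, :, k].any()]
    if not keep:
        raise ValueError("no axial slice intersects the mask")
    if crop_box is None:
        crop_box = tuple((0, n) for n in t2.shape)
    samples: list[SliceSample] = []
    for vol, domain in ((t2, "X"),) + (((adc, "Y"),) if adc is not None else ()):
        vmin, vmax = float(vol.data.min()), float(vol.data.max())
        span = vmax - vmin
        if span == 0:
            raise ValueError(f"constant {domain} volume cannot be rescaled")
        for k in keep:
            img = 2.0 * (vol.data[:, :, k] - vmin) / span - 1.0
            padded, pad = _pad_to_stride(img, fill=-1.0)
            samples.append(SliceSample(
                image=padded, domain=domain, subject_id=subject_id,
                slice_index=k, crop_box=crop_box, pad=pad,
                vmin=vmin, vmax=vmax,
            ))
    return samples


def reinsert_slices(samples: list[SliceSample], template: Volume,
                    fill: float | None = None) -> Volume:
    """Place slice images back at their recorded crop locations.

    Inverts the [-1, 1] rescaling with each sample's recorded range and
    strips the stride padding; voxels not covered by any slice are set to
    ``fill`` (default: the template minimum).
    """
    out = np.full(template.shape,
                  template.data.min() if fill is None else fill,
                  dtype=np.float64)
    for s in samples:
        (i0, i1), (j0, j1), (k0, k1) = s.crop_box
        if not (0 <= i0 <= i1 <= template.shape[0]
                and 0 <= j0 <= j1 <= template.shape[1]
                and 0 <= k0 <= k1 <= template.shape[2]):
            raise ValueError(f"crop box {s.crop_box} outside template grid "
                             f"{template.shape}")
        top, bottom, left, right = s.pad
        img = s.image[top:s.image.shape[0] - bottom,
                      left:s.image.shape[1] - right]
        if img.shape != (i1 - i0, j1 - j0):
            raise ValueError(
                f"slice {img.shape} does not fit crop box {s.crop_box}"
            )
        k = k0 + s.slice_index  # slice_index is relative to the crop box
        if not (k0 <= k < k1):
            raise ValueError(f"slice index {s.slice_index} outside template")
        restored = (img + 1.0) / 2.0 * (s.vmax - s.vmin) + s.vmin
        out[i0:i1, j0:j1, k] = restored
    return Volume(data=out, spacing_mm=template.spacing_mm,
                  affine=template.affine, role=template.role)
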