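"""Synthetic prostate phantom: paired T2W-like and ADC-like volumes with a
binary prostate mask, distinct transition/peripheral zones, optional
hypointense lesions present in both domains, and reproducible artifact
corruptions of the ADC domain.

The prostate is an axis-aligned ellipsoid; the transition zone is an inner
concentric ellipsoid.  Noise-free intensities are a pure function of the
zone/lesion label map, so every downstream stage has exact ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import Volume, save_volume

__all__ = [
    "PhantomSpec", "PhantomSubject", "ARTIFACT_KINDS",
    "generate_subject", "corrupt_adc", "generate_cohort",
    "zone_label_map", "apply_intensity_table",
]

ARTIFACT_KINDS = ("motion_ghost", "distortion_field", "aliasing", "noise")

#: default per-domain intensities: the zone mapping is monotone decreasing
#: (bright T2 tissue is dark on ADC and vice versa), while lesions carry
#: their own labels so they stay hypointense in BOTH domains.
DEFAULT_ZONE_CONTRAST = {
    "t2": {"background": 0.15, "peripheral": 0.80, "transition": 0.50,
           "lesion_offset": -0.30},
    "adc": {"background": 0.85, "peripheral": 0.20, "transition": 0.50,
            "lesion_offset": -0.15},
}

LABEL_BACKGROUND, LABEL_PERIPHERAL, LABEL_TRANSITION = 0, 1, 2
#: lesions get dedicated labels so the label map fully determines intensity
LABEL_LESION_PZ, LABEL_LESION_TZ = 3, 4


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (96, 96, 16)
    spacing_mm: tuple[float, float, float] = (0.75, 0.75, 3.0)
    prostate_axes_mm: tuple[float, float, float] = (24.0, 20.0, 14.0)
    transition_fraction: float = 0.55   # TZ semi-axes as fraction of prostate
    n_lesions: int = 2
    lesion_radius_mm: tuple[float, float] = (3.0, 6.0)
    zone_contrast: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ZONE_CONTRAST.items()}
    )
    noise_sd: float = 0.02
    artifact_menu: tuple[str, ...] = ()
    artifact_magnitude: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.transition_fraction < 1:
            raise ValueError("transition_fraction must be in (0, 1)")
        for ax in range(3):
            half_extent_mm = (self.grid_shape[ax] / 2 - 2) * self.spacing_mm[ax]
            if self.prostate_axes_mm[ax] > half_extent_mm:
                raise ValueError(
                    f"prostate_axes_mm[{ax}]={self.prostate_axes_mm[ax]} does not "
                    f"fit in the grid with a 2-voxel margin (max {half_extent_mm})"
                )
        lo, hi = self.lesion_radius_mm
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid lesion_radius_mm range {self.lesion_radius_mm}")
        if hi >= min(self.prostate_axes_mm):
            raise ValueError(
                f"lesion_radius_mm upper bound {hi} >= smallest prostate semi-axis "
                f"{min(self.prostate_axes_mm)} (lesion larger than prostate)"
            )
        for domain, table in self.zone_contrast.items():
            for key, val in table.items():
                if not np.isfinite(val):
                    raise ValueError(f"zone_contrast[{domain}][{key}] is not finite")
        unknown = set(self.artifact_menu) - set(ARTIFACT_KINDS)
        if unknown:
            raise ValueError(
                f"unknown artifact kinds {sorted(unknown)}; supported: "
                f"{list(ARTIFACT_KINDS)}"
            )


@dataclass
class PhantomSubject:
    t2_volume: Volume
    adc_volume: Volume
    mask_volume: Volume
    lesion_table: list[tuple[tuple[int, int, int], float, str]]
    label_map: np.ndarray


def _ellipsoid(shape, spacing, semi_axes_mm) -> np.ndarray:
    coords = [
        (np.arange(n) - (n - 1) / 2.0) * spacing[i]
        for i, n in enumerate(shape)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    a, b, c = semi_axes_mm
    return (xx / a) ** 2 + (yy / b) ** 2 + (zz / c) ** 2 <= 1.0


def zone_label_map(spec: PhantomSpec, rng: np.random.Generator):
    """Build the zone/lesion label map and the lesion table."""
    prostate = _ellipsoid(spec.grid_shape, spec.spacing_mm, spec.prostate_axes_mm)
    tz_axes = tuple(a * spec.transition_fraction for a in spec.prostate_axes_mm)
    transition = _ellipsoid(spec.grid_shape, spec.spacing_mm, tz_axes)
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    labels[prostate] = LABEL_PERIPHERAL
    labels[transition & prostate] = LABEL_TRANSITION

    centers_mm = [
        (np.arange(n) - (n - 1) / 2.0) * spec.spacing_mm[i]
        for i, n in enumerate(spec.grid_shape)
    ]
    lesion_table = []
    candidates = np.argwhere(prostate)
    for _ in range(spec.n_lesions):
        center = tuple(int(v) for v in candidates[rng.integers(len(candidates))])
        radius = float(rng.uniform(*spec.lesion_radius_mm))
        zone = "transition" if labels[center] == LABEL_TRANSITION else "peripheral"
        cx = [centers_mm[i][center[i]] for i in range(3)]
        xx, yy, zz = np.meshgrid(*centers_mm, indexing="ij")
        sphere = ((xx - cx[0]) ** 2 + (yy - cx[1]) ** 2 + (zz - cx[2]) ** 2
                  <= radius**2)
        region = sphere & prostate
        labels[region & (labels == LABEL_PERIPHERAL)] = LABEL_LESION_PZ
        labels[region & (labels == LABEL_TRANSITION)] = LABEL_LESION_TZ
        lesion_table.append((center, radius, zone))
    return labels, lesion_table, prostate


def apply_intensity_table(labels: np.ndarray, table: dict) -> np.ndarray:
    """Map the label volume to intensities; lesions are their surrounding
    zone intensity plus the (negative) lesion offset."""
    lut = np.array([
        table["background"],
        table["peripheral"],
        table["transition"],
        table["peripheral"] + table["lesion_offset"],
        table["transition"] + table["lesion_offset"],
    ])
    return lut[labels]


def generate_subject(spec: PhantomSpec) -> PhantomSubject:
    """Deterministically generate one phantom subject from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    labels, lesion_table, prostate = zone_label_map(spec, rng)

    t2 = apply_intensity_table(labels, spec.zone_contrast["t2"])
    adc = apply_intensity_table(labels, spec.zone_contrast["adc"])
    if spec.noise_sd > 0:
        t2 = t2 + rng.normal(0.0, spec.noise_sd, size=t2.shape)
        adc = adc + rng.normal(0.0, spec.noise_sd, size=adc.shape)

    affine = np.diag([*spec.spacing_mm, 1.0])
    adc_vol = Volume(adc, spec.spacing_mm, affine.copy(), role="adc")
    for i, kind in enumerate(spec.artifact_menu):
        adc_vol = corrupt_adc(adc_vol, kind, spec.artifact_magnitude,
                              seed=spec.seed * 131 + i)

    return PhantomSubject(
        t2_volume=Volume(t2, spec.spacing_mm, affine.copy(), role="t2"),
        adc_volume=adc_vol,
        mask_volume=Volume(prostate.astype(np.uint8), spec.spacing_mm,
                           affine.copy(), role="mask"),
        lesion_table=lesion_table,
        label_map=labels,
    )


def corrupt_adc(vol: Volume, kind: str, magnitude: float,
                seed: int = 0) -> Volume:
    """Apply a reproducible artifact to a volume; magnitude 0 is identity."""
    if kind not in ARTIFACT_KINDS:
        raise ValueError(
            f"unknown artifact kind {kind!r}; supported: {list(ARTIFACT_KINDS)}"
        )
    data = vol.data.astype(np.float64)
    if magnitude == 0:
        out = data.copy()
    elif kind == "noise":
        rng = np.random.default_rng(seed)
        out = data + rng.normal(0.0, magnitude, size=data.shape)
    elif kind == "motion_ghost":
        # attenuated, shifted copy added along the phase-encode axis
        shift = max(1, vol.shape[0] // 4)
        out = data + magnitude * np.roll(data, shift, axis=0)
    elif kind == "aliasing":
        # wrap-around of a half-FOV shifted band
        out = (1.0 - magnitude) * data + magnitude * np.roll(
            data, vol.shape[0] // 2, axis=0
        )
    else:  # distortion_field
        rng = np.random.default_rng(seed)
        coarse = rng.normal(size=vol.shape)
        smooth = ndimage.gaussian_filter(coarse, sigma=(6, 6, 1))
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth = smooth / peak
        # displacement (in voxels) concentrated at the posterior boundary
        posterior = (np.arange(vol.shape[1]) / max(1, vol.shape[1] - 1)) ** 2
        disp = magnitude * smooth * posterior[None, :, None]
        ii, jj, kk = np.meshgrid(*[np.arange(n) for n in vol.shape],
                                 indexing="ij")
        coords = np.stack([ii + disp, jj.astype(float), kk.astype(float)])
        order = 0 if vol.role == "mask" else 1
        out = ndimage.map_coordinates(data, coords, order=order, mode="nearest")
        if vol.role == "mask":
            out = np.rint(out)
    return Volume(out, vol.spacing_mm, vol.affine.copy(), role=vol.role)


def generate_cohort(n_subjects: int, spec: PhantomSpec, seed: int,
                    out_dir: str | Path) -> pd.DataFrame:
    """Write NIfTI triples + manifest CSV for a cohort of phantom subjects.

    Per-subject seeds are derived deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_subjects):
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0])
        sub_spec = dataclasses.replace(spec, seed=sub_seed)
        subject = generate_subject(sub_spec)
        sid = f"sub-{i:03d}"
        paths = {}
        for role, vol in (("t2", subject.t2_volume), ("adc", subject.adc_volume),
                          ("mask", subject.mask_volume)):
            p = out_dir / f"{sid}_{role}.nii.gz"
            save_volume(vol, p)
            paths[role] = str(p)
        rows.append({"subject_id": sid, "t2_path": paths["t2"],
                     "adc_path": paths["adc"], "mask_path": paths["mask"]})
    manifest = pd.DataFrame(rows, columns=["subject_id", "t2_path", "adc_path",
                                           "mask_path"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
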