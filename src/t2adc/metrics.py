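"""Image-quality metrics: PSNR, SSIM with its luminance/contrast/structure
decomposition, Fréchet distance between Gaussian feature moments, Dice
overlap, and a dataset-level evaluation harness.

Metrics operate on [0, 1]-rescaled images (the inverse of the [-1, 1]
training range); the PSNR peak defaults to the per-image maximum of the
reference image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ImagePairMetrics", "GaussianMoments", "MetricReport",
    "psnr", "ssim", "fid", "embed_features", "dice", "evaluate",
]

PSNR_INF = np.inf


@dataclass
class ImagePairMetrics:
    psnr: float
    ssim: float
    mse: float


@dataclass
class GaussianMoments:
    mean: np.ndarray
    cov: np.ndarray
    n_samples: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64).ravel()
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=np.float64))
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError(
                f"cov shape {self.cov.shape} inconsistent with mean "
                f"dim {self.mean.size}"
            )
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")


@dataclass
class MetricReport:
    per_slice: pd.DataFrame        # columns subject, slice, psnr, ssim
    summary: dict[str, tuple[float, float]]   # metric -> (mean, sd)
    fid: float
    dice: float | None = None

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            self.per_slice.to_csv(fh, index=False)
            fh.write("metric,mean,sd\n")
            for name, (mean, sd) in self.summary.items():
                fh.write(f"{name},{mean},{sd}\n")
            fh.write(f"fid,{self.fid}\n")
            if self.dice is not None:
                fh.write(f"dice,{self.dice}\n")

    def __str__(self) -> str:
        lines = [f"{len(self.per_slice)} slice pairs"]
        for name, (mean, sd) in self.summary.items():
            lines.append(f"  {name}: {mean:.4f} +/- {sd:.4f}")
        lines.append(f"  fid: {self.fid:.4f}")
        if self.dice is not None:
            lines.append(f"  dice: {self.dice:.4f}")
        return "\n".join(lines)


def psnr(reference: np.ndarray, generated: np.ndarray,
         max_i: float | None = None) -> float:
    """10*log10(MAX^2 / MSE) in dB; +inf when MSE is zero.

    ``max_i=None`` uses the maximum pixel value of the reference image.
    """
    reference = np.asarray(reference, dtype=np.float64)
    generated = np.asarray(generated, dtype=np.float64)
    if reference.shape != generated.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {generated.shape}")
    if max_i is None:
        max_i = float(reference.max())
    if max_i <= 0:
        raise ValueError(f"max_i must be > 0, got {max_i}")
    mse = float(np.mean((reference - generated) ** 2))
    if mse == 0:
        return PSNR_INF
    return 10.0 * np.log10(max_i**2 / mse)


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(x: np.ndarray, y: np.ndarray, window: int = 11, sigma: float = 1.5,
         data_range: float = 1.0, full: bool = False):
    """Structural similarity with its luminance/contrast/structure parts.

    Local moments use an 11x11 Gaussian window (sigma 1.5); constants are
    C1=(0.01 R)^2, C2=(0.03 R)^2, c3=C2/2.  Returns the mean SSIM, or with
    ``full=True`` a dict with the ssim/l/c/s maps and their means.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if min(x.shape) < window:
        raise ValueError(f"image {x.shape} smaller than window {window}")
    if data_range <= 0:
        raise ValueError("data_range must be > 0")
    kernel = _gaussian_kernel(window, sigma)

    def filt(a):
        return ndimage.convolve(a, kernel, mode="reflect")

    mu_x, mu_y = filt(x), filt(y)
    var_x = filt(x * x) - mu_x**2
    var_y = filt(y * y) - mu_y**2
    cov = filt(x * y) - mu_x * mu_y
    # guard tiny negative round-off in the variances
    var_x = np.maximum(var_x, 0.0)
    var_y = np.maximum(var_y, 0.0)

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    c3 = c2 / 2.0

    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )
    if not full:
        return float(ssim_map.mean())
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    l_map = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    c_map = (2 * sd_x * sd_y + c2) / (var_x + var_y + c2)
    s_map = (cov + c3) / (sd_x * sd_y + c3)
    return {
        "ssim": float(ssim_map.mean()),
        "ssim_map": ssim_map,
        "l_map": l_map, "c_map": c_map, "s_map": s_map,
        "l": float(l_map.mean()), "c": float(c_map.mean()),
        "s": float(s_map.mean()),
    }


def _sqrtm_psd(mat: np.ndarray, eps: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() < -1e-6 * max(1.0, abs(vals.max())):
        raise ValueError(
            f"matrix not positive semi-definite after regularization "
            f"(min eigenvalue {vals.min():.3e})"
        )
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(real: GaussianMoments, gen: GaussianMoments,
        eps: float = 1e-10) -> float:
    """Fréchet distance between two Gaussians:
    ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2}), with the matrix
    square root evaluated via eigendecomposition of the symmetrized product
    S_r^{1/2} S_g S_r^{1/2}."""
    if real.mean.size != gen.mean.size:
        raise ValueError(
            f"dimension mismatch: {real.mean.size} vs {gen.mean.size}"
        )
    d = real.mean.size
    sr = real.cov + eps * np.eye(d)
    sg = gen.cov + eps * np.eye(d)
    sr_half = _sqrtm_psd(sr, eps)
    middle = _sqrtm_psd(sr_half @ sg @ sr_half, eps)
    val = float(np.sum((real.mean - gen.mean) ** 2)
                + np.trace(sr + sg) - 2.0 * np.trace(middle))
    return max(val, 0.0)


def embed_features(images, extractor: str = "raw_pool", pool_size: int = 8,
                   proj_dim: int = 64, seed: int = 0) -> GaussianMoments:
    """Deterministic feature embedding + Gaussian moments of a slice set.

    ``raw_pool`` block-averages each image to ``pool_size``^2 pixels and
    flattens; ``random_projection`` additionally applies a seeded Gaussian
    projection to ``proj_dim`` dimensions.  (The Inception embedding used
    for reported FID scores is a pluggable external extractor and requires
    pretrained weights; it is intentionally not bundled.)
    """
    images = [np.asarray(im, dtype=np.float64) for im in images]
    if len(images) < 2:
        raise ValueError("need at least 2 images to estimate moments")
    feats = []
    for im in images:
        zoom = (pool_size / im.shape[0], pool_size / im.shape[1])
        pooled = ndimage.zoom(im, zoom, order=1, mode="nearest",
                              grid_mode=True)
        feats.append(pooled.ravel())
    feats = np.stack(feats)
    if extractor == "random_projection":
        rng = np.random.default_rng(seed)
        proj = rng.normal(size=(feats.shape[1], proj_dim)) / np.sqrt(proj_dim)
        feats = feats @ proj
    elif extractor != "raw_pool":
        raise ValueError(
            f"unknown extractor {extractor!r}; supported: raw_pool, "
            f"random_projection"
        )
    mean = feats.mean(axis=0)
    cov = np.cov(feats, rowvar=False)  # unbiased
    return GaussianMoments(mean=mean, cov=np.atleast_2d(cov),
                           n_samples=len(images))


def dice(x_mask: np.ndarray, y_mask: np.ndarray) -> float:
    """2|X&Y| / (|X|+|Y|); defined as 1.0 when both masks are empty."""
    x_mask = np.asarray(x_mask)
    y_mask = np.asarray(y_mask)
    if x_mask.shape != y_mask.shape:
        raise ValueError(f"shape mismatch: {x_mask.shape} vs {y_mask.shape}")
    for name, m in (("x_mask", x_mask), ("y_mask", y_mask)):
        if not np.isin(m, (0, 1, True, False)).all():
            raise ValueError(f"{name} is not binary")
    nx = int(np.count_nonzero(x_mask))
    ny = int(np.count_nonzero(y_mask))
    if nx + ny == 0:
        return 1.0
    inter = int(np.count_nonzero(np.logical_and(x_mask, y_mask)))
    return 2.0 * inter / (nx + ny)


def evaluate(pred_slices: dict, truth_slices: dict, masks: dict | None = None,
             extractor: str = "raw_pool", seed: int = 0) -> MetricReport:
    """Per-slice PSNR/SSIM, one set-level FID, optional mask Dice.

    ``pred_slices``/``truth_slices`` map ``(subject_id, slice_index)`` to
    [0, 1] 2-D images; keys must pair exactly.
    """
    missing = sorted(set(truth_slices) - set(pred_slices))
    extra = sorted(set(pred_slices) - set(truth_slices))
    if missing or extra:
        raise ValueError(
            f"unpaired slices - missing predictions: {missing[:5]}, "
            f"unmatched predictions: {extra[:5]}"
        )
    rows = []
    for key in sorted(truth_slices):
        ref, pred = truth_slices[key], pred_slices[key]
        rows.append({
            "subject": key[0], "slice": key[1],
            "psnr": psnr(ref, pred), "ssim": ssim(ref, pred),
        })
    per_slice = pd.DataFrame(rows, columns=["subject", "slice", "psnr", "ssim"])
    summary = {}
    for name in ("psnr", "ssim"):
        vals = per_slice[name].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size == 0:       # all-perfect predictions
            summary[name] = (float(vals[0]), 0.0)
            continue
        sd = float(finite.std(ddof=0)) if finite.size > 1 else 0.0
        summary[name] = (float(finite.mean()), sd)
    keys = sorted(truth_slices)
    fid_val = fid(
        embed_features([truth_slices[k] for k in keys], extractor, seed=seed),
        embed_features([pred_slices[k] for k in keys], extractor, seed=seed),
    )
    dice_val = None
    if masks:
        dice_val = float(np.mean([
            dice(masks[k][0], masks[k][1]) for k in sorted(masks)
        ]))
    return MetricReport(per_slice=per_slice, summary=summary, fid=fid_val,
                        dice=dice_val)
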