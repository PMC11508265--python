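"""Unpaired training of the translation networks and volume inference.

The trainer alternates a least-squares discriminator step with a joint
generator + projection-head step optimizing the composite objective
(adversarial + self-regularization + patch-contrastive terms for both
domains).  Domains are sampled by independent shuffles — X and Y are never
indexed jointly.  Everything (init, data order, patch locations) is driven
by the run seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import (
    DEFAULT_NCE_LAYERS, GeneratorConfig, PatchDiscriminator, ProjectionHeads,
    ResnetGenerator, build_discriminator, build_generator,
    build_projection_head, encode_patch_features, project_patch_features,
)
from .nn import Adam, Tensor, get_default_dtype, set_default_dtype
from .objectives import LossConfig, lsgan_terms, patch_nce, self_regularization, total_loss
from .preprocess import SliceSample, Volume, crop_to_mask, extract_slices, \
    reinsert_slices, resample, zscore

__all__ = ["TrainConfig", "train", "infer", "load_checkpoint",
           "slices_to_batch", "TEST_PROFILE"]

LOG_COLUMNS = ["iter", "d_loss", "g_adv", "nce_x", "nce_y", "sr", "total"]


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 4
    learning_rate: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    disc_base_width: int = 64
    nce_layers: tuple[int, ...] = DEFAULT_NCE_LAYERS
    n_nce_locations: int = 256
    max_iterations: int | None = None    # cap across epochs (test profile)
    crop_size: tuple[int, int] | None = None  # center crop/pad slices
    target_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    margin_mm: tuple[float, float, float] = (5.0, 5.0, 0.0)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


def TEST_PROFILE(**overrides) -> TrainConfig:
    """CPU-minutes profile: width-16 generator, 64x64 crops, capped
    iterations.  The full-scale profile is ``TrainConfig()``."""
    base = dict(
        epochs=1000,  # iteration cap is the effective stop
        max_iterations=200,
        generator=GeneratorConfig(base_width=16),
        disc_base_width=16,
        n_nce_locations=64,
        crop_size=(64, 64),
        loss=LossConfig(lambda_sr=0.05),
    )
    base.update(overrides)
    return TrainConfig(**base)


def _fit_slice(img: np.ndarray, size: tuple[int, int],
               fill: float = -1.0) -> np.ndarray:
    """Center crop and/or pad a 2-D image to ``size``."""
    out = img
    for ax in range(2):
        n = out.shape[ax]
        want = size[ax]
        if n > want:
            lo = (n - want) // 2
            sl = [slice(None)] * 2
            sl[ax] = slice(lo, lo + want)
            out = out[tuple(sl)]
        elif n < want:
            pad = [(0, 0), (0, 0)]
            pad[ax] = ((want - n) // 2, want - n - (want - n) // 2)
            out = np.pad(out, pad, constant_values=fill)
    return out


def slices_to_batch(samples: list[SliceSample] | list[np.ndarray],
                    idx: np.ndarray,
                    crop_size: tuple[int, int] | None = None) -> Tensor:
    """Stack slices into an (N, 3, H, W) tensor, grayscale replicated."""
    imgs = []
    for i in idx:
        s = samples[int(i)]
        img = s.image if isinstance(s, SliceSample) else np.asarray(s)
        if crop_size is not None:
            img = _fit_slice(img, crop_size)
        imgs.append(np.repeat(img[None], 3, axis=0))
    return Tensor(np.stack(imgs))


def _check_finite(name: str, value: float) -> float:
    if not np.isfinite(value):
        raise RuntimeError(
            f"training aborted: loss term '{name}' is not finite ({value})"
        )
    return value


def train(x_slices, y_slices, cfg: TrainConfig,
          out_dir: str | Path) -> tuple[Path, pd.DataFrame]:
    """Train on unpaired slice sets; returns (checkpoint path, loss log).

    Runs in float32 (CPU speed); checkpoints load back as float64.
    """
    if len(x_slices) == 0 or len(y_slices) == 0:
        raise ValueError("both domains must be non-empty")
    prev_dtype = get_default_dtype()
    set_default_dtype(np.float32)
    try:
        return _train_impl(x_slices, y_slices, cfg, out_dir)
    finally:
        set_default_dtype(prev_dtype)


def _train_impl(x_slices, y_slices, cfg: TrainConfig,
                out_dir: str | Path) -> tuple[Path, pd.DataFrame]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gen, _ = build_generator(cfg.generator, seed=cfg.seed)
    disc = build_discriminator(cfg.generator.out_channels, cfg.disc_base_width,
                               seed=cfg.seed + 1)
    heads = build_projection_head(gen.nce_feature_dims(cfg.nce_layers),
                                  seed=cfg.seed + 2)

    g_params = gen.parameters() + heads.parameters()
    opt_g = Adam(g_params, lr=cfg.learning_rate, betas=cfg.betas)
    opt_d = Adam(disc.parameters(), lr=cfg.learning_rate, betas=cfg.betas)

    data_rng = np.random.default_rng(cfg.seed + 10)
    loc_rng = np.random.default_rng(cfg.seed + 20)

    rows = []
    it = 0
    done = False
    for epoch in range(cfg.epochs):
        perm_x = data_rng.permutation(len(x_slices))
        perm_y = data_rng.permutation(len(y_slices))
        n_batches = min(len(perm_x), len(perm_y)) // cfg.batch_size
        if n_batches == 0:
            raise ValueError(
                f"batch_size {cfg.batch_size} exceeds dataset size "
                f"{min(len(x_slices), len(y_slices))}"
            )
        for b in range(n_batches):
            bx = perm_x[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            by = perm_y[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            x = slices_to_batch(x_slices, bx, cfg.crop_size)
            y = slices_to_batch(y_slices, by, cfg.crop_size)

            fake, x_feats = gen.forward_with_taps(x, cfg.nce_layers)

            # discriminator step on detached fakes
            d_loss, _ = lsgan_terms(disc(y), disc(fake.detach()))
            opt_d.zero_grad()
            d_loss.backward()
            opt_d.step()

            # generator + head step
            _, g_adv = lsgan_terms(Tensor(np.zeros(1)), disc(fake))
            sr = self_regularization(x, fake)
            fq = encode_patch_features(gen, fake, cfg.nce_layers,
                                       cfg.n_nce_locations, heads, rng=loc_rng)
            fk = project_patch_features(x_feats, cfg.nce_layers,
                                        cfg.n_nce_locations, heads,
                                        shared_locations=fq.locations)
            nce_x = patch_nce(fq, fk, cfg.loss.tau)
            idt, y_feats = gen.forward_with_taps(y, cfg.nce_layers)
            fq_y = encode_patch_features(gen, idt, cfg.nce_layers,
                                         cfg.n_nce_locations, heads,
                                         shared_locations=fq.locations)
            fk_y = project_patch_features(y_feats, cfg.nce_layers,
                                          cfg.n_nce_locations, heads,
                                          shared_locations=fq.locations)
            nce_y = patch_nce(fq_y, fk_y, cfg.loss.tau)
            total = total_loss(g_adv, sr, nce_x, nce_y, cfg.loss)
            opt_g.zero_grad()
            total.backward()
            opt_g.step()

            it += 1
            rows.append({
                "iter": it,
                "d_loss": _check_finite("d_loss", d_loss.item()),
                "g_adv": _check_finite("g_adv", g_adv.item()),
                "nce_x": _check_finite("nce_x", nce_x.item()),
                "nce_y": _check_finite("nce_y", nce_y.item()),
                "sr": _check_finite("sr", sr.item()),
                "total": _check_finite("total", total.item()),
            })
            if cfg.max_iterations is not None and it >= cfg.max_iterations:
                done = True
                break
        _save_checkpoint(out_dir / f"checkpoint_epoch{epoch + 1}.npz",
                         gen, disc, heads, cfg)
        if done:
            break

    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    log.to_csv(out_dir / "training_log.csv", index=False)
    ckpt = out_dir / "checkpoint.npz"
    _save_checkpoint(ckpt, gen, disc, heads, cfg)
    return ckpt, log


def _save_checkpoint(path: Path, gen: ResnetGenerator,
                     disc: PatchDiscriminator, heads: ProjectionHeads,
                     cfg: TrainConfig) -> None:
    arrays = {}
    for prefix, module in (("gen", gen), ("disc", disc), ("heads", heads)):
        for name, p in module.named_parameters():
            arrays[f"{prefix}.{name}"] = p.data
    meta = dataclasses.asdict(cfg)
    arrays["__config__"] = np.frombuffer(
        json.dumps(meta, default=list).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path):
    """Rebuild generator (+ discriminator, heads) from a checkpoint."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("__config__")).decode())
    gcfg_d = dict(meta["generator"])
    cbam = gcfg_d.pop("cbam", None)
    from .networks import AttentionConfig
    gcfg = GeneratorConfig(
        **{k: (tuple(v) if isinstance(v, list) else v) for k, v in gcfg_d.items()},
    )
    gcfg.cbam = AttentionConfig(**cbam) if cbam is not None else None
    gen, _ = build_generator(gcfg, seed=0)
    gen.load_state_dict({k[len("gen."):]: v for k, v in arrays.items()
                         if k.startswith("gen.")})
    return gen, meta, arrays


def infer(checkpoint: str | Path, t2, mask: Volume | None = None,
          out_path: str | Path | None = None):
    """Generate ADC-like output from a checkpoint.

    ``t2`` may be a list of preprocessed :class:`SliceSample` (returns
    translated samples) or a :class:`Volume` with a ``mask`` (returns a
    reassembled volume).  Inference is deterministic.
    """
    gen, meta, _ = load_checkpoint(checkpoint)

    def run(samples: list[SliceSample]) -> list[SliceSample]:
        out = []
        for s in samples:
            batch = Tensor(np.repeat(s.image[None, None], 3, axis=1))
            y = gen(batch).numpy()[0].mean(axis=0)
            out.append(dataclasses.replace(s, image=y, domain="Y"))
        return out

    if isinstance(t2, list):
        return run(t2)

    if mask is None:
        raise ValueError("volume inference requires a prostate mask")
    target = tuple(meta["target_spacing"])
    if not np.allclose(t2.spacing_mm, target, atol=1e-6):
        warnings.warn(
            f"input spacing {t2.spacing_mm} differs from training spacing "
            f"{target}; resampling automatically", stacklevel=2,
        )
        t2 = resample(t2, target)
        mask = resample(mask, target)
    cropped, box = crop_to_mask(t2, mask, tuple(meta["margin_mm"]))
    mask_crop = Volume(mask.data[tuple(slice(lo, hi) for lo, hi in box)],
                       mask.spacing_mm, mask.affine, role="mask")
    normed = zscore(cropped)
    samples = extract_slices(normed, None, mask_crop, subject_id="infer",
                             crop_box=box)
    generated = run(samples)
    vol = reinsert_slices(generated, template=t2)
    vol = Volume(vol.data, vol.spacing_mm, vol.affine, role="adc")
    if out_path is not None:
        from .preprocess import save_volume
        save_volume(vol, out_path)
    return vol
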