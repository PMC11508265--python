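"""Translation networks: attention-augmented ResNet generator, patch
discriminator, and the projection heads used by the patch-contrastive loss.

The generator is a fully-convolutional 9-residual-block encoder-decoder
(7x7 stem at base width, two stride-2 downsamples, residual trunk, two
stride-2 transposed-conv upsamples, 7x7 tanh head) with a single
channel+spatial attention block inserted at a configurable encoder stage.
Instance normalization is parameter-free, convolutions carry biases, and
all weights are Glorot-initialized from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv2d, ConvTranspose2d, InstanceNorm2d, LeakyReLU, Linear, Module,
    ReflectionPad2d, ReLU, Sequential, Tanh, Tensor, concat,
)

__all__ = [
    "AttentionConfig", "GeneratorConfig", "FeatureStack",
    "ChannelAttention", "SpatialAttention", "CBAM",
    "channel_attention", "spatial_attention", "cbam_refine",
    "ResnetGenerator", "PatchDiscriminator", "ProjectionHeads",
    "build_generator", "build_discriminator", "build_projection_head",
    "encode_patch_features", "project_patch_features", "DEFAULT_NCE_LAYERS",
]

#: encoder taps used for the patch-contrastive loss: input image, stem
#: output, both downsample outputs, and the 4th residual block.
DEFAULT_NCE_LAYERS = (0, 1, 2, 3, 4)


@dataclass
class AttentionConfig:
    placement: int = 0          # encoder stage: 0 = after stem, 1/2 = after downsamples
    reduction_ratio: int = 8
    spatial_kernel: int = 5

    def validate(self, channels_at_placement: int) -> None:
        if self.placement not in (0, 1, 2):
            raise ValueError(f"placement must be 0, 1 or 2, got {self.placement}")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if channels_at_placement % self.reduction_ratio:
            raise ValueError(
                f"reduction_ratio {self.reduction_ratio} does not divide "
                f"channel count {channels_at_placement}"
            )
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")


@dataclass
class GeneratorConfig:
    in_channels: int = 3
    out_channels: int = 3
    base_width: int = 64
    n_resblocks: int = 9
    cbam: AttentionConfig | None = field(default_factory=AttentionConfig)

    def validate(self) -> None:
        if self.n_resblocks < 1:
            raise ValueError("n_resblocks must be >= 1")
        if self.base_width < 1 or self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.cbam is not None:
            self.cbam.validate(self.base_width * 2**self.cbam.placement)


@dataclass
class FeatureStack:
    """Per-layer unit-norm patch embeddings at sampled spatial locations.

    ``embeddings[l]`` has shape (batch, n_locations, dim); ``locations[l]``
    holds the flattened spatial indices that were sampled at layer ``l``.
    """

    layers: tuple[int, ...]
    embeddings: dict[int, Tensor]
    locations: dict[int, np.ndarray]


class ChannelAttention(Module):
    """Sigmoid channel gate from global average+max pooling through a shared
    bias-free two-layer MLP."""

    def __init__(self, channels: int, reduction_ratio: int = 8,
                 rng: np.random.Generator | None = None):
        self.channels = channels
        self.fc1 = Linear(channels, channels // reduction_ratio, bias=False, rng=rng)
        self.fc2 = Linear(channels // reduction_ratio, channels, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}"
            )
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=(2, 3))
        z = self.fc2(self.fc1(avg).relu()) + self.fc2(self.fc1(mx).relu())
        return z.sigmoid()  # (N, C)


class SpatialAttention(Module):
    """Sigmoid spatial gate from channelwise average+max maps through a
    single kxk convolution."""

    def __init__(self, kernel_size: int = 5,
                 rng: np.random.Generator | None = None):
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2,
                           bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()  # (N, 1, H, W)


class CBAM(Module):
    def __init__(self, channels: int, reduction_ratio: int = 8,
                 spatial_kernel: int = 5,
                 rng: np.random.Generator | None = None):
        self.channel = ChannelAttention(channels, reduction_ratio, rng=rng)
        self.spatial = SpatialAttention(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        mc = self.channel(x).reshape(n, c, 1, 1)
        xp = mc * x
        return self.spatial(xp) * xp


def channel_attention(x, module: ChannelAttention) -> np.ndarray:
    """Functional wrapper: channel weights of shape (C,) for a C,H,W map."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return module(t).numpy()[0]


def spatial_attention(x, module: SpatialAttention) -> np.ndarray:
    """Functional wrapper: spatial weight map of shape (H, W)."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return module(t).numpy()[0, 0]


def cbam_refine(x, module: CBAM) -> np.ndarray:
    """Functional wrapper for the full refine step on a C,H,W map."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if t.ndim == 3:
        t = t.reshape(1, *t.shape)
    return module(t).numpy()[0]


class ResidualBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.body = Sequential(
            ReflectionPad2d(1),
            Conv2d(channels, channels, 3, rng=rng),
            InstanceNorm2d(),
            ReLU(),
            ReflectionPad2d(1),
            Conv2d(channels, channels, 3, rng=rng),
            InstanceNorm2d(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return x + self.body(x)


class ResnetGenerator(Module):
    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        w = config.base_width
        self.stem = Sequential(
            ReflectionPad2d(3),
            Conv2d(config.in_channels, w, 7, rng=rng),
            InstanceNorm2d(),
            ReLU(),
        )
        self.cbam = None
        if config.cbam is not None:
            self.cbam = CBAM(
                w * 2**config.cbam.placement,
                config.cbam.reduction_ratio,
                config.cbam.spatial_kernel,
                rng=rng,
            )
        self.down1 = Sequential(
            Conv2d(w, 2 * w, 3, stride=2, padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
        )
        self.down2 = Sequential(
            Conv2d(2 * w, 4 * w, 3, stride=2, padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
        )
        self.resblocks = [ResidualBlock(4 * w, rng=rng)
                          for _ in range(config.n_resblocks)]
        self.up1 = Sequential(
            ConvTranspose2d(4 * w, 2 * w, 3, stride=2, padding=1,
                            output_padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
        )
        self.up2 = Sequential(
            ConvTranspose2d(2 * w, w, 3, stride=2, padding=1,
                            output_padding=1, rng=rng),
            InstanceNorm2d(), ReLU(),
        )
        self.head = Sequential(
            ReflectionPad2d(3),
            Conv2d(w, config.out_channels, 7, rng=rng),
            Tanh(),
        )

    # encoder with tap outputs; layer ids: 0 input, 1 stem, 2 down1, 3 down2,
    # 4 = output of the 4th residual block (or the last one if fewer).
    def encode(self, x: Tensor, layer_ids: tuple[int, ...]) -> dict[int, Tensor]:
        feats: dict[int, Tensor] = {}
        placement = self.config.cbam.placement if self.cbam is not None else -1
        if 0 in layer_ids:
            feats[0] = x
        h = self.stem(x)
        if placement == 0:
            h = self.cbam(h)
        if 1 in layer_ids:
            feats[1] = h
        h = self.down1(h)
        if placement == 1:
            h = self.cbam(h)
        if 2 in layer_ids:
            feats[2] = h
        h = self.down2(h)
        if placement == 2:
            h = self.cbam(h)
        if 3 in layer_ids:
            feats[3] = h
        if 4 in layer_ids:
            tap = min(3, len(self.resblocks) - 1)
            for block in self.resblocks[: tap + 1]:
                h = block(h)
            feats[4] = h
        return feats

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_with_taps(x, ())[0]

    def forward_with_taps(self, x: Tensor, layer_ids: tuple[int, ...]):
        """Full pass that also returns the requested encoder taps (lets the
        trainer reuse the source-image features for the contrastive loss
        without a second encoder pass)."""
        feats: dict[int, Tensor] = {}
        placement = self.config.cbam.placement if self.cbam is not None else -1
        if 0 in layer_ids:
            feats[0] = x
        h = self.stem(x)
        if placement == 0:
            h = self.cbam(h)
        if 1 in layer_ids:
            feats[1] = h
        h = self.down1(h)
        if placement == 1:
            h = self.cbam(h)
        if 2 in layer_ids:
            feats[2] = h
        h = self.down2(h)
        if placement == 2:
            h = self.cbam(h)
        if 3 in layer_ids:
            feats[3] = h
        tap = min(3, len(self.resblocks) - 1)
        for i, block in enumerate(self.resblocks):
            h = block(h)
            if i == tap and 4 in layer_ids:
                feats[4] = h
        return self.head(self.up2(self.up1(h))), feats

    def nce_feature_dims(self, layer_ids: tuple[int, ...]) -> list[int]:
        w = self.config.base_width
        dims = {0: self.config.in_channels, 1: w, 2: 2 * w, 3: 4 * w, 4: 4 * w}
        return [dims[l] for l in layer_ids]


class PatchDiscriminator(Module):
    """70x70-receptive-field patch classifier; unbounded real-valued score
    map (least-squares adversarial head, no sigmoid)."""

    def __init__(self, in_channels: int = 3, base_width: int = 64,
                 rng: np.random.Generator | None = None):
        w = base_width
        self.body = Sequential(
            Conv2d(in_channels, w, 4, stride=2, padding=1, rng=rng),
            LeakyReLU(0.2),
            Conv2d(w, 2 * w, 4, stride=2, padding=1, rng=rng),
            InstanceNorm2d(), LeakyReLU(0.2),
            Conv2d(2 * w, 4 * w, 4, stride=2, padding=1, rng=rng),
            InstanceNorm2d(), LeakyReLU(0.2),
            Conv2d(4 * w, 8 * w, 4, stride=1, padding=1, rng=rng),
            InstanceNorm2d(), LeakyReLU(0.2),
            Conv2d(8 * w, 1, 4, stride=1, padding=1, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class ProjectionHeads(Module):
    """One independent two-layer MLP per tapped encoder layer."""

    def __init__(self, in_dims: list[int], out_dim: int = 256,
                 rng: np.random.Generator | None = None):
        self.out_dim = out_dim
        self.heads = [
            Sequential(Linear(d, out_dim, rng=rng), ReLU(),
                       Linear(out_dim, out_dim, rng=rng))
            for d in in_dims
        ]

    def forward(self, layer_index: int, x: Tensor) -> Tensor:
        return self.heads[layer_index](x)


def build_generator(config: GeneratorConfig | None = None,
                    seed: int = 0) -> tuple[ResnetGenerator, int]:
    """Construct the generator; returns (model, trainable parameter count)."""
    config = config or GeneratorConfig()
    gen = ResnetGenerator(config, np.random.default_rng(seed))
    return gen, gen.n_parameters()


def build_discriminator(in_channels: int = 3, base_width: int = 64,
                        seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(in_channels, base_width,
                              rng=np.random.default_rng(seed))


def build_projection_head(in_dims: list[int], out_dim: int = 256,
                          seed: int = 0) -> ProjectionHeads:
    return ProjectionHeads(in_dims, out_dim, rng=np.random.default_rng(seed))


def encode_patch_features(
    generator: ResnetGenerator,
    images: Tensor,
    layer_ids: tuple[int, ...],
    n_locations: int,
    heads: ProjectionHeads,
    rng: np.random.Generator | None = None,
    shared_locations: dict[int, np.ndarray] | None = None,
) -> FeatureStack:
    """Sample spatial locations per tapped layer, project and L2-normalize.

    Pass ``shared_locations`` (from a previous stack) to evaluate a second
    image at positionally corresponding patches; otherwise locations are
    drawn without replacement from ``rng``.
    """
    if images.ndim == 3:
        images = images.reshape(1, *images.shape)
    feats = generator.encode(images, tuple(layer_ids))
    return project_patch_features(feats, tuple(layer_ids), n_locations, heads,
                                  rng=rng, shared_locations=shared_locations)


def project_patch_features(
    feats: dict[int, Tensor],
    layer_ids: tuple[int, ...],
    n_locations: int,
    heads: ProjectionHeads,
    rng: np.random.Generator | None = None,
    shared_locations: dict[int, np.ndarray] | None = None,
) -> FeatureStack:
    """Project precomputed encoder taps (see ``encode_patch_features``)."""
    embeddings: dict[int, Tensor] = {}
    locations: dict[int, np.ndarray] = {}
    for i, l in enumerate(layer_ids):
        f = feats[l]  # (N, C, H, W)
        n, c, h, w = f.shape
        p = h * w
        if shared_locations is not None:
            idx = shared_locations[l]
        else:
            if n_locations > p:
                raise ValueError(
                    f"n_locations={n_locations} exceeds {p} spatial positions "
                    f"at layer {l}"
                )
            if rng is None:
                raise ValueError("either rng or shared_locations is required")
            idx = np.sort(rng.choice(p, size=n_locations, replace=False))
        flat = f.reshape(n, c, p).transpose(0, 2, 1)  # (N, P, C)
        sel = flat[:, idx, :]                          # (N, S, C)
        z = heads(i, sel)
        norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
        embeddings[l] = z / norm
        locations[l] = np.asarray(idx)
    return FeatureStack(tuple(layer_ids), embeddings, locations)
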