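"""Trait-conditioned multi-stage generator and discriminator.

The generator is a tree of up to three stages producing images at
64, 128 and 256 pixels.  Stage 1 maps the concatenation of a Gaussian
noise vector z and the normalized trait condition c through a fully
connected block (linear + batchnorm) to a 4x4 feature map, then through
four upsampling blocks (nearest upsample + conv + batchnorm + ReLU) to
the hidden feature h1 at 64x64; a conv + tanh head emits the stage
image.  Each later stage tiles c spatially, concatenates it with the
previous hidden feature along the channel dimension, and applies a
joint block (conv + batchnorm), two residual blocks, and an upsampling
block before its own conv + tanh head at doubled resolution.

Conditioning is pure channel concatenation — there is no stochastic
re-embedding of the condition, so the trait vector reaches the
generator unperturbed.  The noise input z models the many-images-per-
trait-vector ambiguity; z_dim = 0 yields a fully deterministic
trait-to-image mapping.

Each stage's discriminator downsamples its input to a 4x4 feature map
and emits two logits: an unconditional real-vs-fake score, and a
conditional score computed after channel-concatenating the tiled trait
vector, which judges whether the image matches the traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, BatchNorm, Conv2d, Dense, Layer, LeakyReLU, Param,
                 ReLU, Reshape, Sequential, Tanh, Upsample2x,
                 bce_with_logits)

__all__ = ["GeneratorConfig", "GeneratorOutput", "DiscriminatorOutput",
           "Generator", "Discriminator", "ResidualBlock",
           "discriminator_loss", "generator_loss"]

F32 = np.float32


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture hyperparameters of the multi-stage generator."""

    n_stages: int = 3
    base_resolution: int = 64
    z_dim: int = 100
    cond_dim: int = 18
    base_channels: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_stages <= 3:
            raise ValueError("n_stages must be 1, 2 or 3")
        if self.z_dim < 0 or self.cond_dim < 1:
            raise ValueError("invalid z_dim or cond_dim")

    @property
    def stage_resolutions(self) -> tuple[int, ...]:
        return tuple(self.base_resolution * 2**k
                     for k in range(self.n_stages))

    def to_dict(self) -> dict:
        return {"n_stages": self.n_stages,
                "base_resolution": self.base_resolution,
                "z_dim": self.z_dim, "cond_dim": self.cond_dim,
                "base_channels": self.base_channels, "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


@dataclass
class GeneratorOutput:
    """Per-stage images in [-1, 1] plus the hidden features h1, h2, ..."""

    images: list[np.ndarray]
    hidden: list[np.ndarray]


@dataclass
class DiscriminatorOutput:
    """Unconditional (real-vs-fake) and conditional (trait-match) logits."""

    uncond_logit: np.ndarray
    cond_logit: np.ndarray | None = None


class ResidualBlock(Layer):
    """x + (conv-bn-relu-conv-bn)(x), followed by ReLU."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.path = Sequential(
            Conv2d(channels, channels, 3, rng), BatchNorm(channels, rng),
            ReLU(),
            Conv2d(channels, channels, 3, rng), BatchNorm(channels, rng),
        )

    def params(self):
        return self.path.params()

    def forward(self, x, train=True):
        y = x + self.path.forward(x, train)
        self._pos = y > 0
        return y * self._pos

    def backward(self, gout):
        g = gout * self._pos
        return g + self.path.backward(g)


def _tile(c: np.ndarray, side: int) -> np.ndarray:
    """Spatially replicate a (N, T) vector to (N, T, side, side)."""
    return np.broadcast_to(c[:, :, None, None],
                           (c.shape[0], c.shape[1], side, side)).astype(F32)


def _collect_layers(layer: Layer):
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _collect_layers(sub)
    elif isinstance(layer, ResidualBlock):
        yield from _collect_layers(layer.path)


class _Module:
    """State (de)serialization shared by generator and discriminator."""

    def _top_layers(self) -> list[Layer]:
        raise NotImplementedError

    def _flat_layers(self) -> list[Layer]:
        return [lay for top in self._top_layers()
                for lay in _collect_layers(top)]

    def params(self) -> list[Param]:
        return [p for top in self._top_layers() for p in top.params()]

    def state_arrays(self) -> list[np.ndarray]:
        arrays = []
        for lay in self._flat_layers():
            if isinstance(lay, (Conv2d, Dense, BatchNorm)):
                arrays.extend(p.value for p in lay.params())
            if isinstance(lay, BatchNorm):
                arrays.extend([lay.running_mean, lay.running_var])
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for lay in self._flat_layers():
            if isinstance(lay, (Conv2d, Dense, BatchNorm)):
                for p in lay.params():
                    p.value[...] = next(it)
            if isinstance(lay, BatchNorm):
                lay.running_mean[...] = next(it)
                lay.running_var[...] = next(it)
        try:
            next(it)
        except StopIteration:
            return
        raise ValueError("checkpoint has more arrays than the model")


class Generator(_Module):
    """Multi-stage trait-conditioned generator."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        bc = config.base_channels
        c0 = bc * 8
        self.stages: list[Sequential] = []
        self.to_img: list[Sequential] = []
        #: channels expected at each stage's joint block input
        #: (hidden channels of the previous stage + cond_dim)
        self.joint_in_channels: list[int] = []
        self.hidden_channels: list[int] = []

        blocks = [
            Dense(config.z_dim + config.cond_dim, 4 * 4 * c0, rng),
            BatchNorm(4 * 4 * c0, rng), ReLU(), Reshape((c0, 4, 4)),
        ]
        ch = c0
        for _ in range(4):  # 4 -> 8 -> 16 -> 32 -> 64
            nxt = max(ch // 2, 4)
            blocks += [Upsample2x(), Conv2d(ch, nxt, 3, rng),
                       BatchNorm(nxt, rng), ReLU()]
            ch = nxt
        self.stages.append(Sequential(*blocks))
        self.hidden_channels.append(ch)
        self.to_img.append(Sequential(Conv2d(ch, 3, 3, rng), Tanh()))

        for _ in range(1, config.n_stages):
            c_in = ch + config.cond_dim
            self.joint_in_channels.append(c_in)
            nxt = max(ch // 2, 4)
            stage = Sequential(
                Conv2d(c_in, ch, 3, rng), BatchNorm(ch, rng), ReLU(),
                ResidualBlock(ch, rng), ResidualBlock(ch, rng),
                Upsample2x(), Conv2d(ch, nxt, 3, rng),
                BatchNorm(nxt, rng), ReLU(),
            )
            ch = nxt
            self.stages.append(stage)
            self.hidden_channels.append(ch)
            self.to_img.append(Sequential(Conv2d(ch, 3, 3, rng), Tanh()))

    def _top_layers(self):
        return [lay for pair in zip(self.stages, self.to_img)
                for lay in pair]

    def _check_condition(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=F32)
        if c.ndim != 2 or c.shape[1] != self.config.cond_dim:
            raise ValueError(
                f"condition must be (batch, {self.config.cond_dim}), "
                f"got {c.shape}")
        if c.min() < -1e-6 or c.max() > 1.0 + 1e-6:
            raise ValueError("condition values must lie in [0, 1]")
        return np.clip(c, 0.0, 1.0)

    def forward(self, z: np.ndarray, c: np.ndarray,
                train: bool = True) -> GeneratorOutput:
        c = self._check_condition(c)
        z = np.asarray(z, dtype=F32).reshape(c.shape[0], self.config.z_dim)
        h = self.stages[0].forward(np.concatenate([z, c], axis=1), train)
        hidden = [h]
        images = [self.to_img[0].forward(h, train)]
        for k in range(1, self.config.n_stages):
            tiled = _tile(c, h.shape[2])
            h = self.stages[k].forward(
                np.concatenate([h, tiled], axis=1), train)
            hidden.append(h)
            images.append(self.to_img[k].forward(h, train))
        return GeneratorOutput(images=images, hidden=hidden)

    def backward(self, image_grads: list[np.ndarray]) -> None:
        """Back-propagate per-stage image gradients into the weights.

        Must follow a ``forward`` call with ``train=True`` (layer caches
        are consumed).  Hidden features fan out to the stage head and to
        the next stage; their gradients are summed here.
        """
        g_h = None
        for k in range(self.config.n_stages - 1, -1, -1):
            g = self.to_img[k].backward(image_grads[k])
            if g_h is not None:
                g = g + g_h
            g_in = self.stages[k].backward(g)
            if k > 0:
                g_h = g_in[:, :self.hidden_channels[k - 1]]


class Discriminator(_Module):
    """Per-stage discriminator with unconditional and conditional heads."""

    def __init__(self, resolution: int, cond_dim: int,
                 base_channels: int = 32, seed: int = 0):
        if resolution < 8 or resolution & (resolution - 1):
            raise ValueError("resolution must be a power of two >= 8")
        self.resolution = resolution
        self.cond_dim = cond_dim
        rng = np.random.default_rng(seed)
        bc = base_channels

        layers = [Conv2d(3, bc, 4, rng, stride=2, pad=1), LeakyReLU(0.2)]
        ch, side = bc, resolution // 2
        while side > 4:
            nxt = min(ch * 2, bc * 8)
            layers += [Conv2d(ch, nxt, 4, rng, stride=2, pad=1),
                       BatchNorm(nxt, rng), LeakyReLU(0.2)]
            ch, side = nxt, side // 2
        self.backbone = Sequential(*layers)
        self.feat_channels = ch
        self.uncond_head = Sequential(Conv2d(ch, 1, 4, rng, stride=1, pad=0))
        self.cond_head = Sequential(
            Conv2d(ch + cond_dim, ch, 3, rng), BatchNorm(ch, rng),
            LeakyReLU(0.2), Conv2d(ch, 1, 4, rng, stride=1, pad=0))

    def _top_layers(self):
        return [self.backbone, self.uncond_head, self.cond_head]

    def forward(self, image: np.ndarray, c: np.ndarray | None = None,
                train: bool = True) -> DiscriminatorOutput:
        image = np.asarray(image, dtype=F32)
        if image.shape[2] != self.resolution \
                or image.shape[3] != self.resolution:
            raise ValueError(
                f"expected {self.resolution}x{self.resolution} input, got "
                f"{image.shape[2]}x{image.shape[3]}")
        feat = self.backbone.forward(image, train)
        uncond = self.uncond_head.forward(feat, train).reshape(-1)
        cond = None
        if c is not None:
            joint = np.concatenate([feat, _tile(np.asarray(c, dtype=F32),
                                                feat.shape[2])], axis=1)
            cond = self.cond_head.forward(joint, train).reshape(-1)
        self._had_cond = cond is not None
        return DiscriminatorOutput(uncond_logit=uncond, cond_logit=cond)

    def backward(self, g_uncond: np.ndarray,
                 g_cond: np.ndarray | None = None) -> np.ndarray:
        """Return the gradient with respect to the input image."""
        n = g_uncond.shape[0]
        g_feat = self.uncond_head.backward(
            g_uncond.reshape(n, 1, 1, 1).astype(F32))
        if g_cond is not None:
            g_joint = self.cond_head.backward(
                g_cond.reshape(n, 1, 1, 1).astype(F32))
            g_feat = g_feat + g_joint[:, :self.feat_channels]
        return self.backbone.backward(g_feat)


def _stage_d_terms(real: DiscriminatorOutput, fake: DiscriminatorOutput,
                   mismatched: DiscriminatorOutput | None,
                   w_mis: float) -> float:
    loss = bce_with_logits(real.uncond_logit, 1.0)[0]
    loss += bce_with_logits(fake.uncond_logit, 0.0)[0]
    loss += bce_with_logits(real.cond_logit, 1.0)[0]
    loss += bce_with_logits(fake.cond_logit, 0.0)[0]
    if mismatched is not None and w_mis != 0.0:
        loss += w_mis * bce_with_logits(mismatched.cond_logit, 0.0)[0]
    return loss


def discriminator_loss(real, fake, mismatched=None,
                       w_mis: float = 1.0) -> float:
    """Total discriminator loss, summed over stages.

    Per stage: unconditional BCE (real -> 1, fake -> 0), conditional BCE
    with the matched traits (real -> 1, fake -> 0), and optionally the
    mismatched-pair term (real image with wrong traits -> 0) weighted by
    ``w_mis``.  Accepts single DiscriminatorOutputs or per-stage lists.
    """
    if isinstance(real, DiscriminatorOutput):
        real, fake = [real], [fake]
        mismatched = None if mismatched is None else [mismatched]
    total = 0.0
    for k in range(len(real)):
        mis = None if mismatched is None else mismatched[k]
        total += _stage_d_terms(real[k], fake[k], mis, w_mis)
    return total


def generator_loss(fakes) -> float:
    """Generator loss: per stage, uncond(fake -> 1) + cond(fake -> 1)."""
    if isinstance(fakes, DiscriminatorOutput):
        fakes = [fakes]
    total = 0.0
    for out in fakes:
        total += bce_with_logits(out.uncond_logit, 1.0)[0]
        total += bce_with_logits(out.cond_logit, 1.0)[0]
    return total


def make_optimizers(gen: Generator, discs: list[Discriminator],
                    lr: float = 2e-4, beta_1: float = 0.5,
                    beta_2: float = 0.999, epsilon: float = 1e-8):
    g_opt = Adam(gen.params(), lr, beta_1, beta_2, epsilon)
    d_opt = Adam([p for d in discs for p in d.params()],
                 lr, beta_1, beta_2, epsilon)
    return g_opt, d_opt
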