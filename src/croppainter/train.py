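"""Adversarial training loop and trait-to-image generation.

Training alternates one discriminator step over all stages and one
generator step per batch, with Adam (lr 2e-4, beta_1 0.5, beta_2 0.999,
epsilon 1e-8).  Per-stage real images are obtained by area-averaged
downscaling of the stored records, so only one copy of each record is
kept.  The whole loop is a pure function of (manifest, configs, seed):
identical seeds reproduce identical loss logs and checkpoints.

A checkpoint is a single ``.npz`` archive holding the generator
weights together with the generator configuration, the trait schema
and the fitted min-max normalizer, so image generation needs no other
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gan import Discriminator, Generator, GeneratorConfig, make_optimizers
from .nn import bce_with_logits
from .preprocess import DatasetManifest, MinMaxNormalizer
from .traits import TraitSchema

__all__ = ["TrainConfig", "Checkpoint", "train", "generate",
           "DESK_GENERATOR", "DESK_TRAIN"]

F32 = np.float32


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    lr: float = 2e-4
    beta_1: float = 0.5
    beta_2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 16
    epochs: int = 600
    seed: int = 0
    w_mis: float = 1.0
    snapshot_every: int = 0  # 0 = final checkpoint only

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not (0 <= self.beta_1 < 1 and 0 <= self.beta_2 < 1):
            raise ValueError("betas must lie in [0, 1)")


#: Desk-scale presets: a single 64x64 stage with a narrow network and a
#: short noise vector trains in minutes on one CPU while still
#: exercising the full conditional architecture.
DESK_GENERATOR = dict(n_stages=1, base_resolution=64, z_dim=8,
                      base_channels=8)
DESK_TRAIN = dict(batch_size=16, epochs=60)


@dataclass
class Checkpoint:
    """Self-contained generator snapshot."""

    gen_config: GeneratorConfig
    schema: TraitSchema
    normalizer: MinMaxNormalizer
    arrays: list[np.ndarray]

    def save(self, path: str | Path) -> None:
        meta = json.dumps({
            "gen_config": self.gen_config.to_dict(),
            "schema": self.schema.to_dict(),
            "normalizer": self.normalizer.to_dict(),
        })
        named = {f"arr_{i:04d}": a for i, a in enumerate(self.arrays)}
        np.savez(path, meta=np.array(meta), **named)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(str(data["meta"]))
            keys = sorted(k for k in data.files if k.startswith("arr_"))
            arrays = [data[k] for k in keys]
        return cls(GeneratorConfig.from_dict(meta["gen_config"]),
                   TraitSchema.from_dict(meta["schema"]),
                   MinMaxNormalizer.from_dict(meta["normalizer"]),
                   arrays)

    def build_generator(self) -> Generator:
        gen = Generator(self.gen_config)
        gen.load_state(self.arrays)
        return gen


def _to_signed(images_u8: np.ndarray) -> np.ndarray:
    """uint8 HxWx3 stack -> float32 NCHW in [-1, 1]."""
    x = images_u8.astype(F32) / 127.5 - 1.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _downscale(x: np.ndarray, factor: int) -> np.ndarray:
    """Area-averaged downscale of an NCHW batch by a power-of-two factor."""
    if factor == 1:
        return x
    n, c, h, w = x.shape
    return x.reshape(n, c, h // factor, factor,
                     w // factor, factor).mean(axis=(3, 5))


def train(manifest: DatasetManifest,
          gen_config: GeneratorConfig | None = None,
          train_config: TrainConfig | None = None,
          out_dir: str | Path | None = None):
    """Train the conditional GAN on the manifest's training split.

    Returns ``(checkpoint, loss_log)`` where the log has one row per
    batch with the total discriminator and generator losses.  When
    ``out_dir`` is given, writes ``checkpoint.npz``, ``losses.csv`` and
    periodic snapshots.
    """
    cfg = train_config or TrainConfig()
    records = manifest.split_records("train")
    if not records:
        raise ValueError("empty train split")

    schema = manifest.schema
    if gen_config is None:
        gen_config = GeneratorConfig(cond_dim=len(schema.active))
    if gen_config.cond_dim != len(schema.active):
        raise ValueError("gen_config.cond_dim does not match schema.active")
    final_res = gen_config.stage_resolutions[-1]
    if final_res != manifest.target_resolution:
        raise ValueError(
            f"final stage resolution {final_res} does not match manifest "
            f"resolution {manifest.target_resolution}")

    reals_full = _to_signed(np.stack([r.rgb for r in records]))
    stage_reals = [
        _downscale(reals_full, manifest.target_resolution // res)
        for res in gen_config.stage_resolutions
    ]
    conditions = manifest.normalizer.transform(
        manifest.trait_matrix("train", schema.active),
        schema.active).astype(F32)

    gen = Generator(gen_config)
    discs = [Discriminator(res, gen_config.cond_dim,
                           gen_config.base_channels,
                           seed=gen_config.seed + 1000 + k)
             for k, res in enumerate(gen_config.stage_resolutions)]
    g_opt, d_opt = make_optimizers(gen, discs, cfg.lr, cfg.beta_1,
                                   cfg.beta_2, cfg.epsilon)

    rng = np.random.default_rng(cfg.seed)
    n = len(records)
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for b_idx, start in enumerate(range(0, n, cfg.batch_size)):
            idx = order[start:start + cfg.batch_size]
            nb = idx.size
            c = conditions[idx]
            c_mis = np.roll(c, 1, axis=0)
            z = rng.standard_normal((nb, gen_config.z_dim)).astype(F32)

            gen_out = gen.forward(z, c, train=True)

            # --- discriminator step (all stages) ---
            d_opt.zero_grad()
            d_loss = 0.0
            for k, disc in enumerate(discs):
                real = stage_reals[k][idx]
                o = disc.forward(real, c, train=True)
                lu, gu = bce_with_logits(o.uncond_logit, 1.0)
                lc, gc = bce_with_logits(o.cond_logit, 1.0)
                disc.backward(gu, gc)
                d_loss += lu + lc
                if cfg.w_mis != 0.0 and nb > 1:
                    o = disc.forward(real, c_mis, train=True)
                    lm, gm = bce_with_logits(o.cond_logit, 0.0)
                    disc.backward(np.zeros_like(o.uncond_logit),
                                  cfg.w_mis * gm)
                    d_loss += cfg.w_mis * lm
                o = disc.forward(gen_out.images[k], c, train=True)
                lu, gu = bce_with_logits(o.uncond_logit, 0.0)
                lc, gc = bce_with_logits(o.cond_logit, 0.0)
                disc.backward(gu, gc)
                d_loss += lu + lc
            d_opt.step()

            # --- generator step ---
            g_opt.zero_grad()
            g_loss = 0.0
            image_grads = []
            for k, disc in enumerate(discs):
                o = disc.forward(gen_out.images[k], c, train=True)
                lu, gu = bce_with_logits(o.uncond_logit, 1.0)
                lc, gc = bce_with_logits(o.cond_logit, 1.0)
                image_grads.append(disc.backward(gu, gc))
                g_loss += lu + lc
            gen.backward(image_grads)
            g_opt.step()

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} batch {b_idx}: "
                    f"d={d_loss}, g={g_loss}")
            rows.append({"epoch": epoch, "batch": b_idx,
                         "d_loss": d_loss, "g_loss": g_loss})

        if out is not None and cfg.snapshot_every \
                and (epoch + 1) % cfg.snapshot_every == 0:
            Checkpoint(gen_config, schema, manifest.normalizer,
                       gen.state_arrays()).save(
                out / f"checkpoint_epoch{epoch + 1:04d}.npz")

    checkpoint = Checkpoint(gen_config, schema, manifest.normalizer,
                            [a.copy() for a in gen.state_arrays()])
    log = pd.DataFrame(rows)
    if out is not None:
        checkpoint.save(out / "checkpoint.npz")
        log.to_csv(out / "losses.csv", index=False)
    return checkpoint, log


def generate(checkpoint: Checkpoint, trait_table, seed: int = 0,
             batch_size: int = 32) -> np.ndarray:
    """Generate one final-stage image per row of a raw trait table.

    ``trait_table`` is a DataFrame (or CSV path) whose columns must be
    exactly the checkpoint schema's active traits.  Rows are normalized
    with the stored min-max state, noise is drawn from the given seed,
    and final-stage images are returned as a uint8 (N, H, W, 3) stack.
    """
    if isinstance(trait_table, (str, Path)):
        trait_table = pd.read_csv(trait_table)
    active = list(checkpoint.schema.active)
    missing = [c for c in active if c not in trait_table.columns]
    extra = [c for c in trait_table.columns if c not in active]
    if missing or extra:
        raise ValueError(
            f"trait table mismatch: missing columns {missing}, "
            f"unexpected columns {extra}")

    raw = trait_table[active].to_numpy(dtype=float)
    cond = checkpoint.normalizer.transform(raw, active).astype(F32)
    gen = checkpoint.build_generator()
    rng = np.random.default_rng(seed)
    out = []
    for start in range(0, cond.shape[0], batch_size):
        c = cond[start:start + batch_size]
        z = rng.standard_normal((c.shape[0],
                                 checkpoint.gen_config.z_dim)).astype(F32)
        images = gen.forward(z, c, train=False).images[-1]
        u8 = np.clip(np.rint((images + 1.0) * 127.5), 0, 255).astype(np.uint8)
        out.append(u8.transpose(0, 2, 3, 1))
    return np.concatenate(out, axis=0)
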