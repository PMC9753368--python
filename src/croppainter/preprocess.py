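"""Dataset preparation: crop, center, resize, split, normalize.

The pipeline mirrors how phenotyping-platform images are prepared for a
generative model: each plant is cropped to the minimal bounding
rectangle of its mask, centered on a square canvas whose side M is the
dataset-wide maximum bounding-box side, resized to the model
resolution, and split at random into training and testing sets.  Traits
are extracted from the resized image/mask pair so that trait scales
match exactly what the generative model sees; the min-max normalizer
that maps each trait to [0, 1] is fitted on the training split only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .traits import TraitSchema, TraitVector, extract_traits

__all__ = ["CropImageRecord", "DatasetManifest", "MinMaxNormalizer",
           "center_on_canvas", "build_dataset", "build_dataset_from_dirs"]


def _bbox(mask: np.ndarray):
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty foreground")
    return rows[0], rows[-1] + 1, cols[0], cols[-1] + 1


def center_on_canvas(rgb: np.ndarray, mask: np.ndarray, m: int):
    """Center the mask's bounding-box content on an M x M black canvas.

    The crop is placed with top-left offset (floor((M-h)/2),
    floor((M-w)/2)); content pixels are copied bit-identically.
    """
    mask = np.asarray(mask) > 0
    r0, r1, c0, c1 = _bbox(mask)
    h, w = r1 - r0, c1 - c0
    if h > m:
        raise ValueError(f"bounding-box height {h} exceeds canvas M={m}")
    if w > m:
        raise ValueError(f"bounding-box width {w} exceeds canvas M={m}")
    top, left = (m - h) // 2, (m - w) // 2
    out_rgb = np.zeros((m, m, 3), dtype=np.asarray(rgb).dtype)
    out_mask = np.zeros((m, m), dtype=bool)
    out_rgb[top:top + h, left:left + w] = np.asarray(rgb)[r0:r1, c0:c1]
    out_mask[top:top + h, left:left + w] = mask[r0:r1, c0:c1]
    return out_rgb, out_mask


def _resize(rgb: np.ndarray, mask: np.ndarray, side: int):
    """Bilinear resize for rgb, nearest for mask (masks stay binary)."""
    img = Image.fromarray(rgb).resize((side, side), Image.BILINEAR)
    msk = Image.fromarray(mask.astype(np.uint8) * 255).resize(
        (side, side), Image.NEAREST)
    return np.asarray(img), np.asarray(msk) > 0


@dataclass
class MinMaxNormalizer:
    """Per-trait linear rescaling to [0, 1], fitted on the training split.

    Out-of-range values at test time are clamped into [0, 1] so unseen
    extremes cannot leave the condition domain the model was trained
    on; a constant trait (max == min) maps to 0.
    """

    names: tuple[str, ...] = ()
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    def fit(self, matrix: np.ndarray, names) -> "MinMaxNormalizer":
        matrix = np.asarray(matrix, dtype=float)
        self.names = tuple(names)
        self.mins = matrix.min(axis=0)
        self.maxs = matrix.max(axis=0)
        return self

    def _check(self, names):
        if self.mins is None:
            raise ValueError("normalizer is not fitted")
        if tuple(names) != self.names:
            raise ValueError(
                f"schema mismatch: normalizer fitted on {self.names}, "
                f"got {tuple(names)}")

    def transform(self, matrix: np.ndarray, names=None) -> np.ndarray:
        self._check(names if names is not None else self.names)
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        span = self.maxs - self.mins
        out = np.zeros_like(matrix)
        ok = span > 0
        out[:, ok] = (matrix[:, ok] - self.mins[ok]) / span[ok]
        return np.clip(out, 0.0, 1.0)

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        self._check(self.names)
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        return self.mins + matrix * (self.maxs - self.mins)

    def to_dict(self) -> dict:
        return {"names": list(self.names),
                "mins": [float(v) for v in self.mins],
                "maxs": [float(v) for v in self.maxs]}

    @classmethod
    def from_dict(cls, d: dict) -> "MinMaxNormalizer":
        return cls(tuple(d["names"]), np.array(d["mins"], dtype=float),
                   np.array(d["maxs"], dtype=float))


@dataclass
class CropImageRecord:
    image_id: str
    rgb: np.ndarray
    mask: np.ndarray
    traits: TraitVector
    split: str  # "train" | "test"


@dataclass
class DatasetManifest:
    """Prepared dataset: centered/resized records plus normalizer state."""

    records: list[CropImageRecord]
    canvas_m: int
    target_resolution: int
    schema: TraitSchema
    normalizer: MinMaxNormalizer
    seed: int

    def split_records(self, split: str) -> list[CropImageRecord]:
        return [r for r in self.records if r.split == split]

    def trait_matrix(self, split: str | None = None,
                     names=None) -> np.ndarray:
        names = tuple(names) if names is not None else self.schema.active
        recs = self.records if split is None else self.split_records(split)
        return np.array([r.traits.as_array(names) for r in recs])

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        rows = []
        for r in self.records:
            Image.fromarray(r.rgb).save(out / "images" / f"{r.image_id}.png")
            Image.fromarray(r.mask.astype(np.uint8) * 255).save(
                out / "masks" / f"{r.image_id}.png")
            row = {"image_id": r.image_id, "split": r.split}
            row.update({n: r.traits.values[n]
                        for n in self.schema.ordered_names})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "traits.csv", index=False)
        meta = {
            "canvas_M": self.canvas_m,
            "target_resolution": self.target_resolution,
            "schema": self.schema.to_dict(),
            "normalizer": self.normalizer.to_dict(),
            "seed": self.seed,
        }
        (out / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "DatasetManifest":
        src = Path(in_dir)
        meta = json.loads((src / "meta.json").read_text())
        schema = TraitSchema.from_dict(meta["schema"])
        table = pd.read_csv(src / "traits.csv")
        records = []
        for _, row in table.iterrows():
            image_id = row["image_id"]
            rgb = np.asarray(Image.open(src / "images" / f"{image_id}.png")
                             .convert("RGB"))
            mask = np.asarray(Image.open(src / "masks" / f"{image_id}.png")
                              .convert("L")) > 0
            traits = TraitVector({n: float(row[n])
                                  for n in schema.ordered_names})
            records.append(CropImageRecord(image_id, rgb, mask, traits,
                                           row["split"]))
        return cls(records, int(meta["canvas_M"]),
                   int(meta["target_resolution"]), schema,
                   MinMaxNormalizer.from_dict(meta["normalizer"]),
                   int(meta["seed"]))


def split_ids(ids, test_fraction: float, seed: int):
    """Deterministic train/test membership from (ids, fraction, seed)."""
    ids = list(ids)
    order = np.random.default_rng(seed).permutation(len(ids))
    n_test = int(round(len(ids) * test_fraction))
    test = {ids[i] for i in order[:n_test]}
    return {i: ("test" if i in test else "train") for i in ids}


def build_dataset(images, schema: TraitSchema | None = None,
                  target_resolution: int = 256,
                  test_fraction: float = 0.17,
                  seed: int = 0) -> DatasetManifest:
    """Build a manifest from ``(image_id, rgb, mask)`` triples.

    Computes the dataset-wide canvas side M (max bounding-box side over
    all masks), centers every plant on an M x M canvas, resizes to the
    target resolution, extracts traits from the resized pair, splits by
    a seeded shuffle, and fits the min-max normalizer on the training
    split only.
    """
    if schema is None:
        schema = TraitSchema.full()
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    empty = [i for i, _, m in images if not (np.asarray(m) > 0).any()]
    if empty:
        raise ValueError(f"empty foreground for image(s): {empty}")

    canvas_m = 0
    for _, _, mask in images:
        r0, r1, c0, c1 = _bbox(np.asarray(mask) > 0)
        canvas_m = int(max(canvas_m, r1 - r0, c1 - c0))

    membership = split_ids([i for i, _, _ in images], test_fraction, seed)
    records = []
    for image_id, rgb, mask in images:
        c_rgb, c_mask = center_on_canvas(np.asarray(rgb),
                                         np.asarray(mask) > 0, canvas_m)
        r_rgb, r_mask = _resize(c_rgb, c_mask, target_resolution)
        traits = extract_traits(r_rgb, r_mask, schema)
        records.append(CropImageRecord(image_id, r_rgb, r_mask, traits,
                                       membership[image_id]))

    manifest = DatasetManifest(records, canvas_m, target_resolution,
                               schema, MinMaxNormalizer(), seed)
    train_matrix = manifest.trait_matrix("train", schema.active)
    if train_matrix.size == 0:
        raise ValueError("training split is empty; lower test_fraction")
    manifest.normalizer.fit(train_matrix, schema.active)
    return manifest


def build_dataset_from_dirs(images_dir, masks_dir, **kwargs):
    """Build a manifest from paired PNG/JPEG directories (matched by stem)."""
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    triples = []
    for path in sorted(images_dir.iterdir()):
        if path.suffix.lower() not in (".png", ".jpg", ".jpeg"):
            continue
        mask_path = masks_dir / f"{path.stem}.png"
        rgb = np.asarray(Image.open(path).convert("RGB"))
        mask = np.asarray(Image.open(mask_path).convert("L")) > 0
        triples.append((path.stem, rgb, mask))
    return build_dataset(triples, **kwargs)
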