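"""Seeded procedural generator of plant-like image/mask fixtures.

Renders single-plant silhouettes — a vertical stem with alternating
side branches, two levels deep — as green/yellow foreground on a black
background.  Strokes are rasterized without anti-aliasing so the mask
is exactly binary and pixel counts (TPA, P, bounding box) are
integer-exact and hand-checkable.  Two-level branching is the cheapest
geometry that moves the shape ratios (TBR, THR, PAR) and the fractal
dimension away from their degenerate values, and the per-segment
green/yellow switch drives the color traits.

Every function is deterministic given its seed, so datasets can be
regenerated bit-identically instead of being stored.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["PlantParams", "render_plant", "generate_dataset",
           "DEFAULT_PARAM_RANGES"]


@dataclass(frozen=True)
class PlantParams:
    """Parameters of one rendered plant silhouette.

    canvas: square canvas side in pixels (>= 32)
    n_branches: first-level branch count (>= 0)
    branch_angle_spread: branch angle from the stem axis, degrees
    stem_height_frac: stem height as a fraction of the canvas side
    stroke_width: brush width in pixels (>= 1)
    leaf_length_frac: first-level branch length as a canvas fraction
    yellow_fraction: per-segment probability of yellow coloring
    hue_jitter: uniform hue perturbation per segment, degrees
    seed: RNG seed controlling every random choice
    """

    canvas: int = 96
    n_branches: int = 5
    branch_angle_spread: float = 45.0
    stem_height_frac: float = 0.7
    stroke_width: int = 2
    leaf_length_frac: float = 0.35
    yellow_fraction: float = 0.2
    hue_jitter: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        if self.canvas < 32:
            raise ValueError("canvas must be at least 32 pixels")
        if self.stroke_width < 1:
            raise ValueError("stroke_width must be at least 1 pixel")
        if self.n_branches < 0:
            raise ValueError("n_branches must be non-negative")
        for name in ("stem_height_frac", "leaf_length_frac",
                     "yellow_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def _stroke_points(r0, c0, r1, c1):
    """Integer pixel coordinates along the segment, no anti-aliasing."""
    n = int(max(abs(r1 - r0), abs(c1 - c0))) * 2 + 1
    rr = np.rint(np.linspace(r0, r1, n)).astype(int)
    cc = np.rint(np.linspace(c0, c1, n)).astype(int)
    return rr, cc


def _paint(mask, seg_id, rr, cc, width, label):
    """Stamp a width x width brush at every point; record segment id."""
    size = mask.shape[0]
    for dr in range(width):
        for dc in range(width):
            r = np.clip(rr + dr, 0, size - 1)
            c = np.clip(cc + dc, 0, size - 1)
            mask[r, c] = True
            seg_id[r, c] = label


def _segment_color(rng, yellow_fraction, hue_jitter):
    """Per-segment HSV color: green near 120 deg or yellow near 40 deg."""
    if rng.random() < yellow_fraction:
        hue = 40.0 + rng.uniform(-hue_jitter, hue_jitter)
        hue = float(np.clip(hue, 22.0, 58.0))
    else:
        hue = 120.0 + rng.uniform(-hue_jitter, hue_jitter)
        hue = float(np.clip(hue, 62.0, 178.0))
    sat = rng.uniform(0.75, 0.95)
    val = rng.uniform(0.55, 0.9)
    r, g, b = colorsys.hsv_to_rgb(hue / 360.0, sat, val)
    return np.array([round(r * 255), round(g * 255), round(b * 255)],
                    dtype=np.uint8)


def render_plant(params: PlantParams):
    """Render one plant; returns ``(rgb uint8 HxWx3, mask bool HxW)``.

    The mask equals ``rgb != black`` exactly: every painted pixel gets a
    color whose HSV value is at least 0.55, so no drawn pixel rounds to
    black.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.canvas
    mask = np.zeros((size, size), dtype=bool)
    seg_id = np.full((size, size), -1, dtype=np.int32)

    sw = params.stroke_width
    base_row = size - 3
    stem_h = max(sw, round(params.stem_height_frac * (size - 6)))
    top_row = base_row - stem_h + 1
    stem_col = size // 2

    segments = []
    rr, cc = _stroke_points(base_row, stem_col, top_row, stem_col)
    _paint(mask, seg_id, rr, cc, sw, len(segments))
    segments.append("stem")

    # First-level branches alternate sides along the upper part of the
    # stem; each spawns two shorter second-level branches.
    for i in range(params.n_branches):
        frac = 0.25 + 0.7 * (i + 1) / (params.n_branches + 1)
        br = base_row - round(frac * (stem_h - 1))
        side = 1 if i % 2 == 0 else -1
        angle = np.deg2rad(params.branch_angle_spread
                           * rng.uniform(0.6, 1.0))
        length = params.leaf_length_frac * size * rng.uniform(0.7, 1.0)
        er = br - length * np.cos(angle)
        ec = stem_col + side * length * np.sin(angle)
        rr, cc = _stroke_points(br, stem_col, er, ec)
        _paint(mask, seg_id, rr, cc, sw, len(segments))
        segments.append(f"branch{i}")

        for t, rel in ((0.45, 0.55), (0.8, 0.45)):
            sr = br + t * (er - br)
            sc = stem_col + t * (ec - stem_col)
            sub_angle = angle + side * np.deg2rad(rng.uniform(15.0, 35.0))
            sub_len = rel * length
            srr, scc = _stroke_points(
                sr, sc,
                sr - sub_len * np.cos(sub_angle),
                sc + side * sub_len * np.sin(sub_angle))
            _paint(mask, seg_id, srr, scc, max(1, sw - 1), len(segments))
            segments.append(f"branch{i}.sub")

    rgb = np.zeros((size, size, 3), dtype=np.uint8)
    for label in range(len(segments)):
        color = _segment_color(rng, params.yellow_fraction,
                               params.hue_jitter)
        rgb[seg_id == label] = color
    return rgb, mask


#: Default sampling ranges; chosen so that all 18 traits vary across a
#: moderately sized dataset (branching drives shape/fractal traits, the
#: yellow fraction drives the color traits).
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "n_branches": (2, 9),
    "branch_angle_spread": (20.0, 70.0),
    "stem_height_frac": (0.45, 0.95),
    "stroke_width": (1, 3),
    "leaf_length_frac": (0.2, 0.5),
    "yellow_fraction": (0.0, 0.5),
    "hue_jitter": (0.0, 12.0),
}


def sample_params(rng: np.random.Generator, canvas: int = 96,
                  param_ranges: dict | None = None) -> PlantParams:
    """Draw one PlantParams uniformly from the given ranges."""
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    return PlantParams(
        canvas=canvas,
        n_branches=int(rng.integers(int(ranges["n_branches"][0]),
                                    int(ranges["n_branches"][1]) + 1)),
        branch_angle_spread=float(rng.uniform(*ranges["branch_angle_spread"])),
        stem_height_frac=float(rng.uniform(*ranges["stem_height_frac"])),
        stroke_width=int(rng.integers(int(ranges["stroke_width"][0]),
                                      int(ranges["stroke_width"][1]) + 1)),
        leaf_length_frac=float(rng.uniform(*ranges["leaf_length_frac"])),
        yellow_fraction=float(rng.uniform(*ranges["yellow_fraction"])),
        hue_jitter=float(rng.uniform(*ranges["hue_jitter"])),
        seed=int(rng.integers(2**31)),
    )


def generate_dataset(n: int, param_ranges: dict | None = None,
                     seed: int = 0, canvas: int = 96,
                     out_dir: str | Path | None = None):
    """Render ``n`` plants with a master seed.

    Returns a list of ``(image_id, rgb, mask, params)``.  When
    ``out_dir`` is given, writes ``images/<id>.png``, ``masks/<id>.png``
    and a ``params.json`` provenance file recording every sampled
    parameter set.  Masks are guaranteed nonempty (the stem is always
    drawn).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    master = np.random.default_rng(seed)
    records = []
    for i in range(n):
        params = sample_params(master, canvas=canvas,
                               param_ranges=param_ranges)
        rgb, mask = render_plant(params)
        assert mask.any()
        records.append((f"plant_{i:05d}", rgb, mask, params))

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        provenance = {}
        for image_id, rgb, mask, params in records:
            Image.fromarray(rgb).save(out / "images" / f"{image_id}.png")
            Image.fromarray((mask * np.uint8(255))).save(
                out / "masks" / f"{image_id}.png")
            provenance[image_id] = asdict(params)
        (out / "params.json").write_text(json.dumps(provenance, indent=1))
    return records
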