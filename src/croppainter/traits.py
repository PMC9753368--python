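"""Phenotypic trait extraction from segmented crop images.

Eighteen traits describe one plant silhouette: six intensity-histogram
texture statistics (M, SE, S, MU3, U, E), eight morphology descriptors
(TPA, H, W, TBR, CBA, THR, PAR, P plus the derived fractal dimension
FDIC), and three color descriptors (GPA, YPA, YTR).  All traits are
computed from an RGB image together with a binary foreground mask;
segmentation itself is upstream of this module.

Texture statistics are computed over foreground pixels only, with
intensities rescaled to [0, 1], so that the black background cannot
dominate the histogram and the moment-based statistics are stable under
intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.morphology import convex_hull_image

__all__ = [
    "TRAIT_NAMES",
    "TraitSchema",
    "TraitVector",
    "EmptyForegroundError",
    "histogram_stats",
    "morphology_traits",
    "fractal_dimension",
    "color_traits",
    "extract_traits",
]

#: Canonical trait order, serialized with every dataset and checkpoint.
TRAIT_NAMES = (
    "M", "SE", "S", "MU3", "U", "E",
    "TPA", "H", "W", "TBR", "CBA", "THR", "PAR", "FDIC", "P",
    "GPA", "YPA", "YTR",
)

#: Traits dropped for crops with essentially no yellow tissue.
NO_YELLOW_DROPPED = ("YPA", "YTR")


class EmptyForegroundError(ValueError):
    """Raised when a mask contains no foreground pixels."""


@dataclass(frozen=True)
class TraitSchema:
    """Ordered trait names plus the active subset used for conditioning.

    The full schema keeps all 18 traits; the ``no-yellow`` schema drops
    YPA and YTR (appropriate for crops whose images contain almost no
    yellow components), leaving 16 active traits.
    """

    ordered_names: tuple[str, ...] = TRAIT_NAMES
    active: tuple[str, ...] = TRAIT_NAMES

    def __post_init__(self) -> None:
        if not set(self.active) <= set(self.ordered_names):
            raise ValueError("active traits must be a subset of ordered_names")

    @classmethod
    def full(cls) -> "TraitSchema":
        return cls()

    @classmethod
    def no_yellow(cls) -> "TraitSchema":
        names = tuple(n for n in TRAIT_NAMES if n not in NO_YELLOW_DROPPED)
        return cls(ordered_names=names, active=names)

    @classmethod
    def named(cls, name: str) -> "TraitSchema":
        if name == "full":
            return cls.full()
        if name in ("no-yellow", "no_yellow"):
            return cls.no_yellow()
        raise ValueError(f"unknown schema name: {name!r}")

    def to_dict(self) -> dict:
        return {"ordered_names": list(self.ordered_names),
                "active": list(self.active)}

    @classmethod
    def from_dict(cls, d: dict) -> "TraitSchema":
        return cls(tuple(d["ordered_names"]), tuple(d["active"]))


@dataclass(frozen=True)
class TraitVector:
    """The named phenotypic traits of one image."""

    values: dict[str, float] = field(default_factory=dict)

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    def as_array(self, names: tuple[str, ...] = TRAIT_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)


def _as_bool_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be a 2-D binary image")
    return mask > 0 if mask.dtype != bool else mask


def _require_nonempty(mask: np.ndarray) -> np.ndarray:
    mask = _as_bool_mask(mask)
    if not mask.any():
        raise EmptyForegroundError("empty foreground: mask has no on pixels")
    return mask


def histogram_stats(values, n_bins: int = 256):
    """Intensity-histogram texture statistics of a foreground region.

    The histogram uses ``n_bins`` equal-width bins over [0, 1]; each
    occupied bin is represented by the mean of the values it received,
    with probability ``p`` equal to its relative frequency.  Returns
    ``(M, SE, S, MU3, U, E)``:

    * ``M``   mean intensity, ``sum(z * p)``
    * ``SE``  standard deviation, ``sqrt(sum((z - M)^2 * p))``
    * ``S``   smoothness, ``1 - 1 / (1 + SE^2)``
    * ``MU3`` third central moment, ``sum((z - M)^3 * p)``
    * ``U``   uniformity, ``sum(p^2)``
    * ``E``   entropy in bits, ``-sum(p * log2(p))``
    """
    z = np.asarray(values, dtype=float).ravel()
    if z.size == 0:
        raise EmptyForegroundError("empty foreground: no intensity values")
    if z.min() < 0.0 or z.max() > 1.0:
        raise ValueError("intensity values must lie in [0, 1]")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")

    idx = np.minimum((z * n_bins).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=z, minlength=n_bins)
    occupied = counts > 0
    p = counts[occupied] / z.size
    centers = sums[occupied] / counts[occupied]

    m = float(np.sum(centers * p))
    var = float(np.sum((centers - m) ** 2 * p))
    se = float(np.sqrt(var))
    s = 1.0 - 1.0 / (1.0 + var)
    mu3 = float(np.sum((centers - m) ** 3 * p))
    u = float(np.sum(p**2))
    e = float(-np.sum(p * np.log2(p)))
    return m, se, s, mu3, u, e


def morphology_traits(mask: np.ndarray):
    """Morphological descriptors of a binary silhouette.

    Returns ``(TPA, H, W, CBA, TBR, THR, P, PAR)`` where TPA is the
    foreground pixel count, (H, W) the minimal axis-aligned bounding
    rectangle, CBA = H*W, TBR = TPA/CBA, THR = TPA over the pixel count
    of the filled convex hull, P the count of foreground pixels with at
    least one 4-connected background neighbour (the image border counts
    as background), and PAR = P/TPA.
    """
    mask = _require_nonempty(mask)
    tpa = int(mask.sum())
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    h = int(rows[-1] - rows[0] + 1)
    w = int(cols[-1] - cols[0] + 1)
    cba = h * w
    tbr = tpa / cba

    hull_area = int(convex_hull_image(mask).sum())
    thr = tpa / hull_area

    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1]
        & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    p = int((mask & ~interior).sum())
    par = p / tpa
    return tpa, h, w, cba, tbr, thr, p, par


def fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting fractal dimension with image cropping (FDIC).

    The mask is cropped to its bounding box, padded to the next
    power-of-two square, and occupied boxes N(s) are counted for box
    sizes s = 1, 2, 4, ..., side/2.  FDIC is the slope of the
    least-squares fit of log N(s) against log(1/s).  A bounding box too
    small to support the fit (side < 4 after padding) returns 0.0 by
    convention.
    """
    mask = _require_nonempty(mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    crop = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]

    side = 1 << int(np.ceil(np.log2(max(crop.shape))))
    if side < 4:
        return 0.0
    box = np.zeros((side, side), dtype=bool)
    box[:crop.shape[0], :crop.shape[1]] = crop

    sizes = []
    counts = []
    s = 1
    while s <= side // 2:
        n = side // s
        occupied = box.reshape(n, s, n, s).any(axis=(1, 3)).sum()
        sizes.append(s)
        counts.append(int(occupied))
        s *= 2
    slope, _ = np.polyfit(np.log(1.0 / np.array(sizes, dtype=float)),
                          np.log(np.array(counts, dtype=float)), 1)
    return float(slope)


def color_traits(rgb: np.ndarray, mask: np.ndarray,
                 sat_floor: float = 0.15, val_floor: float = 0.15):
    """Green/yellow projected areas and the TPA/YPA ratio.

    Foreground pixels are converted to HSV; GPA counts hue in
    [60°, 180°) and YPA hue in [20°, 60°), both restricted to pixels
    whose saturation and value exceed the configured floors.  The
    half-open hue intervals make boundary pixels unambiguous.  YTR is
    TPA / max(YPA, 1) — the guard keeps YTR finite for crops with no
    yellow tissue at all.
    """
    mask = _require_nonempty(mask)
    rgb = np.asarray(rgb)
    if rgb.shape[:2] != mask.shape:
        raise ValueError(
            f"rgb shape {rgb.shape[:2]} does not match mask shape {mask.shape}")
    hsv = rgb2hsv(_to_float_rgb(rgb))
    hue = hsv[..., 0][mask] * 360.0
    sat = hsv[..., 1][mask]
    val = hsv[..., 2][mask]
    vivid = (sat >= sat_floor) & (val >= val_floor)
    gpa = int(np.sum(vivid & (hue >= 60.0) & (hue < 180.0)))
    ypa = int(np.sum(vivid & (hue >= 20.0) & (hue < 60.0)))
    tpa = int(mask.sum())
    ytr = tpa / max(ypa, 1)
    return gpa, ypa, ytr


def _to_float_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("rgb must be an HxWx3 color image")
    if rgb.dtype == np.uint8:
        return rgb.astype(float) / 255.0
    return rgb.astype(float)


def extract_traits(rgb: np.ndarray, mask: np.ndarray,
                   schema: TraitSchema | None = None,
                   n_bins: int = 256) -> TraitVector:
    """Compute every trait named by ``schema.ordered_names``.

    Texture statistics use the grayscale conversion of ``rgb``
    restricted to the mask; morphology and FDIC use the mask alone;
    color traits use the HSV conversion of the foreground.
    Deterministic for fixed inputs.
    """
    if schema is None:
        schema = TraitSchema.full()
    mask = _require_nonempty(mask)
    rgbf = _to_float_rgb(rgb)
    if rgbf.shape[:2] != mask.shape:
        raise ValueError("rgb and mask dimensions differ")

    gray = rgb2gray(rgbf)
    m, se, s, mu3, u, e = histogram_stats(np.clip(gray[mask], 0.0, 1.0),
                                          n_bins=n_bins)
    tpa, hh, ww, cba, tbr, thr, p, par = morphology_traits(mask)
    fdic = fractal_dimension(mask)
    gpa, ypa, ytr = color_traits(rgbf, mask)

    values = {
        "M": m, "SE": se, "S": s, "MU3": mu3, "U": u, "E": e,
        "TPA": float(tpa), "H": float(hh), "W": float(ww),
        "TBR": tbr, "CBA": float(cba), "THR": thr, "PAR": par,
        "FDIC": fdic, "P": float(p),
        "GPA": float(gpa), "YPA": float(ypa), "YTR": ytr,
    }
    return TraitVector({n: values[n] for n in schema.ordered_names})
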