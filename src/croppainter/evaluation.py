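"""Fidelity and prediction-accuracy evaluation.

Visual fidelity combines the structural similarity index (SSIM, in its
global-statistics form: one mean/variance/covariance per image, no
sliding window) and the Fréchet distance between Gaussian fits of real
and generated image features (FID).  Prediction accuracy re-extracts
phenotypic traits from the generated images and reports per-trait
Pearson correlation against the input traits plus a per-sample cosine
similarity computed on min-max-normalized trait vectors — raw traits
span several orders of magnitude (pixel areas vs dimensionless ratios),
which would make the raw cosine saturate near 1 regardless of quality.

The FID feature extractor is pluggable.  The default "pixel" extractor
(8x8 area-averaged grayscale, 64 features) is deterministic and needs
no pretrained weights; FID values are therefore only comparable within
one extractor, never across extractors.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.morphology import remove_small_objects
from skimage.transform import resize as _sk_resize

from .preprocess import DatasetManifest
from .train import Checkpoint, generate
from .traits import EmptyForegroundError, TraitSchema, extract_traits

__all__ = ["FeatureStats", "EvalReport", "ssim", "fid", "embed",
           "trait_correlation", "cosine_similarity", "assemble_report",
           "evaluate", "mask_from_image"]


@dataclass(frozen=True)
class FeatureStats:
    """Gaussian summary of an image set in feature space."""

    mu: np.ndarray
    sigma: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 samples")
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma shape does not match mu")


@dataclass
class EvalReport:
    ssim_mean: float
    ssim_sd: float
    fid: float
    corr_per_trait: dict[str, float]
    corr_mean: float
    corr_sd: float
    cosine_mean: float
    cosine_sd: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def _to_gray(img: np.ndarray) -> np.ndarray:
    """Plain channel average; SSIM and the pixel extractor use this."""
    img = np.asarray(img, dtype=float)
    return img.mean(axis=-1) if img.ndim == 3 else img


def ssim(x: np.ndarray, y: np.ndarray, dynamic_range: float = 255.0,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Global-statistics structural similarity of two images.

    ``(2 mu_x mu_y + c1)(2 sigma_xy + c2) /
    ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))`` with
    c1 = (k1 L)^2, c2 = (k2 L)^2 and means/variances/covariance taken
    over all pixels at once.
    """
    gx, gy = _to_gray(x), _to_gray(y)
    if gx.shape != gy.shape:
        raise ValueError(f"image shapes differ: {gx.shape} vs {gy.shape}")
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    mx, my = gx.mean(), gy.mean()
    vx, vy = gx.var(), gy.var()
    cov = ((gx - mx) * (gy - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2))
                 / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def _sqrt_trace(sigma_a: np.ndarray, sigma_b: np.ndarray) -> float:
    """tr((sigma_a sigma_b)^{1/2}) via symmetric eigendecompositions."""
    vals_b, vecs_b = np.linalg.eigh(sigma_b)
    if vals_b.min() < -1e-6 * max(1.0, abs(vals_b.max())):
        raise ValueError("covariance is not positive semi-definite")
    root_b = (vecs_b * np.sqrt(np.clip(vals_b, 0.0, None))) @ vecs_b.T
    inner = root_b @ sigma_a @ root_b
    inner = (inner + inner.T) / 2.0
    vals = np.linalg.eigvalsh(inner)
    return float(np.sum(np.sqrt(np.clip(vals, 0.0, None))))


def fid(a: FeatureStats, b: FeatureStats) -> float:
    """Fréchet distance between two Gaussian feature summaries.

    ``|mu_a - mu_b|^2 + tr(sigma_a + sigma_b - 2 (sigma_a sigma_b)^{1/2})``.
    Negative eigenvalues from numerical noise are clipped at zero.
    """
    if a.mu.size != b.mu.size:
        raise ValueError("feature dimensions differ")
    diff = float(np.sum((a.mu - b.mu) ** 2))
    value = diff + float(np.trace(a.sigma) + np.trace(b.sigma)) \
        - 2.0 * _sqrt_trace(a.sigma, b.sigma)
    return max(value, 0.0)


def pixel_features(images) -> np.ndarray:
    """8x8 area-averaged grayscale features (64 per image)."""
    feats = []
    for img in images:
        g = _to_gray(img)
        h, w = g.shape
        if h % 8 == 0 and w % 8 == 0:
            f = g.reshape(8, h // 8, 8, w // 8).mean(axis=(1, 3))
        else:
            f = _sk_resize(g, (8, 8), anti_aliasing=True,
                           preserve_range=True)
        feats.append(f.ravel())
    return np.array(feats)


def embed(images, extractor="pixel") -> FeatureStats:
    """Gaussian fit (mean, covariance) of extracted image features.

    ``extractor`` is either the name "pixel" or any callable mapping an
    image sequence to an (n, d) feature matrix — e.g. a pretrained deep
    embedding when its weights are available.
    """
    images = list(images)
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    if extractor == "pixel":
        fn = pixel_features
    elif extractor == "inception":
        raise ValueError(
            "the inception extractor needs pretrained weights: pass the "
            "embedding as a callable returning an (n, d) feature matrix")
    else:
        fn = extractor
    if not callable(fn):
        raise ValueError(f"unknown extractor: {extractor!r}")
    feats = np.asarray(fn(images), dtype=float)
    mu = feats.mean(axis=0)
    sigma = np.cov(feats, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    return FeatureStats(mu=mu, sigma=(sigma + sigma.T) / 2.0,
                        n=feats.shape[0])


def trait_correlation(real: np.ndarray, virtual: np.ndarray):
    """Per-trait (column-wise) Pearson correlation.

    Columns with zero variance on either side yield NaN ("missing");
    the returned mean and sd are taken over the defined columns.
    """
    real = np.asarray(real, dtype=float)
    virtual = np.asarray(virtual, dtype=float)
    if real.shape != virtual.shape:
        raise ValueError(f"shapes differ: {real.shape} vs {virtual.shape}")
    if real.shape[0] < 3:
        raise ValueError("need at least 3 samples per trait")
    rc = real - real.mean(axis=0)
    vc = virtual - virtual.mean(axis=0)
    num = (rc * vc).sum(axis=0)
    den = np.sqrt((rc**2).sum(axis=0) * (vc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    valid = r[np.isfinite(r)]
    mean = float(valid.mean()) if valid.size else float("nan")
    sd = float(valid.std(ddof=0)) if valid.size else float("nan")
    return r, mean, sd


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of the angle between two trait vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vector lengths differ")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(x, y) / (nx * ny))


def mask_from_image(rgb: np.ndarray, threshold: int = 10,
                    min_object: int = 16) -> np.ndarray:
    """Foreground mask of a generated image by intensity thresholding.

    A pixel is foreground when any channel exceeds ``threshold``.
    Connected components smaller than ``min_object`` pixels are then
    discarded as speckle: generated images carry isolated near-black
    noise pixels that contribute negligible area but would otherwise
    dominate the bounding-box traits (H, W, CBA).  ``min_object`` is
    well below the footprint of any rendered plant part, so genuine
    foreground fragments survive.  If cleanup empties the mask the raw
    threshold mask is returned instead.
    """
    mask = (np.asarray(rgb) > threshold).any(axis=-1)
    if min_object > 1 and mask.any():
        cleaned = remove_small_objects(mask, max_size=min_object - 1)
        if cleaned.any():
            return cleaned
    return mask


def _traits_or_nan(rgb, schema: TraitSchema) -> np.ndarray:
    try:
        mask = mask_from_image(rgb)
        return extract_traits(rgb, mask, schema).as_array(schema.active)
    except EmptyForegroundError:
        return np.full(len(schema.active), np.nan)


def assemble_report(real_images, virtual_images, real_traits,
                    virtual_traits, normalizer, schema: TraitSchema,
                    extractor="pixel") -> EvalReport:
    """Assemble the evaluation summary from paired real/virtual sets.

    ``real_traits``/``virtual_traits`` are raw (unnormalized) matrices
    over ``schema.active``.  SSIM is paired per record; FID compares the
    two sets; correlations are per trait; cosine similarity is per
    record on normalized traits.
    """
    real_images = list(real_images)
    virtual_images = list(virtual_images)
    ssims = np.array([ssim(r, v) for r, v
                      in zip(real_images, virtual_images)])
    fid_value = fid(embed(real_images, extractor),
                    embed(virtual_images, extractor))

    real_traits = np.asarray(real_traits, dtype=float)
    virtual_traits = np.asarray(virtual_traits, dtype=float)
    ok = np.isfinite(virtual_traits).all(axis=1)
    if ok.sum() >= 3:
        r, corr_mean, corr_sd = trait_correlation(real_traits[ok],
                                                  virtual_traits[ok])
    else:  # too few valid pairs for a correlation
        r = np.full(real_traits.shape[1], np.nan)
        corr_mean = corr_sd = float("nan")

    norm_real = normalizer.transform(real_traits, schema.active)
    norm_virt = np.full_like(norm_real, np.nan)
    norm_virt[ok] = normalizer.transform(virtual_traits[ok], schema.active)
    cosines = []
    for i in np.flatnonzero(ok):
        if np.linalg.norm(norm_real[i]) > 0 \
                and np.linalg.norm(norm_virt[i]) > 0:
            cosines.append(cosine_similarity(norm_real[i], norm_virt[i]))
    cosines = np.array(cosines)

    return EvalReport(
        ssim_mean=float(ssims.mean()), ssim_sd=float(ssims.std(ddof=0)),
        fid=fid_value,
        corr_per_trait={name: float(v)
                        for name, v in zip(schema.active, r)},
        corr_mean=corr_mean, corr_sd=corr_sd,
        cosine_mean=float(cosines.mean()) if cosines.size else float("nan"),
        cosine_sd=float(cosines.std(ddof=0)) if cosines.size else float("nan"),
    )


def evaluate(checkpoint: Checkpoint, manifest: DatasetManifest,
             seed: int = 0, extractor="pixel") -> EvalReport:
    """Full evaluation on the manifest's test split.

    Generates one virtual image per test record from its real traits,
    then scores paired SSIM, set-level FID, per-trait correlation of
    re-extracted virtual traits, and per-record cosine similarity.
    """
    import pandas as pd

    records = manifest.split_records("test")
    if not records:
        raise ValueError("empty test split")
    schema = checkpoint.schema
    real_traits = np.array([r.traits.as_array(schema.active)
                            for r in records])
    table = pd.DataFrame(real_traits, columns=list(schema.active))
    virtual = generate(checkpoint, table, seed=seed)

    final_res = checkpoint.gen_config.stage_resolutions[-1]
    real_images = []
    for rec in records:
        img = rec.rgb
        if img.shape[0] != final_res:
            img = np.asarray(_sk_resize(img.astype(float),
                                        (final_res, final_res),
                                        preserve_range=True))
        real_images.append(img)

    virtual_traits = np.array([_traits_or_nan(v, schema) for v in virtual])
    return assemble_report(real_images, list(virtual), real_traits,
                           virtual_traits, checkpoint.normalizer, schema,
                           extractor)
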