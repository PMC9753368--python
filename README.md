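# croppainter

Trait-conditioned crop image synthesis for plant phenotyping.

Plant phenotyping platforms measure quantitative traits — projected
area, bounding-box extent, shape ratios, texture statistics, color
areas, fractal dimension — from segmented plant images. `croppainter`
closes the loop in the other direction: it **paints** a plausible crop
image from a trait vector, so that breeders and phenotyping
researchers can visualize what a combination of measured (or
hypothetical) trait values looks like, and so that trait-prediction
accuracy of a generative model can be quantified by re-measuring the
generated images.

The package provides:

* **Trait extraction** — 18 phenotypic traits from an RGB image plus a
  binary foreground mask: texture (M, SE, S, MU3, U, E), morphology
  (TPA, H, W, TBR, CBA, THR, PAR, FDIC, P) and color (GPA, YPA, YTR);
  a 16-trait variant drops the yellow traits for crops without yellow
  tissue.
* **Dataset preparation** — bounding-box crop, dataset-wide M×M
  centering, resize, seeded train/test split, and min-max trait
  normalization fitted on the training split.
* **A multi-stage conditional GAN** — up to three generator stages at
  64/128/256 px. The normalized trait vector conditions every stage by
  channel concatenation (no stochastic condition embedding) and each
  stage's discriminator scores both realism and trait match. Runs on
  a compact, finite-difference-verified NumPy neural-network backend.
* **Evaluation** — paired SSIM (global form), Fréchet distance between
  feature Gaussians (pluggable extractor), per-trait Pearson
  correlation of re-extracted vs input traits, and per-image cosine
  similarity on normalized traits.
* **A procedural plant generator** — seeded branching silhouettes
  (green/yellow on black) whose masks are exactly binary, so the whole
  pipeline trains and tests at desk scale with no external data.

See `docs/methods.md` for the formulas, assumptions, defaults and
limitations.

## Worked example

Generate a synthetic dataset, train the desk preset (single 64×64
stage, ~6 min on one CPU core), and evaluate:

```sh
croppainter synth --n 500 --out data/ --seed 11
croppainter build --images data/images --masks data/masks \
    --out manifest/ --resolution 64 --test-frac 0.1 --seed 7
croppainter train --manifest manifest/ --out run/ --preset desk --seed 0
croppainter evaluate --checkpoint run/checkpoint.npz \
    --manifest manifest/ --out report.json
```

The evaluate step prints a summary like:

```json
{
 "ssim_mean": 0.3721083160179267,
 "fid": 2952.876574895141,
 "corr_mean": 0.5322475957018841,
 "cosine_mean": 0.8474952008393275
}
```

Reading these numbers: `ssim_mean` is the average structural
similarity between each held-out test image and the image generated
from its traits (1 = identical); `fid` is the Fréchet distance between
the real and generated sets under the deterministic pixel-feature
extractor (comparable only within that extractor, not to published
FIDs from deep embeddings); `corr_mean` averages the per-trait Pearson
correlation between input traits and traits re-measured on the
generated images; `cosine_mean` is the average cosine similarity of
normalized trait vectors. At desk scale the model learns coarse
conditional control — area-type traits correlate strongly (r ≈ 0.9
for TPA) while fine shape traits remain harder.

The same pipeline is available as library calls
(`croppainter.synthetic.generate_dataset`,
`croppainter.preprocess.build_dataset`, `croppainter.train.train`,
`croppainter.evaluation.evaluate`) — the CLI is a thin wrapper.

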