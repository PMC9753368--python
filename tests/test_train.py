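"""Training loop and generation: contracts, determinism, overfit oracle."""

import numpy as np
import pandas as pd
import pytest

from croppainter.evaluation import ssim
from croppainter.gan import Discriminator, Generator, GeneratorConfig, \
    make_optimizers
from croppainter.nn import bce_with_logits
from croppainter.preprocess import build_dataset
from croppainter.train import Checkpoint, TrainConfig, generate, train

TINY_GEN = dict(n_stages=1, base_resolution=64, z_dim=8, base_channels=8)


@pytest.fixture(scope="module")
def tiny_run(small_manifest, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    gc = GeneratorConfig(cond_dim=len(small_manifest.schema.active),
                         seed=0, **TINY_GEN)
    ckpt, log = train(small_manifest, gc,
                      TrainConfig(epochs=2, seed=0), out_dir=out)
    return ckpt, log, out


# conftest builds this fixture once per session; scope the manifest
# fixture through to module level
@pytest.fixture(scope="module")
def small_manifest(request):
    from croppainter.synthetic import generate_dataset
    plants = [(i, r, m) for i, r, m, _ in generate_dataset(30, seed=42)]
    return build_dataset(plants, target_resolution=64,
                         test_fraction=0.2, seed=7)


class TestTrainLoop:
    def test_smoke_checkpoint_and_finite_losses(self, tiny_run):
        ckpt, log, out = tiny_run
        assert (out / "checkpoint.npz").exists()
        assert (out / "losses.csv").exists()
        assert np.isfinite(log["d_loss"]).all()
        assert np.isfinite(log["g_loss"]).all()

    def test_log_length_is_epochs_times_batches(self, tiny_run,
                                                small_manifest):
        _, log, _ = tiny_run
        n_train = len(small_manifest.split_records("train"))
        per_epoch = int(np.ceil(n_train / 16))
        assert len(log) == 2 * per_epoch

    def test_same_seed_reproduces_loss_log(self, small_manifest):
        gc = GeneratorConfig(cond_dim=len(small_manifest.schema.active),
                             seed=0, **TINY_GEN)
        _, log_a = train(small_manifest, gc, TrainConfig(epochs=1, seed=3))
        _, log_b = train(small_manifest, gc, TrainConfig(epochs=1, seed=3))
        pd.testing.assert_frame_equal(log_a, log_b)

    def test_empty_train_split_rejected(self, small_manifest):
        import copy
        broken = copy.copy(small_manifest)
        broken.records = [r for r in small_manifest.records
                          if r.split == "test"]
        with pytest.raises(ValueError, match="train"):
            train(broken)


class TestStepIsolation:
    def test_generator_step_leaves_discriminator_unchanged(self, rng):
        gen = Generator(GeneratorConfig(cond_dim=4, seed=0, **TINY_GEN))
        disc = Discriminator(64, 4, 8, seed=1)
        g_opt, d_opt = make_optimizers(gen, [disc])
        z = rng.standard_normal((2, 8))
        c = rng.uniform(0, 1, (2, 4))

        d_before = [p.value.copy() for p in disc.params()]
        out = gen.forward(z, c, train=True)
        o = disc.forward(out.images[0], c, train=True)
        _, gu = bce_with_logits(o.uncond_logit, 1.0)
        _, gc_ = bce_with_logits(o.cond_logit, 1.0)
        g_img = disc.backward(gu, gc_)
        g_opt.zero_grad()
        gen.backward([g_img])
        g_opt.step()
        for before, p in zip(d_before, disc.params()):
            assert np.array_equal(before, p.value)

    def test_discriminator_step_leaves_generator_unchanged(self, rng):
        gen = Generator(GeneratorConfig(cond_dim=4, seed=0, **TINY_GEN))
        disc = Discriminator(64, 4, 8, seed=1)
        _, d_opt = make_optimizers(gen, [disc])
        c = rng.uniform(0, 1, (2, 4))
        real = rng.uniform(-1, 1, (2, 3, 64, 64)).astype(np.float32)

        g_before = [p.value.copy() for p in gen.params()]
        d_opt.zero_grad()
        o = disc.forward(real, c, train=True)
        _, gu = bce_with_logits(o.uncond_logit, 1.0)
        _, gc_ = bce_with_logits(o.cond_logit, 1.0)
        disc.backward(gu, gc_)
        d_opt.step()
        for before, p in zip(g_before, gen.params()):
            assert np.array_equal(before, p.value)


class TestGenerate:
    def trait_table(self, ckpt, n=5):
        rng = np.random.default_rng(0)
        lo, hi = ckpt.normalizer.mins, ckpt.normalizer.maxs
        raw = rng.uniform(lo, hi, (n, len(ckpt.schema.active)))
        return pd.DataFrame(raw, columns=list(ckpt.schema.active))

    def test_one_image_per_row_at_final_resolution(self, tiny_run):
        ckpt, _, _ = tiny_run
        images = generate(ckpt, self.trait_table(ckpt, 5), seed=1)
        assert images.shape == (5, 64, 64, 3)
        assert images.dtype == np.uint8

    def test_pure_function_of_checkpoint_table_seed(self, tiny_run):
        ckpt, _, _ = tiny_run
        table = self.trait_table(ckpt, 3)
        a = generate(ckpt, table, seed=5)
        b = generate(ckpt, table, seed=5)
        assert np.array_equal(a, b)

    def test_missing_and_extra_columns_named(self, tiny_run):
        ckpt, _, _ = tiny_run
        table = self.trait_table(ckpt, 3)
        bad = table.drop(columns=["TPA"]).assign(BOGUS=1.0)
        with pytest.raises(ValueError) as err:
            generate(ckpt, bad, seed=0)
        assert "TPA" in str(err.value)
        assert "BOGUS" in str(err.value)

    def test_checkpoint_round_trip_generates_identical_images(
            self, tiny_run, tmp_path):
        ckpt, _, _ = tiny_run
        table = self.trait_table(ckpt, 2)
        path = tmp_path / "ck.npz"
        ckpt.save(path)
        reloaded = Checkpoint.load(path)
        assert np.array_equal(generate(ckpt, table, seed=2),
                              generate(reloaded, table, seed=2))


class TestEvaluateSmoke:
    def test_report_fields_finite_on_small_run(self, tiny_run,
                                               small_manifest):
        from croppainter.evaluation import evaluate
        ckpt, _, _ = tiny_run
        report = evaluate(ckpt, small_manifest, seed=0)
        assert np.isfinite(report.ssim_mean)
        assert np.isfinite(report.ssim_sd)
        assert report.fid >= 0.0
        assert -1.0 <= report.cosine_mean <= 1.0
        assert len(report.corr_per_trait) == \
            len(small_manifest.schema.active)


class TestOverfitOracle:
    def test_single_image_ssim_improves_with_training(self):
        """A deterministic generator (z_dim=0) trained on one image must
        reproduce it better after 200 epochs than after 1."""
        from croppainter.synthetic import PlantParams, render_plant
        rgb, mask = render_plant(PlantParams(seed=77))
        manifest = build_dataset([("a", rgb, mask), ("b", rgb, mask)],
                                 target_resolution=64, test_fraction=0.5,
                                 seed=0)
        gc = GeneratorConfig(n_stages=1, base_resolution=64, z_dim=0,
                             base_channels=8,
                             cond_dim=len(manifest.schema.active), seed=0)
        target = manifest.split_records("train")[0]
        table = pd.DataFrame(
            [target.traits.as_array(manifest.schema.active)],
            columns=list(manifest.schema.active))

        ck1, _ = train(manifest, gc, TrainConfig(epochs=1, seed=0,
                                                 batch_size=1))
        ck200, _ = train(manifest, gc, TrainConfig(epochs=200, seed=0,
                                                   batch_size=1))
        early = ssim(target.rgb, generate(ck1, table, seed=0)[0])
        late = ssim(target.rgb, generate(ck200, table, seed=0)[0])
        assert late > early
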