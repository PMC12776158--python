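"""Training-regime contracts: determinism, reductions, freezing, scheduling.

All runs here are deliberately tiny (16x16 patches, few epochs) — they check
mechanics and optimization sanity, not reconstruction quality.
"""

import numpy as np
import pytest

from stormdistill import losses, models, simulate, training
from stormdistill.training import TrainConfig


def _small_cfg(**kw):
    base = dict(epochs=3, batch_size=5, learning_rate=1e-3, rng_seed=42)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def frozen_teacher(tiny_dataset):
    """A briefly trained, frozen teacher shared by the distillation tests."""
    t = models.build_drlstorm(rng_seed=1)
    training.train_baseline(t, tiny_dataset, _small_cfg(epochs=2))
    return t.freeze_all()


class TestBaseline:
    def test_zero_epochs_returns_model_unchanged(self, tiny_dataset):
        m = models.build_srcnn(0)
        digest = m.weights_digest()
        m, hist = training.train_baseline(m, tiny_dataset, _small_cfg(epochs=0))
        assert m.weights_digest() == digest
        assert hist.train_loss == [] and hist.val_loss == [] and hist.lr == []

    def test_single_sample_overfit_halves_loss(self, tiny_dataset):
        x, y = tiny_dataset.split("train")
        one = simulate.PatchDataset(
            x=np.concatenate([x[:1], x[:1]]),
            y=np.concatenate([y[:1], y[:1]]),
            labels=np.array(["train", "val"]),
            patch_size=tiny_dataset.patch_size,
            rng_seed=0,
            norm_mean=tiny_dataset.norm_mean,
            norm_std=tiny_dataset.norm_std,
        )
        m = models.build_srcnn(0)
        _, hist = training.train_baseline(m, one, _small_cfg(epochs=50, batch_size=1))
        assert hist.train_loss[-1] < 0.5 * hist.train_loss[0]

    def test_plateau_drops_lr_by_one_order_of_magnitude(self, tiny_dataset):
        # learning_rate 0 freezes the loss; a huge threshold forces "no change"
        cfg = _small_cfg(epochs=12, learning_rate=1e-9, sched_threshold=1e9,
                         sched_patience=5)
        m = models.build_srcnn(0)
        _, hist = training.train_baseline(m, tiny_dataset, cfg)
        lrs = np.array(hist.lr)
        # epoch 1 establishes the baseline; epochs 2-6 stall, so the drop
        # applied after the fifth stalled epoch is visible from epoch 7 on
        assert lrs[5] == pytest.approx(1e-9)
        assert lrs[6] == pytest.approx(1e-10)
        assert lrs[11] == pytest.approx(1e-11)
        assert np.all(np.diff(lrs) <= 0)  # lr trace is non-increasing

    def test_bit_reproducible_under_fixed_seed(self, tiny_dataset):
        runs = []
        for _ in range(2):
            m = models.build_srcnn(3)
            _, hist = training.train_baseline(m, tiny_dataset, _small_cfg(epochs=2))
            runs.append((m.weights_digest(), hist.train_loss, hist.val_loss))
        assert runs[0] == runs[1]

    def test_history_lengths_match_epochs(self, tiny_dataset):
        m = models.build_srcnn(0)
        _, hist = training.train_baseline(m, tiny_dataset, _small_cfg(epochs=3))
        assert len(hist.train_loss) == len(hist.val_loss) == len(hist.lr) == 3
        frame = hist.to_frame()
        assert list(frame.columns) == ["epoch", "train_loss", "val_loss", "lr"]

    def test_unnormalized_dataset_rejected(self, tiny_dataset):
        raw = simulate.PatchDataset(tiny_dataset.x, tiny_dataset.y, tiny_dataset.labels,
                                    tiny_dataset.patch_size, 0)
        with pytest.raises(ValueError, match="normalized"):
            training.train_baseline(models.build_srcnn(0), raw, _small_cfg())


class TestAILTraining:
    def test_alpha_one_reproduces_baseline_exactly(self, tiny_dataset, frozen_teacher):
        cfg = _small_cfg(epochs=2)
        base = models.build_srcnn(7)
        _, hist_base = training.train_baseline(base, tiny_dataset, cfg)

        ctx = training.make_ail_context(frozen_teacher, tiny_dataset, cfg.lam, alpha=1.0)
        dist = models.build_srcnn(7)
        _, hist_ail = training.train_with_ail(dist, frozen_teacher, tiny_dataset, ctx, cfg)

        assert hist_ail.train_loss == hist_base.train_loss
        assert hist_ail.val_loss == hist_base.val_loss
        assert dist.weights_digest() == base.weights_digest()

    def test_low_alpha_run_yields_finite_metrics(self, tiny_dataset, frozen_teacher):
        from stormdistill.metrics import evaluate

        ctx = training.make_ail_context(frozen_teacher, tiny_dataset, 100.0, alpha=0.1)
        s = models.build_srcnn(2)
        s, hist = training.train_with_ail(s, frozen_teacher, tiny_dataset, ctx,
                                          _small_cfg(epochs=2))
        assert np.all(np.isfinite(hist.train_loss))
        report = evaluate(s, tiny_dataset, split="test")
        assert np.all(np.isfinite(report.nmse)) and np.all(np.isfinite(report.ssim))

    def test_teacher_untouched_by_distillation(self, tiny_dataset, frozen_teacher):
        digest = frozen_teacher.weights_digest()
        ctx = training.make_ail_context(frozen_teacher, tiny_dataset, 100.0, alpha=0.5)
        training.train_with_ail(models.build_srcnn(0), frozen_teacher, tiny_dataset,
                                ctx, _small_cfg(epochs=1))
        assert frozen_teacher.weights_digest() == digest

    def test_missing_context_rejected(self, tiny_dataset, frozen_teacher):
        with pytest.raises(ValueError, match="AILContext"):
            training.train_with_ail(models.build_srcnn(0), frozen_teacher,
                                    tiny_dataset, None, _small_cfg())


class TestHintLearning:
    def test_teacher_copy_is_a_fixed_point(self, tiny_dataset, frozen_teacher):
        clone = models.build_drlstorm(rng_seed=1)
        clone.set_weights(frozen_teacher.get_weights())
        x, _ = tiny_dataset.split("train")
        xb = x[:4][:, None]
        assert losses.hint_loss(clone.forward_hint(xb),
                                frozen_teacher.forward_hint(xb)) == 0.0
        _, hist = training.train_hint(clone, frozen_teacher, tiny_dataset,
                                      _small_cfg(epochs=1, learning_rate=0.0))
        assert clone.weights_digest() == frozen_teacher.weights_digest()

    def test_hint_loss_descends(self, tiny_dataset, frozen_teacher):
        s = models.build_srcnn(4)
        _, hist = training.train_hint(s, frozen_teacher, tiny_dataset,
                                      _small_cfg(epochs=5))
        assert hist.train_loss[-1] <= hist.train_loss[0]

    def test_head_untouched_by_hint_training(self, tiny_dataset, frozen_teacher):
        s = models.build_srcnn(4)
        head_before = [p.value.copy() for p in s.head.params()]
        training.train_hint(s, frozen_teacher, tiny_dataset, _small_cfg(epochs=1))
        for before, p in zip(head_before, s.head.params()):
            assert np.array_equal(before, p.value)


class TestHeadAfterHint:
    def test_requires_frozen_body(self, tiny_dataset, frozen_teacher):
        s = models.build_srcnn(0)
        ctx = training.make_ail_context(frozen_teacher, tiny_dataset, 100.0, alpha=0.5)
        with pytest.raises(ValueError, match="frozen"):
            training.train_head_after_hint(s, frozen_teacher, tiny_dataset, ctx,
                                           _small_cfg())

    def test_body_bit_identical_and_head_trains(self, tiny_dataset, frozen_teacher):
        s = models.build_srcnn(0)
        s.freeze_body()
        body_digest = s.body_digest()
        ctx = training.make_ail_context(frozen_teacher, tiny_dataset, 100.0, alpha=0.5)
        trainable = sum(p.value.size for p in s.trainable_params())
        assert trainable == s.head_param_count
        s, hist = training.train_head_after_hint(s, frozen_teacher, tiny_dataset, ctx,
                                                 _small_cfg(epochs=2))
        assert s.body_digest() == body_digest
        assert np.all(np.isfinite(hist.train_loss))


class TestSweeps:
    def test_lambda_sweep_rows_and_single_value_equivalence(self, tiny_dataset):
        cfg = _small_cfg(epochs=1)
        table = training.sweep_lambda(models.build_srcnn, tiny_dataset, [10.0, 100.0], cfg)
        assert len(table) == 2
        assert set(table["lam"]) == {10.0, 100.0}
        for row in table.itertuples():
            assert len(row.nmse) > 0 and len(row.ssim) > 0

        # a single-lambda sweep equals one baseline train + evaluate
        from dataclasses import replace

        from stormdistill.metrics import evaluate

        single = training.sweep_lambda(models.build_srcnn, tiny_dataset, [10.0], cfg)
        m = models.build_srcnn(cfg.rng_seed)
        training.train_baseline(m, tiny_dataset, replace(cfg, lam=10.0))
        report = evaluate(m, tiny_dataset, split="test")
        assert single["ssim_mean"][0] == pytest.approx(report.ssim.mean(), rel=1e-12)

    def test_alpha_grid_default(self):
        assert training.ALPHA_GRID_DEFAULT == (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

    def test_alpha_sweep_smoke(self, tiny_dataset, frozen_teacher):
        cfg = _small_cfg(epochs=1)
        table = training.sweep_alpha(models.build_srcnn, frozen_teacher, tiny_dataset,
                                     [0.1, 0.9], cfg)
        assert list(table["alpha"]) == [0.1, 0.9]
        assert np.all(np.isfinite(table["ssim_mean"]))

    def test_empty_grids_rejected(self, tiny_dataset, frozen_teacher):
        with pytest.raises(ValueError):
            training.sweep_lambda(models.build_srcnn, tiny_dataset, [], _small_cfg())
        with pytest.raises(ValueError):
            training.sweep_alpha(models.build_srcnn, frozen_teacher, tiny_dataset, [],
                                 _small_cfg())
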