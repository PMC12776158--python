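"""Tests of the synthetic STORM frame simulator and patch datasets."""

import numpy as np
import pytest

from stormdistill import simulate


class TestEmitterField:
    def test_zero_density_gives_empty_field(self):
        f = simulate.simulate_emitter_field(64, 64, 0.1, density_per_um2=0.0, rng_seed=3)
        assert f.n_emitters == 0

    def test_identical_seeds_identical_fields(self):
        a = simulate.simulate_emitter_field(64, 64, 0.1, 13.0, rng_seed=11)
        b = simulate.simulate_emitter_field(64, 64, 0.1, 13.0, rng_seed=11)
        assert a == b
        c = simulate.simulate_emitter_field(64, 64, 0.1, 13.0, rng_seed=12)
        assert not (a == c)

    @pytest.mark.parametrize("density", [13.0, 5.0])
    def test_mean_density_converges(self, density):
        """Mean emitter count over 100 seeded 256x256 fields lies within
        3 standard errors of density * area (Poisson-mean Monte Carlo)."""
        area = 256 * 256 * 0.1**2
        counts = [
            simulate.simulate_emitter_field(256, 256, 0.1, density, rng_seed=s).n_emitters
            for s in range(100)
        ]
        expected = density * area
        se = np.sqrt(expected / 100)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            simulate.simulate_emitter_field(64, 64, 0.1, density_per_um2=-1.0)
        with pytest.raises(ValueError):
            simulate.simulate_emitter_field(0, 64, 0.1, 13.0)
        with pytest.raises(ValueError):
            simulate.simulate_emitter_field(64, 64, -0.1, 13.0)

    def test_out_of_bounds_emitters_rejected(self):
        with pytest.raises(ValueError, match="inside the field"):
            simulate.EmitterField(8, 8, 0.1, np.array([[9.0, 1.0, 100.0]]))
        with pytest.raises(ValueError, match="positive"):
            simulate.EmitterField(8, 8, 0.1, np.array([[1.0, 1.0, 0.0]]))

    def test_lognormal_photon_model(self):
        f = simulate.simulate_emitter_field(64, 64, 0.1, 13.0,
                                            photon_model="lognormal", rng_seed=5)
        assert (f.emitters[:, 2] > 0).all()
        assert np.std(f.emitters[:, 2]) > 0


class TestRenderPair:
    def test_background_only_frame_mean(self):
        f = simulate.simulate_emitter_field(256, 256, 0.1, 0.0, rng_seed=0)
        pair = simulate.render_pair(f, background_level=200.0, rng_seed=1)
        se = np.sqrt(200.0 / 256**2)
        assert abs(pair.x_dl.mean() - 200.0) < 3 * se
        assert np.all(pair.y_gt == 0)

    def test_null_input_gives_zero_images(self):
        f = simulate.simulate_emitter_field(32, 32, 0.1, 0.0, rng_seed=0)
        pair = simulate.render_pair(f, background_level=0.0, noise_model="none")
        assert np.all(pair.x_dl == 0) and np.all(pair.y_gt == 0)

    def test_single_emitter_peak_and_photon_sum(self):
        field = simulate.EmitterField(32, 32, 0.1, np.array([[12.4, 20.7, 850.0]]))
        pair = simulate.render_pair(field, background_level=0.0, noise_model="none")
        r, c = np.unravel_index(np.argmax(pair.x_dl), pair.x_dl.shape)
        assert (r, c) == (20, 12)
        assert pair.y_gt.sum() == pytest.approx(850.0)
        assert pair.y_gt[20, 12] == pytest.approx(850.0)

    def test_render_deterministic_under_seed(self):
        f = simulate.simulate_emitter_field(32, 32, 0.1, 13.0, rng_seed=4)
        a = simulate.render_pair(f, rng_seed=9)
        b = simulate.render_pair(f, rng_seed=9)
        assert np.array_equal(a.x_dl, b.x_dl)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="magnification"):
            simulate.ImagePair(np.zeros((4, 4)), np.zeros((5, 5)))


def _pairs_with_offset_marker(n=3, size=64, seed=0):
    """Image pairs where y = x + 1 everywhere, so paired crops are detectable."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        x = np.abs(rng.normal(size=(size, size)))
        out.append(simulate.ImagePair(x_dl=x, y_gt=x + 1.0))
    return out


class TestPatchDataset:
    def test_counts_and_split_fraction(self):
        pairs = _pairs_with_offset_marker(n=5)
        ds = simulate.build_patch_dataset(pairs, patch_size=16, patches_per_image=200,
                                          rng_seed=21)
        assert len(ds) == 1000
        frac = (ds.labels == "train").mean()
        ci = 2.576 * np.sqrt(0.8 * 0.2 / 1000)  # binomial 99% CI
        assert abs(frac - 0.8) < ci

    def test_split_fractions_converge_at_large_n(self):
        pairs = _pairs_with_offset_marker(n=1, size=16)
        ds = simulate.build_patch_dataset(pairs, patch_size=8, patches_per_image=10_000,
                                          rng_seed=5)
        for p, name in zip((0.8, 0.1, 0.1), simulate.SPLITS):
            frac = (ds.labels == name).mean()
            assert abs(frac - p) < 2.576 * np.sqrt(p * (1 - p) / 10_000)

    def test_zero_patches_gives_empty_dataset(self):
        ds = simulate.build_patch_dataset(_pairs_with_offset_marker(1), 16, 0)
        assert len(ds) == 0

    def test_crops_are_paired(self):
        ds = simulate.build_patch_dataset(_pairs_with_offset_marker(2), 16, 10, rng_seed=2)
        assert np.allclose(ds.y - ds.x, 1.0, atol=1e-6)

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="patch_size"):
            simulate.build_patch_dataset(_pairs_with_offset_marker(1, size=16), 32, 5)

    def test_bit_reproducible(self):
        pairs = _pairs_with_offset_marker(2)
        a = simulate.build_patch_dataset(pairs, 16, 20, rng_seed=3)
        b = simulate.build_patch_dataset(pairs, 16, 20, rng_seed=3)
        assert a == b


class TestNormalize:
    def test_pooled_stats_after_normalization(self):
        ds = simulate.build_patch_dataset(_pairs_with_offset_marker(2), 16, 50, rng_seed=1)
        nds = simulate.normalize_dataset(ds)
        assert abs(float(nds.x.mean(dtype=np.float64))) < 1e-6
        assert float(nds.x.std(dtype=np.float64)) == pytest.approx(1.0, rel=1e-6)
        assert np.array_equal(nds.y, ds.y)  # truth untouched

    def test_idempotent_once_normalized(self):
        ds = simulate.build_patch_dataset(_pairs_with_offset_marker(2), 16, 50, rng_seed=1)
        once = simulate.normalize_dataset(ds)
        twice = simulate.normalize_dataset(once)
        assert np.allclose(once.x, twice.x, atol=1e-6)

    def test_two_patch_toy_set_matches_hand_arithmetic(self):
        x = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
        ds = simulate.PatchDataset(x=x, y=np.zeros_like(x),
                                   labels=np.array(["train", "val"]),
                                   patch_size=2, rng_seed=0)
        nds = simulate.normalize_dataset(ds)
        assert nds.norm_mean == pytest.approx(2.0)
        assert nds.norm_std == pytest.approx(1.0)
        assert np.allclose(nds.x[0], -1.0) and np.allclose(nds.x[1], 1.0)

    def test_constant_dataset_rejected(self):
        x = np.full((3, 2, 2), 5.0)
        ds = simulate.PatchDataset(x=x, y=x.copy(), labels=np.array(["train"] * 3),
                                   patch_size=2, rng_seed=0)
        with pytest.raises(ValueError, match="constant"):
            simulate.normalize_dataset(ds)

    def test_empty_dataset_rejected(self):
        empty = simulate.PatchDataset(np.zeros((0, 4, 4)), np.zeros((0, 4, 4)),
                                      np.array([], dtype="U5"), 4, 0)
        with pytest.raises(ValueError, match="empty"):
            simulate.normalize_dataset(empty)


class TestPersistence:
    def test_round_trip_equality(self, tmp_path):
        ds = simulate.make_dataset(n_images=1, image_size=32, patch_size=8,
                                   patches_per_image=20, rng_seed=2)
        simulate.write_dataset(ds, tmp_path / "bundle")
        back = simulate.read_dataset(tmp_path / "bundle")
        assert back == ds

    def test_truncated_record_raises_parse_error(self, tmp_path):
        ds = simulate.make_dataset(n_images=1, image_size=32, patch_size=8,
                                   patches_per_image=10, rng_seed=2)
        p = simulate.write_dataset(ds, tmp_path / "bundle")
        raw = (p / "x.npy").read_bytes()
        (p / "x.npy").write_bytes(raw[: len(raw) // 2])
        with pytest.raises(simulate.DatasetParseError, match="x.npy"):
            simulate.read_dataset(p)

    def test_missing_record_named(self, tmp_path):
        with pytest.raises(simulate.DatasetParseError, match="missing dataset record"):
            simulate.read_dataset(tmp_path)

    def test_emitter_csv_round_trip(self, tmp_path):
        field = simulate.simulate_emitter_field(64, 48, 0.1, 13.0, rng_seed=6)
        simulate.write_emitters_csv(field, tmp_path / "gt.csv")
        header = (tmp_path / "gt.csv").read_text().splitlines()[0]
        assert header.split(",") == ["id", "frame", "x [nm]", "y [nm]", "intensity [photon]"]
        back = simulate.read_emitters_csv(tmp_path / "gt.csv", 64, 48, 0.1)
        assert np.allclose(back.emitters, field.emitters, rtol=1e-12, atol=1e-9)

    def test_malformed_csv_rejected(self, tmp_path):
        (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
        with pytest.raises(simulate.DatasetParseError, match="columns"):
            simulate.read_emitters_csv(tmp_path / "bad.csv", 8, 8, 0.1)


def test_make_dataset_protocol_metadata(tiny_dataset):
    """The one-call builder records the generation protocol in its sidecar."""
    meta = tiny_dataset.meta
    assert meta["density_per_um2"] == 13.0
    assert meta["background_level"] == 200.0
    assert tiny_dataset.norm_std is not None and tiny_dataset.norm_std > 0
    # unit spike scaling: a lone emitter contributes ~1.0 to Y
    assert tiny_dataset.y.max() >= 1.0
    assert tiny_dataset.y.max() < 10.0
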