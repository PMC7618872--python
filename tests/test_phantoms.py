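"""Synthetic phantom generator: warps, rendering, corruption, datasets."""

import numpy as np
import pytest

from topowarp import (
    Grid2D,
    PhantomSpec,
    augment,
    betti_2d,
    fourier_line_dropout,
    jacobian_determinants,
    make_dataset,
    random_topology_preserving_warp,
    render_phantom,
)
from topowarp.metrics import dice_score
from topowarp.phantoms import PhantomSample, default_prior_spec
from topowarp.priors import make_prior


class TestRandomWarp:
    def test_accepted_fields_are_fold_free(self):
        grid = Grid2D(48, 48)
        for seed in range(5):
            phi = random_topology_preserving_warp(grid, 0.35, 6.0, seed)
            assert jacobian_determinants(phi).percent_nonpositive == 0.0

    def test_small_strength_is_near_identity(self):
        grid = Grid2D(32, 32)
        phi = random_topology_preserving_warp(grid, 1e-4, 6.0, seed=0)
        assert np.abs(phi.displacement.values).max() < 0.05

    def test_seed_reproducibility(self):
        grid = Grid2D(32, 32)
        a = random_topology_preserving_warp(grid, 0.35, 6.0, seed=9)
        b = random_topology_preserving_warp(grid, 0.35, 6.0, seed=9)
        assert np.array_equal(a.displacement.values, b.displacement.values)

    def test_nonpositive_strength_rejected(self):
        with pytest.raises(ValueError):
            random_topology_preserving_warp(Grid2D(16, 16), 0.0, 6.0, 0)


class TestRenderPhantom:
    def test_noise_free_rendering_has_discrete_levels(self, cardiac_64):
        spec = PhantomSpec.for_task("cardiac_scene", intensity=((0.9, 0.6, 0.3), 0.1, 0.0))
        img = render_phantom(cardiac_64, spec, seed=0)
        assert set(np.round(np.unique(img), 6)) == {0.1, 0.3, 0.6, 0.9}

    def test_noise_sd_recovered_from_large_region(self, annulus_64):
        spec = PhantomSpec.for_task("myo", intensity=(0.7, 0.3, 0.1))
        img = render_phantom(annulus_64, spec, seed=1)
        bg = img[annulus_64 == 0]
        assert bg.size > 1e4 * 0.3  # enough pixels for a stable estimate
        assert np.std(bg[(bg > 0.05) & (bg < 0.95)]) == pytest.approx(0.1, rel=0.2)

    def test_seeded_reproducibility(self, annulus_64):
        spec = PhantomSpec.for_task("myo")
        a = render_phantom(annulus_64, spec, seed=3)
        b = render_phantom(annulus_64, spec, seed=3)
        assert np.array_equal(a, b)


class TestFourierLineDropout:
    def test_zero_lines_is_identity(self, rng):
        img = rng.random((32, 32))
        out = fourier_line_dropout(img, 0, seed=0)
        assert np.allclose(out, img, atol=1e-6)

    def test_output_real_via_hermitian_symmetry(self, rng):
        img = rng.random((32, 32))
        F = np.fft.fft2(img)
        out = fourier_line_dropout(img, 4, seed=1)
        # reconstruct without the final clip to measure the imaginary residual
        assert np.all(np.isfinite(out))
        assert out.dtype == float

    def test_energy_never_increases(self, rng):
        for seed in range(10):
            img = rng.random((32, 32))
            out = fourier_line_dropout(img, 6, seed=seed)
            assert (out**2).sum() <= (img**2).sum() + 1e-9

    def test_changes_the_image(self, rng):
        img = rng.random((32, 32))
        out = fourier_line_dropout(img, 6, seed=2)
        assert not np.allclose(out, img, atol=1e-3)


class TestAugment:
    def _sample(self, annulus_64):
        spec = PhantomSpec.for_task("myo")
        img = render_phantom(annulus_64, spec, seed=0)
        return PhantomSample(img, annulus_64[None].copy(), annulus_64[None].copy()), spec

    def test_identity_parameters_change_nothing(self, annulus_64):
        sample, spec = self._sample(annulus_64)
        frozen = PhantomSpec.for_task(
            "myo", rotation_deg=0.0, translation_vox=0.0, flip_prob=0.0, resize_frac=0.0
        )
        out = augment(sample, frozen, seed=0)
        assert np.allclose(out.image, sample.image, atol=1e-6)
        assert np.array_equal(out.label, sample.label)

    def test_label_topology_is_preserved_or_sample_skipped(self, annulus_64):
        sample, spec = self._sample(annulus_64)
        for seed in range(10):
            out = augment(sample, spec, seed)
            assert betti_2d(out.label[0]) == betti_2d(sample.label[0])

    def test_prior_left_untouched(self, annulus_64):
        sample, spec = self._sample(annulus_64)
        out = augment(sample, spec, seed=4)
        assert np.array_equal(out.prior, sample.prior)

    def test_double_horizontal_flip_restores_label(self, annulus_64):
        sample, spec = self._sample(annulus_64)
        flip_only = PhantomSpec.for_task(
            "myo", rotation_deg=0.0, translation_vox=0.0, flip_prob=1.0, resize_frac=0.0
        )
        once = augment(sample, flip_only, seed=1)
        twice = augment(once, flip_only, seed=1)
        assert np.array_equal(twice.label, sample.label)

    def test_small_rotation_roundtrip_dice(self, annulus_64):
        sample, _ = self._sample(annulus_64)
        from scipy import ndimage

        rot = ndimage.rotate(sample.label[0].astype(float), 5.0, reshape=False, order=0)
        back = ndimage.rotate(rot, -5.0, reshape=False, order=0)
        assert dice_score(back > 0.5, sample.label[0] > 0) >= 0.95


class TestMakeDataset:
    def test_split_fractions_and_family_exclusivity(self):
        spec = PhantomSpec.for_task("myo", H=48, W=48, n_samples=40, seed=0)
        ds = make_dataset(spec)
        counts = ds.manifest["split"].value_counts()
        assert counts["train"] == 30 and counts["val"] == 6 and counts["test"] == 4
        per_family = ds.manifest.groupby("family_id")["split"].nunique()
        assert (per_family == 1).all()

    def test_every_label_has_declared_topology(self):
        spec = PhantomSpec.for_task("cardiac_scene", H=64, W=64, n_samples=6, seed=1)
        ds = make_dataset(spec)
        for s in ds.samples:
            assert betti_2d(s.label[0]) == betti_2d(s.prior[0])  # annulus
            assert betti_2d(s.label[1]) == betti_2d(s.prior[1])  # rv
            assert betti_2d(s.label[2]) == betti_2d(s.prior[2])  # lv
            assert betti_2d(np.any(s.label, axis=0)).b0 == 1

    def test_digit_task_cycles_topology_classes(self):
        spec = PhantomSpec.for_task("digits", H=64, W=64, n_samples=6, seed=0)
        ds = make_dataset(spec)
        kinds = list(ds.manifest["prior_kind"])
        assert kinds == ["disc", "annulus", "two_hole_disc"] * 2

    def test_same_spec_same_manifest(self):
        spec = PhantomSpec.for_task("myo", H=48, W=48, n_samples=8, seed=5)
        a = make_dataset(spec)
        b = make_dataset(spec)
        assert a.manifest.equals(b.manifest)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.image, sb.image)
            assert np.array_equal(sa.label, sb.label)

    def test_labels_are_nontrivially_deformed(self):
        spec = PhantomSpec.for_task("myo", H=64, W=64, n_samples=20, seed=2)
        ds = make_dataset(spec)
        d = [dice_score(s.prior[0], s.label[0]) for s in ds.samples]
        assert np.mean(d) < 0.95

    def test_invalid_splits_rejected(self):
        with pytest.raises(ValueError, match="split"):
            PhantomSpec.for_task("myo", splits=(0.8, 0.3, 0.1))

    def test_prior_geometry_scales_with_grid(self):
        spec64 = default_prior_spec("myo", 64, 64)
        prior = make_prior(spec64)
        assert prior.shape == (1, 64, 64)
        assert betti_2d(prior[0]).b1 == 1
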