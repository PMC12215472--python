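"""Augmentation, noise, occluders and the procedural fixture generator."""

from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from avifuse import (AugmentSpec, DatasetManifest, NoiseSpec, OccluderSpec,
                     add_noise, add_occluders, augment_image, balance_class,
                     generate_synthetic_images, make_occluded_subset)


@pytest.fixture(scope="module")
def fixture_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("birds")
    manifest = generate_synthetic_images(3, 6, seed=42, out_dir=root)
    return root, manifest


@pytest.fixture(scope="module")
def sample_image(fixture_dataset):
    root, manifest = fixture_dataset
    rel = manifest.classes["class_00"][0].path
    return np.asarray(Image.open(root / rel).convert("RGB"))


class TestAugment:
    def test_identity_spec_is_noop(self, sample_image):
        out = augment_image(sample_image, AugmentSpec.identity(), seed=1)
        np.testing.assert_array_equal(out, sample_image)

    def test_flip_is_involution(self, sample_image):
        spec = AugmentSpec(hflip_prob=(1.0, 1.0))
        once = augment_image(sample_image, spec, seed=3)
        twice = augment_image(once, spec, seed=3)
        np.testing.assert_array_equal(twice, sample_image)

    def test_seeded_determinism(self, sample_image):
        spec = AugmentSpec.validation()
        a = augment_image(sample_image, spec, seed=9)
        b = augment_image(sample_image, spec, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_sampled_rotations_within_range(self):
        spec = AugmentSpec.validation()
        rots = [abs(spec.sample(np.random.default_rng(s))["rotation"])
                for s in range(1000)]
        assert all(10.0 <= r <= 20.0 for r in rots)

    def test_sampled_parameters_within_all_ranges(self):
        spec = AugmentSpec.validation()
        for s in range(200):
            p = spec.sample(np.random.default_rng(s))
            assert 0.0 <= abs(p["vshift"]) <= 0.1
            assert 0.01 <= p["scale_x"] <= 0.1
            assert 0.01 <= p["scale_y"] <= 0.1

    def test_shape_preserved(self, sample_image):
        out = augment_image(sample_image, AugmentSpec.validation(), seed=11)
        assert out.shape == sample_image.shape

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            augment_image(np.zeros((4, 4, 3), dtype=np.uint8),
                          AugmentSpec.identity(), seed=0)


class TestNoise:
    def test_zero_fraction_unchanged(self, sample_image):
        out = add_noise(sample_image, NoiseSpec(fraction_range=(0.0, 0.0)), seed=5)
        np.testing.assert_array_equal(out, sample_image)

    def test_exact_pixel_count(self, sample_image):
        h, w = sample_image.shape[:2]
        out = add_noise(sample_image, NoiseSpec(fraction_range=(0.30, 0.30)), seed=5)
        changed = (out != sample_image).any(axis=2).sum()
        assert changed == round(0.30 * h * w)

    def test_td_presets_within_declared_ranges(self, sample_image):
        h, w = sample_image.shape[:2]
        for spec, lo, hi in [(NoiseSpec.td1(), 0.25, 0.40),
                             (NoiseSpec.td2(), 0.40, 0.50)]:
            out = add_noise(sample_image, spec, seed=7)
            frac = (out != sample_image).any(axis=2).mean()
            assert lo - 1 / (h * w) <= frac <= hi + 1 / (h * w)

    def test_seeded_determinism(self, sample_image):
        spec = NoiseSpec.td1()
        np.testing.assert_array_equal(add_noise(sample_image, spec, seed=13),
                                      add_noise(sample_image, spec, seed=13))

    def test_corrupted_pixels_are_extremes(self, sample_image):
        out = add_noise(sample_image, NoiseSpec(fraction_range=(0.2, 0.2)), seed=3)
        changed = (out != sample_image).any(axis=2)
        vals = out[changed]
        assert set(np.unique(vals)) <= {0, 255}

    def test_gaussian_mode_changes_shape_free(self, sample_image):
        out = add_noise(sample_image, NoiseSpec(fraction_range=(0.3, 0.3),
                                                kind="gaussian"), seed=3)
        assert out.shape == sample_image.shape

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(fraction_range=(0.5, 1.5))


class TestOccluders:
    def test_zero_coverage_is_noop(self, sample_image):
        out, mask = add_occluders(sample_image, OccluderSpec(coverage=0.0), seed=1)
        np.testing.assert_array_equal(out, sample_image)
        assert not mask.any()

    def test_coverage_within_tolerance(self, sample_image):
        out, mask = add_occluders(sample_image, OccluderSpec(coverage=0.15), seed=2)
        assert 0.12 <= mask.mean() <= 0.18

    def test_mask_equals_changed_pixels_opaque_shapes(self, sample_image):
        spec = OccluderSpec(coverage=0.15, shapes=("leaf", "branch"))
        out, mask = add_occluders(sample_image, spec, seed=4)
        changed = (out != sample_image).any(axis=2)
        np.testing.assert_array_equal(mask, changed)

    def test_dimensions_preserved(self, sample_image):
        out, mask = add_occluders(sample_image, OccluderSpec(coverage=0.1), seed=6)
        assert out.shape == sample_image.shape
        assert mask.shape == sample_image.shape[:2]

    def test_seeded_determinism(self, sample_image):
        spec = OccluderSpec(coverage=0.12)
        a, ma = add_occluders(sample_image, spec, seed=8)
        b, mb = add_occluders(sample_image, spec, seed=8)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ma, mb)

    def test_full_coverage_rejected(self):
        with pytest.raises(ValueError):
            OccluderSpec(coverage=1.0)


class TestBalanceClass:
    def test_topped_up_to_target(self, fixture_dataset, tmp_path):
        root, _ = fixture_dataset
        entries = balance_class(root / "class_00", 15, AugmentSpec.validation(),
                                seed=21, out_dir=tmp_path / "bal")
        assert len(entries) == 15
        tags = [e.provenance for e in entries]
        assert tags.count("original") == 6 and tags.count("augmented") == 9

    def test_originals_conserved(self, fixture_dataset, tmp_path):
        root, manifest = fixture_dataset
        entries = balance_class(root / "class_01", 10, AugmentSpec.validation(),
                                seed=22, out_dir=tmp_path / "bal")
        originals = {Path(e.path).name for e in entries if e.provenance == "original"}
        expected = {Path(e.path).name for e in manifest.classes["class_01"]}
        assert originals == expected

    def test_target_equal_to_count_keeps_originals_only(self, fixture_dataset,
                                                        tmp_path):
        root, _ = fixture_dataset
        entries = balance_class(root / "class_02", 6, AugmentSpec.validation(),
                                seed=23, out_dir=tmp_path / "bal")
        assert all(e.provenance == "original" for e in entries)

    def test_rerun_same_seed_identical_files(self, fixture_dataset, tmp_path):
        root, _ = fixture_dataset
        a = balance_class(root / "class_00", 9, AugmentSpec.validation(), seed=24,
                          out_dir=tmp_path / "a")
        b = balance_class(root / "class_00", 9, AugmentSpec.validation(), seed=24,
                          out_dir=tmp_path / "b")
        for ea, eb in zip(a, b):
            if ea.provenance == "augmented":
                assert Path(ea.path).read_bytes() == Path(eb.path).read_bytes()

    def test_empty_folder_rejected(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(ValueError, match="no images"):
            balance_class(tmp_path / "empty", 5, AugmentSpec.identity(), seed=0)


class TestOccludedSubset:
    def test_fraction_of_each_class_occluded(self, fixture_dataset, tmp_path):
        root, manifest = fixture_dataset
        sub = make_occluded_subset(manifest, OccluderSpec(coverage=0.1), seed=31,
                                   fraction_range=(0.10, 0.15),
                                   out_root=tmp_path / "occ")
        for cls, entries in sub.classes.items():
            n_occ = sum(e.provenance == "occluded" for e in entries)
            n = len(entries)
            assert round(0.10 * n) <= n_occ <= round(0.15 * n)
            assert n == len(manifest.classes[cls])  # tags partition the class

    def test_zero_fraction_unchanged(self, fixture_dataset, tmp_path):
        root, manifest = fixture_dataset
        sub = make_occluded_subset(manifest, OccluderSpec(coverage=0.1), seed=32,
                                   fraction_range=(0.0, 0.0),
                                   out_root=tmp_path / "occ0")
        assert all(e.provenance == "original"
                   for entries in sub.classes.values() for e in entries)


class TestFixtureGenerator:
    def test_counts_and_folders(self, fixture_dataset):
        root, manifest = fixture_dataset
        assert manifest.counts == {"class_00": 6, "class_01": 6, "class_02": 6}
        manifest.verify()

    def test_same_seed_identical_bytes(self, tmp_path):
        a = generate_synthetic_images(2, 2, seed=5, out_dir=tmp_path / "a")
        b = generate_synthetic_images(2, 2, seed=5, out_dir=tmp_path / "b")
        for cls in a.classes:
            for ea, eb in zip(a.classes[cls], b.classes[cls]):
                assert (tmp_path / "a" / ea.path).read_bytes() == \
                    (tmp_path / "b" / eb.path).read_bytes()

    def test_class_palettes_distinct(self, tmp_path):
        from avifuse.challenge import _distinct_palettes
        rng = np.random.default_rng(3)
        pal = _distinct_palettes(8, rng)
        for i in range(8):
            for j in range(i + 1, 8):
                assert np.linalg.norm(np.subtract(pal[i], pal[j])) > 0

    def test_manifest_round_trip(self, fixture_dataset, tmp_path):
        _, manifest = fixture_dataset
        path = tmp_path / "manifest.json"
        manifest.save(path)
        back = DatasetManifest.load(path)
        assert back.counts == manifest.counts
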