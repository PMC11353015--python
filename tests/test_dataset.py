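"""Tests of synthetic backgrounds, Methods 1-3 compositing and manifests."""

import dataclasses

import numpy as np
import pytest
from PIL import Image

from spmcount.dataset import (
    BackgroundSpec,
    DatasetConfig,
    build_hybrid_dataset,
    build_patch_library,
    class_label,
    gen_background,
    make_sample_m1,
    make_sample_m2,
    make_sample_m3,
    quantize_image,
    sample_to_png_array,
    split_manifest,
    write_images,
)
from spmcount.degrade import NOISE_FREE, NoiseSpec
from spmcount.optics import OpticalParams, sample_scene


SMALL_OPTICS = OpticalParams(image_shape=(48, 48))


class TestBackground:
    def test_zero_amplitudes_constant_one(self):
        spec = BackgroundSpec(gradient_amplitude=0, speckle_amplitude=0,
                              streak_amplitude=0, seed=1)
        np.testing.assert_array_equal(gen_background(spec, (32, 32)), 1.0)

    def test_seed_determinism(self):
        spec = BackgroundSpec(seed=7)
        a = gen_background(spec, (64, 64))
        b = gen_background(spec, (64, 64))
        np.testing.assert_array_equal(a, b)

    def test_speckle_correlation_length(self):
        # empirical 1/e autocorrelation width within ±20% of the setting
        corr_len = 8.0
        spec0 = BackgroundSpec(gradient_amplitude=0, streak_amplitude=0,
                               speckle_amplitude=1.0,
                               speckle_correlation_length=corr_len)
        widths = []
        for s in range(50):
            img = gen_background(dataclasses.replace(spec0, seed=s), (128, 128))
            f = img - img.mean()
            # wrap-mode generation makes the circular FFT autocorrelation exact
            spec = np.abs(np.fft.fft2(f)) ** 2
            acf = np.real(np.fft.ifft2(spec))
            acf /= acf[0, 0]
            prof = acf[0, :64]
            below = np.nonzero(prof < np.exp(-1))[0]
            k = below[0]
            # linear interpolation of the 1/e crossing
            frac = (prof[k - 1] - np.exp(-1)) / (prof[k - 1] - prof[k])
            widths.append(k - 1 + frac)
        assert np.mean(widths) == pytest.approx(corr_len, rel=0.2)

    def test_streak_direction(self):
        spec = BackgroundSpec(gradient_amplitude=0, speckle_amplitude=0,
                              streak_amplitude=0.1,
                              streak_direction="horizontal", seed=3)
        img = gen_background(spec, (32, 32))
        # horizontal streaks: constant along rows, varying across rows
        assert np.allclose(img, img[:, :1])
        assert img[:, 0].std() > 0


class TestLabelRule:
    @pytest.mark.parametrize("n,expected",
                             [(0, 0), (5, 5), (9, 9), (10, 10), (14, 10)])
    def test_min_n_10(self, n, expected):
        assert class_label(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            class_label(-1)


class TestMethod1:
    def test_blank_noise_free_is_constant(self):
        s = make_sample_m1(0, NoiseSpec(snr_db=NOISE_FREE), SMALL_OPTICS, seed=0)
        assert s.label == 0
        np.testing.assert_allclose(s.image, 1.0, atol=1e-12)

    def test_overcrowded_maps_to_others(self):
        s = make_sample_m1(12, NoiseSpec(snr_db=NOISE_FREE), SMALL_OPTICS, seed=1)
        assert s.label == 10
        assert s.n_particles == 12

    def test_scene_provenance_count(self):
        s = make_sample_m1(3, NoiseSpec(snr_db=NOISE_FREE), SMALL_OPTICS, seed=5)
        assert s.n_particles == 3
        scene = sample_scene(3, SMALL_OPTICS, rng_seed=5)
        assert len({p.position for p in scene.particles}) == 3


class TestMethod2:
    def test_blank_equals_degraded_background(self):
        bg = gen_background(BackgroundSpec(seed=2), SMALL_OPTICS.image_shape)
        spec = NoiseSpec(snr_db=20)
        s = make_sample_m2(0, bg, SMALL_OPTICS, spec, seed=3)
        from spmcount.degrade import degrade
        from spmcount.dataset import _noise_seed
        expected = degrade(bg, dataclasses.replace(spec, seed=_noise_seed(3)))
        np.testing.assert_allclose(s.image, expected, atol=1e-12)

    def test_flat_background_reduces_to_m1(self):
        flat = np.ones(SMALL_OPTICS.image_shape)
        spec = NoiseSpec(snr_db=15)
        m2 = make_sample_m2(4, flat, SMALL_OPTICS, spec, seed=9)
        m1 = make_sample_m1(4, spec, SMALL_OPTICS, seed=9)
        np.testing.assert_allclose(m2.image, m1.image, atol=1e-10)

    def test_pixelwise_composite_oracle(self):
        from spmcount.optics import render_scene
        bg = gen_background(BackgroundSpec(seed=4), SMALL_OPTICS.image_shape)
        s = make_sample_m2(2, bg, SMALL_OPTICS, NoiseSpec(snr_db=NOISE_FREE),
                           seed=11, apply_degradation=False)
        clean = render_scene(sample_scene(2, SMALL_OPTICS, rng_seed=11))
        for r, c in [(3, 5), (20, 30), (40, 10)]:
            assert s.image[r, c] == pytest.approx(bg[r, c] + clean[r, c] - 1.0,
                                                  abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_sample_m2(1, np.ones((8, 8)), SMALL_OPTICS, NoiseSpec(), seed=0)


class TestPatchLibrary:
    def test_size_and_labels(self):
        lib = build_patch_library(12, SMALL_OPTICS, patch_side=16, seed=0)
        assert len(lib) == 12
        assert all(lab >= 1 for _, lab in lib.patches)
        assert all(p.shape == (16, 16) for p, _ in lib.patches)

    def test_patch_centred_on_particle(self):
        # unit-amplitude particle: the extremal intensity deviation sits at
        # the particle, within the <=2 px shift induced by the plane-wave
        # interference along the propagation axis
        lib = build_patch_library(5, SMALL_OPTICS, amplitude_range=(1.0, 1.0),
                                  patch_side=17, seed=1, snr_db=NOISE_FREE)
        for patch, _ in lib.patches:
            c = patch.shape[0] // 2
            win = np.abs(patch[c - 5:c + 6, c - 5:c + 6] - 1.0)
            r, cc = np.unravel_index(np.argmax(win), win.shape)
            assert abs(r - 5) <= 2 and abs(cc - 5) <= 2

    def test_patch_too_large_rejected(self):
        with pytest.raises(ValueError):
            build_patch_library(1, SMALL_OPTICS, patch_side=64)


class TestMethod3:
    @pytest.fixture()
    def library(self):
        return build_patch_library(8, SMALL_OPTICS, patch_side=16, seed=2)

    def test_zero_particles_background_unchanged(self, library):
        bg = gen_background(BackgroundSpec(seed=5), (48, 48))
        s = make_sample_m3(0, library, bg, seed=0)
        np.testing.assert_array_equal(s.image, bg)

    def test_two_single_patches_count_two(self, library):
        bg = np.ones((48, 48))
        s = make_sample_m3(2, library, bg, seed=1)
        assert s.n_particles == 2
        assert s.label == 2

    def test_paste_mean_shift_arithmetic(self, library):
        # total intensity added = w^2 * (patch mean - patch border mean)
        from spmcount.dataset import _border_mean
        bg = np.zeros((48, 48))
        s = make_sample_m3(1, library, bg, seed=3)
        added = s.image.sum() - bg.sum()
        rng = np.random.default_rng(3)
        idx = rng.integers(len(library.patches))  # same draw order as paste
        patch, _ = library.patches[idx]
        expected = patch.size * (patch.mean() - _border_mean(patch))
        assert added == pytest.approx(expected, abs=1e-10 * patch.size)


REDUCED = DatasetConfig(optics=SMALL_OPTICS, m1_per_condition=3, m2_per_class=4,
                        m3_per_class=2, n_backgrounds=5, n_patches=6)


class TestHybridManifest:
    def test_reduced_counts_per_class_and_method(self):
        man = build_hybrid_dataset(REDUCED, master_seed=1)
        per_class = man.per_class_counts()
        assert (per_class == 3 * 7 + 4 + 2).all()
        per_method = man.per_method_counts()
        assert (per_method["M1"] == 21).all()
        assert (per_method["M2"] == 4).all()
        assert (per_method["M3"] == 2).all()

    def test_label_rule_in_manifest(self):
        man = build_hybrid_dataset(REDUCED, master_seed=1)
        df = man.records
        assert (df["label"] == df["n_particles"].clip(upper=10)).all()
        others = df[df["label"] == 10]
        assert others["n_particles"].between(10, 14).all()
        assert (df.loc[df["label"] < 10, "n_particles"]
                == df.loc[df["label"] < 10, "label"]).all()

    def test_paths_unique(self):
        man = build_hybrid_dataset(REDUCED, master_seed=1)
        assert man.records["path"].is_unique

    def test_manifest_bit_determinism(self):
        a = build_hybrid_dataset(REDUCED, master_seed=42)
        b = build_hybrid_dataset(REDUCED, master_seed=42)
        assert a.manifest_digest() == b.manifest_digest()
        c = build_hybrid_dataset(REDUCED, master_seed=43)
        assert a.manifest_digest() != c.manifest_digest()


class TestSplit:
    def test_split_disjoint_exhaustive_stratified(self):
        man = split_manifest(build_hybrid_dataset(REDUCED, master_seed=2), seed=0)
        counts = man.split_counts()
        n = REDUCED.per_class_total
        assert (counts["val"] == n // 10).all()
        assert (counts["test"] == n // 10).all()
        assert (counts["train"] == n - 2 * (n // 10)).all()
        assert set(man.records["split"]) == {"train", "val", "test"}

    def test_tiny_class_rejected(self):
        tiny = DatasetConfig(optics=SMALL_OPTICS, m1_per_condition=1,
                             m2_per_class=1, m3_per_class=1,
                             noise_grid=(NOISE_FREE,))
        with pytest.raises(ValueError):
            split_manifest(build_hybrid_dataset(tiny, master_seed=0))


class TestWriteImages:
    def test_quantize_policies(self):
        assert (quantize_image(np.full((4, 4), 7.0)) == 128).all()
        rng = np.random.default_rng(0)
        q = quantize_image(rng.uniform(0, 1, (16, 16)))
        assert q.min() == 0 and q.max() == 255

    def test_png_array_shape(self):
        arr = sample_to_png_array(np.random.default_rng(1).uniform(0, 1, (48, 48)))
        assert arr.shape == (224, 224, 3)
        assert (arr[..., 0] == arr[..., 1]).all()

    def test_written_tree(self, tmp_path):
        cfg = dataclasses.replace(REDUCED, m1_per_condition=4, m2_per_class=1,
                                  m3_per_class=1, noise_grid=(NOISE_FREE, 15.0))
        man = split_manifest(build_hybrid_dataset(cfg, master_seed=3), seed=1)
        out = write_images(man, tmp_path / "ds")
        first = man.records.iloc[0]["path"]
        with Image.open(out / first) as im:
            arr = np.asarray(im)
        assert arr.shape == (224, 224, 3)
        assert (out / "manifest.csv").exists()
        assert (out / "config.json").exists()

    def test_blank_noise_free_png_is_mid_gray(self, tmp_path):
        from spmcount.dataset import make_sample_m1
        s = make_sample_m1(0, NoiseSpec(snr_db=NOISE_FREE), SMALL_OPTICS, seed=0)
        arr = sample_to_png_array(s.image)
        assert (arr == 128).all()


def test_blank_images_receive_reference_scaled_noise():
    """N=0 records under finite SNR get noise scaled to the instrument power."""
    from spmcount.dataset import load_dataset_arrays
    cfg = dataclasses.replace(REDUCED, m2_per_class=1, m3_per_class=1,
                              m1_per_condition=2)
    man = build_hybrid_dataset(cfg, master_seed=5)
    df = man.records
    blank_noisy = df[(df["label"] == 0) & (df["method"] == "M1")
                     & (df["snr_db"] == 15.0)]
    assert len(blank_noisy) > 0
    sub = man.records.loc[blank_noisy.index]
    reduced = dataclasses.replace(man, records=sub)
    images, labels = load_dataset_arrays(reduced)
    assert (labels == 0).all()
    assert images.std() > 0  # noise actually injected despite flat clean image
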