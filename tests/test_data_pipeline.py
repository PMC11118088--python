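import numpy as np
import pytest
from PIL import Image

from vesselseg.data_pipeline import (
    PreprocessConfig,
    augment,
    normalize_to_unit_range,
    preprocess,
    prepare_sample,
    read_dataset,
    resize_mask,
    write_dataset,
)
from vesselseg.errors import DatasetError
from vesselseg.phantom import PhantomSpec, generate_phantom, is_connected


def _write_pair(root, stem, size=(16, 20), mask_name=None):
    (root / "images").mkdir(exist_ok=True, parents=True)
    (root / "masks").mkdir(exist_ok=True, parents=True)
    rng = np.random.default_rng(abs(hash(stem)) % 1000)
    img = rng.integers(0, 255, (*size, 3), dtype=np.uint8)
    Image.fromarray(img).save(root / "images" / f"{stem}.png")
    mask = (rng.random(size) > 0.8).astype(np.uint8) * 255
    Image.fromarray(mask).save(root / "masks" / f"{mask_name or stem}.png")


class TestReadDataset:
    def test_enumeration_in_filename_order(self, tmp_path):
        for stem in ("c_03", "a_01", "b_02"):
            _write_pair(tmp_path, stem)
        samples = read_dataset(tmp_path)
        assert [s.source.split("/")[-1] for s in samples] == [
            "a_01.png", "b_02.png", "c_03.png"
        ]

    def test_missing_mask_names_the_stem(self, tmp_path):
        _write_pair(tmp_path, "img_a")
        (tmp_path / "images" / "orphan.png").write_bytes(
            (tmp_path / "images" / "img_a.png").read_bytes()
        )
        with pytest.raises(DatasetError, match="orphan"):
            read_dataset(tmp_path)

    def test_two_annotations_first_chosen(self, tmp_path):
        (tmp_path / "images").mkdir(parents=True)
        (tmp_path / "masks").mkdir(parents=True)
        img = np.zeros((10, 10, 3), np.uint8)
        Image.fromarray(img).save(tmp_path / "images" / "Image_01L.png")
        first = np.zeros((10, 10), np.uint8)
        first[0, 0] = 255
        second = np.zeros((10, 10), np.uint8)
        second[5, 5] = 255
        Image.fromarray(first).save(tmp_path / "masks" / "Image_01L_1stHO.png")
        Image.fromarray(second).save(tmp_path / "masks" / "Image_01L_2ndHO.png")
        (s,) = read_dataset(tmp_path, layout="chasedb1")
        assert s.mask[0, 0] == 1 and s.mask[5, 5] == 0

    def test_empty_directory_is_clean_error(self, tmp_path):
        (tmp_path / "images").mkdir()
        (tmp_path / "masks").mkdir()
        with pytest.raises(DatasetError):
            read_dataset(tmp_path)


class TestPreprocess:
    def test_resize_target(self):
        img = np.random.default_rng(0).integers(0, 255, (584, 565, 3), dtype=np.uint8)
        out = preprocess(img, PreprocessConfig(target_size=448))
        assert out.shape == (448, 448, 3)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_normalization_mapping(self):
        out = normalize_to_unit_range(np.full((4, 4, 3), 128, np.uint8))
        np.testing.assert_allclose(out, 128 / 127.5 - 1.0, atol=1e-6)
        assert abs(out[0, 0, 0] - 0.0039) < 1e-3

    def test_identity_chain_is_pure_mapping(self):
        img = np.random.default_rng(1).integers(0, 255, (32, 32, 3), dtype=np.uint8)
        out = preprocess(img, PreprocessConfig(target_size=32, clahe=False, gamma=1.0))
        np.testing.assert_allclose(out, img / 127.5 - 1.0, atol=1e-6)

    def test_mask_resize_preserves_binarity(self):
        mask = (np.random.default_rng(2).random((37, 41)) > 0.7).astype(np.uint8)
        out = resize_mask(mask, 448)
        assert set(np.unique(out)) <= {0, 1}

    def test_non_rgb_rejected(self):
        with pytest.raises(DatasetError):
            preprocess(np.zeros((10, 10), np.uint8))


class TestAugment:
    def _sample(self):
        return generate_phantom(PhantomSpec(size=64, depth=3, seed=1))

    def test_deterministic_for_seed(self):
        s = self._sample()
        a1 = augment(s, 5)
        a2 = augment(s, 5)
        np.testing.assert_array_equal(a1.image, a2.image)
        np.testing.assert_array_equal(a1.mask, a2.mask)

    def test_flip_is_involution_and_area_preserving(self):
        s = self._sample()
        seen_flip = False
        for seed in range(12):
            a = augment(s, seed)
            assert a.mask.sum() == s.mask.sum()
            if not np.array_equal(a.image, s.image):
                seen_flip = True
                b = augment(a, seed)  # same flips applied again
                np.testing.assert_array_equal(b.image, s.image)
                np.testing.assert_array_equal(b.mask, s.mask)
        assert seen_flip

    def test_mask_follows_image(self):
        s = self._sample()
        for seed in range(8):
            a = augment(s, seed)
            # vessel pixels must stay dark relative to FOV background
            lum = a.image.mean(axis=-1)
            assert lum[a.mask > 0].mean() < lum[(a.mask == 0) & (a.fov > 0)].mean()


class TestPhantom:
    def test_determinism(self):
        s1 = generate_phantom(PhantomSpec(size=64, depth=4, seed=9))
        s2 = generate_phantom(PhantomSpec(size=64, depth=4, seed=9))
        np.testing.assert_array_equal(s1.image, s2.image)
        np.testing.assert_array_equal(s1.mask, s2.mask)

    @pytest.mark.parametrize("size,depth,seed", [
        (96, 5, 0), (96, 5, 1), (96, 5, 2), (96, 5, 3),
        (224, 7, 0), (224, 7, 1),
    ])
    def test_mask_is_single_connected_component(self, size, depth, seed):
        s = generate_phantom(PhantomSpec(size=size, depth=depth, seed=seed))
        assert is_connected(s.mask)

    def test_depth_monotone_foreground(self):
        areas = [
            generate_phantom(PhantomSpec(size=96, depth=d, seed=4)).mask.sum()
            for d in (1, 3, 5)
        ]
        assert areas[0] < areas[1] < areas[2]

    def test_depth_one_area_matches_segment_oracle(self):
        from vesselseg.phantom import _segments

        spec = PhantomSpec(size=128, depth=1, seed=2, noise_sd=0.0)
        (p0, p1, width, _gen), = _segments(spec)
        expected = np.linalg.norm(p1 - p0) * width + np.pi * (width / 2) ** 2
        area = generate_phantom(spec).mask.sum()
        assert abs(area - expected) / expected < 0.2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(depth=0).validate()
        with pytest.raises(ValueError):
            PhantomSpec(fov_radius=0.9).validate()
        with pytest.raises(ValueError):
            PhantomSpec(root_width=-1).validate()

    def test_samples_satisfy_invariants(self):
        s = generate_phantom(PhantomSpec(size=64, depth=3, seed=0))
        s.validate()
        assert s.image.dtype == np.float32

    def test_write_and_read_roundtrip(self, tmp_path):
        from vesselseg.phantom import generate_phantom_set

        samples = generate_phantom_set(2, PhantomSpec(size=64, depth=3, seed=0))
        write_dataset(samples, tmp_path / "ds")
        raws = read_dataset(tmp_path / "ds")
        assert len(raws) == 2
        np.testing.assert_array_equal(raws[0].mask, samples[0].mask)
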