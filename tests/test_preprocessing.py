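"""Slice-pipeline behaviour: IO, trimming, resizing, augmentation, split."""

import numpy as np
import pytest

from strokeseg.preprocessing import (SlicePair, Volume, augment,
                                     extract_slices, load_volume, normalize,
                                     preprocess_subject, remove_blank_slices,
                                     resize_slice, save_volume, split)


@pytest.fixture
def small_volume(rng):
    data = rng.random((10, 24, 24)).astype(np.float32)
    return Volume("sub-000", "DWI", data, spacing=(1.0, 1.0, 1.0))


class TestVolumeIO:
    def test_nifti_round_trip_bit_exact(self, small_volume, tmp_path):
        path = tmp_path / "vol.nii.gz"
        save_volume(small_volume, path)
        back = load_volume(path, "sub-000")
        np.testing.assert_array_equal(back.data, small_volume.data)
        assert back.spacing == small_volume.spacing

    def test_anisotropic_spacing_preserved(self, rng, tmp_path):
        vol = Volume("s", "FLAIR", rng.random((4, 8, 8)).astype(np.float32),
                     spacing=(5.0, 1.0, 2.0))
        path = tmp_path / "aniso.nii"
        save_volume(vol, path)
        assert load_volume(path).spacing == (5.0, 1.0, 2.0)

    def test_truncated_file_raises_with_path(self, tmp_path):
        bad = tmp_path / "broken.nii.gz"
        bad.write_bytes(b"\x1f\x8b not a real nifti")
        with pytest.raises(IOError, match="broken.nii.gz"):
            load_volume(bad)


class TestExtractSlices:
    def test_one_slice_per_axial_index(self, small_volume):
        slices = extract_slices(small_volume)
        assert len(slices) == 10
        np.testing.assert_array_equal(slices[3], small_volume.data[3])

    def test_single_slice_volume(self, rng):
        vol = Volume("s", "T1", rng.random((1, 8, 8)))
        assert len(extract_slices(vol)) == 1

    def test_total_count_across_subjects(self, rng):
        # 4 subjects x 153 slices = 612; the 64-subject case scales to 9792
        vols = [Volume(f"s{i}", "DWI", rng.random((153, 4, 4)))
                for i in range(4)]
        assert sum(len(extract_slices(v)) for v in vols) == 612


class TestBlankRemoval:
    def _stack(self, blank_flags, rng):
        slices, masks = [], []
        for is_blank in blank_flags:
            img = np.zeros((16, 16), dtype=np.float32)
            if not is_blank:
                img[4:12, 4:12] = 0.5 + 0.5 * rng.random((8, 8))
            slices.append(img)
            masks.append((img > 0.6).astype(np.uint8))
        return slices, masks

    def test_trims_only_the_ends(self, rng):
        flags = [True, True, False, False, False, False, False,
                 True, True, True]
        slices, masks = self._stack(flags, rng)
        kept_s, kept_m, idx = remove_blank_slices(slices, masks)
        assert idx == [2, 3, 4, 5, 6]
        assert len(kept_s) == len(kept_m) == 5

    def test_identity_when_nothing_blank(self, rng):
        slices, masks = self._stack([False] * 6, rng)
        _, _, idx = remove_blank_slices(slices, masks)
        assert idx == list(range(6))

    def test_interior_blank_slice_retained(self, rng):
        flags = [True, False, True, False, True]
        slices, masks = self._stack(flags, rng)
        _, _, idx = remove_blank_slices(slices, masks)
        assert idx == [1, 2, 3]

    def test_all_blank_yields_empty_with_warning(self, rng, caplog):
        slices, masks = self._stack([True] * 4, rng)
        with caplog.at_level("WARNING"):
            kept_s, kept_m, idx = remove_blank_slices(slices, masks)
        assert kept_s == [] and idx == []
        assert any("blank" in r.message for r in caplog.records)


class TestResize:
    def test_reference_resolution(self, rng):
        out = resize_slice(rng.random((230, 230)), 192)
        assert out.shape == (192, 192)

    def test_constant_image_stays_constant(self):
        out = resize_slice(np.full((100, 100), 0.7, dtype=np.float32), 64)
        np.testing.assert_allclose(out, 0.7, atol=1e-6)

    def test_mask_stays_binary_under_nearest(self, rng):
        mask = (rng.random((230, 230)) > 0.5).astype(np.uint8)
        out = resize_slice(mask, 192, kind="mask")
        assert set(np.unique(out)) <= {0, 1}

    def test_non_2d_rejected(self, rng):
        with pytest.raises(ValueError, match="2D"):
            resize_slice(rng.random((4, 4, 4)))


class TestNormalize:
    def test_min_max_arithmetic(self):
        np.testing.assert_allclose(normalize(np.array([10.0, 20.0, 30.0])),
                                   [0.0, 0.5, 1.0])

    def test_idempotent_on_full_range(self, rng):
        img = rng.random((8, 8)).astype(np.float32)
        img.flat[0], img.flat[1] = 0.0, 1.0
        np.testing.assert_allclose(normalize(img), img, atol=1e-7)

    def test_constant_slice_maps_to_zeros(self):
        out = normalize(np.full((5, 5), 3.3))
        np.testing.assert_array_equal(out, np.zeros((5, 5)))


class TestAugment:
    def _pairs(self, n, rng):
        out = []
        for i in range(n):
            img = rng.random((32, 32)).astype(np.float32)
            msk = (rng.random((32, 32)) > 0.8).astype(np.uint8)
            out.append(SlicePair(img, msk, "sub-000", i))
        return out

    def test_factor_exact_counts(self, rng):
        pairs = self._pairs(13, rng)
        assert len(augment(pairs, factor=3, seed=0)) == 39
        assert len(augment(pairs[:1], factor=3, seed=0)) == 3
        assert len(augment(pairs, factor=1, seed=0)) == 13

    def test_horizontal_flip_is_involution(self, rng):
        from strokeseg.preprocessing import _transform_pair

        img = rng.random((16, 16)).astype(np.float32)
        msk = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        i1, m1, _ = _transform_pair(img, msk, "flip", rng)
        i2, m2, _ = _transform_pair(i1, m1, "flip", rng)
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(m2, msk)

    def test_masks_stay_binary_and_paired(self, rng):
        pairs = self._pairs(6, rng)
        out = augment(pairs, factor=3, seed=4)
        for pair in out:
            assert set(np.unique(pair.mask)) <= {0, 1}
            assert pair.image.shape == pair.mask.shape
            assert pair.subject_id == "sub-000"

    def test_seeded_reproducibility(self, rng):
        pairs = self._pairs(5, rng)
        a = augment(pairs, factor=3, seed=11)
        b = augment(pairs, factor=3, seed=11)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.image, pb.image)
            assert pa.augmentation == pb.augmentation


class TestSplit:
    def test_eighty_twenty_counts(self):
        part = split(list(range(100)), 0.8, seed=0)
        assert len(part.train) == 80 and len(part.validation) == 20

    def test_seed_determinism_and_sensitivity(self):
        items = list(range(50))
        assert split(items, 0.8, seed=3).train == split(items, 0.8, 3).train
        assert split(items, 0.8, seed=3).train != split(items, 0.8, 4).train

    def test_union_is_input_multiset(self):
        items = [f"p{i}" for i in range(31)]
        part = split(items, 0.8, seed=9)
        assert sorted(part.train + part.validation) == sorted(items)

    def test_too_few_items_rejected(self):
        with pytest.raises(ValueError):
            split([1], 0.8)


class TestEndToEnd:
    def test_subject_pipeline_emits_valid_pairs(self, rng):
        from strokeseg.synthetic import PhantomSpec, make_phantom

        spec = PhantomSpec(n_slices=12, slice_size=64, blank_margins=(2, 3),
                           lesion_radius_range=(3.0, 8.0))
        vol, msk = make_phantom(spec, seed=5)
        pairs = preprocess_subject(vol, msk, target=48)
        assert 0 < len(pairs) <= 12 - 5
        for p in pairs:
            assert p.image.shape == (48, 48)
            assert p.image.min() >= 0.0 and p.image.max() <= 1.0
            assert set(np.unique(p.mask)) <= {0, 1}
            assert p.subject_id == vol.subject_id
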