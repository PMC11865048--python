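"""Data enhancement operators, five-fold expansion and the 8:1:1 split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mungseed import (
    AugmentConfig,
    SplitRatios,
    add_gaussian_noise,
    brighten,
    enhance_dataset,
    enhance_manifest,
    mirror,
    rotate,
    split_counts,
    split_dataset,
)

# Per-variety dataset ledger: effective images, after 5x enhancement,
# and the published train/val/test cells.
DATASET_LEDGER = [
    ("BLC", 1034, 5170, 4136, 517, 517),
    ("GL07C", 881, 4405, 3524, 440, 441),
    ("GL13C", 839, 4195, 3356, 419, 420),
    ("JL05C", 860, 4300, 3440, 430, 430),
    ("JL09C", 917, 4585, 3668, 458, 459),
    ("JL10C", 685, 3425, 2740, 342, 343),
    ("JL11C", 808, 4040, 3232, 404, 404),
    ("JL06C", 954, 4770, 3816, 477, 477),
]


class TestOperators:
    def test_brighten_identity_and_black(self, rng):
        img = (rng.uniform(size=(8, 8, 3)) * 255).astype(np.uint8)
        assert np.array_equal(brighten(img, 1.0), img)
        assert brighten(np.zeros((4, 4, 3), np.uint8), 2.0).max() == 0

    def test_brighten_clips(self):
        img = np.full((4, 4, 3), 200, np.uint8)
        assert (brighten(img, 2.0) == 255).all()

    def test_brighten_rejects_nonpositive_factor(self):
        with pytest.raises(ValueError):
            brighten(np.zeros((2, 2, 3), np.uint8), 0.0)

    def test_noise_degenerate_cases(self):
        img = np.full((4, 4, 3), 100, np.uint8)
        assert np.array_equal(add_gaussian_noise(img, 0.0, 0.0, seed=1), img)
        assert (add_gaussian_noise(img, 1.0, 0.0, seed=1) == 101).all()

    def test_noise_mean_shift(self):
        """Sample mean of the perturbation sits within 3 s.e. of the mean."""
        img = np.full((64, 64, 3), 128, np.uint8)
        noisy = add_gaussian_noise(img, 1.0, 1.5, seed=3)
        diff = noisy.astype(float) - img.astype(float)
        se = 1.5 / np.sqrt(diff.size)
        assert abs(diff.mean() - 1.0) < 3 * se + 0.02  # + uint8 rounding slack

    def test_noise_deterministic(self):
        img = np.full((8, 8, 3), 50, np.uint8)
        a = add_gaussian_noise(img, 1.0, 1.5, seed=9)
        assert np.array_equal(a, add_gaussian_noise(img, 1.0, 1.5, seed=9))

    def test_mirror_involution_and_index(self, rng):
        img = (rng.uniform(size=(6, 9, 3)) * 255).astype(np.uint8)
        assert np.array_equal(mirror(mirror(img)), img)
        flipped = mirror(img, "horizontal")
        assert np.array_equal(flipped[:, -1], img[:, 0])  # col 0 -> col W-1
        assert np.array_equal(mirror(img, "vertical")[-1], img[0])

    def test_mirror_symmetric_unchanged(self):
        img = np.zeros((5, 5, 3), np.uint8)
        img[:, 2] = 7
        assert np.array_equal(mirror(img), img)

    def test_rotate_identity_and_period(self, rng):
        img = (rng.uniform(size=(7, 7, 3)) * 255).astype(np.uint8)
        assert np.array_equal(rotate(img, 0), img)
        out = img
        for _ in range(4):
            out = rotate(out, 90)
        assert np.array_equal(out, img)

    def test_rotate_90_index_mapping(self):
        img = np.arange(9, dtype=np.uint8).reshape(3, 3)
        rot = rotate(np.stack([img] * 3, axis=-1), 90)[..., 0]
        # CCW quarter turn: (r, c) -> (W-1-c, r)
        for r in range(3):
            for c in range(3):
                assert rot[2 - c, r] == img[r, c]


class TestEnhance:
    def test_manifest_expansion_is_five_fold(self):
        manifest = pd.DataFrame({"path": [f"a/{i}.png" for i in range(7)],
                                 "label": ["x"] * 7, "split": "", "origin": "original"})
        out = enhance_manifest(manifest)
        assert len(out) == 35
        assert sorted(out["origin"].unique()) == sorted(
            ["original", "brightness", "noise", "mirror", "rotation"])

    def test_manifest_expansion_empty(self):
        empty = pd.DataFrame(columns=["path", "label", "split", "origin"])
        assert len(enhance_manifest(empty)) == 0

    @pytest.mark.parametrize("n_effective,n_enhanced",
                             [(row[1], row[2]) for row in DATASET_LEDGER])
    def test_published_class_counts(self, n_effective, n_enhanced):
        manifest = pd.DataFrame({"path": [f"p/{i}.png" for i in range(n_effective)],
                                 "label": "c", "split": "", "origin": "original"})
        assert len(enhance_manifest(manifest)) == n_enhanced

    def test_enhance_dataset_writes_variants(self, tiny_dataset, tmp_path):
        _, manifest = tiny_dataset
        out = enhance_dataset(manifest, tmp_path / "enh", AugmentConfig(rng_seed=1))
        assert len(out) == 5 * len(manifest)
        assert all(pd.Series(out["path"]).map(lambda p: __import__("os").path.exists(p)))

    def test_enhance_dataset_missing_files(self, tmp_path):
        manifest = pd.DataFrame({"path": ["nope/missing.png"], "label": "x",
                                 "split": "", "origin": "original"})
        with pytest.raises(FileNotFoundError, match="missing.png"):
            enhance_dataset(manifest, tmp_path)


class TestSplit:
    @pytest.mark.parametrize("name,eff,enh,tr,va,te", DATASET_LEDGER)
    def test_published_split_cells(self, name, eff, enh, tr, va, te):
        assert split_counts(enh) == (tr, va, te)

    def test_published_totals(self):
        parts = np.array([split_counts(row[2]) for row in DATASET_LEDGER])
        assert parts.sum(axis=0).tolist() == [27912, 3487, 3491]
        assert parts.sum() == 34890

    def test_small_n(self):
        assert split_counts(10) == (8, 1, 1)

    @given(st.integers(min_value=0, max_value=100000))
    @settings(max_examples=200, deadline=None)
    def test_split_counts_partition(self, n):
        tr, va, te = split_counts(n)
        assert tr + va + te == n
        assert min(tr, va, te) >= 0
        assert tr == (8 * n) // 10 and va == n // 10

    def test_split_dataset_stratified_disjoint(self):
        manifest = pd.DataFrame({
            "path": [f"p/{c}_{i}.png" for c in "abc" for i in range(50)],
            "label": [c for c in "abc" for _ in range(50)],
            "split": "", "origin": "original"})
        tr, va, te = split_dataset(manifest, seed=3)
        assert len(tr) == 120 and len(va) == 15 and len(te) == 15
        all_paths = pd.concat([tr, va, te])["path"]
        assert all_paths.is_unique and set(all_paths) == set(manifest["path"])
        for part, name in ((tr, "train"), (va, "val"), (te, "test")):
            assert (part["split"] == name).all()
            assert part["label"].value_counts().nunique() == 1  # stratified

    def test_split_dataset_deterministic(self):
        manifest = pd.DataFrame({"path": [f"{i}.png" for i in range(40)],
                                 "label": ["a"] * 20 + ["b"] * 20,
                                 "split": "", "origin": "original"})
        a = split_dataset(manifest, seed=11)
        b = split_dataset(manifest, seed=11)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_group_by_source_keeps_variants_together(self):
        base = pd.DataFrame({"path": [f"d/{i}.png" for i in range(20)],
                             "label": "a", "split": "", "origin": "original"})
        enhanced = enhance_manifest(base)
        tr, va, te = split_dataset(enhanced, seed=2, group_by_source=True)
        for part in (tr, va, te):
            stems = part["path"].str.extract(r"d/(\d+)")[0]
            for other in (tr, va, te):
                if other is part:
                    continue
                other_stems = other["path"].str.extract(r"d/(\d+)")[0]
                assert not set(stems) & set(other_stems)

    def test_ratio_validation(self):
        with pytest.raises(ValueError):
            SplitRatios(0.5, 0.2, 0.2)


def test_augment_config_validation():
    with pytest.raises(ValueError):
        AugmentConfig(brightness_factor=-1)
    with pytest.raises(ValueError):
        AugmentConfig(noise_sd=-0.1)
    with pytest.raises(ValueError):
        AugmentConfig(mirror_axis="diagonal")
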