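"""Similarity and overlap metrics: identities, conventions, small exact cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dwisynth.grid import VolumeGrid
from dwisynth.metrics import (
    LabelImage,
    dice,
    generalized_dice,
    interface_restrict,
    roi_mean_signal,
    tissue_contrast,
    zncc,
)


def gdsc_bruteforce(a: np.ndarray, b: np.ndarray, labels) -> float:
    """Literal double sum over labels and voxels; the independent oracle."""
    num = 0
    den = 0
    for lab in labels:
        for idx in np.ndindex(a.shape):
            i = 1 if a[idx] == lab else 0
            s = 1 if b[idx] == lab else 0
            num += i * s
            den += i + s
    return 1.0 if den == 0 else 2.0 * num / den


class TestROIMeanAndContrast:
    def test_mean_of_constant(self):
        img = np.full((4, 4, 4), 5.0)
        roi = np.zeros((4, 4, 4), dtype=bool)
        roi[:3, :3, :3] = True
        assert roi_mean_signal(img, roi) == 5.0

    def test_two_voxel_mean(self):
        img = np.zeros((2, 1, 1))
        img[0], img[1] = 1.0, 3.0
        assert roi_mean_signal(img, np.ones((2, 1, 1), dtype=bool)) == 2.0

    def test_small_roi_warns_but_returns(self, caplog):
        img = np.ones((3, 3, 3))
        roi = np.zeros((3, 3, 3), dtype=bool)
        roi[0, 0, 0] = True
        with caplog.at_level("WARNING"):
            value = roi_mean_signal(img, roi)
        assert value == 1.0
        assert any("voxels" in rec.message for rec in caplog.records)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_mean_signal(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))

    def test_contrast_identities(self):
        assert tissue_contrast(3.0, 3.0) == 0.0
        assert tissue_contrast(2.0, 0.0) == 1.0
        with pytest.raises(ValueError):
            tissue_contrast(0.0, 0.0)

    @given(
        s_a=st.floats(min_value=1e-3, max_value=1e3),
        s_b=st.floats(min_value=1e-3, max_value=1e3),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_contrast_symmetric_and_scale_invariant(self, s_a, s_b, c):
        assert tissue_contrast(s_a, s_b) == pytest.approx(tissue_contrast(s_b, s_a))
        assert tissue_contrast(c * s_a, c * s_b) == pytest.approx(
            tissue_contrast(s_a, s_b), rel=1e-9
        )


class TestZNCC:
    def test_positive_affine_map_gives_one(self, rng):
        img = rng.normal(size=(6, 6, 6))
        mask = np.ones(img.shape, dtype=bool)
        assert zncc(img, 2 * img + 7, mask) == pytest.approx(1.0, abs=1e-12)

    def test_negation_gives_minus_one(self, rng):
        img = rng.normal(size=(6, 6, 6))
        mask = np.ones(img.shape, dtype=bool)
        assert zncc(img, -img, mask) == pytest.approx(-1.0, abs=1e-12)

    def test_three_voxel_reversal(self):
        a = np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1)
        b = np.array([3.0, 2.0, 1.0]).reshape(3, 1, 1)
        assert zncc(a, b, np.ones((3, 1, 1), dtype=bool)) == pytest.approx(-1.0)

    def test_constant_image_rejected(self):
        mask = np.ones((3, 1, 1), dtype=bool)
        with pytest.raises(ValueError):
            zncc(np.ones((3, 1, 1)), np.arange(3.0).reshape(3, 1, 1), mask)

    def test_masked_region_only(self, rng):
        a = rng.normal(size=(5, 5, 5))
        b = 3 * a + 1
        b[0, 0, 0] = 1e6  # outlier outside the mask must not matter
        mask = np.ones(a.shape, dtype=bool)
        mask[0, 0, 0] = False
        assert zncc(a, b, mask) == pytest.approx(1.0, abs=1e-12)

    @given(
        gain_a=st.floats(min_value=0.01, max_value=100),
        off_a=st.floats(min_value=-50, max_value=50),
        gain_b=st.floats(min_value=0.01, max_value=100),
        off_b=st.floats(min_value=-50, max_value=50),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_invariant_under_independent_affine_maps(self, gain_a, off_a, gain_b, off_b):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(5, 5, 5))
        b = rng.normal(size=(5, 5, 5))
        mask = np.ones(a.shape, dtype=bool)
        base = zncc(a, b, mask)
        mapped = zncc(gain_a * a + off_a, gain_b * b + off_b, mask)
        assert -1.0 <= mapped <= 1.0
        assert mapped == pytest.approx(base, abs=1e-6)


class TestDice:
    def test_identical_nonempty(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0] = True
        assert dice(m, m) == 1.0

    def test_disjoint(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = np.zeros((3, 3, 3), dtype=bool)
        a[0], b[2] = True, True
        assert dice(a, b) == 0.0

    def test_small_exact_case(self):
        a = np.zeros((8, 1, 1), dtype=bool)
        b = np.zeros((8, 1, 1), dtype=bool)
        a[:4] = True
        b[1:5] = True  # |A|=|B|=4, overlap 3
        assert dice(a, b) == 0.75

    def test_both_empty_convention(self):
        empty = np.zeros((2, 2, 2), dtype=bool)
        assert dice(empty, empty) == 1.0


class TestGeneralizedDice:
    def test_identical_and_disjoint(self, rng):
        a = rng.integers(0, 4, size=(6, 6, 6))
        assert generalized_dice(a, a) == 1.0
        b = np.where(a > 0, a + 10, 0)  # same voxels, different label ids
        assert generalized_dice(a, b) == 0.0

    def test_toy_two_label_value(self):
        # per-label sizes (4, 2) vs (4, 2), overlaps (3, 1): 2*(3+1)/(8+4)
        a = np.zeros((8, 1, 1), dtype=int)
        b = np.zeros((8, 1, 1), dtype=int)
        a[:4, 0, 0] = 1
        b[1:5, 0, 0] = 1  # overlap 3
        a[5:7, 0, 0] = 2
        b[6:8, 0, 0] = 2  # overlap 1
        assert generalized_dice(a, b, labels=[1, 2]) == pytest.approx(8 / 12)
        assert gdsc_bruteforce(a, b, [1, 2]) == pytest.approx(8 / 12)

    def test_single_label_reduces_to_dice(self, rng):
        a = rng.integers(0, 2, size=(7, 7, 7))
        b = rng.integers(0, 2, size=(7, 7, 7))
        assert generalized_dice(a, b, labels=[1]) == pytest.approx(dice(a == 1, b == 1))

    def test_matches_bruteforce_oracle_on_random_images(self, rng):
        for _ in range(20):
            shape = tuple(rng.integers(2, 9, size=3))
            a = rng.integers(0, 5, size=shape)
            b = rng.integers(0, 5, size=shape)
            labels = [1, 2, 3, 4]
            assert generalized_dice(a, b, labels) == gdsc_bruteforce(a, b, labels)

    def test_dissimilarity_switch_is_complement(self, rng):
        a = rng.integers(0, 3, size=(5, 5, 5))
        b = rng.integers(0, 3, size=(5, 5, 5))
        sim = generalized_dice(a, b)
        assert generalized_dice(a, b, dissimilarity=True) == pytest.approx(1 - sim)


class TestInterfaceRestrict:
    @pytest.mark.parametrize(
        "wm_offset, kept",
        [
            ((1, 1, 0), True),   # face neighbour
            ((1, 0, 1), True),   # face neighbour (other axis)
            ((0, 1, 2), True),   # edge neighbour
            ((0, 0, 0), False),  # corner-only neighbour: excluded
        ],
    )
    def test_18_connectivity_rule(self, wm_offset, kept):
        labels = np.zeros((3, 3, 3), dtype=int)
        labels[1, 1, 1] = 7
        wm = np.zeros((3, 3, 3), dtype=bool)
        wm[wm_offset] = True
        out = interface_restrict(labels, wm)
        assert bool(out[1, 1, 1] == 7) is kept

    def test_empty_wm_removes_everything(self, rng):
        labels = rng.integers(0, 4, size=(4, 4, 4))
        out = interface_restrict(labels, np.zeros((4, 4, 4), dtype=bool))
        assert np.all(out == 0)

    def test_label_image_wrapper_preserved(self):
        grid = VolumeGrid(shape=(3, 3, 3), affine=np.eye(4))
        li = LabelImage(labels=np.ones((3, 3, 3), dtype=int), grid=grid, names={1: "gm"})
        out = interface_restrict(li, np.ones((3, 3, 3), dtype=bool))
        assert isinstance(out, LabelImage)
        assert out.names == {1: "gm"}
        assert np.all(out.labels == 1)
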