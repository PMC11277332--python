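import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voitex import (
    VOIMask,
    build_glcm,
    extract_texture_vector,
    haralick,
    quantize,
)
from voitex.glcm import GLCM, PARAMETERS, glcm_counts

from conftest import (
    WORKED_COUNTS_0DEG,
    full_mask,
    make_volume,
    random_volume_and_mask,
)
from oracles import glcm_bruteforce, haralick_bruteforce, random_symmetric_glcm


# ---------------------------------------------------------------- quantize


def test_quantize_equal_width_binning():
    vol = make_volume(np.array([0.0, 50.0, 100.0]).reshape(3, 1, 1))
    q = quantize(vol, full_mask((3, 1, 1)), n_levels=4)
    assert q.levels.ravel().tolist() == [0, 2, 3]
    assert not q.degenerate


def test_quantize_constant_voi_flags_degenerate():
    vol = make_volume(np.full((4, 4, 2), 7.0))
    q = quantize(vol, full_mask((4, 4, 2)), n_levels=128)
    assert q.degenerate
    assert set(q.levels[q.mask].tolist()) == {0}


def test_quantize_positive_affine_invariance():
    rng = np.random.default_rng(11)
    vox = rng.normal(50, 20, size=(6, 6, 2))
    mask = full_mask((6, 6, 2))
    q1 = quantize(make_volume(vox), mask, 16)
    q2 = quantize(make_volume(3.5 * vox + 200.0), mask, 16)
    np.testing.assert_array_equal(q1.levels, q2.levels)


def test_quantize_ignores_out_of_mask_intensities():
    vox = np.zeros((3, 3, 1))
    vox[0, 0, 0] = 1e6  # extreme value outside the mask must not shift bins
    mask = np.zeros((3, 3, 1), dtype=bool)
    mask[1:, 1:, 0] = True
    vox[1:, 1:, 0] = [[0, 1], [2, 3]]
    q = quantize(make_volume(vox), VOIMask(voxels=mask), 4)
    assert sorted(q.levels[mask].tolist()) == [0, 1, 2, 3]
    assert q.levels[0, 0, 0] == -1


def test_quantize_needs_two_levels():
    vol = make_volume(np.zeros((2, 2, 1)))
    with pytest.raises(ValueError, match="at least 2"):
        quantize(vol, full_mask((2, 2, 1)), n_levels=1)


# ---------------------------------------------------------------- build_glcm


def test_worked_example_counts(worked_volume):
    vol, mask = worked_volume
    q = quantize(vol, mask, n_levels=4)
    counts = glcm_counts(q, 1, angles=(0,))
    np.testing.assert_array_equal(counts, WORKED_COUNTS_0DEG)
    assert counts.sum() == 24
    g = build_glcm(q, 1, angles=(0,))
    assert g.total_pairs == 24


def test_worked_example_contrast_and_uniformity(worked_volume):
    vol, mask = worked_volume
    q = quantize(vol, mask, n_levels=4)
    vals, _ = haralick(build_glcm(q, 1, angles=(0,)))
    assert vals["contrast"] == pytest.approx(14 / 24, abs=1e-12)
    assert vals["uniformity"] == pytest.approx(84 / 576, abs=1e-12)


def test_constant_region_mass_at_origin():
    vol = make_volume(np.full((5, 5, 2), 3.0))
    for d in (1, 2):
        g = build_glcm(quantize(vol, full_mask((5, 5, 2)), 8), d)
        assert g.p[0, 0] == 1.0


def test_glcm_matches_bruteforce_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(30):
        shape = (int(rng.integers(3, 11)), int(rng.integers(3, 11)), int(rng.integers(1, 4)))
        L = int(rng.integers(2, 9))
        d = int(rng.integers(1, 3))
        vol, mask = random_volume_and_mask(rng, shape, L)
        q = quantize(vol, mask, L)
        expected = glcm_bruteforce(q.levels, mask.voxels, L, d)
        if expected.sum() == 0:
            with pytest.raises(ValueError, match="too small"):
                build_glcm(q, d)
            continue
        np.testing.assert_array_equal(glcm_counts(q, d), expected)


def test_glcm_too_small_voi_raises():
    mask = np.zeros((4, 4, 1), dtype=bool)
    mask[0, 0, 0] = True
    mask[3, 3, 0] = True  # no pair at distance 1
    vol = make_volume(np.arange(16, dtype=float).reshape(4, 4, 1))
    q = quantize(vol, VOIMask(voxels=mask), 4)
    with pytest.raises(ValueError, match="too small for distance 1"):
        build_glcm(q, 1)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_glcm_symmetric_and_normalized(seed):
    rng = np.random.default_rng(seed)
    vol, mask = random_volume_and_mask(rng, (7, 7, 2), 6)
    q = quantize(vol, mask, 6)
    try:
        g = build_glcm(q, 1)
    except ValueError:
        return
    np.testing.assert_array_equal(g.p, g.p.T)
    assert g.p.sum() == pytest.approx(1.0, abs=1e-9)
    assert (g.p >= 0).all()


# ---------------------------------------------------------------- haralick


def test_haralick_constant_region_limits():
    vol = make_volume(np.full((6, 6, 2), 42.0))
    mask = full_mask((6, 6, 2))
    q = quantize(vol, mask, 128)
    g = build_glcm(q, 1)
    vals, flags = haralick(g)
    assert vals["uniformity"] == 1.0
    assert vals["contrast"] == 0.0
    assert vals["entropy"] == 0.0
    assert vals["homogeneity"] == 1.0
    assert vals["variance"] == 0.0
    assert vals["sum_entropy"] == 0.0
    assert vals["difference_entropy"] == 0.0
    assert vals["correlation"] == 0.0
    assert "correlation" in flags


def test_haralick_matches_double_loop_oracle():
    rng = np.random.default_rng(123)
    for _ in range(50):
        p = random_symmetric_glcm(rng, L=8)
        g = GLCM(p=p, distance=1, total_pairs=100)
        vals, _ = haralick(g)
        expected = haralick_bruteforce(p)
        for name in PARAMETERS:
            assert vals[name] == pytest.approx(expected[name], abs=1e-10), name


def test_haralick_rejects_unnormalized_matrix():
    with pytest.raises(ValueError, match="sum to 1"):
        GLCM(p=np.ones((4, 4)), distance=1, total_pairs=10)


def test_haralick_log_base_rescales_entropies():
    rng = np.random.default_rng(5)
    p = random_symmetric_glcm(rng, 6)
    g = GLCM(p=p, distance=1, total_pairs=50)
    nat, _ = haralick(g, log_base=None)
    two, _ = haralick(g, log_base=2.0)
    for name in ("entropy", "sum_entropy", "difference_entropy"):
        assert two[name] == pytest.approx(nat[name] / math.log(2), rel=1e-12)
    assert two["contrast"] == nat["contrast"]


def test_haralick_bounds_on_random_matrices():
    rng = np.random.default_rng(9)
    L = 8
    for _ in range(20):
        p = random_symmetric_glcm(rng, L)
        vals, _ = haralick(GLCM(p=p, distance=1, total_pairs=64))
        assert vals["contrast"] >= 0
        assert 0 <= vals["uniformity"] <= 1
        assert 0 < vals["homogeneity"] <= 1
        assert vals["entropy"] >= 0
        assert vals["entropy"] <= math.log(L * L) + 1e-9
        assert -1 - 1e-9 <= vals["correlation"] <= 1 + 1e-9


# ---------------------------------------------------------------- extraction


def test_extract_vector_has_55_finite_values():
    rng = np.random.default_rng(2)
    vol, mask = random_volume_and_mask(rng, (12, 12, 3), 32)
    tv = extract_texture_vector(vol, mask, "P0")
    assert len(tv.values) == 55
    assert all(np.isfinite(v) for v in tv.values.values())
    assert set(p for p, _ in tv.values) == set(PARAMETERS)


def test_extract_constant_phantom_limits():
    vol = make_volume(np.full((12, 12, 4), 5.0))
    tv = extract_texture_vector(vol, full_mask((12, 12, 4)), "P0")
    for d in range(1, 6):
        assert tv.values[("uniformity", d)] == 1.0
        assert tv.values[("entropy", d)] == 0.0


def test_extract_slice_permutation_invariant():
    rng = np.random.default_rng(8)
    vol, mask = random_volume_and_mask(rng, (10, 10, 4), 16)
    perm = [2, 0, 3, 1]
    vol_p = make_volume(vol.voxels[:, :, perm])
    mask_p = VOIMask(voxels=mask.voxels[:, :, perm])
    tv1 = extract_texture_vector(vol, mask, "a")
    tv2 = extract_texture_vector(vol_p, mask_p, "b")
    assert tv1.values == tv2.values


def test_extract_rotation_invariant():
    rng = np.random.default_rng(13)
    vol, mask = random_volume_and_mask(rng, (9, 9, 2), 16)
    vol_r = make_volume(np.rot90(vol.voxels, axes=(0, 1)))
    mask_r = VOIMask(voxels=np.rot90(mask.voxels, axes=(0, 1)))
    tv1 = extract_texture_vector(vol, mask, "a")
    tv2 = extract_texture_vector(vol_r, mask_r, "b")
    for key, v in tv1.values.items():
        assert tv2.values[key] == pytest.approx(v, rel=1e-9), key


def test_extract_affine_intensity_invariant():
    rng = np.random.default_rng(21)
    vol, mask = random_volume_and_mask(rng, (10, 10, 2), 64)
    vol2 = make_volume(2.5 * vol.voxels - 1000.0)
    tv1 = extract_texture_vector(vol, mask, "a")
    tv2 = extract_texture_vector(vol2, mask, "b")
    assert tv1.values == tv2.values


def test_noise_increases_entropy_decreases_homogeneity():
    """Median entropy is non-decreasing and median homogeneity non-increasing
    as i.i.d. noise of growing amplitude is added to a fixed smooth phantom."""
    from scipy.ndimage import gaussian_filter

    base_rng = np.random.default_rng(100)
    base = gaussian_filter(base_rng.normal(0, 30, size=(24, 24, 3)), (2.5, 2.5, 0))
    mask = full_mask((24, 24, 3))
    # amplitudes below the saturation of the sample-limited GLCM entropy
    amplitudes = [0.0, 2.0, 5.0, 20.0]
    med_ent, med_hom = [], []
    for amp in amplitudes:
        ents, homs = [], []
        for s in range(20):
            rng = np.random.default_rng([200, s])
            vol = make_volume(base + rng.normal(0, amp, size=base.shape) if amp else base)
            tv = extract_texture_vector(vol, mask, "x", distances=(1,), n_levels=32)
            ents.append(tv.values[("entropy", 1)])
            homs.append(tv.values[("homogeneity", 1)])
        med_ent.append(np.median(ents))
        med_hom.append(np.median(homs))
    assert all(a <= b + 1e-12 for a, b in zip(med_ent, med_ent[1:]))
    assert all(a >= b - 1e-12 for a, b in zip(med_hom, med_hom[1:]))


def test_per_slice_mean_mode_matches_pooled_on_single_slice():
    rng = np.random.default_rng(31)
    vol, mask = random_volume_and_mask(rng, (10, 10, 1), 16)
    pooled = extract_texture_vector(vol, mask, "a", pooling="pooled")
    per_slice = extract_texture_vector(vol, mask, "a", pooling="per_slice_mean")
    for key, v in pooled.values.items():
        assert per_slice.values[key] == pytest.approx(v, rel=1e-12)


def test_extract_all_distances_invalid_raises():
    mask = np.zeros((3, 3, 1), dtype=bool)
    mask[1, 1, 0] = True
    vol = make_volume(np.ones((3, 3, 1)))
    with pytest.raises(ValueError, match="no distance"):
        extract_texture_vector(vol, VOIMask(voxels=mask), "x")
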