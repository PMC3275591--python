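import numpy as np
import pytest
from scipy import stats as sps

from dtivba.stats import spearman
from dtivba.vba import (
    RegisteredStack,
    StatMap,
    apply_affine,
    apply_displacement,
    build_stack,
    estimate_affine,
    gaussian_kernel,
    multi_template_consensus,
    resample_like,
    smooth_map,
    voxelwise_correlation,
    voxelwise_group_test,
)


def _stack(data, mask=None, ids=None):
    data = np.asarray(data, dtype=float)
    if mask is None:
        mask = np.ones(data.shape[1:], dtype=bool)
    if ids is None:
        ids = [f"s{i}" for i in range(data.shape[0])]
    return RegisteredStack(data, mask, ids, ids[0], np.ones(3))


# ---------------------------------------------------------------------------
# kernels and smoothing


def test_gaussian_kernel_normalized_and_symmetric():
    k = gaussian_kernel(3, 1.0)
    assert k.shape == (3, 3, 3)
    assert k.sum() == pytest.approx(1.0, abs=1e-14)
    assert np.allclose(k, k[::-1, ::-1, ::-1])
    assert k[1, 1, 1] == k.max()


def test_gaussian_kernel_even_size_error():
    with pytest.raises(ValueError, match="odd"):
        gaussian_kernel(4)


def test_smooth_map_preserves_constants_inside_mask(rng):
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[2:6, 2:6, 2:6] = True
    vol = np.where(mask, 3.7, 0.0)
    out = smooth_map(vol, mask)
    # renormalized weights: constant in-mask values stay exactly constant
    assert np.allclose(out[mask], 3.7, atol=1e-12)
    assert np.all(out[~mask] == 0.0)


def test_smooth_map_matches_manual_renormalization(rng):
    mask = rng.random((6, 6, 6)) > 0.3
    vol = rng.normal(size=(6, 6, 6))
    out = smooth_map(vol, mask, kernel=3, sigma=1.0)
    k = gaussian_kernel(3, 1.0)
    # direct per-voxel oracle
    pad_v = np.pad(np.where(mask, vol, 0.0), 1)
    pad_m = np.pad(mask.astype(float), 1)
    for x, y, z in [(0, 0, 0), (2, 3, 1), (5, 5, 5), (3, 2, 4)]:
        if not mask[x, y, z]:
            continue
        wv = (pad_v[x : x + 3, y : y + 3, z : z + 3] * k[::-1, ::-1, ::-1]).sum()
        wm = (pad_m[x : x + 3, y : y + 3, z : z + 3] * k[::-1, ::-1, ::-1]).sum()
        assert out[x, y, z] == pytest.approx(wv / wm, rel=1e-12)


def test_smooth_map_impulse_spreads():
    vol = np.zeros((7, 7, 7))
    vol[3, 3, 3] = 1.0
    out = smooth_map(vol)  # no mask: plain convolution
    assert out[3, 3, 3] < 1.0
    assert out[3, 3, 4] > 0.0
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# transforms


def test_apply_affine_integer_translation_oracle(rng):
    vol = rng.normal(size=(8, 8, 8))
    A = np.eye(4)
    A[:3, 3] = [2, 0, 0]  # output x reads input x+2
    out = apply_affine(vol, A)
    assert np.allclose(out[:6], vol[2:])
    assert np.allclose(out[6:], 0.0)  # out-of-volume filled with the constant


def test_apply_affine_shape_error():
    with pytest.raises(ValueError, match="4x4"):
        apply_affine(np.zeros((4, 4, 4)), np.eye(3))


def test_apply_displacement_matches_affine_translation(rng):
    vol = rng.normal(size=(8, 8, 8))
    A = np.eye(4)
    A[:3, 3] = [1, 2, 0]
    disp = np.zeros((8, 8, 8, 3))
    disp[..., 0] = 1.0
    disp[..., 1] = 2.0
    assert np.allclose(apply_displacement(vol, disp), apply_affine(vol, A), atol=1e-9)


def test_apply_displacement_shape_error():
    with pytest.raises(ValueError, match="grid-shaped"):
        apply_displacement(np.zeros((4, 4, 4)), np.zeros((4, 4, 2)))


def _blob(shape=(24, 24, 24), shift=(0, 0, 0)):
    idx = np.indices(shape).astype(float)
    c = [(s - 1) / 2.0 + d for s, d in zip(shape, shift)]
    r2 = sum(((g - cc) / a) ** 2 for g, cc, a in zip(idx, c, (8, 7, 6)))
    return np.exp(-r2)


def test_estimate_affine_recovers_translation():
    fixed = _blob()
    moving = _blob(shift=(2, -1, 0))
    tr = estimate_affine(moving, fixed, (0.35, 0.35, 0.35), seed=5)
    aligned = resample_like(moving, fixed, tr, (0.35, 0.35, 0.35))
    before = np.corrcoef(moving.ravel(), fixed.ravel())[0, 1]
    after = np.corrcoef(aligned.ravel(), fixed.ravel())[0, 1]
    assert after > 0.98
    assert after > before


# ---------------------------------------------------------------------------
# stacks


def test_build_stack_identity_and_affine(rng):
    base = rng.random((8, 8, 8))
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[1:7, 1:7, 1:7] = True
    A = np.eye(4)
    A[:3, 3] = [1, 0, 0]
    shifted = apply_affine(base, np.linalg.inv(A))  # shifted by -1 along x
    stack = build_stack(
        [base, shifted],
        [mask, mask],
        ["a", "b"],
        template_index=0,
        voxel_size=(1, 1, 1),
        transforms=[None, A],
        smooth_sigma=None,
    )
    assert stack.provenance == ["identity", "supplied_affine"]
    assert stack.template_id == "a"
    inner = np.zeros((8, 8, 8), dtype=bool)
    inner[2:6, 2:6, 2:6] = True
    assert np.allclose(stack.data[1][inner], base[inner], atol=1e-9)
    # analysis mask is the intersection of the resampled subject masks
    assert not stack.analysis_mask[~mask].any()


def test_build_stack_grid_mismatch_without_transform():
    with pytest.raises(ValueError, match="differs from the template grid"):
        build_stack(
            [np.zeros((4, 4, 4)), np.zeros((5, 5, 5))],
            [np.ones((4, 4, 4), bool), np.ones((5, 5, 5), bool)],
            ["a", "b"],
            0,
            (1, 1, 1),
        )


def test_build_stack_misaligned_inputs():
    with pytest.raises(ValueError, match="must align"):
        build_stack([np.zeros((4, 4, 4))], [], ["a"], 0, (1, 1, 1))


def test_build_stack_unsupported_transform():
    with pytest.raises(TypeError, match="unsupported transform"):
        build_stack(
            [np.zeros((4, 4, 4))] * 2,
            [np.ones((4, 4, 4), bool)] * 2,
            ["a", "b"],
            0,
            (1, 1, 1),
            transforms=[None, "rigid"],
        )


# ---------------------------------------------------------------------------
# voxel-wise statistics


def test_group_test_matches_scipy(rng):
    data = rng.normal(size=(9, 4, 4, 4))
    groups = ["control"] * 4 + ["IUGR"] * 5
    sm = voxelwise_group_test(_stack(data), groups)
    ref_t, ref_p = sps.ttest_ind(data[:4], data[4:], axis=0, equal_var=True)
    assert np.allclose(sm.statistic, ref_t, rtol=1e-10)
    assert np.allclose(sm.p, ref_p, rtol=1e-10)
    assert np.array_equal(sm.sig05, sm.defined_mask & (sm.p < 0.05))
    assert np.all(sm.sig01 <= sm.sig05)
    assert sm.extra["df"] == 7


def test_group_test_zero_variance_voxels():
    data = np.zeros((4, 2, 1, 1))
    data[:, 1, 0, 0] = [1.0, 1.0, 2.0, 2.0]  # constant within each group
    sm = voxelwise_group_test(_stack(data), ["control", "control", "IUGR", "IUGR"])
    assert sm.p[0, 0, 0] == 1.0  # identical everywhere -> no evidence
    assert not sm.defined_mask[1, 0, 0]  # zero variance, unequal means
    assert np.isnan(sm.p[1, 0, 0])


def test_group_test_needs_two_per_group():
    with pytest.raises(ValueError, match="2 subjects per group"):
        voxelwise_group_test(_stack(np.zeros((3, 2, 2, 2))), ["control", "IUGR", "IUGR"])


def test_correlation_matches_scalar_spearman(rng):
    data = rng.normal(size=(8, 3, 3, 3))
    scores = rng.integers(0, 4, 8).astype(float)
    while np.ptp(scores) == 0:
        scores = rng.integers(0, 4, 8).astype(float)
    sm = voxelwise_correlation(_stack(data), list(scores))
    for idx in [(0, 0, 0), (1, 2, 0), (2, 2, 2)]:
        ref = spearman(scores, data[(slice(None),) + idx])
        assert sm.statistic[idx] == pytest.approx(ref.statistic, abs=1e-12)
        assert sm.p[idx] == pytest.approx(ref.p_value, rel=1e-9)
    assert sm.kind == "spearman"
    assert "display_mask" in sm.extra


def test_correlation_drops_missing_scores(rng):
    data = rng.normal(size=(6, 2, 2, 2))
    scores = [1.0, 2.0, np.nan, 3.0, 4.0, 2.0]
    sm = voxelwise_correlation(_stack(data), scores)
    assert sm.extra["n"] == 5


def test_correlation_errors(rng):
    data = rng.normal(size=(6, 2, 2, 2))
    with pytest.raises(ValueError, match="constant"):
        voxelwise_correlation(_stack(data), [2.0] * 6)
    with pytest.raises(ValueError, match="at least 4"):
        voxelwise_correlation(_stack(data), [1.0, 2.0, 3.0] + [np.nan] * 3)


# ---------------------------------------------------------------------------
# consensus


def _statmap(sig01, sig05=None):
    sig01 = np.asarray(sig01, dtype=bool)
    sig05 = sig01 if sig05 is None else np.asarray(sig05, dtype=bool)
    defined = np.ones_like(sig01)
    z = np.zeros(sig01.shape)
    return StatMap(z, z, z, sig01, sig05, defined, "t")


def test_consensus_strict_intersection():
    a = np.zeros((3, 3, 3), dtype=bool)
    b = np.zeros((3, 3, 3), dtype=bool)
    a[0, 0, 0] = a[1, 1, 1] = True
    b[1, 1, 1] = b[2, 2, 2] = True
    cons, support = multi_template_consensus([_statmap(a), _statmap(b)], alpha=0.01)
    assert cons.sum() == 1 and cons[1, 1, 1]
    assert support[0, 0, 0] == 1 and support[1, 1, 1] == 2


def test_consensus_fraction():
    masks = [np.zeros((2, 2, 2), dtype=bool) for _ in range(3)]
    masks[0][0, 0, 0] = masks[1][0, 0, 0] = True
    cons, _ = multi_template_consensus(
        [_statmap(m) for m in masks], alpha=0.01, consensus_fraction=0.5
    )
    assert cons[0, 0, 0]  # 2 of 3 >= ceil(0.5 * 3)
    strict, _ = multi_template_consensus([_statmap(m) for m in masks], alpha=0.01)
    assert not strict.any()


def test_consensus_alpha_selects_mask_level():
    sig01 = np.zeros((2, 2, 2), dtype=bool)
    sig05 = np.ones((2, 2, 2), dtype=bool)
    maps = [_statmap(sig01, sig05)] * 2
    c01, _ = multi_template_consensus(maps, alpha=0.01)
    c05, _ = multi_template_consensus(maps, alpha=0.05)
    assert not c01.any() and c05.all()


def test_consensus_errors():
    m = _statmap(np.zeros((2, 2, 2), dtype=bool))
    with pytest.raises(ValueError, match="at least 2"):
        multi_template_consensus([m])
    with pytest.raises(ValueError, match="alpha"):
        multi_template_consensus([m, m], alpha=0.1)
    other = _statmap(np.zeros((3, 3, 3), dtype=bool))
    with pytest.raises(ValueError, match="common reporting grid"):
        multi_template_consensus([m, other])
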