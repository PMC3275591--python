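import numpy as np
import pytest

from dtivba.gradients import default_scheme
from dtivba.phantom import (
    BehaviorCoupling,
    PhantomSpec,
    Region,
    _prolate,
    _region_fa_moments,
    default_spec,
    deviatoric_scale_for_fa,
    focal_effect_spec,
    generate_cohort,
    generate_ground_truth,
    generate_tensor_field,
    max_feasible_fa,
    null_spec,
    simulate_dwi,
)
from dtivba.tensor import eigenvalues_to_fa


def test_deviatoric_scale_hits_target_and_preserves_trace():
    lam = np.array([1.7e-3, 0.4e-3, 0.3e-3])
    for target in (0.05, 0.2, 0.5):
        out = deviatoric_scale_for_fa(lam, target)
        assert eigenvalues_to_fa(out) == pytest.approx(target, rel=1e-12)
        assert out.sum() == pytest.approx(lam.sum(), rel=1e-12)
    assert np.allclose(deviatoric_scale_for_fa(lam, 0.0), lam.mean())


def test_deviatoric_scale_errors():
    lam = np.array([1.7e-3, 0.4e-3, 0.3e-3])
    with pytest.raises(ValueError, match="out of range"):
        deviatoric_scale_for_fa(lam, 1.5)
    with pytest.raises(ValueError, match="isotropic"):
        deviatoric_scale_for_fa(np.full(3, 1e-3), 0.3)
    with pytest.raises(ValueError, match="negative"):
        deviatoric_scale_for_fa(lam, 0.999 * np.sqrt(1.5))


def test_max_feasible_fa_is_the_positivity_boundary():
    lam = np.array([1.7e-3, 0.4e-3, 0.3e-3])
    cap = max_feasible_fa(lam)
    out = deviatoric_scale_for_fa(lam, 0.999 * cap)
    assert out.min() >= 0
    with pytest.raises(ValueError, match="negative"):
        deviatoric_scale_for_fa(lam, min(1.001 * cap, 1.2))
    assert max_feasible_fa(np.full(3, 1e-3)) == 0.0


def test_prolate_eigenvalues_closed_form():
    lam = np.array(_prolate(0.44e-3, 0.25))
    assert lam.mean() == pytest.approx(0.44e-3, rel=1e-12)
    assert eigenvalues_to_fa(lam) == pytest.approx(0.25, rel=1e-12)
    assert lam[1] == lam[2]


def test_spec_validation_errors():
    mask = np.ones((4, 4, 4), dtype=bool)
    lam = _prolate(0.44e-3, 0.2)
    r1 = Region("a", mask, "GM", None, lam)
    r2 = Region("a", ~mask, "GM", None, lam)
    with pytest.raises(ValueError, match="duplicate region ids"):
        PhantomSpec((4, 4, 4), (1, 1, 1), [r1, r2])
    r3 = Region("b", mask, "GM", None, lam)  # overlaps r1
    with pytest.raises(ValueError, match="overlap"):
        PhantomSpec((4, 4, 4), (1, 1, 1), [r1, r3])
    with pytest.raises(ValueError, match="infeasible"):
        PhantomSpec((4, 4, 4), (1, 1, 1), [r1], group_effect={"a": 0.5})
    with pytest.raises(KeyError, match="no region"):
        PhantomSpec(
            (4, 4, 4),
            (1, 1, 1),
            [r1],
            behavior_couplings=[BehaviorCoupling("head_turn", "zz", 0.5)],
        )


def test_region_validation_errors():
    mask = np.ones((2, 2, 2), dtype=bool)
    with pytest.raises(ValueError, match="positive"):
        Region("r", mask, "GM", None, (1.0, 0.5, -0.1))
    with pytest.raises(ValueError, match="descending"):
        Region("r", mask, "GM", None, (0.5, 1.0, 0.4))
    with pytest.raises(ValueError, match="tissue class"):
        Region("r", mask, "CSF", None, (1.0, 0.5, 0.4))
    with pytest.raises(ValueError, match="fa_jitter_sd"):
        Region("r", mask, "GM", None, (1.0, 0.5, 0.4), fa_jitter_sd=-0.1)


def test_coupling_validation():
    with pytest.raises(ValueError, match="target_correlation"):
        BehaviorCoupling("head_turn", "gm", 1.5)
    with pytest.raises(ValueError, match="unknown score"):
        BehaviorCoupling("levitation", "gm", 0.5)


def test_ground_truth_fast_path_matches_full_generation():
    spec = default_spec(grid_shape=(12, 12, 12))
    _, truth_full = generate_tensor_field(spec, "IUGR", seed=42, keep_field=False)
    truth_fast = generate_ground_truth(spec, "IUGR", seed=42)
    assert truth_full.region_fa == truth_fast.region_fa
    assert truth_full.region_adc == truth_fast.region_adc
    assert truth_full.trace_jitter == truth_fast.trace_jitter


def test_group_effect_is_trace_preserving():
    """Same seed, different group: ADC identical, FA lower by the programmed
    dFA times the subject's global factor, in effect regions only."""
    spec = focal_effect_spec(0.03, grid_shape=(12, 12, 12))
    tc = generate_ground_truth(spec, "control", seed=9)
    ti = generate_ground_truth(spec, "IUGR", seed=9)
    for rid in ("gm", "wm_tract_x", "wm_tract_y"):
        assert ti.region_adc[rid] == pytest.approx(tc.region_adc[rid], rel=1e-12)
    assert ti.region_fa["gm"] == pytest.approx(tc.region_fa["gm"], rel=1e-12)
    drop = tc.region_fa["wm_tract_x"] - ti.region_fa["wm_tract_x"]
    assert drop == pytest.approx(0.03 * tc.global_fa_factor, rel=1e-9)


def test_null_spec_groups_are_exchangeable():
    spec = null_spec(grid_shape=(10, 10, 10))
    tc = generate_ground_truth(spec, "control", seed=4)
    ti = generate_ground_truth(spec, "IUGR", seed=4)
    assert tc.region_fa == ti.region_fa
    assert tc.region_adc == ti.region_adc


def test_region_fa_moments_match_monte_carlo():
    spec = default_spec(grid_shape=(10, 10, 10))
    mean, sd = _region_fa_moments(spec, "wm_tract_x")
    draws = []
    for g in ("control", "IUGR"):
        draws += [
            generate_ground_truth(spec, g, 5000 + i).region_fa["wm_tract_x"]
            for i in range(400)
        ]
    draws = np.asarray(draws)
    assert mean == pytest.approx(draws.mean(), abs=4 * draws.std() / np.sqrt(draws.size))
    assert sd == pytest.approx(draws.std(), rel=0.15)


def test_default_spec_calibration():
    spec = default_spec()
    assert spec.expected_whole_brain_fa("control") == pytest.approx(0.16, abs=0.003)
    assert spec.expected_whole_brain_fa("IUGR") == pytest.approx(0.15, abs=0.003)
    wm_frac = spec.wm_mask.sum() / spec.brain_mask.sum()
    assert 0.10 < wm_frac < 0.20
    # two tracts with distinct orientations
    dirs = [
        r.principal_direction for r in spec.regions if r.tissue_class == "WM"
    ]
    assert len(dirs) == 2
    assert abs(np.dot(dirs[0], dirs[1])) < 0.1


def test_simulate_dwi_noise_models():
    spec = default_spec(grid_shape=(8, 8, 8))
    tf, _ = generate_tensor_field(spec, "control", seed=2)
    scheme = default_scheme(8)
    clean = simulate_dwi(tf, scheme, noise_sigma=0.0)
    rician = simulate_dwi(tf, scheme, noise_sigma=0.05, seed=1)
    assert np.all(rician.data >= 0)  # magnitude signal
    again = simulate_dwi(tf, scheme, noise_sigma=0.05, seed=1)
    assert np.array_equal(rician.data, again.data)  # deterministic
    gauss = simulate_dwi(tf, scheme, noise_sigma=0.05, seed=1, noise_model="gaussian")
    assert not np.array_equal(gauss.data, rician.data)
    # Rician noise inflates the background (magnitude of pure noise)
    bg = ~spec.brain_mask
    assert rician.data[bg].mean() > clean.data[bg].mean()
    with pytest.raises(ValueError, match="noise model"):
        simulate_dwi(tf, scheme, noise_sigma=0.05, noise_model="laplace")
    with pytest.raises(ValueError, match="at least 7"):
        simulate_dwi(tf, default_scheme(5), noise_sigma=0.0)


def test_cohort_determinism_and_records(small_cohort, small_spec):
    again = generate_cohort(
        small_spec, n_per_group=4, scheme=default_scheme(15), seed=7
    )
    assert [s.record.subject_id for s in again.subjects] == [
        s.record.subject_id for s in small_cohort.subjects
    ]
    for a, b in zip(again.subjects, small_cohort.subjects):
        assert np.array_equal(a.dwi.data, b.dwi.data)
        assert a.record.scores == b.record.scores
        assert a.record.birth_weight == b.record.birth_weight
    groups = [s.record.group for s in small_cohort.subjects]
    assert groups.count("control") == 4 and groups.count("IUGR") == 4
    for s in small_cohort.subjects:
        assert len(s.record.scores) == 13  # full battery on every record


def test_cohort_copula_achieves_target_correlation():
    # tiny grid keeps 300 subjects cheap; the latent correlation is the
    # design quantity, the discretized one is attenuated but close
    spec = focal_effect_spec(0.0, grid_shape=(6, 6, 6))
    coh = generate_cohort(spec, n_per_group=150, scheme=default_scheme(6), seed=3)
    target, latent, disc = coh.achieved_correlations["head_turn"]
    assert target == 0.65
    assert latent == pytest.approx(0.65, abs=0.08)
    assert disc == pytest.approx(0.65, abs=0.15)


def test_cohort_birth_weights_by_group(small_cohort):
    w = {
        g: np.mean(
            [s.record.birth_weight for s in small_cohort.subjects if s.record.group == g]
        )
        for g in ("control", "IUGR")
    }
    assert w["control"] > w["IUGR"]


def test_cohort_needs_two_per_group(small_spec):
    with pytest.raises(ValueError, match="n_per_group"):
        generate_cohort(small_spec, n_per_group=1, seed=0)


def test_generate_tensor_field_bad_group(small_spec):
    with pytest.raises(ValueError, match="unknown group"):
        generate_tensor_field(small_spec, "treated", seed=0)
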