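"""Synthetic phantom generator: determinism, HU bands, canal and force truth."""

import numpy as np
import pytest

from drillct.pathway import cylinder_mask, difference_volume
from drillct.phantom import (
    PhantomConfig,
    carve_canal,
    make_phantom,
    simulate_correlated_pair,
    simulate_force_trace,
    true_profile,
    truth_from_json,
    truth_to_json,
)
from drillct.profiles import profile_to_gv, windowed_stats
from drillct.registration import resample
from drillct.stats import spearman


def test_same_seed_is_bit_identical():
    a, ta = make_phantom((48, 48, 48), 0.6, seed=123)
    b, tb = make_phantom((48, 48, 48), 0.6, seed=123)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(ta.path.start, tb.path.start)
    assert np.array_equal(ta.misalignment.params, tb.misalignment.params)


def test_interior_voxel_in_trabecular_band(aligned_phantom):
    pre, truth = aligned_phantom
    cfg = truth.config
    mid = truth.path.point_at(0.7 * truth.path.length)  # deep inside the body
    val = pre.sample(mid[None, :])[0]
    assert abs(val - cfg.trabecular_hu) <= 4 * max(cfg.noise_sd_hu, 1.0)


def test_corner_voxel_is_air(aligned_phantom):
    pre, _ = aligned_phantom
    assert abs(pre.data[0, 0, 0] - (-1000.0)) < 1.0


def test_parameter_validation():
    with pytest.raises(ValueError, match="shape"):
        make_phantom((32, 64, 64), 0.5, seed=0)
    with pytest.raises(ValueError, match="spacing"):
        make_phantom((64, 64, 64), 1.5, seed=0)


def test_carved_canal_is_air_inside(aligned_pair_volumes):
    pre, post, truth = aligned_pair_volumes
    cfg = truth.config
    mid = truth.path.point_at(0.5 * truth.path.length)
    val = post.sample(mid[None, :])[0]
    assert abs(val - cfg.air_hu) <= 4 * max(cfg.air_noise_sd_hu, 1.0)


def test_zero_misalignment_returns_carved_exactly():
    cfg = PhantomConfig(max_rotation_deg=0.0, max_translation_mm=0.0)
    pre, truth = make_phantom((48, 48, 48), 0.6, seed=2, config=cfg)
    assert truth.misalignment.is_identity()
    a = carve_canal(pre, truth)
    b = carve_canal(pre, truth)
    assert np.array_equal(a.data, b.data)  # deterministic carve
    # interpolation-free: the carved volume is the analytic blend itself
    assert a.same_grid(pre)


def test_difference_mass_concentrated_in_canal_tube():
    """After undoing the misalignment, >99% of the segmentable positive
    difference mass lies within one voxel of the true canal tube."""
    pre, truth = make_phantom((72, 72, 72), 0.5, seed=21)
    post = carve_canal(pre, truth)
    realigned = resample(post, truth.misalignment)
    diff = difference_volume(pre, realigned)
    strong = np.where(diff.data >= 400.0, diff.data, 0.0)
    widened = truth.path
    widened = type(widened)(widened.start, widened.end, widened.radius + 0.5)
    tube = cylinder_mask(diff, widened)
    frac = strong[tube].sum() / strong.sum()
    assert frac > 0.99


def test_force_trace_deterministic(aligned_pair_volumes):
    pre, post, truth = aligned_pair_volumes
    prof = windowed_stats(profile_to_gv(true_profile(pre, truth)))
    t1 = simulate_force_trace(prof, truth)
    t2 = simulate_force_trace(prof, truth)
    assert np.array_equal(t1.F, t2.F)


def test_noise_free_force_has_perfect_spearman_with_gv(noisefree_phantom):
    pre, truth = noisefree_phantom
    prof = profile_to_gv(true_profile(pre, truth))
    trace = simulate_force_trace(prof, truth, channel="mean")
    v, s0 = truth.config.feed_velocity_mm_s, truth.insertion_offset_mm
    # samples that land exactly on profile grid points inside the canal
    s_grid = prof.s[:: 5]
    t_idx = np.round((s_grid + s0) / v * truth.config.sample_rate_hz).astype(int)
    gv = np.interp(v * trace.t[t_idx] - s0, prof.s, prof.mean)
    r, _ = spearman(trace.F[t_idx], gv)
    assert r > 1 - 1e-12


def test_null_link_gives_near_zero_spearman(aligned_pair_volumes):
    """b = 0: |r| < 0.2 in >= 95% of 200 replicates at n ~ 300."""
    pre, post, truth0 = aligned_pair_volumes
    prof = windowed_stats(profile_to_gv(true_profile(pre, truth0)))
    v = truth0.config.feed_velocity_mm_s
    fs = truth0.config.sample_rate_hz
    s0 = truth0.insertion_offset_mm
    import dataclasses

    n_ok = 0
    n_rep = 200
    for k in range(n_rep):
        cfg = dataclasses.replace(
            truth0.config, link_slope_n_per_gv=0.0, force_noise_sd_n=0.2
        )
        truth = dataclasses.replace(truth0, config=cfg, link=(0.0, 0.0), seed=50_000 + k)
        trace = simulate_force_trace(prof, truth)
        t_idx = np.round((prof.s + s0) / v * fs).astype(int)
        r, _ = spearman(trace.F[t_idx], prof.mean)
        if abs(r) < 0.2:
            n_ok += 1
    assert n_ok >= 0.95 * n_rep


def test_target_rho_validation(aligned_pair_volumes):
    pre, post, truth = aligned_pair_volumes
    prof = profile_to_gv(true_profile(pre, truth))
    for bad in (0.0, -0.3, 1.5):
        with pytest.raises(ValueError, match="rho"):
            simulate_force_trace(prof, truth, target_rho=bad)


def test_correlated_pair_monotone_limit():
    rng = np.random.default_rng(0)
    x, y = simulate_correlated_pair(1.0, 200, rng)
    assert spearman(x, y)[0] == 1.0


def test_truth_sidecar_roundtrip(tmp_path, aligned_phantom):
    _, truth = aligned_phantom
    p = truth_to_json(truth, tmp_path / "truth.json")
    back = truth_from_json(p)
    assert np.allclose(back.path.start, truth.path.start)
    assert np.allclose(back.misalignment.params, truth.misalignment.params)
    assert back.link == truth.link and back.seed == truth.seed
    assert back.config == truth.config
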