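import itertools

import numpy as np
import pytest

from retinotract.errors import UsageError
from retinotract.formats_io import GradientTable, Streamline, Tractogram, VolumeGrid
from retinotract.phantom import PhantomSpec, make_gradient_table, simulate_dwi
from retinotract.tensor_model import TensorField, tensor_from_eigen
from retinotract.tracking_life import (
    TrackingConfig,
    ensemble_track,
    life_prune,
    predict_from_weights,
    theta_max,
    track_single,
)


def brute_force_nnls(A, y, tol=1e-12):
    """Oracle: enumerate active sets, keep the feasible least-squares
    solution with the smallest residual."""
    n = A.shape[1]
    best_w, best_r = np.zeros(n), np.linalg.norm(y)
    for k in range(1, n + 1):
        for cols in itertools.combinations(range(n), k):
            sub = A[:, cols]
            w, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.all(w >= -tol):
                full = np.zeros(n)
                full[list(cols)] = np.maximum(w, 0.0)
                r = np.linalg.norm(A @ full - y)
                if r < best_r - 1e-15:
                    best_w, best_r = full, r
    return best_w, best_r


# ---------------------------------------------------------------------------
# geometry of the curvature cap
# ---------------------------------------------------------------------------

def test_theta_max_closed_form():
    assert np.isclose(np.degrees(theta_max(1.0, 1.0)), 60.0)
    assert theta_max(1.0, 0.25) == np.pi  # step longer than the chord: no cap
    assert np.isclose(theta_max(0.5, 4.0), 2 * np.arcsin(0.5 / 8.0))


# ---------------------------------------------------------------------------
# straight-field tracking
# ---------------------------------------------------------------------------

def _straight_field(n=20):
    """Uniform stick tensors along +y bridging two ROI slabs."""
    shape = (7, n, 7)
    affine = np.eye(4)
    coeffs = np.zeros(shape + (6,))
    coeffs[...] = tensor_from_eigen((1.7e-3, 0.3e-3, 0.3e-3), [0, 1, 0])
    wm = VolumeGrid(np.ones(shape, dtype=np.uint8), affine)
    field = TensorField(coefficients=coeffs, s0_map=np.ones(shape), grid=wm)
    roi_a = np.zeros(shape, dtype=np.uint8)
    roi_a[:, :2, :] = 1
    roi_b = np.zeros(shape, dtype=np.uint8)
    roi_b[:, -2:, :] = 1
    seed = np.zeros(shape, dtype=np.uint8)
    seed[3, n // 2, 3] = 1
    return field, wm, VolumeGrid(seed, affine), VolumeGrid(roi_a, affine), VolumeGrid(roi_b, affine)


def test_straight_field_monotone_tracks():
    field, wm, seed, roi_a, roi_b = _straight_field()
    cfg = TrackingConfig(max_fibers=10, max_trials=100, min_length_mm=5.0, rng_seed=1)
    t = track_single(field, wm, seed, cfg, radius=1.0, roi_a=roi_a, roi_b=roi_b)
    assert len(t) > 0
    cap = theta_max(cfg.step_mm or 0.5, 1.0)
    for s in t:
        dy = np.diff(s.points[:, 1])
        assert np.all(dy > 0) or np.all(dy < 0)  # monotone along the bridge
        v = np.diff(s.points, axis=0)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        bends = np.arccos(np.clip((v[:-1] * v[1:]).sum(1), -1, 1))
        assert np.all(bends <= cap + 1e-9)


def test_zero_trials_empty():
    field, wm, seed, roi_a, roi_b = _straight_field()
    cfg = TrackingConfig(max_fibers=0, max_trials=0, rng_seed=1)
    assert len(track_single(field, wm, seed, cfg, radius=1.0)) == 0


def test_empty_seed_mask_raises():
    field, wm, seed, *_ = _straight_field()
    empty = seed.with_data(np.zeros_like(np.asarray(seed.data)))
    with pytest.raises(UsageError):
        track_single(field, wm, empty, TrackingConfig(), radius=1.0)


def test_isotropic_field_warns_and_returns_empty():
    field, wm, seed, *_ = _straight_field()
    iso = TensorField(
        coefficients=np.broadcast_to(
            tensor_from_eigen((8e-4, 8e-4, 8e-4), [1, 0, 0]), field.coefficients.shape
        ).copy(),
        s0_map=field.s0_map,
        grid=field.grid,
    )
    cfg = TrackingConfig(max_fibers=5, max_trials=20, rng_seed=1)
    with pytest.warns(UserWarning, match="isotropic"):
        t = track_single(iso, wm, seed, cfg, radius=1.0)
    assert len(t) == 0


def test_tracking_deterministic():
    field, wm, seed, roi_a, roi_b = _straight_field()
    cfg = TrackingConfig(max_fibers=8, max_trials=50, min_length_mm=5.0, rng_seed=9)
    t1 = track_single(field, wm, seed, cfg, radius=2.0, roi_a=roi_a, roi_b=roi_b)
    t2 = track_single(field, wm, seed, cfg, radius=2.0, roi_a=roi_a, roi_b=roi_b)
    assert len(t1) == len(t2)
    for a, b in zip(t1, t2):
        assert np.array_equal(a.points, b.points)


def test_ensemble_is_concatenation():
    field, wm, seed, roi_a, roi_b = _straight_field()
    cfg = TrackingConfig(
        curvature_radii=(0.5, 1.0, 2.0), max_fibers=5, max_trials=40,
        min_length_mm=5.0, rng_seed=3,
    )
    merged, per_radius = ensemble_track(field, wm, seed, cfg, roi_a, roi_b)
    assert len(merged) == sum(per_radius.values())
    single_cfg = TrackingConfig(
        curvature_radii=(1.0,), max_fibers=5, max_trials=40, min_length_mm=5.0, rng_seed=3
    )
    only, _ = ensemble_track(field, wm, seed, single_cfg, roi_a, roi_b)
    direct = track_single(field, wm, seed, single_cfg, 1.0, roi_a, roi_b)
    assert len(only) == len(direct)
    for a, b in zip(only, direct):
        assert np.array_equal(a.points, b.points)


def test_config_validation():
    with pytest.raises(UsageError):
        TrackingConfig(curvature_radii=(0.0,))
    with pytest.raises(UsageError):
        TrackingConfig(max_fibers=10, max_trials=5)
    with pytest.raises(UsageError):
        TrackingConfig(step_mm=-1.0)


# ---------------------------------------------------------------------------
# LiFE pruning
# ---------------------------------------------------------------------------

def _one_voxel_setup(tangents, s0=100.0, snr=np.inf):
    """A tiny grid whose center voxel carries a stick tensor along the first
    tangent; candidates are straight lines through it along each tangent."""
    shape = (3, 3, 3)
    affine = np.eye(4)
    coeffs = np.zeros(shape + (6,))
    coeffs[1, 1, 1] = tensor_from_eigen((1.7e-3, 0.3e-3, 0.3e-3), tangents[0])
    grid = VolumeGrid(np.zeros(shape), affine)
    field = TensorField(coefficients=coeffs, s0_map=np.full(shape, s0), grid=grid)
    gtab = make_gradient_table(PhantomSpec(dirs_per_shell=15, shells=(1000.0,), n_b0=2))
    dwi = simulate_dwi(field, gtab, s0=s0, snr=snr, rng_seed=0)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[1, 1, 1] = 1
    cands = []
    for t in tangents:
        t = np.asarray(t, dtype=float)
        t /= np.linalg.norm(t)
        center = np.array([1.0, 1.0, 1.0])
        cands.append(np.array([center - 0.4 * t, center, center + 0.4 * t]))
    return Tractogram.from_arrays(cands), dwi, gtab, VolumeGrid(mask, affine)


def test_aligned_candidate_kept():
    cands, dwi, gtab, mask = _one_voxel_setup([[0, 1, 0]])
    res = life_prune(cands, dwi, gtab, mask)
    assert res.weights[0] > 0
    assert len(res.kept) == 1


def test_orthogonal_candidate_discarded_matches_bruteforce():
    cands, dwi, gtab, mask = _one_voxel_setup([[0, 1, 0], [1, 0, 0]])
    res = life_prune(cands, dwi, gtab, mask)
    assert res.weights[0] > 0
    assert res.weights[1] == 0.0
    assert list(res.kept_indices) == [0]
    # independent oracle on the same demeaned 1-voxel instance
    b = 1000.0
    sel = gtab.bvals == b
    g = gtab.bvecs[sel]
    A = np.column_stack(
        [
            np.exp(-b * (g @ (np.array(t) / np.linalg.norm(t))) ** 2 * 1.7e-3)
            for t in ([0, 1, 0], [1, 0, 0])
        ]
    )
    A -= A.mean(axis=0)
    meas = np.asarray(dwi.data)[1, 1, 1][sel]
    y = meas - meas.mean()
    w_oracle, _ = brute_force_nnls(A, y)
    assert np.allclose(res.weights, w_oracle, atol=1e-6)


def test_small_instance_matches_bruteforce(rng):
    # <= 5 voxels, <= 6 streamlines, random-ish tangents, noisy signal
    tangents = [
        [0, 1, 0],
        [1, 0, 0],
        [0, 0.6, 0.8],
        [0.5, 0.5, np.sqrt(0.5)],
        [0, 0.96, 0.28],
        [0.28, 0, 0.96],
    ]
    cands, dwi, gtab, mask = _one_voxel_setup(tangents, snr=20.0)
    res = life_prune(cands, dwi, gtab, mask)
    b = 1000.0
    sel = gtab.bvals == b
    g = gtab.bvecs[sel]
    A = np.column_stack(
        [
            np.exp(-b * (g @ (np.asarray(t) / np.linalg.norm(t))) ** 2 * 1.7e-3)
            for t in tangents
        ]
    )
    A -= A.mean(axis=0)
    meas = np.asarray(dwi.data)[1, 1, 1][sel]
    y = meas - meas.mean()
    w_oracle, r_oracle = brute_force_nnls(A, y)
    assert np.allclose(res.weights, w_oracle, atol=1e-6)
    # residual norm no worse than the empty model
    assert np.linalg.norm(A @ res.weights - y) <= np.linalg.norm(y) + 1e-12


def test_duplicated_candidates_prediction_invariant():
    cands, dwi, gtab, mask = _one_voxel_setup([[0, 1, 0], [0, 0.6, 0.8]])
    res1 = life_prune(cands, dwi, gtab, mask)
    doubled = Tractogram(list(cands.streamlines) + [Streamline(s.points.copy()) for s in cands])
    res2 = life_prune(doubled, dwi, gtab, mask)
    p1 = predict_from_weights(res1.weights, cands, dwi, gtab, mask)
    p2 = predict_from_weights(res2.weights, doubled, dwi, gtab, mask)
    assert np.allclose(p1, p2, atol=1e-6)


def test_zero_weight_removal_keeps_residual():
    cands, dwi, gtab, mask = _one_voxel_setup([[0, 1, 0], [1, 0, 0]])
    res = life_prune(cands, dwi, gtab, mask)
    assert res.weights[1] == 0.0
    res_kept = life_prune(res.kept, dwi, gtab, mask)
    e1 = np.asarray(res.error_map.data)
    e2 = np.asarray(res_kept.error_map.data)
    assert np.allclose(e1, e2, atol=1e-10)


def test_empty_candidates_raise():
    _, dwi, gtab, mask = _one_voxel_setup([[0, 1, 0]])
    with pytest.raises(UsageError):
        life_prune(Tractogram([]), dwi, gtab, mask)


def test_dead_column_warns():
    cands, dwi, gtab, mask = _one_voxel_setup([[0, 1, 0]])
    # second candidate entirely outside the mask
    outside = Streamline(np.array([[0.0, 0.0, 0.0], [0.0, 0.4, 0.0]]))
    t = Tractogram(list(cands.streamlines) + [outside])
    with pytest.warns(UserWarning, match="no signal"):
        res = life_prune(t, dwi, gtab, mask)
    assert res.weights[1] == 0.0
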