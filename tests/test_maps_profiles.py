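import numpy as np
import pytest

from retinotract.errors import GeometryError, UsageError
from retinotract.formats_io import Streamline, Tractogram, VolumeGrid
from retinotract.maps_profiles import (
    FWHM_TO_SIGMA,
    consistency_map,
    density_map,
    smooth_volume,
    tract_profile,
)
from retinotract.streamline_ops import resample_streamline
from retinotract.tensor_model import ScalarMaps


def _grid(n=20, vs=1.0):
    return VolumeGrid(np.zeros((n, n, n)), np.diag([vs, vs, vs, 1.0]))


def _line(y0, y1, x=5.0, z=5.0, n=30):
    return Streamline(np.column_stack([np.full(n, x), np.linspace(y0, y1, n), np.full(n, z)]))


# ---------------------------------------------------------------------------
# density map
# ---------------------------------------------------------------------------

def test_density_single_streamline_all_ones():
    grid = _grid()
    dm = density_map(Tractogram([_line(2, 15)]), grid)
    d = np.asarray(dm.data)
    assert set(np.unique(d)) == {0.0, 1.0}
    assert d.max() == 1.0


def test_density_shared_and_solo_voxels():
    grid = _grid()
    shared = [_line(2, 8), _line(2, 8), _line(2, 8, n=40)]
    solo = _line(12, 18, x=10.0)
    dm = density_map(Tractogram(shared + [solo]), grid)
    d = np.asarray(dm.data)
    assert np.isclose(d[5, 5, 5], 1.0)  # 3 streamlines share
    assert np.isclose(d[10, 15, 5], 1 / 3)


def test_density_loop_counts_once():
    grid = _grid()
    n = 40
    t = np.linspace(0, 4 * np.pi, n)  # two full loops through the same voxels
    loop = Streamline(np.column_stack([5 + 2 * np.cos(t), 5 + 2 * np.sin(t), np.full(n, 5.0)]))
    straight = _line(2, 15, x=12.0)
    dm = density_map(Tractogram([loop, straight]), grid)
    assert np.asarray(dm.data).max() == 1.0  # loop voxels counted once


def test_density_empty_raises():
    with pytest.raises(UsageError):
        density_map(Tractogram([]), _grid())


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def test_smooth_fwhm_zero_identity(rng):
    v = VolumeGrid(rng.random((10, 10, 10)), np.eye(4))
    out = smooth_volume(v, 0.0)
    assert np.array_equal(np.asarray(out.data), np.asarray(v.data))


def test_smooth_point_source_mass_and_peak():
    n = 41
    data = np.zeros((n, n, n))
    data[n // 2, n // 2, n // 2] = 1.0
    v = VolumeGrid(data, np.eye(4))
    out = np.asarray(smooth_volume(v, 2.0).data)
    assert abs(out.sum() - 1.0) < 1e-6
    sigma = 2.0 * FWHM_TO_SIGMA
    peak_analytic = (2 * np.pi * sigma**2) ** -1.5  # x 1 mm^3 voxel volume
    assert abs(out.max() - peak_analytic) / peak_analytic < 0.01


def test_smooth_linear(rng):
    v1 = VolumeGrid(rng.random((12, 12, 12)), np.eye(4))
    v2 = VolumeGrid(rng.random((12, 12, 12)), np.eye(4))
    a = 2.7
    lhs = smooth_volume(v1.with_data(a * np.asarray(v1.data) + np.asarray(v2.data)), 2.0)
    rhs = a * np.asarray(smooth_volume(v1, 2.0).data) + np.asarray(smooth_volume(v2, 2.0).data)
    assert np.allclose(np.asarray(lhs.data), rhs, atol=1e-10)


def test_smooth_anisotropic_voxels_per_axis():
    affine = np.diag([1.0, 2.0, 1.0, 1.0])
    n = 41
    data = np.zeros((n, n, n))
    data[n // 2, n // 2, n // 2] = 1.0
    out = np.asarray(smooth_volume(VolumeGrid(data, affine), 4.0).data)
    # mm-isotropic kernel -> narrower in voxel units along the 2 mm axis
    mid = n // 2
    profile_x = out[:, mid, mid]
    profile_y = out[mid, :, mid]
    width_x = (profile_x > out.max() / 2).sum()
    width_y = (profile_y > out.max() / 2).sum()
    assert width_y < width_x


def test_smooth_shear_rejected():
    affine = np.eye(4)
    affine[0, 1] = 0.3
    with pytest.raises(GeometryError):
        smooth_volume(VolumeGrid(np.zeros((5, 5, 5)), affine), 2.0)
    with pytest.raises(UsageError):
        smooth_volume(VolumeGrid(np.zeros((5, 5, 5)), np.eye(4)), -1.0)


# ---------------------------------------------------------------------------
# consistency map
# ---------------------------------------------------------------------------

def test_consistency_identical_subjects():
    grid = _grid()
    t = Tractogram([_line(2, 15)])
    cm = consistency_map([t] * 5, grid, fwhm=2.0)
    counts = np.asarray(cm.counts.data)
    assert counts.max() == 5
    assert set(np.unique(counts)) <= {0, 5}
    assert cm.n_subjects == 5


def test_consistency_single_subject_binary():
    cm = consistency_map([Tractogram([_line(2, 15)])], _grid(), fwhm=2.0)
    assert set(np.unique(np.asarray(cm.counts.data))) <= {0, 1}


def test_consistency_counts_bounded_and_threshold_monotone(rng):
    grid = _grid()
    subjects = [
        Tractogram([_line(2, 15, x=float(5 + rng.integers(-1, 2)))]) for _ in range(6)
    ]
    cm = consistency_map(subjects, grid, fwhm=2.0)
    counts = np.asarray(cm.counts.data)
    assert counts.max() <= 6
    prev = None
    for k in (1, 3, 5):
        kept = (np.asarray(consistency_map(subjects, grid, fwhm=2.0, threshold=k).counts.data) > 0).sum()
        if prev is not None:
            assert kept <= prev
        prev = kept


def test_consistency_threshold_cohort_fraction():
    assert round(100 * 90 / 139) == 65


def test_consistency_empty_raises():
    with pytest.raises(UsageError):
        consistency_map([], _grid())


# ---------------------------------------------------------------------------
# tract profiles
# ---------------------------------------------------------------------------

def _scalar_maps(grid, fa, md=0.8e-3, rd=0.3e-3):
    return ScalarMaps(
        fa=grid.with_data(np.asarray(fa, dtype=float)),
        md=grid.with_data(np.full(grid.shape3, md)),
        rd=grid.with_data(np.full(grid.shape3, rd)),
    )


def test_profile_constant_field_flat():
    grid = _grid()
    scalars = _scalar_maps(grid, np.full(grid.shape3, 0.5))
    t = Tractogram([_line(2, 15), _line(2, 15, x=6.0)])
    prof = tract_profile(t, scalars, n_nodes=100)
    assert len(prof.node_values["fa"]) == 100
    assert np.allclose(prof.node_values["fa"], 0.5, atol=1e-9)
    assert np.allclose(prof.node_values["md"], 0.8e-3)


def test_profile_linear_field_linear():
    grid = _grid()
    fa = np.broadcast_to(np.linspace(0, 1, 20)[None, :, None], (20, 20, 20))
    scalars = _scalar_maps(grid, fa)
    prof = tract_profile(Tractogram([_line(2, 15)]), scalars, n_nodes=100, weighting="uniform")
    got = prof.node_values["fa"]
    want = np.linspace(2 / 19, 15 / 19, 100)
    assert np.allclose(got, want, atol=1e-6)


def test_profile_single_streamline_equals_sampled_nodes():
    grid = _grid()
    rng = np.random.default_rng(5)
    fa = rng.random(grid.shape3)
    scalars = _scalar_maps(grid, fa)
    s = _line(2, 15)
    prof = tract_profile(Tractogram([s]), scalars, n_nodes=100)
    from scipy.ndimage import map_coordinates

    nodes = resample_streamline(s, 100).points
    want = map_coordinates(fa, grid.world_to_voxel(nodes).T, order=1, mode="nearest")
    assert np.allclose(prof.node_values["fa"], want, atol=1e-12)


def test_profile_reorients_flipped_streamlines():
    grid = _grid()
    scalars = _scalar_maps(grid, np.broadcast_to(np.linspace(0, 1, 20)[None, :, None], (20, 20, 20)))
    fwd = _line(2, 15)
    rev = Streamline(fwd.points[::-1].copy())
    p1 = tract_profile(Tractogram([fwd, fwd]), scalars, n_nodes=50, weighting="uniform")
    p2 = tract_profile(Tractogram([fwd, rev]), scalars, n_nodes=50, weighting="uniform")
    assert np.allclose(p1.node_values["fa"], p2.node_values["fa"], atol=1e-9)


def test_profile_phantom_bundles_differ(phantom, fitted):
    _, scalars = fitted
    p1 = tract_profile(phantom.pro1, scalars, tract_label="PRO1")
    p2 = tract_profile(phantom.pro2, scalars, tract_label="PRO2")
    mid = slice(40, 60)
    # the corridors carry different anisotropy, so apex FA separates
    assert abs(p1.node_values["fa"][mid].mean() - p2.node_values["fa"][mid].mean()) > 0.02
    assert np.all(p1.node_values["fa"] <= 1.0) and np.all(p1.node_values["fa"] >= 0.0)


def test_profile_spacing_reported():
    grid = _grid()
    scalars = _scalar_maps(grid, np.zeros(grid.shape3))
    prof = tract_profile(Tractogram([_line(2.0, 15.0)]), scalars, n_nodes=100)
    assert len(prof.node_spacing_mm) == 99
    assert np.allclose(prof.node_spacing_mm, 13.0 / 99, atol=1e-9)
    # inter-node distance between the 25th and 75th node is derivable
    d = prof.node_spacing_mm[24:74].sum()
    assert np.isclose(d, 13.0 * 50 / 99, atol=1e-6)


def test_profile_empty_and_bad_weighting(phantom, fitted):
    _, scalars = fitted
    with pytest.raises(UsageError):
        tract_profile(Tractogram([]), scalars)
    with pytest.raises(UsageError):
        tract_profile(phantom.pro1, scalars, weighting="bogus")
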