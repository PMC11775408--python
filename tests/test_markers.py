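"""Volume and shape markers: analytic phantoms, oracles and invariants."""

import numpy as np
import pytest
import trimesh

from lesionshape import (
    AnisotropicGridError,
    DegenerateHullError,
    EmptyMaskError,
    InsufficientScalesError,
    LesionMask,
    MarkerDomainError,
    SurfaceMesh,
    ball_mask,
    box_counts,
    compute_markers,
    concavity_index,
    convex_hull_metrics,
    convexity,
    fractal_dimension,
    generate_lesion,
    lesion_volume,
    solidity,
    surface_mesh,
)
from lesionshape.markers import boundary_voxels, box_count_sizes
from lesionshape.synthetic import SyntheticLesionSpec


def make_mask(grid, spacing=(1.0, 1.0, 1.0)):
    affine = np.diag(list(spacing) + [1.0])
    return LesionMask(grid=np.asarray(grid), affine=affine)


def cube_mask(edge_vox, spacing=0.5):
    n = edge_vox + 4
    grid = np.zeros((n, n, n), dtype=bool)
    grid[2:2 + edge_vox, 2:2 + edge_vox, 2:2 + edge_vox] = True
    return make_mask(grid, (spacing,) * 3)


# -- volume -----------------------------------------------------------------


def test_volume_of_unit_cube_block():
    grid = np.zeros((12, 12, 12), dtype=bool)
    grid[1:11, 1:11, 1:11] = True
    assert lesion_volume(make_mask(grid)) == pytest.approx(1.0)


def test_volume_of_single_clinical_voxel():
    grid = np.zeros((3, 3, 3), dtype=bool)
    grid[1, 1, 1] = True
    vol = lesion_volume(make_mask(grid, (0.4, 0.4, 5.0)))
    assert vol == pytest.approx(0.0008)


def test_ball_volume_matches_analytic(ball_10mm_markers):
    assert ball_10mm_markers.volume_ml == pytest.approx(
        4.0 / 3.0 * np.pi, rel=0.02)


def test_volume_of_empty_mask_raises():
    with pytest.raises(EmptyMaskError):
        lesion_volume(make_mask(np.zeros((4, 4, 4), dtype=bool)))


# -- surface meshes ---------------------------------------------------------


def test_single_voxel_mesh_is_closed_and_small():
    grid = np.zeros((3, 3, 3), dtype=bool)
    grid[1, 1, 1] = True
    mesh = surface_mesh(make_mask(grid))
    assert 0.0 < mesh.volume <= 1.0
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    assert tm.is_watertight


def test_ball_surface_area_within_3_percent(ball_10mm):
    mesh = surface_mesh(ball_10mm)
    assert mesh.area == pytest.approx(4 * np.pi * 100, rel=0.03)
    assert mesh.volume == pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)


def test_cube_surface_area_within_5_percent():
    mesh = surface_mesh(cube_mask(20, 0.5))  # 10 mm cube
    assert mesh.area == pytest.approx(600.0, rel=0.05)
    assert mesh.volume == pytest.approx(1000.0, rel=0.02)


def test_mesh_accessors_agree_with_trimesh(ball_10mm):
    mesh = surface_mesh(ball_10mm)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    assert tm.is_watertight
    assert mesh.area == pytest.approx(tm.area, rel=1e-9)
    assert mesh.volume == pytest.approx(abs(tm.volume), rel=1e-9)


def test_anisotropic_grid_is_rejected():
    grid = np.zeros((8, 8, 8), dtype=bool)
    grid[2:6, 2:6, 2:6] = True
    with pytest.raises(AnisotropicGridError):
        surface_mesh(make_mask(grid, (0.4, 0.4, 5.0)))
    with pytest.raises(AnisotropicGridError):
        fractal_dimension(make_mask(grid, (0.4, 0.4, 5.0)))


# -- convex hull ------------------------------------------------------------


def test_tetrahedron_hull_closed_form():
    verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    area, volume = convex_hull_metrics(SurfaceMesh(verts, faces))
    assert volume == pytest.approx(1.0 / 6.0, rel=1e-9)
    assert area == pytest.approx((3 + np.sqrt(3)) / 2, rel=1e-9)


def test_ball_hull_volume_close_to_mesh_volume(ball_10mm):
    mesh = surface_mesh(ball_10mm)
    _, hull_volume = convex_hull_metrics(mesh)
    # hull rides the outermost staircase vertices: 2% discretization slack
    assert hull_volume == pytest.approx(mesh.volume, rel=0.02)


def test_l_solid_hull_exceeds_solid_volume():
    # two 10 mm cubes sharing one vertical edge, diagonally
    grid = np.zeros((46, 46, 26), dtype=bool)
    grid[3:23, 3:23, 3:23] = True
    grid[23:43, 23:43, 3:23] = True
    mesh = surface_mesh(make_mask(grid, (0.5, 0.5, 0.5)))
    _, hull_volume = convex_hull_metrics(mesh)
    assert hull_volume > mesh.volume * 1.2


def test_degenerate_hull_raises():
    coplanar = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
    with pytest.raises(DegenerateHullError):
        convex_hull_metrics(coplanar)
    with pytest.raises(DegenerateHullError):
        convex_hull_metrics(coplanar[:3])


# -- ratio markers ----------------------------------------------------------


def test_convexity_and_solidity_arithmetic():
    assert convexity(100.0, 100.0) == pytest.approx(1.0)
    assert solidity(50.0, 100.0) == pytest.approx(0.5)
    with pytest.raises(MarkerDomainError):
        convexity(0.0, 1.0)
    with pytest.raises(MarkerDomainError):
        solidity(-1.0, 1.0)


def test_solidity_above_one_beyond_slack_is_an_error():
    from lesionshape import InconsistentMarkersError
    with pytest.raises(InconsistentMarkersError):
        solidity(110.0, 100.0)


@pytest.mark.parametrize("c, s, expected", [
    (1.0, 1.0, 1.0),
    (0.68, 0.43, 1.445),
    (0.55, 0.36, 1.545),
])
def test_concavity_index_formula(c, s, expected):
    assert concavity_index(c, s) == pytest.approx(expected)


def test_concavity_index_domain():
    with pytest.raises(MarkerDomainError):
        concavity_index(0.5, 1.2)
    with pytest.raises(MarkerDomainError):
        concavity_index(-0.1, 0.5)


def test_l_solid_solidity_two_thirds():
    grid = np.zeros((46, 46, 26), dtype=bool)
    grid[3:23, 3:23, 3:23] = True
    grid[23:43, 23:43, 3:23] = True
    mesh = surface_mesh(make_mask(grid, (0.5, 0.5, 0.5)))
    _, hull_volume = convex_hull_metrics(mesh)
    assert solidity(mesh.volume, hull_volume) == pytest.approx(2 / 3,
                                                               rel=0.03)


# -- fractal dimension ------------------------------------------------------


def naive_box_counts(boundary, sizes):
    """Triple-loop box counter (independent oracle)."""
    idx = np.argwhere(boundary)
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    sub = boundary[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    out = []
    for s in sizes:
        count = 0
        for i in range(0, sub.shape[0], s):
            for j in range(0, sub.shape[1], s):
                for k in range(0, sub.shape[2], s):
                    if sub[i:i + s, j:j + s, k:k + s].any():
                        count += 1
        out.append(count)
    return np.asarray(out)


def test_box_counts_match_naive_oracle(rng):
    masks = [
        ball_mask(8.0, 1.0).grid.astype(bool),
        rng.random((20, 24, 17)) > 0.8,
        rng.random((32, 32, 32)) > 0.95,
    ]
    for grid in masks:
        if not grid.any():
            continue
        boundary = boundary_voxels(grid)
        sizes = [1, 2, 3, 4, 5, 8]
        np.testing.assert_array_equal(
            box_counts(boundary, sizes), naive_box_counts(boundary, sizes)
        )


def test_rod_counts_and_dimension():
    grid = np.zeros((3, 3, 66), dtype=bool)
    grid[1, 1, 1:65] = True
    boundary = boundary_voxels(grid)
    sizes = box_count_sizes((1, 1, 64))
    assert sizes == [2, 4, 8, 16, 32]
    counts = box_counts(boundary, sizes)
    np.testing.assert_array_equal(counts, [int(np.ceil(64 / s))
                                           for s in sizes])
    fd = fractal_dimension(make_mask(grid))
    assert 0.9 <= fd <= 1.2


def test_cube_boundary_dimension_is_surface_like():
    # An axis-aligned cube shell meets m^3 - (m-2)^3 = 6m^2 - 12m + 8 boxes
    # at box count m per edge; the -12m term inflates local slopes to
    # 2.1-2.8 at usable scales, so the estimate sits above 2 but must stay
    # clearly below 3 (surface-like, not volume-like).
    fd = fractal_dimension(cube_mask(64, 1.0))
    assert 2.0 <= fd <= 2.5


def test_ball_boundary_dimension_is_two():
    fd = fractal_dimension(ball_mask(32.0, 1.0))
    assert 1.9 <= fd <= 2.1


def test_too_small_mask_raises_insufficient_scales():
    grid = np.zeros((8, 8, 8), dtype=bool)
    grid[2:6, 2:6, 2:6] = True
    with pytest.raises(InsufficientScalesError):
        fractal_dimension(make_mask(grid))


# -- full marker set --------------------------------------------------------


def test_ball_markers_at_convex_limit(ball_10mm_markers):
    m = ball_10mm_markers
    assert 0.95 <= m.convexity <= 1.02
    assert 0.95 <= m.solidity <= 1.02
    assert 0.99 <= m.concavity_index <= 1.05
    assert 1.9 <= m.fractal_dimension <= 2.1
    assert m.n_components == 1


def test_two_component_mask_sums_volume_shape_on_largest():
    big = ball_mask(10.0, 0.5)
    n = big.grid.shape[0]
    grid = np.zeros((n, n, n + 30), dtype=bool)
    grid[:, :, :n] = big.grid
    small = ball_mask(5.0, 0.5)
    m = small.grid.shape[0]
    grid[2:2 + m, 2:2 + m, n + 4:n + 4 + m] = small.grid
    mask = make_mask(grid, (0.5, 0.5, 0.5))
    result = compute_markers(mask, target_spacing=0.5)
    assert result.n_components == 2
    assert result.volume_ml == pytest.approx(4.19 + 0.52, rel=0.03)
    assert result.largest_component_volume_ml == pytest.approx(4.19,
                                                               rel=0.03)
    # shape from the big ball only: convex limit
    assert 0.95 <= result.convexity <= 1.02


def test_empty_mask_markers_raise():
    with pytest.raises(EmptyMaskError):
        compute_markers(make_mask(np.zeros((4, 4, 4), dtype=bool)))


def test_scale_invariance_of_ratio_markers(ball_10mm):
    base = compute_markers(ball_10mm, target_spacing=0.5)
    scaled_affine = ball_10mm.affine.copy()
    scaled_affine[:3, :] *= 2.0
    scaled = LesionMask(grid=ball_10mm.grid, affine=scaled_affine)
    res = compute_markers(scaled, target_spacing=1.0)
    assert res.volume_ml == pytest.approx(base.volume_ml * 8, rel=1e-6)
    assert res.surface_area_mm2 == pytest.approx(
        base.surface_area_mm2 * 4, rel=1e-6)
    for attr in ("convexity", "solidity", "concavity_index",
                 "fractal_dimension"):
        assert getattr(res, attr) == pytest.approx(getattr(base, attr),
                                                   rel=0.01)


def test_monotone_complexity_response():
    """Deeper surface relief lowers C and S and raises CI; FD trends up."""
    amps = [0.0, 0.1, 0.2, 0.3, 0.4]
    results = []
    for amp in amps:
        spec = SyntheticLesionSpec(base_radius=15, spike_amplitude=amp,
                                   spike_count=16, tendril_count=0, seed=0)
        results.append(compute_markers(generate_lesion(spec, 0.5),
                                       target_spacing=0.5))
    c = [r.convexity for r in results]
    s = [r.solidity for r in results]
    ci = [r.concavity_index for r in results]
    fd = [r.fractal_dimension for r in results]
    assert all(b < a for a, b in zip(c, c[1:]))
    assert all(b < a for a, b in zip(s, s[1:]))
    assert all(b > a for a, b in zip(ci, ci[1:]))
    # FD estimator resolution is ~0.01 per step; require a rising trend
    assert all(b > a - 0.01 for a, b in zip(fd, fd[1:]))
    assert fd[-1] > fd[0] + 0.03


def test_resolution_refinement_is_cauchy():
    """Marker estimates converge as the voxel grid refines (h=2,1,0.5)."""
    spec = SyntheticLesionSpec(base_radius=25, spike_amplitude=0.4,
                               spike_count=16, tendril_count=0, seed=2)
    vals = {}
    for h in (2.0, 1.0, 0.5):
        m = compute_markers(generate_lesion(spec, h), target_spacing=h,
                            include=("hull",))
        vals[h] = np.array([m.volume_ml, m.surface_area_mm2,
                            m.convexity, m.solidity])
    coarse_step = np.abs(vals[1.0] - vals[2.0])
    fine_step = np.abs(vals[0.5] - vals[1.0])
    assert np.all(fine_step < coarse_step)
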