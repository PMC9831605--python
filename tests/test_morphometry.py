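"""Morphometry oracles: thickness, smoothing, curvature, areas, sampling."""

import numpy as np
import pytest

from unfoldcoords.morphometry import (gyrification, mean_curvature,
                                      sample_to_surface, smooth_mesh,
                                      thickness, vertex_area)
from unfoldcoords.surfaces import SurfaceMesh, boundary_vertices

from .conftest import make_flat_grid_mesh


def shifted(mesh, dz):
    from dataclasses import replace

    v = mesh.vertices.copy()
    v[:, 2] += dz
    return replace(mesh, vertices=v)


def test_thickness_parallel_sheets():
    inner = make_flat_grid_mesh(10, 10)
    outer = shifted(inner, 1.2)
    th = thickness(inner, outer)
    assert np.allclose(th.values, 1.2)


def test_thickness_concentric_spheres():
    trimesh = pytest.importorskip("trimesh")
    s = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
    inner = SurfaceMesh(s.vertices, s.faces, "native")
    outer = SurfaceMesh(s.vertices * 1.2, s.faces, "native")  # radial map to r=12
    th = thickness(inner, outer)
    assert np.allclose(th.values, 2.0, atol=1e-6)


def test_thickness_requires_matching_meshes():
    a = make_flat_grid_mesh(5, 5)
    b = make_flat_grid_mesh(6, 6)
    with pytest.raises(ValueError):
        thickness(a, b)


def test_phantom_thickness_recovers_generative_parameter(pipeline_results, phantom_bundle):
    _, truth = phantom_bundle
    th = pipeline_results["metrics"]["unfoldiso"]["thickness"]
    mean = float(np.nanmean(th.values))
    assert abs(mean - truth.params.thickness) / truth.params.thickness < 0.10


def test_smooth_zero_strength_is_identity():
    m = make_flat_grid_mesh(8, 8)
    out = smooth_mesh(m, strength=0.0, iterations=50)
    assert np.array_equal(out.vertices, m.vertices)
    assert np.array_equal(out.triangles, m.triangles)


def test_smooth_flattens_spike():
    m = make_flat_grid_mesh(15, 15)
    v = m.vertices.copy()
    spike = 7 * 15 + 7
    v[spike, 2] = 5.0
    from dataclasses import replace

    spiky = replace(m, vertices=v)
    out = smooth_mesh(spiky)  # defaults: strength 0.6, 100 iterations
    assert abs(out.vertices[spike, 2]) < 0.05 * 5.0


def test_smooth_default_parameters():
    import inspect

    sig = inspect.signature(smooth_mesh)
    assert sig.parameters["strength"].default == 0.6
    assert sig.parameters["iterations"].default == 100


def test_flat_plane_curvature_zero():
    m = make_flat_grid_mesh(12, 12)
    H = mean_curvature(m, presmooth=False).values
    interior = np.setdiff1d(np.arange(m.n_vertices), boundary_vertices(m))
    assert np.nanmax(np.abs(H[interior])) < 1e-6


def test_icosphere_curvature_close_to_inverse_radius():
    trimesh = pytest.importorskip("trimesh")
    s = trimesh.creation.icosphere(subdivisions=3, radius=5.0)
    mesh = SurfaceMesh(s.vertices, s.faces, "native")
    H = mean_curvature(mesh, presmooth=False).values
    assert np.nanmedian(np.abs(np.abs(H) - 0.2)) / 0.2 < 0.05
    assert abs(np.nanmean(np.abs(H)) - 0.2) / 0.2 < 0.05


def test_saddle_curvature_near_zero():
    n = 21
    xs = np.linspace(-1, 1, n)
    XX, YY = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([XX.ravel(), YY.ravel(), (XX * YY).ravel()])
    base = make_flat_grid_mesh(n, n)
    m = SurfaceMesh(verts, base.triangles, "native")
    H = mean_curvature(m, presmooth=False).values
    center = (n // 2) * n + n // 2
    # principal curvatures of z=xy cancel at the origin
    assert abs(H[center]) < 0.05


def test_curvature_sign_flips_under_mirror():
    # mirroring the vertices (same triangle order) reverses the normals,
    # so the signed mean curvature changes sign
    trimesh = pytest.importorskip("trimesh")
    s = trimesh.creation.icosphere(subdivisions=2, radius=5.0)
    m = SurfaceMesh(s.vertices, s.faces, "native")
    mirrored = SurfaceMesh(s.vertices * np.array([-1.0, 1.0, 1.0]), s.faces, "native")
    H = mean_curvature(m, presmooth=False).values
    Hm = mean_curvature(mirrored, presmooth=False).values
    assert np.allclose(Hm, -H, atol=1e-9)


def test_vertex_area_uniform_grid_interior():
    m = make_flat_grid_mesh(9, 9, spacing=1.0)
    areas = vertex_area(m).values
    interior = np.setdiff1d(np.arange(m.n_vertices), boundary_vertices(m))
    assert np.allclose(areas[interior], 0.5)


def test_vertex_area_scales_quadratically():
    from dataclasses import replace

    m = make_flat_grid_mesh(9, 9)
    scaled = replace(m, vertices=m.vertices * 3.0)
    assert np.allclose(vertex_area(scaled).values, 9.0 * vertex_area(m).values)


def test_vertex_area_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    m = make_flat_grid_mesh(8, 8)
    from dataclasses import replace

    v = m.vertices + rng.normal(0, 0.1, m.vertices.shape)
    mesh = replace(m, vertices=v)
    got = vertex_area(mesh).values
    # brute force: loop over vertices, average incident triangle areas
    t = mesh.triangles
    expect = np.zeros(mesh.n_vertices)
    for i in range(mesh.n_vertices):
        inc = [tri for tri in t if i in tri]
        ar = [0.5 * np.linalg.norm(np.cross(v[b] - v[a], v[c] - v[a]))
              for a, b, c in inc]
        expect[i] = np.mean(ar)
    assert np.allclose(got, expect)


def test_gyrification_identity_and_scaling():
    from dataclasses import replace

    m = make_flat_grid_mesh(10, 10)
    assert np.allclose(gyrification(m, m).values, 1.0)
    native = replace(m, vertices=m.vertices * 3.0)
    assert np.allclose(gyrification(native, m).values, 9.0)


def test_phantom_gyrification_matches_analytic_area_ratio(pipeline_results, phantom_bundle):
    _, truth = phantom_bundle
    layers = pipeline_results["surfaces"]["unfoldiso"]
    a_nat = vertex_area(layers["midthickness"]).values.sum()
    a_unf = vertex_area(layers["unfolded_midthickness"]).values.sum()
    analytic = truth.native_mid_area_mm2 / 800.0  # unfolded plane is 40x20 mm
    assert abs(a_nat / a_unf - analytic) / analytic < 0.05


def test_metrics_invariant_under_vertex_renumbering():
    rng = np.random.default_rng(5)
    m = make_flat_grid_mesh(8, 8)
    perm = rng.permutation(m.n_vertices)
    inv = np.argsort(perm)
    m2 = SurfaceMesh(m.vertices[perm], inv[m.triangles], "native")
    a1 = vertex_area(m).values
    a2 = vertex_area(m2).values
    # m2 vertex j carries the geometry of original vertex perm[j]
    assert np.allclose(a2, a1[perm])


def test_sample_constant_and_ramp_images():
    m = make_flat_grid_mesh(6, 6)
    affine = np.eye(4)
    affine[2, 3] = -3.0  # put the z=0 plane mid-volume
    const = np.full((8, 8, 8), 7.0)
    got = sample_to_surface(const, affine, m).values
    assert np.allclose(got[np.isfinite(got)], 7.0)
    ii = np.arange(8, dtype=float)
    ramp = np.broadcast_to(ii[:, None, None], (8, 8, 8)).copy()
    got = sample_to_surface(ramp, affine, m).values
    finite = np.isfinite(got)
    assert np.allclose(got[finite], m.vertices[finite, 0], atol=1e-9)


def test_sample_outside_bounds_is_nan():
    m = make_flat_grid_mesh(4, 4, spacing=10.0)  # extends well past the volume
    got = sample_to_surface(np.ones((5, 5, 5)), np.eye(4), m).values
    assert np.isnan(got).any()


def test_myelin_like_gradient_orders_layers(pipeline_results, phantom_bundle, fields):
    """An image brighter toward the inner boundary samples higher on the
    inner surface than on the midthickness."""
    lm, _ = phantom_bundle
    img = np.nan_to_num(1.0 - fields.io, nan=0.0)  # bright at IO=0 (SRLM side)
    layers = pipeline_results["surfaces"]["unfoldiso"]
    inner = sample_to_surface(img, lm.affine, layers["inner"]).values
    mid = sample_to_surface(img, lm.affine, layers["midthickness"]).values
    ok = np.isfinite(inner) & np.isfinite(mid)
    assert np.nanmean(inner[ok]) > np.nanmean(mid[ok])
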