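"""Native<->unfolded warps, ITK serialization and warp application."""

import numpy as np
import pytest

import unfoldcoords as uc
from unfoldcoords.core import TissueLabelmap, UnfoldedSpaceSpec
from unfoldcoords.laplace import CoordFields
from unfoldcoords.warps import (apply_warp_to_image, apply_warp_to_points,
                                build_native_to_unfolded,
                                build_unfolded_to_native, read_itk_warp,
                                scale_to_unfolded, write_itk_warp)


def test_scale_corners_and_center(spec):
    assert np.allclose(scale_to_unfolded(np.zeros(3), spec), spec.origin)
    top = scale_to_unfolded(np.ones(3), spec)
    assert np.allclose(top, np.array(spec.origin) + [40.0, 20.0, 2.5])
    mid_dg = scale_to_unfolded(np.full(3, 0.5), spec, "dg")
    assert np.allclose(mid_dg, np.array(spec.origin) + np.array([256, 32, 16]) * 0.15625 / 2)


def test_scale_rejects_out_of_range(spec):
    with pytest.raises(ValueError):
        scale_to_unfolded(np.array([1.2, 0.0, 0.0]), spec)


def _prism_fixture():
    """GM filling an axis-aligned prism with exact linear coordinate fields."""
    shape = (24, 40, 12)
    data = np.zeros(shape, np.int16)
    data[2:22, 4:36, 2:10] = 1
    affine = np.diag([0.5, 0.5, 0.5, 1.0])
    lm = TissueLabelmap(data, affine)
    gm = data == 1
    ii, jj, kk = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    ap = np.full(shape, np.nan)
    pd = np.full(shape, np.nan)
    io = np.full(shape, np.nan)
    ap[gm] = (jj[gm] - 4) / 31.0
    pd[gm] = (ii[gm] - 2) / 19.0
    io[gm] = (kk[gm] - 2) / 7.0
    fields = CoordFields(ap=ap, pd=pd, io=io, domain_mask=gm, io_mode="laplace")
    return lm, fields


def test_forward_warp_matches_affine_on_prism(spec):
    lm, fields = _prism_fixture()
    w = build_native_to_unfolded(fields, lm, spec)
    gm = fields.domain_mask
    native = lm.world_coords(gm)
    mapped = native + w.displacement[gm]
    # closed form: the linear fields make this an affine prism-to-prism map
    expected = scale_to_unfolded(
        np.column_stack([fields.ap[gm], fields.pd[gm], fields.io[gm]]), spec)
    assert np.abs(mapped - expected).max() < 1e-9


def test_backward_warp_inverts_forward_on_prism(spec):
    lm, fields = _prism_fixture()
    w_u2n = build_unfolded_to_native(fields, lm, spec)
    gm = fields.domain_mask
    sites = scale_to_unfolded(
        np.column_stack([fields.ap[gm], fields.pd[gm], fields.io[gm]]), spec)
    native = lm.world_coords(gm)
    # interior sites (inside the convex hull) must map back exactly
    interior = np.all((sites > 2.0) & (sites < np.array([38.0, 18.0, 2.3])), axis=1)
    back = apply_warp_to_points(sites[interior], w_u2n)
    assert np.abs(back - native[interior]).max() < 1e-6


def test_gm_images_land_inside_prism(phantom_bundle, fields, warps_pair, spec):
    lm, _ = phantom_bundle
    w_n2u, _ = warps_pair
    gm = fields.domain_mask
    mapped = lm.world_coords(gm) + w_n2u.displacement[gm]
    extent = spec.extent_mm("hipp")
    assert np.all(mapped >= np.array(spec.origin) - 1e-6)
    assert np.all(mapped <= np.array(spec.origin) + extent + 1e-6)


def test_round_trip_error_below_one_unfolded_voxel(warps_pair, spec):
    w_n2u, w_u2n = warps_pair
    rng = np.random.default_rng(7)
    # interior unfolded points: IO in [0.2, 0.8], margins along AP/PD
    n = 8000
    pts = np.column_stack([
        rng.uniform(0.05, 0.95, n), rng.uniform(0.05, 0.95, n),
        rng.uniform(0.2, 0.8, n)])
    pts_u = scale_to_unfolded(pts, spec)
    nat = apply_warp_to_points(pts_u, w_u2n)
    back = apply_warp_to_points(nat, w_n2u)
    err = np.linalg.norm(back - pts_u, axis=1) / spec.voxel_size_unfolded
    assert np.percentile(err, 95) < 1.0


def test_warp_has_no_nonfinite_values(warps_pair):
    for w in warps_pair:
        assert np.all(np.isfinite(w.displacement))


def test_warp_construction_deterministic(slab_bundle, slab_fields, spec):
    lm, _ = slab_bundle
    a = build_unfolded_to_native(slab_fields, lm, spec)
    b = build_unfolded_to_native(slab_fields, lm, spec)
    assert np.array_equal(a.displacement, b.displacement)


def test_ap_monotone_along_longitudinal_lines(phantom_bundle, fields, warps_pair):
    """Unfolded AP images increase strictly along the phantom's long axis."""
    lm, truth = phantom_bundle
    w_n2u, _ = warps_pair
    gm = fields.domain_mask
    # walk voxels along axis 1 at fixed (i,k) where the slab has a long run
    mapped_ap = np.full(lm.data.shape, np.nan)
    mapped_ap[gm] = (lm.world_coords(gm) + w_n2u.displacement[gm])[:, 0]
    checked = 0
    for i in range(0, lm.data.shape[0], 8):
        for k in range(0, lm.data.shape[2], 8):
            line = mapped_ap[i, :, k]
            vals = line[np.isfinite(line)]
            if len(vals) > 30:
                assert np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)
                checked += 1
    assert checked > 3


def test_itk_write_read_round_trip(tmp_path, slab_bundle, slab_fields, spec):
    lm, _ = slab_bundle
    w = build_unfolded_to_native(slab_fields, lm, spec)
    p = write_itk_warp(w, tmp_path / "warp.nii.gz")
    back = read_itk_warp(p)
    assert np.array_equal(back.displacement.astype(np.float32),
                          w.displacement.astype(np.float32))


def test_itk_file_follows_lps_convention(tmp_path, slab_bundle, slab_fields, spec):
    """An independent ITK reader sees the displacement in LPS physical space."""
    sitk = pytest.importorskip("SimpleITK")
    lm, _ = slab_bundle
    w = build_unfolded_to_native(slab_fields, lm, spec)
    p = write_itk_warp(w, tmp_path / "warp.nii.gz")
    img = sitk.ReadImage(str(p))
    field = sitk.GetArrayFromImage(img)  # (z,y,x,3), LPS components in memory
    lps = w.displacement.astype(np.float64) * np.array([-1.0, -1.0, 1.0])
    assert np.allclose(np.transpose(field, (2, 1, 0, 3)), lps, atol=1e-4)


def test_zero_warp_through_independent_itk_reader(tmp_path, spec):
    """A written zero-displacement warp leaves points unchanged when applied
    by SimpleITK's own transform machinery."""
    sitk = pytest.importorskip("SimpleITK")
    w = uc.WarpField(np.zeros((8, 8, 8, 3)), "unfolded_to_native", np.eye(4))
    p = write_itk_warp(w, tmp_path / "zero.nii.gz")
    field = sitk.ReadImage(str(p), sitk.sitkVectorFloat64)
    tx = sitk.DisplacementFieldTransform(field)
    for pt in [(1.0, 2.0, 3.0), (5.5, 0.5, 6.0)]:
        assert np.allclose(tx.TransformPoint(pt), pt, atol=1e-6)


def test_zero_warp_is_identity_on_points_and_images(spec):
    disp = np.zeros((8, 8, 8, 3))
    w = uc.WarpField(disp, "unfolded_to_native", np.eye(4))
    pts = np.random.default_rng(0).uniform(1, 6, (20, 3))
    assert np.allclose(apply_warp_to_points(pts, w), pts)
    img = np.arange(512).reshape(8, 8, 8).astype(np.int16)
    out = apply_warp_to_image(img, np.eye(4), w, "nearest")
    assert np.array_equal(out, img)


def test_nearest_resampling_never_invents_labels(phantom_bundle, warps_pair):
    lm, _ = phantom_bundle
    _, w_u2n = warps_pair
    out = apply_warp_to_image(lm.data, lm.affine, w_u2n, "nearest")
    assert set(np.unique(out)).issubset(set(np.unique(lm.data)))


def test_atlas_pullback_matches_per_voxel_lookup(phantom_bundle, fields,
                                                 warps_pair, schematic_atlas, spec):
    """Pulling the unfolded atlas image to native equals direct (AP,PD) lookup."""
    lm, _ = phantom_bundle
    w_n2u, _ = warps_pair
    gm = fields.domain_mask
    # build a 3D unfolded atlas volume (constant along IO)
    sh = spec.shape_hipp
    nr, nc = schematic_atlas.label_image.shape
    rows = np.clip(np.rint(np.linspace(0, 1, sh[0]) * (nr - 1)), 0, nr - 1).astype(int)
    cols = np.clip(np.rint(np.linspace(0, 1, sh[1]) * (nc - 1)), 0, nc - 1).astype(int)
    atlas_vol = schematic_atlas.label_image[np.ix_(rows, cols)][:, :, None].repeat(sh[2], 2)
    # edge-clamp: the prism spans half a voxel past the outermost grid centers
    pulled = apply_warp_to_image(atlas_vol, spec.affine("hipp"), w_n2u, "nearest",
                                 mode="nearest")
    direct = schematic_atlas.lookup(fields.ap[gm], fields.pd[gm])
    agree = np.mean(pulled[gm] == direct)
    assert agree > 0.97  # differs only at band boundaries by pixel rounding
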