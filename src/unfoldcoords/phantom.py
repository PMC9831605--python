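"""Synthetic folded-sheet phantoms with analytic ground truth.

The hippocampus is topologically a thin curled sheet; the phantom models it
as a parametric surface X(u, v, w): u runs along the long (AP) axis, v
across the sheet (PD), and w through its thickness (IO).  The cross-section
is a circular arc ("curl"), optionally rippled along AP by sinusoidal
digitations, rasterized into the standard cropped grid (128 x 256 x 128
voxels at 0.3 mm isotropic).  All eight boundary tissues are attached where
anatomy puts them: HATA and indusium griseum caps at the anterior/posterior
ends, an MTLc strip on the proximal edge, a dentate flap wrapping the
distal edge, SRLM lining the concave (inner) face and pial the convex
(outer) face.

Because the sheet map has a closed-form inverse, voxels are labelled by
mapping their centers back to (u, v, w) and testing parameter ranges — no
splatting — so the generative coordinates of every tissue voxel are exact
and GM volume matches the analytic value to rasterization error.

Default geometry: a 40 x 20 mm sheet, 1.2 mm thick (within the anatomical
0.5-2 mm range), curled by 0.75 turns with three 1 mm digitations — enough
folding that unfolding is non-trivial while every tissue stays several
voxels thick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .core import DEFAULT_LABEL_SCHEME, TissueLabelmap, flip_hemisphere
from .injection import TemplateShape
from .laplace import CoordFields
from .subfields import CANONICAL_ORDER, SubfieldAtlas

log = logging.getLogger(__name__)

__all__ = ["PhantomParams", "PhantomTruth", "generate_phantom", "generate_template",
           "make_schematic_atlas"]

GRID_SHAPE = (128, 256, 128)

#: default PD band fractions of the schematic five-band subfield atlas
DEFAULT_BAND_FRACTIONS = (0.25, 0.30, 0.10, 0.20, 0.15)


@dataclass(frozen=True)
class PhantomParams:
    curl_turns: float = 0.75
    n_digitations: int = 3
    digitation_amplitude: float = 1.0  # mm
    thickness: float = 1.2  # mm, anatomical range 0.5-2
    length: float = 40.0  # mm along AP
    width: float = 20.0  # mm along PD
    voxel_size: float = 0.3  # mm isotropic
    seed: int = 0
    hemisphere: str = "R"
    n_cysts: int = 0
    cap_mm: float = 1.2  # HATA / IndGris cap depth
    strip_mm: float = 1.5  # MTLc strip width
    lining_mm: float = 0.6  # SRLM / pial lining thickness
    dg_radius: float = 1.5  # mm, dentate flap wrap radius
    dg_turn: float = 4.0  # rad, dentate wrap angle
    dg_thickness: float = 0.6  # mm

    def __post_init__(self) -> None:
        if not (0.5 <= self.thickness <= 2.0):
            raise ValueError("thickness must lie in the anatomical 0.5-2 mm range")
        if min(self.length, self.width, self.voxel_size) <= 0:
            raise ValueError("extents must be positive")
        if self.n_digitations < 0:
            raise ValueError("n_digitations must be >= 0")
        if not 0 <= self.curl_turns < 1.0:
            raise ValueError("curl_turns must lie in [0, 1) (no self-intersection)")


@dataclass
class PhantomTruth:
    """Generative parameters recorded on the emitted labelmap's voxels."""

    true_ap: np.ndarray  # u on GM voxels, NaN elsewhere
    true_pd: np.ndarray
    true_depth: np.ndarray  # laminar fraction w
    expected_gm_volume_mm3: float
    native_mid_area_mm2: float
    dg_truth: dict = field(default_factory=dict)  # ap/pd/io arrays on DG voxels
    params: PhantomParams | None = None


def _digitation(p: PhantomParams, u) -> np.ndarray:
    u = np.asarray(u, float)
    if p.n_digitations == 0 or p.digitation_amplitude == 0:
        return np.zeros_like(u)
    return p.digitation_amplitude * np.sin(2.0 * np.pi * p.n_digitations * u)


def _cross_section(p: PhantomParams, v):
    """Arc point, unit tangent and unit normal in (x,z) for PD parameter v.

    The normal points to the concave side (toward the arc center); for a
    flat sheet it is +z.  Arc length is preserved so v measures uniform
    distance across the sheet.
    """
    v = np.asarray(v, float)
    if p.curl_turns == 0:
        x = (v - 0.5) * p.width
        z = np.zeros_like(x)
        return x, z, np.ones_like(x), np.zeros_like(x), np.zeros_like(x), np.ones_like(x)
    theta = 2.0 * np.pi * p.curl_turns
    R = p.width / theta
    phi = theta * (v - 0.5)
    return (R * np.sin(phi), R * (1.0 - np.cos(phi)),
            np.cos(phi), np.sin(phi), -np.sin(phi), np.cos(phi))


def sheet_points(p: PhantomParams, u, v, w):
    """Forward map X(u, v, w) -> world mm; w=0 is the inner (SRLM) face."""
    x, z, _, _, nx, nz = _cross_section(p, v)
    s = _digitation(p, u) + (0.5 - np.asarray(w, float)) * p.thickness
    y = (np.asarray(u, float) - 0.5) * p.length
    return np.stack([x + s * nx, y, z + s * nz], axis=-1)


def _invert_sheet(p: PhantomParams, X: np.ndarray):
    """Closed-form inverse of the sheet map for world points (...,3)."""
    x, y, z = X[..., 0], X[..., 1], X[..., 2]
    u = y / p.length + 0.5
    if p.curl_turns == 0:
        v = x / p.width + 0.5
        s = z
    else:
        theta = 2.0 * np.pi * p.curl_turns
        R = p.width / theta
        # arc center sits at (0, R); radius decreases toward the concave side
        r = np.hypot(x, R - z)
        phi = np.arctan2(x, R - z)
        v = phi / theta + 0.5
        s = R - r
    w = 0.5 - (s - _digitation(p, u)) / p.thickness
    return u, v, w


def _dg_frame(p: PhantomParams):
    """Flap center and the edge tangent/normal frame at the distal edge."""
    x1, z1, tx, tz, nx, nz = (float(a) for a in _cross_section(p, 1.0))
    cx, cz = x1 + p.dg_radius * nx, z1 + p.dg_radius * nz
    return cx, cz, tx, tz, nx, nz


def dg_points(p: PhantomParams, u, t, w):
    """Dentate flap: an arc of radius ``dg_radius`` continuing the sheet past
    its distal (v=1) edge, wrapping ``dg_turn`` radians; t in [0,1] runs
    around the wrap (the DG's own PD), w through its thickness.  The flap
    follows the digitations of the edge it hangs from."""
    cx, cz, tx, tz, nx, nz = _dg_frame(p)
    psi = np.asarray(t, float) * p.dg_turn
    rx = -np.cos(psi) * nx + np.sin(psi) * tx
    rz = -np.cos(psi) * nz + np.sin(psi) * tz
    rad = p.dg_radius + (np.asarray(w, float) - 0.5) * p.dg_thickness
    d = _digitation(p, u)
    y = (np.asarray(u, float) - 0.5) * p.length
    return np.stack([cx + rad * rx + d * nx, y, cz + rad * rz + d * nz], axis=-1)


def _invert_dg(p: PhantomParams, X: np.ndarray):
    cx, cz, tx, tz, nx, nz = _dg_frame(p)
    u = X[..., 1] / p.length + 0.5
    d = _digitation(p, u)
    qx = X[..., 0] - d * nx - cx
    qz = X[..., 2] - d * nz - cz
    r = np.hypot(qx, qz)
    r = np.maximum(r, 1e-12)
    ex, ez = qx / r, qz / r
    psi = np.arctan2(ex * tx + ez * tz, -(ex * nx + ez * nz)) % (2.0 * np.pi)
    t = psi / p.dg_turn
    w = (r - p.dg_radius) / p.dg_thickness + 0.5
    return u, t, w


def _affine(p: PhantomParams) -> np.ndarray:
    aff = np.diag([p.voxel_size] * 3 + [1.0])
    aff[:3, 3] = -(np.array(GRID_SHAPE) - 1) / 2.0 * p.voxel_size
    return aff


def _check_fits(p: PhantomParams) -> None:
    half = (np.array(GRID_SHAPE) - 1) / 2.0 * p.voxel_size
    y_max = p.length / 2.0 + p.cap_mm
    pad = p.digitation_amplitude + p.thickness + 2 * p.dg_radius + p.dg_thickness
    if p.curl_turns == 0:
        xz_max = p.width / 2.0 + p.strip_mm + pad
    else:
        theta = 2.0 * np.pi * p.curl_turns
        R = p.width / theta
        x_max = R * (1.0 if theta / 2 >= np.pi / 2 else np.sin(theta / 2))
        z_max = R * (1.0 - np.cos(min(theta / 2, np.pi)))
        xz_max = max(x_max, z_max) + pad
    if y_max > half[1] or xz_max > max(half[0], half[2]):
        raise ValueError(
            "phantom sheet exceeds the cropped grid; reduce length/width/"
            "amplitude or increase voxel count")


def generate_phantom(params: PhantomParams | None = None):
    """Rasterize the parametric phantom.

    Returns ``(TissueLabelmap, PhantomTruth)``.  Deterministic given the
    seed (randomness only enters through optional cyst placement).
    """
    p = params or PhantomParams()
    _check_fits(p)
    rng = np.random.default_rng(p.seed)
    aff = _affine(p)
    sch = DEFAULT_LABEL_SCHEME
    T = p.thickness
    cap_u = p.cap_mm / p.length
    strip_v = p.strip_mm / p.width
    line_w = p.lining_mm / T

    ii, jj, kk = np.meshgrid(*[np.arange(s, dtype=float) for s in GRID_SHAPE],
                             indexing="ij")
    X = np.stack([ii, jj, kk], axis=-1) * p.voxel_size + aff[:3, 3]
    u, v, w = _invert_sheet(p, X)

    labels = np.zeros(GRID_SHAPE, np.int16)
    in_u = (u >= 0) & (u <= 1)
    in_v = (v >= 0) & (v <= 1)
    in_w = (w >= 0) & (w <= 1)
    band_w = (w >= -line_w) & (w <= 1 + line_w)
    ext_v = (v >= -strip_v) & (v <= 1)

    gm = in_u & in_v & in_w
    labels[in_u & in_v & (w < 0) & (w >= -line_w)] = sch["SRLM"]
    labels[in_u & in_v & (w > 1) & (w <= 1 + line_w)] = sch["pial"]
    labels[in_u & (v < 0) & (v >= -strip_v) & in_w] = sch["MTLc"]
    hata_u = (u < 0) & (u >= -cap_u)
    ind_u = (u > 1) & (u <= 1 + cap_u)
    labels[hata_u & ext_v & band_w] = sch["HATA"]
    labels[ind_u & ext_v & band_w] = sch["IndGris"]

    # dentate flap wrapping the distal edge
    ud, td, wd = _invert_dg(p, X)
    in_flap = (td >= 0) & (td <= 1) & (wd >= 0) & (wd <= 1)
    dg = in_flap & in_u & ~gm & (labels == 0)
    labels[dg] = sch["DGgranule"]
    labels[in_flap & hata_u & (labels == 0)] = sch["HATA"]
    labels[in_flap & ind_u & (labels == 0)] = sch["IndGris"]
    labels[gm] = sch["GM"]

    # optional cysts: small ellipsoids carved out of GM interior
    if p.n_cysts > 0:
        gm_idx = np.argwhere(labels == sch["GM"])
        centers = gm_idx[rng.integers(0, len(gm_idx), p.n_cysts)]
        for c in centers:
            r = rng.uniform(1.5, 3.0)
            d2 = ((ii - c[0]) ** 2 + ((jj - c[1]) / 1.5) ** 2 + (kk - c[2]) ** 2)
            labels[(d2 <= r**2) & (labels == sch["GM"])] = sch["cyst"]

    gm_mask = labels == sch["GM"]
    dg_mask = labels == sch["DGgranule"]

    def masked(arr, m):
        out = np.full(GRID_SHAPE, np.nan)
        out[m] = arr[m]
        return out

    # analytic volume and midsurface area by quadrature of the exact Jacobian
    u1 = np.linspace(0, 1, 801)
    v1 = np.linspace(0, 1, 201)
    UU, VV = np.meshgrid(u1, v1, indexing="ij")
    mid = sheet_points(p, UU, VV, np.full_like(UU, 0.5))
    Xu = np.gradient(mid, u1, axis=0)
    Xv = np.gradient(mid, v1, axis=1)
    area_el = np.linalg.norm(np.cross(Xu, Xv), axis=-1)
    native_mid_area = float(np.trapezoid(np.trapezoid(area_el, v1, axis=1), u1))
    if p.curl_turns == 0:
        expected_volume = p.length * p.width * T
    else:
        # |det J| = T * L * (W - s*theta); the (0.5-w)T term integrates out
        theta = 2.0 * np.pi * p.curl_turns
        dbar = float(np.trapezoid(_digitation(p, u1), u1))
        expected_volume = T * p.length * (p.width - dbar * theta)

    dg_truth = {"ap": masked(ud, dg_mask), "pd": masked(td, dg_mask),
                "io": masked(wd, dg_mask)}
    lm = TissueLabelmap(labels, aff, dict(sch), "R")
    truth = PhantomTruth(
        true_ap=masked(u, gm_mask),
        true_pd=masked(v, gm_mask),
        true_depth=masked(w, gm_mask),
        expected_gm_volume_mm3=expected_volume,
        native_mid_area_mm2=native_mid_area,
        dg_truth=dg_truth,
        params=p,
    )
    if p.hemisphere == "L":
        lm = flip_hemisphere(lm)  # R-built phantom mirrored to the left
        for name in ("true_ap", "true_pd", "true_depth"):
            setattr(truth, name, getattr(truth, name)[::-1].copy())
        truth.dg_truth = {k: f[::-1].copy() for k, f in truth.dg_truth.items()}
    log.info("phantom: %d GM voxels, expected volume %.1f mm^3",
             int(gm_mask.sum()), expected_volume)
    return lm, truth


def generate_template(params: PhantomParams | None = None) -> TemplateShape:
    """Idealized template: the smooth (undigitated) phantom with analytic
    coordinate fields on its dentate flap."""
    p = params or PhantomParams()
    smooth = dc_replace(p, n_digitations=0, digitation_amplitude=0.0, n_cysts=0,
                        hemisphere="R")
    lm, truth = generate_phantom(smooth)
    dg_mask = lm.mask("DGgranule")
    dg_fields = CoordFields(
        ap=truth.dg_truth["ap"], pd=truth.dg_truth["pd"], io=truth.dg_truth["io"],
        domain_mask=dg_mask, io_mode="laplace", meta={"source": "analytic template"},
    )
    return TemplateShape(labelmap=lm, dg_fields=dg_fields,
                         metadata={"params": smooth})


def make_schematic_atlas(
    band_fractions=DEFAULT_BAND_FRACTIONS,
    shape: tuple[int, int] = (256, 128),
) -> SubfieldAtlas:
    """Schematic five-band unfolded subfield atlas.

    PD-parallel bands Sub, CA1, CA2, CA3, CA4 spanning the full AP extent,
    with the given width fractions.  A stand-in for a histology-derived
    unfolded atlas (synthetic); any labelled unfolded image can replace it.
    """
    fr = np.asarray(band_fractions, float)
    if len(fr) == 0 or np.any(fr <= 0) or abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError("band fractions must be positive and sum to 1")
    nr, nc = shape
    img = np.zeros((nr, nc), np.int32)
    names = {}
    edges = np.concatenate([[0.0], np.cumsum(fr)])
    pd = (np.arange(nc) + 0.5) / nc
    band_names = list(CANONICAL_ORDER[: len(fr)])
    if len(fr) > len(CANONICAL_ORDER):
        band_names += [f"band{i}" for i in range(len(CANONICAL_ORDER), len(fr))]
    for i, name in enumerate(band_names):
        names[name] = i + 1
        cols = (pd >= edges[i]) & (pd <= edges[i + 1] + 1e-12)
        img[:, cols] = i + 1
    names["DG"] = len(band_names) + 1
    return SubfieldAtlas(img, names, provenance="schematic synthetic atlas")
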