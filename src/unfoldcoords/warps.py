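"""Bidirectional transforms between native space and the unfolded prism.

The three Laplace coordinates of every GM voxel are scaled to a standard
rectangular prism (256 x 128 x 16 unfolded voxels at 0.15625 mm for the
hippocampus; 256 x 32 x 16 for the dentate gyrus).  The forward transform
(native -> unfolded) is read directly off the coordinate fields; the
backward transform (unfolded -> native) treats GM voxels as scattered
samples of the inverse map and evaluates a Delaunay piecewise-linear
interpolant on the regular unfolded grid.  Both are serialized as dense
ITK-convention displacement-field NIfTIs usable by standard tooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator, RegularGridInterpolator

from .core import TissueLabelmap, UnfoldedSpaceSpec
from .laplace import CoordFields

log = logging.getLogger(__name__)

__all__ = [
    "WarpField",
    "scale_to_unfolded",
    "build_native_to_unfolded",
    "build_unfolded_to_native",
    "write_itk_warp",
    "read_itk_warp",
    "apply_warp_to_image",
    "apply_warp_to_points",
]


@dataclass
class WarpField:
    """Dense displacement field (mm, RAS) on a reference grid.

    ``displacement[i,j,k]`` maps the world position of reference voxel
    (i,j,k) to its image: ``target = world + displacement``.
    """

    displacement: np.ndarray  # (X,Y,Z,3) mm
    direction: str  # "native_to_unfolded" | "unfolded_to_native"
    reference_affine: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must be (X,Y,Z,3)")
        self.reference_affine = np.asarray(self.reference_affine, float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]

    def _interpolator(self) -> RegularGridInterpolator:
        inv = np.linalg.inv(self.reference_affine)
        grids = [np.arange(s, dtype=float) for s in self.shape]
        rgi = RegularGridInterpolator(
            grids, self.displacement, bounds_error=False, fill_value=None
        )
        self._inv_affine = inv
        return rgi

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Interpolate the displacement (linear) at world points (N,3)."""
        rgi = self._interpolator()
        ijk = points @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]
        return rgi(ijk)


def scale_to_unfolded(
    coords: np.ndarray, spec: UnfoldedSpaceSpec, structure: str = "hipp"
) -> np.ndarray:
    """Scale unit-cube (AP,PD,IO) coordinates to unfolded world mm.

    ``coords`` is (...,3) with values in [0,1]; the result spans the physical
    extent of the prism (shape * voxel size) from the prism origin.
    """
    c = np.asarray(coords, float)
    finite = np.isfinite(c)
    if np.any((c[finite] < -1e-9) | (c[finite] > 1 + 1e-9)):
        raise ValueError("unfolded coordinates must lie in [0,1]")
    extent = spec.extent_mm(structure)
    return np.asarray(spec.origin) + np.clip(c, 0.0, 1.0) * extent


def _fill_and_smooth(disp: np.ndarray, known: np.ndarray, sigma_vox: float = 1.0) -> np.ndarray:
    """Nearest-known fill outside ``known``, then Gaussian-smooth the filled
    voxels only (known values are kept exact)."""
    out = disp.copy()
    if known.all():
        return out
    _, nearest = ndimage.distance_transform_edt(~known, return_indices=True)
    for c in range(3):
        ch = out[..., c]
        ch[~known] = ch[tuple(ind[~known] for ind in nearest)]
        sm = ndimage.gaussian_filter(ch, sigma_vox)
        ch[~known] = sm[~known]
    return out


def build_native_to_unfolded(
    fields: CoordFields,
    lm: TissueLabelmap,
    spec: UnfoldedSpaceSpec | None = None,
    structure: str = "hipp",
) -> WarpField:
    """Forward warp on the native grid: GM voxels map to their scaled
    unfolded coordinates; non-GM voxels are nearest-GM filled and smoothed."""
    spec = spec or UnfoldedSpaceSpec()
    domain = fields.domain_mask
    if not domain.any():
        raise ValueError("empty coordinate domain")
    targets = scale_to_unfolded(fields.stacked(), spec, structure)
    native = lm.world_coords(domain)
    disp = np.zeros(lm.data.shape + (3,))
    disp[domain] = targets - native
    disp = _fill_and_smooth(disp, domain)
    return WarpField(disp, "native_to_unfolded", lm.affine)


def build_unfolded_to_native(
    fields: CoordFields,
    lm: TissueLabelmap,
    spec: UnfoldedSpaceSpec | None = None,
    structure: str = "hipp",
) -> WarpField:
    """Backward warp on the unfolded grid via scattered piecewise-linear
    interpolation of native positions over scaled unfolded sample sites.

    Grid points outside the convex hull of the samples take the value of the
    nearest sample (no NaNs in the emitted field).
    """
    spec = spec or UnfoldedSpaceSpec()
    domain = fields.domain_mask
    sites_unf = scale_to_unfolded(fields.stacked(), spec, structure)
    values_nat = lm.world_coords(domain)
    if len(sites_unf) < 4:
        raise ValueError("need at least 4 non-coplanar GM samples")
    # deterministic triangulation: fixed site ordering by voxel index
    shape = spec.shape(structure)
    aff = spec.affine(structure)
    grids = [np.arange(s, dtype=float) * spec.voxel_size_unfolded + o
             for s, o in zip(shape, spec.origin)]
    AA, PP, II = np.meshgrid(*grids, indexing="ij")
    q = np.column_stack([AA.ravel(), PP.ravel(), II.ravel()])
    li = LinearNDInterpolator(sites_unf, values_nat)
    vals = li(q)
    bad = ~np.isfinite(vals[:, 0])
    if bad.any():
        ni = NearestNDInterpolator(sites_unf, values_nat)
        vals[bad] = ni(q[bad])
    disp = (vals - q).reshape(shape + (3,))
    return WarpField(disp, "unfolded_to_native", aff)


def write_itk_warp(w: WarpField, path, itk_convention: bool = True):
    """Write the warp as a 5D displacement-field NIfTI (X,Y,Z,1,3).

    With ``itk_convention`` (default) the displacement-vector intent code is
    set, which ITK-family tools recognize: their NIfTI IO negates the x/y
    components on read, so the vectors land in ITK physical (LPS) space while
    the file itself stores NIfTI-convention RAS mm.  With ``itk_convention``
    False a plain vector NIfTI (no displacement intent) is written instead.
    """
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = w.displacement.astype(np.float32)[:, :, :, np.newaxis, :]
    img = nib.Nifti1Image(data, w.reference_affine)
    img.header.set_intent("vector")
    if itk_convention:
        img.header["intent_code"] = 1006  # displacement vector
    img.to_filename(str(path))
    return path


def read_itk_warp(path, direction: str = "unfolded_to_native") -> WarpField:
    """Read a displacement-field NIfTI written by :func:`write_itk_warp`."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5:
        data = data[:, :, :, 0, :]
    return WarpField(data.astype(float), direction, img.affine)


def apply_warp_to_points(points: np.ndarray, w: WarpField) -> np.ndarray:
    """Move world points (N,3) through the warp (linear interpolation)."""
    pts = np.asarray(points, float)
    return pts + w.displacement_at(pts)


def apply_warp_to_image(
    data: np.ndarray,
    data_affine: np.ndarray,
    w: WarpField,
    interpolation: str = "linear",
    cval: float = 0.0,
    mode: str = "constant",
) -> np.ndarray:
    """Resample an image through the warp by pulling values.

    For each voxel of the warp's reference grid the value is sampled from
    ``data`` at the displaced world position.  ``interpolation`` is
    ``"nearest"`` (labelmaps; never invents new values) or ``"linear"``.
    ``mode`` controls out-of-bounds behaviour (scipy semantics: ``constant``
    fills with ``cval``, ``nearest`` clamps to the edge).  Returns an array
    on the warp's reference grid.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError("interpolation must be 'nearest' or 'linear'")
    shape = w.shape
    ii, jj, kk = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    ijk = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    world = ijk @ w.reference_affine[:3, :3].T + w.reference_affine[:3, 3]
    moved = world + w.displacement.reshape(-1, 3)
    inv = np.linalg.inv(np.asarray(data_affine, float))
    src = moved @ inv[:3, :3].T + inv[:3, 3]
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(data, float), src.T, order=order, mode=mode, cval=cval
    )
    return out.reshape(shape).astype(data.dtype if order == 0 else float)
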