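"""Domain types, the tissue label scheme, and NIfTI labelmap input/output.

The unfolding engine consumes a voxel labelmap of hippocampal tissue classes
in a cropped, hippocampus-oblique space: grey matter (GM) plus the boundary
and auxiliary tissues that anchor the intrinsic coordinate axes (SRLM, MTLc,
pial, HATA, indusium griseum, cysts, and the DG granule cell layer).  All
volumes are NIfTI-1; world coordinates follow the NIfTI affine in RAS mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "DEFAULT_LABEL_SCHEME",
    "REQUIRED_LABELS",
    "TissueLabelmap",
    "UnfoldedSpaceSpec",
    "ValidationReport",
    "read_labelmap",
    "write_labelmap",
    "save_scalar_field",
    "flip_hemisphere",
    "validate_labelmap",
]

#: Fixed integer coding of the tissue classes.  The class inventory is
#: anatomical; the integers are a package convention and may be overridden
#: by a JSON label-scheme file.
DEFAULT_LABEL_SCHEME: dict[str, int] = {
    "background": 0,
    "GM": 1,
    "SRLM": 2,
    "cyst": 3,
    "DGgranule": 4,
    "MTLc": 5,
    "pial": 6,
    "HATA": 7,
    "IndGris": 8,
}

#: Labels that must be present for unfolding: GM is the solution domain and
#: the rest carry the Dirichlet endpoints of the three coordinate axes.
REQUIRED_LABELS = ("GM", "SRLM", "HATA", "IndGris", "MTLc", "DGgranule")


@dataclass
class TissueLabelmap:
    """Integer tissue labels on a regular 3D grid with a world affine.

    Parameters
    ----------
    data
        3D integer array of voxel labels.
    affine
        4x4 voxel-to-world transform in mm (RAS).
    label_scheme
        Mapping tissue-name -> integer label value.
    hemisphere
        ``"L"`` or ``"R"``.
    """

    data: np.ndarray
    affine: np.ndarray
    label_scheme: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_SCHEME))
    hemisphere: str = "R"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D labelmap, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data)
            if not np.allclose(self.data, as_int, atol=1e-6):
                raise ValueError("labelmap data must be integer-valued")
            self.data = as_int.astype(np.int16)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm per axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the voxels carrying any of the named labels."""
        vals = [self.label_scheme[n] for n in names]
        return np.isin(self.data, vals)

    def value(self, name: str) -> int:
        return self.label_scheme[name]

    def world_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World (mm) coordinates of voxel centers, (N,3) for masked voxels."""
        if mask is None:
            mask = np.ones(self.data.shape, bool)
        ijk = np.argwhere(mask).astype(float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class UnfoldedSpaceSpec:
    """Geometry of the standardized unfolded rectangular prism.

    The hippocampal prism is 256 x 128 x 16 voxels in (AP, PD, IO) order at
    0.15625 mm isotropic (40 x 20 x 2.5 mm); the dentate gyrus uses a
    narrower 256 x 32 x 16 block.  The origin of the first voxel center is a
    package convention (0,0,0 mm in unfolded space).
    """

    shape_hipp: tuple[int, int, int] = (256, 128, 16)
    shape_dg: tuple[int, int, int] = (256, 32, 16)
    voxel_size_unfolded: float = 0.15625
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def shape(self, structure: str) -> tuple[int, int, int]:
        if structure == "hipp":
            return self.shape_hipp
        if structure == "dg":
            return self.shape_dg
        raise ValueError(f"unknown structure {structure!r}")

    def extent_mm(self, structure: str) -> np.ndarray:
        """Physical edge lengths of the prism in mm."""
        return np.array(self.shape(structure), float) * self.voxel_size_unfolded

    def affine(self, structure: str) -> np.ndarray:
        aff = np.diag([self.voxel_size_unfolded] * 3 + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class ValidationReport:
    """Outcome of labelmap sanity checks (reporting only, never raises)."""

    missing_labels: list[str] = field(default_factory=list)
    gm_component_count: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.missing_labels and self.gm_component_count == 1


def read_labelmap(
    path: str | Path,
    label_scheme: dict[str, int] | str | Path | None = None,
    hemisphere: str = "R",
) -> TissueLabelmap:
    """Read a NIfTI tissue labelmap.

    ``label_scheme`` may be a mapping or a path to a JSON file mapping tissue
    names to integers; by default :data:`DEFAULT_LABEL_SCHEME` is used.
    Raises for missing files, non-3D volumes, and non-integer data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D labelmap, got {data.ndim}D volume {path}")
    if isinstance(label_scheme, (str, Path)):
        label_scheme = {k: int(v) for k, v in json.loads(Path(label_scheme).read_text()).items()}
    return TissueLabelmap(
        data=data,
        affine=img.affine,
        label_scheme=dict(label_scheme or DEFAULT_LABEL_SCHEME),
        hemisphere=hemisphere,
    )


def write_labelmap(lm: TissueLabelmap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(lm.data.astype(np.int16), lm.affine)
    img.to_filename(str(path))
    return path


def save_scalar_field(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a float32 scalar field (NaN outside its domain) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(np.asarray(data, np.float32), np.asarray(affine, float)).to_filename(str(path))
    return path


def flip_hemisphere(lm: TissueLabelmap, target: str | None = None) -> TissueLabelmap:
    """Mirror a labelmap sagittally (axis 0) so left hippocampi resemble right.

    The voxel array is reversed along the first axis and the affine updated so
    tissue world coordinates are mirrored about the mid-sagittal plane of the
    grid; the hemisphere flag is toggled.  If ``target`` equals the current
    hemisphere the labelmap is returned unchanged.
    """
    if target is not None and target == lm.hemisphere:
        return lm
    n = lm.data.shape[0]
    flipped = lm.data[::-1].copy()
    # index i -> n-1-i: compose the affine with that index map, then negate
    # the world x column so the anatomy is mirrored, not just re-indexed.
    reindex = np.eye(4)
    reindex[0, 0] = -1.0
    reindex[0, 3] = n - 1
    affine = lm.affine @ reindex
    affine[0, :] *= -1.0
    return replace(lm, data=flipped, affine=affine,
                   hemisphere="L" if lm.hemisphere == "R" else "R")


def validate_labelmap(lm: TissueLabelmap) -> ValidationReport:
    """Check label completeness, GM connectivity and unknown label values."""
    report = ValidationReport()
    present = set(np.unique(lm.data).tolist())
    known = set(lm.label_scheme.values())
    for name in REQUIRED_LABELS:
        if lm.label_scheme[name] not in present:
            report.missing_labels.append(name)
    unknown = sorted(present - known)
    for v in unknown:
        report.warnings.append(f"unknown label value {v} present in labelmap")
    gm = lm.mask("GM")
    if gm.any():
        _, n = ndimage.label(gm, structure=np.ones((3, 3, 3), bool))
        report.gm_component_count = int(n)
        if n > 1:
            report.warnings.append(f"GM has {n} 26-connected components (expected 1)")
    else:
        report.gm_component_count = 0
    return report
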