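"""Subfield parcellation applied identically to all subjects in unfolded space.

Because every subject shares the same unfolded coordinate frame, a single
2D label image over the (AP, PD) plane defines subfield boundaries for all
hippocampi at once: surface vertices are labelled by nearest-pixel lookup of
their unfolded coordinates, and native volumetric labels are produced by
looking up each GM voxel's own (AP, PD) coordinate.  The parcellation is
therefore topologically constrained by construction — bands keep their
order and adjacency — which :func:`check_topology` verifies.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .core import TissueLabelmap
from .laplace import CoordFields
from .surfaces import SurfaceMesh

log = logging.getLogger(__name__)

__all__ = [
    "SubfieldAtlas",
    "TopologyReport",
    "CANONICAL_ORDER",
    "label_vertices",
    "fill_volumetric_subfields",
    "check_topology",
    "read_atlas",
    "write_atlas",
]

#: proximal-to-distal order of the subfield bands
CANONICAL_ORDER = ("Sub", "CA1", "CA2", "CA3", "CA4")


@dataclass
class SubfieldAtlas:
    """Unfolded-plane subfield label image.

    ``label_image`` is indexed as [AP, PD] with AP in [0,1] mapping to rows
    and PD to columns.  All pixels are labelled.
    """

    label_image: np.ndarray  # 2D int
    label_names: dict[str, int]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image)
        if self.label_image.ndim != 2:
            raise ValueError("atlas label image must be 2D")

    def lookup(self, ap: np.ndarray, pd: np.ndarray) -> np.ndarray:
        """Nearest-pixel label lookup at normalized (AP, PD) coordinates."""
        nr, nc = self.label_image.shape
        r = np.clip(np.rint(np.asarray(ap, float) * (nr - 1)), 0, nr - 1).astype(int)
        c = np.clip(np.rint(np.asarray(pd, float) * (nc - 1)), 0, nc - 1).astype(int)
        return self.label_image[r, c]

    def name_of(self, value: int) -> str:
        for k, v in self.label_names.items():
            if v == value:
                return k
        return str(value)


@dataclass
class TopologyReport:
    components_per_label: dict[str, int] = field(default_factory=dict)
    adjacency_violations: list[tuple[str, str]] = field(default_factory=list)
    full_ap_extent: dict[str, bool] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return (
            all(v == 1 for v in self.components_per_label.values())
            and not self.adjacency_violations
        )


def label_vertices(atlas: SubfieldAtlas, mesh: SurfaceMesh) -> np.ndarray:
    """Label every vertex by its (AP, PD) position in the atlas image."""
    if mesh.uv is None:
        raise ValueError("mesh carries no unfolded (AP,PD) coordinates")
    return atlas.lookup(mesh.uv[:, 0], mesh.uv[:, 1])


def fill_volumetric_subfields(
    atlas: SubfieldAtlas,
    fields: CoordFields,
    lm: TissueLabelmap,
    dg_mask: np.ndarray | None = None,
    dg_label: str = "DG",
) -> TissueLabelmap:
    """Native volumetric subfield labels between the inner and outer surfaces.

    Every GM voxel receives the atlas label at its own (AP, PD) coordinate;
    voxels whose coordinates are NaN fall back to the nearest labelled
    coordinate (count logged).  DG voxels get the DG label; all non-GM
    voxels are untouched (0 in the output).
    """
    out = np.zeros(lm.data.shape, np.int16)
    gm = fields.domain_mask
    ap = fields.ap[gm]
    pd = fields.pd[gm]
    ok = np.isfinite(ap) & np.isfinite(pd)
    labels = np.zeros(int(gm.sum()), np.int16)
    labels[ok] = atlas.lookup(ap[ok], pd[ok])
    n_bad = int((~ok).sum())
    if n_bad:
        from scipy.interpolate import NearestNDInterpolator

        idx = np.argwhere(gm)
        ni = NearestNDInterpolator(idx[ok], labels[ok])
        labels[~ok] = ni(idx[~ok])
        log.info("fill_volumetric_subfields: %d voxel(s) used nearest-coordinate fallback", n_bad)
    out[gm] = labels
    if dg_mask is not None and dg_label in atlas.label_names:
        out[dg_mask] = atlas.label_names[dg_label]
    return replace(lm, data=out, label_scheme=dict(atlas.label_names))


def check_topology(labels: np.ndarray, mesh: SurfaceMesh, atlas: SubfieldAtlas) -> TopologyReport:
    """Connected components and adjacency ordering of a vertex parcellation.

    Each label should form a single connected component on the mesh graph,
    span the full AP extent, and only touch its canonical PD neighbours
    (e.g. CA1 next to Sub and CA2, never CA3).
    """
    report = TopologyReport()
    e = mesh.edges()
    n = mesh.n_vertices
    order = {name: i for i, name in enumerate(CANONICAL_ORDER)}
    present = np.unique(labels)
    for val in present:
        sel = labels == val
        sub_idx = np.where(sel)[0]
        remap = -np.ones(n, np.int64)
        remap[sub_idx] = np.arange(len(sub_idx))
        ee = e[sel[e[:, 0]] & sel[e[:, 1]]]
        g = sparse.csr_matrix(
            (np.ones(len(ee)), (remap[ee[:, 0]], remap[ee[:, 1]])),
            shape=(len(sub_idx), len(sub_idx)),
        )
        ncomp, _ = connected_components(g, directed=False)
        name = atlas.name_of(int(val))
        report.components_per_label[name] = int(ncomp)
        if mesh.uv is not None:
            ap = mesh.uv[sel, 0]
            report.full_ap_extent[name] = bool(ap.min() < 0.01 and ap.max() > 0.99)
    cross = labels[e]
    diff = cross[:, 0] != cross[:, 1]
    pairs = {
        tuple(sorted((atlas.name_of(int(a)), atlas.name_of(int(b)))))
        for a, b in cross[diff]
    }
    for a, b in sorted(pairs):
        if a in order and b in order and abs(order[a] - order[b]) > 1:
            report.adjacency_violations.append((a, b))
    return report


def read_atlas(path: str | Path) -> SubfieldAtlas:
    """Read an unfolded atlas: 2D NIfTI plus a JSON label table alongside.

    For ``atlas.nii[.gz]`` the label table is ``atlas.json`` (mapping
    name -> integer).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise ValueError("atlas volume must reduce to a 2D (AP,PD) image")
    jpath = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    jpath = jpath.with_suffix(".json")
    names = {k: int(v) for k, v in json.loads(jpath.read_text()).items()}
    return SubfieldAtlas(data.astype(np.int32), names, provenance=str(path))


def write_atlas(atlas: SubfieldAtlas, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.Nifti1Image(atlas.label_image[..., np.newaxis].astype(np.int16), np.eye(4)).to_filename(str(path))
    jpath = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    jpath.with_suffix(".json").write_text(json.dumps(atlas.label_names, indent=1))
    return path
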