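"""GIfTI writers for surfaces, per-vertex metrics and vertex labels.

File naming follows BIDS-derivatives style:
``sub-<id>_hemi-<L|R>_space-<native|unfolded>_den-<density>_<suffix>``.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
from nibabel import gifti

from .morphometry import MetricMap
from .surfaces import SurfaceMesh

__all__ = ["write_surface", "read_surface", "write_metric", "write_labels", "bids_name"]


def bids_name(sub: str, hemi: str, space: str, density: str, suffix: str) -> str:
    return f"sub-{sub}_hemi-{hemi}_space-{space}_den-{density}_{suffix}"


def write_surface(mesh: SurfaceMesh, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pts = gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    tri = gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    img = gifti.GiftiImage(darrays=[pts, tri])
    md = {"space": mesh.space, "density": mesh.density,
          "structure": mesh.structure, "layer": mesh.layer}
    img.meta = gifti.GiftiMetaData(**md)
    nib.save(img, str(path))
    return path


def read_surface(path: str | Path) -> SurfaceMesh:
    img = nib.load(str(path))
    pts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tri = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    meta = dict(img.meta) if img.meta else {}
    return SurfaceMesh(
        np.asarray(pts, float), np.asarray(tri, np.int64),
        meta.get("space", "native"), meta.get("density", "unfoldiso"),
        meta.get("structure", "hipp"), meta.get("layer", "midthickness"),
    )


def write_metric(metric: MetricMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    da = gifti.GiftiDataArray(
        metric.values.astype(np.float32), intent="NIFTI_INTENT_SHAPE"
    )
    img = gifti.GiftiImage(darrays=[da])
    img.meta = gifti.GiftiMetaData(name=metric.metric_name, units=metric.units)
    nib.save(img, str(path))
    return path


def write_labels(labels: np.ndarray, label_names: dict[str, int], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    da = gifti.GiftiDataArray(
        np.asarray(labels, np.int32), intent="NIFTI_INTENT_LABEL"
    )
    table = gifti.GiftiLabelTable()
    rng = np.random.default_rng(0)  # stable pseudo-colors per label index
    for name, val in sorted(label_names.items(), key=lambda kv: kv[1]):
        r, g, b = rng.uniform(0.2, 1.0, 3)
        lab = gifti.GiftiLabel(key=int(val), red=float(r), green=float(g),
                               blue=float(b), alpha=1.0)
        lab.label = name
        table.labels.append(lab)
    img = gifti.GiftiImage(darrays=[da], labeltable=table)
    nib.save(img, str(path))
    return path
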