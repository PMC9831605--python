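"""Vertex-wise surface morphometry: thickness, curvature, area, gyrification.

Thickness is the Euclidean distance between corresponding inner and outer
vertices (the layers share a triangulation by construction).  Curvature is
the discrete mean curvature from the cotangent Laplacian, computed on a
midthickness surface smoothed by neighbourhood averaging (strength 0.6,
100 iterations).  Gyrification is the per-vertex ratio of native to
unfolded surface area, each vertex's area being the average of its incident
triangle areas.  Quantitative volumes can be sampled onto native surfaces
by trilinear interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, sparse

from .surfaces import SurfaceMesh

log = logging.getLogger(__name__)

__all__ = [
    "MetricMap",
    "thickness",
    "smooth_mesh",
    "mean_curvature",
    "vertex_area",
    "gyrification",
    "sample_to_surface",
]


@dataclass
class MetricMap:
    """Per-vertex scalar measure on a reference mesh."""

    values: np.ndarray
    metric_name: str
    units: str
    mesh_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)


def _ref(mesh: SurfaceMesh) -> str:
    return f"{mesh.structure}/{mesh.density}/{mesh.layer}"


def thickness(inner: SurfaceMesh, outer: SurfaceMesh) -> MetricMap:
    """Distance (mm) between corresponding inner and outer vertices.

    Not defined for dentate-gyrus surfaces, whose laminar axis wraps around
    the CA4 terminus rather than spanning a depth.
    """
    if inner.structure == "dg" or outer.structure == "dg":
        raise ValueError("thickness is not measured across DG surfaces")
    if inner.n_vertices != outer.n_vertices:
        raise ValueError("inner/outer vertex counts differ")
    d = np.linalg.norm(outer.vertices - inner.vertices, axis=1)
    return MetricMap(d, "thickness", "mm", _ref(inner))


def _adjacency(mesh: SurfaceMesh) -> sparse.csr_matrix:
    e = mesh.edges()
    n = mesh.n_vertices
    data = np.ones(2 * len(e))
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def smooth_mesh(mesh: SurfaceMesh, strength: float = 0.6, iterations: int = 100) -> SurfaceMesh:
    """Neighbourhood-averaging smoothing: v <- (1-s) v + s mean(neighbours).

    The triangulation is unchanged.  Defaults (strength 0.6, 100 iterations)
    are those used before curvature estimation.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0,1]")
    if strength == 0.0 or iterations == 0:
        return mesh
    A = _adjacency(mesh)
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = (1.0 - strength) * v + strength * (A @ v) / deg[:, None]
    return replace(mesh, vertices=v)


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    t = mesh.triangles
    v = mesh.vertices
    fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    vn = np.zeros_like(v)
    for c in range(3):
        np.add.at(vn, t[:, c], fn)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return vn / norm


def mean_curvature(mesh: SurfaceMesh, presmooth: bool = True) -> MetricMap:
    """Discrete mean curvature H (1/mm) via the cotangent Laplacian.

    The mean-curvature normal is K(v) = (1 / 2A_v) * sum_j (cot a_ij +
    cot b_ij)(v - v_j) with A_v the barycentric vertex area; H = |K| / 2,
    signed positive when the surface bends toward the outward normal.
    Boundary vertices of the open sheet are reported as NaN (the one-ring
    there is incomplete).  By default the mesh is first smoothed with the
    standard neighbourhood averaging.
    """
    from .surfaces import boundary_vertices

    if presmooth:
        mesh = smooth_mesh(mesh)
    v = mesh.vertices
    t = mesh.triangles
    n = mesh.n_vertices

    lap = np.zeros((n, 3))
    wsum = np.zeros(n)
    area = np.zeros(n)
    skipped = 0
    for c in range(3):
        i = t[:, c]
        j = t[:, (c + 1) % 3]
        k = t[:, (c + 2) % 3]
        # angle at k, opposite edge (i,j)
        e1 = v[i] - v[k]
        e2 = v[j] - v[k]
        cross = np.cross(e1, e2)
        cn = np.linalg.norm(cross, axis=1)
        degenerate = cn < 1e-12
        skipped += int(degenerate.sum())
        cn[degenerate] = 1.0
        cot = np.einsum("ij,ij->i", e1, e2) / cn
        cot[degenerate] = 0.0
        w = 0.5 * cot
        diff = v[i] - v[j]
        np.add.at(lap, i, w[:, None] * diff)
        np.add.at(lap, j, -w[:, None] * diff)
        np.add.at(wsum, i, w)
        np.add.at(wsum, j, w)
        np.add.at(area, i, (0.5 * cn) / 3.0)
    if skipped:
        warnings.warn(f"skipped {skipped} degenerate triangle corner(s) in curvature",
                      stacklevel=2)
    area[area == 0] = np.inf
    # each edge accumulated (cot a + cot b)/2, so lap/(2A) is H*n directly
    K = lap / (2.0 * area[:, None])
    H = np.linalg.norm(K, axis=1)
    normals = _vertex_normals(mesh)
    sign = -np.sign(np.einsum("ij,ij->i", K, normals))
    sign[sign == 0] = 1.0
    H = H * sign
    H[boundary_vertices(mesh)] = np.nan
    return MetricMap(H, "curvature", "mm^-1", _ref(mesh))


def vertex_area(mesh: SurfaceMesh) -> MetricMap:
    """Per-vertex surface area: the average of incident triangle areas (mm^2).

    Isolated vertices (no incident triangle) get area 0 with a warning.
    """
    v = mesh.vertices
    t = mesh.triangles
    fa = 0.5 * np.linalg.norm(
        np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
    )
    tot = np.zeros(mesh.n_vertices)
    cnt = np.zeros(mesh.n_vertices)
    for c in range(3):
        np.add.at(tot, t[:, c], fa)
        np.add.at(cnt, t[:, c], 1.0)
    if np.any(cnt == 0):
        warnings.warn(f"{int((cnt == 0).sum())} isolated vertex(es) with zero area",
                      stacklevel=2)
    out = np.divide(tot, cnt, out=np.zeros_like(tot), where=cnt > 0)
    return MetricMap(out, "area", "mm^2", _ref(mesh))


def gyrification(native_mid: SurfaceMesh, unfolded_mid: SurfaceMesh) -> MetricMap:
    """Ratio of native to unfolded vertex area (dimensionless, > 1 on folds)."""
    if native_mid.n_vertices != unfolded_mid.n_vertices:
        raise ValueError("meshes must share vertices")
    a_nat = vertex_area(native_mid).values
    a_unf = vertex_area(unfolded_mid).values
    if np.all(a_unf <= 0):
        raise ValueError("unfolded vertex area must be positive")
    bad = a_unf <= 0
    if bad.any():
        # decimated meshes can hold unfolded-degenerate triangles
        warnings.warn(f"{int(bad.sum())} vertex(es) with zero unfolded area -> NaN",
                      stacklevel=2)
    out = np.divide(a_nat, a_unf, out=np.full_like(a_nat, np.nan), where=~bad)
    return MetricMap(out, "gyrification", "ratio", _ref(native_mid))


def sample_to_surface(
    data: np.ndarray, affine: np.ndarray, mesh: SurfaceMesh, metric_name: str = "custom"
) -> MetricMap:
    """Trilinear sampling of a volume at native vertex positions.

    Vertices falling outside the volume get NaN (count logged).
    """
    inv = np.linalg.inv(np.asarray(affine, float))
    ijk = mesh.vertices @ inv[:3, :3].T + inv[:3, 3]
    vals = ndimage.map_coordinates(
        np.asarray(data, float), ijk.T, order=1, mode="constant", cval=np.nan
    )
    shape = np.array(data.shape)
    outside = np.any((ijk < -0.5) | (ijk > shape - 0.5), axis=1)
    vals[outside] = np.nan
    n_out = int(np.isnan(vals).sum())
    if n_out:
        log.info("sample_to_surface: %d vertex(es) outside the volume", n_out)
    return MetricMap(vals, metric_name, "input units", _ref(mesh))
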