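"""Unfolded-space tessellations and folded (native) layer surfaces.

Standardized meshes are built on the unfolded rectangle and carried to each
subject's folded configuration through the unfolded-to-native warp, so that
vertex indices correspond positionally across layers (inner / midthickness /
outer), across densities of the same preset, and across subjects.

Density presets follow average native vertex spacing (0.5, 1, 2 mm) obtained
by greedy edge-collapse decimation of a uniform 512x256 base grid, plus the
legacy ``unfoldiso`` grid (254x126 hippocampus = 32,004 vertices; 254x30
dentate gyrus = 7,620 vertices) which is uniform in unfolded space and is
never decimated.
"""

from __future__ import annotations

import heapq
import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import UnfoldedSpaceSpec
from .warps import WarpField, apply_warp_to_points, scale_to_unfolded

log = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "DENSITY_SPACING_MM",
    "make_grid_mesh",
    "decimate_to_spacing",
    "build_layer_surfaces",
    "make_dg_surfaces",
    "edge_lengths",
    "boundary_vertices",
]

#: target average native vertex spacing per density preset (mm)
DENSITY_SPACING_MM = {"0p5mm": 0.5, "1mm": 1.0, "2mm": 2.0}

#: rows x cols of the uniform base grid decimation starts from
BASE_GRID = {"hipp": (512, 256), "dg": (512, 64)}

#: rows x cols of the legacy uniform unfolded-space tessellation
UNFOLDISO_GRID = {"hipp": (254, 126), "dg": (254, 30)}


@dataclass
class SurfaceMesh:
    """Triangulated open sheet.

    ``vertices`` are mm positions in ``space`` ("unfolded" or "native");
    ``uv`` keeps each vertex's normalized (AP, PD) unfolded coordinates so
    meshes remain addressable in the unfolded plane after warping.
    """

    vertices: np.ndarray  # (N,3) mm
    triangles: np.ndarray  # (M,3) int
    space: str = "unfolded"
    density: str = "unfoldiso"
    structure: str = "hipp"
    layer: str = "midthickness"
    uv: np.ndarray | None = None  # (N,2) in [0,1]^2

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        self.triangles = np.asarray(self.triangles, np.int64)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges (E,2), sorted rows."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def vertex_adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b in self.edges():
            adj[a].add(int(b))
            adj[b].add(int(a))
        return adj


def edge_lengths(mesh: SurfaceMesh) -> np.ndarray:
    e = mesh.edges()
    return np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)


def boundary_vertices(mesh: SurfaceMesh) -> np.ndarray:
    """Vertices on the open boundary (incident to an edge of only 1 triangle)."""
    t = mesh.triangles
    e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    e.sort(axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def make_grid_mesh(
    rows: int,
    cols: int,
    spec: UnfoldedSpaceSpec | None = None,
    structure: str = "hipp",
    io_level: float = 0.5,
    density: str = "unfoldiso",
) -> SurfaceMesh:
    """Uniform grid tessellation of the unfolded AP x PD rectangle.

    rows*cols vertices; 2*(rows-1)*(cols-1) triangles; every quad is split
    along its (+AP,+PD) diagonal, a fixed deterministic orientation.
    """
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must be >= 2")
    spec = spec or UnfoldedSpaceSpec()
    u = np.linspace(0.0, 1.0, rows)
    v = np.linspace(0.0, 1.0, cols)
    UU, VV = np.meshgrid(u, v, indexing="ij")
    uv = np.column_stack([UU.ravel(), VV.ravel()])
    coords = np.column_stack([uv, np.full(len(uv), io_level)])
    verts = scale_to_unfolded(coords, spec, structure)
    r = np.arange(rows - 1)[:, None]
    c = np.arange(cols - 1)[None, :]
    v00 = (r * cols + c).ravel()
    v10 = v00 + cols
    v01 = v00 + 1
    v11 = v10 + 1
    tris = np.vstack(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    # interleave so triangle order walks the grid quad by quad
    tris = tris.reshape(2, -1, 3).transpose(1, 0, 2).reshape(-1, 3)
    return SurfaceMesh(verts, tris, "unfolded", density, structure, "midthickness", uv)


def decimate_to_spacing(
    mesh: SurfaceMesh,
    native_positions: np.ndarray,
    target_spacing: float,
) -> SurfaceMesh:
    """Greedy edge-collapse decimation toward a native vertex spacing.

    The globally shortest edge -- measured on ``native_positions`` -- is
    collapsed (its vertex with the smallest incident edge is removed, the
    surviving endpoint re-triangulating the hole) until the median native
    edge length reaches ``target_spacing`` or no edge shorter than the
    target remains.  Boundary vertices are preserved preferentially: an
    interior endpoint is always the one removed, boundary vertices only
    collapse along boundary edges, and the four rectangle corners are
    pinned.  Collapses that would pinch the sheet (link-condition
    violations) are skipped.  Deterministic given its input.
    """
    native_positions = np.asarray(native_positions, float)
    if len(native_positions) != mesh.n_vertices:
        raise ValueError("native_positions length must match vertex count")
    e0 = mesh.edges()
    lens0 = np.linalg.norm(native_positions[e0[:, 0]] - native_positions[e0[:, 1]], axis=1)
    med0 = float(np.median(lens0))
    if target_spacing <= med0:
        warnings.warn(
            f"target spacing {target_spacing} mm <= current median {med0:.3g} mm; "
            "returning mesh unchanged", stacklevel=2)
        return mesh

    pos = [tuple(p) for p in native_positions]
    adj = mesh.vertex_adjacency()
    tris: dict[int, tuple[int, int, int]] = {i: tuple(t) for i, t in enumerate(mesh.triangles)}
    v2t: list[set[int]] = [set() for _ in range(mesh.n_vertices)]
    edge_tris: dict[tuple[int, int], set[int]] = {}
    # incremental median bookkeeping: the median is >= target exactly when
    # at most half of the current edges are shorter than the target
    n_edges = 0
    n_below = 0

    def add_edge(e, tid):
        nonlocal n_edges, n_below
        s = edge_tris.get(e)
        if s is None:
            edge_tris[e] = {tid}
            n_edges += 1
            if math.dist(pos[e[0]], pos[e[1]]) < target_spacing:
                n_below += 1
        else:
            s.add(tid)

    def del_edge(e, tid):
        nonlocal n_edges, n_below
        s = edge_tris[e]
        s.discard(tid)
        if not s:
            del edge_tris[e]
            n_edges -= 1
            if math.dist(pos[e[0]], pos[e[1]]) < target_spacing:
                n_below -= 1

    for tid, t in tris.items():
        for v in t:
            v2t[v].add(tid)
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            add_edge((min(a, b), max(a, b)), tid)

    def is_boundary(v: int) -> bool:
        return any(len(edge_tris.get((min(v, w), max(v, w)), ())) < 2 for w in adj[v])

    corners = set()
    if mesh.uv is not None:
        for cu in (0.0, 1.0):
            for cv in (0.0, 1.0):
                corners.add(int(np.argmin(np.abs(mesh.uv[:, 0] - cu) + np.abs(mesh.uv[:, 1] - cv))))

    alive = [True] * mesh.n_vertices
    heap = [(float(l), int(a), int(b)) for (a, b), l in zip(e0, lens0)]
    heapq.heapify(heap)

    def collapse(dead: int, surv: int) -> None:
        for tid in list(v2t[dead]):
            t = tris[tid]
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                del_edge((min(a, b), max(a, b)), tid)
            for x in t:
                v2t[x].discard(tid)
            if surv in t:
                del tris[tid]
                continue
            nt = tuple(surv if x == dead else x for x in t)
            tris[tid] = nt
            for x in nt:
                v2t[x].add(tid)
            for a, b in ((nt[0], nt[1]), (nt[1], nt[2]), (nt[2], nt[0])):
                add_edge((min(a, b), max(a, b)), tid)
        for w in adj[dead]:
            adj[w].discard(dead)
            if w != surv:
                adj[w].add(surv)
                adj[surv].add(w)
        adj[dead] = set()
        alive[dead] = False
        for w in adj[surv]:
            heapq.heappush(heap, (math.dist(pos[surv], pos[w]), min(surv, w), max(surv, w)))

    while heap and n_below * 2 > n_edges:
        l, a, b = heapq.heappop(heap)
        if not alive[a] or not alive[b] or b not in adj[a]:
            continue
        cur = math.dist(pos[a], pos[b])
        if cur > l + 1e-12:
            heapq.heappush(heap, (cur, a, b))
            continue
        if cur >= target_spacing:
            break
        a_c, b_c = a in corners, b in corners
        if a_c and b_c:
            continue
        a_b, b_b = is_boundary(a), is_boundary(b)
        shared = edge_tris.get((min(a, b), max(a, b)), set())
        if a_b and b_b and len(shared) >= 2:
            continue  # chord between two boundary vertices: collapsing pinches
        # survivor: corner > boundary > lower index (deterministic)
        if a_c or (a_b and not b_b):
            surv, dead = a, b
        elif b_c or (b_b and not a_b):
            surv, dead = b, a
        else:
            surv, dead = (a, b) if a < b else (b, a)
        opposite = {x for tid in shared for x in tris[tid] if x not in (dead, surv)}
        if (adj[dead] & adj[surv]) != opposite:
            continue  # link condition: collapse would pinch the sheet
        collapse(dead, surv)

    referenced = set()
    for t in tris.values():
        referenced.update(t)
    keep = np.array(sorted(referenced), np.int64)
    remap = -np.ones(mesh.n_vertices, np.int64)
    remap[keep] = np.arange(len(keep))
    new_tris = np.array([[remap[x] for x in t] for _, t in sorted(tris.items())], np.int64)
    out = replace(
        mesh,
        vertices=mesh.vertices[keep],
        triangles=new_tris,
        uv=None if mesh.uv is None else mesh.uv[keep],
    )
    log.info("decimated %d -> %d vertices (target %.3g mm)", mesh.n_vertices, len(keep), target_spacing)
    return out


def _unfolded_mesh_for_density(
    density: str,
    structure: str,
    spec: UnfoldedSpaceSpec,
    warp_u2n: WarpField | None,
    io_level: float = 0.5,
) -> SurfaceMesh:
    if density == "unfoldiso":
        rows, cols = UNFOLDISO_GRID[structure]
        return make_grid_mesh(rows, cols, spec, structure, io_level, density)
    if density not in DENSITY_SPACING_MM:
        raise ValueError(f"unknown density {density!r}")
    if warp_u2n is None:
        raise ValueError("spacing-based densities require the unfolded-to-native warp")
    rows, cols = BASE_GRID[structure]
    base = make_grid_mesh(rows, cols, spec, structure, io_level, density)
    native = apply_warp_to_points(base.vertices, warp_u2n)
    return decimate_to_spacing(base, native, DENSITY_SPACING_MM[density])


def build_layer_surfaces(
    warp_u2n: WarpField,
    density: str = "unfoldiso",
    spec: UnfoldedSpaceSpec | None = None,
    structure: str = "hipp",
) -> dict[str, SurfaceMesh]:
    """Native inner / midthickness / outer surfaces for one density.

    The density's unfolded tessellation is instantiated at IO = 0, 0.5 and 1
    and each copy is carried through the unfolded-to-native warp; the three
    layers share the triangle array and vertex ordering exactly.
    """
    spec = spec or UnfoldedSpaceSpec()
    unfolded = _unfolded_mesh_for_density(density, structure, spec, warp_u2n)
    out: dict[str, SurfaceMesh] = {}
    for layer, io in (("inner", 0.0), ("midthickness", 0.5), ("outer", 1.0)):
        coords = np.column_stack([unfolded.uv, np.full(unfolded.n_vertices, io)])
        unf_pts = scale_to_unfolded(coords, spec, structure)
        nat = apply_warp_to_points(unf_pts, warp_u2n)
        out[layer] = SurfaceMesh(
            nat, unfolded.triangles.copy(), "native", density, structure, layer,
            uv=unfolded.uv.copy(),
        )
    out["unfolded_midthickness"] = unfolded
    return out


def make_dg_surfaces(
    warp_u2n_dg: WarpField,
    density: str = "unfoldiso",
    spec: UnfoldedSpaceSpec | None = None,
) -> dict[str, SurfaceMesh]:
    """Dentate-gyrus surfaces over the narrow 256x32-aspect unfolded domain.

    Same construction as the hippocampal layers; thickness is never measured
    on DG surfaces (its laminar axis is topologically a wrap, not a depth).
    """
    return build_layer_surfaces(warp_u2n_dg, density, spec, structure="dg")
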