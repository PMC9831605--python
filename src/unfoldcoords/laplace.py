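"""Laplace-equation coordinate fields over the hippocampal grey-matter domain.

Three harmonic scalar fields are solved over GM voxels, one per intrinsic
axis: anterior-posterior (AP, 0 at the HATA boundary, 1 at the indusium
griseum), proximal-distal (PD, MTLc to DG granule layer), and inner-outer
(IO, SRLM/cyst to the outer boundary).  Each field satisfies the discrete
Laplace equation with Dirichlet values on the named boundary labels and
no-flux conditions elsewhere.  The IO Laplace field is by default replaced
by an equivolumetric depth, which preserves laminar volume fractions between
the curved inner and outer surfaces instead of equal spacing.

Discretization: Dirichlet values live on the boundary *label* voxels, which
share a face with domain voxels; their contribution to a domain voxel's
neighbour average is weighted 2 (the boundary value is attributed to the
shared face, half a voxel away), a finite-volume convention under which a
slab's solution is exactly the linear profile (i + 0.5)/n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage, sparse

from .core import TissueLabelmap

log = logging.getLogger(__name__)

__all__ = [
    "BoundaryConditions",
    "CoordFields",
    "init_field_geodesic",
    "solve_laplace",
    "equivolume_transform",
    "equivolume_inverse",
    "compute_coord_fields",
]

_OFFSETS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet endpoints of one coordinate axis.

    ``source_labels`` voxels carry value 0, ``sink_labels`` value 1.
    """

    source_labels: frozenset[str]
    sink_labels: frozenset[str]
    axis: str  # "AP" | "PD" | "IO"

    def __post_init__(self) -> None:
        if not self.source_labels or not self.sink_labels:
            raise ValueError("source and sink label sets must be non-empty")
        if self.source_labels & self.sink_labels:
            raise ValueError("source and sink label sets must be disjoint")


@dataclass
class CoordFields:
    """AP/PD/IO coordinate fields in [0,1], NaN outside ``domain_mask``."""

    ap: np.ndarray
    pd: np.ndarray
    io: np.ndarray
    domain_mask: np.ndarray
    io_mode: str = "equivolume"  # "laplace" | "equivolume"
    meta: dict = dfield(default_factory=dict)

    def stacked(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(N,3) array of (ap,pd,io) at masked voxels (default: the domain)."""
        m = self.domain_mask if mask is None else mask
        return np.column_stack([self.ap[m], self.pd[m], self.io[m]])


def _offsets(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return _OFFSETS6
    offs = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    if connectivity == 18:
        offs = [o for o in offs if sum(abs(x) for x in o) <= 2]
    elif connectivity != 26:
        raise ValueError("connectivity must be 6, 18, or 26")
    return np.array(offs)


def _geodesic_distance(domain: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Chamfer (iterated BFS) geodesic distance inside ``domain`` from seeds.

    Distances are in voxel steps (face connectivity); unreachable voxels are
    +inf.  Seeds are boundary voxels outside the domain; distance is counted
    from the first in-domain voxel (value 1 at a voxel face-adjacent to a
    seed).
    """
    dist = np.full(domain.shape, np.inf)
    frontier = seeds.copy()
    d = 0
    visited = np.zeros(domain.shape, bool)
    struct = ndimage.generate_binary_structure(3, 1)
    while frontier.any():
        grown = ndimage.binary_dilation(frontier, structure=struct)
        new = grown & domain & ~visited & ~frontier
        d += 1
        dist[new] = d
        visited |= new
        frontier = new
        if d > sum(domain.shape):  # pragma: no cover - safety bound
            break
    return dist


def init_field_geodesic(domain: np.ndarray, src_mask: np.ndarray, snk_mask: np.ndarray) -> np.ndarray:
    """Geodesic-distance initialization d_src / (d_src + d_snk) on the domain.

    Voxels unreachable from both boundaries get 0.5 with a warning.  Returns
    a full-grid array, NaN outside the domain.
    """
    d_src = _geodesic_distance(domain, src_mask)
    d_snk = _geodesic_distance(domain, snk_mask)
    out = np.full(domain.shape, np.nan)
    with np.errstate(invalid="ignore"):
        frac = d_src / (d_src + d_snk)
    # one-sided reachability: clamp to the reachable endpoint
    frac[np.isinf(d_src) & np.isfinite(d_snk)] = 1.0
    frac[np.isfinite(d_src) & np.isinf(d_snk)] = 0.0
    isolated = domain & np.isinf(d_src) & np.isinf(d_snk)
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} domain voxel(s) unreachable from both "
            "boundaries; initialized to 0.5",
            stacklevel=2,
        )
        frac[isolated] = 0.5
    out[domain] = frac[domain]
    return out


def solve_laplace(
    domain: np.ndarray,
    src_mask: np.ndarray,
    snk_mask: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 10_000,
    connectivity: int = 6,
    omega: float = 1.8,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Solve the discrete Laplace equation on a voxel domain.

    Red-black successive over-relaxation: each domain voxel converges to the
    weighted mean of its neighbours, where in-domain neighbours have weight 1
    and Dirichlet (source=0 / sink=1) neighbours weight 2; neighbours outside
    domain+boundary are omitted (no-flux).  Iteration stops when the maximum
    absolute update falls below ``tol``.

    Returns a full-grid float array, NaN outside the domain.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    domain = np.asarray(domain, bool)
    offs = _offsets(connectivity)
    idx = np.argwhere(domain)
    n = len(idx)
    if n == 0:
        raise ValueError("empty domain")
    lin = np.full(domain.shape, -1, np.int64)
    lin[domain] = np.arange(n)

    shape = np.array(domain.shape)
    rows, cols, fixed_sum, deg = [], [], np.zeros(n), np.zeros(n)
    for off in offs:
        nb = idx + off
        inside = np.all((nb >= 0) & (nb < shape), axis=1)
        nb_t = tuple(nb[inside].T)
        who = np.where(inside)[0]
        nb_lin = lin[nb_t]
        in_dom = nb_lin >= 0
        rows.append(who[in_dom])
        cols.append(nb_lin[in_dom])
        # Dirichlet neighbours: value on the shared face, half spacing -> weight 2
        is_src = src_mask[nb_t] & ~in_dom
        is_snk = snk_mask[nb_t] & ~in_dom
        np.add.at(deg, who[in_dom], 1.0)
        np.add.at(deg, who[is_src], 2.0)
        np.add.at(deg, who[is_snk], 2.0)
        np.add.at(fixed_sum, who[is_snk], 2.0)  # sink value 1
    A = sparse.csr_matrix(
        (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    indeg = np.asarray(A.sum(axis=1)).ravel()
    # deg = indeg + 2*(#src neighbours) + 2*(#snk neighbours); fixed_sum = 2*(#snk)
    has_snk = fixed_sum.sum() > 0
    has_src = np.sum(deg - indeg - fixed_sum) > 0
    if not has_src or not has_snk:
        raise ValueError("axis endpoints not connected to domain")

    if init is None:
        u = np.full(n, 0.5)
    else:
        u = np.asarray(init[domain], float).copy()
        u[~np.isfinite(u)] = 0.5

    # isolated voxels (no neighbours at all): keep init value
    deg_safe = np.where(deg > 0, deg, 1.0)

    parity = idx.sum(axis=1) % 2 == 0
    groups = (np.where(parity)[0], np.where(~parity)[0])
    A_half = [A[g] for g in groups]
    fs_half = [fixed_sum[g] for g in groups]
    deg_half = [deg_safe[g] for g in groups]

    it = 0
    for it in range(1, max_iter + 1):
        max_upd = 0.0
        for g, Ah, fsh, dh in zip(groups, A_half, fs_half, deg_half):
            new = (Ah @ u + fsh) / dh
            delta = omega * (new - u[g])
            u[g] += delta
            if len(delta):
                max_upd = max(max_upd, float(np.max(np.abs(delta))))
        if max_upd < tol:
            break
    else:  # pragma: no cover - logged fallback
        log.warning("Laplace solver hit max_iter=%d (last update %.2e)", max_iter, max_upd)
    log.debug("Laplace solve: %d voxels, %d iterations", n, it)

    np.clip(u, 0.0, 1.0, out=u)
    out = np.full(domain.shape, np.nan)
    out[domain] = u
    return out


def equivolume_transform(
    io_laplace: np.ndarray,
    inner_area: np.ndarray | float,
    outer_area: np.ndarray | float,
) -> np.ndarray:
    """Remap a laminar fraction to equivolumetric depth.

    With local inner/outer surface areas ``A_in``/``A_out`` and the laminar
    cross-section interpolating linearly between them, the depth at which the
    cumulative volume fraction equals ``alpha`` is

        rho = (-A_in + sqrt(alpha*A_out**2 + (1-alpha)*A_in**2)) / (A_out - A_in)

    reducing to ``rho = alpha`` when the areas are equal (flat-sheet limit).
    """
    a = np.asarray(io_laplace, float)
    A_in = np.broadcast_to(np.asarray(inner_area, float), a.shape)
    A_out = np.broadcast_to(np.asarray(outer_area, float), a.shape)
    if np.any(A_in <= 0) or np.any(A_out <= 0):
        raise ValueError("inner/outer areas must be positive")
    diff = A_out - A_in
    degen = np.abs(diff) < 1e-9 * A_in
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (-A_in + np.sqrt(a * A_out**2 + (1.0 - a) * A_in**2)) / diff
    rho = np.where(degen, a, rho)
    nanmask = ~np.isfinite(a)
    rho = np.clip(rho, 0.0, 1.0)
    rho[nanmask] = np.nan
    return rho


def equivolume_inverse(
    rho: np.ndarray, inner_area: np.ndarray | float, outer_area: np.ndarray | float
) -> np.ndarray:
    """Inverse of :func:`equivolume_transform`: volume fraction at depth rho."""
    r = np.asarray(rho, float)
    A_in = np.broadcast_to(np.asarray(inner_area, float), r.shape)
    A_out = np.broadcast_to(np.asarray(outer_area, float), r.shape)
    degen = np.abs(A_out - A_in) < 1e-9 * A_in
    alpha = (2.0 * A_in * r + (A_out - A_in) * r**2) / (A_in + A_out)
    return np.where(degen, r, alpha)


def _bc_masks(lm: TissueLabelmap, bc: BoundaryConditions, domain: np.ndarray):
    def mk(names: frozenset[str]) -> np.ndarray:
        m = np.zeros(lm.data.shape, bool)
        for name in names:
            if name == "outside":
                m |= lm.data == lm.label_scheme["background"]
            else:
                m |= lm.data == lm.label_scheme[name]
        return m & ~domain

    return mk(bc.source_labels), mk(bc.sink_labels)


def default_boundary_conditions(io_outer: str = "union") -> dict[str, BoundaryConditions]:
    """Anatomical Dirichlet endpoints for the three hippocampal axes.

    ``io_outer`` selects the IO sink: ``"pial"`` for the pial label only, or
    ``"union"`` (default) for pial plus any background touching GM.
    """
    io_sink = {"pial"} if io_outer == "pial" else {"pial", "outside"}
    return {
        "AP": BoundaryConditions(frozenset({"HATA"}), frozenset({"IndGris"}), "AP"),
        "PD": BoundaryConditions(frozenset({"MTLc"}), frozenset({"DGgranule"}), "PD"),
        "IO": BoundaryConditions(frozenset({"SRLM", "cyst"}), frozenset(io_sink), "IO"),
    }


def _column_areas(
    ap: np.ndarray,
    pd: np.ndarray,
    io_lap: np.ndarray,
    lm: TissueLabelmap,
    domain: np.ndarray,
    grid_shape: tuple[int, int] = (64, 32),
):
    """Estimate per-(AP,PD)-column inner and outer surface areas.

    A coarse unfolded grid is mapped to native space at IO=0 and IO=1 via the
    same scattered interpolant used for warps; local area elements come from
    the cross product of the mapped grid tangents.  Returns bilinear
    interpolators evaluated per domain voxel: (A_in, A_out) arrays aligned
    with ``domain`` voxels.
    """
    from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator, RegularGridInterpolator

    pts = np.column_stack([ap[domain], pd[domain], io_lap[domain]])
    xyz = lm.world_coords(domain)
    nr, nc = grid_shape
    ga = np.linspace(0.02, 0.98, nr)
    gp = np.linspace(0.02, 0.98, nc)

    def surf(io_val: float) -> np.ndarray:
        AA, PP = np.meshgrid(ga, gp, indexing="ij")
        q = np.column_stack([AA.ravel(), PP.ravel(), np.full(AA.size, io_val)])
        li = LinearNDInterpolator(pts, xyz)
        vals = li(q)
        bad = ~np.isfinite(vals[:, 0])
        if bad.any():
            ni = NearestNDInterpolator(pts, xyz)
            vals[bad] = ni(q[bad])
        return vals.reshape(nr, nc, 3)

    def areas(surface: np.ndarray) -> np.ndarray:
        du = np.gradient(surface, ga, axis=0)
        dv = np.gradient(surface, gp, axis=1)
        return np.linalg.norm(np.cross(du, dv), axis=2)

    a_in = areas(surf(0.05))
    a_out = areas(surf(0.95))
    a_in = np.maximum(a_in, 1e-9)
    a_out = np.maximum(a_out, 1e-9)
    fi = RegularGridInterpolator((ga, gp), a_in, bounds_error=False, fill_value=None)
    fo = RegularGridInterpolator((ga, gp), a_out, bounds_error=False, fill_value=None)
    q = np.column_stack([
        np.clip(ap[domain], ga[0], ga[-1]), np.clip(pd[domain], gp[0], gp[-1])
    ])
    floor = 1e-3 * float(np.median(a_in))
    return np.maximum(fi(q), floor), np.maximum(fo(q), floor)


def compute_coord_fields(
    lm: TissueLabelmap,
    io_mode: str = "equivolume",
    io_outer: str = "union",
    include_cysts_in_gm: bool = True,
    tol: float = 1e-5,
    max_iter: int = 10_000,
    connectivity: int = 6,
) -> CoordFields:
    """Solve AP, PD and IO Laplace fields over GM and apply the equivolume
    replacement of IO unless ``io_mode="laplace"``.

    Cyst voxels interrupt GM internally; they stay out of the solution domain
    and act as part of the IO inner boundary together with the SRLM (set
    ``include_cysts_in_gm=False`` to exclude them from the IO source set too).
    """
    domain = lm.mask("GM")
    if not domain.any():
        raise ValueError("labelmap contains no GM voxels")
    bcs = default_boundary_conditions(io_outer)
    if not include_cysts_in_gm:
        bcs["IO"] = BoundaryConditions(frozenset({"SRLM"}), bcs["IO"].sink_labels, "IO")
    fields = {}
    for axis in ("AP", "PD", "IO"):
        src, snk = _bc_masks(lm, bcs[axis], domain)
        init = init_field_geodesic(domain, src, snk)
        fields[axis] = solve_laplace(
            domain, src, snk, tol=tol, max_iter=max_iter,
            connectivity=connectivity, init=init,
        )
    io = fields["IO"]
    meta = {"io_outer": io_outer}
    if io_mode == "equivolume":
        a_in, a_out = _column_areas(fields["AP"], fields["PD"], io, lm, domain)
        io = io.copy()
        io[domain] = equivolume_transform(io[domain], a_in, a_out)
    elif io_mode != "laplace":
        raise ValueError("io_mode must be 'laplace' or 'equivolume'")
    return CoordFields(
        ap=fields["AP"], pd=fields["PD"], io=io,
        domain_mask=domain, io_mode=io_mode, meta=meta,
    )
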