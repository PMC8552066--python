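"""Synthetic atrial surface: two fused ellipsoidal chambers with vein stubs.

The surface is star-shaped around the origin, built from a Fibonacci point
set on the unit sphere, radially displaced by the support function of two
overlapping spheres (the "chambers") plus Gaussian bumps for the pulmonary
vein ostia and the appendage.  Triangulation comes from the convex hull of
the unit directions, which is a valid spherical triangulation and therefore
a valid (closed, orientable) triangulation of any star-shaped displacement.

Seven anatomical regions are laid out as spherical Voronoi sectors around
fixed seed directions: PLAW, LIPV, LSPV, RIPV, RSPV, RAA, RAFW.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp
from scipy.spatial import ConvexHull

REGION_NAMES: Dict[int, str] = {
    1: "PLAW",
    2: "LIPV",
    3: "LSPV",
    4: "RIPV",
    5: "RSPV",
    6: "RAA",
    7: "RAFW",
}

# Unit-ish seed directions for the 7 angular sectors.  The left chamber sits
# toward -x, the right chamber toward +x; veins cluster on the posterior
# (-y) aspect of the left chamber.
_REGION_SEEDS = {
    1: (-0.55, -0.80, 0.00),   # posterior left atrial wall
    2: (-0.85, -0.30, -0.60),  # left inferior PV
    3: (-0.85, -0.30, 0.60),   # left superior PV
    4: (-0.15, -0.55, -0.75),  # right inferior PV
    5: (-0.15, -0.55, 0.75),   # right superior PV
    6: (0.85, 0.45, 0.35),     # right atrial appendage
    7: (0.90, -0.05, -0.45),   # right atrial free wall
}

# Radial bump directions (vein stubs / appendage), amplitudes relative to
# the local radius, and angular widths in radians.
_BUMPS = [
    ((-0.85, -0.30, -0.60), 0.18, 0.28),
    ((-0.85, -0.30, 0.60), 0.18, 0.28),
    ((-0.15, -0.55, -0.75), 0.16, 0.26),
    ((-0.15, -0.55, 0.75), 0.16, 0.26),
    ((0.85, 0.45, 0.35), 0.20, 0.33),
]

_DEFAULT_GEOMETRY = {
    "left_center": (-12.0, 0.0, 0.0),
    "left_radius": 30.0,
    "right_center": (14.0, 0.0, 0.0),
    "right_radius": 26.0,
    "jitter": 0.04,  # fraction of mean angular spacing (kept small: short edges shrink the stable dt)
    # mm^2/ms; tuned on the default 2,048-node mesh.  Lower values block
    # propagation on this coarse graph, so the planar conduction velocity
    # comes out near 0.9 mm/ms longitudinal rather than the 0.6 target.
    "d_long": 1.2,
    "d_trans": 0.3,
}


def diffusion_coefficient(d_long, d_trans, alpha):
    """Anisotropic edge diffusion: ``d_long*cos^2(alpha) + d_trans*sin^2(alpha)``.

    ``alpha`` is the angle between the fiber direction and the internode
    vector.  Accepts scalars or arrays (broadcast).
    """
    d_long = np.asarray(d_long, dtype=float)
    d_trans = np.asarray(d_trans, dtype=float)
    if np.any(d_long < 0) or np.any(d_trans < 0):
        raise ValueError("diffusion coefficients must be non-negative")
    if np.any(d_trans > d_long):
        raise ValueError("d_long must be >= d_trans")
    c = np.cos(alpha)
    s = np.sin(alpha)
    return d_long * c * c + d_trans * s * s


@dataclasses.dataclass
class AtrialMesh:
    """Closed triangulated atrial surface with fibers, regions and diffusion.

    Distances are in mm, diffusion coefficients in mm^2/ms.  ``fibrotic``
    marks nodes whose incident diffusion is forced to zero.
    """

    node_coords: np.ndarray          # (N, 3)
    triangles: np.ndarray            # (T, 3) int
    fiber_dir: np.ndarray            # (N, 3) unit
    region_id: np.ndarray            # (N,) int in 1..7
    d_long: float
    d_trans: float
    fibrotic: np.ndarray = None      # (N,) bool
    seed: Optional[int] = None

    # derived connectivity (filled lazily)
    _edges: np.ndarray = dataclasses.field(default=None, repr=False)
    _edge_dist: np.ndarray = dataclasses.field(default=None, repr=False)
    _neighbors: List[np.ndarray] = dataclasses.field(default=None, repr=False)

    def __post_init__(self):
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.fibrotic is None:
            self.fibrotic = np.zeros(self.n_nodes, dtype=bool)
        self.fibrotic = np.asarray(self.fibrotic, dtype=bool)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    @property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (P, 2), i < j."""
        if self._edges is None:
            t = self.triangles
            e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
            e.sort(axis=1)
            self._edges = np.unique(e, axis=0)
        return self._edges

    @property
    def internode_dist(self) -> np.ndarray:
        """Edge lengths d_{k,i} in mm, aligned with :attr:`edges`."""
        if self._edge_dist is None:
            e = self.edges
            d = self.node_coords[e[:, 0]] - self.node_coords[e[:, 1]]
            self._edge_dist = np.linalg.norm(d, axis=1)
        return self._edge_dist

    @property
    def neighbors(self) -> List[np.ndarray]:
        """Adjacency list (sorted neighbor indices per node)."""
        if self._neighbors is None:
            adj = [[] for _ in range(self.n_nodes)]
            for a, b in self.edges:
                adj[a].append(b)
                adj[b].append(a)
            self._neighbors = [np.array(sorted(v), dtype=np.int64) for v in adj]
        return self._neighbors

    # -- physics -----------------------------------------------------------
    def edge_diffusion(self) -> np.ndarray:
        """Per-edge diffusion D_{k,i}, symmetrized over both endpoint fibers.

        Edges touching a fibrotic node carry zero diffusion.
        """
        e = self.edges
        vec = self.node_coords[e[:, 1]] - self.node_coords[e[:, 0]]
        vec = vec / np.linalg.norm(vec, axis=1, keepdims=True)
        d_vals = np.empty(len(e))
        for side in (0, 1):
            f = self.fiber_dir[e[:, side]]
            cos_a = np.clip(np.abs(np.sum(f * vec, axis=1)), 0.0, 1.0)
            alpha = np.arccos(cos_a)
            d_side = diffusion_coefficient(self.d_long, self.d_trans, alpha)
            d_vals = d_side if side == 0 else 0.5 * (d_vals + d_side)
        dead = self.fibrotic[e[:, 0]] | self.fibrotic[e[:, 1]]
        d_vals[dead] = 0.0
        return d_vals

    def coupling_matrix(self) -> sp.csr_matrix:
        """Symmetric W with w_{k,i} = D_{k,i} / d_{k,i}^2 on edges (1/ms)."""
        e = self.edges
        w = self.edge_diffusion() / self.internode_dist**2
        n = self.n_nodes
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        vals = np.concatenate([w, w])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def laplacian(self) -> sp.csr_matrix:
        """Graph Laplacian L such that (L v)_k = sum_i w_{k,i} (v_k - v_i)."""
        w = self.coupling_matrix()
        deg = np.asarray(w.sum(axis=1)).ravel()
        return (sp.diags(deg) - w).tocsr()

    def area_weights(self) -> np.ndarray:
        """Per-node surface weight: a third of each incident triangle's area."""
        tri = self.triangles
        p = self.node_coords
        cross = np.cross(p[tri[:, 1]] - p[tri[:, 0]], p[tri[:, 2]] - p[tri[:, 0]])
        area = 0.5 * np.linalg.norm(cross, axis=1)
        w = np.zeros(self.n_nodes)
        for c in range(3):
            np.add.at(w, tri[:, c], area / 3.0)
        return w

    def ordered_one_ring(self, node: int) -> Optional[np.ndarray]:
        """Neighbors of ``node`` ordered as a closed fan, or None if open."""
        tris = self.triangles[np.any(self.triangles == node, axis=1)]
        succ = {}
        for t in tris:
            k = np.where(t == node)[0][0]
            a, b = t[(k + 1) % 3], t[(k + 2) % 3]
            succ[int(a)] = int(b)
        if not succ:
            return None
        start = next(iter(succ))
        ring = [start]
        while True:
            nxt = succ.get(ring[-1])
            if nxt is None:
                return None
            if nxt == start:
                break
            if nxt in ring:  # defensive: malformed fan
                return None
            ring.append(nxt)
        return np.array(ring, dtype=np.int64)

    def region_center(self, region: int) -> np.ndarray:
        """Centroid node coordinate of a region (on-surface representative)."""
        mask = self.region_id == region
        if not mask.any():
            raise ValueError(f"region {region} is empty")
        c = self.node_coords[mask].mean(axis=0)
        idx = np.argmin(np.linalg.norm(self.node_coords[mask] - c, axis=1))
        return self.node_coords[mask][idx]

    def copy(self) -> "AtrialMesh":
        m = AtrialMesh(
            node_coords=self.node_coords.copy(),
            triangles=self.triangles.copy(),
            fiber_dir=self.fiber_dir.copy(),
            region_id=self.region_id.copy(),
            d_long=self.d_long,
            d_trans=self.d_trans,
            fibrotic=self.fibrotic.copy(),
            seed=self.seed,
        )
        return m


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _support_radius(dirs: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Distance from the origin to a sphere's surface along each direction."""
    cd = dirs @ center
    disc = radius**2 - (center @ center - cd**2)
    out = np.full(len(dirs), -np.inf)
    ok = disc > 0
    out[ok] = cd[ok] + np.sqrt(disc[ok])
    return out


def build_synthetic_atria(
    n_nodes: int = 2048,
    geometry_params: Optional[dict] = None,
    rng_seed: int = 0,
) -> AtrialMesh:
    """Build the default two-chamber synthetic atrial surface.

    Raises ``ValueError`` when ``n_nodes`` is too small to host seven
    non-trivial regions (fewer than 128 nodes).
    """
    if n_nodes < 128:
        raise ValueError(
            f"n_nodes={n_nodes} is too small to partition into 7 regions "
            "with at least 2 nodes each; use n_nodes >= 128"
        )
    params = dict(_DEFAULT_GEOMETRY)
    if geometry_params:
        params.update(geometry_params)
    rng = np.random.default_rng(rng_seed)

    dirs = _fibonacci_directions(n_nodes)
    # small tangential jitter so different seeds give different meshes
    spacing = np.sqrt(4.0 * np.pi / n_nodes)
    jitter = params["jitter"] * spacing * rng.standard_normal((n_nodes, 3))
    dirs = dirs + jitter - dirs * np.sum(jitter * dirs, axis=1, keepdims=True)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    r_left = _support_radius(dirs, np.asarray(params["left_center"]), params["left_radius"])
    r_right = _support_radius(dirs, np.asarray(params["right_center"]), params["right_radius"])
    radius = np.maximum(r_left, r_right)
    if not np.all(np.isfinite(radius)) or np.any(radius <= 0):
        raise ValueError("chamber spheres must overlap the origin (star-shaped body)")

    for bdir, amp, width in _BUMPS:
        b = np.asarray(bdir, dtype=float)
        b /= np.linalg.norm(b)
        ang = np.arccos(np.clip(dirs @ b, -1.0, 1.0))
        radius *= 1.0 + amp * np.exp(-0.5 * (ang / width) ** 2)

    coords = dirs * radius[:, None]

    hull = ConvexHull(dirs)
    tri = hull.simplices.copy()
    # orient all faces outward (hull does not guarantee winding)
    p = dirs
    nrm = np.cross(p[tri[:, 1]] - p[tri[:, 0]], p[tri[:, 2]] - p[tri[:, 0]])
    centers = (p[tri[:, 0]] + p[tri[:, 1]] + p[tri[:, 2]]) / 3.0
    flip = np.sum(nrm * centers, axis=1) < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]

    seeds = np.array([_REGION_SEEDS[k] for k in range(1, 8)])
    seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
    region_id = 1 + np.argmax(dirs @ seeds.T, axis=1)
    counts = np.bincount(region_id, minlength=8)[1:]
    if np.any(counts < 2):
        missing = [REGION_NAMES[i + 1] for i in range(7) if counts[i] < 2]
        raise ValueError(f"regions too small at n_nodes={n_nodes}: {missing}")

    # roughly circumferential fibers (tangent to the surface around z)
    z_axis = np.array([0.0, 0.0, 1.0])
    fiber = np.cross(np.broadcast_to(z_axis, dirs.shape), dirs)
    norms = np.linalg.norm(fiber, axis=1)
    polar = norms < 1e-8
    if polar.any():
        alt = np.cross(np.broadcast_to([0.0, 1.0, 0.0], dirs.shape), dirs)
        fiber[polar] = alt[polar]
        norms = np.linalg.norm(fiber, axis=1)
    fiber /= norms[:, None]

    return AtrialMesh(
        node_coords=coords,
        triangles=tri,
        fiber_dir=fiber,
        region_id=region_id.astype(np.int64),
        d_long=float(params["d_long"]),
        d_trans=float(params["d_trans"]),
        seed=rng_seed,
    )


def apply_fibrosis(mesh: AtrialMesh, fraction: float, rng_seed: int = 0) -> AtrialMesh:
    """Disconnect ``round(fraction * N)`` randomly selected nodes.

    Returns a copy; selection is reproducible from ``rng_seed``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fibrosis fraction must be in [0, 1), got {fraction}")
    out = mesh.copy()
    n_pick = int(round(fraction * mesh.n_nodes))
    if n_pick:
        rng = np.random.default_rng(rng_seed)
        picked = rng.choice(mesh.n_nodes, size=n_pick, replace=False)
        out.fibrotic[picked] = True
    return out


def disconnect_nodes(mesh: AtrialMesh, nodes: np.ndarray) -> AtrialMesh:
    """Return a copy with the given nodes marked fibrotic (zero diffusion)."""
    out = mesh.copy()
    nodes = np.asarray(nodes, dtype=np.int64)
    if nodes.size and (nodes.min() < 0 or nodes.max() >= mesh.n_nodes):
        raise ValueError("node indices out of range")
    out.fibrotic[nodes] = True
    return out


def validate_mesh(mesh: AtrialMesh, tol: float = 1e-9) -> None:
    """Assert structural invariants; raises AssertionError on violation."""
    tri = mesh.triangles
    n, t = mesh.n_nodes, mesh.n_triangles
    # every directed edge must occur exactly once (closed orientable surface)
    directed = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    key = directed[:, 0] * n + directed[:, 1]
    assert len(np.unique(key)) == len(key), "surface is not consistently oriented"
    p = len(mesh.edges)
    assert n - p + t == 2, f"Euler characteristic {n - p + t} != 2 (not a closed sphere)"
    assert min(len(v) for v in mesh.neighbors) >= 3, "node with fewer than 3 neighbors"
    assert np.bincount(mesh.region_id, minlength=8)[1:].min() > 0, "empty region"
    norms = np.linalg.norm(mesh.fiber_dir, axis=1)
    assert np.all(np.abs(norms - 1.0) < tol), "fiber directions not unit-norm"
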