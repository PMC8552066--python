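"""Forward problem: node potentials -> electrode potentials.

The transfer matrix composes a per-node surface gradient operator
(quadratic least-squares fit on >= 9 stencil neighbors) with an
infinite-homogeneous-medium dipole kernel evaluated at the electrode
positions, then applies Wilson-Central-Terminal referencing:

    y_ref = (A - 1/N_WCT * M_WCT) x = A_WCT x

where M_WCT replicates the summed WCT rows of A into every row, so the
mean of the referenced output over the WCT leads is identically zero.
A boundary-element backend would slot in by replacing ``build_transfer_matrix``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import List, Optional, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay

from .atrial_sim.geometry import AtrialMesh

GUARD_FRACTION = 0.01  # of torso radius

#: vest grid extents
N_ROWS = 6
N_FRONT_COLS = 4
N_BACK_COLS = 4
N_SIDE_COLS = 4      # two per side
SIDE_ROWS = (2, 3, 4, 5)  # side electrodes occupy the last 4 rows


@dataclasses.dataclass
class TorsoGeometry:
    """Electrode cloud enclosing the atrial mesh (positions in mm)."""

    electrode_coords: np.ndarray          # (M, 3)
    electrode_names: List[str]
    wct_indices: np.ndarray               # indices of the WCT leads

    def __post_init__(self):
        self.electrode_coords = np.asarray(self.electrode_coords, dtype=float)
        self.wct_indices = np.asarray(self.wct_indices, dtype=np.int64)
        if self.electrode_coords.shape[0] < 64:
            raise ValueError("torso must carry at least 64 electrodes")
        if self.wct_indices.size < 3:
            raise ValueError("WCT needs at least 3 leads")

    @property
    def n_electrodes(self) -> int:
        return self.electrode_coords.shape[0]

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.electrode_coords, axis=1).max())


def default_vest(
    radius_mm: float = 120.0,
    z_min: float = -65.0,
    z_max: float = 65.0,
) -> Tuple[TorsoGeometry, pd.DataFrame]:
    """Cylindrical 64-electrode vest: 12 columns x 6 rows, sides half-filled.

    Columns 0-3 front, 4-5 left side, 6-9 back, 10-11 right side; side
    columns carry electrodes only on the last 4 rows.  Channel order is
    canonical: front (row-major), back (row-major), then side columns
    (left pair then right pair, top to bottom).  The WCT leads approximate
    the two shoulders and the lower-left torso.
    """
    angles = {}
    panels = {}
    for c in range(12):
        angles[c] = 2.0 * np.pi * c / 12.0
        panels[c] = "front" if c < 4 else ("side" if c in (4, 5, 10, 11) else "back")
    rows_z = np.linspace(z_max, z_min, N_ROWS)

    records = []

    def add(panel, row, col, cyl_col):
        a = angles[cyl_col]
        records.append(
            dict(
                name=f"{panel[0].upper()}{row}{col}",
                x=radius_mm * np.cos(a),
                y=radius_mm * np.sin(a),
                z=rows_z[row],
                vest_row=row,
                vest_col=col,
                panel=panel,
                cylinder_col=cyl_col,
            )
        )

    for row in range(N_ROWS):
        for col in range(N_FRONT_COLS):
            add("front", row, col, col)
    for row in range(N_ROWS):
        for col in range(N_BACK_COLS):
            add("back", row, col, 6 + col)
    for side_col, cyl_col in enumerate((4, 5, 10, 11)):
        for row in SIDE_ROWS:
            add("side", row, side_col, cyl_col)

    table = pd.DataFrame.from_records(records)
    table["channel"] = np.arange(len(table))
    coords = table[["x", "y", "z"]].to_numpy()
    # WCT: right shoulder (front row 0, col 0), left shoulder (front row 0,
    # col 3), lower-left torso (left-side column, bottom row)
    wct = [0, 3, int(table.index[(table.panel == "side") & (table.vest_row == 5)][0])]
    torso = TorsoGeometry(coords, list(table.name), np.array(wct))
    return torso, table


def save_electrode_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def load_electrode_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# surface gradients
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GradientDiagnostics:
    n_stencil: int
    rank: int
    residual: float
    fallback_linear: bool


def _stencil(mesh: AtrialMesh, node: int, min_size: int = 9) -> np.ndarray:
    """1-ring stencil, expanded ring by ring until >= min_size neighbors."""
    seen = {node}
    frontier = {node}
    stencil: List[int] = []
    while len(stencil) < min_size:
        nxt = set()
        for f in frontier:
            for nb in mesh.neighbors[f]:
                nb = int(nb)
                if nb not in seen:
                    seen.add(nb)
                    nxt.add(nb)
                    stencil.append(nb)
        if not nxt:
            break
        frontier = nxt
    return np.array(sorted(stencil), dtype=np.int64)


_QUAD_RANK_TOL = 1e-8


def _fit_matrix(dx: np.ndarray) -> Tuple[np.ndarray, int, bool]:
    """Pseudo-inverse of the quadratic design matrix on offsets ``dx``.

    Returns (pinv, rank, fallback_linear); falls back to a linear fit when
    the quadratic system is rank-deficient (e.g. a coplanar stencil).
    """
    x, y, z = dx[:, 0], dx[:, 1], dx[:, 2]
    design = np.column_stack(
        [x, y, z, x * x, y * y, z * z, x * y, y * z, x * z]
    )
    s = np.linalg.svd(design, compute_uv=False)
    rank = int(np.sum(s > s[0] * _QUAD_RANK_TOL)) if s.size else 0
    if rank < 9:
        lin = dx
        return np.linalg.pinv(lin), rank, True
    return np.linalg.pinv(design), rank, False


def fit_quadratic_gradient(
    mesh: AtrialMesh, vm_frame: np.ndarray, node: int
) -> Tuple[np.ndarray, GradientDiagnostics]:
    """Gradient of vm at ``node`` from the 9-coefficient quadratic fit.

    The first three least-squares coefficients of the expansion of
    ``vm_i - vm_node`` in the offsets are the gradient components.
    """
    st = _stencil(mesh, node)
    if len(st) < 3:
        raise ValueError(f"node {node} has a degenerate stencil ({len(st)} neighbors)")
    dx = mesh.node_coords[st] - mesh.node_coords[node]
    b = np.asarray(vm_frame, dtype=float)[st] - float(vm_frame[node])
    pinv, rank, fallback = _fit_matrix(dx)
    coef = pinv @ b
    grad = coef[:3]
    resid = float(np.linalg.norm(b - (dx @ coef[:3] if fallback else _design(dx) @ coef)))
    return grad, GradientDiagnostics(len(st), rank, resid, fallback)


def _design(dx: np.ndarray) -> np.ndarray:
    x, y, z = dx[:, 0], dx[:, 1], dx[:, 2]
    return np.column_stack([x, y, z, x * x, y * y, z * z, x * y, y * z, x * z])


def build_gradient_operator(
    mesh: AtrialMesh,
) -> Tuple[sp.csr_matrix, List[GradientDiagnostics]]:
    """Sparse (3N x N) operator G with (G v)[3k:3k+3] = grad v at node k."""
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    diags = []
    for k in range(n):
        st = _stencil(mesh, k)
        dx = mesh.node_coords[st] - mesh.node_coords[k]
        pinv, rank, fallback = _fit_matrix(dx)
        g_rows = pinv[:3]  # (3, n_st): gradient = g_rows @ (v[st] - v[k])
        for c in range(3):
            rows.extend([3 * k + c] * (len(st) + 1))
            cols.extend(list(st) + [k])
            vals.extend(list(g_rows[c]) + [-float(g_rows[c].sum())])
        diags.append(GradientDiagnostics(len(st), rank, 0.0, fallback))
    g = sp.csr_matrix((vals, (rows, cols)), shape=(3 * n, n))
    return g, diags


# ---------------------------------------------------------------------------
# dipole summation and transfer matrix
# ---------------------------------------------------------------------------

def dipole_potential(
    mesh: AtrialMesh,
    gradient_field: np.ndarray,
    obs_point: np.ndarray,
    weights: Optional[np.ndarray] = None,
    guard_radius: float = 0.0,
) -> float:
    """Potential at ``obs_point``: sum_k w_k (r_k / r_k^3) . grad_k.

    ``r_k`` points from source node k to the observer.  Arbitrary units
    (no medium constants); raises when the observer violates the guard
    radius around any source node.
    """
    obs = np.asarray(obs_point, dtype=float)
    r = obs[None, :] - mesh.node_coords
    dist = np.linalg.norm(r, axis=1)
    if guard_radius > 0 and dist.min() <= guard_radius:
        raise ValueError(
            f"observation point within guard radius ({dist.min():.3g} <= {guard_radius:.3g})"
        )
    if dist.min() == 0:
        raise ValueError("observation point coincides with a source node")
    w = mesh.area_weights() if weights is None else np.asarray(weights, dtype=float)
    kernel = r / dist[:, None] ** 3
    return float(np.sum(w[:, None] * kernel * np.asarray(gradient_field, dtype=float)))


@dataclasses.dataclass
class TransferMatrix:
    a: np.ndarray          # (M, N) unreferenced
    a_wct: np.ndarray      # (M, N) WCT-referenced
    wct_indices: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.a.shape


def wct_correct(a: np.ndarray, wct_indices: Sequence[int]) -> np.ndarray:
    """A_WCT = A - (1/N_WCT) * M_WCT, M_WCT = summed WCT rows in every row."""
    wct = np.asarray(wct_indices, dtype=np.int64)
    if wct.size == 0:
        raise ValueError("wct_indices must be non-empty")
    if wct.min() < 0 or wct.max() >= a.shape[0]:
        raise ValueError("wct_indices outside matrix rows")
    m_wct = np.broadcast_to(a[wct].sum(axis=0), a.shape)
    return a - m_wct / wct.size


def _mesh_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def build_transfer_matrix(
    mesh: AtrialMesh,
    torso: TorsoGeometry,
    weighted: bool = True,
) -> TransferMatrix:
    """Assemble A (and A_WCT) so that A @ vm equals per-frame dipole summation."""
    coords = torso.electrode_coords
    guard = GUARD_FRACTION * torso.radius
    # enclosure check: every atrial node inside the electrode convex hull
    hull = Delaunay(coords)
    if np.any(hull.find_simplex(mesh.node_coords) < 0):
        raise ValueError("torso does not enclose the atrial mesh")
    d_all = np.linalg.norm(
        coords[:, None, :] - mesh.node_coords[None, :, :], axis=2
    )
    too_close = np.where(d_all.min(axis=1) <= guard)[0]
    if too_close.size:
        name = torso.electrode_names[too_close[0]]
        raise ValueError(f"electrode '{name}' is within the guard radius of the atria")

    w = mesh.area_weights() if weighted else np.ones(mesh.n_nodes)
    n = mesh.n_nodes
    g, _ = build_gradient_operator(mesh)
    # kernel K: (M, 3N) with K[m, 3k:3k+3] = w_k * r / |r|^3
    r = coords[:, None, :] - mesh.node_coords[None, :, :]   # (M, N, 3)
    kern = w[None, :, None] * r / d_all[:, :, None] ** 3
    k_mat = kern.reshape(coords.shape[0], 3 * n)
    a = np.asarray(k_mat @ g)
    a_wct = wct_correct(a, torso.wct_indices)
    prov = {
        "mesh_hash": _mesh_hash(mesh.node_coords),
        "torso_hash": _mesh_hash(coords),
        "weighted": weighted,
    }
    return TransferMatrix(a=a, a_wct=a_wct, wct_indices=torso.wct_indices.copy(), provenance=prov)


def forward_bsp(tm: TransferMatrix, x_series: np.ndarray, referenced: bool = True) -> np.ndarray:
    """Apply the transfer matrix to a (N,) frame or (N, S) series."""
    mat = tm.a_wct if referenced else tm.a
    return mat @ np.asarray(x_series, dtype=float)


def wct_reference(tm: TransferMatrix, x_series: np.ndarray) -> np.ndarray:
    """WCT-referenced BSP: A_WCT @ x."""
    if tm.wct_indices.size == 0:
        raise ValueError("transfer matrix has no WCT leads")
    return tm.a_wct @ np.asarray(x_series, dtype=float)


def save_transfer_matrix(tm: TransferMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("a", data=tm.a)
        f.create_dataset("a_wct", data=tm.a_wct)
        f.create_dataset("wct_indices", data=tm.wct_indices)
        for k, v in tm.provenance.items():
            f.attrs[k] = v


def load_transfer_matrix(path) -> TransferMatrix:
    with h5py.File(path, "r") as f:
        return TransferMatrix(
            a=f["a"][()],
            a_wct=f["a_wct"][()],
            wct_indices=f["wct_indices"][()],
            provenance=dict(f.attrs),
        )
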