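"""Monodomain propagation on the atrial surface graph.

dV_k/dt = reaction(V_k, gates_k) - sum_i D_{k,i} (V_k - V_i) / d_{k,i}^2 + I_stim

integrated with explicit fixed-step RK4 and downsampled to the output
sampling rate.  Driver episodes are induced with a cross-field S1–S2
protocol: a planar S1 wave followed by a disc-shaped S2 delivered into the
repolarization tail at the target region, which breaks the wave into a
counter-rotating spiral pair whose cores sit inside the target region.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

from .geometry import AtrialMesh, apply_fibrosis, disconnect_nodes
from .ionic import IonicModel

STABILITY_FACTOR = 0.25

_KINDS = ("planar_wave", "cross_field_rotor", "focal", "none")


@dataclasses.dataclass
class StimulusProtocol:
    """Stimulation recipe for one episode."""

    kind: str = "none"
    target_region: Optional[int] = None
    fibrosis_fraction: float = 0.0
    rng_seed: int = 0
    amplitude: float = 0.8          # stimulus current, 1/ms in u units
    s1_times_ms: tuple = (5.0,)
    s1_width_mm: float = 8.0
    s1_duration_ms: float = 2.0
    s2_radius_mm: float = 22.0
    s2_trigger_u: float = 0.4       # fire S2 when the target center repolarizes past this
    s2_delay_ms: float = 0.0
    anchor_radius_mm: float = 10.0  # fibrotic pinning patch at the target center
    s2_duration_ms: float = 3.0
    focal_period_ms: float = 180.0
    label_margin_ms: float = 60.0   # rotor considered established this long after S2
    stim_nodes: Optional[np.ndarray] = None  # explicit override for focal/planar sites

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown protocol kind '{self.kind}'; one of {_KINDS}")
        if not 0.0 <= self.fibrosis_fraction < 1.0:
            raise ValueError("fibrosis_fraction must be in [0, 1)")
        if self.kind in ("cross_field_rotor", "focal") and self.target_region is None:
            raise ValueError(f"kind '{self.kind}' requires target_region")
        if self.stim_nodes is not None:
            self.stim_nodes = np.asarray(self.stim_nodes, dtype=np.int64)

    def validate_nodes(self, n_nodes: int) -> None:
        if self.stim_nodes is not None and self.stim_nodes.size:
            if self.stim_nodes.min() < 0 or self.stim_nodes.max() >= n_nodes:
                raise ValueError("stim_nodes contains invalid node indices")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        if d["stim_nodes"] is not None:
            d["stim_nodes"] = [int(i) for i in np.ravel(d["stim_nodes"])]
        return json.dumps(d)


@dataclasses.dataclass
class VmSeries:
    """Per-node transmembrane series plus per-frame ground-truth labels."""

    vm: np.ndarray            # (N, S) float32, normalized units
    fs: float                 # Hz
    duration_s: float
    ground_truth_driver: np.ndarray  # (S,) int, 0 or region id
    protocol: Optional[StimulusProtocol] = None
    meta: dict = dataclasses.field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.vm.shape[1]


def stability_dt(mesh: AtrialMesh) -> float:
    """Conservative explicit-step bound: c * min(d^2) / max(D)."""
    d_edge = mesh.edge_diffusion()
    d_max = d_edge.max() if d_edge.size else 0.0
    if d_max <= 0:
        return np.inf
    return STABILITY_FACTOR * float(mesh.internode_dist.min() ** 2) / float(d_max)


def integrate_network(
    laplacian: sp.spmatrix,
    model: IonicModel,
    duration_ms: float,
    dt_ms: float,
    record_every: int = 1,
    stim_fn: Optional[Callable[[float, np.ndarray], np.ndarray]] = None,
    u0: Optional[np.ndarray] = None,
    gates0: Optional[np.ndarray] = None,
):
    """RK4-integrate the coupled system, recording every ``record_every`` steps.

    ``stim_fn(t_ms, u)`` is evaluated once per step (stimulus held constant
    within the step) and may observe the state, which lets protocols
    self-time their S2.  Returns (times_ms, vm[N, frames], (u, gates)).
    """
    lap = sp.csr_matrix(laplacian)
    n = lap.shape[0]
    u_rest, g_rest = model.resting_state()
    u = np.full(n, u_rest, dtype=float) if u0 is None else np.asarray(u0, dtype=float).copy()
    gates = (
        np.tile(np.asarray(g_rest, dtype=float)[:, None], (1, n))
        if gates0 is None
        else np.asarray(gates0, dtype=float).copy()
    )

    n_steps = int(round(duration_ms / dt_ms))
    n_rec = n_steps // record_every + 1
    vm = np.empty((n, n_rec), dtype=np.float32)
    times = np.empty(n_rec)
    vm[:, 0] = u
    times[0] = 0.0
    rec = 1

    def deriv(uu, gg, stim):
        du_r, dg = model.rhs(uu, gg)
        du = du_r - lap @ uu
        if stim is not None:
            du = du + stim
        return du, dg

    t = 0.0
    for step in range(1, n_steps + 1):
        stim = stim_fn(t, u) if stim_fn is not None else None
        k1u, k1g = deriv(u, gates, stim)
        k2u, k2g = deriv(u + 0.5 * dt_ms * k1u, gates + 0.5 * dt_ms * k1g, stim)
        k3u, k3g = deriv(u + 0.5 * dt_ms * k2u, gates + 0.5 * dt_ms * k2g, stim)
        k4u, k4g = deriv(u + dt_ms * k3u, gates + dt_ms * k3g, stim)
        u = u + (dt_ms / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        gates = gates + (dt_ms / 6.0) * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
        t = step * dt_ms
        if step % record_every == 0:
            if not np.all(np.isfinite(u)):
                raise RuntimeError(f"NaN/Inf in transmembrane potential at frame {rec}")
            vm[:, rec] = u
            times[rec] = t
            rec += 1
    return times[:rec], vm[:, :rec], (u, gates)


def _nearest_node(mesh: AtrialMesh, point: np.ndarray, exclude_fibrotic: bool = True) -> int:
    d = np.linalg.norm(mesh.node_coords - point, axis=1)
    if exclude_fibrotic and (~mesh.fibrotic).any():
        d[mesh.fibrotic] = np.inf
    return int(np.argmin(d))


def simulate_propagation(
    mesh: AtrialMesh,
    ionic_model: IonicModel,
    protocol: StimulusProtocol,
    duration_s: float = 2.0,
    fs: float = 500.0,
    dt_ms: float = 0.05,
) -> VmSeries:
    """Simulate one episode and fill per-frame ground-truth driver labels.

    Labels are the protocol's target region for frames after the S2-induced
    rotor is established (and while fibrillatory activity persists), and 0
    for planar/focal/quiescent frames.
    """
    if duration_s * fs < 2:
        raise ValueError("duration * fs must be at least 2 frames")
    protocol.validate_nodes(mesh.n_nodes)

    work = mesh
    if protocol.fibrosis_fraction > 0:
        work = apply_fibrosis(mesh, protocol.fibrosis_fraction, protocol.rng_seed)
    if protocol.kind == "cross_field_rotor" and protocol.anchor_radius_mm > 0:
        # pinning patch: rotors anchored on a small inexcitable island stay
        # inside their target region instead of meandering across the atria
        c = mesh.region_center(protocol.target_region)
        dc = np.linalg.norm(mesh.node_coords - c, axis=1)
        work = disconnect_nodes(work, np.where(dc < protocol.anchor_radius_mm)[0])

    dt_max = stability_dt(work)
    if dt_ms > dt_max:
        raise ValueError(
            f"dt={dt_ms} ms exceeds the stability bound {dt_max:.4g} ms; "
            f"use dt <= {dt_max:.4g}"
        )

    frame_ms = 1000.0 / fs
    record_every = max(1, int(round(frame_ms / dt_ms)))
    dt = frame_ms / record_every  # snap dt so frames land exactly on steps
    n_frames = int(round(duration_s * fs))
    duration_ms = (n_frames - 1) * frame_ms

    # --- stimulus site geometry ------------------------------------------
    s2_nodes = np.empty(0, dtype=np.int64)
    center_node = None
    if protocol.kind == "cross_field_rotor":
        center = mesh.region_center(protocol.target_region)
        center_node = _nearest_node(work, center)
        d = np.linalg.norm(mesh.node_coords - mesh.node_coords[center_node], axis=1)
        s2_nodes = np.where(d < protocol.s2_radius_mm)[0]
        # launch S1 from the far side of the surface so the planar wave
        # sweeps across the target region with a clean repolarization tail
        away = -mesh.node_coords[center_node]
        away = away / np.linalg.norm(away)
        proj = mesh.node_coords @ away
        s1_nodes = np.where(proj > proj.max() - protocol.s1_width_mm)[0]
    else:
        z = mesh.node_coords[:, 2]
        s1_nodes = np.where(z > z.max() - protocol.s1_width_mm)[0]
        if protocol.kind == "planar_wave" and protocol.stim_nodes is not None:
            s1_nodes = protocol.stim_nodes

    focal_nodes = np.empty(0, dtype=np.int64)
    if protocol.kind == "focal":
        if protocol.stim_nodes is not None:
            focal_nodes = protocol.stim_nodes
        else:
            center = mesh.region_center(protocol.target_region)
            d = np.linalg.norm(mesh.node_coords - center, axis=1)
            focal_nodes = np.where(d < 4.0)[0]

    # --- self-timed stimulus controller ----------------------------------
    state = {"phase": "wait_act", "t_s2": None, "t_act": None}
    amp = protocol.amplitude
    stim_vec = np.zeros(mesh.n_nodes)

    def stim_fn(t, u):
        stim_vec[:] = 0.0
        active = False
        if protocol.kind in ("planar_wave", "cross_field_rotor"):
            for t0 in protocol.s1_times_ms:
                if t0 <= t < t0 + protocol.s1_duration_ms:
                    stim_vec[s1_nodes] = amp
                    active = True
        if protocol.kind == "cross_field_rotor":
            if state["phase"] == "wait_act" and u[center_node] > 0.8:
                state["phase"] = "wait_rec"
                state["t_act"] = t
            elif (
                state["phase"] == "wait_rec"
                and t > state["t_act"] + 15.0
                and u[center_node] < protocol.s2_trigger_u
            ):
                state["phase"] = "fire"
                state["t_s2"] = t + protocol.s2_delay_ms
            if state["phase"] == "fire" and state["t_s2"] is not None:
                if state["t_s2"] <= t < state["t_s2"] + protocol.s2_duration_ms:
                    stim_vec[s2_nodes] = amp
                    active = True
                elif t >= state["t_s2"] + protocol.s2_duration_ms:
                    state["phase"] = "done"
        if protocol.kind == "focal":
            phase = (t - 20.0) % protocol.focal_period_ms
            if t >= 20.0 and phase < protocol.s1_duration_ms:
                stim_vec[focal_nodes] = amp
                active = True
        return stim_vec if active else None

    _, vm, _ = integrate_network(
        work.laplacian(), ionic_model, duration_ms, dt, record_every, stim_fn
    )
    vm = vm[:, :n_frames]

    labels = np.zeros(n_frames, dtype=np.int64)
    t_s2 = state["t_s2"]
    if protocol.kind == "cross_field_rotor" and t_s2 is not None:
        alive = ~work.fibrotic
        spread = vm[alive].max(axis=0) - vm[alive].min(axis=0)
        times_ms = np.arange(n_frames) * frame_ms
        established = times_ms >= t_s2 + protocol.label_margin_ms
        labels[established & (spread > 0.2)] = protocol.target_region
        # once activity dies, keep the tail quiescent even if spread flickers
        dead = np.where(established & (spread <= 0.2))[0]
        if dead.size:
            labels[dead[0]:] = 0

    meta = {
        "t_s2_ms": t_s2,
        "dt_ms": dt,
        "seed": protocol.rng_seed,
        "protocol": protocol.to_json(),
        "ionic_model": ionic_model.name,
    }
    return VmSeries(
        vm=vm.astype(np.float32),
        fs=fs,
        duration_s=duration_s,
        ground_truth_driver=labels,
        protocol=protocol,
        meta=meta,
    )
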