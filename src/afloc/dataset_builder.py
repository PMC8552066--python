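"""Frame labeling, tensor dataset assembly, train/val/test splits, class weights.

Labels 1..7 name the atrial region hosting the driver; 0 means no driver.
The primary label source is the simulation protocol's ground truth; a
phase-singularity detector (analytic-signal phase + ring winding numbers)
is available as an independent verification mode.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np
from scipy.signal import hilbert

from .atrial_sim.geometry import AtrialMesh
from .atrial_sim.propagation import VmSeries
from .tensorizer import (
    VestLayout,
    bilinear_resize,
    default_layout,
    make_1channel,
    make_3channel,
    normalize_tensor,
)

N_CLASSES = 8


# ---------------------------------------------------------------------------
# phase-singularity machinery
# ---------------------------------------------------------------------------

def compute_phase(vm: np.ndarray) -> np.ndarray:
    """Analytic-signal phase of the mean-subtracted series, per node."""
    vm = np.asarray(vm, dtype=float)
    return np.angle(hilbert(vm - vm.mean(axis=1, keepdims=True), axis=1))


class PhaseSingularityDetector:
    """Finds rotor cores from +-2*pi phase windings.

    Two detection paths:

    * functional reentry: nodes whose (fully active) 1-ring phase winds by
      a full turn;
    * reentry around an inexcitable island (e.g. a fibrotic patch): the
      phase winding is evaluated along the angle-ordered cycle of active
      nodes bordering each inactive connected component — the core then
      sits on the island itself, whose own rings carry no usable phase.
    """

    def __init__(self, mesh: AtrialMesh, vm_series: VmSeries, activity_sd: float = 0.05):
        self.mesh = mesh
        self.phase = compute_phase(vm_series.vm)
        active = vm_series.vm.std(axis=1) > activity_sd
        self.rings: List[Optional[np.ndarray]] = []
        ring_nodes, cur, nxt, ptr = [], [], [], [0]
        for k in range(mesh.n_nodes):
            ring = mesh.ordered_one_ring(k)
            if ring is None or not active[k] or not active[ring].all():
                self.rings.append(None)
                continue
            self.rings.append(ring)
            ring_nodes.append(k)
            cur.extend(ring)
            nxt.extend(np.roll(ring, -1))
            ptr.append(len(cur))
        self._ring_nodes = np.array(ring_nodes, dtype=np.int64)
        self._cur = np.array(cur, dtype=np.int64)
        self._nxt = np.array(nxt, dtype=np.int64)
        self._ptr = np.array(ptr[:-1], dtype=np.int64)
        self._island_loops = self._build_island_loops(active)

    def _build_island_loops(self, active: np.ndarray):
        """(island nodes, ordered active boundary cycle) per inactive patch."""
        inactive = np.where(~active)[0]
        loops = []
        seen = set()
        inactive_set = set(int(i) for i in inactive)
        for start in inactive:
            start = int(start)
            if start in seen:
                continue
            comp = {start}
            stack = [start]
            while stack:
                node = stack.pop()
                for nb in self.mesh.neighbors[node]:
                    nb = int(nb)
                    if nb in inactive_set and nb not in comp:
                        comp.add(nb)
                        stack.append(nb)
            seen |= comp
            boundary = sorted(
                {int(nb) for n in comp for nb in self.mesh.neighbors[n] if active[nb]}
            )
            if len(boundary) < 4:
                continue
            coords = self.mesh.node_coords[boundary]
            center = self.mesh.node_coords[list(comp)].mean(axis=0)
            rel = coords - center
            # angle-order in the plane orthogonal to the island's mean normal
            normal = center / (np.linalg.norm(center) + 1e-12)
            e1 = np.cross(normal, [0.0, 0.0, 1.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(normal, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(normal, e1)
            order = np.argsort(np.arctan2(rel @ e2, rel @ e1))
            loops.append(
                (np.array(sorted(comp), dtype=np.int64),
                 np.array(boundary, dtype=np.int64)[order])
            )
        return loops

    def singular_nodes(self, frame: int) -> np.ndarray:
        ph = self.phase[:, frame]
        hits = []
        if self._ring_nodes.size:
            d = ph[self._nxt] - ph[self._cur]
            d = (d + np.pi) % (2.0 * np.pi) - np.pi
            winding = np.add.reduceat(d, self._ptr)
            hits.append(self._ring_nodes[np.abs(winding) > np.pi])
        for island, cycle in self._island_loops:
            d = np.diff(np.r_[ph[cycle], ph[cycle[0]]])
            d = (d + np.pi) % (2.0 * np.pi) - np.pi
            if abs(d.sum()) > np.pi:
                hits.append(island)
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))


def detect_driver_label(
    vm_series: VmSeries,
    mesh: AtrialMesh,
    frame: int,
    mode: str = "protocol",
    detector: Optional[PhaseSingularityDetector] = None,
) -> int:
    """Label one frame: 0 (no driver) or the driver's region id.

    ``mode='protocol'`` returns the simulation ground truth (primary);
    ``mode='phase'`` locates phase singularities and returns the most
    common region among singular nodes, 0 when none are found.
    """
    if mode == "protocol":
        return int(vm_series.ground_truth_driver[frame])
    if mode == "phase":
        if detector is None:
            detector = PhaseSingularityDetector(mesh, vm_series)
        nodes = detector.singular_nodes(frame)
        if nodes.size == 0:
            return 0
        regions = mesh.region_id[nodes]
        counts = np.bincount(regions, minlength=N_CLASSES)
        return int(np.argmax(counts))
    raise ValueError(f"unknown labeling mode '{mode}'")


# ---------------------------------------------------------------------------
# dataset containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TensorSample:
    image: np.ndarray
    label: int
    frame_idx: int
    episode_id: int


@dataclasses.dataclass
class LabeledDataset:
    """Frame tensors with labels, grouped by episode (frame order preserved)."""

    images: np.ndarray        # (n, H, W, C) float32
    labels: np.ndarray        # (n,)
    episode_ids: np.ndarray   # (n,)
    frame_idx: np.ndarray     # (n,)
    manifest: Dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.size and (labels.min() < 0 or labels.max() >= N_CLASSES):
            raise ValueError("labels must be in 0..7")
        for ep in np.unique(self.episode_ids):
            fi = self.frame_idx[self.episode_ids == ep]
            if np.any(np.diff(fi) <= 0):
                raise ValueError(f"episode {ep} frames not strictly increasing")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def label_histogram(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=N_CLASSES)

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        order = idx[np.lexsort((self.frame_idx[idx], self.episode_ids[idx]))]
        return LabeledDataset(
            images=self.images[order],
            labels=self.labels[order],
            episode_ids=self.episode_ids[order],
            frame_idx=self.frame_idx[order],
            manifest=dict(self.manifest),
        )


def build_tensor_dataset(
    frames_by_episode: Sequence[Tuple[int, np.ndarray, np.ndarray]],
    layout: Optional[VestLayout] = None,
    mode: str = "1ch",
    resize_shape: Optional[Tuple[int, int]] = None,
    normalization: str = "zscore",
) -> LabeledDataset:
    """Tensorize (episode_id, bsp[64, S], labels[S]) groups into a dataset.

    ``mode`` selects the 1-channel or 3-channel layout; ``resize_shape``
    defaults to (78, 192) / (150, 152) respectively.
    """
    layout = layout or default_layout()
    if mode not in ("1ch", "3ch"):
        raise ValueError("mode must be '1ch' or '3ch'")
    if resize_shape is None:
        resize_shape = (78, 192) if mode == "1ch" else (150, 152)
    images, labels, eps, fidx = [], [], [], []
    for ep_id, bsp, lab in frames_by_episode:
        bsp = np.asarray(bsp)
        if bsp.shape[0] != 64:
            raise ValueError("expected 64-channel BSP")
        if bsp.shape[1] != len(lab):
            raise ValueError("labels length must match frame count")
        for s in range(bsp.shape[1]):
            tens = make_1channel(bsp[:, s], layout) if mode == "1ch" else make_3channel(bsp[:, s], layout)
            tens = bilinear_resize(tens, *resize_shape)
            if tens.ndim == 2:
                tens = tens[:, :, None]
            tens = normalize_tensor(tens, normalization).image
            images.append(tens.astype(np.float32))
            labels.append(int(lab[s]))
            eps.append(ep_id)
            fidx.append(s)
    manifest = {
        "mode": mode,
        "resize_shape": list(resize_shape),
        "normalization": normalization,
        "episodes": [int(e) for e, _, _ in frames_by_episode],
    }
    return LabeledDataset(
        images=np.stack(images),
        labels=np.asarray(labels, dtype=np.int64),
        episode_ids=np.asarray(eps, dtype=np.int64),
        frame_idx=np.asarray(fidx, dtype=np.int64),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Splits:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    scheme: str
    seed: Optional[int] = None


def split_time_independent(ds: LabeledDataset, seed: int = 0) -> Splits:
    """Frame-level random split: 64% train / 16% val / 20% test."""
    n = len(ds)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(0.2 * n))
    n_trainval = n - n_test
    n_val = int(round(0.2 * n_trainval))
    test = perm[:n_test]
    val = perm[n_test:n_test + n_val]
    train = perm[n_test + n_val:]
    return Splits(np.sort(train), np.sort(val), np.sort(test), "time_independent", seed)


def split_blocks(ds: LabeledDataset) -> Splits:
    """Per-episode consecutive blocks: first 64% / next 16% / last 20%."""
    train, val, test = [], [], []
    for ep in np.unique(ds.episode_ids):
        idx = np.where(ds.episode_ids == ep)[0]
        idx = idx[np.argsort(ds.frame_idx[idx])]
        s = len(idx)
        if s < 5:
            raise ValueError(f"episode {ep} too short to split into blocks ({s} frames)")
        n_train = int(round(0.64 * s))
        n_val = int(round(0.80 * s)) - n_train
        train.append(idx[:n_train])
        val.append(idx[n_train:n_train + n_val])
        test.append(idx[n_train + n_val:])
    return Splits(
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
        "blocks",
    )


def class_weights(labels: Sequence[int], n_classes: int = N_CLASSES) -> np.ndarray:
    """Inverse-frequency weights, mean one over samples; absent classes get 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("need at least one label")
    counts = np.bincount(labels, minlength=n_classes).astype(float)
    present = counts > 0
    w = np.zeros(n_classes)
    w[present] = labels.size / (present.sum() * counts[present])
    return w


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_dataset_h5(ds: LabeledDataset, path) -> None:
    import json

    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=ds.images, compression="gzip", compression_opts=4)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("episode_id", data=ds.episode_ids)
        f.create_dataset("frame_idx", data=ds.frame_idx)
        f.attrs["manifest"] = json.dumps(ds.manifest)


def load_dataset_h5(path) -> LabeledDataset:
    import json

    with h5py.File(path, "r") as f:
        return LabeledDataset(
            images=f["images"][()],
            labels=f["labels"][()],
            episode_ids=f["episode_id"][()],
            frame_idx=f["frame_idx"][()],
            manifest=json.loads(f.attrs.get("manifest", "{}")),
        )
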