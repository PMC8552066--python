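"""End-to-end orchestration shared by the CLI, the tests and the
acceptance script: corpus simulation with a rotor quality gate, forward
projection, conditioning, tensorization, training and evaluation."""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .atrial_sim import (
    AtrialMesh,
    StimulusProtocol,
    VmSeries,
    build_synthetic_atria,
    get_ionic_model,
    simulate_propagation,
)
from .bsp_processing import BSPRecording, add_noise, bandpass_filter, sample_vest
from .dataset_builder import (
    LabeledDataset,
    PhaseSingularityDetector,
    Splits,
    build_tensor_dataset,
    class_weights,
    split_blocks,
    split_time_independent,
)
from .driver_cnn import TrainConfig, build_custom_cnn, predict, train_model
from .evaluation import metrics_report, noise_robustness_sweep
from .forward_ecg import TransferMatrix, build_transfer_matrix, default_vest, wct_reference


@dataclasses.dataclass
class Episode:
    episode_id: int
    vm: VmSeries
    bsp_clean: BSPRecording       # WCT-referenced, unfiltered, 64 channels

    @property
    def labels(self) -> np.ndarray:
        return self.vm.ground_truth_driver


def default_episode_plan(regions: Sequence[int] = range(1, 8), n_driver_free: int = 2) -> List[dict]:
    """One rotor episode per region plus planar-wave driver-free episodes."""
    plan = [{"kind": "cross_field_rotor", "target_region": int(r)} for r in regions]
    for i in range(n_driver_free):
        plan.append({"kind": "planar_wave" if i % 2 == 0 else "focal",
                     "target_region": None if i % 2 == 0 else int(1 + i % 7)})
    return plan


def simulate_episode_with_retries(
    mesh: AtrialMesh,
    plan_entry: dict,
    duration_s: float,
    fs: float,
    dt_ms: float,
    seed: int,
    max_attempts: int = 6,
    min_driver_fraction: float = 0.5,
    ps_check: bool = False,
    min_ps_agreement: float = 0.8,
) -> VmSeries:
    """Simulate one episode; rotor episodes are retried with perturbed S2
    settings until the reentry is sustained (and, optionally, the phase-
    singularity detector confirms the core region)."""
    ionic = get_ionic_model()
    kind = plan_entry["kind"]
    target = plan_entry.get("target_region")
    tweaks = [
        {},
        {"s2_radius_mm": 26.0},
        {"anchor_radius_mm": 12.0},
        {"s2_trigger_u": 0.5},
        {"anchor_radius_mm": 12.0, "s2_radius_mm": 26.0},
        {"anchor_radius_mm": 8.0, "s2_radius_mm": 18.0, "s2_trigger_u": 0.3},
    ]
    last = None
    for attempt in range(max_attempts if kind == "cross_field_rotor" else 1):
        proto = StimulusProtocol(
            kind=kind,
            target_region=target,
            rng_seed=seed + 1000 * attempt,
            fibrosis_fraction=plan_entry.get("fibrosis_fraction", 0.0),
            **tweaks[attempt % len(tweaks)],
        )
        vs = simulate_propagation(mesh, ionic, proto, duration_s=duration_s, fs=fs, dt_ms=dt_ms)
        last = vs
        if kind != "cross_field_rotor":
            return vs
        frac = np.mean(vs.ground_truth_driver == target)
        if frac < min_driver_fraction:
            continue
        if ps_check:
            det = PhaseSingularityDetector(mesh, vs)
            frames = np.where(vs.ground_truth_driver == target)[0][::10]
            hits = sum(
                1 for fr in frames
                if np.any(mesh.region_id[det.singular_nodes(fr)] == target)
            )
            if frames.size and hits / frames.size < min_ps_agreement:
                continue
        return vs
    return last  # best effort; labels still honest (driver frames only while active)


def project_episode(vm: VmSeries, tm: TransferMatrix, electrode_table) -> BSPRecording:
    """Forward-project an episode to the 64 WCT-referenced vest channels."""
    y = wct_reference(tm, vm.vm.astype(float))
    full = BSPRecording(potentials=y, fs=vm.fs)
    return sample_vest(full, electrode_table)


def make_corpus(
    n_nodes: int = 2048,
    duration_s: float = 2.0,
    fs: float = 500.0,
    dt_ms: float = 0.1,
    seed: int = 0,
    plan: Optional[List[dict]] = None,
    torso_radius_mm: float = 120.0,
) -> Tuple[List[Episode], AtrialMesh, TransferMatrix]:
    """Simulate the full multi-episode corpus and project it to clean BSP."""
    root = np.random.SeedSequence(seed)
    mesh_seed, *ep_seeds = [int(s) for s in root.generate_state(1 + len(plan or default_episode_plan()) )]
    plan = plan or default_episode_plan()
    mesh = build_synthetic_atria(n_nodes, rng_seed=mesh_seed % (2**31))
    torso, table = default_vest(radius_mm=torso_radius_mm)
    tm = build_transfer_matrix(mesh, torso)
    episodes = []
    for i, entry in enumerate(plan):
        vs = simulate_episode_with_retries(
            mesh, entry, duration_s, fs, dt_ms, seed=ep_seeds[i] % (2**31)
        )
        bsp = project_episode(vs, tm, table)
        episodes.append(Episode(episode_id=i, vm=vs, bsp_clean=bsp))
    return episodes, mesh, tm


def condition_bsp(bsp: BSPRecording, snr_db: Optional[float], rng_seed: int) -> BSPRecording:
    """The corruption chain: additive noise, then band-pass filtering."""
    return bandpass_filter(add_noise(bsp, snr_db, rng_seed))


def episodes_to_dataset(
    episodes: Sequence[Episode],
    snr_db: Optional[float],
    seed: int,
    mode: str = "1ch",
    resize_shape: Optional[Tuple[int, int]] = None,
    normalization: str = "zscore",
) -> LabeledDataset:
    root = np.random.SeedSequence(seed)
    noise_seeds = root.generate_state(len(episodes))
    groups = []
    for ep, ns in zip(episodes, noise_seeds):
        cond = condition_bsp(ep.bsp_clean, snr_db, int(ns))
        groups.append((ep.episode_id, cond.potentials, ep.labels))
    return build_tensor_dataset(groups, mode=mode, resize_shape=resize_shape,
                                normalization=normalization)


@dataclasses.dataclass
class ExperimentResult:
    trained: object
    splits: Splits
    report: object
    dataset: LabeledDataset


def run_experiment(
    ds: LabeledDataset,
    split_scheme: str = "time_independent",
    seed: int = 0,
    train_config: Optional[TrainConfig] = None,
    verbose: bool = False,
) -> ExperimentResult:
    """Split, train the CNN with class weights, evaluate on the test split."""
    splits = (
        split_time_independent(ds, seed=seed)
        if split_scheme == "time_independent"
        else split_blocks(ds)
    )
    config = train_config or TrainConfig(rng_seed=seed)
    spec, model = build_custom_cnn(ds.images.shape[1:], rng_seed=seed)
    cw = class_weights(ds.labels[splits.train])
    trained = train_model(
        model,
        ds.images[splits.train], ds.labels[splits.train],
        ds.images[splits.val], ds.labels[splits.val],
        config=config, class_weight=cw, spec=spec, verbose=verbose,
    )
    _, y_pred = predict(trained.model, ds.images[splits.test])
    report = metrics_report(
        ds.labels[splits.test], y_pred,
        provenance={"split": split_scheme, "seed": seed},
    )
    return ExperimentResult(trained=trained, splits=splits, report=report, dataset=ds)


def make_sweep_predict_fn(
    trained_model,
    episodes: Sequence[Episode],
    test_mask_by_episode: dict,
    mode: str = "1ch",
    resize_shape: Optional[Tuple[int, int]] = None,
    normalization: str = "zscore",
):
    """Build the corrupt -> filter -> tensorize -> predict closure used by
    :func:`afloc.evaluation.noise_robustness_sweep`.

    ``test_mask_by_episode`` maps episode_id -> boolean frame mask selecting
    the held-out frames evaluated at every SNR/repetition.
    """

    def predict_fn(snr_db, rng_seed):
        groups = []
        for ep in episodes:
            mask = test_mask_by_episode.get(ep.episode_id)
            if mask is None or not mask.any():
                continue
            cond = condition_bsp(ep.bsp_clean, snr_db, rng_seed + ep.episode_id)
            groups.append((ep.episode_id, cond.potentials[:, mask], ep.labels[mask]))
        ds = build_tensor_dataset(groups, mode=mode, resize_shape=resize_shape,
                                  normalization=normalization)
        _, y_pred = predict(trained_model, ds.images)
        return ds.labels, y_pred

    return predict_fn


def run_sweep(
    trained_model,
    episodes: Sequence[Episode],
    splits: Splits,
    dataset: LabeledDataset,
    snrs=range(5, 55, 5),
    n_reps: int = 20,
    seed: int = 0,
    resize_shape: Optional[Tuple[int, int]] = None,
    max_test_frames: Optional[int] = None,
):
    """Noise-robustness sweep over the held-out test frames."""
    mode = dataset.manifest.get("mode", "1ch")
    resize_shape = resize_shape or tuple(dataset.manifest.get("resize_shape", (78, 192)))
    test_idx = splits.test
    if max_test_frames is not None and len(test_idx) > max_test_frames:
        rng = np.random.default_rng(seed)
        test_idx = np.sort(rng.choice(test_idx, size=max_test_frames, replace=False))
    masks = {}
    for ep in episodes:
        n = ep.vm.n_frames
        mask = np.zeros(n, dtype=bool)
        sel = test_idx[dataset.episode_ids[test_idx] == ep.episode_id]
        mask[dataset.frame_idx[sel]] = True
        masks[ep.episode_id] = mask
    fn = make_sweep_predict_fn(
        trained_model, episodes, masks, mode=mode, resize_shape=resize_shape,
        normalization=dataset.manifest.get("normalization", "zscore"),
    )
    return noise_robustness_sweep(fn, snrs=list(snrs), n_reps=n_reps, seed=seed)
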