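# afloc

Non-invasive localization of atrial-fibrillation (AF) drivers from body-surface
potentials (BSP), as a fully synthetic, end-to-end tested pipeline:

1. **atrial_sim** — synthetic two-chamber atrial surface (2,048 nodes, seven
   labeled regions: PLAW, LIPV, LSPV, RIPV, RSPV, RAA, RAFW) and monodomain
   propagation with a 3-variable phenomenological ionic model (explicit RK4).
   AF drivers are induced with a cross-field S1–S2 protocol anchored at a
   target region; driver-free episodes use planar/focal stimulation.
2. **forward_ecg** — quadratic least-squares surface gradients, infinite-medium
   dipole summation, M×N transfer matrix, Wilson-Central-Terminal referencing.
3. **bsp_processing** — calibrated additive Gaussian noise (SNR in dB),
   zero-phase 4th-order Butterworth band-pass (3–30 Hz), 64-electrode vest
   sampling.
4. **tensorizer** — per-frame image layouts: 3-channel (6×4×3, front/sides/back)
   and 1-channel (6×16 unrolled cylinder with gap filling and mirror columns),
   align-corners bilinear resize to (150×152×3) / (78×192×1).
5. **dataset_builder** — per-frame labels 0–7 (0 = no driver), phase-singularity
   verification (Hilbert phase + ring winding numbers), frame-random and
   consecutive-block splits, inverse-frequency class weights.
6. **driver_cnn** — pure-numpy CNN (conv 32/64/64 3×3 + 2×2 max-pool, dense
   128/64 with 0.6 dropout, 8-unit softmax), Adam, LR reduction, early
   stopping, best-model checkpointing.
7. **evaluation** — accuracy, Cohen's kappa, per-class TPR/TNR, confusion
   matrices, SNR-robustness sweep (mean ± SD over repeated noise draws).
8. **cli** — the `afloc` command-line app orchestrating everything from a YAML
   config with full seed provenance.

No external data is required; everything is simulated.

## CLI

```bash
afloc simulate       --config config.yaml --out run/   # episode corpus + clean BSP
afloc build-dataset  --config config.yaml --out run/   # tensors + labels
afloc train          --config config.yaml --out run/ --split time
afloc evaluate       --config config.yaml --out run/
afloc sweep          --config config.yaml --out run/ --snr-db 5 --snr-db 20
```

Any subset of the YAML config can be given; unspecified fields use the
defaults in `afloc.cli.DEFAULT_CONFIG`. A minimal smoke config:

```yaml
geometry: {n_nodes: 2048}
simulation: {duration_s: 0.5, regions: [3, 6], n_driver_free: 2}
dataset: {resize_shape: [30, 64]}
training: {max_epochs: 2, early_stop_patience: 1}
sweep: {snrs: [20], n_reps: 2}
seed: 4
```

Each stage writes a JSON manifest next to its artifacts; downstream commands
refuse to run if the upstream manifest is missing and name the command to run.

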