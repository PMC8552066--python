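"""BSP conditioning: calibrated Gaussian noise, band-pass filter, vest sampling.

Processing order follows the acquisition chain: noise is added to the raw
referenced potentials, then the 4th-order Butterworth band-pass (3–30 Hz)
is applied zero-phase, then the 64 vest channels are selected.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional

import h5py
import numpy as np
import pandas as pd
from scipy import signal


@dataclasses.dataclass
class BSPRecording:
    """Electrode-by-time potentials with processing provenance."""

    potentials: np.ndarray           # (E, S)
    fs: float
    snr_db: Optional[float] = None
    filter_spec: Optional[dict] = None
    electrode_names: Optional[List[str]] = None

    def __post_init__(self):
        self.potentials = np.asarray(self.potentials, dtype=float)
        if self.potentials.ndim != 2:
            raise ValueError("potentials must be (electrodes, samples)")
        if not np.all(np.isfinite(self.potentials)):
            raise ValueError("potentials contain NaN/Inf")

    @property
    def n_electrodes(self) -> int:
        return self.potentials.shape[0]

    @property
    def n_samples(self) -> int:
        return self.potentials.shape[1]

    def replace(self, **kw) -> "BSPRecording":
        return dataclasses.replace(self, **kw)


def add_noise(bsp: BSPRecording, snr_db: Optional[float], rng_seed: int = 0) -> BSPRecording:
    """Additive white Gaussian noise, calibrated per electrode.

    Noise variance per electrode is that electrode's clean mean power
    divided by 10^(snr/10), so the realized SNR converges to ``snr_db``.
    ``snr_db=None`` returns the input unchanged.
    """
    if snr_db is None:
        return bsp
    if not np.isfinite(snr_db):
        return bsp  # infinite SNR == clean
    power = np.mean(bsp.potentials**2, axis=1)
    if np.any(power <= 0):
        bad = int(np.where(power <= 0)[0][0])
        raise ValueError(f"electrode {bad} has zero power; SNR undefined")
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(rng_seed)
    noise = sigma[:, None] * rng.standard_normal(bsp.potentials.shape)
    return bsp.replace(potentials=bsp.potentials + noise, snr_db=float(snr_db))


def bandpass_filter(
    bsp: BSPRecording, order: int = 4, f_lo: float = 3.0, f_hi: float = 30.0
) -> BSPRecording:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    if f_hi >= bsp.fs / 2.0:
        raise ValueError(f"f_hi={f_hi} must be below Nyquist ({bsp.fs / 2.0})")
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=bsp.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, bsp.potentials, axis=1)
    spec = {"type": "butterworth", "order": order, "band_hz": [f_lo, f_hi], "zero_phase": True}
    return bsp.replace(potentials=filtered, filter_spec=spec)


def butter_magnitude_response(freqs_hz, fs: float, order: int = 4, f_lo: float = 3.0, f_hi: float = 30.0):
    """Single-pass magnitude response of the designed digital filter."""
    sos = signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * np.atleast_1d(freqs_hz) / fs)
    return np.abs(h)


def sample_vest(bsp_full: BSPRecording, electrode_table: pd.DataFrame) -> BSPRecording:
    """Select the 64 vest channels in canonical order.

    The table must provide a ``channel`` column (row index into the full
    recording) plus panel/vest_row/vest_col assignments; the mapping must
    be bijective onto 64 distinct electrodes.
    """
    required = {"channel", "panel", "vest_row", "vest_col"}
    missing = required - set(electrode_table.columns)
    if missing:
        raise ValueError(f"electrode table missing columns: {sorted(missing)}")
    if len(electrode_table) != 64:
        raise ValueError(f"vest table must have exactly 64 rows, got {len(electrode_table)}")
    idx = electrode_table["channel"].to_numpy()
    if len(np.unique(idx)) != 64:
        raise ValueError("electrode table maps duplicate channels")
    if idx.min() < 0 or idx.max() >= bsp_full.n_electrodes:
        raise ValueError("electrode table channel index out of range")
    names = None
    if "name" in electrode_table.columns:
        names = list(electrode_table["name"])
    return bsp_full.replace(potentials=bsp_full.potentials[idx].copy(), electrode_names=names)


def realized_snr_db(clean: np.ndarray, noisy: np.ndarray) -> float:
    """Empirical SNR (dB) of ``noisy`` against the clean reference."""
    noise = np.asarray(noisy) - np.asarray(clean)
    return 10.0 * np.log10(np.mean(np.asarray(clean) ** 2) / np.mean(noise**2))


def save_bsp_h5(bsp: BSPRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("bsp", data=bsp.potentials)
        f.create_dataset("fs", data=float(bsp.fs))
        if bsp.snr_db is not None:
            f.attrs["snr_db"] = bsp.snr_db
        if bsp.filter_spec is not None:
            f.attrs["filter"] = str(bsp.filter_spec)
        if bsp.electrode_names is not None:
            f.attrs["electrodes"] = ",".join(bsp.electrode_names)


def load_bsp_h5(path) -> BSPRecording:
    with h5py.File(path, "r") as f:
        names = f.attrs.get("electrodes")
        return BSPRecording(
            potentials=f["bsp"][()],
            fs=float(f["fs"][()]),
            snr_db=float(f.attrs["snr_db"]) if "snr_db" in f.attrs else None,
            electrode_names=names.split(",") if names else None,
        )
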