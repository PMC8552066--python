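"""Phenomenological ionic models for the monodomain simulation.

The default is a three-variable Fenton–Karma-style model (normalized
membrane variable u in [0, ~1], fast gate v, slow gate w) with parameters
tuned for short, atrial-like action potentials that sustain spiral waves on
the coarse synthetic surface.  Time unit is ms throughout.
"""

from __future__ import annotations

import abc
from typing import Dict, Tuple

import numpy as np


class IonicModel(abc.ABC):
    """Single-cell reaction kinetics contract.

    ``rhs`` returns the reaction part of du/dt (i.e. -I_ion / C_m in
    normalized units) and the gate derivatives; diffusion and stimulus are
    added by the tissue integrator.
    """

    name: str = "abstract"
    n_gates: int = 0

    @abc.abstractmethod
    def resting_state(self) -> Tuple[float, np.ndarray]:
        """(u_rest, gate_rest) fixed point of the kinetics."""

    @abc.abstractmethod
    def rhs(self, u: np.ndarray, gates: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """du_reaction/dt (per ms) and dgates/dt, vectorized over nodes."""


class FentonKarma(IonicModel):
    """Three-variable model: u (voltage), v (fast inactivation), w (slow).

    Parameter names follow the common tau_* convention; ``cm_scale``
    multiplies the voltage equation (a C_m knob in normalized units).
    """

    name = "fenton_karma"
    n_gates = 2

    #: defaults give a short, AF-like APD (~45 ms) whose tight spiral cores
    #: stay compact and distinctive on the default 2,048-node surface
    DEFAULTS: Dict[str, float] = {
        "tau_d": 0.25,
        "tau_o": 12.5,
        "tau_r": 29.0,
        "tau_si": 29.0,
        "tau_vp": 3.33,
        "tau_v1m": 19.6,
        "tau_v2m": 60.0,
        "tau_wp": 870.0,
        "tau_wm": 41.0,
        "u_c": 0.13,
        "u_v": 0.04,
        "u_csi": 0.85,
        "k": 10.0,
        "cm_scale": 1.0,
    }

    def __init__(self, **overrides: float):
        unknown = set(overrides) - set(self.DEFAULTS)
        if unknown:
            raise ValueError(f"unknown FentonKarma parameters: {sorted(unknown)}")
        self.params = {**self.DEFAULTS, **overrides}

    def resting_state(self) -> Tuple[float, np.ndarray]:
        return 0.0, np.array([1.0, 1.0])

    def rhs(self, u: np.ndarray, gates: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        p = self.params
        v, w = gates[0], gates[1]
        above = u >= p["u_c"]
        j_fi = np.where(
            above, -v * (u - p["u_c"]) * (1.0 - u) / p["tau_d"], 0.0
        )
        j_so = np.where(above, 1.0 / p["tau_r"], u / p["tau_o"])
        j_si = -w * (1.0 + np.tanh(p["k"] * (u - p["u_csi"]))) / (2.0 * p["tau_si"])
        du = -(j_fi + j_so + j_si) / p["cm_scale"]

        tau_vm = np.where(u >= p["u_v"], p["tau_v1m"], p["tau_v2m"])
        dv = np.where(above, -v / p["tau_vp"], (1.0 - v) / tau_vm)
        dw = np.where(above, -w / p["tau_wp"], (1.0 - w) / p["tau_wm"])
        return du, np.stack([dv, dw])


_REGISTRY = {FentonKarma.name: FentonKarma, "fk": FentonKarma}


def get_ionic_model(name: str = "fenton_karma", **overrides) -> IonicModel:
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(f"unknown ionic model '{name}'; known: {sorted(_REGISTRY)}")
    return cls(**overrides)
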