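"""Hierarchical phenotype record: volume, geometry, mechanics, motility,
secretion, cycle, and death state for one cell."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from multicell.errors import ConfigurationError
from multicell.volume import VolumeState, equilibrium_volume_state


@dataclass
class SecretionState:
    """Per-substrate secretion/uptake rates for one cell.

    ``secretion`` and ``uptake`` are (n_substrates,) rate vectors
    (1/min); ``saturation`` is the density at which secretion stops.
    The cell's current volume is the source weight W_k.
    """

    secretion: np.ndarray
    uptake: np.ndarray
    saturation: np.ndarray

    @classmethod
    def zeros(cls, n_substrates: int) -> "SecretionState":
        return cls(
            secretion=np.zeros(n_substrates),
            uptake=np.zeros(n_substrates),
            saturation=np.zeros(n_substrates),
        )

    def copy(self) -> "SecretionState":
        return SecretionState(
            self.secretion.copy(), self.uptake.copy(), self.saturation.copy()
        )

    def validate(self) -> None:
        if np.any(self.secretion < 0) or np.any(self.uptake < 0):
            raise ConfigurationError("secretion/uptake rates must be nonnegative")


@dataclass
class MotilityState:
    """Biased persistent random walk parameters and current migration velocity.

    The migration velocity is redrawn with probability dt/T_per per
    mechanics step as ``s_mot * ((1-b) xi + b d_bias) / ||..||`` with
    ``xi`` uniform on the unit sphere; ``b=0`` is Brownian, ``b=1``
    deterministic taxis along ``d_bias``.
    """

    enabled: bool = False
    T_per: float = 1.0          # persistence time (min)
    s_mot: float = 1.0          # migration speed (um/min)
    b: float = 0.0              # bias in [0, 1]
    d_bias: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    v_mot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    #: optional callable (cell, field) -> None setting d_bias, b, s_mot
    update_bias_hook: Optional[Callable] = None

    def copy(self) -> "MotilityState":
        return MotilityState(
            enabled=self.enabled, T_per=self.T_per, s_mot=self.s_mot,
            b=self.b, d_bias=self.d_bias.copy(), v_mot=self.v_mot.copy(),
            update_bias_hook=self.update_bias_hook,
        )


@dataclass
class MechanicsParams:
    """Adhesion/repulsion strengths and interaction ranges (Eq-10-style
    potentials).  Strengths have velocity units (um/min); the maximum
    adhesion distance is ``R_A_multiple`` times the cell radius."""

    c_cca: float = 0.4      # cell-cell adhesion strength
    c_ccr: float = 10.0     # cell-cell repulsion strength
    c_cba: float = 0.0      # cell-BM adhesion strength
    c_cbr: float = 10.0     # cell-BM repulsion strength
    R_A_multiple: float = 1.25
    n: int = 1              # potential smoothness exponent

    def __post_init__(self):
        if min(self.c_cca, self.c_ccr, self.c_cba, self.c_cbr) < 0:
            raise ConfigurationError("mechanics strengths must be nonnegative")
        if self.R_A_multiple <= 1.0:
            raise ConfigurationError("R_A_multiple must exceed 1")

    def copy(self) -> "MechanicsParams":
        return replace(self)


@dataclass
class Phenotype:
    """Hierarchical parameter/state record for one cell.

    Geometry (radius, nuclear radius, surface area, maximum adhesion
    distance) is derived from the volume state assuming spherical
    shape and is recomputed whenever the volume changes.
    """

    volume: VolumeState
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    motility: MotilityState = field(default_factory=MotilityState)
    secretion: SecretionState = field(default_factory=lambda: SecretionState.zeros(0))
    cycle: object = None    # CycleState, set by the cycle module
    death: object = None    # DeathState, set by the death module

    @property
    def radius(self) -> float:
        return self.volume.radius

    @property
    def max_adhesion_distance(self) -> float:
        return self.mechanics.R_A_multiple * self.volume.radius

    def copy(self) -> "Phenotype":
        import copy as _copy

        return Phenotype(
            volume=replace(self.volume),
            mechanics=self.mechanics.copy(),
            motility=self.motility.copy(),
            secretion=self.secretion.copy(),
            cycle=_copy.copy(self.cycle),
            death=_copy.copy(self.death),
        )


def default_phenotype(n_substrates: int = 0, **volume_kwargs) -> Phenotype:
    """Reference phenotype at the mature-volume fixed point."""
    return Phenotype(
        volume=equilibrium_volume_state(**volume_kwargs),
        secretion=SecretionState.zeros(n_substrates),
    )
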