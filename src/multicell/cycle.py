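"""Cell cycle framework: phase graphs with stochastic or fixed-duration
transitions, plus the built-in Ki67-advanced and live-cell models.

A cycle model is a directed graph of phases {X_i} with per-edge
transition rates r_ij (1/min).  In a step of length dt a stochastic
edge fires with probability r_ij * dt (clamped to 1) unless arrested; a
fixed-duration edge fires deterministically once the time in phase
reaches 1/r_ij.  An edge may be marked as the division transition, in
which case traversing it emits a division event.

Built-in models:

* ``ki67_advanced`` -- phases K1 (Ki67+, pre-division), K2 (Ki67+,
  post-division) and Q (Ki67-, quiescent).  Division occurs on the
  K1 -> K2 edge.  The Q -> K1 entry rate is typically driven by local
  oxygenation (see :func:`ki67_Q_to_K1_rate`); entering K1 doubles the
  nuclear solid target.
* ``live`` -- a single phase with a division-marked self-edge at a
  mutable birth rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

from multicell.errors import ConfigurationError

log = logging.getLogger(__name__)

_warned_large_prob = set()


@dataclass
class Transition:
    """One edge of a cycle model graph."""

    to_phase: str
    rate: float                      # 1/min; fixed-duration edges last 1/rate
    fixed_duration: bool = False
    division: bool = False           # traversing this edge divides the cell
    arrest: Optional[Callable] = None  # predicate(cell) -> True blocks firing


@dataclass
class CyclePhase:
    name: str
    transitions: list[Transition] = field(default_factory=list)
    entry_hook: Optional[Callable] = None   # called as hook(cell)
    exit_hook: Optional[Callable] = None


class CycleModel:
    """Directed graph of :class:`CyclePhase` with runtime-mutable rates."""

    def __init__(self, name: str, phases: list[CyclePhase], initial_phase: str | None = None):
        names = [p.name for p in phases]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate phase names in cycle model {name!r}")
        for p in phases:
            for tr in p.transitions:
                if tr.rate < 0:
                    raise ConfigurationError("transition rates must be nonnegative")
                if tr.to_phase not in names:
                    raise ConfigurationError(
                        f"transition {p.name} -> {tr.to_phase} targets unknown phase")
        self.name = name
        self.phases = {p.name: p for p in phases}
        self.initial_phase = initial_phase or phases[0].name

    def new_state(self, phase: str | None = None) -> "CycleState":
        return CycleState(model=self, current_phase=phase or self.initial_phase)


@dataclass
class CycleState:
    """Per-cell cycle state: current phase, time in phase, and optional
    per-cell rate overrides keyed by (from_phase, to_phase)."""

    model: CycleModel
    current_phase: str
    time_in_phase: float = 0.0
    rate_overrides: dict = field(default_factory=dict)

    def rate(self, from_phase: str, tr: Transition) -> float:
        return self.rate_overrides.get((from_phase, tr.to_phase), tr.rate)

    def set_rate(self, from_phase: str, to_phase: str, rate: float) -> None:
        if rate < 0:
            raise ConfigurationError("transition rates must be nonnegative")
        self.rate_overrides[(from_phase, to_phase)] = rate

    def copy(self) -> "CycleState":
        return replace(self, rate_overrides=dict(self.rate_overrides))


def advance_cycle(cell, dt: float, rng) -> list[tuple]:
    """Advance one cell's cycle by dt; returns emitted events.

    Events are ``("transition", from_phase, to_phase)`` and
    ``("division",)``.  At most one edge fires per step; candidate
    edges are examined in their declared order.  On firing: exit hook,
    phase change, time-in-phase reset, entry hook; a division-marked
    edge additionally emits a division event.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    state: CycleState = cell.phenotype.cycle
    phase = state.model.phases[state.current_phase]
    events: list[tuple] = []
    for tr in phase.transitions:
        rate = state.rate(phase.name, tr)
        if rate <= 0:
            continue
        if tr.arrest is not None and tr.arrest(cell):
            continue
        if tr.fixed_duration:
            # fires on the step where the accumulated time first reaches 1/r
            fires = state.time_in_phase + dt >= 1.0 / rate - 1e-9
        else:
            prob = rate * dt
            if prob > 1.0 and (phase.name, tr.to_phase) not in _warned_large_prob:
                _warned_large_prob.add((phase.name, tr.to_phase))
                log.warning(
                    "transition probability r*dt = %.3g > 1 for %s -> %s; "
                    "reduce the cell time step", prob, phase.name, tr.to_phase)
            fires = rng.random() < min(prob, 1.0)
        if fires:
            if phase.exit_hook is not None:
                phase.exit_hook(cell)
            state.current_phase = tr.to_phase
            state.time_in_phase = 0.0
            events.append(("transition", phase.name, tr.to_phase))
            new_phase = state.model.phases[tr.to_phase]
            if new_phase.entry_hook is not None:
                new_phase.entry_hook(cell)
            if tr.division:
                events.append(("division",))
            return events
    state.time_in_phase += dt
    return events


# --------------------------------------------------------------------- models

@dataclass
class Ki67AdvancedParams:
    """Mean phase durations (min) and the oxygen scale of cycle entry.

    Cells spend a mean time ``T_Q_bar`` in Q at the reference oxygen
    tension ``pO2_bar``; the Q -> K1 rate falls linearly to zero at
    ``pO2_hypoxia``.
    """

    T_1: float = 13.0 * 60.0        # mean K1 duration
    T_2: float = 2.5 * 60.0         # mean K2 duration
    T_Q_bar: float = 74.35 * 60.0   # mean Q duration at pO2_bar
    pO2_hypoxia: float = 5.0        # mmHg
    pO2_bar: float = 38.0           # mmHg (physioxic reference)

    def __post_init__(self):
        if min(self.T_1, self.T_2, self.T_Q_bar) <= 0:
            raise ConfigurationError("phase durations must be positive")
        if self.pO2_bar <= self.pO2_hypoxia:
            raise ConfigurationError("pO2_bar must exceed pO2_hypoxia")


def ki67_Q_to_K1_rate(pO2: float, params: Ki67AdvancedParams) -> float:
    """Oxygen-dependent quiescence exit rate (1/min):

        r = (1 / T_Q_bar) * max{(pO2 - pO2_hyp) / (pO2_bar - pO2_hyp), 0}
    """
    frac = (pO2 - params.pO2_hypoxia) / (params.pO2_bar - params.pO2_hypoxia)
    return max(frac, 0.0) / params.T_Q_bar


def _reentry_hook(cell):
    if cell.phenotype.volume is not None:
        cell.phenotype.volume.on_cycle_reentry()


def ki67_advanced_model(
    params: Ki67AdvancedParams | None = None,
    fixed_durations: bool = True,
) -> CycleModel:
    """The Ki67-advanced cycle model.

    ``fixed_durations`` makes K1 and K2 deterministic with durations
    T_1 and T_2 (as used in the tumor growth examples); otherwise they
    are exponential with those means.  The Q -> K1 rate defaults to the
    value at the reference oxygen tension; microenvironment-dependent
    simulations override it per cell each phenotype update.
    """
    p = params or Ki67AdvancedParams()
    k1 = CyclePhase(
        "K1",
        transitions=[Transition("K2", 1.0 / p.T_1, fixed_duration=fixed_durations,
                                division=True)],
        entry_hook=_reentry_hook,
    )
    k2 = CyclePhase(
        "K2",
        transitions=[Transition("Q", 1.0 / p.T_2, fixed_duration=fixed_durations)],
    )
    q = CyclePhase(
        "Q",
        transitions=[Transition("K1", 1.0 / p.T_Q_bar)],
    )
    model = CycleModel("ki67_advanced", [k1, k2, q], initial_phase="Q")
    model.params = p
    return model


def live_model(birth_rate: float = 0.0432 / 60.0) -> CycleModel:
    """Single-phase 'live cells' model: a division-marked self-edge at a
    mutable birth rate (default ~0.0432/h, a typical tumor-cell rate)."""
    live = CyclePhase(
        "live",
        transitions=[Transition("live", birth_rate, division=True)],
    )
    return CycleModel("live", [live])
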