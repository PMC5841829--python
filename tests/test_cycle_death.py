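"""Cycle phase graphs, transition statistics, and death processes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multicell.cell import Cell
from multicell.cycle import (CycleModel, CyclePhase, Ki67AdvancedParams,
                             Transition, advance_cycle, ki67_Q_to_K1_rate,
                             ki67_advanced_model, live_model)
from multicell.death import (DeathState, MODE_APOPTOTIC,
                             MODE_NECROTIC_LYSED, MODE_NECROTIC_SWELLING,
                             check_death, death_probability, death_progress,
                             start_apoptosis, start_necrosis,
                             stochastic_necrosis_rate)
from multicell.phenotype import Phenotype, SecretionState
from multicell.volume import equilibrium_volume_state


def _cell(model=None, death=None, cid=0):
    ph = Phenotype(volume=equilibrium_volume_state(),
                   secretion=SecretionState.zeros(1),
                   cycle=model.new_state() if model else None,
                   death=death)
    return Cell(cid, ph, (0.0, 0.0, 0.0))


# ------------------------------------------------------------------- cycle

def test_zero_rates_stay_forever(rng):
    model = CycleModel("idle", [CyclePhase("X", [Transition("X", 0.0)])])
    cell = _cell(model)
    for _ in range(100):
        assert advance_cycle(cell, 6.0, rng) == []
    assert cell.phenotype.cycle.time_in_phase == pytest.approx(600.0)


def test_fixed_duration_fires_when_time_reaches_duration(rng):
    model = CycleModel("timer", [
        CyclePhase("X", [Transition("Y", 1.0 / 60.0, fixed_duration=True)]),
        CyclePhase("Y", [])])
    cell = _cell(model)
    calls = 0
    while cell.phenotype.cycle.current_phase == "X":
        events = advance_cycle(cell, 6.0, rng)
        calls += 1
        assert calls < 50
    assert calls == 10  # fires on the step where accumulated time reaches 60
    assert events == [("transition", "X", "Y")]


def test_stochastic_mean_residence_time(rng):
    """Per-step Bernoulli at r*dt gives geometric waits with mean 1/r."""
    r, dt, n = 0.01, 6.0, 10000
    model = CycleModel("exp", [CyclePhase("X", [Transition("Y", r)]),
                               CyclePhase("Y", [])])
    times = np.empty(n)
    for i in range(n):
        cell = _cell(model)
        steps = 0
        while cell.phenotype.cycle.current_phase == "X":
            advance_cycle(cell, dt, rng)
            steps += 1
        times[i] = steps * dt
    p = r * dt
    expect = dt / p
    se = dt * math.sqrt(1 - p) / p / math.sqrt(n)
    assert abs(times.mean() - expect) < 3 * se


def test_division_marked_edge_emits_division_event(rng):
    model = live_model(birth_rate=1.0)  # fires every step at dt >= 1
    cell = _cell(model)
    events = advance_cycle(cell, 1.0, rng)
    assert ("division",) in events


def test_arrest_condition_blocks_transition(rng):
    model = CycleModel("gate", [
        CyclePhase("X", [Transition("Y", 10.0, arrest=lambda c: True)]),
        CyclePhase("Y", [])])
    cell = _cell(model)
    for _ in range(50):
        assert advance_cycle(cell, 6.0, rng) == []


def test_entry_and_exit_hooks_run_in_order(rng):
    trace = []
    model = CycleModel("hooked", [
        CyclePhase("X", [Transition("Y", 100.0)],
                   exit_hook=lambda c: trace.append("exit_X")),
        CyclePhase("Y", [], entry_hook=lambda c: trace.append("enter_Y"))])
    cell = _cell(model)
    advance_cycle(cell, 6.0, rng)
    assert trace == ["exit_X", "enter_Y"]
    assert cell.phenotype.cycle.time_in_phase == 0.0


def test_ki67_Q_to_K1_rate_clamped_linear():
    p = Ki67AdvancedParams()
    assert ki67_Q_to_K1_rate(p.pO2_hypoxia, p) == 0.0
    assert ki67_Q_to_K1_rate(p.pO2_hypoxia - 3.0, p) == 0.0
    assert ki67_Q_to_K1_rate(p.pO2_bar, p) == pytest.approx(1.0 / p.T_Q_bar)
    mid = 0.5 * (p.pO2_bar + p.pO2_hypoxia)
    assert ki67_Q_to_K1_rate(mid, p) == pytest.approx(0.5 / p.T_Q_bar)


def test_ki67_advanced_reentry_doubles_nuclear_target(rng):
    model = ki67_advanced_model(fixed_durations=True)
    cell = _cell(model)
    cell.phenotype.cycle.set_rate("Q", "K1", 10.0)  # force immediate entry
    events = advance_cycle(cell, 6.0, rng)
    assert ("transition", "Q", "K1") in events
    assert cell.phenotype.volume.V_NS_star == pytest.approx(270.0)


# ------------------------------------------------------------------- death

def test_death_probability_values():
    assert death_probability(0.0, 6.0) == 0.0
    assert death_probability(0.01, 6.0) == pytest.approx(1.0 - math.exp(-0.06))
    assert death_probability(math.inf, 6.0) == 1.0


@settings(max_examples=50, deadline=None)
@given(rate=st.floats(0, 1e3), dt=st.floats(1e-3, 1e3))
def test_death_probability_in_unit_interval(rate, dt):
    assert 0.0 <= death_probability(rate, dt) <= 1.0


def test_stochastic_necrosis_rate_branches():
    ds = DeathState(pO2_threshold=5.0, pO2_crit=2.5, r_N_max=1.0 / 360.0)
    assert stochastic_necrosis_rate(10.0, ds) == 0.0
    assert stochastic_necrosis_rate(2.5, ds) == pytest.approx(1.0 / 360.0)
    assert stochastic_necrosis_rate(1.0, ds) == pytest.approx(1.0 / 360.0)
    assert stochastic_necrosis_rate(3.75, ds) == pytest.approx(0.5 / 360.0)


def test_apoptosis_precedence_and_mode(rng):
    cell = _cell(death=DeathState(r_A=1e9, r_N_death=1e9))
    assert check_death(cell, 6.0, rng) == MODE_APOPTOTIC


def test_start_apoptosis_targets_and_monotone_shrink(rng):
    cell = _cell(death=DeathState())
    start_apoptosis(cell, rng)
    vs = cell.phenotype.volume
    assert vs.f_CN == 0.0 and vs.V_NS_star == 0.0 and vs.f_F == 0.0
    assert np.all(cell.phenotype.secretion.secretion == 0.0)
    prev = vs.V
    removed = False
    for _ in range(200):
        vs.update(6.0)
        assert vs.V <= prev + 1e-9
        prev = vs.V
        if death_progress(cell, 6.0):
            removed = True
            break
    assert removed  # via volume threshold or elapsed duration


def test_apoptosis_removal_after_mean_duration():
    cell = _cell(death=DeathState(T_A=60.0))
    cell.phenotype.volume.removal_volume = 0.0  # isolate the duration rule
    start_apoptosis(cell)
    elapsed = 0.0
    while not death_progress(cell, 6.0):
        elapsed += 6.0
        assert elapsed < 120.0
    assert elapsed + 6.0 == pytest.approx(60.0)


def test_necrosis_swelling_lysis_sequence_one_way():
    cell = _cell(death=DeathState())
    start_necrosis(cell)
    vs = cell.phenotype.volume
    ds = cell.phenotype.death
    assert vs.f_F == 1.0 and vs.f_CN == 0.0 and vs.V_NS_star == 0.0
    assert ds.mode == MODE_NECROTIC_SWELLING
    swelled = False
    lysed_at = None
    prev_mode = ds.mode
    for step in range(100000):
        vs.update(6.0)
        removed = death_progress(cell, 6.0)
        if ds.mode == MODE_NECROTIC_LYSED and lysed_at is None:
            lysed_at = step
            assert vs.V >= vs.rupture_volume  # lysis exactly at threshold pass
            assert vs.f_F == 0.0
            swelled = True
        if lysed_at is not None:
            assert ds.mode == MODE_NECROTIC_LYSED  # one-way
        if removed:
            break
    assert swelled
    assert vs.V <= 20.0  # removal volume


def test_dead_cells_never_resume_cycle(rng):
    model = live_model(birth_rate=10.0)
    cell = _cell(model, death=DeathState(r_A=1e9))
    mode = check_death(cell, 6.0, rng)
    assert mode == MODE_APOPTOTIC
    start_apoptosis(cell, rng)
    assert cell.is_dead
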