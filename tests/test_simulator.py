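"""Main loop: clock cadence, serial queues, determinism, RNG streams."""

import numpy as np
import pytest

from multicell.cycle import live_model
from multicell.microenvironment import Mesh, MicroenvironmentField
from multicell.phenotype import default_phenotype
from multicell.simulator import Scheduler, Simulator, rng_streams
from multicell.errors import ConfigurationError


def _sim(seed=1, dt_diff=0.01, dt_mech=0.1, dt_cells=6.0, t_max=12.0,
         dt_save=1e9, substrate=None, shape=(5, 5, 5)):
    sub = substrate or {"name": "s", "D": 0.0, "lambda": 0.0, "initial": 1.0}
    field = MicroenvironmentField.create(Mesh((-50, -50, -50), shape, 20.0), [sub])
    sch = Scheduler(dt_diff=dt_diff, dt_mech=dt_mech, dt_cells=dt_cells,
                    dt_save=dt_save, t_max=t_max)
    return Simulator(field, sch, seed=seed)


def _add_plain_cell(sim, position=(0.0, 0.0, 0.0), cycle=None):
    ph = default_phenotype(1)
    ph.death = None
    ph.cycle = cycle
    return sim.add_cell(ph, position)


def test_zero_cells_pure_decay_matches_oracle():
    sim = _sim(substrate={"name": "s", "D": 0.0, "lambda": 0.1, "initial": 1.0},
               t_max=1.0)
    sim.run()
    n_steps = 100
    np.testing.assert_allclose(sim.field.rho,
                               (1.0 + 0.1 * 0.01) ** (-n_steps), rtol=1e-4)


def test_default_clock_cadence():
    """With default steps, cell processes run every 600 diffusion steps
    and mechanics every 10."""
    sim = _sim(t_max=12.0)
    cell = _add_plain_cell(sim)
    counts = {"phenotype": 0, "mech": 0}
    cell.update_phenotype = lambda c, f, dt: counts.__setitem__(
        "phenotype", counts["phenotype"] + 1)
    cell.custom_cell_rule = lambda c, s: counts.__setitem__(
        "mech", counts["mech"] + 1)
    sim.run()
    assert counts["phenotype"] == 2   # t = 6, 12 over 1200 diffusion steps
    assert counts["mech"] == 120


def test_scheduler_validation():
    with pytest.raises(ConfigurationError):
        Scheduler(dt_diff=-1.0)


def test_single_scheduled_division():
    """One cell with a fixed 60-min division edge: two cells by t=61,
    volumes halved, daughters placed symmetrically about the parent."""
    from multicell.cycle import CycleModel, CyclePhase, Transition

    model = CycleModel("div60", [CyclePhase("X", [
        Transition("X", 1.0 / 60.0, fixed_duration=True, division=True)])])
    sim = _sim(t_max=61.0)
    cell = _add_plain_cell(sim, cycle=model.new_state())
    parent_V = cell.volume
    sim.run()
    assert len(sim.population) == 2
    a, b = sim.population.cells
    assert a.volume + b.volume == pytest.approx(parent_V, rel=1e-12)
    assert a.id != b.id
    assert a in sim.grid and b in sim.grid


def test_division_placement_symmetric_about_parent():
    sim = _sim(t_max=1.0)
    cell = _add_plain_cell(sim, position=(3.0, -2.0, 1.0))
    parent_pos = cell.position.copy()
    parent_R = cell.radius
    cell.flagged_for_division = True
    sim.population.division_queue = [cell]
    sim.process_division_queue()
    a, b = sim.population.cells
    np.testing.assert_allclose(0.5 * (a.position + b.position), parent_pos,
                               atol=1e-12)
    sep = np.linalg.norm(a.position - b.position)
    assert sep == pytest.approx(parent_R / 2.0, rel=1e-9)


def test_ki67_division_leaves_both_daughters_in_K2():
    from multicell.cycle import ki67_advanced_model

    sim = _sim(t_max=7.0)
    model = ki67_advanced_model(fixed_durations=True)
    state = model.new_state("K1")
    state.time_in_phase = model.params.T_1  # due to divide this step
    cell = _add_plain_cell(sim, cycle=state)
    sim.run()
    assert len(sim.population) == 2
    for c in sim.population:
        assert c.phenotype.cycle.current_phase == "K2"


def test_removal_of_only_cell_empties_population_and_grid():
    sim = _sim(t_max=7.0)
    cell = _add_plain_cell(sim)
    cell.phenotype.death = None
    cell.flagged_for_removal = True
    sim.population.removal_queue = [cell]
    sim.process_removal_queue()
    assert len(sim.population) == 0
    assert cell not in sim.grid
    assert sim.grid.neighbor_candidates(cell) == []


def test_death_wins_over_division():
    sim = _sim(t_max=1.0)
    cell = _add_plain_cell(sim)
    cell.flagged_for_division = True
    cell.flagged_for_removal = True
    pop = sim.population
    pop.division_queue = [c for c in pop.cells
                          if c.flagged_for_division and not c.flagged_for_removal]
    pop.removal_queue = [c for c in pop.cells if c.flagged_for_removal]
    sim.process_division_queue()
    sim.process_removal_queue()
    assert len(pop) == 0


def test_same_seed_bit_identical_trajectories():
    def run():
        sim = _sim(seed=42, t_max=30.0)
        ph = default_phenotype(1)
        ph.death = None
        ph.cycle = live_model(0.01).new_state()
        ph.motility.enabled = True
        ph.motility.s_mot = 2.0
        ph.motility.T_per = 1.0
        for pos in ([0, 0, 0], [15, 0, 0], [0, 18, 0]):
            sim.add_cell(default_phenotype(1), pos).phenotype.motility = \
                ph.motility.copy()
        for c in sim.population:
            c.phenotype.death = None
            c.phenotype.motility.enabled = True
        sim.run()
        return np.array([c.position for c in sim.population])

    np.testing.assert_array_equal(run(), run())


def test_rng_streams_independent_and_reproducible():
    s1 = rng_streams(7)
    s2 = rng_streams(7)
    # consuming the motility stream leaves the cycle stream untouched
    s1["motility"].random(1000)
    np.testing.assert_array_equal(s1["cycle"].random(5), s2["cycle"].random(5))


def test_division_times_independent_of_motility_stream():
    """Mechanics-free check: cycle draws are identical whether or not
    the motility stream is consumed."""
    def division_count(motile):
        sim = _sim(seed=3, t_max=120.0)
        for i in range(10):
            ph = default_phenotype(1)
            ph.death = None
            ph.cycle = live_model(0.002).new_state()
            ph.motility.enabled = motile
            ph.motility.s_mot = 0.0  # no displacement even when 'motile'
            sim.add_cell(ph, (i * 40.0 - 180.0, 0.0, 0.0))
        sim.run()
        return len(sim.population)

    assert division_count(True) == division_count(False)


def test_first_snapshot_at_time_zero():
    sim = _sim(t_max=2.0, dt_save=1.0)
    saved = []
    sim.observers.append(lambda s: saved.append(s.scheduler.t))
    sim.run()
    assert saved[0] == 0.0
    assert len(saved) == 3  # t = 0, 1, 2


def test_cell_count_changes_only_via_queues():
    sim = _sim(seed=5, t_max=60.0)
    ph = default_phenotype(1)
    ph.death = None
    ph.cycle = live_model(0.05).new_state()
    sim.add_cell(ph, (0, 0, 0))
    counts = []
    orig_div = sim.process_division_queue

    def tracked():
        before = len(sim.population)
        orig_div()
        counts.append(len(sim.population) - before)

    sim.process_division_queue = tracked
    sim.run()
    assert len(sim.population) == 1 + sum(counts)
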