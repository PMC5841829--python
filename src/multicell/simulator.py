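"""Simulation orchestration: the three-clock main loop, serial
division/removal queues, and RNG stream management.

The loop advances three nested clocks: diffusive transport every
``dt_diff`` (default 0.01 min), cell movement every ``dt_mech``
(default 0.1 min), and cell processes -- phenotype updates, cycle,
death, volume -- every ``dt_cells`` (default 6 min).  Each iteration:

1. save the state if the save clock is due (the first snapshot is at
   t = 0);
2. update the microenvironment (bulk source/sinks, cell-centered
   source/sinks, diffusion-decay) for the frozen cell positions;
3. if due, run the cell processes per cell and then process the
   division and removal queues serially;
4. if due, update motility, compute all velocities against frozen
   positions, apply elastic attachments and custom rules, then move
   the cells (Adams-Bashforth) and refresh the interaction grid;
5. advance time by dt_diff.

Per-cell phenotype, cycle/death, volume and velocity computations are
independent given frozen shared state; structural mutations (division,
removal, position/grid updates) happen only in the serial phases, so
the per-cell loops are parallelizable in principle.  The reference
implementation is single-threaded and deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Optional

import numpy as np

from multicell import death as death_mod
from multicell import mechanics
from multicell.cell import Cell
from multicell.cycle import advance_cycle
from multicell.errors import ConfigurationError
from multicell.grid import InteractionGrid
from multicell.microenvironment import MicroenvironmentField

log = logging.getLogger(__name__)


def rng_streams(seed: Optional[int] = None) -> dict[str, np.random.Generator]:
    """Independent, reproducible generators per stochastic purpose.

    Separate streams for cycle/death draws, motility, initialization,
    and division placement mean that toggling one stochastic feature
    does not perturb the others.  ``None`` seeds from OS entropy (and
    logs the chosen seed).
    """
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.info("no seed given; using entropy seed %d", seed)
    children = np.random.SeedSequence(seed).spawn(5)
    names = ("cycle", "motility", "init", "placement", "contact")
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


@dataclass
class Scheduler:
    """The three time steps and their next-event times (all minutes)."""

    dt_diff: float = 0.01
    dt_mech: float = 0.1
    dt_cells: float = 6.0
    dt_save: float = 60.0
    t: float = 0.0
    t_max: float = 0.0
    t_mech: float = dataclass_field(init=False)
    t_cells: float = dataclass_field(init=False)
    t_save: float = dataclass_field(init=False)

    def __post_init__(self):
        if min(self.dt_diff, self.dt_mech, self.dt_cells) <= 0:
            raise ConfigurationError("time steps must be positive")
        if not (self.dt_diff <= self.dt_mech <= self.dt_cells):
            log.warning(
                "time steps violate dt_diff <= dt_mech <= dt_cells: %g, %g, %g",
                self.dt_diff, self.dt_mech, self.dt_cells)
        if self.dt_diff > self.dt_mech / 10.0 + 1e-12:
            log.warning("recommended dt_diff <= dt_mech/10; got %g vs %g",
                        self.dt_diff, self.dt_mech)
        self.t_mech = self.dt_mech
        self.t_cells = self.dt_cells
        self.t_save = 0.0

    def due(self, t_event: float) -> bool:
        # half-step slack avoids floating-point drift over ~1e6 steps
        return self.t >= t_event - 0.5 * self.dt_diff


class CellPopulation:
    """The live cell list plus serial division/removal queues."""

    def __init__(self):
        self.cells: list[Cell] = []
        self._next_id = 0
        self.division_queue: list[Cell] = []
        self.removal_queue: list[Cell] = []

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def new_cell(self, phenotype, position, type_name: str = "default") -> Cell:
        cell = Cell(self._next_id, phenotype, position, type_name)
        self._next_id += 1
        self.cells.append(cell)
        return cell

    def counts_by_phase(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.cells:
            if c.is_dead:
                key = c.phenotype.death.mode
            elif c.phenotype.cycle is not None:
                key = c.phenotype.cycle.current_phase
            else:
                key = "live"
            out[key] = out.get(key, 0) + 1
        return out


class Simulator:
    """Couples a cell population to a microenvironment field.

    Parameters
    ----------
    field : MicroenvironmentField
    scheduler : Scheduler
    seed : int, optional
        Seeds all RNG streams; same seed => bit-identical trajectories.
    bm : BasementMembrane, optional
    mechanics_voxel_edge : float
        Interaction-grid voxel edge (um); must be at least the maximum
        cell-cell interaction distance (asserted at startup).
    """

    def __init__(self, field: MicroenvironmentField, scheduler: Scheduler,
                 seed: Optional[int] = None, bm=None,
                 mechanics_voxel_edge: float = 30.0):
        self.field = field
        self.scheduler = scheduler
        self.rng = rng_streams(seed)
        self.bm = bm
        self.grid = InteractionGrid(mechanics_voxel_edge)
        self.population = CellPopulation()
        #: callables(sim) run at each save event
        self.observers: list[Callable] = []
        #: callable(sim, t) writing a snapshot, set by the CLI/IO layer
        self.snapshot_writer: Optional[Callable] = None
        self._max_interaction_checked = False
        # cached cell source/sink factors; valid while positions, volumes
        # and secretion rates are unchanged (i.e. between cell/mech phases)
        self._prepared_sources = None

    # ------------------------------------------------------------- population

    def add_cell(self, phenotype, position, type_name: str = "default") -> Cell:
        cell = self.population.new_cell(phenotype, position, type_name)
        self.grid.register(cell)
        return cell

    def _check_interaction_range(self) -> None:
        for cell in self.population:
            reach = 2.0 * cell.phenotype.max_adhesion_distance
            if reach > self.grid.edge + 1e-9:
                raise ConfigurationError(
                    f"mechanics voxel edge {self.grid.edge} um is below the "
                    f"maximum interaction distance {reach:.1f} um of cell {cell.id}")
        self._max_interaction_checked = True

    # ------------------------------------------------------------ cell phase

    def _cell_step(self, cell: Cell, dt: float) -> None:
        if cell.update_phenotype is not None:
            cell.update_phenotype(cell, self.field, dt)
        ds = cell.phenotype.death
        if ds is not None and not ds.dead:
            mode = death_mod.check_death(cell, dt, self.rng["cycle"])
            if mode == death_mod.MODE_APOPTOTIC:
                cell.detach_all()
                death_mod.start_apoptosis(cell, self.rng["cycle"])
            elif mode == death_mod.MODE_NECROTIC_SWELLING:
                cell.detach_all()
                death_mod.start_necrosis(cell)
        alive = ds is None or not ds.dead
        if alive and cell.phenotype.cycle is not None:
            for event in advance_cycle(cell, dt, self.rng["cycle"]):
                if event == ("division",):
                    cell.flagged_for_division = True
        cell.phenotype.volume.update(dt)
        if ds is not None and ds.dead:
            if death_mod.death_progress(cell, dt):
                cell.flagged_for_removal = True

    def run_cell_processes(self, dt: float) -> None:
        for cell in list(self.population.cells):
            self._cell_step(cell, dt)
        pop = self.population
        pop.division_queue = [c for c in pop.cells
                              if c.flagged_for_division and not c.flagged_for_removal]
        pop.removal_queue = [c for c in pop.cells if c.flagged_for_removal]
        self.process_division_queue()
        self.process_removal_queue()
        self._prepared_sources = None

    # ---------------------------------------------------------- serial queues

    def process_division_queue(self) -> None:
        """Each flagged parent spawns one daughter.  Both receive the
        halved (daughter) volume state and are placed symmetrically
        about the parent center, separated by half the parent radius
        along a uniformly random direction."""
        rng = self.rng["placement"]
        for parent in self.population.division_queue:
            parent.flagged_for_division = False
            radius = parent.phenotype.volume.radius
            direction = rng.standard_normal(3)
            nrm = np.linalg.norm(direction)
            direction = direction / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
            center = parent.position.copy()
            offset = 0.25 * radius * direction

            daughter_phenotype = parent.phenotype.copy()
            daughter_phenotype.volume = parent.phenotype.volume.divide()
            parent.phenotype.volume = parent.phenotype.volume.divide()
            if daughter_phenotype.cycle is not None:
                daughter_phenotype.cycle = parent.phenotype.cycle.copy()
                daughter_phenotype.cycle.time_in_phase = 0.0

            daughter = self.population.new_cell(
                daughter_phenotype, center + offset, parent.type_name)
            daughter.custom = dict(parent.custom)
            daughter.update_phenotype = parent.update_phenotype
            daughter.custom_cell_rule = parent.custom_cell_rule
            parent.position = center - offset
            # both daughters restart the velocity history (Euler bootstrap)
            parent.previous_velocity = None
            self.grid.update(parent)
            self.grid.register(daughter)
        self.population.division_queue = []

    def process_removal_queue(self) -> None:
        removed = {c.id for c in self.population.removal_queue}
        if not removed:
            self.population.removal_queue = []
            return
        for cell in self.population.removal_queue:
            cell.detach_all()
            self.grid.deregister(cell)
        self.population.cells = [c for c in self.population.cells
                                 if c.id not in removed]
        self.population.removal_queue = []

    # ------------------------------------------------------- mechanics phase

    def run_mechanics(self, dt: float) -> None:
        cells = self.population.cells
        if not cells:
            return
        if not self._max_interaction_checked:
            self._check_interaction_range()
        for cell in cells:
            mechanics.update_motility(cell, dt, self.rng["motility"], self.field)
        v = mechanics.compute_velocities(cells, bm=self.bm, grid_edge=self.grid.edge)
        for idx, cell in enumerate(cells):
            cell.velocity = v[idx]
        # custom per-cell rules and elastic attachments (serial, may mutate velocity)
        for cell in cells:
            if cell.custom_cell_rule is not None:
                cell.custom_cell_rule(cell, self)
            for link in cell.attachments:
                cell.velocity = cell.velocity + link.k * (
                    link.partner.position - cell.position)
        for cell in cells:
            mechanics.update_position(cell, dt)
            self.grid.update(cell)
        self._prepared_sources = None

    # -------------------------------------------------------------- main loop

    def save(self) -> None:
        if self.snapshot_writer is not None:
            self.snapshot_writer(self, self.scheduler.t)
        for obs in self.observers:
            obs(self)
        counts = self.population.counts_by_phase()
        if self.field.n_substrates:
            rho0 = self.field.rho[..., 0]
            log.info("t=%8.2f min  cells=%d  %s  substrate[0] min/mean/max = "
                     "%.3g/%.3g/%.3g", self.scheduler.t, len(self.population),
                     counts, rho0.min(), rho0.mean(), rho0.max())

    def run(self, t_max: Optional[float] = None) -> None:
        """Run the main loop until ``t_max`` (minutes)."""
        sch = self.scheduler
        if t_max is not None:
            sch.t_max = t_max
        if not self.population.cells and self.field is None:
            raise ConfigurationError("nothing to simulate")
        while sch.t < sch.t_max - 0.5 * sch.dt_diff:
            if sch.due(sch.t_save):
                self.save()
                sch.t_save += sch.dt_save
            if self._prepared_sources is None and self.population.cells:
                self._prepared_sources = self.field.prepare_cell_sources(
                    self.population.cells, sch.dt_diff)
            self.field.step(self.population.cells, sch.dt_diff,
                            prepared=self._prepared_sources)
            if sch.due(sch.t_cells):
                self.run_cell_processes(sch.dt_cells)
                sch.t_cells += sch.dt_cells
            if sch.due(sch.t_mech):
                self.run_mechanics(sch.dt_mech)
                sch.t_mech += sch.dt_mech
            sch.t += sch.dt_diff
        # events scheduled exactly at t_max still run (without a further
        # transport step), and the final state is saved
        if sch.due(sch.t_cells):
            self.run_cell_processes(sch.dt_cells)
            sch.t_cells += sch.dt_cells
        if sch.due(sch.t_mech):
            self.run_mechanics(sch.dt_mech)
            sch.t_mech += sch.dt_mech
        if sch.due(sch.t_save):
            self.save()
            sch.t_save += sch.dt_save
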