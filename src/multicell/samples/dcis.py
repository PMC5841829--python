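"""Ductal carcinoma in situ (DCIS), desk scale.

Tumor cells fill a breast duct represented as a 3-D "test tube"
(cylinder plus hemispherical cap) level-set membrane.  Oxygen diffuses
in from outside the duct (Dirichlet boundary on the domain faces),
cells adhere to each other and to the duct wall, cycle entry scales
with oxygenation, and an inner hypoxic core necroses.  The tumor
leading edge advances along the duct at a near-constant speed.

Scaled surrogate: a 0.25 mm duct segment seeded with a few hundred
cells (the published system is a 1 mm duct over 30 days reaching
~1 cm/year front speed).  ``build_dcis(full_scale=True)`` builds the
1 mm, 30-day configuration for the optional long-running check.
"""

from __future__ import annotations

import numpy as np

from multicell import reference
from multicell.fixtures import dcis_seed
from multicell.mechanics import TestTubeMembrane
from multicell.microenvironment import Mesh, MicroenvironmentField
from multicell.samples.common import (SCALED_OXYGEN_D,
                                      make_oxygen_phenotype_hook,
                                      oxygen_substrate)
from multicell.samples.spheroid import (UPTAKE, scaled_cycle_params,
                                        tumor_phenotype)
from multicell.simulator import Scheduler, Simulator

DUCT_RADIUS = 158.75  # um (317.5 um diameter duct)


def leading_edge(population) -> float:
    """Largest duct-axis coordinate among viable cells (um)."""
    xs = [c.position[0] for c in population if not c.is_dead]
    return float(max(xs)) if xs else float("nan")


def build_dcis(seed=None, n_cells: int = 250, duct_length: float = 250.0,
               necrosis: str = "stochastic", t_max: float = 24.0 * 60.0,
               uptake: float = UPTAKE, oxygen_D: float = SCALED_OXYGEN_D,
               dt_diff: float = 0.05,
               dt_save: float = 360.0, full_scale: bool = False):
    """Build the DCIS simulator (scaled by default)."""
    if full_scale:
        n_cells, duct_length, t_max = 1500, 1000.0, 30.0 * 24.0 * 60.0
        oxygen_D = reference.OXYGEN["D"]
    dx = 20.0
    pad = 3 * dx
    # duct along +x; cap at x = 0; domain paddings carry the oxygen boundary
    x_min, x_max = -pad - dx, duct_length + pad
    half_w = DUCT_RADIUS + pad
    nx = int(round((x_max - x_min) / dx))
    nyz = int(round(2 * half_w / dx))
    mesh = Mesh((x_min, -half_w, -half_w), (nx, nyz, nyz), dx)
    field = MicroenvironmentField.create(mesh, [oxygen_substrate(D=oxygen_D)])
    sch = Scheduler(dt_diff=dt_diff, dt_mech=0.1, dt_cells=6.0,
                    dt_save=dt_save, t_max=t_max)
    bm = TestTubeMembrane(DUCT_RADIUS, x_cap=0.0)
    sim = Simulator(field, sch, seed=seed, bm=bm,
                    mechanics_voxel_edge=reference.MECHANICS_VOXEL_EDGE)
    params = scaled_cycle_params(1.0 if full_scale else 6.0)
    hook = make_oxygen_phenotype_hook(params=params, necrosis_type=necrosis)
    fixture = dcis_seed(n_cells, DUCT_RADIUS, x_cap=0.0, seed=seed or 0)
    for pos in fixture.positions:
        ph = tumor_phenotype(1, necrosis, uptake, cycle_params=params)
        ph.mechanics.c_cba = reference.MECHANICS["c_cba"]
        cell = sim.add_cell(ph, pos, "tumor")
        cell.update_phenotype = hook
    return sim


def dcis_growth_rate(sim, sample_every: float = 360.0) -> tuple:
    """Run the simulator, tracking the leading edge; returns
    (times_min, edges_um, slope_um_per_min)."""
    times, edges = [], []

    def observer(s):
        times.append(s.scheduler.t)
        edges.append(leading_edge(s.population))

    sim.scheduler.dt_save = sample_every
    sim.observers.append(observer)
    sim.run()
    t = np.asarray(times)
    e = np.asarray(edges)
    n_late = max(3, len(t) // 2)
    slope = np.polyfit(t[-n_late:], e[-n_late:], 1)[0]
    return t, e, float(slope)
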