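"""Shared building blocks for the showcase models: oxygen-dependent
phenotype hooks, chemotaxis bias hooks, and contact testing."""

from __future__ import annotations

import math

import numpy as np

from multicell import reference
from multicell.cycle import Ki67AdvancedParams, ki67_Q_to_K1_rate
from multicell.death import stochastic_necrosis_rate
from multicell.microenvironment import Mesh, MicroenvironmentField
from multicell.simulator import Scheduler, Simulator


#: oxygen diffusion coefficient for desk-scale runs (um^2/min).  The
#: showcase geometries are ~1/6 of the published ones; shrinking space by
#: a factor s with D -> s^2 D preserves the diffusion profile on the
#: scaled geometry, so hypoxic cores appear at ~60-100 um spheroid radii.
SCALED_OXYGEN_D = 2.0e3


def oxygen_substrate(initial: float | None = None,
                     boundary: float | None = None,
                     D: float | None = None) -> dict:
    b = reference.OXYGEN["boundary_value"] if boundary is None else boundary
    return {
        "name": "oxygen", "units": "mmHg",
        "D": reference.OXYGEN["D"] if D is None else D,
        "lambda": reference.OXYGEN["lambda"],
        "initial": b if initial is None else initial,
        "boundary": {"type": "dirichlet", "value": b},
    }


def make_oxygen_phenotype_hook(params: Ki67AdvancedParams | None = None,
                               necrosis_type: str = "stochastic",
                               rate_scale_key: str | None = None,
                               base_birth_rate: float | None = None):
    """Phenotype-update hook linking the local oxygen tension to cycle
    entry and necrosis.

    For the Ki67-advanced model the Q -> K1 rate follows the clamped
    linear oxygen response; for the live model the birth rate is the
    same response scaled to ``base_birth_rate`` at reference oxygen,
    optionally multiplied by the cell's custom scalar
    ``rate_scale_key`` (the heterogeneity oncoprotein).
    """
    p = params or Ki67AdvancedParams(**reference.KI67_ADVANCED)

    def hook(cell, field, dt):
        pO2 = field.density_at(cell.position, "oxygen")
        cyc = cell.phenotype.cycle
        if cyc is not None:
            if cyc.model.name == "ki67_advanced":
                cyc.set_rate("Q", "K1", ki67_Q_to_K1_rate(pO2, p))
            elif cyc.model.name == "live":
                base = base_birth_rate if base_birth_rate is not None else 1.0 / p.T_Q_bar
                frac = max((pO2 - p.pO2_hypoxia) / (p.pO2_bar - p.pO2_hypoxia), 0.0)
                rate = base * frac
                if rate_scale_key is not None:
                    rate *= cell.custom.get(rate_scale_key, 1.0)
                cyc.set_rate("live", "live", rate)
        ds = cell.phenotype.death
        if ds is not None and not ds.dead:
            if necrosis_type == "deterministic":
                ds.r_N_death = math.inf if pO2 < ds.pO2_threshold else 0.0
            else:
                ds.r_N_death = stochastic_necrosis_rate(pO2, ds)

    return hook


def make_chemotaxis_bias_hook(substrate: str, b: float, direction: float = 1.0):
    """Motility bias hook: point d_bias along (or against, for
    ``direction=-1``) the local substrate gradient, with bias b."""

    def hook(cell, field):
        ms = cell.phenotype.motility
        g = direction * field.gradient_at(cell.position, substrate)
        norm = np.linalg.norm(g)
        if norm > 1e-30:
            ms.d_bias = g / norm
            ms.b = b
        else:
            ms.b = 0.0

    return hook


def in_contact(cell, other) -> bool:
    """Contact = center distance below the sum of radii."""
    d = np.linalg.norm(cell.position - other.position)
    return d < cell.phenotype.volume.radius + other.phenotype.volume.radius


def contacts(cell, sim) -> list:
    """Cells currently in contact with ``cell`` (grid-accelerated)."""
    return [c for c in sim.grid.neighbor_candidates(cell) if in_contact(cell, c)]


def cubic_simulator(side_um: float, substrates: list[dict], seed,
                    dt_diff: float = 0.05, dt_mech: float = 0.1,
                    dt_cells: float = 6.0, dt_save: float = 60.0,
                    t_max: float = 60.0, dx: float = 20.0, bm=None) -> Simulator:
    """Centered cubic domain helper used by the showcase builders.

    The showcase defaults use dt_diff = 0.05 min (stable for the
    backward-Euler solver; chosen over the 0.01 min reference value to
    keep desk-scale runs short).
    """
    n = int(round(side_um / dx))
    mesh = Mesh((-side_um / 2, -side_um / 2, -side_um / 2), (n, n, n), dx)
    field = MicroenvironmentField.create(mesh, substrates)
    sch = Scheduler(dt_diff=dt_diff, dt_mech=dt_mech, dt_cells=dt_cells,
                    dt_save=dt_save, t_max=t_max)
    return Simulator(field, sch, seed=seed, bm=bm,
                     mechanics_voxel_edge=reference.MECHANICS_VOXEL_EDGE)
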