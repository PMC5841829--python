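"""Cellular cargo-delivery system ("biorobots").

Three cell types interact through two diffusible chemoattractants:

* directors -- static; secrete attractant c1;
* cargo cells -- carry a surface receptor R in {0, 1}; while R = 1 they
  secrete attractant c2, and they stop when R = 0;
* workers -- motile.  Unadhered workers chemotax up grad(c2) and test
  for contact with cargo; on contact with an R = 1 cargo they form an
  elastic adhesion and set the cargo's R = 0.  Adhered workers chemotax
  up grad(c1) and release their cargo once c1 exceeds a threshold,
  then return for more -- completing repeated round trips.
"""

from __future__ import annotations

import numpy as np

from multicell import reference
from multicell.death import DeathState
from multicell.fixtures import sphere_packed_positions
from multicell.phenotype import (MechanicsParams, MotilityState, Phenotype,
                                 SecretionState)
from multicell.samples.common import contacts, cubic_simulator
from multicell.volume import equilibrium_volume_state

ELASTIC_K = 0.05          # 1/min, worker-cargo adhesion spring
C1_RELEASE_THRESHOLD = 0.10   # cargo released above this c1 (a.u.)
CARGO_SECRETION = 10.0    # 1/min while R = 1
DIRECTOR_SECRETION = 10.0


def elastic_attachment_velocity(cell_i, cell_j, k: float):
    """Velocity additions (v_i_add, v_j_add) of an elastic adhesion:
    k (x_j - x_i) on i and the opposite on j."""
    d = cell_j.position - cell_i.position
    return k * d, -k * d


def _plain_phenotype(n_substrates, motile=False, s_mot=4.0, T_per=5.0, b=0.75):
    return Phenotype(
        volume=equilibrium_volume_state(**reference.VOLUME_RATES),
        mechanics=MechanicsParams(**reference.MECHANICS),
        motility=MotilityState(enabled=motile, s_mot=s_mot, T_per=T_per, b=b),
        secretion=SecretionState.zeros(n_substrates),
        cycle=None,
        death=None,
    )


def cargo_phenotype_hook(cell, field, dt):
    """Cargo secrete c2 while their receptor R = 1."""
    s = field.substrate_index("c2")
    on = cell.custom.get("R", 0) >= 1
    cell.phenotype.secretion.secretion[s] = CARGO_SECRETION if on else 0.0
    cell.phenotype.secretion.saturation[s] = 1.0


def worker_bias_hook(cell, field):
    """Unadhered workers follow grad(c2) (seek cargo); adhered workers
    follow grad(c1) (seek directors).  Where the signal has no
    gradient the walk falls back to unbiased until the next redraw."""
    ms = cell.phenotype.motility
    target = "c1" if cell.attachments else "c2"
    g = field.gradient_at(cell.position, target)
    norm = np.linalg.norm(g)
    if norm > 1e-30:
        ms.d_bias = g / norm
        ms.b = cell.custom.get("b0", 0.75)
    else:
        ms.b = 0.0


def worker_cargo_rules(worker, cargo_contacts, field, dt) -> list[tuple]:
    """The worker-cargo state machine; returns emitted events.

    Unadhered + contact with R = 1 cargo: form the elastic link, set
    R = 0 (the cargo stops secreting c2).  Adhered + local c1 above the
    release threshold: break the bond (a delivery).
    """
    events = []
    if not worker.attachments:
        for cargo in cargo_contacts:
            if cargo.type_name == "cargo" and cargo.custom.get("R", 0) >= 1:
                worker.attach_to(cargo, ELASTIC_K)
                cargo.custom["R"] = 0
                worker.custom["pickups"] = worker.custom.get("pickups", 0) + 1
                events.append(("pickup", cargo.id))
                break
    else:
        c1 = field.density_at(worker.position, "c1")
        if c1 > C1_RELEASE_THRESHOLD:
            for link in list(worker.attachments):
                worker.detach_from(link.partner)
                events.append(("delivery", link.partner.id))
            worker.custom["deliveries"] = worker.custom.get("deliveries", 0) + 1
    return events


def _worker_rule(worker, sim):
    worker_cargo_rules(worker, contacts(worker, sim), sim.field,
                       sim.scheduler.dt_mech)


def build_biorobots(seed=None, n_directors: int = 8, n_cargo: int = 30,
                    n_workers: int = 4, side_um: float = 400.0,
                    t_max: float = 600.0, dt_save: float = 60.0):
    substrates = [
        {"name": "c1", "units": "a.u.", "D": 1000.0, "lambda": 0.1, "initial": 0.0},
        {"name": "c2", "units": "a.u.", "D": 1000.0, "lambda": 0.1, "initial": 0.0},
    ]
    sim = cubic_simulator(side_um, substrates, seed, t_max=t_max, dt_save=dt_save)
    rng = sim.rng["init"]

    for pos in sphere_packed_positions(n_directors, (-120.0, 0.0, 0.0), 18.0, rng):
        ph = _plain_phenotype(2)
        ph.secretion.secretion[0] = DIRECTOR_SECRETION
        ph.secretion.saturation[0] = 1.0
        sim.add_cell(ph, pos, "director")

    for pos in sphere_packed_positions(n_cargo, (120.0, 0.0, 0.0), 18.0, rng):
        cell = sim.add_cell(_plain_phenotype(2), pos, "cargo")
        cell.custom["R"] = 1
        cell.update_phenotype = cargo_phenotype_hook

    for pos in sphere_packed_positions(n_workers, (60.0, 0.0, 0.0), 20.0, rng):
        ph = _plain_phenotype(2, motile=True)
        ph.motility.update_bias_hook = worker_bias_hook
        cell = sim.add_cell(ph, pos, "worker")
        cell.custom["deliveries"] = 0
        cell.custom["pickups"] = 0
        cell.custom_cell_rule = _worker_rule
    return sim
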