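"""Tumor-immune interaction on the heterogeneous tumor.

Tumor cells secrete an immunostimulatory factor c; their mutant
oncoprotein expression p doubles as an immunogenicity marker.  Immune
cells perform a biased random walk (b = 0.5) up grad(c); on contact
they form an elastic adhesion with probability r_adhesion dt and stop
migrating.  While adhered they induce apoptosis with probability
r_kill p dt (then detach and resume their search) or detach anyway
with probability r_detach dt.

The example rates below are reference placeholders at desk scale (the
published study explored these rates in a large parameter sweep).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from multicell import reference
from multicell.death import start_apoptosis
from multicell.fixtures import sphere_packed_positions, spheroid_seed
from multicell.phenotype import (MechanicsParams, MotilityState, Phenotype,
                                 SecretionState)
from multicell.samples.biorobots import ELASTIC_K
from multicell.samples.common import (contacts, cubic_simulator,
                                      make_chemotaxis_bias_hook)
from multicell.samples.heterogeneity import draw_oncoprotein, live_tumor_phenotype
from multicell.volume import equilibrium_volume_state

IMMUNO_SECRETION = 10.0


@dataclass
class ImmuneParams:
    """Adhesion/kill/detach rates (1/min) and migration bias."""

    r_adhesion: float = 0.2
    r_kill: float = 1.0 / 15.0     # kill rate for a p = 1 target
    r_detach: float = 1.0 / 30.0
    b: float = 0.5

    def __post_init__(self):
        if min(self.r_adhesion, self.r_kill, self.r_detach) < 0:
            raise ValueError("immune rates must be nonnegative")


def immune_contact_rules(immune_cell, cell_contacts, dt: float, rng,
                         params: ImmuneParams) -> list[tuple]:
    """One step of the immune cell state machine; returns events.

    Unadhered: adhere to each contacted live tumor cell with
    probability r_adhesion dt (first success wins) and switch off
    motility.  Adhered: kill with probability r_kill p dt, then detach
    and resume the search; otherwise detach with probability
    r_detach dt.
    """
    events: list[tuple] = []
    ms = immune_cell.phenotype.motility
    if not immune_cell.attachments:
        for target in cell_contacts:
            if target.type_name != "tumor" or target.is_dead:
                continue
            if rng.random() < min(params.r_adhesion * dt, 1.0):
                immune_cell.attach_to(target, ELASTIC_K)
                ms.enabled = False
                events.append(("adhere", target.id))
                break
    else:
        target = immune_cell.attachments[0].partner
        p = np.clip(target.custom.get("p", 1.0), 0.0, 2.0)
        if not target.is_dead and rng.random() < min(params.r_kill * p * dt, 1.0):
            start_apoptosis(target, rng)
            immune_cell.detach_from(target)
            ms.enabled = True
            events.append(("kill", target.id))
        elif rng.random() < min(params.r_detach * dt, 1.0):
            immune_cell.detach_from(target)
            ms.enabled = True
            events.append(("detach", target.id))
    return events


def make_immune_rule(params: ImmuneParams):
    def rule(cell, sim):
        for event in immune_contact_rules(cell, contacts(cell, sim),
                                          sim.scheduler.dt_mech,
                                          sim.rng["contact"], params):
            if event[0] == "kill":
                cell.custom["kills"] = cell.custom.get("kills", 0) + 1

    return rule


def immune_phenotype(n_substrates: int, params: ImmuneParams) -> Phenotype:
    return Phenotype(
        volume=equilibrium_volume_state(**reference.VOLUME_RATES),
        mechanics=MechanicsParams(**reference.MECHANICS),
        motility=MotilityState(enabled=True, s_mot=4.0, T_per=5.0, b=params.b,
                               update_bias_hook=make_chemotaxis_bias_hook(
                                   "immuno", params.b)),
        secretion=SecretionState.zeros(n_substrates),
        cycle=None,
        death=None,
    )


def _tumor_hook(cell, field, dt):
    """Tumor cells secrete the immunostimulatory factor and divide at a
    p-proportional rate (no oxygen coupling in this reduced setting)."""
    s = field.substrate_index("immuno")
    cell.phenotype.secretion.secretion[s] = IMMUNO_SECRETION
    cell.phenotype.secretion.saturation[s] = 1.0
    from multicell.samples.heterogeneity import BASE_BIRTH_RATE, heterogeneity_rate_hook

    cell.phenotype.cycle.set_rate("live", "live",
                                  heterogeneity_rate_hook(cell, BASE_BIRTH_RATE))


def build_tumor_immune(seed=None, n_tumor: int = 200, n_immune: int = 40,
                       side_um: float = 500.0, t_max: float = 720.0,
                       params: ImmuneParams | None = None,
                       dt_save: float = 60.0):
    params = params or ImmuneParams()
    substrates = [
        {"name": "immuno", "units": "a.u.", "D": 1000.0, "lambda": 0.1,
         "initial": 0.0},
    ]
    sim = cubic_simulator(side_um, substrates, seed, t_max=t_max, dt_save=dt_save)
    p_values = draw_oncoprotein(sim.rng["init"], n_tumor)
    for pos, p in zip(spheroid_seed(n_tumor, seed=seed or 0).positions, p_values):
        cell = sim.add_cell(live_tumor_phenotype(1, uptake=0.0), pos, "tumor")
        cell.custom["p"] = float(p)
        cell.update_phenotype = _tumor_hook
    rule = make_immune_rule(params)
    for pos in sphere_packed_positions(n_immune, (side_um / 2 - 60.0, 0.0, 0.0),
                                       20.0, sim.rng["init"]):
        cell = sim.add_cell(immune_phenotype(1, params), pos, "immune")
        cell.custom_cell_rule = rule
    return sim
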