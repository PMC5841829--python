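"""Anti-cancer biorobots: hypoxia-homing cargo delivery of a drug.

No directors: the growing tumor consumes oxygen, and the hypoxic
gradient itself guides adhered workers (biased migration along
-grad(pO2)).  Cargo cells detach from their workers where
pO2 < pO2_drop and then secrete a diffusible therapeutic.  Tumor cells
accumulate drug-induced damage

    d[damage]/dt = r_damage [drug] - r_repair [damage]

and apoptose with probability r_death [damage] dt per cell step.
"""

from __future__ import annotations

import numpy as np

from multicell import reference
from multicell.cycle import Ki67AdvancedParams
from multicell.death import DeathState
from multicell.fixtures import spheroid_seed, worker_cargo_injection
from multicell.phenotype import SecretionState
from multicell.samples.biorobots import (ELASTIC_K, _plain_phenotype,
                                         cargo_phenotype_hook)
from multicell.samples.common import (SCALED_OXYGEN_D, contacts,
                                      cubic_simulator,
                                      make_oxygen_phenotype_hook,
                                      oxygen_substrate)
from multicell.samples.spheroid import UPTAKE
from multicell.volume import equilibrium_volume_state

PO2_DROP = 10.0            # mmHg; cargo release tension
C2_MOTILITY_THRESHOLD = 1e-4  # unadhered workers disable motility below this
DRUG_SECRETION = 10.0      # 1/min
#: damage model rates (1/min)
DAMAGE_RATES = {"r_damage": 0.03, "r_repair": 0.004, "r_death": 0.004}


def update_damage(damage: float, drug: float, dt: float,
                  r_damage: float = DAMAGE_RATES["r_damage"],
                  r_repair: float = DAMAGE_RATES["r_repair"],
                  r_death: float = DAMAGE_RATES["r_death"]) -> tuple[float, float]:
    """One forward-Euler step of the damage ODE; returns
    (new_damage, apoptosis probability over dt, clamped to [0, 1])."""
    new_damage = damage + dt * (r_damage * drug - r_repair * damage)
    new_damage = max(new_damage, 0.0)
    prob = min(max(r_death * new_damage * dt, 0.0), 1.0)
    return new_damage, prob


def make_tumor_damage_hook(oxygen_hook):
    """Tumor phenotype hook: oxygen response plus drug damage.

    The damage-driven kill probability r_death*[damage]*dt enters as an
    addition to the cell's apoptosis rate (1 - exp(-r dt) ~ r dt), so
    the standard death machinery performs the draw.
    """
    base_r_A = reference.DEATH["apoptosis_rate"]

    def hook(cell, field, dt):
        oxygen_hook(cell, field, dt)
        drug = field.density_at(cell.position, "drug")
        damage, _prob = update_damage(cell.custom.get("damage", 0.0), drug, dt)
        cell.custom["damage"] = damage
        cell.phenotype.death.r_A = base_r_A + DAMAGE_RATES["r_death"] * damage

    return hook


def make_cargo_drop_hook(pO2_drop: float = PO2_DROP):
    """Cargo rule: secrete c2 while R = 1; when adhered (being carried)
    and pO2 < pO2_drop, detach from the worker and secrete the drug."""

    def hook(cell, field, dt):
        cargo_phenotype_hook(cell, field, dt)
        if cell.custom.get("dropped"):
            return
        if cell.attachments:
            pO2 = field.density_at(cell.position, "oxygen")
            if pO2 < pO2_drop:
                cell.detach_all()
                cell.custom["dropped"] = True
                s = field.substrate_index("drug")
                cell.phenotype.secretion.secretion[s] = DRUG_SECRETION
                cell.phenotype.secretion.saturation[s] = 1.0

    return hook


def worker_hypoxia_bias_hook(cell, field):
    """Adhered workers home along -grad(pO2); unadhered workers seek
    cargo along +grad(c2), pausing where the cargo signal is absent."""
    ms = cell.phenotype.motility
    if cell.attachments:
        g = -field.gradient_at(cell.position, "oxygen")
    else:
        c2 = field.density_at(cell.position, "c2")
        if c2 < C2_MOTILITY_THRESHOLD:
            ms.s_mot = 0.0
            return
        ms.s_mot = cell.custom.get("s_mot0", 4.0)
        g = field.gradient_at(cell.position, "c2")
    norm = np.linalg.norm(g)
    if norm > 1e-30:
        ms.d_bias = g / norm
        ms.b = cell.custom.get("b0", 0.75)
    else:
        ms.b = 0.0


def _worker_pickup_rule(worker, sim):
    if worker.attachments:
        return
    for cargo in contacts(worker, sim):
        if cargo.type_name == "cargo" and cargo.custom.get("R", 0) >= 1 \
                and not cargo.custom.get("dropped"):
            worker.attach_to(cargo, ELASTIC_K)
            cargo.custom["R"] = 0
            break


def build_anticancer_biorobots(seed=None, n_tumor: int = 250,
                               n_injection: int = 60, side_um: float = 600.0,
                               t_max: float = 720.0, pO2_drop: float = PO2_DROP,
                               dt_save: float = 60.0):
    substrates = [
        oxygen_substrate(D=SCALED_OXYGEN_D),
        {"name": "c2", "units": "a.u.", "D": 1000.0, "lambda": 0.1, "initial": 0.0},
        {"name": "drug", "units": "a.u.", "D": 1.0e4, "lambda": 0.05, "initial": 0.0},
    ]
    sim = cubic_simulator(side_um, substrates, seed, t_max=t_max, dt_save=dt_save)
    rng = sim.rng["init"]

    from multicell.samples.heterogeneity import live_tumor_phenotype

    oxygen_hook = make_oxygen_phenotype_hook(necrosis_type="stochastic",
                                             base_birth_rate=1.0 / (18.0 * 60.0))
    tumor_hook = make_tumor_damage_hook(oxygen_hook)
    for pos in spheroid_seed(n_tumor, seed=(seed or 0) + 17).positions:
        cell = sim.add_cell(live_tumor_phenotype(3, uptake=UPTAKE), pos, "tumor")
        cell.custom["damage"] = 0.0
        cell.update_phenotype = tumor_hook

    inj = worker_cargo_injection(n_injection, (side_um / 2 - 80.0, 0.0, 0.0),
                                 seed=seed or 0)
    drop_hook = make_cargo_drop_hook(pO2_drop)
    for pos, kind in zip(inj.positions, inj.types):
        if kind == "worker":
            ph = _plain_phenotype(3, motile=True)
            ph.motility.update_bias_hook = worker_hypoxia_bias_hook
            cell = sim.add_cell(ph, pos, "worker")
            cell.custom["s_mot0"] = ph.motility.s_mot
            cell.custom_cell_rule = _worker_pickup_rule
        else:
            cell = sim.add_cell(_plain_phenotype(3), pos, "cargo")
            cell.custom["R"] = 1
            cell.update_phenotype = drop_hook
    return sim
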