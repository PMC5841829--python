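"""Tumor heterogeneity: selection on a mutant oncoprotein.

Each tumor cell carries a dimensionless oncoprotein expression
p in [0, 2], initially Normal(1, 0.3) clipped to the bounds and
inherited by daughters.  The rate of cycle entry (live-cell model)
scales proportionally to p on top of the oxygen response, so
better-expressing clones divide faster and the population mean of p
rises -- selection visible within a few simulated days.
"""

from __future__ import annotations

import numpy as np

from multicell import reference
from multicell.cycle import live_model
from multicell.death import DeathState
from multicell.fixtures import spheroid_seed
from multicell.phenotype import (MechanicsParams, MotilityState, Phenotype,
                                 SecretionState)
from multicell.samples.common import (SCALED_OXYGEN_D, cubic_simulator,
                                      make_oxygen_phenotype_hook,
                                      oxygen_substrate)
from multicell.samples.spheroid import UPTAKE
from multicell.volume import equilibrium_volume_state

ONCOPROTEIN_MEAN = 1.0
ONCOPROTEIN_SD = 0.3
#: birth rate of a p = 1 cell at reference oxygen (1/min; ~18 h cycle)
BASE_BIRTH_RATE = 1.0 / (18.0 * 60.0)


def draw_oncoprotein(rng, n: int) -> np.ndarray:
    """Initial oncoprotein expression: Normal(1, 0.3) clipped to [0, 2]."""
    return np.clip(rng.normal(ONCOPROTEIN_MEAN, ONCOPROTEIN_SD, size=n), 0.0, 2.0)


def heterogeneity_rate_hook(cell, base_rate: float) -> float:
    """Live-model birth rate proportional to the cell's oncoprotein."""
    return np.clip(cell.custom.get("p", 1.0), 0.0, 2.0) * base_rate


def live_tumor_phenotype(n_substrates: int = 1,
                         uptake: float = UPTAKE) -> Phenotype:
    secretion = SecretionState.zeros(n_substrates)
    secretion.uptake[0] = uptake
    return Phenotype(
        volume=equilibrium_volume_state(**reference.VOLUME_RATES),
        mechanics=MechanicsParams(**reference.MECHANICS),
        motility=MotilityState(enabled=False),
        secretion=secretion,
        cycle=live_model(BASE_BIRTH_RATE).new_state(),
        death=DeathState(
            r_A=reference.DEATH["apoptosis_rate"],
            T_A=reference.DEATH["T_A"],
            pO2_threshold=reference.DEATH["pO2_threshold"],
            pO2_crit=reference.DEATH["pO2_crit"],
            r_N_max=reference.DEATH["r_N_max"],
            necrosis_type="stochastic",
        ),
    )


def build_heterogeneity(seed=None, n_cells: int = 250, side_um: float = 600.0,
                        t_max: float = 48.0 * 60.0, uptake: float = UPTAKE,
                        oxygen_D: float = SCALED_OXYGEN_D, dt_save: float = 360.0):
    sim = cubic_simulator(side_um, [oxygen_substrate(D=oxygen_D)], seed,
                          t_max=t_max, dt_save=dt_save)
    hook = make_oxygen_phenotype_hook(rate_scale_key="p",
                                      base_birth_rate=BASE_BIRTH_RATE)
    p_values = draw_oncoprotein(sim.rng["init"], n_cells)
    for pos, p in zip(spheroid_seed(n_cells, seed=seed or 0).positions, p_values):
        cell = sim.add_cell(live_tumor_phenotype(1, uptake), pos, "tumor")
        cell.custom["p"] = float(p)
        cell.update_phenotype = hook
    return sim
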