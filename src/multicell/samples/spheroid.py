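"""Hanging-drop tumor spheroid, desk scale.

A seeded cluster of Ki67-advanced cycling cells grows in a physioxic
(38 mmHg Dirichlet boundary) domain while consuming oxygen.  Hypoxic
gradients limit cycle entry to the outer shell, an anoxic core
necroses, and the diameter grows linearly at late times.

Scaled surrogate: a few hundred seed cells in a sub-millimeter domain
(the published system starts from ~2300 cells in 8 mm^3 and reaches
~1e6 cells).  Space is scaled down by a factor ~6 with the oxygen
diffusion coefficient scaled as the square of that factor, which
preserves the shape of the oxygen profile, so hypoxia and necrosis
appear at ~60-100 um spheroid radii instead of several hundred um.
"""

from __future__ import annotations

from multicell import reference
from multicell.cycle import Ki67AdvancedParams, ki67_advanced_model
from multicell.death import DeathState
from multicell.fixtures import spheroid_seed
from multicell.phenotype import (MechanicsParams, MotilityState, Phenotype,
                                 SecretionState)
from multicell.samples.common import (SCALED_OXYGEN_D, cubic_simulator,
                                      make_oxygen_phenotype_hook,
                                      oxygen_substrate)
from multicell.volume import equilibrium_volume_state

#: per-cell oxygen uptake rate (1/min), reference value
UPTAKE = reference.OXYGEN["uptake_rate"]
SCALED_UPTAKE = UPTAKE  # kept as an alias for the scaled builders

#: time scale-down of the cell cycle for desk-scale runs.  The published
#: growth curves span ~18 days; compressing the cycle durations by this
#: factor reproduces the same growth regimes (rim-limited, then linear)
#: within a 1-2 day simulated window.
SCALED_CYCLE_TIME_FACTOR = 6.0


def scaled_cycle_params(factor: float = SCALED_CYCLE_TIME_FACTOR) -> Ki67AdvancedParams:
    ref = reference.KI67_ADVANCED
    return Ki67AdvancedParams(
        T_1=ref["T_1"] / factor, T_2=ref["T_2"] / factor,
        T_Q_bar=ref["T_Q_bar"] / factor,
        pO2_hypoxia=ref["pO2_hypoxia"], pO2_bar=ref["pO2_bar"],
    )


def tumor_phenotype(n_substrates: int = 1, necrosis: str = "stochastic",
                    uptake: float = SCALED_UPTAKE,
                    cycle_params: Ki67AdvancedParams | None = None) -> Phenotype:
    secretion = SecretionState.zeros(n_substrates)
    secretion.uptake[0] = uptake
    params = cycle_params or Ki67AdvancedParams(**reference.KI67_ADVANCED)
    return Phenotype(
        volume=equilibrium_volume_state(**reference.VOLUME_RATES),
        mechanics=MechanicsParams(**reference.MECHANICS),
        motility=MotilityState(enabled=False),
        secretion=secretion,
        cycle=ki67_advanced_model(params, fixed_durations=True).new_state(),
        death=DeathState(
            r_A=reference.DEATH["apoptosis_rate"],
            T_A=reference.DEATH["T_A"],
            pO2_threshold=reference.DEATH["pO2_threshold"],
            pO2_crit=reference.DEATH["pO2_crit"],
            r_N_max=reference.DEATH["r_N_max"],
            necrosis_type=necrosis,
        ),
    )


def build_spheroid(seed=None, n_cells: int = 300, side_um: float = 600.0,
                   necrosis: str = "stochastic", t_max: float = 48.0 * 60.0,
                   uptake: float = UPTAKE, oxygen_D: float = SCALED_OXYGEN_D,
                   cycle_time_factor: float = SCALED_CYCLE_TIME_FACTOR,
                   dt_diff: float = 0.05, dt_save: float = 360.0):
    """Build the scaled hanging-drop spheroid simulator."""
    sim = cubic_simulator(side_um, [oxygen_substrate(D=oxygen_D)], seed,
                          dt_diff=dt_diff, t_max=t_max, dt_save=dt_save)
    params = scaled_cycle_params(cycle_time_factor)
    hook = make_oxygen_phenotype_hook(params=params, necrosis_type=necrosis)
    fixture = spheroid_seed(n_cells, seed=seed or 0)
    for pos in fixture.positions:
        cell = sim.add_cell(
            tumor_phenotype(1, necrosis, uptake, cycle_params=params), pos, "tumor")
        cell.update_phenotype = hook
    return sim
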