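"""Cell death processes: apoptosis and (deterministic or stochastic) necrosis.

Each live cell carries an apoptosis rate r_A and a necrosis rate r_N
that may be updated continually (e.g. from local oxygenation).  Over a
step dt the cell enters a death state with probability 1 - exp(-r dt).

Apoptosis shrinks the cell: the cytoplasmic:nuclear target, nuclear
solid target and fluid-fraction target are all set to zero and the
volume relaxation rates switched to apoptotic time scales; the cell is
removed once its volume falls below the removal threshold or after the
apoptosis duration T_A elapses.  Necrosis first swells the cell
(oncosis, target fluid fraction 1); once the volume passes the rupture
threshold the cell lyses (fluid target 0) and shrinks until removal at
V <= 20 um^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from multicell.errors import ConfigurationError

MODE_NONE = "none"
MODE_APOPTOTIC = "apoptotic"
MODE_NECROTIC_SWELLING = "necrotic_swelling"
MODE_NECROTIC_LYSED = "necrotic_lysed"

#: volume relaxation rates during apoptosis (1/min)
APOPTOSIS_RATES = {"r_F": 3.0 / 60.0, "r_C": 1.0 / 60.0, "r_N": 0.35 / 60.0}
#: volume relaxation rates during necrotic swelling (1/min)
NECROSIS_SWELLING_RATES = {"r_F": 0.67 / 60.0, "r_C": 0.0032 / 60.0, "r_N": 0.013 / 60.0}
#: fluid loss rate after lysis (1/min)
NECROSIS_LYSED_FLUID_RATE = 0.05 / 60.0


@dataclass
class DeathState:
    """Death rates, mode, and the oxygen thresholds of the necrosis ramp."""

    r_A: float = 5.31667e-05          # apoptosis trigger rate (1/min)
    r_N_death: float = 0.0            # current necrosis trigger rate (1/min)
    mode: str = MODE_NONE
    T_A: float = 8.6 * 60.0           # mean apoptosis duration (min)
    pO2_threshold: float = 5.0        # mmHg; necrosis begins below this
    pO2_crit: float = 2.5             # mmHg; necrosis rate saturates below this
    r_N_max: float = 1.0 / 360.0      # saturated necrosis rate (1/min)
    necrosis_type: str = "stochastic"  # or "deterministic"
    stochastic_apoptosis_duration: bool = False
    #: set when a death process starts
    time_in_death: float = 0.0
    apoptosis_duration: float = 0.0
    #: whether dead cells keep exchanging substrates (see methods note)
    secrete_when_dead: bool = False

    def __post_init__(self):
        if min(self.r_A, self.r_N_death, self.r_N_max) < 0:
            raise ConfigurationError("death rates must be nonnegative")
        if self.pO2_crit >= self.pO2_threshold:
            raise ConfigurationError("pO2_crit must be below pO2_threshold")

    @property
    def dead(self) -> bool:
        return self.mode != MODE_NONE


def death_probability(rate: float, dt: float) -> float:
    """Probability of a death trigger over [t, t+dt]: 1 - exp(-r dt)."""
    if rate <= 0:
        return 0.0
    return 1.0 - math.exp(-rate * dt)


def stochastic_necrosis_rate(pO2: float, ds: DeathState) -> float:
    """Oxygen-dependent necrosis trigger rate (1/min): zero above the
    threshold, ramping linearly to the saturated maximum at/below the
    critical tension."""
    if pO2 > ds.pO2_threshold:
        return 0.0
    if pO2 <= ds.pO2_crit:
        return ds.r_N_max
    return ds.r_N_max * (ds.pO2_threshold - pO2) / (ds.pO2_threshold - ds.pO2_crit)


def check_death(cell, dt: float, rng) -> str | None:
    """Test the active death rates over one step; returns the death mode
    triggered (or None).  If both apoptosis and necrosis fire in the
    same step, apoptosis takes precedence."""
    ds: DeathState = cell.phenotype.death
    if ds.dead:
        return None
    if rng.random() < death_probability(ds.r_A, dt):
        return MODE_APOPTOTIC
    if rng.random() < death_probability(ds.r_N_death, dt):
        return MODE_NECROTIC_SWELLING
    return None


def start_apoptosis(cell, rng=None) -> None:
    """Switch the cell into the apoptotic state.

    Targets: f_CN = 0 (cytoplasmic blebbing), V_NS* = 0 (nuclear
    degradation), f_F = 0 (water elimination); relaxation rates move to
    apoptotic time scales; secretion stops; the cycle halts.
    """
    ds: DeathState = cell.phenotype.death
    vs = cell.phenotype.volume
    vs.f_CN = 0.0
    vs.V_NS_star = 0.0
    vs.f_F = 0.0
    vs.r_F = APOPTOSIS_RATES["r_F"]
    vs.r_C = APOPTOSIS_RATES["r_C"]
    vs.r_N = APOPTOSIS_RATES["r_N"]
    ds.mode = MODE_APOPTOTIC
    ds.time_in_death = 0.0
    if ds.stochastic_apoptosis_duration and rng is not None:
        ds.apoptosis_duration = rng.exponential(ds.T_A)
    else:
        ds.apoptosis_duration = ds.T_A
    cell.phenotype.secretion.secretion[:] = 0.0
    if not ds.secrete_when_dead:
        cell.phenotype.secretion.uptake[:] = 0.0


def start_necrosis(cell) -> None:
    """Switch the cell into the necrotic (oncotic swelling) state:
    f_CN = V_NS* = 0, target fluid fraction 1, necrotic time scales."""
    ds: DeathState = cell.phenotype.death
    vs = cell.phenotype.volume
    vs.f_CN = 0.0
    vs.V_NS_star = 0.0
    vs.f_F = 1.0
    vs.r_F = NECROSIS_SWELLING_RATES["r_F"]
    vs.r_C = NECROSIS_SWELLING_RATES["r_C"]
    vs.r_N = NECROSIS_SWELLING_RATES["r_N"]
    ds.mode = MODE_NECROTIC_SWELLING
    ds.time_in_death = 0.0
    cell.phenotype.secretion.secretion[:] = 0.0


def death_progress(cell, dt: float) -> bool:
    """Advance the death bookkeeping by one cell step; returns True when
    the cell should be flagged for removal.

    Necrotic swelling flips (once) to the lysed state when the volume
    passes the rupture threshold; lysed cells stop oxygen uptake (the
    membrane is gone) and drain fluid until the removal volume.
    """
    ds: DeathState = cell.phenotype.death
    vs = cell.phenotype.volume
    if not ds.dead:
        return False
    ds.time_in_death += dt
    if ds.mode == MODE_APOPTOTIC:
        return vs.V < vs.removal_volume or ds.time_in_death >= ds.apoptosis_duration
    if ds.mode == MODE_NECROTIC_SWELLING:
        if vs.V >= vs.rupture_volume:
            ds.mode = MODE_NECROTIC_LYSED
            vs.f_F = 0.0
            vs.r_F = NECROSIS_LYSED_FLUID_RATE
            if not ds.secrete_when_dead:
                cell.phenotype.secretion.uptake[:] = 0.0
        return False
    # lysed
    return vs.V <= vs.removal_volume
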