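"""Cell volume regulation: relaxation of fluid and solid sub-volumes.

Each cell partitions its total volume V into fluid V_F and solid
V_S = V_NS + V_CS (nuclear and cytoplasmic solids).  The sub-volumes
relax toward phenotype-controlled targets:

    dV_F/dt  = r_F (f_F * V    - V_F)
    dV_NS/dt = r_N (V_NS*      - V_NS)
    dV_CS/dt = r_C (f_CN V_NS* - V_CS)

where f_F is the target fluid fraction, V_NS* the target nuclear solid
volume and f_CN the target cytoplasmic:nuclear solid ratio.  The ODEs
are integrated with forward Euler (targets evaluated at the start of
the step).  Cycle and death processes steer the cell by moving the
targets: V_NS* halves at division and doubles at cycle re-entry;
apoptosis zeroes all targets; necrotic swelling sets f_F = 1 until
lysis.  All volumes in um^3, rates in 1/min.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from multicell.errors import ConfigurationError

log = logging.getLogger(__name__)

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def radius_of_volume(volume: float) -> float:
    """Radius of the sphere with the given volume: (3V / 4 pi)^(1/3)."""
    return (volume / _FOUR_THIRDS_PI) ** (1.0 / 3.0)


@dataclass
class VolumeState:
    """Instantaneous sub-volumes, their targets, and relaxation rates.

    The bookkeeping identities ``V = V_F + V_NS + V_CS`` and
    ``V = V_N + V_C`` hold after every update.  The nuclear/cytoplasmic
    split of the fluid compartment is proportional, so both compartments
    share the cell-wide instantaneous fluid fraction.
    """

    V: float
    V_F: float
    V_NS: float
    V_CS: float
    V_N: float = 0.0
    V_C: float = 0.0
    # relaxation rates (1/min)
    r_F: float = 0.05
    r_N: float = 0.0055
    r_C: float = 0.0045
    # targets
    f_F: float = 0.75
    f_CN: float = 3.6
    V_NS_star: float = 135.0
    # thresholds
    rupture_volume_rel: float = 2.0
    removal_volume: float = 20.0
    #: mature total volume, fixed at construction; rupture threshold reference
    V_mature: float = 2494.0

    def __post_init__(self):
        if min(self.r_F, self.r_N, self.r_C) < 0:
            raise ConfigurationError("volume relaxation rates must be nonnegative")
        self._partition()

    # -------------------------------------------------------------- derived

    def _partition(self) -> None:
        """Recompute V, V_N, V_C from the independent sub-volumes."""
        self.V = self.V_F + self.V_NS + self.V_CS
        if self.V > 0:
            fluid_frac = self.V_F / self.V
        else:
            fluid_frac = 0.0
        # nuclear compartment carries its solids plus a proportional fluid share
        if fluid_frac < 1.0:
            self.V_N = self.V_NS / (1.0 - fluid_frac) if self.V_NS > 0 else 0.0
        else:
            self.V_N = self.V_NS
        self.V_C = self.V - self.V_N

    @property
    def radius(self) -> float:
        return radius_of_volume(self.V)

    @property
    def nuclear_radius(self) -> float:
        return radius_of_volume(self.V_N)

    @property
    def surface_area(self) -> float:
        r = self.radius
        return 4.0 * math.pi * r * r

    @property
    def rupture_volume(self) -> float:
        return self.rupture_volume_rel * self.V_mature

    def derived_geometry(self) -> tuple[float, float, float]:
        """(radius, nuclear radius, surface area), spherical convention."""
        return self.radius, self.nuclear_radius, self.surface_area

    # -------------------------------------------------------------- updates

    def update(self, dt: float) -> "VolumeState":
        """One forward-Euler step of the three relaxation ODEs (in place).

        Targets are evaluated at the start of the step.  A large dt that
        overshoots below zero is clamped at zero with a warning.
        """
        if dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {dt}")
        dVF = self.r_F * (self.f_F * self.V - self.V_F)
        dVNS = self.r_N * (self.V_NS_star - self.V_NS)
        dVCS = self.r_C * (self.f_CN * self.V_NS_star - self.V_CS)
        self.V_F += dt * dVF
        self.V_NS += dt * dVNS
        self.V_CS += dt * dVCS
        for name in ("V_F", "V_NS", "V_CS"):
            if getattr(self, name) < 0:
                log.warning("volume overshoot: %s clamped to 0 (dt=%g)", name, dt)
                setattr(self, name, 0.0)
        self._partition()
        return self

    def divide(self) -> "VolumeState":
        """Daughter volume state: V_NS* and every sub-volume halved."""
        daughter = replace(
            self,
            V_F=self.V_F / 2.0,
            V_NS=self.V_NS / 2.0,
            V_CS=self.V_CS / 2.0,
            V_NS_star=self.V_NS_star / 2.0,
        )
        daughter._partition()
        return daughter

    def on_cycle_reentry(self) -> "VolumeState":
        """Double the nuclear solid target on re-entry to a pre-mitotic
        phase (the cell grows toward doubled nuclear content)."""
        self.V_NS_star *= 2.0
        return self

    def exact_solution(self, t: float) -> "VolumeState":
        """Closed-form solution of the linear ODE system at time ``t``
        from the current state, for constant targets.

        V_NS and V_CS relax independently toward constant targets.  The
        (V, V_F) pair is linear with a time-varying forcing from the
        solids; substituting V = V_F + V_S(t) gives a scalar linear ODE
        for V_F with exponential forcing, solved exactly here.  Used as
        an oracle for convergence testing.
        """
        vns_inf = self.V_NS_star
        vcs_inf = self.f_CN * self.V_NS_star
        e_n = math.exp(-self.r_N * t)
        e_c = math.exp(-self.r_C * t)
        V_NS = vns_inf + (self.V_NS - vns_inf) * e_n
        V_CS = vcs_inf + (self.V_CS - vcs_inf) * e_c

        # dV_F/dt = rF*fF*(V_NS(t)+V_CS(t)) - rF*(1-fF)*V_F
        k = self.r_F * (1.0 - self.f_F)
        a = self.r_F * self.f_F

        def forced(c0, cinf, rate, e_rt):
            # integral contribution of cinf + (c0-cinf) e^{-rate t} under decay k
            if abs(k) < 1e-300:
                raise ConfigurationError("f_F = 1 with r_F > 0 has no finite fixed point")
            const = cinf / k * (1.0 - math.exp(-k * t))
            if abs(k - rate) < 1e-12 * max(abs(k), 1.0):
                trans = (c0 - cinf) * t * math.exp(-k * t)
            else:
                trans = (c0 - cinf) * (e_rt - math.exp(-k * t)) / (k - rate)
            return const + trans

        if k == 0.0:
            # f_F == 1: pure growth of fluid toward total volume; integrate directly
            integral = (vns_inf + vcs_inf) * t
            integral += (self.V_NS - vns_inf) * (1.0 - e_n) / self.r_N if self.r_N else 0.0
            integral += (self.V_CS - vcs_inf) * (1.0 - e_c) / self.r_C if self.r_C else 0.0
            V_F = self.V_F + a * integral
        else:
            V_F = self.V_F * math.exp(-k * t) + a * (
                forced(self.V_NS, vns_inf, self.r_N, e_n)
                + forced(self.V_CS, vcs_inf, self.r_C, e_c)
            )
        out = replace(self, V_F=V_F, V_NS=V_NS, V_CS=V_CS)
        out._partition()
        return out


def equilibrium_volume_state(
    V_mature: float = 2494.0,
    f_F: float = 0.75,
    V_NS_star: float = 135.0,
    **overrides,
) -> VolumeState:
    """Volume state at its fixed point for the given mature volume.

    The cytoplasmic:nuclear solid target ratio is derived from
    consistency: solids = (1 - f_F) V, V_CS = solids - V_NS*.
    """
    solids = (1.0 - f_F) * V_mature
    V_NS = V_NS_star
    V_CS = solids - V_NS
    if V_CS <= 0:
        raise ConfigurationError("V_NS_star exceeds total solid volume")
    f_CN = V_CS / V_NS
    return VolumeState(
        V=V_mature,
        V_F=f_F * V_mature,
        V_NS=V_NS,
        V_CS=V_CS,
        f_F=f_F,
        f_CN=f_CN,
        V_NS_star=V_NS_star,
        V_mature=V_mature,
        **overrides,
    )
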