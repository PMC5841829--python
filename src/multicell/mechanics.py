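"""Cell mechanics and motion: interaction potentials, basement-membrane
forces, motility, and the Adams-Bashforth position update.

Velocities follow from an inertialess force balance.  Cell-cell
adhesion and repulsion act through finite-range potentials; for a
separation vector x with ||x|| = s the gradient forms used are

    grad phi_{n,R}(x)  =  (1 - s/R)^(n+1) x_hat      (adhesion,  s <= R)
    grad psi_{n,R}(x)  = -(1 - s/R)^(n+1) x_hat      (repulsion, s <= R)

and zero beyond R, with smoothness exponent n (default 1).  The
velocity contribution of cell j on cell i is

    - sqrt(c_cca_i c_cca_j) grad phi_{n, R_iA + R_jA}(x_i - x_j)
    - sqrt(c_ccr_i c_ccr_j) grad psi_{n, R_i + R_j}(x_i - x_j)

so adhesion attracts, repulsion repels, and the pair contributions are
equal and opposite for identical coefficients.  Basement-membrane
terms are the single-cell analogues evaluated on the signed distance
to the membrane surface.  Positions advance by second-order
Adams-Bashforth (bootstrapped with forward Euler on the first step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from multicell.errors import ConfigurationError
from multicell.grid import candidate_pairs

__all__ = [
    "potential_gradient_magnitude",
    "pair_velocity_contribution",
    "bm_velocity_contribution",
    "BasementMembrane",
    "PlaneMembrane",
    "TestTubeMembrane",
    "compute_velocities",
    "compute_velocity",
    "update_motility",
    "update_position",
]


def potential_gradient_magnitude(s: float, R: float, n: int = 1) -> float:
    """Magnitude (1 - s/R)^(n+1) of the potential gradient, zero beyond R."""
    if s >= R or R <= 0:
        return 0.0
    return (1.0 - s / R) ** (n + 1)


def _coincident_fallback(cell_i, cell_j) -> np.ndarray:
    """Deterministic separation axis for exactly coincident centers:
    +x jittered by a cell-index-seeded generator (breaks symmetry)."""
    rng = np.random.default_rng(min(cell_i.id, cell_j.id))
    axis = np.array([1.0, 0.0, 0.0]) + 1e-3 * rng.standard_normal(3)
    return axis / np.linalg.norm(axis)


def pair_velocity_contribution(cell_i, cell_j, params=None) -> np.ndarray:
    """Velocity contribution (um/min) of cell j on cell i.

    Coefficients combine as geometric means of the two cells'
    adhesion/repulsion strengths unless ``params`` overrides both.
    """
    mi = params or cell_i.phenotype.mechanics
    mj = params or cell_j.phenotype.mechanics
    d = cell_i.position - cell_j.position
    s = float(np.linalg.norm(d))
    Ri = cell_i.phenotype.volume.radius
    Rj = cell_j.phenotype.volume.radius
    RAi = mi.R_A_multiple * Ri
    RAj = mj.R_A_multiple * Rj
    if s == 0.0:
        unit = _coincident_fallback(cell_i, cell_j)
        s_eff = 0.0
    else:
        unit = d / s
        s_eff = s
    n = mi.n
    adh = math.sqrt(mi.c_cca * mj.c_cca) * potential_gradient_magnitude(s_eff, RAi + RAj, n)
    rep = math.sqrt(mi.c_ccr * mj.c_ccr) * potential_gradient_magnitude(s_eff, Ri + Rj, n)
    return (rep - adh) * unit


# ---------------------------------------------------------- basement membrane

class BasementMembrane:
    """Signed-distance representation of a confining tissue surface.

    ``distance`` is positive on the allowed (interior) side; ``normal``
    is the unit gradient of the distance, pointing from the surface
    into the allowed region.
    """

    def distance(self, positions: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def normal(self, positions: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class PlaneMembrane(BasementMembrane):
    """Flat wall through ``point`` with inward unit normal ``normal``."""

    point: tuple[float, float, float]
    inward_normal: tuple[float, float, float]

    def __post_init__(self):
        n = np.asarray(self.inward_normal, dtype=float)
        self._n = n / np.linalg.norm(n)
        self._p = np.asarray(self.point, dtype=float)

    def distance(self, positions):
        return (np.atleast_2d(positions) - self._p) @ self._n

    def normal(self, positions):
        return np.broadcast_to(self._n, np.atleast_2d(positions).shape).copy()


@dataclass
class TestTubeMembrane(BasementMembrane):
    """A 3-D 'test tube': a cylinder of radius ``radius`` along the
    x-axis, closed by a hemispherical cap at ``x_cap`` (the breast-duct
    geometry).  The interior (allowed region) has positive distance."""

    __test__ = False  # not a test case despite the name

    radius: float
    x_cap: float = 0.0
    center_yz: tuple[float, float] = (0.0, 0.0)

    def _split(self, positions):
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        y = pos[:, 1] - self.center_yz[0]
        z = pos[:, 2] - self.center_yz[1]
        in_tube = pos[:, 0] >= self.x_cap
        return pos, y, z, in_tube

    def distance(self, positions):
        pos, y, z, in_tube = self._split(positions)
        rho = np.hypot(y, z)
        d_tube = self.radius - rho
        r_cap = np.sqrt((pos[:, 0] - self.x_cap) ** 2 + y**2 + z**2)
        d_cap = self.radius - r_cap
        return np.where(in_tube, d_tube, d_cap)

    def normal(self, positions):
        pos, y, z, in_tube = self._split(positions)
        out = np.zeros_like(pos)
        rho = np.hypot(y, z)
        safe = np.where(rho > 0, rho, 1.0)
        # cylinder: inward normal is -radial direction
        out[:, 1] = -y / safe
        out[:, 2] = -z / safe
        out[rho == 0] = [0.0, 1.0, 0.0]
        cap = ~in_tube
        if cap.any():
            v = pos[cap].copy()
            v[:, 0] -= self.x_cap
            v[:, 1] = y[cap]
            v[:, 2] = z[cap]
            norm = np.linalg.norm(v, axis=1)
            norm = np.where(norm > 0, norm, 1.0)
            out[cap] = -v / norm[:, None]
        return out


def bm_velocity_contribution(cell, bm: BasementMembrane, params=None) -> np.ndarray:
    """Velocity contribution of the basement membrane on one cell:
    adhesion toward (within R_A) and repulsion away from (within R_i)
    the nearest membrane point."""
    m = params or cell.phenotype.mechanics
    pos = cell.position[None, :]
    d = float(bm.distance(pos)[0])
    n_hat = bm.normal(pos)[0]
    R = cell.phenotype.volume.radius
    RA = m.R_A_multiple * R
    sd = 1.0 if d >= 0 else -1.0
    ad = abs(d)
    adh = m.c_cba * potential_gradient_magnitude(ad, RA, m.n)
    rep = m.c_cbr * potential_gradient_magnitude(ad, R, m.n)
    return (rep - adh) * sd * n_hat


# ------------------------------------------------------------------- motility

def update_motility(cell, dt_mech: float, rng, field=None) -> None:
    """Stochastic migration-velocity update for one cell.

    With probability dt_mech / T_per the cell redraws its migration
    velocity: the bias hook (if any) first updates d_bias, b and s_mot
    from the local microenvironment, then

        v_mot = s_mot * ((1-b) xi + b d_bias) / ||(1-b) xi + b d_bias||

    with xi uniform on the unit sphere.  Otherwise v_mot is unchanged.
    """
    ms = cell.phenotype.motility
    if not ms.enabled:
        ms.v_mot[:] = 0.0
        return
    if rng.random() >= dt_mech / ms.T_per:
        return
    if ms.update_bias_hook is not None:
        ms.update_bias_hook(cell, field)
    for _ in range(100):
        xi = rng.standard_normal(3)
        norm = np.linalg.norm(xi)
        if norm == 0.0:
            continue
        xi /= norm
        direction = (1.0 - ms.b) * xi + ms.b * ms.d_bias
        dnorm = np.linalg.norm(direction)
        if dnorm > 1e-12:
            ms.v_mot = ms.s_mot * direction / dnorm
            return
    raise ConfigurationError("could not draw a migration direction")


# ------------------------------------------------------------------ velocity

def compute_velocities(cells, bm: BasementMembrane | None = None,
                       grid_edge: float = 30.0) -> np.ndarray:
    """Vectorized velocities for all cells against frozen positions.

    Sums pairwise adhesion/repulsion over grid candidate pairs,
    basement-membrane terms, and each cell's current migration
    velocity.  Pure function of the current state: does not mutate
    positions.  Returns an (n, 3) array ordered like ``cells``.
    """
    n_cells = len(cells)
    v = np.zeros((n_cells, 3))
    if n_cells == 0:
        return v
    pos = np.array([c.position for c in cells])
    R = np.array([c.phenotype.volume.radius for c in cells])
    mech = [c.phenotype.mechanics for c in cells]
    RA = np.array([m.R_A_multiple for m in mech]) * R
    sq_cca = np.sqrt([m.c_cca for m in mech])
    sq_ccr = np.sqrt([m.c_ccr for m in mech])
    n_exp = mech[0].n

    i_idx, j_idx = candidate_pairs(pos, grid_edge)
    if i_idx.size:
        d = pos[i_idx] - pos[j_idx]
        s = np.linalg.norm(d, axis=1)
        zero = s == 0.0
        if zero.any():
            for p in np.flatnonzero(zero):
                d[p] = _coincident_fallback(cells[i_idx[p]], cells[j_idx[p]])
            s[zero] = 0.0
        unit = d / np.where(s > 0, s, 1.0)[:, None]
        unit[zero] = d[zero]

        adh_R = RA[i_idx] + RA[j_idx]
        rep_R = R[i_idx] + R[j_idx]
        with np.errstate(invalid="ignore"):
            adh = np.where(s < adh_R,
                           sq_cca[i_idx] * sq_cca[j_idx]
                           * (1.0 - s / adh_R) ** (n_exp + 1), 0.0)
            rep = np.where(s < rep_R,
                           sq_ccr[i_idx] * sq_ccr[j_idx]
                           * (1.0 - s / rep_R) ** (n_exp + 1), 0.0)
        net = (rep - adh)[:, None] * unit
        np.add.at(v, i_idx, net)
        np.subtract.at(v, j_idx, net)

    if bm is not None:
        dist = np.asarray(bm.distance(pos))
        normals = np.asarray(bm.normal(pos))
        c_cba = np.array([m.c_cba for m in mech])
        c_cbr = np.array([m.c_cbr for m in mech])
        ad = np.abs(dist)
        sd = np.where(dist >= 0, 1.0, -1.0)
        adh = np.where(ad < RA, c_cba * (1.0 - ad / np.where(RA > 0, RA, 1.0)) ** (n_exp + 1), 0.0)
        rep = np.where(ad < R, c_cbr * (1.0 - ad / R) ** (n_exp + 1), 0.0)
        v += ((rep - adh) * sd)[:, None] * normals

    for idx, cell in enumerate(cells):
        ms = cell.phenotype.motility
        if ms.enabled:
            v[idx] += ms.v_mot
    return v


def compute_velocity(cell, grid, bm: BasementMembrane | None = None,
                     custom_rules=None) -> np.ndarray:
    """Reference per-cell velocity: pair terms over the grid candidate
    set, membrane terms, migration velocity, and any custom additions."""
    v = np.zeros(3)
    for other in grid.neighbor_candidates(cell):
        v += pair_velocity_contribution(cell, other)
    if bm is not None:
        v += bm_velocity_contribution(cell, bm)
    ms = cell.phenotype.motility
    if ms.enabled:
        v += ms.v_mot
    if custom_rules:
        for rule in custom_rules:
            add = rule(cell)
            if add is not None:
                v += add
    return v


# ------------------------------------------------------------------ position

def update_position(cell, dt_mech: float) -> None:
    """Second-order Adams-Bashforth position update:

        x(t+dt) = x(t) + dt (3/2 v(t) - 1/2 v(t-dt))

    bootstrapped with forward Euler on the first step.  Rotates the
    previous-velocity slot; grid re-registration is the caller's job.
    """
    if cell.previous_velocity is None:
        cell.position = cell.position + dt_mech * cell.velocity
    else:
        cell.position = cell.position + dt_mech * (
            1.5 * cell.velocity - 0.5 * cell.previous_velocity)
    cell.previous_velocity = cell.velocity.copy()
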