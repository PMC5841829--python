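"""Executable validation battery: convergence of the mechanics, volume
and stochastic-cycle sub-models, and the analytic neighbor-set bounds.

Reference solutions: fine-time-step self-reference for mechanics
(default dt/100), closed-form exponentials for the linear volume ODEs,
and a matrix-exponential solution of the coarse-grained population ODE
for the stochastic cycle test.  The error norm is the maximum relative
error over the sampled times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.linalg import expm

from multicell import mechanics, reference
from multicell.cell import Cell
from multicell.cycle import (Ki67AdvancedParams, advance_cycle,
                             ki67_advanced_model)
from multicell.death import (DeathState, MODE_APOPTOTIC, check_death,
                             death_progress, start_apoptosis, start_necrosis)
from multicell.errors import ConfigurationError
from multicell.fixtures import compressed_cluster, two_cell_overlap
from multicell.grid import InteractionGrid, candidate_pairs
from multicell.phenotype import Phenotype, default_phenotype
from multicell.volume import VolumeState, equilibrium_volume_state

#: single place for the validation tolerances
TOLERANCES = {
    "max_rel_error": 0.05,       # 5% accuracy at the default step sizes
    "order_band": 0.2,           # +-20% on dt-halving error ratios
}


@dataclass
class ConvergenceReport:
    """Error-vs-step-size summary with a fitted convergence order."""

    quantity: str
    dts: list
    errors: list                         # max relative error per dt
    fitted_order: float
    tolerance: float = TOLERANCES["max_rel_error"]
    passed: bool = False
    per_time_errors: dict = dc_field(default_factory=dict)
    extras: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if len(self.dts) < 3:
            raise ConfigurationError("need >= 3 step sizes for an order fit")
        if any(e < 0 for e in self.errors):
            raise ConfigurationError("errors must be nonnegative")

    @staticmethod
    def fit_order(dts, errors) -> float:
        dts = np.asarray(dts, dtype=float)
        errors = np.maximum(np.asarray(errors, dtype=float), 1e-300)
        return float(np.polyfit(np.log(dts), np.log(errors), 1)[0])


# ------------------------------------------------------ diffusion accuracy

class _StaticSink:
    """Immobile oxygen-consuming point sink (a stand-in cell for
    transport accuracy measurements)."""

    __slots__ = ("id", "position", "volume", "secretion_rates",
                 "uptake_rates", "saturation_densities")

    def __init__(self, cid, position, uptake, volume=2494.0):
        self.id = cid
        self.position = np.asarray(position, dtype=float)
        self.volume = volume
        self.secretion_rates = np.zeros(1)
        self.uptake_rates = np.array([uptake])
        self.saturation_densities = np.zeros(1)


def diffusion_accuracy_test(domain_um: float = 1000.0, dx: float = 20.0,
                            t_final: float = 10.0, dt: float = 0.01,
                            ref_factor: int = 100, n_sinks: int = 500,
                            uptake: float = 10.0, seed: int = 0) -> dict:
    """Operator-split solver accuracy on an oxygen-like problem.

    One substrate (D = 1e5 um^2/min, decay 0.01/min) with Dirichlet
    boundary at 38 mmHg, uniform initial condition, and a central ball
    of immobile cell-like uptake sinks; solved to ``t_final`` at ``dt``
    and at ``dt / ref_factor``; reports the maximum relative error.
    """
    from multicell.microenvironment import Mesh, MicroenvironmentField

    n = int(round(domain_um / dx))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    radius = domain_um / 4.0
    pts = rng.normal(size=(n_sinks, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    pts *= radius * rng.uniform(0, 1, size=(n_sinks, 1)) ** (1.0 / 3.0)
    center = domain_um / 2.0
    sinks = [_StaticSink(i, p + center, uptake) for i, p in enumerate(pts)]

    def solve(step):
        mesh = Mesh((0.0, 0.0, 0.0), (n, n, n), dx)
        field = MicroenvironmentField.create(mesh, [{
            "name": "oxygen", "units": "mmHg", "D": 1.0e5, "lambda": 0.01,
            "initial": 38.0, "boundary": {"type": "dirichlet", "value": 38.0},
        }])
        prepared = field.prepare_cell_sources(sinks, step)
        n_steps = int(round(t_final / step))
        for _ in range(n_steps):
            field.step(None, step, prepared=prepared)
        return field.rho[..., 0]

    coarse = solve(dt)
    ref = solve(dt / ref_factor)
    rel = np.abs(coarse - ref) / np.maximum(ref, 1e-12)
    return {
        "dt": dt, "ref_dt": dt / ref_factor, "t_final": t_final,
        "n_voxels": n**3, "n_sinks": n_sinks,
        "max_rel_error": float(rel.max()),
        "max_rel_error_pct": float(rel.max() * 100.0),
        "mean_rel_error_pct": float(rel.mean() * 100.0),
        "passed": bool(rel.max() <= TOLERANCES["max_rel_error"]),
    }


# ----------------------------------------------------------- mechanics tests

def _make_mechanics_cell(cid: int, position) -> Cell:
    ph = default_phenotype()
    ph.death = None
    return Cell(cid, ph, position)


def _relax_positions(positions, dt: float, t_samples) -> list[np.ndarray]:
    """Integrate pure adhesion-repulsion relaxation; returns positions
    snapshots at each sample time (first step Euler, then AB2)."""
    cells = [_make_mechanics_cell(i, p) for i, p in enumerate(positions)]
    out = []
    t = 0.0
    samples = list(t_samples)
    n_steps = int(round(samples[-1] / dt))
    next_i = 0
    for step in range(n_steps):
        v = mechanics.compute_velocities(cells, grid_edge=reference.MECHANICS_VOXEL_EDGE)
        for idx, c in enumerate(cells):
            c.velocity = v[idx]
            mechanics.update_position(c, dt)
        t = (step + 1) * dt
        while next_i < len(samples) and t >= samples[next_i] - dt / 2:
            out.append(np.array([c.position for c in cells]))
            next_i += 1
    while next_i < len(samples):
        out.append(np.array([c.position for c in cells]))
        next_i += 1
    return out


def two_cell_relaxation_test(dt_list=(0.2, 0.1, 0.05), t_final: float = 60.0,
                             ref_factor: int = 100,
                             overlap_fraction: float = 0.5) -> ConvergenceReport:
    """Two overlapping cells relax to their equilibrium spacing; the
    spacing at several times is compared against a dt/ref_factor
    reference run."""
    t_samples = [f * t_final for f in (0.05, 0.1, 0.2, 0.4, 0.7, 1.0)]
    start = two_cell_overlap(overlap_fraction)

    def spacings(dt):
        snaps = _relax_positions(start, dt, t_samples)
        return np.array([np.linalg.norm(s[0] - s[1]) for s in snaps])

    ref = spacings(min(dt_list) / ref_factor)
    errors, per_time = [], {}
    for dt in dt_list:
        s = spacings(dt)
        rel = np.abs(s - ref) / ref
        per_time[dt] = rel.tolist()
        errors.append(float(rel.max()))
    # oscillation check on the finest trajectory: spacing monotone
    fine = spacings(min(dt_list))
    monotone = bool(np.all(np.diff(fine) >= -1e-9))
    order = ConvergenceReport.fit_order(dt_list, errors)
    rep = ConvergenceReport("two-cell spacing", list(dt_list), errors, order,
                            per_time_errors=per_time,
                            extras={"monotone": monotone,
                                    "equilibrium_spacing": float(ref[-1])})
    rep.passed = (errors[list(dt_list).index(min(dt_list, key=lambda d: abs(d - 0.1)))]
                  <= rep.tolerance) and monotone
    return rep


def cluster_relaxation_test(n: int = 300, dt_list=(0.4, 0.2, 0.1),
                            t_final: float = 10.0,
                            ref_factor: int = 100, seed: int = 0) -> ConvergenceReport:
    """A compressed cluster decompresses; its diameter at several times
    is compared against a fine-dt reference."""
    t_samples = [f * t_final for f in (0.05, 0.2, 0.5, 1.0)]
    start = compressed_cluster(n, seed=seed).positions

    def diameters(dt):
        snaps = _relax_positions(start, dt, t_samples)
        out = []
        for s in snaps:
            center = s.mean(axis=0)
            out.append(2.0 * np.linalg.norm(s - center, axis=1).max())
        return np.array(out)

    ref = diameters(min(dt_list) / ref_factor)
    errors, per_time = [], {}
    for dt in dt_list:
        d = diameters(dt)
        rel = np.abs(d - ref) / ref
        per_time[dt] = rel.tolist()
        errors.append(float(rel.max()))
    monotone = bool(np.all(np.diff(diameters(min(dt_list))) >= -1e-9))
    order = ConvergenceReport.fit_order(dt_list, errors)
    rep = ConvergenceReport("cluster diameter", list(dt_list), errors, order,
                            per_time_errors=per_time,
                            extras={"monotone_decompression": monotone})
    rep.passed = errors[-1] <= rep.tolerance
    return rep


# -------------------------------------------------------------- volume tests

def _euler_volume_trajectory(trajectory: str, dt: float, t_samples):
    """Forward-Euler sub-volume trajectories using the real cell/death
    machinery; returns arrays (len(t_samples), 4): V, V_F, V_NS, V_CS."""
    ph = Phenotype(volume=equilibrium_volume_state(**reference.VOLUME_RATES),
                   death=DeathState())
    cell = Cell(0, ph, (0.0, 0.0, 0.0))
    vs = ph.volume
    if trajectory == "cycling":
        vs.V_F *= 0.5
        vs.V_NS *= 0.5
        vs.V_CS *= 0.5
        vs._partition()
    elif trajectory == "apoptotic":
        start_apoptosis(cell)
    elif trajectory == "necrotic":
        start_necrosis(cell)
    else:
        raise ConfigurationError(f"unknown trajectory {trajectory!r}")
    out = []
    t = 0.0
    next_i = 0
    samples = list(t_samples)
    n_steps = int(round(samples[-1] / dt))
    for step in range(n_steps):
        vs.update(dt)
        if ph.death.dead:
            death_progress(cell, dt)
        t = (step + 1) * dt
        while next_i < len(samples) and t >= samples[next_i] - dt / 2:
            out.append([vs.V, vs.V_F, vs.V_NS, vs.V_CS])
            next_i += 1
    return np.array(out)


def _exact_volume_trajectory(trajectory: str, t_samples):
    """Piecewise closed-form solution of the same trajectories."""
    ph = Phenotype(volume=equilibrium_volume_state(**reference.VOLUME_RATES),
                   death=DeathState())
    cell = Cell(0, ph, (0.0, 0.0, 0.0))
    vs = ph.volume
    if trajectory == "cycling":
        vs.V_F *= 0.5
        vs.V_NS *= 0.5
        vs.V_CS *= 0.5
        vs._partition()
        segments = [(vs, math.inf)]
    elif trajectory == "apoptotic":
        start_apoptosis(cell)
        segments = [(vs, math.inf)]
    elif trajectory == "necrotic":
        start_necrosis(cell)
        # find the lysis time on the exact swelling solution by bisection
        rupture = vs.rupture_volume
        if vs.exact_solution(0.0).V >= rupture:
            t_star = 0.0
        else:
            lo, hi = 0.0, 1.0
            while vs.exact_solution(hi).V < rupture and hi < 1e7:
                hi *= 2.0
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if vs.exact_solution(mid).V < rupture:
                    lo = mid
                else:
                    hi = mid
            t_star = 0.5 * (lo + hi)
        at_lysis = vs.exact_solution(t_star)
        at_lysis.f_F = 0.0
        from multicell.death import NECROSIS_LYSED_FLUID_RATE

        at_lysis.r_F = NECROSIS_LYSED_FLUID_RATE
        segments = [(vs, t_star), (at_lysis, math.inf)]
    else:
        raise ConfigurationError(f"unknown trajectory {trajectory!r}")

    out = []
    for t in t_samples:
        t_remaining = t
        state = None
        t_origin = 0.0
        for seg_state, seg_end in segments:
            if t <= seg_end or seg_end == math.inf:
                state = seg_state.exact_solution(t - t_origin)
                break
            t_origin = seg_end
        else:  # pragma: no cover
            state = segments[-1][0].exact_solution(t - t_origin)
        out.append([state.V, state.V_F, state.V_NS, state.V_CS])
    return np.array(out)


#: default horizons spanning a few time constants of each trajectory
_VOLUME_T_FINAL = {"cycling": 2880.0, "apoptotic": 720.0, "necrotic": 2880.0}


def single_cell_volume_test(trajectory: str = "cycling",
                            dt_list=(24.0, 12.0, 6.0),
                            t_final: float | None = None) -> ConvergenceReport:
    """Forward-Euler sub-volumes vs the exact linear-ODE solution for a
    cycling, apoptotic, or necrotic single cell.

    Errors are relative to each compartment's running magnitude
    (its largest exact value over the sampled window), so compartments
    that decay to zero are not judged on their vanishing tails.
    """
    if t_final is None:
        t_final = _VOLUME_T_FINAL.get(trajectory, 2880.0)
    t_samples = [f * t_final for f in (0.125, 0.25, 0.5, 0.75, 1.0)]
    exact = _exact_volume_trajectory(trajectory, t_samples)
    # characteristic magnitude of each compartment, including its t=0 value
    exact0 = _exact_volume_trajectory(trajectory, [0.0])
    scale = np.maximum(np.abs(np.vstack([exact0, exact])).max(axis=0, keepdims=True),
                       1.0)
    errors, per_time = [], {}
    for dt in dt_list:
        euler = _euler_volume_trajectory(trajectory, dt, t_samples)
        rel = np.abs(euler - exact) / scale
        per_time[dt] = rel.max(axis=1).tolist()
        errors.append(float(rel.max()))
    order = ConvergenceReport.fit_order(dt_list, errors)
    rep = ConvergenceReport(f"volume trajectory ({trajectory})",
                            list(dt_list), errors, order,
                            per_time_errors=per_time)
    rep.passed = errors[list(dt_list).index(6.0)] <= rep.tolerance \
        if 6.0 in dt_list else errors[-1] <= rep.tolerance
    return rep


# ------------------------------------------------- stochastic population test

def _coarse_grained_ki67_counts(n0: int, params: Ki67AdvancedParams,
                                r_A: float, T_A: float, t_samples) -> np.ndarray:
    """Mean-field linear ODE for (K1, K2, Q, A) with division doubling
    the K1 outflux into K2, solved by matrix exponential."""
    k1, k2, rq = 1.0 / params.T_1, 1.0 / params.T_2, 1.0 / params.T_Q_bar
    A = np.array([
        [-(k1 + r_A), 0.0,          rq,          0.0],
        [2.0 * k1,    -(k2 + r_A),  0.0,         0.0],
        [0.0,         k2,           -(rq + r_A), 0.0],
        [r_A,         r_A,          r_A,         -1.0 / T_A],
    ])
    y0 = np.array([0.0, 0.0, float(n0), 0.0])
    return np.array([expm(A * t) @ y0 for t in t_samples])


def _simulate_ki67_cohort(n0: int, dt: float, t_samples, rng,
                          params: Ki67AdvancedParams, r_A: float,
                          T_A: float) -> np.ndarray:
    """Space-free cohort using the real cycle/death transition code;
    apoptotic cells persist for an exponential duration, then leave."""
    model = ki67_advanced_model(params, fixed_durations=False)
    # rate overrides keep Q->K1 at the reference-oxygen value
    death_proto = dict(r_A=r_A, T_A=T_A, stochastic_apoptosis_duration=True)

    class _Pheno:
        __slots__ = ("cycle", "death", "volume")

    def new_cell(phase):
        ph = _Pheno()
        ph.cycle = model.new_state(phase)
        ph.death = DeathState(**death_proto)
        ph.volume = None

        class _C:
            __slots__ = ("phenotype", "t_dead", "dead_duration")

        c = _C()
        c.phenotype = ph
        c.t_dead = None
        c.dead_duration = None
        return c

    cells = [new_cell("Q") for _ in range(n0)]
    out = []
    samples = list(t_samples)
    next_i = 0
    n_steps = int(round(samples[-1] / dt))
    t = 0.0
    for step in range(n_steps):
        born = []
        for c in cells:
            ds = c.phenotype.death
            if ds.dead:
                continue
            if check_death(c, dt, rng) == MODE_APOPTOTIC:
                ds.mode = MODE_APOPTOTIC
                c.t_dead = 0.0
                c.dead_duration = rng.exponential(T_A)
                continue
            for event in advance_cycle(c, dt, rng):
                if event == ("division",):
                    born.append(new_cell(c.phenotype.cycle.current_phase))
        for c in cells:
            if c.phenotype.death.dead:
                c.t_dead += dt
        cells = [c for c in cells
                 if not (c.phenotype.death.dead and c.t_dead >= c.dead_duration)]
        cells.extend(born)
        t = (step + 1) * dt
        while next_i < len(samples) and t >= samples[next_i] - dt / 2:
            counts = {"K1": 0, "K2": 0, "Q": 0, "A": 0}
            for c in cells:
                if c.phenotype.death.dead:
                    counts["A"] += 1
                else:
                    counts[c.phenotype.cycle.current_phase] += 1
            out.append([counts["K1"], counts["K2"], counts["Q"], counts["A"]])
            next_i += 1
    return np.array(out, dtype=float)


def stochastic_population_test(dt: float = 6.0, reps: int = 100, n0: int = 100,
                               t_final: float = 1440.0, seed: int = 0,
                               r_A: float | None = None) -> dict:
    """Mean sub-population counts of the Ki67-advanced model (stochastic
    durations) over ``reps`` replicates vs the coarse-grained ODE.

    Returns a report dict with per-time z-scores of the Monte-Carlo
    mean against the ODE solution.
    """
    params = Ki67AdvancedParams(**reference.KI67_ADVANCED)
    r_A = reference.DEATH["apoptosis_rate"] if r_A is None else r_A
    T_A = reference.DEATH["T_A"]
    t_samples = [t_final * f for f in (0.25, 0.5, 0.75, 1.0)]
    rng = np.random.default_rng(np.random.SeedSequence((seed, 99)))
    runs = np.array([
        _simulate_ki67_cohort(n0, dt, t_samples, rng, params, r_A, T_A)
        for _ in range(reps)
    ])
    mean = runs.mean(axis=0)
    se = runs.std(axis=0, ddof=1) / math.sqrt(reps)
    ode = _coarse_grained_ki67_counts(n0, params, r_A, T_A, t_samples)
    z = np.where(se > 0, (mean - ode) / np.where(se > 0, se, 1.0), 0.0)
    return {
        "dt": dt, "reps": reps, "n0": n0,
        "t_samples": t_samples,
        "phases": ["K1", "K2", "Q", "A"],
        "mean": mean, "se": se, "ode": ode, "z": z,
        "max_abs_z": float(np.abs(z).max()),
        "passed": bool(np.abs(z).max() < 3.0),
    }


# -------------------------------------------------------- neighbor-set audit

def neighbor_bound_audit(cells, grid_edge: float = reference.MECHANICS_VOXEL_EDGE) -> dict:
    """Audit the interaction-grid candidate sets against the analytic
    bound |N(i)| <= 27 V_mech / min_i V_i."""
    grid = InteractionGrid(grid_edge)
    grid.rebuild(cells)
    observed = grid.max_candidate_count()
    min_volume = min((c.phenotype.volume.V for c in cells), default=np.inf)
    bound = 27.0 * grid.voxel_volume / min_volume
    return {
        "n_cells": len(list(cells)),
        "observed_max": observed,
        "bound": bound,
        "min_volume": min_volume,
        "ok": observed <= bound,
    }


def pair_operation_counts(ns, density_spacing: float = 15.0,
                          grid_edge: float = reference.MECHANICS_VOXEL_EDGE,
                          seed: int = 0) -> list[tuple[int, int]]:
    """Candidate-pair counts for random packings of fixed density at
    several population sizes (for the O(n) cost-scaling check)."""
    out = []
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    for n in ns:
        side = density_spacing * n ** (1.0 / 3.0)
        pos = rng.uniform(0.0, side, size=(n, 3))
        i_idx, _ = candidate_pairs(pos, grid_edge)
        out.append((n, int(i_idx.size)))
    return out
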