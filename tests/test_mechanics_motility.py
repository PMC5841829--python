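"""Mechanics: potentials, membrane forces, motility statistics, the
Adams-Bashforth integrator, and the interaction grid."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from conftest import make_mech_cell
from multicell import mechanics
from multicell.grid import InteractionGrid, candidate_pairs
from multicell.mechanics import (PlaneMembrane, TestTubeMembrane,
                                 bm_velocity_contribution,
                                 pair_velocity_contribution,
                                 update_motility, update_position)
from multicell.phenotype import MotilityState
from multicell.validation import neighbor_bound_audit, pair_operation_counts


# ---------------------------------------------------------------- pairwise

def test_zero_beyond_interaction_range():
    a = make_mech_cell(0, (0.0, 0.0, 0.0))
    R_A = a.phenotype.max_adhesion_distance
    b = make_mech_cell(1, (2 * R_A + 1.0, 0.0, 0.0))
    np.testing.assert_array_equal(pair_velocity_contribution(a, b), np.zeros(3))


def test_pair_contributions_equal_and_opposite():
    a = make_mech_cell(0, (0.0, 0.0, 0.0))
    b = make_mech_cell(1, (10.0, 3.0, -2.0))
    va = pair_velocity_contribution(a, b)
    vb = pair_velocity_contribution(b, a)
    np.testing.assert_allclose(va, -vb, rtol=1e-12)


def test_overlapping_cells_repel_and_distant_cells_attract():
    a = make_mech_cell(0, (0.0, 0.0, 0.0))
    R = a.phenotype.volume.radius
    close = make_mech_cell(1, (0.5 * R, 0.0, 0.0))
    far = make_mech_cell(2, (2.2 * R, 0.0, 0.0))  # beyond 2R, within 2R_A
    assert pair_velocity_contribution(a, close)[0] < 0  # pushed away
    assert pair_velocity_contribution(a, far)[0] > 0    # pulled toward


def test_equilibrium_spacing_matches_scalar_root():
    """Net radial velocity vanishes where adhesion balances repulsion;
    locate that spacing independently by 1-D root finding."""
    a = make_mech_cell(0, (0.0, 0.0, 0.0))
    m = a.phenotype.mechanics
    R = a.phenotype.volume.radius
    RA = m.R_A_multiple * R

    def net(s):
        rep = m.c_ccr * max(1 - s / (2 * R), 0.0) ** 2
        adh = m.c_cca * max(1 - s / (2 * RA), 0.0) ** 2
        return rep - adh

    s_star = brentq(net, 0.5 * R, 2 * R)
    b = make_mech_cell(1, (s_star, 0.0, 0.0))
    v = pair_velocity_contribution(a, b)
    assert abs(v[0]) < 1e-10
    # sign flips around the root
    b.position[0] = s_star - 0.5
    assert pair_velocity_contribution(a, b)[0] < 0
    b.position[0] = s_star + 0.5
    assert pair_velocity_contribution(a, b)[0] > 0


def test_coincident_centers_deterministic_fallback():
    a = make_mech_cell(0, (5.0, 5.0, 5.0))
    b = make_mech_cell(1, (5.0, 5.0, 5.0))
    v1 = pair_velocity_contribution(a, b)
    v2 = pair_velocity_contribution(a, b)
    np.testing.assert_array_equal(v1, v2)
    assert np.linalg.norm(v1) > 0
    assert v1[0] > 0  # roughly +x


# --------------------------------------------------------------- membrane

def test_bm_zero_beyond_adhesion_range_and_at_radius_edge():
    wall = PlaneMembrane((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    cell = make_mech_cell(0, (100.0, 0.0, 0.0))
    np.testing.assert_array_equal(bm_velocity_contribution(cell, wall), np.zeros(3))
    R = cell.phenotype.volume.radius
    cell.phenotype.mechanics.c_cba = 0.0
    cell.position = np.array([R, 0.0, 0.0])
    np.testing.assert_allclose(bm_velocity_contribution(cell, wall), 0.0,
                               atol=1e-12)


def test_cell_overlapping_wall_relaxes_to_standoff_without_oscillation():
    wall = PlaneMembrane((0.0, 0.0, 0.0), (1.0, 0.0, 0.0))
    cell = make_mech_cell(0, (2.0, 0.0, 0.0))
    cell.phenotype.mechanics.c_cba = 0.0
    R = cell.phenotype.volume.radius
    prev_x = cell.position[0]
    for _ in range(3000):
        cell.velocity = bm_velocity_contribution(cell, wall)
        update_position(cell, 0.1)
        assert cell.position[0] >= prev_x - 1e-9  # monotone, no oscillation
        prev_x = cell.position[0]
    assert cell.position[0] == pytest.approx(R, rel=0.02)


def test_test_tube_membrane_geometry():
    duct = TestTubeMembrane(radius=100.0, x_cap=0.0)
    # inside the tube
    assert duct.distance([[50.0, 0.0, 0.0]])[0] == pytest.approx(100.0)
    assert duct.distance([[50.0, 80.0, 0.0]])[0] == pytest.approx(20.0)
    np.testing.assert_allclose(duct.normal([[50.0, 80.0, 0.0]])[0],
                               [0.0, -1.0, 0.0])
    # inside the hemispherical cap
    assert duct.distance([[-60.0, 0.0, 0.0]])[0] == pytest.approx(40.0)
    np.testing.assert_allclose(duct.normal([[-60.0, 0.0, 0.0]])[0],
                               [1.0, 0.0, 0.0])
    # outside the wall: negative distance
    assert duct.distance([[50.0, 120.0, 0.0]])[0] == pytest.approx(-20.0)


# ---------------------------------------------------------------- motility

def test_full_bias_gives_deterministic_taxis(rng):
    cell = make_mech_cell(0, (0, 0, 0))
    cell.phenotype.motility = MotilityState(
        enabled=True, T_per=0.1, s_mot=2.0, b=1.0,
        d_bias=np.array([0.0, 1.0, 0.0]))
    update_motility(cell, 0.1, rng)  # redraw probability 1
    np.testing.assert_allclose(cell.phenotype.motility.v_mot, [0.0, 2.0, 0.0],
                               rtol=1e-12)


def test_zero_bias_preserves_speed(rng):
    cell = make_mech_cell(0, (0, 0, 0))
    cell.phenotype.motility = MotilityState(enabled=True, T_per=0.1, s_mot=3.0, b=0.0)
    update_motility(cell, 0.1, rng)
    assert np.linalg.norm(cell.phenotype.motility.v_mot) == pytest.approx(3.0)


def test_redraw_count_binomial(rng):
    """Redraw probability dt/T_per = 0.01; over 1e4 steps expect ~100."""
    cell = make_mech_cell(0, (0, 0, 0))
    ms = MotilityState(enabled=True, T_per=10.0, s_mot=1.0, b=0.0)
    cell.phenotype.motility = ms
    changes = 0
    prev = ms.v_mot.copy()
    for _ in range(10000):
        update_motility(cell, 0.1, rng)
        if not np.array_equal(ms.v_mot, prev):
            changes += 1
            prev = ms.v_mot.copy()
    assert abs(changes - 100) < 30  # ~3 sigma of Binomial(1e4, 0.01)


def test_disabled_motility_has_zero_velocity(rng):
    cell = make_mech_cell(0, (0, 0, 0))
    cell.phenotype.motility.enabled = False
    cell.phenotype.motility.v_mot = np.array([1.0, 1.0, 1.0])
    update_motility(cell, 0.1, rng)
    np.testing.assert_array_equal(cell.phenotype.motility.v_mot, np.zeros(3))


# --------------------------------------------------------------- position

def test_position_update_degenerate_cases():
    cell = make_mech_cell(0, (1.0, 2.0, 3.0))
    cell.velocity = np.zeros(3)
    cell.previous_velocity = np.zeros(3)
    update_position(cell, 0.1)
    np.testing.assert_array_equal(cell.position, [1.0, 2.0, 3.0])
    # constant velocity: displacement exactly dt*v (3/2 - 1/2 = 1)
    v = np.array([2.0, -1.0, 0.5])
    cell.velocity = v
    cell.previous_velocity = v.copy()
    update_position(cell, 0.1)
    np.testing.assert_allclose(cell.position, [1.2, 1.9, 3.05], rtol=1e-12)


def test_adams_bashforth_second_order_on_linear_relaxation():
    """dx/dt = -k x: global error vs e^(-kt) shrinks ~4x when dt halves."""
    k, t_final = 0.5, 10.0

    def run(dt):
        cell = make_mech_cell(0, (1.0, 0.0, 0.0))
        for _ in range(int(round(t_final / dt))):
            cell.velocity = -k * cell.position
            update_position(cell, dt)
        return abs(cell.position[0] - math.exp(-k * t_final))

    ratio = run(0.1) / run(0.05)
    assert 3.0 <= ratio <= 5.0


# ------------------------------------------------------------------- grid

def test_neighbor_candidates_basic():
    grid = InteractionGrid(30.0)
    lone = make_mech_cell(0, (5.0, 5.0, 5.0))
    grid.register(lone)
    assert grid.neighbor_candidates(lone) == []
    other = make_mech_cell(1, (8.0, 2.0, 4.0))
    grid.register(other)
    assert grid.neighbor_candidates(lone) == [other]
    assert grid.neighbor_candidates(other) == [lone]


def test_candidate_set_superset_of_brute_force_within_range(rng):
    positions = rng.uniform(0, 300, size=(500, 3))
    cells = [make_mech_cell(i, p) for i, p in enumerate(positions)]
    grid = InteractionGrid(30.0)
    grid.rebuild(cells)
    reach = 2.0 * cells[0].phenotype.max_adhesion_distance  # ~21 um < 30
    d = np.linalg.norm(positions[:, None] - positions[None, :], axis=2)
    for i in range(0, 500, 23):
        cand = {c.id for c in grid.neighbor_candidates(cells[i])}
        in_range = {j for j in range(500) if j != i and d[i, j] <= reach}
        assert in_range <= cand


def test_candidate_pairs_match_grid_candidates(rng):
    positions = rng.uniform(0, 200, size=(200, 3))
    i_idx, j_idx = candidate_pairs(positions, 30.0)
    pairs = {tuple(sorted(p)) for p in zip(i_idx.tolist(), j_idx.tolist())}
    assert len(pairs) == i_idx.size  # no duplicates
    cells = [make_mech_cell(i, p) for i, p in enumerate(positions)]
    grid = InteractionGrid(30.0)
    grid.rebuild(cells)
    expected = set()
    for c in cells:
        for other in grid.neighbor_candidates(c):
            expected.add(tuple(sorted((c.id, other.id))))
    assert pairs == expected


def test_velocities_invariant_to_far_away_cells(rng):
    near = [make_mech_cell(i, p) for i, p in
            enumerate(rng.uniform(0, 40, size=(10, 3)))]
    v1 = mechanics.compute_velocities(near, grid_edge=30.0)
    far = [make_mech_cell(100 + i, p) for i, p in
           enumerate(rng.uniform(500, 600, size=(20, 3)))]
    v2 = mechanics.compute_velocities(near + far, grid_edge=30.0)
    np.testing.assert_allclose(v1, v2[:10], rtol=1e-12)


def test_total_momentum_vanishes_for_identical_coefficients(rng):
    cells = [make_mech_cell(i, p) for i, p in
             enumerate(rng.uniform(0, 60, size=(50, 3)))]
    v = mechanics.compute_velocities(cells, grid_edge=30.0)
    np.testing.assert_allclose(v.sum(axis=0), np.zeros(3), atol=1e-9)


def test_compute_velocities_does_not_move_cells(rng):
    cells = [make_mech_cell(i, p) for i, p in
             enumerate(rng.uniform(0, 60, size=(20, 3)))]
    before = np.array([c.position for c in cells])
    mechanics.compute_velocities(cells, grid_edge=30.0)
    np.testing.assert_array_equal(before, np.array([c.position for c in cells]))


def test_per_cell_reference_matches_vectorized_path(rng):
    cells = [make_mech_cell(i, p) for i, p in
             enumerate(rng.uniform(0, 80, size=(30, 3)))]
    grid = InteractionGrid(30.0)
    grid.rebuild(cells)
    vec = mechanics.compute_velocities(cells, grid_edge=30.0)
    for idx in (0, 7, 29):
        ref = mechanics.compute_velocity(cells[idx], grid)
        np.testing.assert_allclose(vec[idx], ref, rtol=1e-10, atol=1e-12)


def test_neighbor_bound_audit_on_dense_packing(rng):
    from multicell.fixtures import compressed_cluster

    cells = [make_mech_cell(i, p) for i, p in
             enumerate(compressed_cluster(400, seed=1).positions)]
    report = neighbor_bound_audit(cells)
    assert report["ok"]
    assert report["observed_max"] > 0


def test_pair_count_scales_linearly_with_n():
    counts = pair_operation_counts([500, 1000, 2000], density_spacing=15.0)
    per_cell = [c / n for n, c in counts]
    assert max(per_cell) / min(per_cell) < 1.3
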