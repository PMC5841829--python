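"""Microenvironment solver: Thomas algorithm, LOD diffusion-decay,
operator-split source/sink updates, and the mesh conventions."""

import numpy as np
import pytest
from scipy.linalg import solve_banded

from multicell.errors import ConfigurationError, NumericError
from multicell.microenvironment import (Mesh, MicroenvironmentField,
                                        thomas_solve)


def _field(shape=(10, 10, 10), dx=20.0, **spec):
    sub = {"name": "s", "D": 0.0, "lambda": 0.0, "initial": 0.0}
    sub.update(spec)
    return MicroenvironmentField.create(Mesh((0, 0, 0), shape, dx), [sub])


class _FakeCell:
    def __init__(self, cid, position, S=0.0, U=0.0, rho_star=0.0, W=2494.0):
        self.id = cid
        self.position = np.asarray(position, dtype=float)
        self.volume = W
        self.secretion_rates = np.array([S])
        self.uptake_rates = np.array([U])
        self.saturation_densities = np.array([rho_star])


# ---------------------------------------------------------------- thomas

def test_thomas_identity():
    rhs = np.array([1.0, -2.0, 3.0, 4.0])
    x = thomas_solve(np.zeros(3), np.ones(4), np.zeros(3), rhs)
    np.testing.assert_allclose(x, rhs)


def test_thomas_matches_dense_solver(rng):
    n = 10
    a = rng.random(n - 1)
    c = rng.random(n - 1)
    b = 4.0 + rng.random(n)  # diagonally dominant
    d = rng.random(n)
    x = thomas_solve(a, b, c, d)
    ab = np.zeros((3, n))
    ab[0, 1:] = c
    ab[1] = b
    ab[2, :-1] = a
    expected = solve_banded((1, 1), ab, d)
    np.testing.assert_allclose(x, expected, rtol=1e-12)


def test_thomas_zero_flux_uniform_rhs_gives_uniform_solution():
    # backward-Euler diffusion matrix with zero-flux closure: row sums 1
    n, r = 12, 3.7
    b = np.full(n, 1 + 2 * r)
    b[0] = b[-1] = 1 + r
    x = thomas_solve(np.full(n - 1, -r), b, np.full(n - 1, -r), np.full(n, 5.0))
    np.testing.assert_allclose(x, 5.0, rtol=1e-12)


def test_thomas_zero_pivot_raises():
    with pytest.raises(NumericError):
        thomas_solve(np.array([1.0]), np.array([0.0, 1.0]), np.array([1.0]),
                     np.array([1.0, 1.0]))


# ------------------------------------------------------- diffusion-decay

def test_uniform_field_unchanged_by_diffusion():
    f = _field(D=1e5, initial=7.5)
    f.diffusion_decay_step(0.01)
    np.testing.assert_allclose(f.rho, 7.5, rtol=1e-13)


def test_pure_decay_matches_backward_euler_factor():
    f = _field(D=0.0, **{"lambda": 0.1}, initial=1.0)
    f.diffusion_decay_step(0.01)
    np.testing.assert_allclose(f.rho, 1.0 / (1.0 + 0.1 * 0.01), rtol=1e-5)


def test_multi_substrate_independence(rng):
    mesh = Mesh((0, 0, 0), (8, 8, 8), 20.0)
    init = rng.random(mesh.shape)
    subs = [{"name": f"s{i}", "D": 900.0, "lambda": 0.02, "initial": 0.0}
            for i in range(10)]
    multi = MicroenvironmentField.create(mesh, subs)
    single = MicroenvironmentField.create(mesh, subs[:1])
    for s in range(10):
        multi.rho[..., s] = init
    single.rho[..., 0] = init
    for _ in range(5):
        multi.diffusion_decay_step(0.01)
        single.diffusion_decay_step(0.01)
    for s in range(10):
        np.testing.assert_allclose(multi.rho[..., s], single.rho[..., 0],
                                   rtol=1e-13)


def test_mass_conservation_zero_flux(rng):
    f = _field(D=2e3)
    f.rho[..., 0] = rng.random(f.mesh.shape)
    m0 = f.total_mass(0)
    for _ in range(20):
        f.diffusion_decay_step(0.01)
        assert abs(f.total_mass(0) - m0) / m0 < 1e-10


def test_stability_large_dt_pure_decay_no_oscillation():
    f = _field(D=0.0, **{"lambda": 2.0}, initial=1.0)
    prev = 1.0
    for _ in range(10):
        f.diffusion_decay_step(10.0)  # lambda*dt = 20: explicit would blow up
        val = float(f.rho[0, 0, 0, 0])
        assert 0.0 <= val <= prev
        prev = val


def test_first_order_temporal_convergence():
    """Error vs a dt/100 reference roughly halves when dt halves
    (nonzero D, decay, and cell uptake)."""
    def solve(dt):
        f = _field(shape=(8, 8, 8), D=1e3, **{"lambda": 0.05}, initial=10.0)
        cells = [_FakeCell(0, (70, 70, 70), U=10.0), _FakeCell(1, (30, 90, 50), U=5.0)]
        n = int(round(2.0 / dt))
        for _ in range(n):
            f.step(cells, dt)
        return f.rho[..., 0].copy()

    ref = solve(0.04 / 100)
    errs = [np.abs(solve(dt) - ref).max() for dt in (0.04, 0.02, 0.01)]
    r1, r2 = errs[0] / errs[1], errs[1] / errs[2]
    assert 1.6 <= r1 <= 2.4
    assert 1.6 <= r2 <= 2.4


def test_dirichlet_voxels_hold_value_after_every_step():
    f = _field(D=1e4, **{"lambda": 0.01}, initial=0.0,
               boundary={"type": "dirichlet", "value": 38.0})
    for _ in range(10):
        f.step([_FakeCell(0, (90, 90, 90), U=10.0)], 0.05)
    boundary = np.ones(f.mesh.shape, dtype=bool)
    boundary[1:-1, 1:-1, 1:-1] = False
    np.testing.assert_allclose(f.rho[..., 0][boundary], 38.0)
    assert f.rho[..., 0][5, 5, 5] < 38.0  # interior depleted by the sink


def test_invalid_configuration_errors():
    f = _field(D=10.0)
    with pytest.raises(ConfigurationError):
        f.diffusion_decay_step(0.0)
    with pytest.raises(ConfigurationError):
        Mesh((0, 0, 0), (4, 4, 4), -1.0)
    f.rho[0, 0, 0, 0] = np.nan
    with pytest.raises(NumericError):
        f.diffusion_decay_step(0.01)


# ------------------------------------------------------------ source/sinks

def test_bulk_source_sink_formula_and_fixed_points():
    f = _field(initial=0.0)
    f.S_bulk = np.array([1.0])
    f.U_bulk = np.array([0.0])
    f.rho_star_bulk = np.array([1.0])
    f.bulk_source_sink_step(0.01)
    np.testing.assert_allclose(f.rho, 0.01 / 1.01, rtol=1e-12)

    # saturation is a fixed point
    f2 = _field(initial=1.0)
    f2.S_bulk, f2.U_bulk, f2.rho_star_bulk = (np.array([2.0]), np.array([0.0]),
                                              np.array([1.0]))
    f2.bulk_source_sink_step(0.01)
    np.testing.assert_allclose(f2.rho, 1.0, rtol=1e-12)

    # no rates -> unchanged
    f3 = _field(initial=3.0)
    f3.bulk_source_sink_step(0.01)
    np.testing.assert_allclose(f3.rho, 3.0)


def test_cell_sink_backward_euler_value():
    f = _field(shape=(4, 4, 4), initial=38.0)
    cell = _FakeCell(0, (30.0, 30.0, 30.0), U=10.0, W=2494.0)
    f.cell_source_sink_step([cell], 0.01)
    w = 2494.0 / 8000.0
    expected = 38.0 / (1.0 + 0.01 * w * 10.0)
    i, j, k = f.mesh.voxel_of(cell.position)
    assert np.isclose(f.rho[i, j, k, 0], expected, rtol=1e-12)
    assert abs(expected - 36.85) < 0.01


def test_cell_source_fixed_point_and_no_op():
    f = _field(shape=(4, 4, 4), initial=1.0)
    sat = _FakeCell(0, (10, 10, 10), S=5.0, rho_star=1.0)
    f.cell_source_sink_step([sat], 0.1)
    np.testing.assert_allclose(f.rho, 1.0, rtol=1e-12)
    inert = _FakeCell(1, (10, 10, 10))
    f.cell_source_sink_step([inert], 0.1)
    np.testing.assert_allclose(f.rho, 1.0, rtol=1e-12)


def test_cells_in_distinct_voxels_order_independent():
    a = _FakeCell(0, (10, 10, 10), U=7.0)
    b = _FakeCell(1, (70, 70, 70), S=2.0, rho_star=5.0)
    f1 = _field(shape=(4, 4, 4), initial=3.0)
    f1.cell_source_sink_step([a, b], 0.05)
    f2 = _field(shape=(4, 4, 4), initial=3.0)
    f2.cell_source_sink_step([b, a], 0.05)
    np.testing.assert_allclose(f1.rho, f2.rho, rtol=1e-14)


def test_cells_sharing_voxel_apply_sequentially_in_index_order():
    a = _FakeCell(0, (10, 10, 10), U=7.0)
    b = _FakeCell(1, (12, 11, 9), S=2.0, rho_star=5.0)
    f = _field(shape=(4, 4, 4), initial=3.0)
    f.cell_source_sink_step([a, b], 0.05)
    # manual sequential application, ascending index
    w = 2494.0 / 8000.0
    rho = 3.0 / (1.0 + 0.05 * w * 7.0)
    rho = (rho + 0.05 * w * 2.0 * 5.0) / (1.0 + 0.05 * w * 2.0)
    assert np.isclose(f.rho[0, 0, 0, 0], rho, rtol=1e-12)


def test_prepared_sources_match_direct_application():
    cells = [_FakeCell(0, (10, 10, 10), U=7.0),
             _FakeCell(1, (12, 11, 9), S=2.0, rho_star=5.0),
             _FakeCell(2, (70, 30, 50), U=1.0)]
    f1 = _field(shape=(4, 4, 4), initial=3.0)
    f1.cell_source_sink_step(cells, 0.05)
    f2 = _field(shape=(4, 4, 4), initial=3.0)
    prepared = f2.prepare_cell_sources(cells, 0.05)
    prepared.apply(f2)
    np.testing.assert_allclose(f1.rho, f2.rho, rtol=1e-14)


def test_cell_outside_domain_clamped_with_warning(caplog):
    f = _field(shape=(4, 4, 4), initial=2.0)
    out = _FakeCell(7, (1e4, -50.0, 40.0), U=3.0)
    with caplog.at_level("WARNING", logger="multicell.microenvironment"):
        f.cell_source_sink_step([out], 0.01)
    assert any("outside domain" in r.message for r in caplog.records)
    assert f.rho[3, 0, 2, 0] < 2.0  # applied in the clamped voxel


# ------------------------------------------------------------------ mesh

def test_voxel_of_conventions():
    mesh = Mesh((0, 0, 0), (5, 5, 5), 20.0)
    assert mesh.voxel_of((0.0, 0.0, 0.0)) == (0, 0, 0)
    assert mesh.voxel_of((30.0, 30.0, 30.0)) == (1, 1, 1)  # voxel center
    # interior boundary belongs to the upper voxel (half-open rule)
    assert mesh.voxel_of((40.0, 0.0, 0.0)) == (2, 0, 0)
    # last voxel is closed; outside clamps
    assert mesh.voxel_of((100.0, 100.0, 100.0)) == (4, 4, 4)
    assert mesh.voxel_of((-5.0, 500.0, 50.0)) == (0, 4, 2)


def test_gradient_at_linear_profile():
    f = _field(shape=(6, 6, 6))
    xs = f.mesh.axis_centers(0)
    f.rho[..., 0] = xs[:, None, None] * 0.5
    g = f.gradient_at((60.0, 60.0, 60.0), 0)
    np.testing.assert_allclose(g, [0.5, 0.0, 0.0], atol=1e-12)
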