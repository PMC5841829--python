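"""Deterministic initial-state fixtures for tests and showcase runs.

Every fixture is bit-reproducible from ``(name, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from multicell.errors import ConfigurationError
from multicell.reference import MATURE_VOLUME
from multicell.volume import radius_of_volume

#: radius of the reference mature cell, um
_R_REF = radius_of_volume(MATURE_VOLUME)


@dataclass
class Fixture:
    """Initial placement: (n, 3) positions and a per-cell type label."""

    name: str
    positions: np.ndarray
    types: list[str] = dc_field(default_factory=list)

    def __post_init__(self):
        if not self.types:
            self.types = ["default"] * len(self.positions)


def _lattice_ball(n: int, spacing: float, rng=None) -> np.ndarray:
    """First ``n`` points of a jittered cubic lattice, sorted by distance
    from the origin -- a deterministic sphere-packed cluster."""
    if n < 1:
        raise ConfigurationError("fixture size must be >= 1")
    side = int(np.ceil((2.0 * n) ** (1.0 / 3.0))) + 2
    ax = np.arange(-side, side + 1) * spacing
    pts = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1).reshape(-1, 3)
    # offset alternate layers for a denser, less columnar packing
    layer = np.round(pts[:, 2] / spacing).astype(int)
    pts[:, 0] += (layer % 2) * 0.5 * spacing
    pts[:, 1] += (layer % 2) * 0.5 * spacing
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    pts = pts[order[:n]]
    if rng is not None:
        pts = pts + rng.uniform(-0.05, 0.05, size=pts.shape) * spacing
    return pts


def sphere_packed_positions(n: int, center, spacing: float = 15.0, rng=None) -> np.ndarray:
    return _lattice_ball(n, spacing, rng) + np.asarray(center, dtype=float)


def two_cell_overlap(overlap_fraction: float = 0.5,
                     radius: float = _R_REF) -> np.ndarray:
    """Two cells along the x-axis at separation
    ``overlap_fraction * 2 * radius`` (< 2R, i.e. partial overlap)."""
    if not 0.0 < overlap_fraction < 1.0:
        raise ConfigurationError("overlap_fraction must be in (0, 1)")
    s = overlap_fraction * 2.0 * radius
    return np.array([[-s / 2.0, 0.0, 0.0], [s / 2.0, 0.0, 0.0]])


def compressed_cluster(n: int, seed: int = 0, compression: float = 0.8,
                       equilibrium_spacing: float | None = None) -> Fixture:
    """Cluster of ``n`` cells packed at ``compression`` times the
    two-cell equilibrium spacing: every nearest-neighbor separation is
    below equilibrium, so the cluster relaxes outward."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    eq = equilibrium_spacing if equilibrium_spacing is not None else 2.0 * _R_REF
    pos = _lattice_ball(n, compression * eq, rng)
    return Fixture("compressed_cluster", pos)


def spheroid_seed(n: int, seed: int = 0, center=(0.0, 0.0, 0.0),
                  spacing: float | None = None) -> Fixture:
    """Sphere-packed tumor-spheroid seed cluster (near-confluent)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
    sp = spacing if spacing is not None else 1.9 * _R_REF
    pos = sphere_packed_positions(n, center, sp, rng)
    return Fixture("spheroid_seed", pos)


def dcis_seed(n: int, duct_radius: float, x_cap: float = 0.0, seed: int = 0) -> Fixture:
    """Partially filled breast duct: cells packed from the closed
    (capped) end of a test-tube geometry along +x."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    sp = 1.9 * _R_REF
    margin = _R_REF
    pts = []
    x = x_cap + margin - _R_REF  # start inside the hemispherical cap
    while len(pts) < n:
        x += sp * 0.87
        ring_r = duct_radius - margin
        ax = np.arange(-duct_radius, duct_radius + sp, sp)
        for y in ax:
            for z in ax:
                if y * y + z * z <= ring_r * ring_r and len(pts) < n:
                    if x >= x_cap or (x - x_cap) ** 2 + y * y + z * z <= ring_r**2:
                        pts.append([x, y, z])
    pos = np.asarray(pts[:n], dtype=float)
    pos += rng.uniform(-0.05, 0.05, size=pos.shape) * sp
    return Fixture("dcis_seed", pos)


def worker_cargo_injection(n: int, center, seed: int = 0,
                           worker_fraction: float = 0.10,
                           spacing: float | None = None) -> Fixture:
    """Mixed injection of worker and cargo cells (default 10% : 90%),
    shuffled deterministically within a packed ball."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
    sp = spacing if spacing is not None else 2.0 * _R_REF
    pos = sphere_packed_positions(n, center, sp, rng)
    n_workers = max(1, int(round(worker_fraction * n)))
    types = ["worker"] * n_workers + ["cargo"] * (n - n_workers)
    perm = rng.permutation(n)
    types = [types[i] for i in perm]
    return Fixture("worker_cargo_injection", pos, types)


_FIXTURES = {
    "two_cell_overlap": lambda seed, **kw: Fixture(
        "two_cell_overlap", two_cell_overlap(**kw)),
    "compressed_cluster": lambda seed, n=2000, **kw: compressed_cluster(n, seed, **kw),
    "spheroid_seed": lambda seed, n=300, **kw: spheroid_seed(n, seed, **kw),
    "dcis_seed": lambda seed, n=200, duct_radius=158.75, **kw: dcis_seed(
        n, duct_radius, seed=seed, **kw),
    "worker_cargo_injection": lambda seed, n=100, center=(0.0, 0.0, 0.0), **kw:
        worker_cargo_injection(n, center, seed, **kw),
}


def generate_fixture(name: str, seed: int = 0, **kwargs) -> Fixture:
    """Named deterministic fixture; bit-reproducible from (name, seed)."""
    try:
        maker = _FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}") from None
    return maker(seed, **kwargs)
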