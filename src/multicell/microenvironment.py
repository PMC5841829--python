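"""Multi-substrate reaction-diffusion microenvironment on a Cartesian mesh.

The chemical microenvironment is a vector of substrate densities
``rho(x, t)`` governed, per substrate, by

    d rho / dt = D lap(rho) - lam rho + S (rho* - rho) - U rho
                 + sum_k delta(x - x_k) W_k [S_k (rho*_k - rho) - U_k rho]

with zero-flux conditions on the domain boundary and optional per-voxel
Dirichlet overrides (e.g. a fixed 38 mmHg oxygen tension on the outer
boundary of a culture domain).  The solution is advanced by first-order
operator splitting: bulk source/sink terms (backward Euler per voxel),
then cell-centered source/sink terms (backward Euler in the voxel
containing each cell center), then diffusion-decay via the locally
one-dimensional (LOD) method -- one backward-Euler sweep per axis, each
sweep solved exactly with a tailored Thomas tridiagonal solver whose
forward-sweep coefficients are cached between steps.

Units: lengths in um, times in min, densities in the substrate's own
units (e.g. mmHg for oxygen partial pressure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from multicell import _kernels
from multicell.errors import ConfigurationError, NumericError

log = logging.getLogger(__name__)

#: default voxel edge length (um); comparable to one cell diameter,
#: required for the cell-centered source/sink discretization to be accurate
DEFAULT_DX = 20.0


@dataclass(frozen=True)
class Mesh:
    """Uniform Cartesian voxel mesh with identical edge length on all axes."""

    origin: tuple[float, float, float]
    shape: tuple[int, int, int]
    dx: float = DEFAULT_DX

    def __post_init__(self):
        if self.dx <= 0:
            raise ConfigurationError(f"voxel edge length must be positive, got {self.dx}")
        if any(n < 1 for n in self.shape):
            raise ConfigurationError(f"mesh shape must be positive, got {self.shape}")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return self.dx**3

    @property
    def extents(self) -> np.ndarray:
        """(3, 2) array of [lower, upper] bounds per axis."""
        lo = np.asarray(self.origin, dtype=float)
        hi = lo + self.dx * np.asarray(self.shape, dtype=float)
        return np.stack([lo, hi], axis=1)

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + self.dx * (np.arange(self.shape[axis]) + 0.5)

    def voxel_of(self, position) -> tuple[int, int, int]:
        """Voxel index containing ``position``.

        Voxels follow the half-open convention [lower, upper) along each
        axis; the last voxel is closed.  Positions outside the domain
        clamp to the nearest voxel.
        """
        idx = self.voxel_of_batch(np.asarray(position, dtype=float)[None, :])
        return tuple(int(v) for v in idx[0])

    def voxel_of_batch(self, positions: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`voxel_of` for an (n, 3) position array."""
        rel = (positions - np.asarray(self.origin)) / self.dx
        idx = np.floor(rel).astype(np.int64)
        np.clip(idx, 0, np.asarray(self.shape) - 1, out=idx)
        return idx

    def contains(self, positions: np.ndarray) -> np.ndarray:
        ext = self.extents
        pos = np.atleast_2d(positions)
        return np.all((pos >= ext[:, 0]) & (pos <= ext[:, 1]), axis=1)

    def flatten_index(self, idx: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.shape
        return (idx[..., 0] * ny + idx[..., 1]) * nz + idx[..., 2]


def thomas_solve(sub_diag, diag, super_diag, rhs):
    """Solve a tridiagonal system exactly by the Thomas algorithm.

    Parameters are the sub-diagonal (length n-1), diagonal (length n),
    super-diagonal (length n-1) and right-hand side (length n).  The
    system must be nonsingular along the elimination path (diagonal
    dominance guarantees this).

    Raises :class:`NumericError` on a zero pivot.
    """
    a = np.asarray(sub_diag, dtype=float)
    b = np.asarray(diag, dtype=float)
    c = np.asarray(super_diag, dtype=float)
    d = np.asarray(rhs, dtype=float)
    n = b.size
    if a.size != n - 1 or c.size != n - 1 or d.size != n:
        raise ConfigurationError("inconsistent tridiagonal system sizes")
    cp = np.empty(n)
    dp = np.empty(n)
    if b[0] == 0.0:
        raise NumericError("zero pivot at row 0")
    cp[0] = c[0] / b[0] if n > 1 else 0.0
    dp[0] = d[0] / b[0]
    for i in range(1, n):
        denom = b[i] - a[i - 1] * cp[i - 1]
        if denom == 0.0:
            raise NumericError(f"zero pivot at row {i}")
        cp[i] = c[i] / denom if i < n - 1 else 0.0
        dp[i] = (d[i] - a[i - 1] * dp[i - 1]) / denom
    x = np.empty(n)
    x[-1] = dp[-1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


@dataclass
class MicroenvironmentField:
    """Vector of substrate densities plus per-substrate transport metadata.

    ``rho`` has shape ``(nx, ny, nz, n_substrates)``.  ``D`` (um^2/min)
    and ``lam`` (1/min) are per-substrate vectors.  Bulk supply/uptake
    rates ``S_bulk``/``U_bulk`` (1/min) and the bulk saturation density
    ``rho_star_bulk`` may be per-substrate scalars or full per-voxel
    arrays broadcastable against ``rho``.  ``dirichlet_mask`` /
    ``dirichlet_value`` hold per-voxel, per-substrate fixed-value
    overrides re-imposed after every solver sub-step.
    """

    mesh: Mesh
    substrate_names: list[str]
    rho: np.ndarray
    D: np.ndarray
    lam: np.ndarray
    S_bulk: np.ndarray | None = None
    U_bulk: np.ndarray | None = None
    rho_star_bulk: np.ndarray | None = None
    dirichlet_mask: np.ndarray | None = None
    dirichlet_value: np.ndarray | None = None
    units: list[str] = field(default_factory=list)

    _coef_cache: dict = field(default_factory=dict, repr=False)
    _warned_outside: set = field(default_factory=set, repr=False)

    # ------------------------------------------------------------------ setup

    @classmethod
    def create(cls, mesh: Mesh, substrates: list[dict]) -> "MicroenvironmentField":
        """Build a field from a list of substrate definitions.

        Each definition is a dict with keys ``name``, ``D``, ``lambda``,
        ``initial`` and optionally ``units``, ``S``, ``U``, ``rho_star``,
        and ``boundary`` (``{"type": "dirichlet"|"zero_flux", "value": v}``).
        A Dirichlet boundary pins every face voxel of that substrate.
        """
        ns = len(substrates)
        if ns == 0:
            raise ConfigurationError("at least one substrate is required")
        shape = (*mesh.shape, ns)
        rho = np.zeros(shape)
        D = np.zeros(ns)
        lam = np.zeros(ns)
        S = np.zeros(ns)
        U = np.zeros(ns)
        rho_star = np.zeros(ns)
        mask = np.zeros(shape, dtype=bool)
        value = np.zeros(shape)
        names, units = [], []
        for s, spec in enumerate(substrates):
            names.append(spec["name"])
            units.append(spec.get("units", "a.u."))
            D[s] = spec.get("D", 0.0)
            lam[s] = spec.get("lambda", 0.0)
            S[s] = spec.get("S", 0.0)
            U[s] = spec.get("U", 0.0)
            rho_star[s] = spec.get("rho_star", 0.0)
            rho[..., s] = spec.get("initial", 0.0)
            bc = spec.get("boundary")
            if bc and bc.get("type") == "dirichlet":
                v = float(bc["value"])
                face = np.zeros(mesh.shape, dtype=bool)
                face[0, :, :] = face[-1, :, :] = True
                face[:, 0, :] = face[:, -1, :] = True
                face[:, :, 0] = face[:, :, -1] = True
                mask[..., s] = face
                value[..., s][face] = v
        obj = cls(
            mesh=mesh, substrate_names=names, rho=rho, D=D, lam=lam,
            S_bulk=S, U_bulk=U, rho_star_bulk=rho_star,
            dirichlet_mask=mask, dirichlet_value=value, units=units,
        )
        obj.apply_dirichlet()
        return obj

    @property
    def n_substrates(self) -> int:
        return len(self.substrate_names)

    def substrate_index(self, name: str) -> int:
        return self.substrate_names.index(name)

    # -------------------------------------------------------------- utilities

    def apply_dirichlet(self) -> None:
        if self.dirichlet_mask is not None:
            np.copyto(self.rho, self.dirichlet_value, where=self.dirichlet_mask)

    def set_dirichlet(self, idx: tuple[int, int, int], substrate: int, value: float) -> None:
        shape = (*self.mesh.shape, self.n_substrates)
        if self.dirichlet_mask is None:
            self.dirichlet_mask = np.zeros(shape, dtype=bool)
            self.dirichlet_value = np.zeros(shape)
        self.dirichlet_mask[(*idx, substrate)] = True
        self.dirichlet_value[(*idx, substrate)] = value
        self.rho[(*idx, substrate)] = value
        self._coef_cache.pop(("dirichlet", substrate), None)

    def density_at(self, position, substrate: int | str | None = None):
        """Substrate density in the voxel containing ``position``."""
        i, j, k = self.mesh.voxel_of(position)
        if substrate is None:
            return self.rho[i, j, k, :].copy()
        if isinstance(substrate, str):
            substrate = self.substrate_index(substrate)
        return float(self.rho[i, j, k, substrate])

    def gradient_at(self, position, substrate: int | str) -> np.ndarray:
        """Central-difference gradient (one-sided at faces) at the voxel
        containing ``position`` (units of density per um)."""
        if isinstance(substrate, str):
            substrate = self.substrate_index(substrate)
        i, j, k = self.mesh.voxel_of(position)
        rho = self.rho[..., substrate]
        g = np.empty(3)
        for axis, (n, idx) in enumerate(zip(self.mesh.shape, (i, j, k))):
            lo = max(idx - 1, 0)
            hi = min(idx + 1, n - 1)
            sel = [i, j, k]
            sel[axis] = hi
            v_hi = rho[tuple(sel)]
            sel[axis] = lo
            v_lo = rho[tuple(sel)]
            span = (hi - lo) * self.mesh.dx
            g[axis] = 0.0 if span == 0 else (v_hi - v_lo) / span
        return g

    def total_mass(self, substrate: int | str) -> float:
        """Integral of density over the domain (density units x um^3)."""
        if isinstance(substrate, str):
            substrate = self.substrate_index(substrate)
        return float(self.rho[..., substrate].sum() * self.mesh.voxel_volume)

    def _check_finite(self) -> None:
        if not np.all(np.isfinite(self.rho)):
            bad = np.argwhere(~np.isfinite(self.rho))
            raise NumericError(f"non-finite density at voxel index {tuple(bad[0])}")

    # ----------------------------------------------------------- solver steps

    def diffusion_decay_step(self, dt: float) -> "MicroenvironmentField":
        """One LOD step of diffusion and decay for every substrate.

        Applies an x-, then y-, then z-sweep of backward-Euler-in-time,
        centered-in-space 1-D solves.  Each sweep carries one third of
        the decay term so the composition is first-order accurate.
        Dirichlet voxels are re-imposed after each sweep; all other
        domain faces are zero-flux.  Mutates and returns ``self``.
        """
        if dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {dt}")
        self._check_finite()
        dx2 = self.mesh.dx**2
        for s in range(self.n_substrates):
            r = float(self.D[s]) * dt / dx2
            ldt3 = float(self.lam[s]) * dt / 3.0
            rho_s = np.ascontiguousarray(self.rho[..., s])
            dir_cache = self._coef_cache.get(("dirichlet", s))
            if dir_cache is None and self.dirichlet_mask is not None:
                m = self.dirichlet_mask[..., s]
                dir_cache = (np.flatnonzero(m.ravel()),
                             self.dirichlet_value[..., s][m])
                self._coef_cache[("dirichlet", s)] = dir_cache
            for axis in range(3):
                n = self.mesh.shape[axis]
                key = (n, r, ldt3)
                coef = self._coef_cache.get(key)
                if coef is None:
                    coef = _kernels.thomas_coefficients(n, r, ldt3)
                    self._coef_cache[key] = coef
                _kernels.sweep(axis, rho_s, r, *coef)
                if dir_cache is not None and dir_cache[0].size:
                    rho_s.ravel()[dir_cache[0]] = dir_cache[1]
            self.rho[..., s] = rho_s
        return self

    def bulk_source_sink_step(self, dt: float) -> "MicroenvironmentField":
        """Backward-Euler update of the bulk supply/uptake terms, per voxel:

            rho <- (rho + dt * S * rho*) / (1 + dt * (S + U))
        """
        if dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {dt}")
        if self.S_bulk is None and self.U_bulk is None:
            return self
        S = np.asarray(self.S_bulk if self.S_bulk is not None else 0.0)
        U = np.asarray(self.U_bulk if self.U_bulk is not None else 0.0)
        if np.any(S < 0) or np.any(U < 0):
            raise ConfigurationError("bulk supply/uptake rates must be nonnegative")
        rho_star = np.asarray(self.rho_star_bulk if self.rho_star_bulk is not None else 0.0)
        self.rho[:] = (self.rho + dt * S * rho_star) / (1.0 + dt * (S + U))
        self.apply_dirichlet()
        return self

    def cell_source_sink_step(self, cells, dt: float) -> "MicroenvironmentField":
        """Backward-Euler update of cell-centered sources and sinks.

        ``cells`` is an iterable of objects exposing ``position``,
        ``volume`` (the source weight W_k, um^3) and per-substrate
        ``secretion_rates``, ``uptake_rates``, ``saturation_densities``
        arrays.  In the voxel containing each cell center:

            rho <- (rho + dt*(W/V_voxel)*S_k*rho*_k) / (1 + dt*(W/V_voxel)*(S_k+U_k))

        Cells sharing a voxel are processed sequentially in ascending
        cell order; cells outside the domain are clamped to the nearest
        voxel with a once-per-cell warning.
        """
        cells = list(cells)
        if not cells:
            return self
        positions = np.array([c.position for c in cells], dtype=float)
        W = np.array([c.volume for c in cells], dtype=float)
        S = np.array([c.secretion_rates for c in cells], dtype=float)
        U = np.array([c.uptake_rates for c in cells], dtype=float)
        rho_star = np.array([c.saturation_densities for c in cells], dtype=float)
        ids = [getattr(c, "id", i) for i, c in enumerate(cells)]
        return self.source_sink_batch(positions, W, S, U, rho_star, dt, ids=ids)

    def source_sink_batch(self, positions, W, S, U, rho_star, dt: float,
                          ids=None) -> "MicroenvironmentField":
        """Vectorized form of :meth:`cell_source_sink_step` on plain arrays."""
        if dt <= 0:
            raise ConfigurationError(f"dt must be positive, got {dt}")
        if np.any(S < 0) or np.any(U < 0):
            raise ConfigurationError("cell secretion/uptake rates must be nonnegative")
        inside = self.mesh.contains(positions)
        if not inside.all() and ids is not None:
            for i in np.flatnonzero(~inside):
                cid = ids[i]
                if cid not in self._warned_outside:
                    self._warned_outside.add(cid)
                    log.warning("cell %s outside domain; clamped to nearest voxel", cid)
        idx = self.mesh.voxel_of_batch(np.atleast_2d(positions))
        flat = self.mesh.flatten_index(idx)
        w = (np.asarray(W, dtype=float) / self.mesh.voxel_volume)[:, None]
        num = dt * w * S * rho_star
        den = dt * w * (S + U)
        rho_flat = self.rho.reshape(-1, self.n_substrates)

        # sequential rounds handle multiple cells per voxel in ascending order
        order = np.lexsort((np.arange(flat.size), flat))
        sorted_flat = flat[order]
        first = np.ones(flat.size, dtype=bool)
        first[1:] = sorted_flat[1:] != sorted_flat[:-1]
        rank = np.arange(flat.size) - np.maximum.accumulate(
            np.where(first, np.arange(flat.size), 0))
        max_rank = int(rank.max()) if flat.size else 0
        for rnd in range(max_rank + 1):
            sel = order[rank == rnd]
            v = flat[sel]
            rho_flat[v] = (rho_flat[v] + num[sel]) / (1.0 + den[sel])
        self.apply_dirichlet()
        return self

    def prepare_cell_sources(self, cells, dt: float) -> "PreparedCellSources":
        """Precompute the per-voxel backward-Euler factors for a fixed
        set of cells (positions, volumes and rates frozen).  Applying
        the prepared object is equivalent to :meth:`cell_source_sink_step`
        but costs only a few vector operations per diffusion step."""
        cells = list(cells)
        positions = np.array([c.position for c in cells], dtype=float)
        W = np.array([c.volume for c in cells], dtype=float)
        S = np.array([c.secretion_rates for c in cells], dtype=float)
        U = np.array([c.uptake_rates for c in cells], dtype=float)
        rho_star = np.array([c.saturation_densities for c in cells], dtype=float)
        if np.any(S < 0) or np.any(U < 0):
            raise ConfigurationError("cell secretion/uptake rates must be nonnegative")
        inside = self.mesh.contains(positions) if len(cells) else np.ones(0, bool)
        if len(cells) and not inside.all():
            for i in np.flatnonzero(~inside):
                cid = cells[i].id
                if cid not in self._warned_outside:
                    self._warned_outside.add(cid)
                    log.warning("cell %s outside domain; clamped to nearest voxel", cid)
        idx = self.mesh.voxel_of_batch(np.atleast_2d(positions)) if len(cells) else None
        flat = self.mesh.flatten_index(idx) if len(cells) else np.empty(0, np.int64)
        w = (W / self.mesh.voxel_volume)[:, None] if len(cells) else None
        num = dt * w * S * rho_star if len(cells) else None
        den = dt * w * (S + U) if len(cells) else None
        rounds = []
        if len(cells):
            order = np.lexsort((np.arange(flat.size), flat))
            sorted_flat = flat[order]
            first = np.ones(flat.size, dtype=bool)
            first[1:] = sorted_flat[1:] != sorted_flat[:-1]
            rank = np.arange(flat.size) - np.maximum.accumulate(
                np.where(first, np.arange(flat.size), 0))
            for rnd in range(int(rank.max()) + 1):
                sel = order[rank == rnd]
                rounds.append((flat[sel], num[sel], 1.0 + den[sel]))
        return PreparedCellSources(rounds)

    def step(self, cells, dt: float,
             prepared: "PreparedCellSources | None" = None) -> "MicroenvironmentField":
        """One full operator-split microenvironment update:
        bulk source/sinks, then cell source/sinks, then diffusion-decay."""
        self.bulk_source_sink_step(dt)
        if prepared is not None:
            prepared.apply(self)
            self.apply_dirichlet()
        elif cells:
            self.cell_source_sink_step(cells, dt)
        return self.diffusion_decay_step(dt)


@dataclass
class PreparedCellSources:
    """Cached cell source/sink update (see
    :meth:`MicroenvironmentField.prepare_cell_sources`)."""

    rounds: list

    def apply(self, field: "MicroenvironmentField") -> None:
        rho_flat = field.rho.reshape(-1, field.n_substrates)
        for v, num, den in self.rounds:
            rho_flat[v] = (rho_flat[v] + num) / den
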