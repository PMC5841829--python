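"""Numba kernels for the locally one-dimensional diffusion sweeps.

Each sweep solves, in every 1-D strip along one axis, the tridiagonal
system arising from backward-Euler time discretization and centered
second differences of the diffusion operator, with one third of the
decay term carried per sweep.  The forward-sweep coefficients depend
only on (axis length, diffusion number, decay number) and are
precomputed once and cached by the caller.

All kernels mutate ``rho`` (a 3-D array for one substrate) in place.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def thomas_coefficients(n, r, ldt3):
    """Forward-sweep coefficients for the 1-D diffusion-decay matrix.

    Matrix rows: interior ``[-r, 1+2r+ldt3, -r]``; first and last rows
    ``[1+r+ldt3, -r]`` (zero-flux closure).  Returns ``(cprime, inv_denom)``
    arrays of length n such that the forward elimination is

        d'_0 = d_0 * inv_denom[0]
        d'_i = (d_i + r * d'_{i-1}) * inv_denom[i]

    and back substitution is ``x_i = d'_i - cprime[i] * x_{i+1}``.
    """
    cprime = np.empty(n)
    inv_denom = np.empty(n)
    b_first = 1.0 + r + ldt3
    b_mid = 1.0 + 2.0 * r + ldt3
    cprime[0] = -r / b_first
    inv_denom[0] = 1.0 / b_first
    for i in range(1, n - 1):
        denom = b_mid + r * cprime[i - 1]  # b - a*c' with a = -r
        cprime[i] = -r / denom
        inv_denom[i] = 1.0 / denom
    if n > 1:
        denom = b_first + r * cprime[n - 2]
        cprime[n - 1] = 0.0
        inv_denom[n - 1] = 1.0 / denom
    return cprime, inv_denom


@njit(cache=True)
def sweep_x(rho, r, cprime, inv_denom):
    nx, ny, nz = rho.shape
    for j in range(ny):
        for k in range(nz):
            rho[0, j, k] = rho[0, j, k] * inv_denom[0]
            for i in range(1, nx):
                rho[i, j, k] = (rho[i, j, k] + r * rho[i - 1, j, k]) * inv_denom[i]
            for i in range(nx - 2, -1, -1):
                rho[i, j, k] -= cprime[i] * rho[i + 1, j, k]


@njit(cache=True)
def sweep_y(rho, r, cprime, inv_denom):
    nx, ny, nz = rho.shape
    for i in range(nx):
        for k in range(nz):
            rho[i, 0, k] = rho[i, 0, k] * inv_denom[0]
            for j in range(1, ny):
                rho[i, j, k] = (rho[i, j, k] + r * rho[i, j - 1, k]) * inv_denom[j]
            for j in range(ny - 2, -1, -1):
                rho[i, j, k] -= cprime[j] * rho[i, j + 1, k]


@njit(cache=True)
def sweep_z(rho, r, cprime, inv_denom):
    nx, ny, nz = rho.shape
    for i in range(nx):
        for j in range(ny):
            rho[i, j, 0] = rho[i, j, 0] * inv_denom[0]
            for k in range(1, nz):
                rho[i, j, k] = (rho[i, j, k] + r * rho[i, j, k - 1]) * inv_denom[k]
            for k in range(nz - 2, -1, -1):
                rho[i, j, k] -= cprime[k] * rho[i, j, k + 1]


_SWEEPS = (sweep_x, sweep_y, sweep_z)


def sweep(axis, rho, r, cprime, inv_denom):
    """Run one tridiagonal sweep along ``axis`` (0, 1 or 2) in place."""
    _SWEEPS[axis](rho, r, cprime, inv_denom)
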