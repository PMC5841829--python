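"""Post-processing of showcase runs: growth curves, spatial statistics."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from multicell.errors import ConfigurationError


@dataclass
class GrowthFit:
    """Diameter-vs-time series with a late-time linear fit."""

    times: np.ndarray          # min
    diameters: np.ndarray      # um
    slope: float               # um/min, fitted over the late-time window
    intercept: float
    r_squared: float
    method: str                # how the diameter was measured


def equivalent_diameter(population) -> float:
    """Diameter of the sphere holding the population's total cell volume."""
    total = sum(c.phenotype.volume.V for c in population)
    return 2.0 * (3.0 * total / (4.0 * math.pi)) ** (1.0 / 3.0)


def spatial_diameter(population, volume_fraction: float = 0.90) -> float:
    """Physical tumor diameter: twice the radius (from the
    volume-weighted centroid) that encloses the given fraction of the
    total cell volume.  More robust to single stray cells than a
    max-extent measure."""
    pos = np.array([c.position for c in population])
    V = np.array([c.phenotype.volume.V for c in population])
    center = np.average(pos, axis=0, weights=V)
    r = np.linalg.norm(pos - center, axis=1)
    order = np.argsort(r)
    cum = np.cumsum(V[order])
    k = min(int(np.searchsorted(cum, volume_fraction * cum[-1])), len(r) - 1)
    return 2.0 * float(r[order][k])


def spheroid_growth_analysis(snapshots, late_fraction: float = 0.5,
                             method: str = "equivalent_volume",
                             smooth_window: int = 1) -> GrowthFit:
    """Fit the late-time slope of the diameter-vs-time curve.

    ``snapshots`` is a sequence of ``(t_min, population_or_diameter)``
    pairs.  With growth confined to an outer shell of fixed thickness,
    dV/dt ~ surface area implies dR/dt = const, i.e. a linear
    late-time diameter curve.  ``method`` selects the diameter measure
    when populations are given ("equivalent_volume" or "spatial").
    ``smooth_window`` > 1 applies a centered moving average before the
    fit: at desk scale single division/removal events are visible in
    the diameter (one cell is ~1 um of diameter), a granularity the
    published populations average out.
    """
    if len(snapshots) < 3:
        raise ConfigurationError("need at least 3 snapshots for a growth fit")
    measure = spatial_diameter if method == "spatial" else equivalent_diameter
    times, diams = [], []
    for t, item in snapshots:
        times.append(float(t))
        if np.isscalar(item) or isinstance(item, float):
            diams.append(float(item))
        else:
            diams.append(measure(item))
    times = np.asarray(times)
    diams = np.asarray(diams)
    if smooth_window > 1:
        k = smooth_window
        diams = np.convolve(diams, np.ones(k) / k, mode="valid")
        times = times[(k - 1) // 2: (k - 1) // 2 + diams.size]
    n_late = max(3, int(round(late_fraction * len(times))))
    t_fit, d_fit = times[-n_late:], diams[-n_late:]
    slope, intercept = np.polyfit(t_fit, d_fit, 1)
    pred = slope * t_fit + intercept
    ss_res = float(np.sum((d_fit - pred) ** 2))
    ss_tot = float(np.sum((d_fit - d_fit.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GrowthFit(times, diams, float(slope), float(intercept), r2, method)


def radial_positions(population, center=None) -> np.ndarray:
    pos = np.array([c.position for c in population])
    if center is None:
        center = pos.mean(axis=0)
    return np.linalg.norm(pos - center, axis=1)


def perinecrotic_mixing_width(population, center=None,
                              lo_pct: float = 5.0, hi_pct: float = 95.0) -> float:
    """Width (um) of the radial band where viable and necrotic cells
    intermix: distance from the 5th-percentile viable radius up to the
    95th-percentile necrotic radius.  Near zero for a sharp interface;
    one to several cell diameters for a stochastic perinecrotic
    transition zone."""
    pos = np.array([c.position for c in population])
    if center is None:
        center = pos.mean(axis=0)
    r = np.linalg.norm(pos - center, axis=1)
    necrotic = np.array([c.is_dead and "necrotic" in c.phenotype.death.mode
                         for c in population])
    viable = ~np.array([c.is_dead for c in population])
    if not necrotic.any() or not viable.any():
        return 0.0
    r_nec_hi = np.percentile(r[necrotic], hi_pct)
    r_via_lo = np.percentile(r[viable], lo_pct)
    return float(max(r_nec_hi - r_via_lo, 0.0))


def hypoxic_viable_fraction(population, field, threshold: float = 5.0) -> tuple[float, int]:
    """(fraction of cells in hypoxic voxels that are still viable,
    number of hypoxic cells).

    Deterministic necrosis kills every cell the moment its voxel drops
    below the threshold, so this fraction stays near zero (a sharp
    perinecrotic interface); stochastic necrosis lets viable cells
    linger in hypoxia, producing a mixed perinecrotic zone.
    """
    hypoxic = [c for c in population
               if field.density_at(c.position, "oxygen") < threshold]
    if not hypoxic:
        return 0.0, 0
    viable = sum(1 for c in hypoxic if not c.is_dead)
    return viable / len(hypoxic), len(hypoxic)


def mean_cycling_radius_excess(population, cycling_phases=("K1", "K2"),
                               center=None) -> float:
    """Mean radial position of cycling (Ki67+) cells minus that of all
    viable cells (um).  Positive when proliferation concentrates in the
    outer, better-oxygenated shell."""
    viable = [c for c in population if not c.is_dead]
    cycling = [c for c in viable
               if c.phenotype.cycle is not None
               and c.phenotype.cycle.current_phase in cycling_phases]
    if not cycling or not viable:
        return 0.0
    pos = np.array([c.position for c in viable])
    if center is None:
        center = pos.mean(axis=0)
    r_all = np.linalg.norm(pos - center, axis=1).mean()
    r_cyc = np.linalg.norm(
        np.array([c.position for c in cycling]) - center, axis=1).mean()
    return float(r_cyc - r_all)


def mean_custom(population, key: str, default: float = np.nan) -> float:
    values = [c.custom.get(key) for c in population if key in c.custom]
    return float(np.mean(values)) if values else default
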