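"""Snapshot I/O: cell tables as CSV, substrate fields as HDF5 (one
dataset per substrate with mesh metadata), RNG states as JSON.

Write-then-read round trips reproduce positions and volumes exactly
(floats are serialized with round-trip precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from multicell.errors import ConfigurationError

VOLUME_COLUMNS = ["total", "fluid", "nuclear_solid", "cyto_solid",
                  "nuclear", "cyto", "target_ns", "target_ff"]


def _stamp(t: float) -> str:
    return f"{t:012.3f}"


def cells_to_frame(population) -> pd.DataFrame:
    """Per-cell snapshot table."""
    rows = []
    custom_keys: list[str] = []
    for c in population:
        for k in c.custom:
            if k not in custom_keys:
                custom_keys.append(k)
    for c in population:
        vs = c.phenotype.volume
        cyc = c.phenotype.cycle
        ds = c.phenotype.death
        partner = c.attachments[0].partner.id if c.attachments else -1
        row = {
            "id": c.id,
            "type": c.type_name,
            "x": c.position[0], "y": c.position[1], "z": c.position[2],
            "phase": cyc.current_phase if cyc is not None else "live",
            "time_in_phase": cyc.time_in_phase if cyc is not None else 0.0,
            "death_mode": ds.mode if ds is not None else "none",
            "total": vs.V, "fluid": vs.V_F,
            "nuclear_solid": vs.V_NS, "cyto_solid": vs.V_CS,
            "nuclear": vs.V_N, "cyto": vs.V_C,
            "target_ns": vs.V_NS_star, "target_ff": vs.f_F,
            "attachment_partner": partner,
        }
        for k in custom_keys:
            row[k] = c.custom.get(k, np.nan)
        rows.append(row)
    columns = ["id", "type", "x", "y", "z", "phase", "time_in_phase",
               "death_mode", *VOLUME_COLUMNS, "attachment_partner", *custom_keys]
    return pd.DataFrame(rows, columns=columns)


def write_snapshot(population, field, t: float, out_dir) -> Path:
    """Write the cell table and field arrays for time ``t`` (minutes).

    Returns the directory written into.  Files:
    ``cells_<t>.csv`` and ``field_<t>.h5``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(t)
    frame = cells_to_frame(population)
    frame.to_csv(out / f"cells_{stamp}.csv", index=False, float_format="%.17g")
    if field is not None:
        with h5py.File(out / f"field_{stamp}.h5", "w") as h5:
            h5.attrs["t"] = t
            h5.attrs["origin"] = field.mesh.origin
            h5.attrs["dx"] = field.mesh.dx
            h5.attrs["shape"] = field.mesh.shape
            for s, name in enumerate(field.substrate_names):
                h5.create_dataset(name, data=field.rho[..., s])
    return out


def read_snapshot(snap_dir, t: float):
    """Read back a snapshot: (cells DataFrame, {substrate: array}, mesh_meta)."""
    snap = Path(snap_dir)
    stamp = _stamp(t)
    cells_path = snap / f"cells_{stamp}.csv"
    if not cells_path.exists():
        raise ConfigurationError(f"no snapshot at t={t} in {snap}")
    cells = pd.read_csv(cells_path, float_precision="round_trip")
    fields: dict[str, np.ndarray] = {}
    meta: dict = {}
    h5_path = snap / f"field_{stamp}.h5"
    if h5_path.exists():
        with h5py.File(h5_path, "r") as h5:
            meta = {"t": float(h5.attrs["t"]),
                    "origin": tuple(h5.attrs["origin"]),
                    "dx": float(h5.attrs["dx"]),
                    "shape": tuple(int(v) for v in h5.attrs["shape"])}
            for name in h5:
                fields[name] = h5[name][...]
    return cells, fields, meta


def field_to_csv(field, path, substrates=None) -> Path:
    """Per-voxel delimited-text export: x, y, z followed by one column
    per substrate (voxel centers, um)."""
    names = substrates or field.substrate_names
    xs = field.mesh.axis_centers(0)
    ys = field.mesh.axis_centers(1)
    zs = field.mesh.axis_centers(2)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    data = {"x": X.ravel(), "y": Y.ravel(), "z": Z.ravel()}
    for name in names:
        data[name] = field.rho[..., field.substrate_index(name)].ravel()
    pd.DataFrame(data).to_csv(path, index=False)
    return Path(path)


def save_rng_state(rng_streams: dict, path) -> None:
    """Serialize the bit-generator state of every RNG stream to JSON so
    an interrupted run can continue with identical draws."""
    state = {name: gen.bit_generator.state for name, gen in rng_streams.items()}
    Path(path).write_text(json.dumps(state, default=int))


def load_rng_state(rng_streams: dict, path) -> None:
    state = json.loads(Path(path).read_text())
    for name, gen in rng_streams.items():
        if name in state:
            gen.bit_generator.state = state[name]


def restore_population(sim, cells: pd.DataFrame, config, type_map=None) -> None:
    """Rebuild a population from a snapshot table into an empty
    simulator built from the same config.

    Phenotypes are reconstructed from the config cell types and then
    overwritten with the per-cell state columns (position, sub-volumes,
    phase, time in phase, death mode).
    """
    from multicell import death as death_mod
    from multicell.cell import Cell

    if len(sim.population):
        raise ConfigurationError("restore requires an empty simulator")
    by_name = {ct["name"]: ct for ct in config.cell_types}
    names = sim.field.substrate_names
    for _, row in cells.iterrows():
        ct = by_name.get(row["type"], {"name": row["type"]})
        ph = config.build_phenotype(ct, sim.field.n_substrates, names)
        cell = Cell(int(row["id"]), ph,
                    np.array([row["x"], row["y"], row["z"]]), row["type"])
        sim.population.cells.append(cell)
        sim.grid.register(cell)
        vs = ph.volume
        vs.V_F = row["fluid"]
        vs.V_NS = row["nuclear_solid"]
        vs.V_CS = row["cyto_solid"]
        vs.V_NS_star = row["target_ns"]
        vs.f_F = row["target_ff"]
        vs._partition()
        if ph.cycle is not None and row["death_mode"] == "none":
            ph.cycle.current_phase = row["phase"]
            ph.cycle.time_in_phase = row["time_in_phase"]
        mode = row["death_mode"]
        if mode != "none" and ph.death is not None:
            if mode == death_mod.MODE_APOPTOTIC:
                death_mod.start_apoptosis(cell)
            else:
                death_mod.start_necrosis(cell)
                if mode == death_mod.MODE_NECROTIC_LYSED:
                    vs.f_F = 0.0
                    ph.death.mode = mode
    # ids continue past the snapshot so they are never reused
    max_id = int(cells["id"].max()) if len(cells) else -1
    sim.population._next_id = max(sim.population._next_id, max_id + 1)
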