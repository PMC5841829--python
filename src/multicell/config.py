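"""Structured-text (YAML) configuration: schema validation and
construction of a ready-to-run :class:`~multicell.simulator.Simulator`.

Unknown keys are rejected with their location; units are as declared
throughout the package (um, min, mmHg).  Defaults are injected from
the reference parameter table (:mod:`multicell.reference`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from multicell import reference
from multicell.cycle import (Ki67AdvancedParams, ki67_advanced_model, live_model)
from multicell.death import DeathState
from multicell.errors import ConfigurationError
from multicell.mechanics import PlaneMembrane, TestTubeMembrane
from multicell.microenvironment import Mesh, MicroenvironmentField
from multicell.phenotype import (MechanicsParams, MotilityState, Phenotype,
                                 SecretionState)
from multicell.simulator import Scheduler, Simulator
from multicell.volume import equilibrium_volume_state

_TOP_KEYS = {"domain", "time", "substrates", "cell_types", "placements",
             "output", "seed", "mechanics_voxel_edge", "basement_membrane",
             "sample_model"}
_DOMAIN_KEYS = {"x_min", "x_max", "y_min", "y_max", "z_min", "z_max", "dx"}
_TIME_KEYS = {"dt_diff", "dt_mech", "dt_cells", "dt_save", "t_max"}
_SUBSTRATE_KEYS = {"name", "units", "D", "lambda", "initial", "S", "U",
                   "rho_star", "boundary"}
_BOUNDARY_KEYS = {"type", "value"}
_CELL_TYPE_KEYS = {"name", "volume", "mechanics", "motility", "secretion",
                   "cycle", "death"}
_PLACEMENT_KEYS = {"type", "cell_type", "n", "center", "radius", "positions",
                   "file", "spacing"}


def _check_keys(mapping: dict, allowed: set, path: str) -> None:
    if not isinstance(mapping, dict):
        raise ConfigurationError(f"{path}: expected a mapping")
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}")


@dataclass
class SimulationConfig:
    """Validated simulation configuration."""

    domain: dict
    time: dict
    substrates: list
    cell_types: list = dc_field(default_factory=list)
    placements: list = dc_field(default_factory=list)
    output: dict = dc_field(default_factory=dict)
    seed: int | None = None
    mechanics_voxel_edge: float = reference.MECHANICS_VOXEL_EDGE
    basement_membrane: dict | None = None
    sample_model: str | None = None

    # ------------------------------------------------------------ validation

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        _check_keys(raw, _TOP_KEYS, "config")
        if "domain" not in raw:
            raise ConfigurationError("config: missing required section 'domain'")
        if "substrates" not in raw or not raw["substrates"]:
            raise ConfigurationError("config: at least one substrate is required")
        _check_keys(raw["domain"], _DOMAIN_KEYS, "domain")
        time = dict(raw.get("time", {}))
        _check_keys(time, _TIME_KEYS, "time")
        time.setdefault("dt_diff", 0.01)
        time.setdefault("dt_mech", 0.1)
        time.setdefault("dt_cells", 6.0)
        time.setdefault("dt_save", 60.0)
        time.setdefault("t_max", 60.0)
        if time["dt_mech"] < time["dt_diff"]:
            raise ConfigurationError(
                f"time: dt_mech ({time['dt_mech']}) must not be below "
                f"dt_diff ({time['dt_diff']})")
        if time["dt_cells"] < time["dt_mech"]:
            raise ConfigurationError(
                f"time: dt_cells ({time['dt_cells']}) must not be below "
                f"dt_mech ({time['dt_mech']})")
        for i, sub in enumerate(raw["substrates"]):
            _check_keys(sub, _SUBSTRATE_KEYS, f"substrates[{i}]")
            if "name" not in sub:
                raise ConfigurationError(f"substrates[{i}]: missing 'name'")
            if "boundary" in sub:
                _check_keys(sub["boundary"], _BOUNDARY_KEYS, f"substrates[{i}].boundary")
                btype = sub["boundary"].get("type")
                if btype not in ("dirichlet", "zero_flux"):
                    raise ConfigurationError(
                        f"substrates[{i}].boundary.type must be "
                        f"'dirichlet' or 'zero_flux', got {btype!r}")
        for i, ct in enumerate(raw.get("cell_types", [])):
            _check_keys(ct, _CELL_TYPE_KEYS, f"cell_types[{i}]")
        for i, pl in enumerate(raw.get("placements", [])):
            _check_keys(pl, _PLACEMENT_KEYS, f"placements[{i}]")
        return cls(
            domain=dict(raw["domain"]),
            time=time,
            substrates=[dict(s) for s in raw["substrates"]],
            cell_types=[dict(c) for c in raw.get("cell_types", [])],
            placements=[dict(p) for p in raw.get("placements", [])],
            output=dict(raw.get("output", {})),
            seed=raw.get("seed"),
            mechanics_voxel_edge=raw.get("mechanics_voxel_edge",
                                         reference.MECHANICS_VOXEL_EDGE),
            basement_membrane=raw.get("basement_membrane"),
            sample_model=raw.get("sample_model"),
        )

    # ---------------------------------------------------------- construction

    def build_mesh(self) -> Mesh:
        d = self.domain
        dx = float(d.get("dx", 20.0))
        origin = (float(d["x_min"]), float(d["y_min"]), float(d["z_min"]))
        shape = []
        for axis in ("x", "y", "z"):
            span = float(d[f"{axis}_max"]) - float(d[f"{axis}_min"])
            if span <= 0:
                raise ConfigurationError(f"domain: {axis}_max must exceed {axis}_min")
            n = int(round(span / dx))
            if abs(n * dx - span) > 1e-6 * dx:
                raise ConfigurationError(
                    f"domain: {axis} extent {span} is not a multiple of dx={dx}")
            shape.append(n)
        return Mesh(origin, tuple(shape), dx)

    def build_membrane(self):
        bm = self.basement_membrane
        if not bm or bm.get("type", "none") == "none":
            return None
        kind = bm["type"]
        if kind == "plane":
            return PlaneMembrane(tuple(bm["point"]), tuple(bm["inward_normal"]))
        if kind == "test_tube":
            return TestTubeMembrane(float(bm["radius"]), float(bm.get("x_cap", 0.0)),
                                    tuple(bm.get("center_yz", (0.0, 0.0))))
        raise ConfigurationError(f"basement_membrane.type unknown: {kind!r}")

    def build_phenotype(self, cell_type: dict, n_substrates: int,
                        substrate_names: list[str]) -> Phenotype:
        vol_cfg = dict(cell_type.get("volume", {}))
        vs = equilibrium_volume_state(
            V_mature=vol_cfg.pop("V_mature", reference.MATURE_VOLUME),
            f_F=vol_cfg.pop("f_F", reference.FLUID_FRACTION),
            V_NS_star=vol_cfg.pop("V_NS_star", reference.NUCLEAR_SOLID_TARGET),
            r_F=vol_cfg.pop("r_F", reference.VOLUME_RATES["r_F"]),
            r_N=vol_cfg.pop("r_N", reference.VOLUME_RATES["r_N"]),
            r_C=vol_cfg.pop("r_C", reference.VOLUME_RATES["r_C"]),
            **vol_cfg,
        )
        mech = MechanicsParams(**{**reference.MECHANICS,
                                  **cell_type.get("mechanics", {})})
        mot_cfg = dict(cell_type.get("motility", {}))
        motility = MotilityState(
            enabled=mot_cfg.get("enabled", False),
            T_per=mot_cfg.get("T_per", 1.0),
            s_mot=mot_cfg.get("s_mot", 1.0),
            b=mot_cfg.get("b", 0.0),
        )
        secretion = SecretionState.zeros(n_substrates)
        for name, rates in cell_type.get("secretion", {}).items():
            if name not in substrate_names:
                raise ConfigurationError(
                    f"cell type {cell_type.get('name')}: secretion targets "
                    f"unknown substrate {name!r}")
            s = substrate_names.index(name)
            secretion.secretion[s] = rates.get("S", 0.0)
            secretion.uptake[s] = rates.get("U", 0.0)
            secretion.saturation[s] = rates.get("rho_star", 0.0)

        cycle_cfg = dict(cell_type.get("cycle", {"model": "none"}))
        model_name = cycle_cfg.pop("model", "none")
        if model_name == "ki67_advanced":
            fixed = cycle_cfg.pop("fixed_durations", True)
            params = Ki67AdvancedParams(**{**reference.KI67_ADVANCED, **cycle_cfg})
            cycle_state = ki67_advanced_model(params, fixed_durations=fixed).new_state()
        elif model_name == "live":
            cycle_state = live_model(cycle_cfg.pop("birth_rate", 0.0432 / 60.0)).new_state()
        elif model_name == "none":
            cycle_state = None
        else:
            raise ConfigurationError(f"cycle.model unknown: {model_name!r}")

        death_cfg = dict(cell_type.get("death", {}))
        necrosis = dict(death_cfg.pop("necrosis", {}))
        death_state = DeathState(
            r_A=death_cfg.pop("apoptosis_rate", reference.DEATH["apoptosis_rate"]),
            T_A=death_cfg.pop("T_A", reference.DEATH["T_A"]),
            pO2_threshold=necrosis.get("pO2_threshold",
                                       reference.DEATH["pO2_threshold"]),
            pO2_crit=necrosis.get("pO2_crit", reference.DEATH["pO2_crit"]),
            r_N_max=necrosis.get("r_max", reference.DEATH["r_N_max"]),
            necrosis_type=necrosis.get("type", "stochastic"),
        )
        if death_cfg:
            raise ConfigurationError(
                f"cell type {cell_type.get('name')}: unknown death key(s) "
                f"{sorted(death_cfg)}")
        return Phenotype(volume=vs, mechanics=mech, motility=motility,
                         secretion=secretion, cycle=cycle_state, death=death_state)

    def build_simulator(self, seed: int | None = None) -> Simulator:
        """Construct the simulator: mesh, field, scheduler, membrane,
        phenotypes, and initial cell placements."""
        mesh = self.build_mesh()
        field = MicroenvironmentField.create(mesh, self.substrates)
        t = self.time
        sch = Scheduler(dt_diff=t["dt_diff"], dt_mech=t["dt_mech"],
                        dt_cells=t["dt_cells"], dt_save=t["dt_save"],
                        t_max=t["t_max"])
        sim = Simulator(field, sch, seed=seed if seed is not None else self.seed,
                        bm=self.build_membrane(),
                        mechanics_voxel_edge=self.mechanics_voxel_edge)
        phenotypes = {ct["name"]: ct for ct in self.cell_types}
        names = field.substrate_names
        for pl in self.placements:
            type_name = pl.get("cell_type", "default")
            if type_name not in phenotypes:
                raise ConfigurationError(f"placement uses unknown cell type {type_name!r}")
            ct = phenotypes[type_name]
            for position in _placement_positions(pl, mesh, sim.rng["init"]):
                sim.add_cell(self.build_phenotype(ct, field.n_substrates, names),
                             position, type_name)
        return sim


def _placement_positions(pl: dict, mesh: Mesh, rng) -> list:
    kind = pl.get("type", "list")
    if kind == "list":
        return [np.asarray(p, dtype=float) for p in pl.get("positions", [])]
    if kind == "file":
        table = np.loadtxt(pl["file"], delimiter=",", skiprows=1, ndmin=2)
        return [row[:3] for row in table]
    if kind == "spheroid":
        from multicell.fixtures import sphere_packed_positions

        center = np.asarray(pl.get("center", np.mean(mesh.extents, axis=1)), dtype=float)
        return list(sphere_packed_positions(int(pl["n"]), center,
                                            spacing=float(pl.get("spacing", 15.0)),
                                            rng=rng))
    raise ConfigurationError(f"placement type unknown: {kind!r}")


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return SimulationConfig.from_dict(raw)
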