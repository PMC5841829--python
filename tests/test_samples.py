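"""Showcase model rules at unit level: elastic links, drug damage,
immune contact machinery, worker-cargo state machine, growth analysis."""

import numpy as np
import pytest

from conftest import make_mech_cell
from multicell.microenvironment import Mesh, MicroenvironmentField
from multicell.samples.analysis import GrowthFit, spheroid_growth_analysis
from multicell.samples.anticancer import DAMAGE_RATES, update_damage
from multicell.samples.biorobots import (elastic_attachment_velocity,
                                         worker_cargo_rules)
from multicell.samples.heterogeneity import (draw_oncoprotein,
                                             heterogeneity_rate_hook)
from multicell.samples.immune import ImmuneParams, immune_contact_rules


def _field_with(name_values: dict, shape=(4, 4, 4)):
    subs = [{"name": k, "D": 0.0, "lambda": 0.0, "initial": v}
            for k, v in name_values.items()]
    return MicroenvironmentField.create(Mesh((-40, -40, -40), shape, 20.0), subs)


# ------------------------------------------------------ elastic attachment

def test_elastic_attachment_velocity_values():
    a = make_mech_cell(0, (0.0, 0.0, 0.0))
    b = make_mech_cell(1, (10.0, 0.0, 0.0))
    va, vb = elastic_attachment_velocity(a, b, k=0.05)
    np.testing.assert_allclose(va, [0.5, 0.0, 0.0])
    np.testing.assert_allclose(va + vb, np.zeros(3))
    coincident = make_mech_cell(2, (0.0, 0.0, 0.0))
    v0, _ = elastic_attachment_velocity(a, coincident, k=0.05)
    np.testing.assert_array_equal(v0, np.zeros(3))


def test_attachment_links_are_symmetric_and_dissolve():
    a = make_mech_cell(0, (0, 0, 0))
    b = make_mech_cell(1, (5, 0, 0))
    a.attach_to(b, 0.05)
    assert a.attachments[0].partner is b
    assert b.attachments[0].partner is a
    a.attach_to(b, 0.05)  # idempotent
    assert len(a.attachments) == 1
    b.detach_all()
    assert a.attachments == [] and b.attachments == []


# ------------------------------------------------------------ drug damage

def test_update_damage_fixed_point_and_death_rate_definition():
    # no drug, no damage: nothing happens
    d, p = update_damage(0.0, 0.0, 6.0)
    assert d == 0.0 and p == 0.0
    # steady state: r_damage * drug / r_repair
    drug = 0.8
    steady = DAMAGE_RATES["r_damage"] * drug / DAMAGE_RATES["r_repair"]
    d, _ = update_damage(steady, drug, 6.0)
    assert d == pytest.approx(steady, rel=1e-12)
    # r_death is the death rate at [damage] = 1
    _, p = update_damage(1.0, DAMAGE_RATES["r_repair"] / DAMAGE_RATES["r_damage"], 6.0)
    assert p == pytest.approx(DAMAGE_RATES["r_death"] * 6.0, rel=1e-9)


def test_damage_euler_step_value():
    d, _ = update_damage(0.2, 1.0, 6.0, r_damage=0.03, r_repair=0.004)
    assert d == pytest.approx(0.2 + 6.0 * (0.03 * 1.0 - 0.004 * 0.2), rel=1e-12)


# ------------------------------------------------------------ immune rules

def _tumor_target(p, cid=1):
    from multicell.death import DeathState

    cell = make_mech_cell(cid, (5.0, 0.0, 0.0))
    cell.type_name = "tumor"
    cell.custom["p"] = p
    cell.phenotype.death = DeathState()
    return cell


def test_immune_zero_oncoprotein_never_killed(rng):
    params = ImmuneParams(r_adhesion=1e9, r_kill=1e9, r_detach=0.0)
    immune = make_mech_cell(0, (0, 0, 0))
    immune.type_name = "immune"
    target = _tumor_target(0.0)
    immune_contact_rules(immune, [target], 0.1, rng, params)  # adheres
    assert immune.attachments
    for _ in range(200):
        events = immune_contact_rules(immune, [], 0.1, rng, params)
        assert not any(e[0] == "kill" for e in events)
    assert not target.is_dead


def test_immune_adhesion_probability_statistics(rng):
    params = ImmuneParams(r_adhesion=0.1, r_kill=0.0, r_detach=0.0)
    n, hits = 4000, 0
    for i in range(n):
        immune = make_mech_cell(2 * i, (0, 0, 0))
        immune.type_name = "immune"
        target = _tumor_target(1.0, cid=2 * i + 1)
        events = immune_contact_rules(immune, [target], 0.1, rng, params)
        hits += bool(events)
    p = 0.1 * 0.1
    se = np.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 4 * se


def test_immune_kill_then_detach_and_resume_search(rng):
    params = ImmuneParams(r_adhesion=1e9, r_kill=1e9, r_detach=0.0)
    immune = make_mech_cell(0, (0, 0, 0))
    immune.type_name = "immune"
    target = _tumor_target(1.0)
    immune_contact_rules(immune, [target], 0.1, rng, params)
    assert not immune.phenotype.motility.enabled
    events = immune_contact_rules(immune, [], 0.1, rng, params)
    assert ("kill", target.id) in events
    assert target.is_dead
    assert immune.attachments == []
    assert immune.phenotype.motility.enabled


# ------------------------------------------------------------ worker-cargo

def test_worker_picks_up_cargo_and_switches_off_receptor():
    field = _field_with({"c1": 0.0, "c2": 0.0})
    worker = make_mech_cell(0, (0, 0, 0))
    worker.type_name = "worker"
    cargo = make_mech_cell(1, (5, 0, 0))
    cargo.type_name = "cargo"
    cargo.custom["R"] = 1
    events = worker_cargo_rules(worker, [cargo], field, 0.1)
    assert ("pickup", cargo.id) in events
    assert cargo.custom["R"] == 0
    assert worker.attachments[0].partner is cargo
    # R = 0 cargo is not picked up again
    worker.detach_all()
    assert worker_cargo_rules(worker, [cargo], field, 0.1) == []


def test_worker_releases_cargo_above_c1_threshold():
    field = _field_with({"c1": 1.0, "c2": 0.0})
    worker = make_mech_cell(0, (0, 0, 0))
    worker.type_name = "worker"
    cargo = make_mech_cell(1, (5, 0, 0))
    cargo.type_name = "cargo"
    cargo.custom["R"] = 1
    worker_cargo_rules(worker, [cargo], _field_with({"c1": 0.0, "c2": 0.0}), 0.1)
    events = worker_cargo_rules(worker, [], field, 0.1)
    assert ("delivery", cargo.id) in events
    assert worker.attachments == []
    assert worker.custom["deliveries"] == 1


def test_anticancer_cargo_drops_below_oxygen_threshold():
    from multicell.samples.anticancer import make_cargo_drop_hook

    field = _field_with({"oxygen": 9.0, "c2": 0.0, "drug": 0.0})
    worker = make_mech_cell(0, (0, 0, 0))
    cargo = make_mech_cell(1, (5, 0, 0))
    cargo.type_name = "cargo"
    cargo.custom["R"] = 0
    cargo.phenotype.secretion.secretion = np.zeros(3)
    cargo.phenotype.secretion.uptake = np.zeros(3)
    cargo.phenotype.secretion.saturation = np.zeros(3)
    worker.attach_to(cargo, 0.05)
    hook = make_cargo_drop_hook(pO2_drop=10.0)
    hook(cargo, field, 6.0)
    assert cargo.custom["dropped"] is True
    assert cargo.attachments == []
    assert cargo.phenotype.secretion.secretion[field.substrate_index("drug")] > 0


# ---------------------------------------------------------- heterogeneity

def test_oncoprotein_distribution_and_rate_scaling(rng):
    p = draw_oncoprotein(rng, 5000)
    assert np.all((p >= 0.0) & (p <= 2.0))
    assert abs(p.mean() - 1.0) < 0.02
    cell = make_mech_cell(0, (0, 0, 0))
    cell.custom["p"] = 0.0
    assert heterogeneity_rate_hook(cell, 1e-3) == 0.0
    cell.custom["p"] = 2.0
    assert heterogeneity_rate_hook(cell, 1e-3) == pytest.approx(2e-3)


# -------------------------------------------------------- growth analysis

def test_growth_fit_static_population_zero_slope():
    snaps = [(t, 100.0) for t in np.arange(0, 600, 60.0)]
    fit = spheroid_growth_analysis(snaps)
    assert fit.slope == pytest.approx(0.0, abs=1e-12)


def test_growth_fit_recovers_synthetic_linear_slope():
    c = 0.035
    snaps = [(t, 80.0 + c * t) for t in np.arange(0, 2880, 180.0)]
    fit = spheroid_growth_analysis(snaps)
    assert fit.slope == pytest.approx(c, rel=0.01)
    assert fit.r_squared > 0.999
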