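"""Predator-pest dynamics: conservation, closed forms, events, coupling."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from hedgescape.dynamics import (
    Integrator,
    InoculationConfig,
    PesticideConfig,
    SpeciesParams,
    advance_pesticide,
    apply_pesticide_rule,
    draw_inoculation_schedule,
    exchange_interface,
    initial_state,
    inoculate,
    run_simulation,
    step,
)
from hedgescape.landscape import build_tessellation_fixture
from hedgescape.mesh import build_mesh
from tests.conftest import manual_allocation


def quiet_params(**kw):
    """All rates zero unless overridden (pure-transport scenarios)."""
    base = dict(
        d2v=0.0, d1v=0.0, m_v=0.0, beta=0.0, r_v=0.0, rho12=0.0, rho21=0.0,
        d2u=0.0, r_u=0.0, m_u=0.0,
    )
    base.update(kw)
    return SpeciesParams(**base)


def total_mass(state, mesh):
    return (
        state.u.sum() * mesh.cell_area,
        state.v_field.sum() * mesh.cell_area
        + float((state.v_hedge * mesh.hnode_len).sum()),
    )


@pytest.fixture(scope="module")
def mesh60(tess60, alloc60):
    return build_mesh(tess60, alloc60, 0.3)


class TestStep:
    def test_zero_state_stays_zero(self, tess60, alloc60, mesh60):
        state = initial_state(mesh60, quiet_params())
        state.v_hedge[:] = 0.0
        out = step(state, mesh60, SpeciesParams(), 0.5)
        assert not out.u.any()
        assert not out.v_field.any()
        assert not out.v_hedge.any()

    def test_pure_diffusion_conserves_mass(self, mesh60):
        p = quiet_params(d2u=0.01, d2v=0.008, d1v=0.012)
        state = initial_state(mesh60, p)
        rng = np.random.default_rng(0)
        state.u = rng.uniform(0, 1, mesh60.n_cells)
        state.v_field = rng.uniform(0, 1, mesh60.n_cells)
        state.v_hedge = rng.uniform(0, 1, mesh60.n_hedge_nodes)
        mu0, mv0 = total_mass(state, mesh60)
        integ = Integrator(mesh60, p, 0.5)
        for _ in range(50):
            integ.step(state)
        mu1, mv1 = total_mass(state, mesh60)
        assert abs(mu1 - mu0) / mu0 < 1e-10
        assert abs(mv1 - mv0) / mv0 < 1e-10

    def test_hedge_logistic_matches_closed_form(self, square1):
        # isolated hedge, no diffusion or migration: exact logistic curve
        alloc = manual_allocation(square1, [False], [True, False, False, False])
        mesh = build_mesh(square1, alloc, 0.25)
        p = quiet_params(r_v=0.02)
        state = initial_state(mesh, p)
        k = p.k_hedge
        state.v_hedge[:] = k / 2
        integ = Integrator(mesh, p, 0.5)
        for _ in range(100):  # t = 50 d
            integ.step(state)
        t = 50.0
        expected = k / (1.0 + math.exp(-p.r_v * t))
        assert np.allclose(state.v_hedge, expected, rtol=1e-9)

    def test_non_crop_exponential_decay(self, square1):
        alloc = manual_allocation(square1, [False], [False] * 4)
        mesh = build_mesh(square1, alloc, 0.25)
        p = quiet_params(m_u=0.03)
        state = initial_state(mesh, p)
        state.u[:] = 0.7
        integ = Integrator(mesh, p, 0.25)
        for _ in range(400):  # t = 100 d
            integ.step(state)
        assert np.allclose(state.u, 0.7 * math.exp(-0.03 * 100), rtol=1e-6)

    def test_nan_state_aborts_with_diagnostics(self, mesh60):
        p = SpeciesParams()
        state = initial_state(mesh60, p)
        state.u[0] = np.nan
        with pytest.raises(RuntimeError, match="non-finite"):
            step(state, mesh60, p, 0.5)

    def test_densities_stay_nonnegative(self, tess60, alloc60, mesh60):
        p = SpeciesParams(beta=0.1, r_u=0.02, rho12=0.05, rho21=0.05)
        state = initial_state(mesh60, p)
        rng = np.random.default_rng(1)
        state.u = rng.uniform(0, 20, mesh60.n_cells)
        state.v_field = rng.uniform(0, 1, mesh60.n_cells)
        integ = Integrator(mesh60, p, 1.0)  # deliberately coarse step
        for _ in range(100):
            integ.step(state)
            assert (state.u >= 0).all()
            assert (state.v_field >= 0).all()
            assert (state.v_hedge >= 0).all()


class TestInterfaceExchange:
    def test_no_migration_is_noop(self, mesh60):
        p = quiet_params()
        state = initial_state(mesh60, p)
        state.v_field[:] = 1.0
        dv_f, dv_h = exchange_interface(state, mesh60, p, 1.0)
        assert not dv_f.any()
        assert not dv_h.any()

    def test_one_way_flux_into_hedge(self, mesh60):
        p = quiet_params(rho21=0.05)  # rho12 = 0: hedge is a pure sink
        state = initial_state(mesh60, p)
        state.v_field[:] = 1.0
        state.v_hedge[:] = 0.5
        dv_f, dv_h = exchange_interface(state, mesh60, p, 1.0)
        assert (dv_h >= 0).all() and dv_h.max() > 0
        assert (dv_f <= 0).all() and dv_f.min() < 0

    def test_two_compartment_equilibrium_and_conservation(self, square1):
        # closed field-hedge system (hedges all around, so the field stays
        # spatially flat): total individuals conserved, density ratio
        # relaxes to rho21/rho12 (two-ODE oracle fixed point)
        alloc = manual_allocation(square1, [False], [True] * 4)
        mesh = build_mesh(square1, alloc, 0.5)
        p = quiet_params(rho12=0.01, rho21=0.04)
        state = initial_state(mesh, p)
        state.v_field[:] = 1.0
        state.v_hedge[:] = 0.0
        _, m0 = total_mass(state, mesh)
        integ = Integrator(mesh, p, 0.5)
        for _ in range(3000):  # 1500 d, far past the relaxation time
            integ.step(state)
        _, m1 = total_mass(state, mesh)
        assert abs(m1 - m0) / m0 < 1e-10
        exchanged = np.unique(mesh.if_cell)
        ratio = state.v_hedge / state.v_field[exchanged].mean()
        assert np.allclose(ratio, p.rho21 / p.rho12, rtol=1e-3)

    def test_migration_asymmetry_enforced(self):
        with pytest.raises(ValueError, match="rho12"):
            SpeciesParams(rho12=0.1, rho21=0.05)


class TestPesticideRule:
    @pytest.fixture
    def crop_mesh(self, square1):
        alloc = manual_allocation(square1, [True], [False] * 4)
        return build_mesh(square1, alloc, 0.25)

    def test_trigger_reduces_capacity_to_k_over_factor(self, crop_mesh):
        p = SpeciesParams()
        state = initial_state(crop_mesh, p)
        state.u[:] = 0.25
        cfg = PesticideConfig(threshold=0.2, reduction_factor=200.0)
        events = apply_pesticide_rule(state, crop_mesh, cfg)
        assert len(events) == 1
        assert math.isclose(state.C[0], 0.1)  # 20 / 200
        assert cfg.efficacy == pytest.approx(0.995)

    def test_threshold_is_strict(self, crop_mesh):
        state = initial_state(crop_mesh, SpeciesParams())
        # a float-exact boundary value: the field mean equals the
        # threshold, and equality must not trigger a spray
        state.u[:] = 0.25
        cfg = PesticideConfig(threshold=0.25)
        assert apply_pesticide_rule(state, crop_mesh, cfg) == []
        assert state.C[0] == 20.0

    def test_no_retrigger_while_active_and_reverts_after(self, crop_mesh):
        state = initial_state(crop_mesh, SpeciesParams())
        state.u[:] = 1.0
        cfg = PesticideConfig(duration=3.0)
        assert len(apply_pesticide_rule(state, crop_mesh, cfg)) == 1
        for _ in range(2):
            advance_pesticide(state, cfg, 1.0)
            assert apply_pesticide_rule(state, crop_mesh, cfg) == []
            assert state.C[0] == pytest.approx(0.1)
        advance_pesticide(state, cfg, 1.0)  # expiry
        assert state.C[0] == 20.0
        assert len(apply_pesticide_rule(state, crop_mesh, cfg)) == 1

    def test_non_crop_fields_never_sprayed(self, square1):
        alloc = manual_allocation(square1, [False], [False] * 4)
        mesh = build_mesh(square1, alloc, 0.25)
        state = initial_state(mesh, SpeciesParams())
        state.u[:] = 5.0
        assert apply_pesticide_rule(state, mesh, PesticideConfig()) == []

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            PesticideConfig(threshold=0.0)
        with pytest.raises(ValueError):
            PesticideConfig(reduction_factor=0.5)


class TestInoculation:
    def test_all_crop_mean_count(self, tess60):
        # expected arrivals equal the configured maximum when the whole
        # landscape is cropped
        alloc = manual_allocation(
            tess60, np.ones(tess60.n_polygons, bool),
            np.zeros(tess60.n_edges, bool),
        )
        cfg = InoculationConfig(max_mean_events=25.0)
        rng = np.random.default_rng(123)
        counts = [
            len(draw_inoculation_schedule(tess60, alloc, cfg, 100.0, rng))
            for _ in range(3000)
        ]
        se = math.sqrt(25.0 / 3000)
        assert abs(np.mean(counts) - 25.0) < 5 * se

    def test_no_crop_no_events(self, tess60):
        alloc = manual_allocation(
            tess60, np.zeros(tess60.n_polygons, bool),
            np.zeros(tess60.n_edges, bool),
        )
        for seed in range(50):
            assert draw_inoculation_schedule(
                tess60, alloc, InoculationConfig(), 100.0, seed
            ) == []

    def test_mean_proportional_to_crop_area(self, tess60):
        areas = np.array([p.area for p in tess60.polygons])
        order = np.argsort(areas)[::-1]
        crop = np.zeros(tess60.n_polygons, bool)
        cum = 0.0
        for i in order:  # take largest fields until ~40% of the area
            if cum / areas.sum() >= 0.4:
                break
            crop[i] = True
            cum += areas[i]
        p_area = areas[crop].sum() / areas.sum()
        alloc = manual_allocation(tess60, crop, np.zeros(tess60.n_edges, bool))
        rng = np.random.default_rng(5)
        counts = [
            len(draw_inoculation_schedule(tess60, alloc,
                                          InoculationConfig(), 100.0, rng))
            for _ in range(3000)
        ]
        target = 25.0 * p_area
        assert abs(np.mean(counts) - target) < 5 * math.sqrt(target / 3000)

    def test_events_land_in_crop_fields_with_mass_conserved(self, tess60,
                                                            alloc60):
        mesh = build_mesh(tess60, alloc60, 0.3)
        state = initial_state(mesh, SpeciesParams())
        cfg = InoculationConfig(seed=8)
        events = inoculate(state, mesh, tess60, alloc60, cfg)
        assert all(alloc60.crop_label[e["polygon"]] for e in events)
        expected_mass = (
            len(events) * cfg.amount * 2 * math.pi * cfg.spatial_spread**2
        )
        assert math.isclose(
            state.u.sum() * mesh.cell_area, expected_mass, rel_tol=1e-9
        )


class TestRunSimulation:
    def test_no_hedges_no_inoculation_stays_empty(self, tess60):
        alloc = manual_allocation(
            tess60, np.ones(tess60.n_polygons, bool),
            np.zeros(tess60.n_edges, bool),
        )
        rs = run_simulation(
            tess60, alloc,
            inoculation=InoculationConfig(max_mean_events=0.0),
            seed=1, resolution=0.4, dt_internal=0.5,
        )
        assert rs.mean_pest == 0.0
        assert rs.mean_predator == 0.0
        assert rs.n_applications_total == 0

    def test_logistic_equilibria_reached(self, square1):
        # all-crop, predator-free: pest relaxes to the crop capacity;
        # hedge predators relax to the hedge capacity
        alloc = manual_allocation(square1, [True], [True, False, False, False])
        mesh = build_mesh(square1, alloc, 0.25)
        p = quiet_params(r_u=0.05, r_v=0.05)
        state = initial_state(mesh, p)
        state.u[:] = 1.0
        state.v_hedge[:] = 0.1
        integ = Integrator(mesh, p, 0.5)
        for _ in range(2 * 400):  # 400 d
            integ.step(state)
        assert np.allclose(state.u, p.k_field, rtol=1e-3)
        assert np.allclose(state.v_hedge, p.k_hedge, rtol=1e-3)

    def test_first_application_day_matches_refined_oracle(self):
        tess = build_tessellation_fixture(2.0, 1, seed=0)
        alloc = manual_allocation(tess, [True], [False] * 4)
        p = quiet_params(r_u=0.02, d2u=0.006)
        kw = dict(
            params=p,
            inoculation=InoculationConfig(amount=1.5, seed=None),
            seed=42,
        )
        coarse = run_simulation(tess, alloc, resolution=0.4, dt_internal=0.5,
                                **kw)
        fine = run_simulation(tess, alloc, resolution=0.2, dt_internal=0.05,
                              **kw)
        day = [
            min(e["day"] for e in rs.event_log if e["type"] == "pesticide")
            for rs in (coarse, fine)
        ]
        assert coarse.n_applications_total >= 1
        assert abs(day[0] - day[1]) <= 1.0

    def test_pest_hotspots_avoid_predator_exposure(self, tess60, alloc60):
        # end-of-season pest concentrates where predators were scarce:
        # under strong predation the rank correlation between final pest
        # density and seasonal predator exposure is negative on average
        # over arrival histories
        mesh = build_mesh(tess60, alloc60, 0.3)
        p = SpeciesParams(beta=0.1, rho12=0.05)
        rhos = []
        for seed in (2, 11, 21):
            rs = run_simulation(tess60, alloc60, p, seed=seed, mesh=mesh,
                                dt_internal=0.25, keep_fields=True)
            crop = mesh.crop_cell & (rs.final_u > 0)
            rhos.append(
                spearmanr(rs.final_u[crop],
                          rs.cell_mean_predator[crop]).statistic
            )
        assert np.mean(rhos) < 0

    def test_more_spillover_means_less_pest(self):
        # predation-pressure monotonicity in a small landscape
        tess = build_tessellation_fixture(2.0, 4, seed=3)
        alloc = manual_allocation(
            tess, np.ones(4, bool), np.ones(tess.n_edges, bool)
        )
        means = []
        for rho12 in (0.0, 0.02, 0.05):
            p = SpeciesParams(rho12=rho12, beta=0.05)
            rs = run_simulation(
                tess, alloc, p, seed=21, resolution=0.25, dt_internal=0.25,
                pesticide=PesticideConfig(threshold=1e9),
            )
            means.append(rs.mean_pest)
        assert means[0] > means[1] > means[2]

    def test_event_log_consistent_with_counts(self, tess60, alloc60):
        rs = run_simulation(tess60, alloc60, seed=2, resolution=0.37,
                            dt_internal=0.25)
        n_sprays = sum(1 for e in rs.event_log if e["type"] == "pesticide")
        assert n_sprays == rs.n_applications_total
        assert (rs.n_applications >= rs.application_presence).all()
        per_poly = np.zeros_like(rs.n_applications)
        for e in rs.event_log:
            if e["type"] == "pesticide":
                per_poly[e["polygon"]] += 1
        assert np.array_equal(per_poly, rs.n_applications)
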