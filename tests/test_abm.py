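"""Agent-based model: rate laws, fields, mechanics, cell cycle, stepping."""

import numpy as np
import pytest
from scipy.special import k0

from wpcf.abm import (
    ABMParams,
    ABMState,
    DiffusibleField,
    MACROPHAGE,
    NECROTIC,
    STROMAL,
    TUMOUR,
    attempt_extravasation,
    attempt_killing,
    chemotactic_forces,
    extravasation_probability,
    initial_state,
    kill_probability,
    mechanical_forces,
    run,
    step,
    update_cell_cycle,
    update_phenotypes,
)
from wpcf.pointcloud import Domain


def bare_state(params, seed=0, csf1=0.0):
    """A state with vessels and a CSF-1 field but no cells, bypassing the
    full initial condition (fast for microscopic unit tests)."""
    state = ABMState(params, np.random.default_rng(seed))
    rng = np.random.default_rng(99)
    dom = params.domain
    state.vessels = np.column_stack(
        [
            rng.uniform(dom.x_min + 1, dom.x_max - 1, params.n_vessels),
            rng.uniform(dom.y_min + 1, dom.y_max - 1, params.n_vessels),
        ]
    )
    state.fields = {
        "csf1": DiffusibleField("csf1", dom, params.D_c, params.lambda_c, initial=csf1)
    }
    return state


def tiny_params(**overrides):
    """A small, fast parameter set for unit tests."""
    defaults = dict(
        domain=Domain(0, 20, 0, 20),
        n_vessels=4,
        vessel_min_sep=3.0,
        vessel_exclusion_radius=5.0,
        n_tumour_init=10,
        stroma_spacing=4.0,
    )
    defaults.update(overrides)
    return ABMParams(**defaults)


class TestRateLaws:
    def test_extravasation_half_saturation(self):
        p = ABMParams()
        assert extravasation_probability(p.c_half, p) == pytest.approx(p.P_star / 2)

    def test_extravasation_limits(self):
        p = ABMParams()
        assert extravasation_probability(0.0, p) == 0.0
        assert extravasation_probability(1e9, p) == pytest.approx(p.P_star, rel=1e-6)

    def test_extravasation_monotone(self):
        p = ABMParams()
        c = np.linspace(0, 5, 50)
        vals = [extravasation_probability(x, p) for x in c]
        assert np.all(np.diff(vals) >= 0)

    def test_kill_probability_values(self):
        p = ABMParams()
        assert kill_probability(0.0, p.t_cool, p) == pytest.approx(p.P_phi_star)
        assert kill_probability(0.5, p.t_cool, p) == pytest.approx(p.P_phi_star / 2)
        # fully M2: a residual 1/1025 of the maximum
        assert kill_probability(1.0, p.t_cool, p) == pytest.approx(
            p.P_phi_star * 2.0**-10 / (1 + 2.0**-10)
        )

    def test_kill_probability_zero_during_cooldown(self):
        p = ABMParams()
        assert kill_probability(0.0, p.t_cool - 0.01, p) == 0.0

    def test_kill_probability_decreasing_in_phenotype(self):
        p = ABMParams()
        vals = [kill_probability(x, p.t_cool, p) for x in np.linspace(0, 1, 20)]
        assert np.all(np.diff(vals) <= 0)


class TestChemotaxis:
    def test_phenotype_interpolates_the_two_forces(self):
        p = ABMParams()
        ex = np.array([[1.0, 0.0]])
        f0 = chemotactic_forces(0.0, ex, ex, p)[0]
        f1 = chemotactic_forces(1.0, ex, ex, p)[0]
        fh = chemotactic_forces(0.5, ex, ex, p)[0]
        assert f0[0] == pytest.approx(p.chi_c_m)
        assert f1[0] == pytest.approx(p.chi_xi_m)
        assert fh[0] == pytest.approx((p.chi_c_m + p.chi_xi_m) / 2)

    def test_gradient_magnitude_does_not_matter(self):
        p = ABMParams()
        small = chemotactic_forces(0.3, [[1e-6, 0]], [[0, 2e-6]], p)[0]
        large = chemotactic_forces(0.3, [[10, 0]], [[0, 20]], p)[0]
        np.testing.assert_allclose(small, large)

    def test_zero_gradient_contributes_no_force(self):
        p = ABMParams()
        f = chemotactic_forces(0.5, [[0.0, 0.0]], [[0.0, 0.0]], p)[0]
        np.testing.assert_array_equal(f, [0.0, 0.0])


class TestFields:
    def test_uniform_decay_matches_closed_form(self):
        dom = Domain(0, 10, 0, 10, boundary_mode="periodic")
        f = DiffusibleField("egf", dom, D=5.0, lam=0.3, spacing=0.5, initial=2.0)
        for _ in range(100):
            f.step(0.05)
        expected = 2.0 * np.exp(-0.3 * 5.0)
        assert np.allclose(f.grid, expected, rtol=1e-6)

    def test_mass_budget_on_periodic_domain(self):
        dom = Domain(0, 10, 0, 10, boundary_mode="periodic")
        f = DiffusibleField("csf1", dom, D=3.0, lam=0.2, spacing=0.5, initial=1.0)
        src = f.deposit(np.array([[5.0, 5.0]]), np.array([2.0]))
        m0 = f.total_mass
        dt = 0.01
        f.step(dt, src)
        expected = (m0 + dt * 2.0) * np.exp(-0.2 * dt)
        assert f.total_mass == pytest.approx(expected, rel=1e-6)

    def test_point_source_steady_state_is_bessel_k0(self):
        """A single stationary source on a periodic domain relaxes to the 2D
        Green's function profile K0(r sqrt(lambda/D)) / (2 pi D)."""
        dom = Domain(0, 20, 0, 20, boundary_mode="periodic")
        f = DiffusibleField("egf", dom, D=1.0, lam=1.0, spacing=0.25)
        src = f.deposit(np.array([[10.0, 10.0]]), np.array([1.0]))
        for _ in range(300):
            f.step(0.05, src)
        radii = np.linspace(1.5, 5.0, 12)
        angles = np.linspace(0, 2 * np.pi, 72, endpoint=False)
        values = np.array(
            [
                f.value_at(
                    np.column_stack([10 + r * np.cos(angles), 10 + r * np.sin(angles)])
                ).mean()
                for r in radii
            ]
        )
        reference = k0(radii) / (2 * np.pi)
        np.testing.assert_allclose(values, reference, rtol=0.02)

    def test_concentrations_stay_nonnegative_under_consumption(self):
        dom = Domain(0, 10, 0, 10)
        f = DiffusibleField("oxygen", dom, D=5.0, lam=0.1, spacing=1.0, initial=0.01)
        sink = -f.deposit(np.array([[5.0, 5.0]]), np.array([100.0]))
        for _ in range(50):
            f.step(0.05, sink)
        assert (f.grid >= 0).all()


class TestMechanics:
    def test_two_cells_at_rest_length_feel_no_force(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[5.0, 5.0], [6.0, 5.0]]), TUMOUR)
        forces = mechanical_forces(state)
        np.testing.assert_allclose(forces, 0.0, atol=1e-12)

    def test_pairwise_forces_sum_to_zero(self):
        params = tiny_params()
        state = initial_state(params, seed=1)
        # exclude stochastic per-cell forces: only stromal/tumour springs
        state.remove_cells(state.types == MACROPHAGE)
        state.fields["egf"].grid[:] = 0.0
        forces = mechanical_forces(state)
        np.testing.assert_allclose(forces.sum(axis=0), 0.0, atol=1e-9)

    def test_overlapping_pair_relaxes_to_rest_length(self):
        """Forward-Euler dynamics of a compressed two-cell system approach
        the linear-spring fixed point s = s_rest."""
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[5.0, 5.0], [5.6, 5.0]]), TUMOUR)
        for _ in range(400):
            f = mechanical_forces(state)
            state.positions += f * (params.dt / params.nu)
        sep = np.linalg.norm(state.positions[1] - state.positions[0])
        assert sep == pytest.approx(1.0, abs=0.02)


class TestPhenotype:
    def test_ramp_time_is_inverse_rate(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.add_cells(np.array([[5.0, 5.0]]), MACROPHAGE)
        state.fields["tgfb"].grid[:] = params.g_crit * 2  # above threshold
        mac = state.types == MACROPHAGE
        steps = int(round(1.0 / params.delta_p / params.dt))
        for _ in range(steps - 1):
            update_phenotypes(state, params.dt)
            assert state.phenotype[mac].max() < 1.0
        update_phenotypes(state, params.dt)
        assert state.phenotype[mac].max() == pytest.approx(1.0)

    def test_no_increase_below_threshold(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.add_cells(np.array([[5.0, 5.0]]), MACROPHAGE)
        state.fields["tgfb"].grid[:] = params.g_crit / 2
        update_phenotypes(state, params.dt)
        assert state.phenotype[state.types == MACROPHAGE].max() == 0.0

    def test_capped_at_one(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.add_cells(np.array([[5.0, 5.0]]), MACROPHAGE)
        state.phenotype[state.types == MACROPHAGE] = 1.0
        state.fields["tgfb"].grid[:] = 10.0
        for _ in range(10):
            update_phenotypes(state, params.dt)
        assert state.phenotype[state.types == MACROPHAGE].max() == 1.0


class TestExtravasationAndKilling:
    def test_no_csf1_no_entries(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        for f in state.fields.values():
            f.grid[:] = 0.0
        for _ in range(200):
            attempt_extravasation(state, params.dt)
        assert state.n_of(MACROPHAGE) == 0

    def test_saturating_csf1_entry_rate(self):
        """At saturating CSF-1 the expected entries over T hours approach
        n_vessels * P_star * T (binomial, checked within 4 sigma)."""
        params = tiny_params()
        hours = 40.0
        n_steps = int(hours / params.dt)
        total = 0
        reps = 20
        for rep in range(reps):
            state = bare_state(params, seed=rep, csf1=1e6)
            for _ in range(n_steps):
                attempt_extravasation(state, params.dt)
            total += state.n_of(MACROPHAGE)
        p_step = params.P_star * params.dt
        n_trials = reps * n_steps * params.n_vessels
        expected = n_trials * p_step
        sigma = np.sqrt(n_trials * p_step * (1 - p_step))
        assert abs(total - expected) < 4 * sigma

    def test_new_macrophages_start_m1_and_eligible(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.fields["csf1"].grid[:] = 1e6
        for _ in range(100):
            attempt_extravasation(state, params.dt)
        mac = state.types == MACROPHAGE
        assert mac.any()
        assert np.all(state.phenotype[mac] == 0.0)
        assert np.all(state.kill_timer[mac] >= params.t_cool)

    def test_kill_requires_proximity(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[2.0, 2.0]]), TUMOUR)
        state.add_cells(np.array([[10.0, 10.0]]), MACROPHAGE, kill_timer=params.t_cool)
        for _ in range(100):
            attempt_killing(state, params.dt)
        assert state.n_of(TUMOUR) == 1

    def test_certain_kill_resets_cooldown(self):
        params = tiny_params(P_phi_star=1.0, dt=1.0, P_star=1.0)
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[5.0, 5.0]]), TUMOUR)
        state.add_cells(np.array([[5.5, 5.0]]), MACROPHAGE, kill_timer=params.t_cool)
        kills = attempt_killing(state, params.dt)
        assert kills == 1
        assert state.n_of(TUMOUR) == 0
        assert state.n_of(NECROTIC) == 1
        mac = state.types == MACROPHAGE
        assert state.kill_timer[mac][0] == 0.0

    def test_victim_chosen_uniformly(self):
        """With three candidates in range, each is selected about 1/3 of the
        time over many replicates."""
        params = tiny_params(P_phi_star=1.0, dt=1.0, P_star=1.0)
        counts = np.zeros(3)
        targets = np.array([[5.0, 4.4], [5.6, 5.0], [5.0, 5.6]])
        for rep in range(600):
            state = bare_state(params, seed=rep)
            state.add_cells(targets, TUMOUR)
            state.add_cells(np.array([[5.0, 5.0]]), MACROPHAGE, kill_timer=params.t_cool)
            attempt_killing(state, params.dt)
            necrotic = np.flatnonzero(state.types == NECROTIC)
            assert len(necrotic) == 1
            counts[necrotic[0]] += 1
        assert np.all(np.abs(counts / 600 - 1 / 3) < 0.08)


class TestCellCycle:
    def test_isolated_cell_divides_once_per_cycle(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[10.0, 10.0]]), TUMOUR)
        state.cycle_length[:] = params.cycle_duration
        state.fields["oxygen"].grid[:] = 1.0  # abundant oxygen
        steps = int(round(params.cycle_duration / params.dt)) + 1
        for _ in range(steps):
            update_cell_cycle(state, params.dt)
        assert state.n_of(TUMOUR) == 2

    def test_hypoxic_pause_is_reversible(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[10.0, 10.0]]), TUMOUR)
        mid = (params.omega_N_tum + params.omega_H_tum) / 2
        state.fields["oxygen"].grid[:] = mid
        update_cell_cycle(state, params.dt)
        assert state.cycle_clock[0] == 0.0  # frozen
        state.fields["oxygen"].grid[:] = 1.0
        update_cell_cycle(state, params.dt)
        assert state.cycle_clock[0] == pytest.approx(params.dt)

    def test_necrosis_is_irreversible(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[10.0, 10.0]]), TUMOUR)
        state.fields["oxygen"].grid[:] = params.omega_N_tum / 2
        update_cell_cycle(state, params.dt)
        assert state.types[0] == NECROTIC
        state.fields["oxygen"].grid[:] = 1.0
        update_cell_cycle(state, params.dt)
        assert state.types[0] == NECROTIC

    def test_necrotic_cells_shrink_and_are_removed(self):
        params = tiny_params()
        state = initial_state(params, seed=0)
        state.remove_cells(np.ones(len(state.positions), dtype=bool))
        state.add_cells(np.array([[10.0, 10.0]]), TUMOUR)
        state.types[0] = NECROTIC
        half = int(round(params.necrosis_clear_time / params.dt / 2))
        for _ in range(half):
            update_cell_cycle(state, params.dt)
        assert 0 < state.radii[0] < params.cell_radius
        for _ in range(half + 2):
            update_cell_cycle(state, params.dt)
        assert len(state.positions) == 0


class TestStepAndRun:
    def test_identical_seeds_give_identical_trajectories(self):
        params = tiny_params()
        snaps_a = run(params, t_end=2.0, snapshot_every=1.0, seed=7)
        snaps_b = run(params, t_end=2.0, snapshot_every=1.0, seed=7)
        for a, b in zip(snaps_a, snaps_b):
            np.testing.assert_array_equal(a.positions, b.positions)
            np.testing.assert_array_equal(a.categories, b.categories)

    def test_different_seeds_differ(self):
        params = tiny_params()
        a = run(params, t_end=5.0, snapshot_every=5.0, seed=1)[-1]
        b = run(params, t_end=5.0, snapshot_every=5.0, seed=2)[-1]
        assert (len(a) != len(b)) or not np.array_equal(a.positions, b.positions)

    def test_snapshot_count_and_times(self):
        params = tiny_params()
        snaps = run(params, t_end=3.0, snapshot_every=1.0, seed=0)
        assert len(snaps) == 4
        assert [round(s.time) for s in snaps] == [0, 1, 2, 3]

    def test_t_end_zero_gives_single_snapshot(self):
        params = tiny_params()
        snaps = run(params, t_end=0.0, seed=0)
        assert len(snaps) == 1
        assert snaps[0].time == 0.0

    def test_snapshots_are_valid_point_clouds(self):
        params = tiny_params()
        snap = run(params, t_end=5.0, snapshot_every=5.0, seed=3)[-1]
        assert snap.count("B") == params.n_vessels
        defined = ~np.isnan(snap.marks)
        assert set(snap.categories[defined]) <= {"M"}
        assert snap.domain.contains(snap.positions).all()

    def test_phenotype_never_decreases_over_a_run(self):
        params = tiny_params()
        state = initial_state(params, seed=5)
        state.fields["csf1"].grid[:] = 5.0  # recruit macrophages quickly
        previous: dict[int, float] = {}
        for _ in range(400):
            step(state)
            mac = state.types == MACROPHAGE
            for cid, ph in zip(state.ids[mac], state.phenotype[mac]):
                assert ph >= previous.get(int(cid), 0.0) - 1e-12
                previous[int(cid)] = float(ph)

    def test_fields_stay_nonnegative_during_simulation(self):
        params = tiny_params()
        state = initial_state(params, seed=4)
        for _ in range(200):
            step(state)
            for f in state.fields.values():
                assert (f.grid >= 0).all()

    def test_probability_overflow_rejected(self):
        with pytest.raises(ValueError, match="rate overflow"):
            tiny_params(P_star=25.0)


class TestParams:
    def test_toml_roundtrip(self, tmp_path):
        path = tmp_path / "params.toml"
        path.write_text(
            "chi_c_m = 2.5\nc_half = 0.4\n\n[domain]\n"
            "x_min = 0.0\nx_max = 30.0\ny_min = 0.0\ny_max = 30.0\n"
        )
        params = ABMParams.from_toml(path)
        assert params.chi_c_m == 2.5
        assert params.c_half == 0.4
        assert params.domain.width == 30.0

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ABMParams(omega_N_tum=0.5, omega_H_tum=0.4)
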