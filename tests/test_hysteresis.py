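"""Two-level Stoner–Wohlfarth dynamics: energy landscape, barriers,
switching astroid, population kinetics and loop/ensemble behaviour."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spasim import hysteresis as hy
from spasim import lrt
from spasim.core import K_B, FieldProtocol, MediumSpec, ParticleSpec
from spasim.dipolar import DipolarConfig


def astroid(psi: float) -> float:
    """Closed-form SW switching field h_sw(ψ)."""
    if psi in (0.0, np.pi / 2):
        return 1.0
    return (np.cos(psi) ** (2 / 3) + np.sin(psi) ** (2 / 3)) ** -1.5


class TestEnergyLandscape:
    def test_zero_field_degenerate_minima_and_unit_barrier(self):
        # minima at phi = psi, psi + pi with energy 0; barrier 1 at psi = 0
        assert hy.sw_energy(0.0, 0.3, 0.3) == pytest.approx(0.0, abs=1e-12)
        assert hy.sw_energy(0.0, 0.3, 0.3 + np.pi) == pytest.approx(0.0, abs=1e-12)
        d_plus, d_minus = hy.energy_barriers(0.0, 0.0)
        assert d_plus == pytest.approx(1.0, abs=1e-6)
        assert d_minus == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("h", [0.05, 0.1, 0.3, 0.5, 0.7, 0.9])
    def test_aligned_barriers_match_closed_form(self, h):
        d_plus, d_minus = hy.energy_barriers(h, 0.0)
        assert d_plus == pytest.approx((1 - h) ** 2, abs=1e-6)
        assert d_minus == pytest.approx((1 + h) ** 2, abs=1e-6)

    def test_metastable_minimum_vanishes_at_switching(self):
        d_plus, _ = hy.energy_barriers(1.05, 0.0)
        assert d_plus == 0.0
        d_plus, _ = hy.energy_barriers(0.6, np.deg2rad(45.0))  # h_sw = 0.5
        assert d_plus == 0.0

    @pytest.mark.parametrize("psi_deg", [0.0, 15.0, 45.0, 75.0, 90.0])
    def test_switching_field_matches_astroid(self, psi_deg):
        psi = np.deg2rad(psi_deg)
        assert hy.switching_field(psi) == pytest.approx(astroid(psi), abs=1e-3)

    def test_negative_field_rejected(self):
        with pytest.raises(ValueError):
            hy.energy_barriers(-0.1, 0.0)


class TestAdvancePopulations:
    volume = 8.18e-24
    k_eff = 5.0 * K_B * 300.0 / 8.18e-24  # sigma = 5 at 300 K

    def test_long_step_reaches_boltzmann_equilibrium(self):
        state = hy.TwoLevelState(L=0.0, n=(1.0, 0.0), M=1.0)
        # asymmetric barriers: equilibrium n1/n2 = exp(sigma*(b1-b2))
        out = hy.advance_populations(
            state, (0.8, 0.4), self.k_eff, self.volume, 1e-9, 300.0, dt=1.0
        )
        expected_n1 = np.exp(5 * 0.8) / (np.exp(5 * 0.8) + np.exp(5 * 0.4))
        assert out.n[0] == pytest.approx(expected_n1, rel=1e-9)
        assert out.L == pytest.approx(1.0, abs=1e-9)
        assert sum(out.n) == pytest.approx(1.0, abs=1e-12)

    def test_short_step_leaves_populations_blocked(self):
        state = hy.TwoLevelState(L=0.0, n=(0.9, 0.1), M=0.8)
        out = hy.advance_populations(
            state, (0.8, 0.4), self.k_eff, self.volume, 1e-9, 300.0, dt=1e-15
        )
        assert out.n[0] == pytest.approx(0.9, abs=1e-6)
        assert out.L == pytest.approx(0.0, abs=1e-5)

    def test_vanished_well_drains_within_a_few_steps(self):
        state = hy.TwoLevelState(L=0.0, n=(1.0, 0.0), M=1.0)
        tau0 = 1e-9
        for _ in range(10):  # 10 steps of dt = 2*tau0
            state = hy.advance_populations(
                state, (0.0, 2.0), self.k_eff, self.volume, tau0, 300.0, dt=2 * tau0
            )
        assert state.n[0] < 1e-4

    def test_matches_ode_oracle(self):
        # independent check: integrate the linear master equation numerically
        b1, b2, tau0, temp, dt = 0.55, 0.15, 1e-9, 300.0, 5e-7
        sigma = self.k_eff * self.volume / (K_B * temp)
        nu1 = np.exp(-sigma * b1) / (2 * tau0)
        nu2 = np.exp(-sigma * b2) / (2 * tau0)
        sol = solve_ivp(
            lambda t, y: [-nu1 * y[0] + nu2 * (1 - y[0])],
            (0.0, dt),
            [0.7],
            rtol=1e-11,
            atol=1e-13,
        )
        state = hy.advance_populations(
            hy.TwoLevelState(L=0.0, n=(0.7, 0.3), M=0.0),
            (b1, b2),
            self.k_eff,
            self.volume,
            tau0,
            temp,
            dt,
        )
        assert state.n[0] == pytest.approx(sol.y[0, -1], rel=1e-8)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            hy.advance_populations(
                hy.TwoLevelState(L=0.0, n=(1.0, 0.0), M=1.0),
                (1.0, 1.0),
                self.k_eff,
                self.volume,
                1e-9,
                300.0,
                dt=0.0,
            )


class TestSimulateLoop:
    def test_athermal_aligned_square_loop(self, pei_particle):
        # T = 0, psi = 0, H0 > H_A: coercivity H_A, area 4*Ms*H_A
        field = FieldProtocol(H0=1.2 * 34.5e3, f=560e3)
        loop = hy.simulate_loop(pei_particle, field, temperature=0.0, psi=0.0)
        assert loop.area == pytest.approx(4 * 51.0 * 34.5e3, rel=1e-2)
        # switch happens at |H| = H_A on each branch
        m_at = np.interp(0.0, loop.M_trace[::-1], loop.H_trace[::-1])
        assert abs(m_at) <= 34.5e3 * 1.01

    def test_athermal_minor_loop_closes_reversibly(self, pei_particle):
        # psi = 45 deg: h_sw = 0.5; below it the loop is reversible (zero
        # area), above it the area is the major-loop value, independent of H0
        psi = np.deg2rad(45.0)
        areas = {}
        for ratio in (0.45, 0.55, 0.7):
            field = FieldProtocol(H0=ratio * 34.5e3, f=560e3)
            areas[ratio] = hy.simulate_loop(
                pei_particle, field, temperature=0.0, psi=psi
            ).area
        scale = 4 * 51.0 * 34.5e3
        assert areas[0.45] < 1e-3 * scale
        assert areas[0.55] > 0.05 * scale
        assert areas[0.7] == pytest.approx(areas[0.55], rel=1e-2)

    def test_superparamagnetic_limit_has_no_hysteresis(self):
        # sigma ~ 0.4: equilibrium response, loop area ~ 0
        tiny = ParticleSpec(d_mean=8e-9, d_sd=0, Ms_mass=51, H_A=34.5e3, tau0=1e-9)
        loop = hy.simulate_loop(
            tiny, FieldProtocol(H0=20e3, f=560e3), temperature=300.0, psi=0.5
        )
        assert loop.spa < 1e-3 * lrt.MU0 * 560e3 * 4 * 51 * 20e3

    def test_magnetization_bounded_and_loop_odd_symmetric(self, pei_mono):
        field = FieldProtocol(H0=20e3, f=560e3, n_cycles=6)
        loop = hy.simulate_loop(
            pei_mono, field, temperature=300.0, psi=np.deg2rad(60.0)
        )
        m = loop.M_trace[:-1]
        assert np.all(np.abs(m) <= 51.0 * (1 + 1e-9))
        half = len(m) // 2
        asym = np.max(np.abs(m + np.roll(m, -half)))
        assert asym < 0.02 * 51.0

    def test_loop_area_nonnegative_and_spa_consistent(self, pei_mono):
        loop = hy.simulate_loop(
            pei_mono, FieldProtocol(H0=15e3, f=560e3), 300.0, psi=1.0
        )
        assert loop.area >= 0.0
        assert loop.spa == pytest.approx(lrt.MU0 * 560e3 * loop.area, rel=1e-12)

    def test_negative_temperature_rejected(self, pei_mono):
        with pytest.raises(ValueError):
            hy.simulate_loop(pei_mono, FieldProtocol(H0=1e3, f=560e3), -1.0)


class TestEnsemble:
    def test_agrees_with_linear_response_at_small_field(self, room_medium):
        # sigma ~ 5.6 so that 2*pi*f*tau ~ 1; H0/H_A = 0.05
        p = ParticleSpec(d_mean=19.8e-9, d_sd=0.0, Ms_mass=51, H_A=34.5e3, tau0=1e-9)
        field = FieldProtocol(H0=0.05 * 34.5e3, f=560e3)
        no_coupling = DipolarConfig(coupling_min=0.0, coupling_max=0.0)
        spa_sim, _ = hy.ensemble_spa(
            p, room_medium, field, no_coupling, 250, seed=7
        )
        spa_lin = lrt.lrt_spa(p, room_medium, field).spa
        assert spa_sim == pytest.approx(spa_lin, rel=0.15)

    def test_seed_determinism_is_bitwise(self, pei_particle, room_medium):
        field = FieldProtocol(H0=20e3, f=560e3, steps_per_cycle=250)
        dip = DipolarConfig()
        a = hy.ensemble_spa(pei_particle, room_medium, field, dip, 12, seed=5)
        b = hy.ensemble_spa(pei_particle, room_medium, field, dip, 12, seed=5)
        assert a == b

    def test_spa_nondecreasing_in_field(self, pei_particle, room_medium):
        field = FieldProtocol(H0=1e3, f=560e3, steps_per_cycle=500)
        rows = hy.spa_vs_field(
            pei_particle,
            room_medium,
            field,
            np.array([6e3, 10e3, 14e3, 18e3]),
            DipolarConfig(),
            30,
            seed=9,
        )
        spas = np.array([r[1] for r in rows])
        assert np.all(np.diff(spas) >= -0.01 * spas.max())

    def test_lognormal_size_option_runs(self, pei_particle, room_medium):
        field = FieldProtocol(H0=15e3, f=560e3, steps_per_cycle=250)
        spa, se = hy.ensemble_spa(
            pei_particle,
            room_medium,
            field,
            DipolarConfig(),
            12,
            seed=3,
            size_distribution="lognormal",
        )
        assert spa > 0 and se >= 0

    def test_input_validation(self, pei_particle, room_medium):
        field = FieldProtocol(H0=15e3, f=560e3)
        with pytest.raises(ValueError):
            hy.ensemble_spa(pei_particle, room_medium, field, DipolarConfig(), 1)
        with pytest.raises(ValueError, match="empty"):
            hy.spa_vs_field(
                pei_particle, room_medium, field, [], DipolarConfig(), 10
            )
        with pytest.raises(ValueError, match="ascending"):
            hy.spa_vs_field(
                pei_particle,
                room_medium,
                field,
                [2e3, 1e3],
                DipolarConfig(),
                10,
            )
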