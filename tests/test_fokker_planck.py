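"""Drift-diffusion solver: equilibrium, conservation, flux and passage times."""

import math

import numpy as np
import pytest

from translokit.flux import FluxInputs, FrictionModel, f_of_N_quadrature
from translokit.fokker_planck import (DriftDiffusionProblem, evolve,
                                      first_passage_histogram, fixed_value,
                                      mean_first_passage_time,
                                      steady_state_flux)
from translokit.free_energy import ParabolicBarrier


def flat(m):
    return np.zeros_like(np.asarray(m, dtype=float))


class TestEvolve:
    def test_relaxes_to_boltzmann_with_reflecting_walls(self):
        pb = ParabolicBarrier(0.02, 0.8)
        prob = DriftDiffusionProblem(N=40.0, potential=pb, diffusion=1.0,
                                     boundary_at_N="reflecting")
        field = evolve(prob, t_final=4000.0, n_grid=256, dt=2.0, store_every=500)
        P = field.P[-1]
        ref = np.exp(-prob.beta * prob.total_potential(field.grid))
        ref /= ref.sum() * field.h
        assert np.abs(P - ref).sum() * field.h < 1e-6

    def test_mass_conserved_with_reflecting_walls(self):
        prob = DriftDiffusionProblem(N=10.0, potential=flat,
                                     boundary_at_N="reflecting")
        field = evolve(prob, t_final=5.0, n_grid=64, dt=0.01)
        assert np.all(np.abs(field.survival - field.survival[0]) < 1e-10)

    def test_slowest_decay_rate_of_absorbing_escape(self):
        # flat potential, reflect at 0 / absorb at N: rate = pi^2 D / (4 N^2)
        prob = DriftDiffusionProblem(N=10.0, potential=flat, diffusion=1.0)
        field = evolve(prob, t_final=120.0, n_grid=256, dt=0.05, store_every=20)
        mask = field.survival < 0.3
        lam = -np.polyfit(field.times[mask], np.log(field.survival[mask]), 1)[0]
        assert lam == pytest.approx(math.pi**2 / 400.0, rel=0.01)

    def test_discrete_continuity_per_cell(self):
        """d(cell mass)/dt equals the face-flux difference (implicit Euler)."""
        pb = ParabolicBarrier(0.05, 0.4)
        prob = DriftDiffusionProblem(N=10.0, potential=pb,
                                     boundary_at_0=fixed_value(0.5))
        dt = 0.01
        field = evolve(prob, t_final=1.0, n_grid=64, dt=dt)
        for k in (10, 50, 99):
            dmass = (field.P[k + 1] - field.P[k]) * field.h
            dflux = field.J[k + 1][:-1] - field.J[k + 1][1:]
            assert np.allclose(dmass / dt, dflux, atol=1e-8)

    def test_rejects_bad_inputs(self):
        prob = DriftDiffusionProblem(N=10.0, potential=flat)
        with pytest.raises(ValueError):
            evolve(prob, t_final=-1.0)
        with pytest.raises(ValueError):
            evolve(prob, t_final=1.0, n_grid=8)
        with pytest.raises(ValueError):
            evolve(prob, t_final=1.0, initial=np.full(512, -1.0))
        with pytest.raises(ValueError):
            DriftDiffusionProblem(N=10.0, potential=flat, boundary_at_0="open")


class TestSteadyStateFlux:
    def test_no_barrier_linear_profile(self):
        prob = DriftDiffusionProblem(N=50.0, potential=flat, diffusion=2.0,
                                     boundary_at_0=fixed_value(0.7))
        assert steady_state_flux(prob, 512) == pytest.approx(0.7 * 2.0 / 50.0,
                                                             rel=1e-6)

    def test_matches_barrier_integral_quadrature(self):
        pb = ParabolicBarrier(0.01, 1.0)
        fric = FrictionModel(0.0, 1.0)
        fi = FluxInputs(pb=pb, friction=fric, N=100.0, beta=1.0, P0=1.0)
        Jref = 1.0 / f_of_N_quadrature(fi)
        prob = DriftDiffusionProblem(
            N=100.0, potential=pb, diffusion=lambda m: 1.0 / fric(m),
            beta=1.0, boundary_at_0=fixed_value(1.0))
        J = steady_state_flux(prob, n_grid=1024)
        assert J == pytest.approx(Jref, rel=1e-4)

    def test_second_order_grid_convergence(self):
        pb = ParabolicBarrier(0.01, 1.0)
        fric = FrictionModel(0.0, 1.0)
        fi = FluxInputs(pb=pb, friction=fric, N=100.0)
        Jref = 1.0 / f_of_N_quadrature(fi)
        prob = DriftDiffusionProblem(N=100.0, potential=pb,
                                     diffusion=lambda m: 1.0 / fric(m),
                                     boundary_at_0=fixed_value(1.0))
        errs = [abs(steady_state_flux(prob, n) - Jref) / Jref
                for n in (128, 256, 512)]
        assert errs[0] / errs[1] > 3.0
        assert errs[1] / errs[2] > 3.0

    def test_kramers_barrier_height_ratio(self):
        # raising the barrier peak by 2 kT multiplies 1/J by ~ e^2
        b1 = 0.02
        peaks = (4.0, 6.0)
        Js = []
        for peak in peaks:
            b2 = math.sqrt(4.0 * b1 * peak)
            prob = DriftDiffusionProblem(N=60.0,
                                         potential=ParabolicBarrier(b1, b2),
                                         boundary_at_0=fixed_value(1.0))
            Js.append(steady_state_flux(prob, 1024))
        assert Js[0] / Js[1] == pytest.approx(math.e**2, rel=0.2)

    def test_requires_fixed_inlet(self):
        prob = DriftDiffusionProblem(N=10.0, potential=flat)
        with pytest.raises(ValueError):
            steady_state_flux(prob)


class TestMeanFirstPassage:
    def test_flat_potential_classical_value(self):
        prob = DriftDiffusionProblem(N=20.0, potential=flat, diffusion=1.0)
        res = mean_first_passage_time(prob)
        assert res.tau_quadrature == pytest.approx(200.0, rel=1e-6)
        assert res.relative_difference < 0.01

    def test_drift_dominated_limit(self):
        # strong downhill tilt: tau -> N / (k0 beta |F'|)
        slope = 2.0
        prob = DriftDiffusionProblem(N=40.0, potential=lambda m: -slope * m,
                                     diffusion=1.0)
        res = mean_first_passage_time(prob)
        assert res.tau_quadrature == pytest.approx(40.0 / slope, rel=0.05)
        assert res.relative_difference < 0.01

    def test_monotone_in_barrier_height(self):
        taus = []
        for b2 in (0.2, 0.5, 1.0):
            prob = DriftDiffusionProblem(N=30.0,
                                         potential=ParabolicBarrier(0.02, b2))
            taus.append(mean_first_passage_time(prob).tau_quadrature)
        assert taus[0] < taus[1] < taus[2]

    def test_coordinate_change_leaves_observables_invariant(self):
        """Solving in x = a m (stretched domain, rescaled inlet density)
        reproduces the m-coordinate flux and MFPT."""
        a = 2.0
        pb = ParabolicBarrier(0.05, 0.6)
        prob_m = DriftDiffusionProblem(N=20.0, potential=pb, diffusion=1.0,
                                       a=a, boundary_at_0=fixed_value(1.0))
        prob_x = DriftDiffusionProblem(
            N=20.0 * a, potential=lambda x: pb(x / a), diffusion=1.0,
            a=1.0, boundary_at_0=fixed_value(1.0 / a))
        Jm = steady_state_flux(prob_m, 1024)
        Jx = steady_state_flux(prob_x, 1024)
        assert Jx == pytest.approx(Jm, rel=1e-8)
        tm = mean_first_passage_time(
            DriftDiffusionProblem(N=20.0, potential=pb, a=a)).tau_quadrature
        tx = mean_first_passage_time(
            DriftDiffusionProblem(N=40.0, potential=lambda x: pb(x / a),
                                  a=1.0)).tau_quadrature
        assert tx == pytest.approx(tm, rel=1e-8)

    def test_requires_reflecting_absorbing_setup(self):
        prob = DriftDiffusionProblem(N=10.0, potential=flat,
                                     boundary_at_0=fixed_value(0.5))
        with pytest.raises(ValueError):
            mean_first_passage_time(prob)


class TestFirstPassageHistogram:
    def test_density_integrates_to_one_and_matches_mfpt(self):
        prob = DriftDiffusionProblem(N=10.0, potential=flat, diffusion=1.0)
        tau = mean_first_passage_time(prob).tau_quadrature  # 50
        tgrid = np.linspace(0.0, 12.0 * tau, 600)
        t, rho = first_passage_histogram(prob, 0.0, tgrid)
        total = np.trapezoid(rho, t)
        assert total == pytest.approx(1.0, abs=1e-4)
        first_moment = np.trapezoid(t * rho, t)
        assert first_moment == pytest.approx(tau, rel=0.01)

    def test_strong_drift_density_is_right_skewed(self):
        prob = DriftDiffusionProblem(N=20.0, potential=lambda m: -2.0 * m)
        tau = mean_first_passage_time(prob).tau_quadrature
        tgrid = np.linspace(0.0, 8.0 * tau, 400)
        t, rho = first_passage_histogram(prob, 0.0, tgrid)
        w = np.trapezoid(rho, t)
        mu = np.trapezoid(t * rho, t) / w
        m2 = np.trapezoid((t - mu) ** 2 * rho, t) / w
        m3 = np.trapezoid((t - mu) ** 3 * rho, t) / w
        assert m3 / m2**1.5 > 0.0

    def test_rejects_bad_time_grid(self):
        prob = DriftDiffusionProblem(N=10.0, potential=flat)
        with pytest.raises(ValueError):
            first_passage_histogram(prob, 0.0, np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            first_passage_histogram(prob, 0.0, np.array([0.0, 2.0, 1.0]))
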