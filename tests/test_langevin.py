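"""Exact-OU integrator physics and translocation event bookkeeping."""

import math

import numpy as np
import pytest

from translokit.langevin import (BeadSpringPolymer, DrivingField,
                                 LangevinParams, MembranePore, chain_forces,
                                 langevin_step, ou_coefficients,
                                 run_translocation, si_field_to_reduced_force,
                                 stokes_drift_velocity)


def free_bead(n=1, dim=2):
    return BeadSpringPolymer(positions=np.zeros((n, dim)),
                             velocities=np.zeros((n, dim)), bond_k=0.0)


class TestOUCoefficients:
    def test_small_damping_taylor_limit(self):
        dt = 0.01
        _, k1, k2, *_ = ou_coefficients(1e-8, dt, 1.0, 1.0)
        assert k1 == pytest.approx(dt, rel=1e-6)
        assert k2 == pytest.approx(dt * dt / 2.0, rel=1e-6)

    def test_zero_damping_is_newtonian_and_noiseless(self):
        E1, k1, k2, sv, xc, xr = ou_coefficients(0.0, 0.05, 1.0, 1.0)
        assert E1 == 1.0 and k1 == 0.05
        assert k2 == pytest.approx(0.00125, rel=1e-12)
        assert sv == xc == xr == 0.0

    def test_noise_covariance_positive_semidefinite(self):
        for u in (1e-6, 1e-3, 0.1, 1.0, 10.0):
            _, _, _, sv, xc, xr = ou_coefficients(u / 0.01, 0.01, 2.0, 3.0)
            assert sv >= 0 and xr >= 0

    def test_velocity_variance_is_exact_ou(self):
        gamma, dt, kT, M = 1.7, 0.3, 2.0, 0.5
        E1, _, _, sv, _, _ = ou_coefficients(gamma, dt, kT, M)
        assert sv**2 == pytest.approx((kT / M) * (1 - E1**2), rel=1e-12)


class TestLangevinStep:
    def test_zero_force_noiseless_drifts_ballistically(self):
        p = free_bead()
        p.velocities[0, 0] = 1.3
        params = LangevinParams(gamma_damp=1e-9, dt=0.01, noise_on=False)
        langevin_step(p, params, np.zeros((1, 2)))
        assert p.positions[0, 0] == pytest.approx(1.3 * 0.01, rel=1e-6)

    def test_terminal_velocity_under_constant_force(self):
        p = free_bead()
        params = LangevinParams(gamma_damp=2.0, dt=0.01, noise_on=False)
        f = np.array([[3.0, 0.0]])
        for _ in range(4000):
            langevin_step(p, params, f)
        assert p.velocities[0, 0] == pytest.approx(3.0 / 2.0, rel=1e-9)

    def test_one_step_equals_two_half_steps_exactly(self):
        f = np.array([[0.7, -0.2]])
        p1 = free_bead(); p1.velocities[:] = [[1.0, -0.5]]
        p2 = free_bead(); p2.velocities[:] = [[1.0, -0.5]]
        langevin_step(p1, LangevinParams(gamma_damp=1.7, dt=0.2, noise_on=False), f)
        half = LangevinParams(gamma_damp=1.7, dt=0.1, noise_on=False)
        langevin_step(p2, half, f)
        langevin_step(p2, half, f)
        assert np.allclose(p1.positions, p2.positions, atol=1e-14)
        assert np.allclose(p1.velocities, p2.velocities, atol=1e-14)

    def test_equipartition_velocity_variance(self):
        kT, M = 1.5, 2.0
        params = LangevinParams(gamma_damp=1.0, kT=kT, mass=M, dt=0.05)
        rng = np.random.default_rng(42)
        p = free_bead(n=200)
        zero = np.zeros((200, 2))
        samples = []
        for i in range(1500):
            langevin_step(p, params, zero, rng=rng)
            if i > 300:
                samples.append(p.velocities.copy())
        v = np.concatenate(samples).ravel()   # ~4.8e5 samples
        se = math.sqrt(2.0 / v.size) * (kT / M)  # var-of-variance, Gaussian
        assert abs(v.var() - kT / M) < 3 * se * 3  # correlated draws: margin x3

    def test_mobility_under_constant_force(self):
        gamma, M, f0 = 2.0, 1.0, 1.4
        params = LangevinParams(gamma_damp=gamma, mass=M, dt=0.05)
        rng = np.random.default_rng(3)
        p = free_bead(n=400)
        f = np.zeros((400, 2)); f[:, 0] = f0
        vs = []
        for i in range(1200):
            langevin_step(p, params, f, rng=rng)
            if i > 200:
                vs.append(p.velocities[:, 0].copy())
        v = np.concatenate(vs)
        se = v.std() / math.sqrt(400)  # ~independent walkers
        assert abs(v.mean() - f0 / (M * gamma)) < 3 * se

    def test_harmonic_well_position_variance(self):
        kT, k_spring = 1.0, 4.0
        params = LangevinParams(gamma_damp=1.0, kT=kT, dt=0.02)
        rng = np.random.default_rng(11)
        p = free_bead(n=300)
        xs = []
        for i in range(4000):
            langevin_step(p, params, -k_spring * p.positions, rng=rng)
            if i > 1000 and i % 10 == 0:
                xs.append(p.positions[:, 0].copy())
        x = np.concatenate(xs)
        se = math.sqrt(2.0 / 300) * (kT / k_spring)  # by independent walkers
        assert abs(x.var() - kT / k_spring) < 3 * se

    def test_nan_force_names_the_bead(self):
        p = free_bead(n=3)
        f = np.zeros((3, 2)); f[1, 0] = np.nan
        with pytest.raises(FloatingPointError, match="bead 1"):
            langevin_step(p, LangevinParams(), f)


class TestStokesAndFieldMapping:
    def test_zero_field_zero_velocity(self):
        assert stokes_drift_velocity(1.6e-19, 0.0, 1e-3, 1e-9) == 0.0

    def test_linear_in_field(self):
        v1 = stokes_drift_velocity(1.6e-19, 1e6, 1e-3, 1e-9)
        v2 = stokes_drift_velocity(1.6e-19, 2e6, 1e-3, 1e-9)
        assert v2 == pytest.approx(2 * v1)

    def test_coulomb_stokes_balance_value(self):
        v = stokes_drift_velocity(1.6e-19, 1e6, 1e-3, 1e-9)
        assert v == pytest.approx(8.49e-3, rel=1e-3)

    def test_reduced_force_scales_with_field_and_charge(self):
        f1 = si_field_to_reduced_force(1e6)
        assert si_field_to_reduced_force(2e6) == pytest.approx(2 * f1)
        assert si_field_to_reduced_force(1e6, q=2 * 1.602176634e-19) == \
            pytest.approx(2 * f1)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            stokes_drift_velocity(1.0, 1.0, -1.0, 1.0)


class TestChainForces:
    def test_bonds_at_rest_length_give_zero_force(self):
        chain = BeadSpringPolymer.straight_chain(5, dim=2)
        f = chain_forces(chain, None, None)
        assert np.allclose(f, 0.0)

    def test_stretched_bond_pulls_beads_together(self):
        chain = BeadSpringPolymer(positions=[[0.0, 0.0], [1.5, 0.0]],
                                  velocities=np.zeros((2, 2)), bond_k=100.0)
        f = chain_forces(chain, None, None)
        assert f[0, 0] == pytest.approx(+50.0)
        assert f[1, 0] == pytest.approx(-50.0)

    def test_wall_repels_outside_the_pore_only(self):
        pore = MembranePore()
        inside = BeadSpringPolymer(positions=[[0.2, 0.0]],
                                   velocities=np.zeros((1, 2)), bond_k=0.0)
        assert np.allclose(chain_forces(inside, pore, None), 0.0)
        blocked = BeadSpringPolymer(positions=[[0.2, 2.0]],
                                    velocities=np.zeros((1, 2)), bond_k=0.0)
        f = chain_forces(blocked, pore, None)
        assert f[0, 0] > 0.0  # pushed out towards the nearer (trans) side

    def test_driving_modes_touch_the_right_beads(self):
        pore = MembranePore()
        chain = BeadSpringPolymer(positions=[[0.0, 0.0], [-1.0, 0.0]],
                                  velocities=np.zeros((2, 2)), bond_k=0.0)
        f_end = chain_forces(chain, pore, DrivingField(mode="end_force",
                                                       end_force_f=2.0))
        assert f_end[0, 0] == pytest.approx(2.0) and f_end[1, 0] == 0.0
        f_uni = chain_forces(chain, pore,
                             DrivingField(mode="electric_uniform",
                                          reduced_force=2.0))
        assert np.allclose(f_uni[:, 0], 2.0)
        f_pore = chain_forces(chain, pore,
                              DrivingField(mode="electric_in_pore",
                                           reduced_force=2.0))
        assert f_pore[0, 0] == pytest.approx(2.0)  # inside the slab
        assert f_pore[1, 0] == 0.0                 # outside


class TestRunTranslocation:
    def test_identical_seed_identical_event(self):
        chain = BeadSpringPolymer.straight_chain(8, dim=2)
        pore = MembranePore()
        drive = DrivingField(mode="end_force", end_force_f=5.0)
        params = LangevinParams(dt=0.01)
        ev1 = run_translocation(chain, pore, drive, params, 2000.0, seed=9)
        ev2 = run_translocation(chain, pore, drive, params, 2000.0, seed=9)
        assert ev1 == ev2
        assert ev1.success and ev1.tau > 0

    def test_single_bead_ballistic_crossing_time(self):
        # noise off, overdamped: crossing from the mouth to the midpoint at
        # terminal velocity v = f/(M gamma)
        gamma, f0 = 20.0, 2.0
        chain = BeadSpringPolymer.straight_chain(1, dim=2)
        pore = MembranePore()
        drive = DrivingField(mode="electric_in_pore", reduced_force=f0)
        params = LangevinParams(gamma_damp=gamma, dt=0.001, noise_on=False)
        ev = run_translocation(chain, pore, drive, params, 100.0, seed=1)
        distance = pore.wall_thickness / 2.0  # mouth -> midpoint
        assert ev.success
        assert ev.tau == pytest.approx(distance / (f0 / gamma), rel=0.10)

    def test_dimension_mismatch_rejected(self):
        chain = BeadSpringPolymer.straight_chain(4, dim=3)
        with pytest.raises(ValueError):
            run_translocation(chain, MembranePore(dimension=2),
                              DrivingField(mode="end_force", end_force_f=1.0),
                              LangevinParams(), 10.0)

    def test_unthreadable_pore_rejected(self):
        chain = BeadSpringPolymer.straight_chain(4, dim=2)
        with pytest.raises(ValueError):
            run_translocation(chain, MembranePore(pore_radius=0.3),
                              DrivingField(mode="end_force", end_force_f=1.0),
                              LangevinParams(), 10.0)
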