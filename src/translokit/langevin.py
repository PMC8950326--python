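"""Driven bead-spring Langevin dynamics of nanopore translocation.

A chain of ``N`` beads (mass ``M``, harmonic bonds of rest length ``a``)
obeys the underdamped Langevin equation

    dx = v dt
    dv = M^-1 F(x) dt - gamma v dt + sqrt(2 gamma kT) M^-1/2 dW(t)

integrated with the *exact* exponential (Ornstein-Uhlenbeck) propagator:
over a step in which the force is held at its start-of-step value, the
position picks up ``(1 - e^{-gamma dt})/gamma * v`` plus the force and noise
convolution kernels, and the (position, velocity) noise pair is jointly
Gaussian with the exact OU covariance.  With the noise switched off and a
constant force the update reduces to the closed deterministic recursion
(the kernels compose exactly: one step of ``dt`` equals two of ``dt/2``).

The membrane is a repulsive slab normal to the x axis with a cylindrical
(3-D) or slit (2-D) opening; driving is a constant force on the leading
bead, a uniform field, or a field applied only inside the pore (the whole
potential drop across the pore).  The engine runs in reduced units
(``a = kT = M = 1``); :func:`si_field_to_reduced_force` maps an electric
field in V/m onto the reduced per-bead force through the Coulomb force
``qE`` and the thermal energy scale, so field sweeps can be quoted in SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import _langevin_kernels as _k

__all__ = [
    "LangevinParams",
    "BeadSpringPolymer",
    "MembranePore",
    "DrivingField",
    "TranslocationEvent",
    "TauHistogram",
    "ou_coefficients",
    "langevin_step",
    "stokes_drift_velocity",
    "si_field_to_reduced_force",
    "run_translocation",
    "escape_time_surface",
    "translocation_histogram",
]

ELEMENTARY_CHARGE = 1.602176634e-19   # C
KT_ROOM = 1.380649e-23 * 300.0        # J, thermal energy at 300 K
MONOMER_SIZE_SI = 1.0e-9              # m, nominal monomer size
#: effective charge of one coarse-grained bead.  A bead stands for a
#: multi-base polyelectrolyte segment, not a single ion; 30 elementary
#: charges maps fields of 1e6-7e6 V/m onto reduced drives of ~1.2-8 kT/a,
#: the window spanning weakly to strongly driven threading.
BEAD_CHARGE = 30.0 * ELEMENTARY_CHARGE


@dataclass(frozen=True)
class LangevinParams:
    """Integrator constants: damping gamma (1/time), kT, per-bead mass,
    time step and RNG seed.  Fluctuation-dissipation fixes the noise
    amplitude at sqrt(2 gamma kT / M); gamma = 0 is the noiseless
    Newtonian limit."""

    gamma_damp: float = 1.0
    kT: float = 1.0
    mass: float = 1.0
    dt: float = 0.01
    seed: int = 0
    noise_on: bool = True

    def __post_init__(self) -> None:
        if self.gamma_damp < 0:
            raise ValueError("gamma_damp must be >= 0")
        if self.dt <= 0 or self.kT <= 0 or self.mass <= 0:
            raise ValueError("dt, kT and mass must be positive")
        if not np.isfinite(math.exp(-self.gamma_damp * self.dt)):
            raise ValueError("gamma * dt produces non-finite exponentials")


@dataclass
class BeadSpringPolymer:
    """Chain state: positions/velocities (N, dim), harmonic bonds, charge."""

    positions: np.ndarray
    velocities: np.ndarray
    bond_k: float = 100.0
    bond_length: float = 1.0
    charge: float = BEAD_CHARGE
    excluded_volume: str = "off"    # "off" | "purely_repulsive"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape or self.positions.ndim != 2:
            raise ValueError("positions and velocities must share shape (N, dim)")
        if self.excluded_volume not in ("off", "purely_repulsive"):
            raise ValueError("excluded_volume must be 'off' or 'purely_repulsive'")

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @classmethod
    def straight_chain(cls, N: int, dim: int = 2, bond_length: float = 1.0,
                       bond_k: float = 100.0, start=None, axis: int = 0,
                       **kw) -> "BeadSpringPolymer":
        """Chain laid out along ``-axis`` from ``start`` (default origin)."""
        pos = np.zeros((N, dim))
        if start is not None:
            pos[:] = np.asarray(start, dtype=float)
        pos[:, axis] -= bond_length * np.arange(N)
        return cls(positions=pos, velocities=np.zeros((N, dim)),
                   bond_k=bond_k, bond_length=bond_length, **kw)


@dataclass(frozen=True)
class MembranePore:
    """Repulsive membrane slab with an opening, normal to axis 0."""

    wall_position: float = 0.0
    wall_thickness: float = 1.0
    pore_radius: float = 0.6
    dimension: int = 2
    wall_stiffness: float = 200.0

    def __post_init__(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError("dimension must be 2 or 3")
        if self.pore_radius <= 0 or self.wall_thickness <= 0:
            raise ValueError("pore_radius and wall_thickness must be positive")

    def check_threadable(self, bond_length: float) -> None:
        if self.pore_radius < bond_length / 2.0:
            raise ValueError(
                f"pore radius {self.pore_radius} below half the bond length "
                f"{bond_length}: chain cannot thread"
            )


@dataclass(frozen=True)
class DrivingField:
    """Driving mode and magnitude.

    ``end_force`` pulls the leading bead with ``end_force_f`` (reduced
    units); the electric modes convert field ``E`` (V/m) and bead charge
    ``q`` to a reduced per-bead force via :func:`si_field_to_reduced_force`
    unless ``reduced_force`` overrides the mapping.
    """

    mode: str = "electric_in_pore"   # electric_in_pore | electric_uniform | end_force
    E: float = 0.0
    q: float = BEAD_CHARGE
    end_force_f: float = 0.0
    viscosity_eta: float = 1.0e-3
    reduced_force: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("electric_in_pore", "electric_uniform", "end_force"):
            raise ValueError(f"unknown driving mode {self.mode!r}")
        if self.mode.startswith("electric") and self.reduced_force is None and self.q == 0:
            raise ValueError("electric driving requires a bead charge q")

    @property
    def kernel_mode(self) -> int:
        return {"end_force": _k.MODE_END_FORCE,
                "electric_uniform": _k.MODE_UNIFORM,
                "electric_in_pore": _k.MODE_IN_PORE}[self.mode]

    @property
    def kernel_force(self) -> float:
        if self.mode == "end_force":
            return float(self.end_force_f)
        if self.reduced_force is not None:
            return float(self.reduced_force)
        return si_field_to_reduced_force(self.E, q=self.q)


@dataclass(frozen=True)
class TranslocationEvent:
    """One simulated passage attempt."""

    t_entry: float
    t_exit: float
    tau: float
    success: bool
    n_steps: int
    seed: int


@dataclass(frozen=True)
class TauHistogram:
    """Escape-time sample with moments and an upper-decile exponential fit."""

    taus: np.ndarray
    counts: np.ndarray
    edges: np.ndarray
    mean: float
    sd: float
    skewness: float
    tail_rate: float   # MLE decay rate of exceedances above the 90th percentile


def ou_coefficients(gamma: float, dt: float, kT: float, mass: float
                    ) -> tuple[float, float, float, float, float, float]:
    """Exact OU propagation constants (E1, k1, k2, sv, x_corr, x_res).

    E1 = e^{-gamma dt}; k1 = (1 - E1)/gamma multiplies the initial velocity;
    k2 = (gamma dt - 1 + E1)/gamma^2 multiplies the acceleration F/M.  The
    joint noise is  dv = sv xi_v,  dx = x_corr xi_v + x_res xi_x  with
    sv^2   = (kT/M)(1 - E1^2)
    cov    = (kT/(M gamma))(1 - E1)^2
    sx^2   = (kT/(M gamma^2))(2 gamma dt - 3 + 4 E1 - E1^2)
    x_corr = cov/sv,  x_res = sqrt(sx^2 - x_corr^2).
    Series are used near gamma dt -> 0 where the closed forms cancel; at
    gamma = 0 fluctuation-dissipation turns the noise off and the kernels
    reduce to the Newtonian dt, dt^2/2.
    """
    if gamma == 0.0:
        return 1.0, dt, 0.5 * dt * dt, 0.0, 0.0, 0.0
    u = gamma * dt
    E1 = math.exp(-u)
    k1 = -math.expm1(-u) / gamma
    if u < 1e-3:
        # (dt - k1)/gamma cancels catastrophically for small gamma dt
        k2 = dt * dt * (0.5 - u / 6.0 + u * u / 24.0 - u**3 / 120.0)
    else:
        k2 = (dt - k1) / gamma
    kTm = kT / mass
    sv2 = kTm * (-math.expm1(-2.0 * u))
    cov = kTm / gamma * math.expm1(-u) ** 2
    if u < 1e-3:
        sx2 = kTm / gamma**2 * (2.0 / 3.0 * u**3 - 0.5 * u**4 + 0.3 * u**5)
    else:
        sx2 = kTm / gamma**2 * (2.0 * u - 3.0 + 4.0 * E1 - E1 * E1)
    sv = math.sqrt(sv2)
    x_corr = cov / sv if sv > 0 else 0.0
    x_res = math.sqrt(max(sx2 - x_corr * x_corr, 0.0))
    return E1, k1, k2, sv, x_corr, x_res


def langevin_step(polymer: BeadSpringPolymer, params: LangevinParams, forces,
                  rng: np.random.Generator | None = None) -> BeadSpringPolymer:
    """Advance the chain by one exact-OU step under the given start-of-step
    forces (array of shape (N, dim)).  Mutates and returns ``polymer``."""
    forces = np.asarray(forces, dtype=float)
    if forces.shape != polymer.positions.shape:
        raise ValueError("forces must match the (N, dim) chain shape")
    if not np.all(np.isfinite(forces)):
        bad = int(np.argwhere(~np.isfinite(forces).all(axis=1))[0][0])
        raise FloatingPointError(f"non-finite force on bead {bad}")
    E1, k1, k2, sv, x_corr, x_res = ou_coefficients(
        params.gamma_damp, params.dt, params.kT, params.mass)
    fm = forces / params.mass
    v0 = polymer.velocities
    if params.noise_on and sv > 0.0:
        if rng is None:
            rng = np.random.default_rng(params.seed)
        xi_v = rng.standard_normal(v0.shape)
        xi_x = rng.standard_normal(v0.shape)
        polymer.positions += v0 * k1 + fm * k2 + x_corr * xi_v + x_res * xi_x
        polymer.velocities = v0 * E1 + fm * k1 + sv * xi_v
    else:
        polymer.positions += v0 * k1 + fm * k2
        polymer.velocities = v0 * E1 + fm * k1
    return polymer


def chain_forces(polymer: BeadSpringPolymer, pore: MembranePore | None,
                 driving: DrivingField | None,
                 tether_first: bool = False) -> np.ndarray:
    """Total force on every bead (bonds + wall + driving), via the compiled
    kernel so the API path and the event loops share one force model."""
    forces = np.zeros_like(polymer.positions)
    mode = driving.kernel_mode if driving is not None else _k.MODE_END_FORCE
    fmag = driving.kernel_force if driving is not None else 0.0
    if pore is None:
        # wall_half < 0 makes the slab test inside the kernel always false
        wall_pos, wall_half, pore_r2, k_wall = 0.0, -1.0, 0.0, 0.0
    else:
        wall_pos = pore.wall_position
        wall_half = pore.wall_thickness / 2.0
        pore_r2 = pore.pore_radius**2
        k_wall = pore.wall_stiffness
    _k.compute_forces(polymer.positions, forces, polymer.bond_k,
                      polymer.bond_length, wall_pos, wall_half, pore_r2,
                      k_wall, mode, fmag,
                      polymer.excluded_volume == "purely_repulsive", 50.0,
                      tether_first)
    return forces


def stokes_drift_velocity(q: float, E: float, eta: float, a: float) -> float:
    """Terminal velocity qE / (6 pi eta a) from the Coulomb/Stokes balance."""
    if eta <= 0 or a <= 0:
        raise ValueError("viscosity and monomer radius must be positive")
    return q * E / (6.0 * math.pi * eta * a)


def si_field_to_reduced_force(E: float, q: float = ELEMENTARY_CHARGE,
                              a_si: float = MONOMER_SIZE_SI,
                              kT_si: float = KT_ROOM) -> float:
    """Reduced per-bead force for a field E in V/m: qE a / kT.

    The engine's unit of force is kT/a; a monomer-sized charge q in a field
    E feels qE, hence the dimensionless drive qE a / kT.
    """
    return q * E * a_si / kT_si


def _event_seed(root_seed: int, index: int) -> int:
    ss = np.random.SeedSequence(entropy=(int(root_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_translocation(polymer: BeadSpringPolymer, pore: MembranePore,
                      driving: DrivingField, params: LangevinParams,
                      max_time: float, seed: int | None = None,
                      tether_leading_bead: bool = True) -> TranslocationEvent:
    """Simulate one threading attempt and return the escape event.

    The chain template supplies N, bond constants and charge; the run builds
    its own initial condition (chain straight on the cis side, leading bead
    just inside the pore mouth), equilibrates with the leading bead pinned
    and the drive off for ten bond-relaxation times per bead, then releases
    and steps until every bead has passed the pore midpoint or ``max_time``
    elapses.  Identical inputs and seed give identical events.

    By default the leading bead may not retract behind the cis pore mouth
    once released (``tether_leading_bead``): the threading coordinate has a
    reflecting boundary at m = 0, matching the drift-diffusion engine's
    cis-side condition, and the chain cannot wander off and lose the pore.
    """
    pore.check_threadable(polymer.bond_length)
    if seed is None:
        seed = params.seed
    N, dim = polymer.N, polymer.dim
    if dim != pore.dimension:
        raise ValueError(f"chain dimension {dim} != pore dimension {pore.dimension}")
    wall_half = pore.wall_thickness / 2.0
    mouth = pore.wall_position - wall_half + 1e-3 * polymer.bond_length
    pos = np.zeros((N, dim))
    pos[:, 0] = mouth - polymer.bond_length * np.arange(N)
    vel = np.zeros((N, dim))

    E1, k1, k2, sv, x_corr, x_res = ou_coefficients(
        params.gamma_damp, params.dt, params.kT, params.mass)
    bond_relax = params.gamma_damp / polymer.bond_k if polymer.bond_k > 0 else 0.0
    n_eq = int(round(10.0 * N * bond_relax / params.dt)) if params.noise_on else 0
    max_steps = max(1, int(max_time / params.dt))
    tau, success, n_steps = _k.run_event(
        pos, vel, 1.0 / params.mass, polymer.bond_k, polymer.bond_length,
        pore.wall_position, wall_half, pore.pore_radius**2, pore.wall_stiffness,
        driving.kernel_mode, driving.kernel_force,
        polymer.excluded_volume == "purely_repulsive", 50.0,
        E1, k1, k2, sv, x_corr, x_res, params.noise_on and sv > 0.0,
        seed, n_eq, max_steps, params.dt, tether_leading_bead)
    return TranslocationEvent(t_entry=0.0, t_exit=tau, tau=tau,
                              success=bool(success), n_steps=int(n_steps),
                              seed=int(seed))


def escape_time_surface(E_values, N_values, replicates: int,
                        params: LangevinParams | None = None,
                        pore: MembranePore | None = None,
                        driving: DrivingField | None = None,
                        bond_k: float = 100.0, bond_length: float = 1.0,
                        max_time: float = 2000.0, seed: int = 0) -> pd.DataFrame:
    """Mean escape time over an (E, N) grid from seeded replicates.

    ``E_values`` are electric fields in V/m (mapped to reduced drive through
    the Coulomb/thermal scale); default ranges of interest are
    E in [1e6, 7e6] V/m, N in [5, 50].  Returns a long-format table with
    columns E, N, mean_tau, sd_tau, n_success, timed_out; a cell whose
    every replicate times out is flagged, never dropped.
    """
    E_values = np.atleast_1d(np.asarray(E_values, dtype=float))
    N_values = np.atleast_1d(np.asarray(N_values, dtype=int))
    if replicates < 1 or E_values.size == 0 or N_values.size == 0:
        raise ValueError("need replicates >= 1 and non-empty E and N grids")
    params = params or LangevinParams()
    base_drive = driving or DrivingField(mode="electric_in_pore")
    rows = []
    idx = 0
    for E in E_values:
        drive = replace(base_drive, E=float(E), reduced_force=None) \
            if base_drive.mode.startswith("electric") else base_drive
        for N in N_values:
            pore_N = pore or MembranePore()
            chain = BeadSpringPolymer.straight_chain(
                int(N), dim=pore_N.dimension, bond_length=bond_length, bond_k=bond_k)
            taus = []
            for _ in range(replicates):
                ev = run_translocation(chain, pore_N, drive, params, max_time,
                                       seed=_event_seed(seed, idx))
                idx += 1
                if ev.success:
                    taus.append(ev.tau)
            n_succ = len(taus)
            rows.append({
                "E": float(E), "N": int(N),
                "mean_tau": float(np.mean(taus)) if n_succ else np.nan,
                "sd_tau": float(np.std(taus, ddof=1)) if n_succ > 1 else np.nan,
                "n_success": n_succ,
                "timed_out": n_succ == 0,
            })
    return pd.DataFrame(rows)


def translocation_histogram(n_events: int,
                            N: int = 16,
                            params: LangevinParams | None = None,
                            pore: MembranePore | None = None,
                            driving: DrivingField | None = None,
                            bond_k: float = 100.0, bond_length: float = 1.0,
                            max_time: float = 5000.0, seed: int = 0,
                            bins: int = 30) -> TauHistogram:
    """Escape-time histogram with moments and an exponential-tail fit.

    Requires ``n_events >= 100`` attempts and refuses statistics if fewer
    than 100 succeed.  The tail rate is the maximum-likelihood exponential
    decay constant of exceedances above the 90th percentile.
    """
    if n_events < 100:
        raise ValueError("histogram statistics need at least 100 events")
    params = params or LangevinParams()
    pore = pore or MembranePore()
    driving = driving or DrivingField(mode="electric_in_pore", E=2e6)
    chain = BeadSpringPolymer.straight_chain(
        N, dim=pore.dimension, bond_length=bond_length, bond_k=bond_k)
    taus = []
    for i in range(n_events):
        ev = run_translocation(chain, pore, driving, params, max_time,
                               seed=_event_seed(seed, i))
        if ev.success:
            taus.append(ev.tau)
    if len(taus) < 100:
        raise RuntimeError(
            f"only {len(taus)} of {n_events} events succeeded; "
            "statistics refused (raise max_time or the drive)"
        )
    taus = np.asarray(taus)
    counts, edges = np.histogram(taus, bins=bins)
    q90 = float(np.quantile(taus, 0.9))
    exceed = taus[taus > q90] - q90
    tail_rate = 1.0 / float(np.mean(exceed)) if exceed.size else np.nan
    sd = float(np.std(taus, ddof=1))
    skew = float(stats.skew(taus, bias=False)) if sd > 0 else 0.0
    return TauHistogram(taus=taus, counts=counts, edges=edges,
                        mean=float(np.mean(taus)), sd=sd, skewness=skew,
                        tail_rate=tail_rate)
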