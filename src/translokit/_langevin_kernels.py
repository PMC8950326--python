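"""Numba-compiled inner loops for the bead-spring Langevin engine.

The exact Ornstein-Uhlenbeck propagation coefficients are precomputed in
:func:`translokit.langevin.ou_coefficients` (plain Python) and passed in as
scalars; these kernels only loop.  All randomness comes from numba's own
Mersenne-Twister stream, seeded explicitly per call, so identical inputs
give identical trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# driving-field modes
MODE_END_FORCE = 0
MODE_UNIFORM = 1
MODE_IN_PORE = 2

_NOISE_CHUNK = 64  # steps of noise drawn per batch inside event loops


@njit(cache=True)
def compute_forces(pos, forces, bond_k, bond_a,
                   wall_pos, wall_half, pore_r2, k_wall,
                   fmode, fmag, ev_on, k_ev, tether_first):
    n, dim = pos.shape
    for i in range(n):
        for d in range(dim):
            forces[i, d] = 0.0
    # harmonic bonds between consecutive beads, rest length bond_a
    for i in range(n - 1):
        r2 = 0.0
        for d in range(dim):
            dx = pos[i + 1, d] - pos[i, d]
            r2 += dx * dx
        r = np.sqrt(r2)
        if r > 1e-12:
            fmagb = bond_k * (r - bond_a) / r
            for d in range(dim):
                dx = pos[i + 1, d] - pos[i, d]
                forces[i, d] += fmagb * dx
                forces[i + 1, d] -= fmagb * dx
    # membrane wall: impenetrable slab of half-thickness wall_half around
    # wall_pos along axis 0, open inside the pore radius
    for i in range(n):
        ax = pos[i, 0] - wall_pos
        if -wall_half < ax < wall_half:
            rp2 = 0.0
            for d in range(1, dim):
                rp2 += pos[i, d] * pos[i, d]
            if rp2 > pore_r2:
                pen = wall_half - abs(ax)
                if ax >= 0.0:
                    forces[i, 0] += k_wall * pen
                else:
                    forces[i, 0] -= k_wall * pen
    # once threading has started the leading bead may not retract behind
    # the cis pore mouth (the m = 0 boundary is reflecting: the chain
    # cannot fully un-thread)
    if tether_first:
        back = pos[0, 0] - (wall_pos - wall_half)
        if back < 0.0:
            forces[0, 0] -= k_wall * back
    # driving field along +axis0
    if fmode == MODE_END_FORCE:
        forces[0, 0] += fmag
    elif fmode == MODE_UNIFORM:
        for i in range(n):
            forces[i, 0] += fmag
    else:  # MODE_IN_PORE: the potential drop lives inside the pore
        for i in range(n):
            ax = pos[i, 0] - wall_pos
            if -wall_half < ax < wall_half:
                forces[i, 0] += fmag
    # optional purely repulsive excluded volume (harmonic contact)
    if ev_on:
        for i in range(n):
            for j in range(i + 2, n):  # bonded neighbours excluded
                r2 = 0.0
                for d in range(dim):
                    dx = pos[j, d] - pos[i, d]
                    r2 += dx * dx
                if r2 < bond_a * bond_a and r2 > 1e-24:
                    r = np.sqrt(r2)
                    fm = k_ev * (bond_a - r) / r
                    for d in range(dim):
                        dx = pos[j, d] - pos[i, d]
                        forces[i, d] -= fm * dx
                        forces[j, d] += fm * dx
    return forces


@njit(cache=True)
def ou_advance_det(pos, vel, forces, inv_mass, E1, k1, k2, pin_first):
    n, dim = pos.shape
    start = 1 if pin_first else 0
    for i in range(start, n):
        for d in range(dim):
            fm = forces[i, d] * inv_mass
            v0 = vel[i, d]
            vel[i, d] = v0 * E1 + fm * k1
            pos[i, d] += v0 * k1 + fm * k2


@njit(cache=True)
def ou_advance_noise(pos, vel, forces, inv_mass,
                     E1, k1, k2, sv, x_corr, x_res, xi, off, pin_first):
    """Advance one step; xi holds pre-drawn standard normals, consumed from
    offset ``off`` (two per coordinate, fixed layout for determinism)."""
    n, dim = pos.shape
    start = 1 if pin_first else 0
    for i in range(start, n):
        for d in range(dim):
            fm = forces[i, d] * inv_mass
            v0 = vel[i, d]
            j = off + 2 * (i * dim + d)
            xi_v = xi[j]
            xi_x = xi[j + 1]
            vel[i, d] = v0 * E1 + fm * k1 + sv * xi_v
            pos[i, d] += v0 * k1 + fm * k2 + x_corr * xi_v + x_res * xi_x


@njit(cache=True)
def ou_advance(pos, vel, forces, inv_mass,
               E1, k1, k2, sv, x_corr, x_res, noise_on, pin_first):
    """Single-call step (draws its own noise); event loops use the chunked
    variants above."""
    if noise_on:
        xi = np.random.standard_normal(2 * pos.size)
        ou_advance_noise(pos, vel, forces, inv_mass, E1, k1, k2, sv,
                         x_corr, x_res, xi, 0, pin_first)
    else:
        ou_advance_det(pos, vel, forces, inv_mass, E1, k1, k2, pin_first)


@njit(cache=True)
def run_event(pos, vel, inv_mass, bond_k, bond_a,
              wall_pos, wall_half, pore_r2, k_wall,
              fmode, fmag, ev_on, k_ev,
              E1, k1, k2, sv, x_corr, x_res, noise_on,
              seed, n_eq_steps, max_steps, dt, tether_first):
    """Equilibrate (bead 0 pinned, no drive), release, run until the whole
    chain has passed the pore midpoint.  Returns (tau, success, n_steps)."""
    np.random.seed(seed)
    n, dim = pos.shape
    forces = np.zeros_like(pos)
    per_step = 2 * n * dim
    xi = np.empty(0)
    ptr_steps = _NOISE_CHUNK  # force an initial draw
    for _ in range(n_eq_steps):
        compute_forces(pos, forces, bond_k, bond_a, wall_pos, wall_half,
                       pore_r2, k_wall, fmode, 0.0, ev_on, k_ev, False)
        if noise_on:
            if ptr_steps >= _NOISE_CHUNK:
                xi = np.random.standard_normal(per_step * _NOISE_CHUNK)
                ptr_steps = 0
            ou_advance_noise(pos, vel, forces, inv_mass, E1, k1, k2, sv,
                             x_corr, x_res, xi, per_step * ptr_steps, True)
            ptr_steps += 1
        else:
            ou_advance_det(pos, vel, forces, inv_mass, E1, k1, k2, True)
    steps = 0
    ptr_steps = _NOISE_CHUNK
    for step_i in range(max_steps):
        compute_forces(pos, forces, bond_k, bond_a, wall_pos, wall_half,
                       pore_r2, k_wall, fmode, fmag, ev_on, k_ev, tether_first)
        if noise_on:
            if ptr_steps >= _NOISE_CHUNK:
                xi = np.random.standard_normal(per_step * _NOISE_CHUNK)
                ptr_steps = 0
            ou_advance_noise(pos, vel, forces, inv_mass, E1, k1, k2, sv,
                             x_corr, x_res, xi, per_step * ptr_steps, False)
            ptr_steps += 1
        else:
            ou_advance_det(pos, vel, forces, inv_mass, E1, k1, k2, False)
        steps = step_i + 1
        m = 0
        for i in range(n):
            if pos[i, 0] > wall_pos:
                m += 1
        if m == n:
            return steps * dt, True, steps
    return max_steps * dt, False, steps


@njit(cache=True)
def run_single_barrier_escape(x0, L, b1, b2, k_wall,
                              E1, k1, k2, sv, x_corr, x_res,
                              inv_mass, seed, max_steps, dt):
    """1-D single bead in F(x) = -b1 x^2 + b2 x, reflecting (soft wall) at 0,
    absorbed at x >= L.  Force = -dF/dx = 2 b1 x - b2, plus the wall push.
    Returns (tau, success)."""
    np.random.seed(seed)
    x = x0
    v = 0.0
    buf = np.random.standard_normal(8192)
    ptr = 0
    for step_i in range(max_steps):
        f = 2.0 * b1 * x - b2
        if x < 0.0:
            f += -k_wall * x
        fm = f * inv_mass
        if ptr >= 8192:
            buf = np.random.standard_normal(8192)
            ptr = 0
        xi_v = buf[ptr]
        xi_x = buf[ptr + 1]
        ptr += 2
        v_new = v * E1 + fm * k1 + sv * xi_v
        x = x + v * k1 + fm * k2 + x_corr * xi_v + x_res * xi_x
        v = v_new
        if x >= L:
            return (step_i + 1) * dt, True
    return max_steps * dt, False
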