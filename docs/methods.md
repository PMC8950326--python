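# Methods

`translokit` models the passage (translocation) of a linear polymer through
a nanometre-scale pore in a membrane, at three levels that check one
another: a one-dimensional free-energy barrier over the threading
coordinate, closed-form and PDE treatments of the drift-diffusion dynamics
on that barrier, and an explicit bead-spring Langevin simulation of the
driven chain.  This note records the models, their assumptions, the
defaults and why they were chosen, and what the desk-scale runs do and do
not demonstrate.

## 1. Threading coordinate and free energy

The reaction coordinate is `m`, the number of monomers that have crossed
the pore midpoint (chain of `N` segments of size `a`).  A chain half
tethered at an impenetrable wall has partition sum `Z_m ~ m^(gamma-1)`
with partition exponent `gamma` (1/2 for ideal chains, ≈0.69 for
self-avoiding chains, 1 for rod-like chains), so with `m` segments on the
trans side and `N-m` on the cis side,

    beta F(m) = (1 - gamma1) ln(N - m) + (1 - gamma2) ln(m) + m beta dmu,

where `dmu = mu_cis - mu_trans` is the chemical-potential step per segment
(negative values favour translocation — stated explicitly because the sign
convention matters and is easy to get backwards).  Constant terms are
dropped: only free-energy *differences* are observable.

Numerical choices:

* For `gamma < 1` the log terms diverge at `m = 0, N`.  Continuous
  evaluation is clamped to `[delta, N - delta]`, `delta = 1e-6 N` by
  default (configurable); integer-monomer work uses `m = 1..N-1`.  `m` is
  treated as a continuous variable everywhere in the analytic modules; its
  discreteness only matters to the particle simulator.
* The barrier maximum is located by bracketed root finding on `dF/dm`
  (Brent, tolerance `1e-12 N`); the profile is strictly concave between
  the clamped endpoints, so the bracket is safe.  Profiles with
  `gamma1 = gamma2 = 1` are linear and raise a dedicated "no interior
  maximum" error rather than returning an endpoint.
* The parabolic surrogate `F(m) = -b1 m^2 + b2 m + b3` (`b1 > 0`) is fitted
  by least squares on `[0.1 N, 0.9 N]` with 81 uniform samples by default —
  wide enough to cover the barrier bulk, clear of the log singularities.
  `b3` is pure gauge: no observable depends on it, it is kept only so
  fitted curves overlay the original profile.

## 2. Closed-form stationary flux

With a linear friction profile `C(m) = c1 m + c2` and the parabolic
barrier, the stationary flux through the pore is `J = P0 / f(N)` with

    f(N) = a^2 beta * Int_0^N C(m) exp(beta [F(m) - F(0)]) dm,

`P0` the probability that the chain end sits at the pore inlet.  The
integral has an erf closed form; the full derivation (complete the square,
Gaussian integral, `m e^{...}` by parts) is spelled out step by step in the
module docstring of `translokit/flux.py`, and adaptive quadrature of the
defining integral is kept as the independent arbiter.  Every closed-form
evaluation used by `flux()` is gated against quadrature at `1e-6` relative
(the library's own tests require `1e-8`).

* Sharp barriers overflow double precision (`exp(beta b2^2 / 4 b1)` can
  exceed `1e300000` in the validated parameter domain), so both routes are
  computed in log space: the quadrature is peak-scaled, and the closed form
  is assembled from signed log-magnitudes using the scaled complementary
  error function `erfcx` for `e^{z^2} erf(z)` products.  Equivalence is
  asserted on `log f(N)`, which is the same relative-error statement
  whenever `f(N)` is representable.
* `b1 = 0` (no curvature) is served by quadrature only; the closed form's
  `b1^{3/2}` denominator is singular there.
* The inlet probability is in general flux-dependent; the library computes
  the flux-independent case and exposes a fixed-point hook
  (`inlet_probability=callable`) that ships as the identity map.
* Units are model units (`a`, `kT`, monomer friction); no SI conversion in
  this module.

## 3. Smoluchowski dynamics of P(m, t)

The density `P(m, t)` obeys the drift-diffusion equation
`dP/dt = d/dm [D dP/dm + beta D F' P]` with flux
`J = -(D/a^2)(dP/dm + beta F' P)`; `D(m)` is the local rate constant
(`k0`, the model time unit, when constant — position-dependent `D` is
accepted as a callable evaluated at cell faces).

* **Scheme.** Cell-centered finite volumes with Scharfetter–Gummel
  (exponentially fitted) face fluxes and implicit Euler stepping, uniform
  grid, default `n_grid = 512` (1024 for steady-state flux).  The scheme is
  positivity preserving, conserves mass to round-off with reflecting walls,
  reproduces the Boltzmann profile exactly at equilibrium, and is
  second-order in the grid spacing (verified by the convergence test).
* **Boundaries.**  Absorption at `m = N` is the model's defining
  irreversibility (the fully passed chain never returns).  The cis side is
  *not* fixed by the model: the stationary-flux derivation pins
  `P(0) = P0`, while transient escape-time runs use a reflecting wall (the
  chain cannot un-thread below `m = 0`).  Both are exposed;
  `steady_state_flux` requires the pinned inlet, `mean_first_passage_time`
  the reflecting one.  A reflecting trans-side variant exists for
  equilibrium studies.
* **MFPT two ways.** The mean escape time is computed by the classical
  double-integral quadrature for 1-D diffusion (dense-grid cumulative
  trapezoids with midrange exponent shifting) *and* as the time integral of
  the survival probability from the PDE solve (default `dt` is
  `1.25e-3` of the quadrature estimate, stepping until survival falls
  below `1e-10`, with an exponential-tail correction for the remainder).
  Both values are returned; a disagreement above 1 % raises.
* A constant driving force enters as a linear potential term through the
  separate `drive_force` parameter, deliberately not conflated with the
  free energy `F(m)`.

## 4. Bead-spring Langevin simulator

The chain is `N` beads of mass `M` joined by harmonic bonds (stiffness
`k_bond = 100 kT/a^2`, rest length `a`), moving under

    dx = v dt,
    dv = M^-1 F(x) dt - gamma v dt + sqrt(2 gamma kT) M^-1/2 dW,

in reduced units `a = kT = M = 1` with `gamma = 1/time` the damping.

* **Integrator.** The exact exponential (Ornstein–Uhlenbeck) propagator:
  forces are frozen at their start-of-step values and the linear SDE is
  solved exactly over `dt`, including the *joint* Gaussian
  (position, velocity) noise with the full OU covariance — the
  position-only update with the `(1 - e^{-gamma dt})/gamma` kernel is the
  marginal of this propagator, and the noise-free constant-force variant is
  kept as a deterministic regression mode.  Kernels are evaluated with
  `expm1`/series forms near `gamma dt -> 0`; `gamma = 0` reduces exactly to
  Newtonian drift with zero noise (fluctuation–dissipation).  For a free
  particle under constant force the kernels compose exactly: one step of
  `dt` equals two steps of `dt/2` to machine precision.
* **Geometry.** The membrane is a soft repulsive slab (stiffness
  `200 kT/a^2`, thickness `1 a`) normal to the x axis with a slit (2-D) or
  cylindrical (3-D) opening of radius `0.6 a`; beads inside the slab but
  outside the opening are pushed back to the nearer side.  Simulations are
  2-D by default (cheapest realization of the driven threading problem;
  3-D is available).
* **Driving.** Three modes: constant force on the leading bead
  (`end_force`), uniform field, or field applied only inside the pore
  (default — the entire potential drop is across the pore).  Electric
  fields are quoted in V/m and mapped to the reduced per-bead force
  `q E a / kT` with `a = 1 nm` and `kT` at 300 K.  The default effective
  bead charge is 30 elementary charges: a bead stands for a multi-base
  polyelectrolyte segment, and this choice places the field window
  `1e6–7e6 V/m` at reduced drives of ≈1.2–8 `kT/a`, spanning weakly to
  strongly driven threading (the regime in which escape times both
  complete and vary strongly).  The Stokes/Coulomb balance
  `v = qE/(6 pi eta a)` is provided as an SI-side helper.
* **Protocol.** Each event builds a straight cis-side chain with the
  leading bead just inside the pore mouth, equilibrates for ten
  bond-relaxation times per bead with that bead pinned and the drive off,
  then releases; timing starts at release and the event completes when
  every bead has passed the pore midpoint.  Once released, the leading
  bead cannot retract behind the cis mouth (half-harmonic tether): the
  threading coordinate has a reflecting boundary at `m = 0`, matching the
  PDE engine's cis-side condition.  Without this, a weakly driven chain
  that backs out of a pore-localized field simply diffuses away and never
  returns — an artefact of starting at the mouth, not translocation
  physics.
* **Excluded volume** is off by default (ideal chain); a purely repulsive
  harmonic contact force is available for self-avoiding runs.
* Event loops are JIT-compiled (numba) with chunked noise generation; a
  pure-numpy `langevin_step` is the reference implementation and the two
  are held together by the shared force kernel and the integrator tests.
  All stochastic runs are seeded and bit-reproducible per code path.

## 5. Scaling exponents

* **Partition exponent gamma.** Realized exactly: the number of `m`-step
  ±1 walks from the origin that never go below it (the minimal wall-
  tethered ideal chain) is enumerated by dynamic programming in exact
  integer arithmetic (it equals the central binomial `C(m, m/2)`, which the
  tests verify independently, alongside brute-force path enumeration at
  small `m`).  Fitting `log(Z_m / 2^m)` against `log m` for
  `m = 64..4096` gives `gamma = 1 + slope ≈ 0.50`.
* **Flory exponent nu.** Pivot-algorithm Markov chain on simple-lattice
  self-avoiding walks (random non-identity hyperoctahedral symmetry applied
  at a random pivot site; overlap test by integer site hashing), burn-in
  `3N` attempts from a straight rod, sampling every 5 attempts.  The fit
  window starts at `N = 32` to suppress corrections to scaling; at
  `N = 32..512` with 1e4 samples per length the 3-D estimate lands near
  0.59–0.60 (the residual upward bias is a finite-size correction, ~0.01
  above the asymptotic 0.588) and the 2-D estimate reproduces the exact
  3/4.
* **Translocation-time exponent.** Chains pulled by a constant force on
  the leading bead.  In the strong-force regime (`F N^nu / kT >> 1`,
  checked at the smallest N; default `F = 50 kT/a`) the mean escape time
  approaches the total-drag law `tau ≈ gamma N^2 a / F`, i.e.
  `tau_N ~ N^2 / F`.  The force default is chosen deep in the regime so
  the asymptotic exponent is visible at desk-scale `N`: the measured ratio
  `tau / (gamma N^2/F)` still decays from ≈1.24 (N=16) to ≈1.11 (N=128),
  a finite-size correction that biases the fitted exponent slightly below
  2 (≈1.9 over N = 16–128).  At weaker forces the correction is larger and
  the apparent exponent lower; the `F` and `2F` runs at fixed `N` verify
  the `1/F` dependence directly.
* The unforced (`F = 0`) escape-time law `tau ~ N^{2+nu}` is provided as a
  mode of `measure_tau_scaling` but is a long-running experiment: undriven
  escapes are slow and small-`N` exponents are strongly biased by
  finite-size effects, so no routine run asserts it.
* `fit_power_law` is ordinary least squares on log–log axes with a seeded
  bootstrap (200 resamples) standard error.

## 6. What the desk-scale runs show — and what they do not

The synthetic conditions are the model's own: ideal (or purely repulsive)
chains, a structureless soft wall, a single constant field or force, no
hydrodynamic interactions, no ionic-current physics, no monomer-specific
pore chemistry.  Passing tests therefore demonstrate internal consistency
of the three modelling layers and reproduction of the known exponents and
limits — not agreement with any particular experimental pore/polymer
system.  Escape-time histograms reproduce the qualitative shapes (near-
symmetric under strong drive at larger `N`; long positive exponential tail
under weak drive) but their absolute scales are reduced-unit quantities.

Problem sizes of the standard runs were chosen to keep each check at
seconds-to-minutes scale: 1000-point parameter sweeps for the closed-form
flux; `n_grid = 1024` stationary solves; 400-event cross-engine escape
comparisons; a 3×3 (E, N) grid with 25 replicates per cell for the trend
tests; `N ≤ 512` / 1e4 samples for the pivot runs; `N ≤ 128` / ≥200 events
for the strong-force scaling.

## 7. Known limitations

* The Langevin/Smoluchowski cross-check is a single-bead comparison; a
  full-chain mapping of the bead dynamics onto the 1-D `F(m)` model would
  require a measured `C(m)` and is out of scope.
* The in-pore driving mode applies the field per bead inside the slab;
  the discrete handoff between consecutive beads makes the effective total
  drive fluctuate by O(1 bead).
* The pivot sampler uses full-walk overlap checks (O(N) per attempt), fine
  at `N ≤ 512` but not tuned for much longer chains.
* The wall is soft: beads can penetrate by `~sqrt(2 kT / k_wall) ≈ 0.1 a`.
  Matched-potential comparisons must include the same wall in the PDE
  potential (the cross-engine test does).
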