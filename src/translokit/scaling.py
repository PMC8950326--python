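"""Chain-statistics exponents: partition gamma, Flory nu, and tau(N) scaling.

Three exponents characterize the model chains:

* the partition exponent ``gamma`` of a wall-tethered chain,
  ``Z_m ~ m^(gamma-1)`` (1/2 for ideal chains, ~0.69 self-avoiding, 1
  rod-like), realized here exactly as the census of m-step +-1 walks that
  never go below the origin — the minimal half-space ideal-chain model,
  whose count is the central binomial C(m, floor(m/2)) ~ 2^m m^(-1/2);
* the Flory exponent ``nu`` of self-avoiding chains, ``<R^2> ~ N^(2 nu)``
  (3/4 exactly in 2-D, ~0.588 in 3-D), estimated by pivot-algorithm
  sampling of lattice self-avoiding walks;
* the translocation-time exponent ``alpha`` in ``tau_N ~ N^alpha`` for a
  chain pulled through the pore by a constant end force: in the strong
  force regime (F N^nu / kT >> 1) the passage time crosses over to
  ``tau_N ~ N^2 / F``.

All stochastic estimators take explicit seeds and are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .langevin import (BeadSpringPolymer, DrivingField, LangevinParams,
                       MembranePore, _event_seed, run_translocation)

__all__ = [
    "PowerLawFit",
    "count_halfspace_walks",
    "halfspace_walk_counts",
    "estimate_gamma",
    "estimate_flory_nu",
    "fit_power_law",
    "measure_tau_scaling",
]

MAX_WALK_LENGTH = 4096
FLORY_NU_3D = 0.588


@dataclass(frozen=True)
class PowerLawFit:
    """Result of a log-log power-law fit y ~ x^exponent."""

    exponent: float
    intercept: float
    stderr: float
    x_range: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a power-law fit needs at least 3 points")
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")


def halfspace_walk_counts(m_values) -> dict[int, int]:
    """Exact counts of nonnegative +-1 walks for every requested length.

    Dynamic programming over the height profile in a single sweep to the
    largest requested m; arbitrary-precision integers throughout.
    """
    m_values = sorted({int(m) for m in np.atleast_1d(m_values)})
    if not m_values or m_values[0] < 1 or m_values[-1] > MAX_WALK_LENGTH:
        raise ValueError(f"walk lengths must lie in [1, {MAX_WALK_LENGTH}]")
    wanted = set(m_values)
    m_max = m_values[-1]
    # counts[h] = number of walks of the current length ending at height h
    counts = [1] + [0] * (m_max + 1)
    out: dict[int, int] = {}
    for step in range(1, m_max + 1):
        new = [0] * (m_max + 2)
        for h in range(step + 1):
            c = counts[h]
            if c:
                new[h + 1] += c
                if h > 0:
                    new[h - 1] += c
        counts = new
        if step in wanted:
            out[step] = sum(counts)
    return out


def count_halfspace_walks(m: int) -> int:
    """Number of m-step +-1 walks from the origin never going below it.

    Equals the central binomial coefficient C(m, floor(m/2)).
    """
    return halfspace_walk_counts([m])[int(m)]


def _ols_loglog(logx: np.ndarray, logy: np.ndarray) -> tuple[float, float, float]:
    A = np.column_stack([logx, np.ones_like(logx)])
    coef, res, *_ = np.linalg.lstsq(A, logy, rcond=None)
    n = logx.size
    if n > 2:
        rss = float(res[0]) if res.size else float(np.sum((A @ coef - logy) ** 2))
        sigma2 = rss / (n - 2)
        sxx = float(np.sum((logx - logx.mean()) ** 2))
        se = math.sqrt(sigma2 / sxx) if sxx > 0 else 0.0
    else:
        se = 0.0
    return float(coef[0]), float(coef[1]), se


def fit_power_law(x, y, n_boot: int = 200, seed: int = 0) -> PowerLawFit:
    """OLS power-law fit on (log x, log y) with a bootstrap standard error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit needs strictly positive data")
    lx, ly = np.log(x), np.log(y)
    slope, intercept, _ = _ols_loglog(lx, ly)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, x.size, x.size)
        if np.unique(lx[idx]).size < 2:
            continue
        s, _, _ = _ols_loglog(lx[idx], ly[idx])
        boots.append(s)
    stderr = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0
    return PowerLawFit(exponent=slope, intercept=intercept, stderr=stderr,
                       x_range=(float(x.min()), float(x.max())), n_points=x.size)


def estimate_gamma(m_values, counts=None, growth_base: float = 2.0,
                   n_boot: int = 200, seed: int = 0) -> PowerLawFit:
    """Partition exponent gamma from Z_m ~ m^(gamma-1).

    Removes the connective growth factor ``growth_base**m`` from the walk
    counts (exact enumeration when ``counts`` is None) and fits
    ``log(Z_m / base^m)`` against ``log m``; the returned fit's ``exponent``
    field holds gamma = 1 + slope.  Requires the m values to span at least
    1.5 decades.
    """
    m_arr = np.asarray(sorted({int(m) for m in np.atleast_1d(m_values)}), dtype=float)
    if m_arr.size < 3:
        raise ValueError("gamma fit needs at least 3 chain lengths")
    if math.log10(m_arr[-1] / m_arr[0]) < 1.5:
        raise ValueError("m values must span at least 1.5 decades")
    if counts is None:
        table = halfspace_walk_counts(m_arr.astype(int))
        logZ = np.array([math.log(table[int(m)]) for m in m_arr])
    else:
        counts = np.atleast_1d(counts)
        if counts.shape[0] != m_arr.size:
            raise ValueError("counts must align with m_values")
        logZ = np.array([math.log(c) for c in counts])
    resid = logZ - m_arr * math.log(growth_base)
    # shift to positive territory for the shared log-log fitter
    y = np.exp(resid - resid.max())
    fit = fit_power_law(m_arr, y, n_boot=n_boot, seed=seed)
    return PowerLawFit(exponent=1.0 + fit.exponent, intercept=fit.intercept,
                       stderr=fit.stderr, x_range=fit.x_range,
                       n_points=fit.n_points)


# ---------------------------------------------------------------------------
# pivot sampling of lattice self-avoiding walks


def _lattice_symmetries(dim: int) -> np.ndarray:
    """All signed axis permutations (hyperoctahedral group) except identity."""
    from itertools import permutations, product
    mats = []
    eye = np.eye(dim, dtype=np.int64)
    for perm in permutations(range(dim)):
        for signs in product((1, -1), repeat=dim):
            S = np.zeros((dim, dim), dtype=np.int64)
            for i, (p, s) in enumerate(zip(perm, signs)):
                S[i, p] = s
            if not np.array_equal(S, eye):
                mats.append(S)
    return np.array(mats)


def _is_self_avoiding(walk: np.ndarray, span: int) -> bool:
    keys = walk @ np.array([(2 * span + 1) ** d for d in range(walk.shape[1])],
                           dtype=np.int64)
    return np.unique(keys).size == walk.shape[0]


def sample_saw_r2(N: int, n_samples: int, dim: int = 3, seed: int = 0,
                  stride: int = 5, burn_in_factor: int = 3,
                  max_reject_streak: int = 10000) -> np.ndarray:
    """Squared end-to-end distances of pivot-sampled self-avoiding walks.

    Markov chain on N-step simple-lattice SAWs: pick a pivot site and a
    random non-identity lattice symmetry, rotate/reflect the tail, accept
    if the result is self-avoiding.  Samples R^2 every ``stride`` attempts
    after ``burn_in_factor * N`` burn-in attempts.
    """
    if N < 2:
        raise ValueError("need N >= 2 steps")
    rng = np.random.default_rng(seed)
    syms = _lattice_symmetries(dim)
    walk = np.zeros((N + 1, dim), dtype=np.int64)
    walk[:, 0] = np.arange(N + 1)  # straight rod start
    span = N + 1
    reject_streak = 0
    samples = np.empty(n_samples)
    n_attempts = burn_in_factor * N + stride * n_samples
    k = 0
    for attempt in range(n_attempts):
        i = int(rng.integers(1, N))          # pivot site, interior
        S = syms[int(rng.integers(0, len(syms)))]
        pivot = walk[i]
        tail = (walk[i + 1:] - pivot) @ S.T + pivot
        cand = np.concatenate([walk[: i + 1], tail])
        if _is_self_avoiding(cand, span):
            walk = cand
            reject_streak = 0
        else:
            reject_streak += 1
            if reject_streak > max_reject_streak:
                raise RuntimeError(
                    f"pivot acceptance collapsed (> {max_reject_streak} "
                    f"consecutive rejections at N={N})"
                )
        if attempt >= burn_in_factor * N and (attempt - burn_in_factor * N) % stride == stride - 1:
            d = walk[-1] - walk[0]
            samples[k] = float(d @ d)
            k += 1
            if k == n_samples:
                break
    return samples[:k]


def estimate_flory_nu(dimension: int, N_values, samples_per_N: int,
                      seed: int = 0, stride: int = 5) -> PowerLawFit:
    """Flory exponent nu from <R^2> ~ N^(2 nu) of pivot-sampled SAWs.

    Fits the log-log slope of the mean squared end-to-end distance against
    chain length; the returned ``exponent`` field holds nu = slope / 2.
    ``N_values`` must span at least a factor 8.
    """
    if dimension not in (1, 2, 3):
        raise ValueError("dimension must be 1, 2 or 3")
    N_arr = np.asarray(sorted({int(n) for n in np.atleast_1d(N_values)}), dtype=int)
    if N_arr.size < 3:
        raise ValueError("nu fit needs at least 3 chain lengths")
    if N_arr[-1] < 8 * N_arr[0]:
        raise ValueError("N values must span at least a factor 8")
    if dimension == 1:
        # fully extended chain: R = N exactly, nu = 1
        mean_r2 = N_arr.astype(float) ** 2
    else:
        mean_r2 = np.empty(N_arr.size)
        for j, N in enumerate(N_arr):
            r2 = sample_saw_r2(int(N), samples_per_N, dim=dimension,
                               seed=_event_seed(seed, 1000 + j), stride=stride)
            mean_r2[j] = float(np.mean(r2))
    fit = fit_power_law(N_arr.astype(float), mean_r2, seed=seed)
    return PowerLawFit(exponent=0.5 * fit.exponent, intercept=fit.intercept,
                       stderr=0.5 * fit.stderr, x_range=fit.x_range,
                       n_points=fit.n_points)


def measure_tau_scaling(mode: str, N_values, force: float, replicates: int,
                        seed: int = 0, params: LangevinParams | None = None,
                        pore: MembranePore | None = None,
                        max_time: float | None = None,
                        min_success: int = 50) -> PowerLawFit:
    """Translocation-time exponent alpha of mean tau ~ N^alpha.

    ``mode="end_pulled_strong_force"`` pulls the leading bead with the
    constant reduced force ``force``; the strong-force condition
    F N^nu / kT >> 1 is checked for every N (using the 3-D Flory value).
    ``mode="unforced"`` runs undriven escapes — slow, provided for long
    experiments, not exercised by default workflows.  Any (N, force) cell
    with fewer than ``min_success`` completed events is refused.
    """
    if mode not in ("end_pulled_strong_force", "unforced"):
        raise ValueError(f"unknown mode {mode!r}")
    N_arr = np.asarray(sorted({int(n) for n in np.atleast_1d(N_values)}), dtype=int)
    if N_arr.size < 3:
        raise ValueError("tau scaling needs at least 3 chain lengths")
    params = params or LangevinParams()
    pore = pore or MembranePore()
    if mode == "end_pulled_strong_force":
        if force <= 0:
            raise ValueError("strong-force mode needs a positive force")
        weakest = force * float(N_arr[0]) ** FLORY_NU_3D / params.kT
        if weakest < 5.0:
            raise ValueError(
                f"F N^nu / kT = {weakest:.2f} at the smallest N: not in the "
                "strong-force regime (need >> 1)"
            )
        drive = DrivingField(mode="end_force", end_force_f=force)
    else:
        drive = DrivingField(mode="end_force", end_force_f=0.0)
    mean_tau = np.empty(N_arr.size)
    for j, N in enumerate(N_arr):
        if max_time is None:
            # generous ceiling: several times the dragged-chain estimate
            drag = params.gamma_damp * params.mass * N * N / max(force, 1e-6)
            cell_max_time = 20.0 * max(drag, 10.0)
        else:
            cell_max_time = max_time
        chain = BeadSpringPolymer.straight_chain(N, dim=pore.dimension)
        taus = []
        for r in range(replicates):
            ev = run_translocation(chain, pore, drive, params, cell_max_time,
                                   seed=_event_seed(seed, j * 100003 + r))
            if ev.success:
                taus.append(ev.tau)
        if len(taus) < min_success:
            raise RuntimeError(
                f"only {len(taus)}/{replicates} events completed at N={N}; "
                f"need {min_success} (raise max_time or the force)"
            )
        mean_tau[j] = float(np.mean(taus))
    return fit_power_law(N_arr.astype(float), mean_tau, seed=seed)
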