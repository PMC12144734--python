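"""Monte-Carlo power and sample-size determination.

``calculate_power`` simulates the design many times, tests each replicate
with the switching-adjusted margin

    delta_star = R1*(tau) - R1(tau) + delta

(where R1*(tau), the RMST of the mixed switching arm, is the average of KM
RMST estimates over dedicated simulations, and R1(tau) is analytic), and
reports the rejection fraction plus expected event counts per arm.

``calculate_size`` evaluates the power on a grid of control-arm sizes
n_L + j*w (w = round((n_U - n_L)/B)), fits a monotone nondecreasing curve
through the Monte-Carlo powers, and reads off the smallest integer n whose
fitted power reaches the requested level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .design import DesignConfig, SolvedDesign, round_half_up, solve_design
from .rmst import ni_test, rmst_from_arrays
from .simulate import simulate_arm, simulate_trial

__all__ = [
    "PowerResult",
    "SizeResult",
    "estimate_adjusted_margin",
    "calculate_power",
    "fit_monotone_curve",
    "calculate_size",
]


@dataclass(frozen=True)
class PowerResult:
    power: float
    e1: float
    e2: float
    delta: float
    delta_star: float
    r_pure: float
    r_mixed: float | None
    n: int
    r: float
    n_simulations: int
    seed: int
    power_se: float = 0.0

    def as_dict(self) -> dict:
        return {
            "power": self.power, "power_se": self.power_se,
            "E1": self.e1, "E2": self.e2,
            "delta": self.delta, "delta_star": self.delta_star,
            "R_pure": self.r_pure, "R_mixed": self.r_mixed,
            "n": self.n, "r": self.r,
            "n_simulations": self.n_simulations, "seed": self.seed,
        }


@dataclass(frozen=True)
class SizeResult:
    required_n: int
    grid_n: np.ndarray
    raw_powers: np.ndarray
    fitted_grid: np.ndarray      # fitted powers at grid_n
    curve_n: np.ndarray          # integer grid [min(grid_n), max(grid_n)]
    curve_power: np.ndarray
    epwr: float
    n_lower: int
    n_upper: int
    n_intervals: int
    delta: float
    delta_stars: np.ndarray
    power_results: tuple[PowerResult, ...] = field(repr=False, default=())

    def as_dict(self) -> dict:
        return {
            "required_n": self.required_n,
            "epwr": self.epwr,
            "nL": self.n_lower, "nU": self.n_upper, "B": self.n_intervals,
            "grid_n": self.grid_n.tolist(),
            "raw_powers": self.raw_powers.tolist(),
            "fitted_powers": self.fitted_grid.tolist(),
            "delta": self.delta,
            "delta_stars": self.delta_stars.tolist(),
        }


def _switching_arm(config: DesignConfig, solved: SolvedDesign):
    """Law, size and analytic pure RMST of the arm subject to switching."""
    if config.tx_switch == "1to2":
        return solved.control, config.n, solved.r1_pure
    return solved.experimental, config.n_experimental, solved.r2_pure


def estimate_adjusted_margin(
    config: DesignConfig,
    solved: SolvedDesign,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[float, float | None]:
    """delta_star and the simulated mixed-arm RMST average.

    Short-circuits to delta exactly when ps = 0 or the acceleration factor is
    1 (switching then leaves event times unchanged).  For the reverse
    direction the sign flips: delta_star = delta + R2(tau) - R2*(tau), which
    preserves the equivalence with the no-switching test.
    """
    if config.ps == 0 or solved.accel == 1.0:
        return solved.delta, None
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed).spawn(2)[0]
    law, size, r_pure = _switching_arm(config, solved)
    tau = config.tau_resolved
    estimates = np.empty(config.n_simulations)
    for i, child in enumerate(seed_seq.spawn(config.n_simulations)):
        rng = np.random.default_rng(child)
        arm = simulate_arm(
            law, size, solved.entry, solved.dropout, rng,
            switch=solved.switch, accel=solved.accel,
        )
        estimates[i] = rmst_from_arrays(arm.observed, arm.event, tau).estimate
    r_mixed = float(estimates.mean())
    if config.tx_switch == "1to2":
        delta_star = r_mixed - r_pure + solved.delta
    else:
        delta_star = solved.delta + r_pure - r_mixed
    if delta_star <= 0:
        raise ValueError(
            f"adjusted margin is not positive (delta_star={delta_star:.6g}): the "
            "switching-induced RMST shift exceeds the margin; the design is infeasible"
        )
    return delta_star, r_mixed


def _power_given_margin(
    config: DesignConfig,
    solved: SolvedDesign,
    margin: float,
    seed_seq: np.random.SeedSequence,
) -> tuple[float, float, float]:
    """Rejection fraction and mean per-arm event counts over the simulations."""
    tau = config.tau_resolved
    rejects = 0
    e1 = 0.0
    e2 = 0.0
    nsim = config.n_simulations
    for child in seed_seq.spawn(nsim):
        rng = np.random.default_rng(child)
        trial = simulate_trial(config, solved, rng)
        est_c = rmst_from_arrays(trial.control.observed, trial.control.event, tau)
        est_e = rmst_from_arrays(
            trial.experimental.observed, trial.experimental.event, tau
        )
        res = ni_test(est_c, est_e, margin, config.one_sided_alpha)
        rejects += res.reject
        e1 += trial.control.n_events
        e2 += trial.experimental.n_events
    return rejects / nsim, e1 / nsim, e2 / nsim


def calculate_power(
    config: DesignConfig,
    solved: SolvedDesign | None = None,
    seed_seq: np.random.SeedSequence | None = None,
    adjust_margin: bool = True,
) -> PowerResult:
    """Monte-Carlo power of the design (or its type-I error under a null config).

    ``adjust_margin=False`` tests with the unadjusted margin delta, which is
    how the inflation caused by switching is quantified.
    """
    if solved is None:
        solved = solve_design(config)
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    ss_star, ss_power = seed_seq.spawn(2)
    if adjust_margin:
        delta_star, r_mixed = estimate_adjusted_margin(config, solved, ss_star)
    else:
        delta_star, r_mixed = solved.delta, None
    power, e1, e2 = _power_given_margin(config, solved, delta_star, ss_power)
    _, _, r_pure = _switching_arm(config, solved)
    se = float(np.sqrt(power * (1 - power) / config.n_simulations))
    return PowerResult(
        power=power, e1=e1, e2=e2, delta=solved.delta, delta_star=delta_star,
        r_pure=r_pure, r_mixed=r_mixed, n=config.n, r=config.r,
        n_simulations=config.n_simulations, seed=config.seed, power_se=se,
    )


def _ispline_design(x: np.ndarray, x_grid: np.ndarray, degree: int = 2,
                    n_interior: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Monotone (integrated B-spline) basis evaluated at x and x_grid."""
    x0, x1 = x.min(), x.max()
    interior = np.linspace(x0, x1, n_interior + 2)[1:-1]
    t = np.concatenate((np.repeat(x0, degree + 1), interior, np.repeat(x1, degree + 1)))
    n_basis = len(t) - degree - 1
    cols, cols_grid = [], []
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        anti = BSpline(t, c, degree, extrapolate=False).antiderivative()
        cols.append(np.nan_to_num(anti(x) - anti(x0)))
        cols_grid.append(np.nan_to_num(anti(x_grid) - anti(x0)))
    return np.column_stack(cols), np.column_stack(cols_grid)


def fit_monotone_curve(
    ns, powers
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a smooth nondecreasing curve through (n, power) Monte-Carlo points.

    Uses an I-spline (integrated B-spline) basis with nonnegative slopes fit
    by nonnegative least squares; with fewer than 4 points it falls back to
    isotonic regression plus monotone interpolation.  Returns the integer
    grid spanning [min(ns), max(ns)] and fitted powers clipped to [0, 1].
    """
    ns = np.asarray(ns, dtype=float)
    powers = np.asarray(powers, dtype=float)
    if ns.size != powers.size or ns.size < 2:
        raise ValueError("need matching grids of at least 2 points")
    if np.any((powers < 0) | (powers > 1)):
        raise ValueError("powers must lie in [0, 1]")
    order = np.argsort(ns)
    ns, powers = ns[order], powers[order]
    grid = np.arange(int(np.ceil(ns[0])), int(np.floor(ns[-1])) + 1, dtype=float)

    if ns.size < 4:
        warnings.warn("fewer than 4 grid points: falling back to isotonic fit",
                      stacklevel=2)
        iso = _pava(powers)
        fitted = np.interp(grid, ns, iso)
        return grid.astype(int), np.clip(fitted, 0.0, 1.0)

    n_interior = min(max(int(ns.size) - 3, 1), 6)
    d_fit, d_grid = _ispline_design(ns, grid, n_interior=n_interior)
    # free intercept (split into +/- parts) + nonnegative spline increments
    ones = np.ones((ns.size, 1))
    a = np.hstack((ones, -ones, d_fit))
    coef, _ = nnls(a, powers)
    fitted = coef[0] - coef[1] + d_grid @ coef[2:]
    # guard against flat numerical wiggle from the basis evaluation
    fitted = np.maximum.accumulate(fitted)
    return grid.astype(int), np.clip(fitted, 0.0, 1.0)


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators isotonic regression (nondecreasing, unit weights)."""
    vals: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for v in np.asarray(y, dtype=float):
        vals.append(v); wts.append(1.0); counts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v2, w2, c2 = vals.pop(), wts.pop(), counts.pop()
            v1, w1, c1 = vals.pop(), wts.pop(), counts.pop()
            vals.append((v1 * w1 + v2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            counts.append(c1 + c2)
    out = np.concatenate([np.full(c, v) for v, c in zip(vals, counts)])
    return out


def calculate_size(
    config: DesignConfig,
    n_lower: int,
    n_upper: int,
    n_intervals: int = 10,
    epwr: float = 0.80,
) -> SizeResult:
    """Smallest control-arm n whose fitted monotone power reaches ``epwr``.

    ``config.n`` is ignored; the grid is n_L + j*w, j = 0..B with
    w = round((n_U - n_L)/B).  The adjusted margin is re-estimated at every
    grid point.
    """
    if n_lower >= n_upper:
        raise ValueError("need n_L < n_U")
    if n_intervals < 2:
        raise ValueError("B must be >= 2")
    if not 0 < epwr < 1:
        raise ValueError("epwr must lie in (0, 1)")
    w = round_half_up((n_upper - n_lower) / n_intervals)
    if w == 0:
        grid_n = np.arange(n_lower, n_upper + 1)
    else:
        grid_n = np.unique(
            np.minimum(n_lower + w * np.arange(n_intervals + 1), n_upper)
        )
    base = config.with_n(int(grid_n[0]))
    solved0 = solve_design(base)
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(grid_n))
    results = []
    for nj, child in zip(grid_n, children):
        cfg = config.with_n(int(nj))
        solved = _resolve_for_n(cfg, solved0)
        results.append(calculate_power(cfg, solved=solved, seed_seq=child))
    raw = np.array([r.power for r in results])
    curve_n, curve_p = fit_monotone_curve(grid_n, raw)
    fitted_grid = curve_p[np.searchsorted(curve_n, grid_n)]
    if curve_p[-1] < epwr:
        raise ValueError(
            f"fitted power at n_U={n_upper} is {curve_p[-1]:.3f} < epwr={epwr}; "
            "increase n_U"
        )
    if curve_p[0] >= epwr:
        warnings.warn(
            f"fitted power at n_L={n_lower} already reaches epwr={epwr}; "
            "consider a smaller n_L", stacklevel=2,
        )
        required = int(curve_n[0])
    else:
        required = int(curve_n[np.argmax(curve_p >= epwr)])
    return SizeResult(
        required_n=required,
        grid_n=grid_n.astype(int),
        raw_powers=raw,
        fitted_grid=fitted_grid,
        curve_n=curve_n,
        curve_power=curve_p,
        epwr=epwr,
        n_lower=n_lower,
        n_upper=n_upper,
        n_intervals=n_intervals,
        delta=solved0.delta,
        delta_stars=np.array([r.delta_star for r in results]),
        power_results=tuple(results),
    )


def _resolve_for_n(config: DesignConfig, solved_base: SolvedDesign) -> SolvedDesign:
    """The design calibrations are n-independent; reuse them across grid points."""
    return solved_base
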