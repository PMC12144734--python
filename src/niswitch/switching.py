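"""Treatment-switching times and the counterfactual time transformation.

The switch time S of a control-arm participant is modelled either as
S = X * T1 with a mixing variable X independent of the latent event time T1
(``unif``, ``beta``, ``gamma`` options), as an independent exponential time
(``indepExp``), or as a fixed calendar time.  The beta/gamma parameters are
moment-matched to the design summaries

    r_s   = E(S) / E(T1)          (mean switch time relative to mean event time)
    rho_s = corr(S, T1)

and a switch that actually happens (eligibility S < T1 plus an independent
coin with probability p_s) stretches the residual time by the acceleration
factor, the rank-preserving structural failure time rule

    T1* = s + (T1 - s) * accel,   accel = af * m2/m1 (or af * m1/m2 for the
                                  reverse switching direction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .distributions import GenGammaSpec, gg_moment

__all__ = ["SwitchSpec", "SolvedSwitch", "solve_switch_params",
           "sample_switch_times", "apply_switch"]

SwitchDist = Literal["unif", "beta", "gamma", "indepExp", "fixed"]
Direction = Literal["1to2", "2to1"]


@dataclass(frozen=True)
class SwitchSpec:
    """Design-level description of treatment switching."""

    dist: SwitchDist = "gamma"
    ps: float = 0.2
    rs: float = 0.5
    rho_s: float = 0.775
    fixed_time: float | None = None
    direction: Direction = "1to2"
    af: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ps <= 1.0:
            raise ValueError(f"ps must lie in [0, 1], got {self.ps!r}")
        if self.dist not in ("unif", "beta", "gamma", "indepExp", "fixed"):
            raise ValueError(f"unknown switching distribution {self.dist!r}")
        if self.dist == "fixed":
            if self.fixed_time is None or self.fixed_time < 0:
                raise ValueError("fixed switching requires a nonnegative fixed_time")
        elif self.rs <= 0:
            raise ValueError("rs must be positive")
        if self.dist in ("beta", "gamma") and not 0.0 < self.rho_s < 1.0:
            raise ValueError(f"rho_s must lie in (0, 1), got {self.rho_s!r}")
        if self.direction not in ("1to2", "2to1"):
            raise ValueError(f"unknown switching direction {self.direction!r}")
        if self.af <= 0:
            raise ValueError("af must be positive")


@dataclass(frozen=True)
class SolvedSwitch:
    """SwitchSpec with its distribution parameters resolved against the control law.

    beta: X ~ Beta(shape1, shape2); gamma: X ~ Gamma(shape, rate);
    indepExp: S ~ Exponential(rate); unif/fixed carry no parameters.
    """

    spec: SwitchSpec
    shape1: float | None = None
    shape2: float | None = None
    rate: float | None = None


def _mixing_variance(rs: float, rho: float, var_t: float, e_t2: float) -> float:
    """Var(X) implied by corr(X*T, T) = rho with E(X) = rs and X independent of T.

    cov(S, T) = E(X) Var(T) and Var(S) = E(X)^2 Var(T) + Var(X) E(T^2), so
    rho^2 = rs^2 Var(T) / (rs^2 Var(T) + Var(X) E(T^2)).
    """
    return rs**2 * var_t * (1.0 - rho**2) / (rho**2 * e_t2)


def solve_switch_params(spec: SwitchSpec, control: GenGammaSpec) -> SolvedSwitch:
    """Moment-match the switch-time law to (rs, rho_s) for the given control law."""
    if spec.dist == "fixed":
        return SolvedSwitch(spec)
    e_t = gg_moment(control, 1)
    e_t2 = gg_moment(control, 2)
    var_t = e_t2 - e_t**2

    if spec.dist == "unif":
        if abs(spec.rs - 0.5) > 1e-12:
            raise ValueError(
                "dist='unif' forces rs = E(X) = 0.5 with X ~ U(0,1); "
                f"rs={spec.rs!r} is not satisfiable"
            )
        return SolvedSwitch(spec)

    if spec.dist == "indepExp":
        rate = 1.0 / (spec.rs * e_t)
        return SolvedSwitch(spec, rate=rate)

    var_x = _mixing_variance(spec.rs, spec.rho_s, var_t, e_t2)
    if spec.dist == "gamma":
        # E(X) = a/b, Var(X) = a/b^2
        rate = spec.rs / var_x
        solved = SolvedSwitch(spec, shape1=spec.rs * rate, rate=rate)
    else:  # beta: E(X) = a/(a+b), Var(X) = ab / ((a+b)^2 (a+b+1))
        mean_var_cap = spec.rs * (1.0 - spec.rs)
        if spec.rs >= 1.0 or var_x >= mean_var_cap:
            rho_min = np.sqrt(
                spec.rs**2 * var_t / (spec.rs**2 * var_t + mean_var_cap * e_t2)
            )
            raise ValueError(
                f"(rs={spec.rs}, rho_s={spec.rho_s}) is infeasible for a beta "
                f"mixing law; attainable rho_s range is ({rho_min:.4f}, 1) "
                "for this control law"
            )
        total = mean_var_cap / var_x - 1.0
        solved = SolvedSwitch(spec, shape1=spec.rs * total, shape2=(1.0 - spec.rs) * total)
    _verify_moments(solved, spec, var_t, e_t2)
    return solved


def _verify_moments(solved: SolvedSwitch, spec: SwitchSpec, var_t: float, e_t2: float) -> None:
    """Check the solved parameters reproduce (rs, rho_s) to 1e-8."""
    if spec.dist == "gamma":
        mean_x = solved.shape1 / solved.rate
        var_x = solved.shape1 / solved.rate**2
    else:
        a, b = solved.shape1, solved.shape2
        mean_x = a / (a + b)
        var_x = a * b / ((a + b) ** 2 * (a + b + 1.0))
    rho = mean_x * np.sqrt(var_t) / np.sqrt(mean_x**2 * var_t + var_x * e_t2)
    if abs(mean_x - spec.rs) > 1e-8 or abs(rho - spec.rho_s) > 1e-8:
        raise RuntimeError(
            f"switch-parameter solution failed verification: E(X)={mean_x:.10f} "
            f"vs rs={spec.rs}, rho={rho:.10f} vs rho_s={spec.rho_s}"
        )


def sample_switch_times(
    solved: SolvedSwitch, t1_latent: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw switch times for one arm and decide who actually switches.

    Returns (eligible, switch_times, switched): eligibility requires the switch
    to precede the latent event (S < T1); among eligible participants an
    independent coin with probability ps decides the actual switch.
    """
    t1 = np.asarray(t1_latent, dtype=float)
    if np.any(t1 <= 0):
        raise ValueError("latent event times must be positive")
    spec = solved.spec
    n = t1.size
    if spec.dist == "unif":
        s = rng.random(n) * t1
    elif spec.dist == "beta":
        s = rng.beta(solved.shape1, solved.shape2, size=n) * t1
    elif spec.dist == "gamma":
        s = rng.gamma(solved.shape1, 1.0 / solved.rate, size=n) * t1
    elif spec.dist == "indepExp":
        s = rng.exponential(1.0 / solved.rate, size=n)
    else:  # fixed
        s = np.full(n, spec.fixed_time, dtype=float)
    eligible = s < t1
    switched = eligible & (rng.random(n) < spec.ps)
    return eligible, s, switched


def apply_switch(t1, s, accel: float):
    """Counterfactual event time s + (T1 - s) * accel; the identity when accel = 1."""
    t1 = np.asarray(t1, dtype=float)
    s = np.asarray(s, dtype=float)
    if accel <= 0:
        raise ValueError("acceleration multiplier must be positive")
    if np.any(s >= t1):
        raise ValueError("switch time must precede the latent event time")
    out = s + (t1 - s) * accel
    return float(out) if out.ndim == 0 else out
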