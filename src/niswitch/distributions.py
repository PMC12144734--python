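"""Parametric building blocks of the trial design.

Event times follow a three-parameter generalized gamma law (Stacy
parameterization) with density

    f(t | a, b, k) = b / Gamma(k) * t^(b k - 1) / a^(b k) * exp(-(t/a)^b),

which contains the gamma (b = 1), Weibull (k = 1) and exponential
(b = k = 1) families as special cases.  Accrual entry times follow a
linear-density law on [0, T_a] (decreasing, uniform or increasing), and
censoring is the minimum of a dropout time (uniform or exponential, or
absent) and the administrative horizon T_e - entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import integrate, optimize, special

__all__ = [
    "GenGammaSpec",
    "EntrySpec",
    "DropoutSpec",
    "scale_from_median",
    "gg_survival",
    "gg_moment",
    "true_rmst",
    "sample_entry",
    "admin_censor_prob",
    "total_censor_prob",
    "solve_dropout_param",
    "sample_censoring",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=200)


@dataclass(frozen=True)
class GenGammaSpec:
    """Generalized gamma event-time law with scale ``a`` and shapes ``b, k``."""

    scale: float
    shape_b: float = 1.0
    shape_k: float = 1.0

    def __post_init__(self) -> None:
        for name in ("scale", "shape_b", "shape_k"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be a positive finite number, got {v!r}")

    def survival(self, t):
        """P(T > t) = Q(k, (t/a)^b), the regularized upper incomplete gamma."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival requires t >= 0")
        out = special.gammaincc(self.shape_k, (t / self.scale) ** self.shape_b)
        return float(out) if out.ndim == 0 else out

    def density(self, t):
        t = np.asarray(t, dtype=float)
        a, b, k = self.scale, self.shape_b, self.shape_k
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                t > 0,
                b / special.gamma(k) * t ** (b * k - 1) / a ** (b * k)
                * np.exp(-((t / a) ** b)),
                0.0,
            )
        return float(out) if out.ndim == 0 else out

    def moment(self, order: int) -> float:
        return gg_moment(self, order)

    @property
    def median(self) -> float:
        return self.scale * special.gammaincinv(self.shape_k, 0.5) ** (1.0 / self.shape_b)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw event times as a * G^(1/b) with G ~ Gamma(k, 1)."""
        g = rng.gamma(self.shape_k, size=size)
        return self.scale * g ** (1.0 / self.shape_b)


def scale_from_median(median: float, shape_b: float = 1.0, shape_k: float = 1.0) -> GenGammaSpec:
    """Calibrate the scale so that survival(median) = 1/2.

    Inverts S(m) = Q(k, (m/a)^b) = 1/2 through the inverse regularized
    incomplete gamma function; the shape parameters pass through unchanged.
    """
    if median <= 0:
        raise ValueError(f"median must be positive, got {median!r}")
    if shape_b <= 0 or shape_k <= 0:
        raise ValueError("shape parameters must be positive")
    scale = median / special.gammaincinv(shape_k, 0.5) ** (1.0 / shape_b)
    return GenGammaSpec(scale=scale, shape_b=shape_b, shape_k=shape_k)


def gg_survival(t, spec: GenGammaSpec):
    return spec.survival(t)


def gg_moment(spec: GenGammaSpec, order: int) -> float:
    """E(T^order) = a^order * Gamma(k + order/b) / Gamma(k)."""
    if order <= 0:
        raise ValueError("order must be a positive integer")
    a, b, k = spec.scale, spec.shape_b, spec.shape_k
    return a**order * special.gamma(k + order / b) / special.gamma(k)


def true_rmst(survival: Callable[[float], float] | GenGammaSpec, tau: float) -> float:
    """Restricted mean survival time: the integral of S over [0, tau]."""
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau!r}")
    fn = survival.survival if isinstance(survival, GenGammaSpec) else survival
    value, _ = integrate.quad(fn, 0.0, tau, **_QUAD_KW)
    return value


# --------------------------------------------------------------------------
# Accrual entry
# --------------------------------------------------------------------------

EntryPattern = Literal["decreasing", "unif", "increasing"]


@dataclass(frozen=True)
class EntrySpec:
    """Accrual law with linear density a* + b* v on [0, T_a].

    decreasing: a* = 2/T_a, b* = -2/T_a^2 (triangular, mode at 0)
    unif:       a* = 1/T_a, b* = 0
    increasing: a* = 0,     b* = 2/T_a^2 (triangular, mode at T_a)

    ``accrual_duration = 0`` degenerates to all entries at time 0.
    """

    pattern: EntryPattern = "unif"
    accrual_duration: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in ("decreasing", "unif", "increasing"):
            raise ValueError(f"unknown entry pattern {self.pattern!r}")
        if self.accrual_duration < 0:
            raise ValueError("accrual_duration must be >= 0")

    def pdf(self, v):
        v = np.asarray(v, dtype=float)
        ta = self.accrual_duration
        if ta == 0:
            raise ValueError("degenerate entry (T_a = 0) has no density")
        if self.pattern == "decreasing":
            out = 2.0 / ta - 2.0 / ta**2 * v
        elif self.pattern == "unif":
            out = np.full_like(v, 1.0 / ta)
        else:
            out = 2.0 / ta**2 * v
        out = np.where((v >= 0) & (v <= ta), out, 0.0)
        return float(out) if out.ndim == 0 else out

    def cdf(self, v):
        v = np.clip(np.asarray(v, dtype=float), 0.0, self.accrual_duration)
        ta = self.accrual_duration
        if ta == 0:
            return np.ones_like(v)
        if self.pattern == "decreasing":
            out = 2 * v / ta - v**2 / ta**2
        elif self.pattern == "unif":
            out = v / ta
        else:
            out = v**2 / ta**2
        return float(out) if out.ndim == 0 else out

    def sample(self, count: int, rng: np.random.Generator) -> np.ndarray:
        return sample_entry(self, count, rng)


def sample_entry(entry: EntrySpec, count: int, rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draws of entry times; exact zeros when T_a = 0."""
    if count < 1:
        raise ValueError("count must be >= 1")
    ta = entry.accrual_duration
    if ta == 0:
        return np.zeros(count)
    u = rng.random(count)
    if entry.pattern == "decreasing":
        return ta * (1.0 - np.sqrt(1.0 - u))
    if entry.pattern == "unif":
        return ta * u
    return ta * np.sqrt(u)


# --------------------------------------------------------------------------
# Censoring: dropout + administrative
# --------------------------------------------------------------------------

DropoutFamily = Literal["none", "unif", "exp"]


@dataclass(frozen=True)
class DropoutSpec:
    """Dropout-censoring law; censoring time is min(D, T_e - entry).

    family="unif": D ~ Uniform(0, param); family="exp": D ~ Exponential(rate=param);
    family="none": D = +inf, so censoring is purely administrative.
    """

    family: DropoutFamily
    trial_duration: float
    param: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("none", "unif", "exp"):
            raise ValueError(f"unknown dropout family {self.family!r}")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.family == "none":
            if self.param is not None:
                raise ValueError("family='none' takes no parameter")
        elif self.param is None or self.param <= 0:
            raise ValueError("dropout parameter must be positive")

    def dropout_survival(self, c):
        """D-bar(c) = P(D > c)."""
        c = np.asarray(c, dtype=float)
        if self.family == "none":
            out = np.ones_like(c)
        elif self.family == "unif":
            out = np.clip(1.0 - c / self.param, 0.0, 1.0)
        else:
            out = np.exp(-self.param * c)
        return float(out) if out.ndim == 0 else out

    def sample(self, entry_time, rng: np.random.Generator):
        return sample_censoring(self, entry_time, rng)


def sample_censoring(dropout: DropoutSpec, entry_time, rng: np.random.Generator):
    """Draw censoring times min(D, T_e - v); the atom at T_e - v has mass D-bar(T_e - v)."""
    v = np.atleast_1d(np.asarray(entry_time, dtype=float))
    te = dropout.trial_duration
    if np.any(v > te):
        raise ValueError("entry_time exceeds the trial duration")
    admin = te - v
    if dropout.family == "none":
        out = admin
    elif dropout.family == "unif":
        out = np.minimum(rng.uniform(0.0, dropout.param, size=v.shape), admin)
    else:
        out = np.minimum(rng.exponential(1.0 / dropout.param, size=v.shape), admin)
    return out if np.ndim(entry_time) else float(out[0])


def admin_censor_prob(event: GenGammaSpec, entry: EntrySpec, trial_duration: float) -> float:
    """P(T > T_e - V): probability of administrative censoring alone."""
    if trial_duration < entry.accrual_duration:
        raise ValueError(
            f"trial_duration {trial_duration} shorter than accrual "
            f"duration {entry.accrual_duration}"
        )
    ta = entry.accrual_duration
    if ta == 0:
        return float(event.survival(trial_duration))
    value, _ = integrate.quad(
        lambda v: entry.pdf(v) * event.survival(trial_duration - v), 0.0, ta, **_QUAD_KW
    )
    return float(value)


def _censor_prob_given_entry(
    event: GenGammaSpec, dropout: DropoutSpec, horizon: float
) -> float:
    """P(min(D, horizon) < T) for one entry time (horizon = T_e - v)."""
    if dropout.family == "none":
        return float(event.survival(horizon))
    atom = float(dropout.dropout_survival(horizon)) * float(event.survival(horizon))
    if dropout.family == "unif":
        upper = min(dropout.param, horizon)
        integral, _ = integrate.quad(event.survival, 0.0, upper, **_QUAD_KW)
        return integral / dropout.param + atom
    # integrate on the scaled variable w = lam * c so the integrand stays
    # well-conditioned for very large dropout rates
    lam = dropout.param
    upper = min(lam * horizon, 50.0)
    integral, _ = integrate.quad(
        lambda w: np.exp(-w) * event.survival(w / lam), 0.0, upper, **_QUAD_KW
    )
    return integral + atom


def total_censor_prob(
    event: GenGammaSpec, entry: EntrySpec, dropout: DropoutSpec
) -> float:
    """Overall censoring probability P(min(D, T_e - V) < T) by nested quadrature."""
    te = dropout.trial_duration
    ta = entry.accrual_duration
    if ta == 0:
        return _censor_prob_given_entry(event, dropout, te)
    value, _ = integrate.quad(
        lambda v: entry.pdf(v) * _censor_prob_given_entry(event, dropout, te - v),
        0.0,
        ta,
        epsabs=1e-9,
        epsrel=1e-9,
        limit=100,
    )
    return float(value)


def solve_dropout_param(
    target_censoring_prob: float,
    event: GenGammaSpec,
    entry: EntrySpec,
    trial_duration: float,
    family: Literal["unif", "exp"] = "unif",
) -> DropoutSpec:
    """Calibrate the dropout parameter to a total control-arm censoring probability.

    Solves P(min(D, T_e - V) < T1) = target by monotone bracketing on the log
    parameter; the probability is evaluated by nested quadrature.  A target at
    (or within 1e-6 of) the administrative-only probability returns
    ``family='none'`` with a warning; a target below it is infeasible.
    """
    if not 0 < target_censoring_prob < 1:
        raise ValueError("target censoring probability must lie in (0, 1)")
    if family not in ("unif", "exp"):
        raise ValueError(f"unknown dropout family {family!r}")
    admin = admin_censor_prob(event, entry, trial_duration)
    if target_censoring_prob < admin - 1e-9:
        raise ValueError(
            f"target censoring probability {target_censoring_prob:.6g} is below the "
            f"administrative-censoring floor {admin:.6g}; it cannot be reached by "
            "adding dropout"
        )
    if target_censoring_prob <= admin + 1e-6:
        warnings.warn(
            "target censoring probability coincides with administrative censoring; "
            "returning a no-dropout law",
            stacklevel=2,
        )
        return DropoutSpec(family="none", trial_duration=trial_duration)

    def gap(log_param: float) -> float:
        d = DropoutSpec(family=family, trial_duration=trial_duration, param=np.exp(log_param))
        return total_censor_prob(event, entry, d) - target_censoring_prob

    # unif: probability decreases in the support width; exp: increases in the rate.
    lo, hi = -40.0, 40.0
    glo, ghi = gap(lo), gap(hi)
    if glo * ghi > 0:
        raise ValueError(
            "could not bracket the dropout parameter for target "
            f"{target_censoring_prob:.6g} (family={family!r})"
        )
    sol = optimize.brentq(gap, lo, hi, xtol=1e-12, rtol=1e-14, maxiter=200)
    spec = DropoutSpec(family=family, trial_duration=trial_duration, param=float(np.exp(sol)))
    achieved = total_censor_prob(event, entry, spec)
    if abs(achieved - target_censoring_prob) > 1e-8:
        raise RuntimeError(
            f"dropout calibration did not converge: achieved {achieved:.10f} "
            f"vs target {target_censoring_prob:.10f}"
        )
    return spec
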