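"""Non-inferiority margins for the difference in restricted mean survival times.

Three constructions are offered:

1. preserved fraction of the active control's RMST:
       delta = (1 - f1) * R1(tau)
2. preserved fraction of the control-vs-hypothetical-placebo DRMST:
       delta = (1 - f2) * (R1(tau) - R0(tau))
3. conversion of a hazard-ratio margin 1/theta > 1 under proportional hazards:
       delta = int_0^tau S1(t) dt - int_0^tau S1(t)^(1/theta) dt

plus a user-supplied numeric margin, which takes precedence over both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

from scipy import integrate

from .distributions import GenGammaSpec, scale_from_median, true_rmst

if TYPE_CHECKING:  # pragma: no cover
    from .design import DesignConfig

__all__ = [
    "MarginAudit",
    "margin_preserved_rmst",
    "margin_preserved_drmst",
    "margin_from_hr",
    "resolve_margin",
]


@dataclass(frozen=True)
class MarginAudit:
    """How the margin was resolved: mode, value and the RMSTs that produced it."""

    mode: str
    delta: float
    r1: float | None = None
    r0: float | None = None
    ignored: tuple[str, ...] = ()


def margin_preserved_rmst(f1: float, r1: float) -> float:
    """delta = (1 - f1) * R1(tau)."""
    if not 0 < f1 < 1:
        raise ValueError(f"f1 must lie in (0, 1), got {f1!r}")
    if r1 <= 0:
        raise ValueError("R1(tau) must be positive")
    return (1.0 - f1) * r1


def margin_preserved_drmst(f2: float, r1: float, r0: float) -> float:
    """delta = (1 - f2) * (R1(tau) - R0(tau)) against a hypothetical placebo."""
    if not 0 < f2 < 1:
        raise ValueError(f"f2 must lie in (0, 1), got {f2!r}")
    if r0 <= 0:
        raise ValueError("R0(tau) must be positive")
    if r1 <= r0:
        raise ValueError(
            "hypothetical placebo must be worse than active control "
            f"(R1={r1:.6g} <= R0={r0:.6g})"
        )
    return (1.0 - f2) * (r1 - r0)


def margin_from_hr(hr_margin: float, control: GenGammaSpec, tau: float) -> float:
    """Convert an HR margin 1/theta > 1 into a DRMST margin under PH."""
    if hr_margin <= 1:
        raise ValueError(f"HR margin must exceed 1, got {hr_margin!r}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    r1 = true_rmst(control, tau)
    r_theta, _ = integrate.quad(
        lambda t: control.survival(t) ** hr_margin, 0.0, tau,
        epsabs=1e-10, epsrel=1e-10, limit=200,
    )
    return r1 - r_theta


def resolve_margin(config: "DesignConfig") -> tuple[float, MarginAudit]:
    """Dispatch the margin options with precedence numeric > (f2, m0) > f1.

    When several options are supplied their resolved values must agree to
    1e-9 (warning) or the conflict is a hard error.
    """
    control = scale_from_median(config.m1, config.shape, config.k)
    tau = config.tau_resolved
    candidates: list[tuple[str, float, MarginAudit]] = []

    if config.margin is not None:
        if config.margin <= 0:
            raise ValueError("numeric margin must be positive")
        candidates.append(
            ("numeric", float(config.margin), MarginAudit("numeric", float(config.margin)))
        )
    if config.f2 is not None or config.m0 is not None:
        if config.f2 is None or config.m0 is None:
            raise ValueError("margin option 2 requires both m0 and f2")
        r1 = true_rmst(control, tau)
        placebo = scale_from_median(config.m0, config.shape, config.k)
        r0 = true_rmst(placebo, tau)
        delta = margin_preserved_drmst(config.f2, r1, r0)
        candidates.append(
            ("preserved_drmst", delta, MarginAudit("preserved_drmst", delta, r1=r1, r0=r0))
        )
    if config.f1 is not None:
        r1 = true_rmst(control, tau)
        delta = margin_preserved_rmst(config.f1, r1)
        candidates.append(
            ("preserved_rmst", delta, MarginAudit("preserved_rmst", delta, r1=r1))
        )

    if not candidates:
        raise ValueError(
            "no margin option supplied: set a numeric margin, or f1, or (m0, f2)"
        )
    mode, delta, audit = candidates[0]
    ignored = tuple(m for m, _, _ in candidates[1:])
    if ignored:
        # An explicit numeric margin overrides anything (with a warning); the
        # two preserved-fraction options rank only when they agree.
        for other_mode, other_delta, _ in candidates[1:]:
            if abs(other_delta - delta) > 1e-9 and mode != "numeric":
                raise ValueError(
                    f"conflicting margin options: {mode!r} gives delta={delta:.6g} "
                    f"but {other_mode!r} gives delta={other_delta:.6g}"
                )
            if abs(other_delta - delta) > 1e-9:
                warnings.warn(
                    f"margin option {other_mode!r} (delta={other_delta:.6g}) is "
                    f"overridden by {mode!r} (delta={delta:.6g})",
                    stacklevel=2,
                )
        audit = MarginAudit(audit.mode, audit.delta, audit.r1, audit.r0, ignored)
    return delta, audit
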