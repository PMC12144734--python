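"""The full trial design surface and its solved (calibrated) counterpart.

``DesignConfig`` mirrors the user-facing parameter table of the tool: arm
sizes, median survivals and generalized-gamma shapes, margin options, the
switching model, accrual/censoring/follow-up structure, the analysis horizon
tau, the one-sided level, and Monte-Carlo controls.  ``solve_design`` turns it
into concrete laws: event-time specs per arm, a calibrated dropout law, the
solved switch-time distribution and the resolved (unadjusted) margin delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .distributions import (
    DropoutSpec,
    EntrySpec,
    GenGammaSpec,
    scale_from_median,
    solve_dropout_param,
    true_rmst,
)
from .margins import MarginAudit, resolve_margin
from .switching import SolvedSwitch, SwitchSpec, solve_switch_params

__all__ = ["DesignConfig", "SolvedDesign", "solve_design", "round_half_up"]


def round_half_up(x: float) -> int:
    """round(r*n) with halves away from zero (0.5 -> 1), independent of banker's rounding."""
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class DesignConfig:
    """One non-inferiority trial design (defaults follow the tool's parameter table)."""

    n: int
    m1: float
    m2: float
    ta: float
    te: float
    r: float = 1.0
    shape: float = 1.0
    k: float = 1.0
    f1: float | None = None
    m0: float | None = None
    f2: float | None = None
    margin: float | None = None
    ps: float = 0.2
    rs: float = 0.5
    rhos: float = 0.775
    s_dist: str | float = "gamma"
    entry: str = "unif"
    censoring_prob: str | float = "AC.only"
    lossfu_dist: str = "unif"
    tau: float | None = None
    one_sided_alpha: float = 0.025
    tx_switch: str = "1to2"
    af: float = 1.0
    n_simulations: int = 5000
    seed: int = 2024

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("control-arm size n must be >= 2")
        if self.r < 0:
            raise ValueError("allocation ratio r must be >= 0")
        if self.n_experimental < 2:
            raise ValueError("experimental-arm size round(r*n) must be >= 2")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("median survivals must be positive")
        if self.shape <= 0 or self.k <= 0:
            raise ValueError("shape parameters must be positive")
        if not 0 <= self.ta <= self.te:
            raise ValueError("need 0 <= Ta <= Te")
        if self.te <= 0:
            raise ValueError("trial duration Te must be positive")
        tau = self.tau_resolved
        if not 0 < tau <= self.te:
            raise ValueError("need 0 < tau <= Te")
        if not 0 < self.one_sided_alpha < 0.5:
            raise ValueError("one_sided_alpha must lie in (0, 0.5)")
        if isinstance(self.censoring_prob, str):
            if self.censoring_prob != "AC.only":
                raise ValueError(
                    "censoring_prob must be a probability or the string 'AC.only'"
                )
        elif not 0 < self.censoring_prob < 1:
            raise ValueError("censoring_prob must lie in (0, 1)")
        if self.lossfu_dist not in ("unif", "exp"):
            raise ValueError("lossfu_dist must be 'unif' or 'exp'")
        if self.entry not in ("decreasing", "unif", "increasing"):
            raise ValueError("entry must be 'decreasing', 'unif' or 'increasing'")
        if self.n_simulations < 1:
            raise ValueError("n_simulations must be >= 1")
        self.switch_spec()  # validates ps/rs/rhos/s_dist/TXswitch/af

    @property
    def n_experimental(self) -> int:
        return round_half_up(self.r * self.n)

    @property
    def tau_resolved(self) -> float:
        return self.te if self.tau is None else self.tau

    def control_law(self) -> GenGammaSpec:
        return scale_from_median(self.m1, self.shape, self.k)

    def experimental_law(self) -> GenGammaSpec:
        return scale_from_median(self.m2, self.shape, self.k)

    def entry_spec(self) -> EntrySpec:
        return EntrySpec(pattern=self.entry, accrual_duration=self.ta)

    def switch_spec(self) -> SwitchSpec:
        if isinstance(self.s_dist, str) and self.s_dist not in (
            "unif", "beta", "gamma", "indepExp",
        ):
            raise ValueError(f"unknown s_dist {self.s_dist!r}")
        if isinstance(self.s_dist, str):
            return SwitchSpec(
                dist=self.s_dist, ps=self.ps, rs=self.rs, rho_s=self.rhos,
                direction=self.tx_switch, af=self.af,
            )
        return SwitchSpec(
            dist="fixed", ps=self.ps, fixed_time=float(self.s_dist),
            direction=self.tx_switch, af=self.af,
        )

    def acceleration(self) -> float:
        """af * m2/m1 for control-to-experimental switches, af * m1/m2 reversed."""
        ratio = self.m2 / self.m1 if self.tx_switch == "1to2" else self.m1 / self.m2
        return self.af * ratio

    def with_n(self, n: int) -> "DesignConfig":
        return replace(self, n=n)


@dataclass(frozen=True)
class SolvedDesign:
    """Concrete laws and calibrated parameters derived from a DesignConfig."""

    control: GenGammaSpec
    experimental: GenGammaSpec
    entry: EntrySpec
    dropout: DropoutSpec
    switch: SolvedSwitch
    delta: float
    margin_audit: MarginAudit
    accel: float
    r1_pure: float
    r2_pure: float


def solve_design(config: DesignConfig) -> SolvedDesign:
    """Run every design-time calibration once: laws, dropout, switching, margin."""
    control = config.control_law()
    experimental = config.experimental_law()
    entry = config.entry_spec()
    if config.censoring_prob == "AC.only":
        dropout = DropoutSpec(family="none", trial_duration=config.te)
    else:
        dropout = solve_dropout_param(
            float(config.censoring_prob), control, entry, config.te,
            family=config.lossfu_dist,
        )
    spec = config.switch_spec()
    donor = control if config.tx_switch == "1to2" else experimental
    switch = solve_switch_params(spec, donor)
    delta, audit = resolve_margin(config)
    tau = config.tau_resolved
    return SolvedDesign(
        control=control,
        experimental=experimental,
        entry=entry,
        dropout=dropout,
        switch=switch,
        delta=delta,
        margin_audit=audit,
        accel=config.acceleration(),
        r1_pure=true_rmst(control, tau),
        r2_pure=true_rmst(experimental, tau),
    )
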