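"""Generation of one complete intention-to-treat trial dataset.

Each subject gets an entry time on [0, T_a], a deterministic arm assignment
(exactly n control and round(r*n) experimental subjects), a latent event time
from their arm's generalized gamma law, a possible switch with its
counterfactual event time, and a censoring time min(dropout, T_e - entry).
The observed pair is (min(counterfactual, censor), event flag), on the clock
that starts at each subject's own randomization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignConfig, SolvedDesign
from .distributions import DropoutSpec, EntrySpec, GenGammaSpec, sample_censoring
from .switching import SolvedSwitch, apply_switch, sample_switch_times

__all__ = ["ArmData", "TrialData", "simulate_arm", "simulate_trial"]


@dataclass(frozen=True)
class ArmData:
    """Per-subject columns for one arm (parallel arrays)."""

    entry: np.ndarray
    latent_event: np.ndarray
    switched: np.ndarray
    switch_time: np.ndarray  # NaN for non-switchers
    counterfactual_event: np.ndarray
    censor: np.ndarray
    observed: np.ndarray
    event: np.ndarray

    @property
    def n(self) -> int:
        return self.observed.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass(frozen=True)
class TrialData:
    """One simulated trial: a control arm and an experimental arm."""

    control: ArmData
    experimental: ArmData

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name, arm in (("control", self.control), ("experimental", self.experimental)):
            frames.append(
                pd.DataFrame(
                    {
                        "arm": name,
                        "entry": arm.entry,
                        "time": arm.observed,
                        "event": arm.event.astype(int),
                        "switched": arm.switched.astype(int),
                        "switch_time": arm.switch_time,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def simulate_arm(
    law: GenGammaSpec,
    n: int,
    entry: EntrySpec,
    dropout: DropoutSpec,
    rng: np.random.Generator,
    switch: SolvedSwitch | None = None,
    accel: float = 1.0,
) -> ArmData:
    """Simulate one arm; ``switch`` is None for the arm that cannot switch."""
    v = entry.sample(n, rng)
    t_latent = law.rvs(n, rng)
    switch_time = np.full(n, np.nan)
    switched = np.zeros(n, dtype=bool)
    t_cf = t_latent.copy()
    if switch is not None and switch.spec.ps > 0:
        _, s, switched = sample_switch_times(switch, t_latent, rng)
        if switched.any():
            t_cf[switched] = apply_switch(t_latent[switched], s[switched], accel)
            switch_time[switched] = s[switched]
    censor = sample_censoring(dropout, v, rng)
    observed = np.minimum(t_cf, censor)
    event = t_cf <= censor  # ties count as events
    return ArmData(v, t_latent, switched, switch_time, t_cf, censor, observed, event)


def simulate_trial(
    config: DesignConfig, solved: SolvedDesign, rng: np.random.Generator
) -> TrialData:
    """One full trial under the solved design; control arm is simulated first."""
    switch_control = solved.switch if config.tx_switch == "1to2" else None
    switch_exp = solved.switch if config.tx_switch == "2to1" else None
    control = simulate_arm(
        solved.control, config.n, solved.entry, solved.dropout, rng,
        switch=switch_control, accel=solved.accel,
    )
    experimental = simulate_arm(
        solved.experimental, config.n_experimental, solved.entry, solved.dropout, rng,
        switch=switch_exp, accel=solved.accel,
    )
    return TrialData(control=control, experimental=experimental)
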