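"""Drug deployment strategies as time-dependent dose schedules.

Every drug-using strategy spends the same total budget (240 dosage units per
patient at any instant); they differ in how the budget is split across drugs,
patients and time:

* ``NONE`` — no drugs (baseline before the antibiotic era).
* ``CONTROL`` — drug A at full dose with resistance unable to evolve
  (resistant compartments start, and stay, at zero).
* ``SINGLE`` — drug A at full dose for everyone, all strains present.
* ``CYCLING`` — the whole ward alternates drug A and drug B every ``pi``
  time units.
* ``MIXING`` — half the ward is on drug A and half on drug B, and the two
  halves swap drugs every ``pi`` time units (two treatment arms).
* ``COCKTAIL_CMB`` / ``COCKTAIL_SEP`` — everyone gets both drugs at half
  dose (120:120), under the suppressive (combined) or additive (separate)
  cocktail pharmacodynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pharmacodynamics import (
    PharmacodynamicParams,
    StrainProfile,
    growth_combined,
    growth_separate,
    growth_single,
)

__all__ = ["STRATEGIES", "PERIODIC_STRATEGIES", "StrategySchedule", "doses_at", "growth_for_strategy"]

STRATEGIES = ("NONE", "CONTROL", "SINGLE", "CYCLING", "MIXING", "COCKTAIL_CMB", "COCKTAIL_SEP")
PERIODIC_STRATEGIES = ("CYCLING", "MIXING")


@dataclass(frozen=True)
class StrategySchedule:
    """A named deployment strategy with its period and dose budget.

    ``period_pi`` is required (and only meaningful) for CYCLING and MIXING.
    """

    name: str
    period_pi: float | None = None
    dose_budget: float = 240.0

    def __post_init__(self) -> None:
        if self.name not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.name!r}; expected one of {STRATEGIES}")
        if self.name in PERIODIC_STRATEGIES:
            if self.period_pi is None or self.period_pi <= 0.0:
                raise ValueError(f"{self.name} requires a positive period_pi")
        if self.dose_budget < 0.0:
            raise ValueError("dose_budget must be nonnegative")

    @property
    def n_arms(self) -> int:
        return 2 if self.name == "MIXING" else 1

    @property
    def arm_weights(self) -> np.ndarray:
        return np.full(self.n_arms, 1.0 / self.n_arms)

    @property
    def is_periodic(self) -> bool:
        return self.name in PERIODIC_STRATEGIES


def doses_at(schedule: StrategySchedule, t: float) -> tuple[tuple[float, float], ...]:
    """Per-arm drug concentrations ``(a, b)`` in force at time ``t``.

    CYCLING serves drug A on even periods and drug B on odd ones
    (``floor(t / pi)`` parity); MIXING's second arm is in exact antiphase.
    The per-arm doses of every drug-using strategy sum to the budget.
    """
    if t < 0.0:
        raise ValueError(f"time must be nonnegative, got {t}")
    d = schedule.dose_budget
    name = schedule.name
    if name == "NONE":
        return ((0.0, 0.0),)
    if name in ("CONTROL", "SINGLE"):
        return ((d, 0.0),)
    if name in ("COCKTAIL_CMB", "COCKTAIL_SEP"):
        return ((d / 2.0, d / 2.0),)
    odd = int(t // schedule.period_pi) % 2
    on_a = (d, 0.0)
    on_b = (0.0, d)
    if name == "CYCLING":
        return (on_b,) if odd else (on_a,)
    # MIXING: arm 0 follows the CYCLING pattern, arm 1 is in antiphase
    return (on_b, on_a) if odd else (on_a, on_b)


def growth_for_strategy(
    schedule: StrategySchedule,
    strains: tuple[StrainProfile, ...],
    t: float,
    pd: PharmacodynamicParams | None = None,
) -> np.ndarray:
    """Per-arm strain growth rates under the doses in force at time ``t``.

    Returns an ``(n_arms, 4)`` array ordered (S, R1, R2, R3).  Cocktail
    strategies use their dedicated two-drug growth functions; all
    one-drug-at-a-time strategies use the single-drug curve against the MIC
    of whichever drug is being served.
    """
    pd = pd or PharmacodynamicParams()
    if len(strains) != 4:
        raise ValueError("expected the four strain profiles (S, R1, R2, R3)")
    arms = doses_at(schedule, t)
    out = np.empty((len(arms), 4))
    for ai, (a, b) in enumerate(arms):
        for si, strain in enumerate(strains):
            if schedule.name == "COCKTAIL_CMB":
                out[ai, si] = growth_combined(a, b, strain, pd)
            elif schedule.name == "COCKTAIL_SEP":
                out[ai, si] = growth_separate(a, b, strain, pd)
            elif b > 0.0:
                out[ai, si] = growth_single(b, strain.mic_b, pd)
            elif a > 0.0:
                out[ai, si] = growth_single(a, strain.mic_a, pd)
            else:
                out[ai, si] = pd.phi_max
    return out
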