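"""Closed five-compartment ward transmission model.

Patients are uninfected (X) or colonized by one of four bacterial strains:
sensitive S, single-resistant R1 (drug A) and R2 (drug B), or
double-resistant R3.  The system is closed (no admission/discharge), so the
five frequencies sum to one and the right-hand side conserves that sum
exactly.  Processes:

* infection: X patients acquire strain i by mass action at rate ``beta``,
  discounted to ``beta * (1 - c)`` for resistant strains (cost of resistance
  acts on transmission);
* superinfection: sensitive bacteria colonize and take over resistant
  carriers at rate ``sigma * beta * c`` — the takeover is possible precisely
  because resistant strains pay the competitive cost ``c``, so a cost-free
  strain cannot be taken over; resistant strains never take over S;
* clearance: each infected compartment is cured at rate ``-(G_i - gamma)``,
  where ``G_i`` is the strain's current pharmacodynamic net growth rate and
  ``gamma`` the immune clearance rate; cured patients return to X.

The same right-hand side generalizes to several treatment arms (used by the
MIXING strategy): each infected compartment is split per arm, new infections
from X are assigned to arms by fixed weights, and superinfection acts through
the total S frequency while patients keep their arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EpiParams",
    "PopulationState",
    "GrowthVector",
    "rhs",
    "rhs_multi",
    "per_capita_recovery",
    "dominant_strain",
    "PAYS_COST",
]

#: which of (S, R1, R2, R3) pay the transmission cost of resistance
PAYS_COST = np.array([0.0, 1.0, 1.0, 1.0])


@dataclass(frozen=True)
class EpiParams:
    """Epidemiological rate constants (all per unit time except the
    dimensionless superinfection factor ``sigma`` and cost ``cost_c``)."""

    beta: float = 1.0
    sigma: float = 0.25
    gamma: float = 0.25
    cost_c: float = 0.1

    def __post_init__(self) -> None:
        for name in ("beta", "sigma", "gamma", "cost_c"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be nonnegative")
        if not (self.cost_c < 1.0):
            raise ValueError(f"cost_c must be < 1, got {self.cost_c}")


@dataclass(frozen=True)
class PopulationState:
    """Frequencies of the five patient compartments (must sum to ~1)."""

    x: float
    s: float
    r1: float
    r2: float
    r3: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(np.isnan(vals)):
            raise ValueError("population state contains NaN")
        if np.any(vals < -1e-9) or np.any(vals > 1.0 + 1e-9):
            raise ValueError(f"frequencies must lie in [0, 1], got {vals}")
        if abs(vals.sum() - 1.0) > 1e-6:
            raise ValueError(f"frequencies must sum to 1, got {vals.sum()}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.s, self.r1, self.r2, self.r3])

    @property
    def infected(self) -> float:
        return self.s + self.r1 + self.r2 + self.r3


@dataclass(frozen=True)
class GrowthVector:
    """Net growth rates of the four strains under the doses currently in force."""

    g_s: float
    g_1: float
    g_2: float
    g_3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.g_s, self.g_1, self.g_2, self.g_3])


def rhs_multi(
    y: np.ndarray,
    growth: np.ndarray,
    weights: np.ndarray,
    epi: EpiParams,
) -> np.ndarray:
    """Time derivative of the multi-arm state vector.

    ``y`` has layout ``[X, S^1, R1^1, R2^1, R3^1, S^2, ...]`` for arms
    1..m; ``growth`` is an (m, 4) array of per-arm strain growth rates and
    ``weights`` the (m,) arm weights (new infections from X are split by
    weight).  The component sum of the derivative is exactly zero.
    """
    m = growth.shape[0]
    comps = y[1:].reshape(m, 4)
    tot = comps.sum(axis=0)  # total frequency per strain
    x = y[0]

    beta_eff = epi.beta * (1.0 - epi.cost_c * PAYS_COST)
    inf = beta_eff * x * tot  # new infections per strain, all arms pooled

    # superinfection: total S takes over cost-paying carriers of every arm
    sup = epi.sigma * epi.beta * epi.cost_c * PAYS_COST[1:] * tot[0] * comps[:, 1:]

    clear = (growth - epi.gamma) * comps  # (m, 4), <= 0 per compartment

    dcomps = weights[:, None] * inf[None, :] + clear
    dcomps[:, 0] += sup.sum(axis=1)
    dcomps[:, 1:] -= sup

    dy = np.empty_like(y)
    dy[0] = -inf.sum() - clear.sum()
    dy[1:] = dcomps.ravel()
    return dy


def rhs(state: PopulationState, g: GrowthVector, epi: EpiParams) -> np.ndarray:
    """Single-arm right-hand side.

    Returns the derivative ``[dx, ds, dr1, dr2, dr3]`` (per unit time); its
    components sum to zero exactly up to floating-point rounding.
    """
    garr = g.as_array()
    if np.any(np.isnan(garr)):
        raise ValueError("growth vector contains NaN")
    return rhs_multi(state.as_array(), garr[None, :], np.array([1.0]), epi)


def per_capita_recovery(state_or_freqs, g: GrowthVector, epi: EpiParams) -> float:
    """Per-capita recovery rate of infected patients.

    The population recovery flux is ``z = -sum_i (G_i - gamma) * n_i`` over
    the four infected compartments; the per-capita rate is ``z`` divided by
    the total infected frequency.  Nonnegative whenever ``G_i <= gamma``.

    Raises
    ------
    ValueError
        If the population is fully uninfected (the rate is undefined).
    """
    if isinstance(state_or_freqs, PopulationState):
        freqs = state_or_freqs.as_array()[1:]
    else:
        freqs = np.asarray(state_or_freqs, dtype=float)
    infected = freqs.sum()
    if infected <= 0.0:
        raise ValueError("per-capita recovery rate undefined: no infected patients")
    z = -((g.as_array() - epi.gamma) * freqs).sum()
    return z / infected


def dominant_strain(state_or_freqs, tie_tol: float = 1e-9) -> tuple[str, ...]:
    """Most common bacterial strain(s) in the infected population.

    Returns the argmax over (S, R1, R2, R3) frequencies; strains within
    ``tie_tol`` of the maximum are reported together (e.g. the symmetric
    R1/R2 mixture under two-drug strategies).
    """
    if isinstance(state_or_freqs, PopulationState):
        freqs = state_or_freqs.as_array()[1:]
    else:
        freqs = np.asarray(state_or_freqs, dtype=float)
    top = freqs.max()
    names = ("S", "R1", "R2", "R3")
    return tuple(n for n, f in zip(names, freqs) if f >= top - tie_tol)
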