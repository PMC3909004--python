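"""Scenario sweeps, dominance thresholds and closed-form cross-checks.

The central summary statistic throughout is ``X_hat``, the equilibrium (or
cycle-averaged) frequency of uninfected patients.  For static regimens where
a single infected strain dominates alone, the ODE admits the closed form

    X_hat = (gamma - G_i) / (beta * (1 - c * pays_cost_i))

which :func:`analytic_equilibrium` evaluates as an independent oracle for the
numerical integrator.  :func:`find_dominance_threshold` bisects the tradeoff
strength ``omega`` on the identity of the most common strain at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import EquilibriumResult, IntegrationSettings, run_to_equilibrium
from .pharmacodynamics import PharmacodynamicParams, StrainProfile, standard_strains
from .population import EpiParams
from .treatments import PERIODIC_STRATEGIES, StrategySchedule, growth_for_strategy

__all__ = [
    "SweepSpec",
    "ThresholdResult",
    "sweep",
    "find_dominance_threshold",
    "analytic_equilibrium",
    "recovery_vs_xhat",
]


@dataclass(frozen=True)
class SweepSpec:
    """Grid of scenarios: strategies x omega values (x periods, if periodic)."""

    strategies: tuple[str, ...] = (
        "NONE",
        "CONTROL",
        "SINGLE",
        "CYCLING",
        "MIXING",
        "COCKTAIL_CMB",
        "COCKTAIL_SEP",
    )
    omegas: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 10))
    pis: tuple[float, ...] = (1.0, 50.0, 50000.0)
    dose_budget: float = 240.0
    base_mic_a1: float = 240.0
    base_mic_b2: float = 240.0

    def __post_init__(self) -> None:
        if any(not (0.0 <= w <= 1.0) for w in self.omegas):
            raise ValueError("omega grid must lie within [0, 1]")
        if any(p <= 0.0 for p in self.pis):
            raise ValueError("pi values must be positive")


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of bisecting omega on the dominant-strain identity."""

    strategy: str
    pi: float | None
    omega_star: float | None
    from_strain: tuple[str, ...]
    to_strain: tuple[str, ...]
    bracket: tuple[float, float]
    n_evaluations: int = 0

    @property
    def width(self) -> float:
        return self.bracket[1] - self.bracket[0]


def _run_point(
    strategy: str,
    omega: float,
    pi: float | None,
    epi: EpiParams,
    pd_params: PharmacodynamicParams,
    settings: IntegrationSettings,
    dose_budget: float = 240.0,
    base_mic_a1: float = 240.0,
    base_mic_b2: float = 240.0,
) -> EquilibriumResult:
    schedule = StrategySchedule(strategy, period_pi=pi, dose_budget=dose_budget)
    strains = standard_strains(omega, base_mic_a1, base_mic_b2)
    return run_to_equilibrium(schedule, strains, epi, pd_params, settings)


def sweep(
    spec: SweepSpec,
    epi: EpiParams | None = None,
    pd_params: PharmacodynamicParams | None = None,
    settings: IntegrationSettings | None = None,
) -> pd.DataFrame:
    """Run one equilibrium per grid point and return a tidy long table.

    Periodic strategies are crossed with every ``pi`` in the spec; static
    ones carry ``pi = NaN``.  Non-converged cells are flagged in the
    ``converged`` column, never dropped.  All parameters are echoed per row
    for provenance, so identical specs give bit-identical tables.
    """
    epi = epi or EpiParams()
    pd_params = pd_params or PharmacodynamicParams()
    settings = settings or IntegrationSettings()
    rows = []
    for strategy in spec.strategies:
        pis = spec.pis if strategy in PERIODIC_STRATEGIES else (None,)
        for pi in pis:
            for omega in spec.omegas:
                res = _run_point(
                    strategy, omega, pi, epi, pd_params, settings,
                    spec.dose_budget, spec.base_mic_a1, spec.base_mic_b2,
                )
                row = {
                    "strategy": strategy,
                    "omega": omega,
                    "pi": np.nan if pi is None else pi,
                    "x_hat": res.x_hat,
                    "dominant": "+".join(res.dominant),
                    "recovery_per_capita": res.recovery_per_capita,
                    "converged": res.converged,
                    "time_to_convergence": res.time_to_convergence,
                }
                row.update({k.lower(): v for k, v in res.strain_freqs.items()})
                row.update(
                    beta=epi.beta, sigma=epi.sigma, gamma=epi.gamma, cost_c=epi.cost_c,
                    phi_max=pd_params.phi_max, phi_min=pd_params.phi_min,
                    hill_k=pd_params.hill_k, dose_budget=spec.dose_budget,
                    dt=settings.dt, convergence_tol=settings.convergence_tol,
                )
                rows.append(row)
    return pd.DataFrame(rows)


def find_dominance_threshold(
    strategy: str,
    pi: float | None = None,
    tolerance: float = 0.005,
    epi: EpiParams | None = None,
    pd_params: PharmacodynamicParams | None = None,
    settings: IntegrationSettings | None = None,
    dose_budget: float = 240.0,
) -> ThresholdResult:
    """Bisect omega in [0, 1] for the switch away from R3 dominance.

    The predicate is whether R3 belongs to the dominant-strain set of the
    equilibrium.  The bracket is narrowed until its width is at most
    ``tolerance`` and the reported ``omega_star`` is the bracket midpoint.
    If the dominant strain does not switch between omega 0 and 1, an
    explicit no-threshold result is returned (``omega_star = None``).
    """
    epi = epi or EpiParams()
    pd_params = pd_params or PharmacodynamicParams()
    settings = settings or IntegrationSettings()

    n_evals = 0

    def dominant(omega: float) -> tuple[str, ...]:
        nonlocal n_evals
        n_evals += 1
        return _run_point(
            strategy, omega, pi, epi, pd_params, settings, dose_budget
        ).dominant

    dom_lo = dominant(0.0)
    dom_hi = dominant(1.0)
    has_r3_lo = "R3" in dom_lo
    if has_r3_lo == ("R3" in dom_hi):
        return ThresholdResult(strategy, pi, None, dom_lo, dom_hi, (0.0, 1.0), n_evals)

    lo, hi = 0.0, 1.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if ("R3" in dominant(mid)) == has_r3_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(
        strategy, pi, 0.5 * (lo + hi), dom_lo, dom_hi, (lo, hi), n_evals
    )


def analytic_equilibrium(
    strategy: str,
    omega: float,
    epi: EpiParams | None = None,
    pd_params: PharmacodynamicParams | None = None,
    dominant: str | None = None,
    dose_budget: float = 240.0,
    base_mic_a1: float = 240.0,
    base_mic_b2: float = 240.0,
) -> float | None:
    """Closed-form equilibrium X_hat for static regimens, or None.

    Evaluates ``(gamma - G_i) / (beta * (1 - c * pays_cost_i))`` for the
    dominant strain.  If ``dominant`` is not given, the winner is taken by
    competitive exclusion: the seeded strain with the smallest persistence
    threshold wins.  CYCLING and MIXING fluctuate and have no closed form,
    so they return ``None``.
    """
    if strategy in PERIODIC_STRATEGIES:
        return None
    epi = epi or EpiParams()
    pd_params = pd_params or PharmacodynamicParams()
    schedule = StrategySchedule(strategy, dose_budget=dose_budget)
    strains = standard_strains(omega, base_mic_a1, base_mic_b2)
    growth = growth_for_strategy(schedule, strains, 0.0, pd_params)[0]

    def x_star(idx: int, strain: StrainProfile) -> float:
        denom = epi.beta * (1.0 - epi.cost_c * float(strain.pays_cost))
        return float(np.clip((epi.gamma - growth[idx]) / denom, 0.0, 1.0))

    if dominant is not None:
        idx = [s.name for s in strains].index(dominant)
        return x_star(idx, strains[idx])
    seeded = [0] if strategy == "CONTROL" else [0, 1, 2, 3]
    return min(x_star(i, strains[i]) for i in seeded)


def recovery_vs_xhat(table: pd.DataFrame) -> pd.DataFrame:
    """Per-strategy association between X_hat and per-capita recovery.

    Takes a sweep table and returns one row per strategy with the number of
    distinct points, the Spearman rank correlation between ``x_hat`` and
    ``recovery_per_capita`` and its sign (``positive`` / ``negative`` /
    ``none`` / ``undefined`` for degenerate single-point series).
    """
    from scipy.stats import spearmanr

    rows = []
    for strategy, grp in table.groupby("strategy", sort=False):
        pairs = grp[["x_hat", "recovery_per_capita"]].dropna().drop_duplicates()
        if len(pairs) < 2 or pairs["x_hat"].nunique() < 2:
            rho, label = np.nan, "undefined"
        else:
            rho = spearmanr(pairs["x_hat"], pairs["recovery_per_capita"]).statistic
            label = "positive" if rho > 0 else ("negative" if rho < 0 else "none")
        rows.append(
            {"strategy": strategy, "n_points": len(pairs), "spearman_rho": rho,
             "association": label}
        )
    return pd.DataFrame(rows)
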