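"""Pharmacodynamic growth functions for single drugs and two-drug cocktails.

Bacterial net growth is modeled as a Hill-type function of drug concentration
(Regoes-style dose response): it equals ``phi_max`` with no drug, crosses zero
exactly at the strain's minimal inhibitory concentration (MIC), and saturates
at ``phi_min`` (< 0) at high dose.  Two cocktail variants are provided:

* *combined* (suppressive pair): the two MIC-scaled doses are summed inside a
  single drug-effect term, so the pair can never do more damage than one
  saturating drug;
* *separate* (additive pair): each drug contributes its own effect term, so a
  strain sensitive to both drugs is doubly hurt and net growth may fall below
  ``phi_min``.

Double resistance is constrained by a tradeoff parameter ``omega`` in [0, 1]:
the double-resistant strain's MICs are ``(1 - omega)`` times the single
resistants' MICs, so ``omega = 0`` is a super-resistant mutant and
``omega = 1`` a super-sensitive one.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "MIC_FLOOR",
    "PharmacodynamicParams",
    "StrainProfile",
    "TradeoffSpec",
    "growth_single",
    "growth_combined",
    "growth_separate",
    "tradeoff_mics",
    "standard_strains",
    "STRAIN_NAMES",
]

#: Zero MICs are reset to this floor at construction time to avoid division
#: by zero; a strain at the floor is effectively fully sensitive.
MIC_FLOOR = 1e-6

STRAIN_NAMES = ("S", "R1", "R2", "R3")


@dataclass(frozen=True)
class PharmacodynamicParams:
    """Shape of the dose-response curve, shared by all strains.

    Parameters
    ----------
    phi_max : float
        Maximal net growth rate (per unit time) in the absence of drug.
    phi_min : float
        Minimal net growth rate (per unit time) at saturating dose; negative.
    hill_k : float
        Hill exponent of the dose response.  All standard scenarios use 1.
    """

    phi_max: float = 0.25
    phi_min: float = -0.25
    hill_k: float = 1.0

    def __post_init__(self) -> None:
        if not (self.phi_max > 0.0):
            raise ValueError(f"phi_max must be positive, got {self.phi_max}")
        if not (self.phi_min < 0.0):
            raise ValueError(f"phi_min must be negative, got {self.phi_min}")
        if not (self.phi_max > self.phi_min):
            raise ValueError("phi_max must exceed phi_min")
        if not (self.hill_k > 0.0):
            raise ValueError(f"hill_k must be positive, got {self.hill_k}")


@dataclass(frozen=True)
class StrainProfile:
    """A bacterial strain's resistance phenotype.

    MICs below :data:`MIC_FLOOR` (including zero) are clamped up to the floor
    when the profile is built, so growth functions never divide by zero.
    ``pays_cost`` marks strains that pay the transmission cost of resistance.
    """

    name: str
    mic_a: float
    mic_b: float
    pays_cost: bool = True

    def __post_init__(self) -> None:
        if self.name not in STRAIN_NAMES:
            raise ValueError(f"strain name must be one of {STRAIN_NAMES}, got {self.name!r}")
        if self.mic_a < 0.0 or self.mic_b < 0.0:
            raise ValueError("MICs must be nonnegative")
        object.__setattr__(self, "mic_a", max(self.mic_a, MIC_FLOOR))
        object.__setattr__(self, "mic_b", max(self.mic_b, MIC_FLOOR))


@dataclass(frozen=True)
class TradeoffSpec:
    """Pleiotropic tradeoff linking the double-resistant strain's two MICs.

    ``omega = 0.5`` is a linear tradeoff; larger values are stronger
    constraints, with ``omega = 1`` collapsing both MICs to the floor.
    """

    omega: float
    base_mic_a1: float = 240.0
    base_mic_b2: float = 240.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega <= 1.0):
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if self.base_mic_a1 <= 0.0 or self.base_mic_b2 <= 0.0:
            raise ValueError("base MICs must be positive")


def _check_dose(value: float, label: str) -> None:
    if value < 0.0:
        raise ValueError(f"{label} must be nonnegative, got {value}")


def _effect(scaled_dose: float, pd: PharmacodynamicParams) -> float:
    """Drug-effect term ``T(r)`` of the Regoes curve for MIC-scaled dose r.

    ``T(0) = 0``, ``T(1) = phi_max`` (zero net growth at the MIC) and
    ``T(inf) = phi_max - phi_min``.
    """
    r = scaled_dose ** pd.hill_k
    return (pd.phi_max - pd.phi_min) * r / (r - pd.phi_min / pd.phi_max)


def growth_single(a: float, mic: float, pd: PharmacodynamicParams | None = None) -> float:
    """Net growth rate under a single drug at concentration ``a``.

    Strictly decreasing in ``a``, equal to ``phi_max`` at zero dose, zero at
    ``a == mic`` and approaching ``phi_min`` at high dose.
    """
    pd = pd or PharmacodynamicParams()
    _check_dose(a, "concentration")
    if mic < MIC_FLOOR:
        raise ValueError(f"MIC must be at least the floor {MIC_FLOOR}, got {mic}")
    return pd.phi_max - _effect(a / mic, pd)


def growth_combined(
    a: float, b: float, strain: StrainProfile, pd: PharmacodynamicParams | None = None
) -> float:
    """Net growth under a suppressive (*combined*) two-drug cocktail.

    The MIC-scaled doses are pooled into one effect term,
    ``G = phi_max - T(a/mic_a + b/mic_b)``, so the result is bounded below by
    ``phi_min`` and reduces to :func:`growth_single` when one dose (and the
    other drug's contribution) vanishes.
    """
    pd = pd or PharmacodynamicParams()
    _check_dose(a, "concentration a")
    _check_dose(b, "concentration b")
    return pd.phi_max - _effect(a / strain.mic_a + b / strain.mic_b, pd)


def growth_separate(
    a: float, b: float, strain: StrainProfile, pd: PharmacodynamicParams | None = None
) -> float:
    """Net growth under an additive (*separate*) two-drug cocktail.

    Each drug contributes its own effect term,
    ``G = phi_max - T(a/mic_a) - T(b/mic_b)``; with both drugs active the
    result can fall below ``phi_min`` (double damage).
    """
    pd = pd or PharmacodynamicParams()
    _check_dose(a, "concentration a")
    _check_dose(b, "concentration b")
    return pd.phi_max - _effect(a / strain.mic_a, pd) - _effect(b / strain.mic_b, pd)


def tradeoff_mics(spec: TradeoffSpec) -> tuple[float, float]:
    """MICs of the double-resistant strain under tradeoff strength ``omega``.

    Returns ``((1 - omega) * base_mic_a1, (1 - omega) * base_mic_b2)``, each
    clamped up to :data:`MIC_FLOOR`.
    """
    mic_a3 = max((1.0 - spec.omega) * spec.base_mic_a1, MIC_FLOOR)
    mic_b3 = max((1.0 - spec.omega) * spec.base_mic_b2, MIC_FLOOR)
    return mic_a3, mic_b3


def standard_strains(
    omega: float, base_mic_a1: float = 240.0, base_mic_b2: float = 240.0
) -> tuple[StrainProfile, StrainProfile, StrainProfile, StrainProfile]:
    """The standard four-strain set (S, R1, R2, R3) for a given tradeoff.

    S is fully sensitive (both MICs at the floor), R1 resists drug A only,
    R2 drug B only, and R3 carries the tradeoff-constrained double resistance.
    """
    spec = TradeoffSpec(omega=omega, base_mic_a1=base_mic_a1, base_mic_b2=base_mic_b2)
    mic_a3, mic_b3 = tradeoff_mics(spec)
    return (
        StrainProfile("S", 0.0, 0.0, pays_cost=False),
        StrainProfile("R1", base_mic_a1, 0.0, pays_cost=True),
        StrainProfile("R2", 0.0, base_mic_b2, pays_cost=True),
        StrainProfile("R3", mic_a3, mic_b3, pays_cost=True),
    )
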