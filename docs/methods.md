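# Model and methods

## The system

`abxward` models a closed hospital ward in which patients are either
uninfected (`X`) or colonized by one of four bacterial strains: drug-sensitive
`S`, single-resistant `R1` (resists drug A) and `R2` (resists drug B), and
double-resistant `R3`. The five compartment frequencies sum to one; there is
no admission or discharge, so drug policy alone drives the dynamics.

State dynamics (per unit time, dot = time derivative):

```
Ṡ   = β X S            + σβc S (R1+R2+R3) + (G_S − γ) S
Ṙⱼ  = β(1−c) X Rⱼ      − σβc S Rⱼ          + (G_j − γ) Rⱼ      j = 1,2,3
Ẋ   = −β X S − β(1−c) X (R1+R2+R3) − Σᵢ (G_i − γ)·(compartment i)
```

* **Infection** is mass action at rate β; resistant strains transmit at
  β(1−c), the cost of resistance.
* **Superinfection**: sensitive bacteria take over resistant carriers. The
  takeover is possible precisely because resistant strains pay the
  competitive cost c, so the rate is σβc and a cost-free strain cannot be
  displaced. Resistant strains never take over `S` carriers.
* **Clearance**: each infected compartment recovers at rate −(G_i − γ),
  where γ is immune clearance and G_i the strain's pharmacodynamic net
  growth rate under the doses currently in force; recovered patients return
  to `X`. With the standard parameters G_i ≤ 0 under treatment, so the
  clearance term is never a source of infection.

The right-hand side conserves the total frequency identically (every gain in
one compartment is a loss in another), which the integrator tracks to
< 1e-9 over full trajectories.

## Pharmacodynamics

Net growth under a single drug at concentration `a` follows a Hill-type
curve with exponent k (k = 1 throughout the standard scenarios):

```
G_sgl(a) = φ_max − (φ_max − φ_min) · (a/MIC)^k / ((a/MIC)^k − φ_min/φ_max)
```

G equals φ_max drug-free, crosses zero exactly at the MIC, and saturates at
φ_min < 0. Two-drug cocktails come in two flavours:

* **combined** (suppressive pair): one effect term over the pooled
  MIC-scaled dose, `G_cmb = φ_max − T(a/MIC_A + b/MIC_B)`. Bounded below by
  φ_min — the pair can never outdamage one saturating drug.
* **separate** (additive pair): two effect terms,
  `G_sep = φ_max − T(a/MIC_A) − T(b/MIC_B)`; a strain sensitive to both
  drugs is doubly hurt and G may fall below φ_min.

Double resistance is constrained by a tradeoff ω ∈ [0,1]:
`MIC_A(R3) = (1−ω)·MIC_A(R1)` and `MIC_B(R3) = (1−ω)·MIC_B(R2)`. ω = 0 is a
super-resistant mutant, ω = 0.5 a linear tradeoff, ω = 1 a super-sensitive
one. Zero MICs are clamped to a floor of 1e-6 at construction time so the
curves never divide by zero.

## Deployment strategies

All drug-using strategies spend 240 dosage units per patient at all times:

| strategy | doses | arms |
|---|---|---|
| NONE | 0:0 | 1 |
| CONTROL | 240:0, resistant compartments pinned at 0 | 1 |
| SINGLE | 240:0 | 1 |
| CYCLING | 240:0 ↔ 0:240 ward-wide every π | 1 |
| MIXING | two half-wards in antiphase, drugs swapped every π | 2 |
| COCKTAIL (cmb/sep) | 120:120 | 1 |

MIXING duplicates each infected compartment per treatment arm: new
infections from `X` are split 50/50 between arms, superinfection acts
through the total `S` frequency, patients keep their arm while the arm's
drug flips at each period boundary.

## Numerical protocol

* Classic fixed-step RK4, default dt = 0.1; dt must divide π exactly so no
  step straddles a dose switch (doses are piecewise constant and re-read
  only at grid-aligned boundaries). A dt-halving check is part of the test
  suite.
* **Static regimens** run until the per-step sup-norm change falls below
  `convergence_tol` (default 1e-12, near the float64 floor for these
  dynamics), with an optional extra recording leg afterwards
  (`post_convergence_steps`, default 0 — it does not change the result at
  this tolerance).
* **Periodic regimens** are forced with period 2π (drug A for π, then drug
  B). Convergence is judged on per-compartment envelope (min/max) bounds of
  successive 2π blocks; comparing single π-periods would never converge
  because consecutive periods are mirror images under the R1↔R2 swap. After
  convergence, every step is averaged over `cycle_average_periods` (default
  1000) drug periods; the reported equilibrium is that cycle mean.
* **Stall detection.** The cycle-averaged X̂ is pinned by the persisting
  strain's zero log-return (see below) at exactly the value that renders
  the mirror strain neutrally stable, so CYCLING owns a one-parameter
  family of periodic orbits. Discretization drifts slowly along this family
  and the envelope difference plateaus (≈5e-10) instead of vanishing; a
  relative change below 0.1% per block for 16 consecutive blocks is
  accepted as the numerically attainable floor. Runs that exhaust
  `max_time` without meeting either criterion are flagged
  `converged=False`, never dropped.
* Default initial state: X = 0.96 with each strain at 0.01 (CONTROL:
  X = 0.99, S = 0.01, resistant exactly 0 — every resistant gain term is
  proportional to its own frequency, so the pin holds without clamping).
  Static equilibria are basin-independent across the tested starting
  points; no extinction floor is applied (compartments decay
  asymptotically).

## Analytic oracle

When a single infected strain dominates alone at a static equilibrium,

```
X̂ = (γ − G_i) / (β · (1 − c·[pays cost]))
```

This closed form is evaluated independently of the integrator and the two
agree to 1e-6 for NONE, CONTROL, SINGLE and both cocktails. With standard
parameters it gives the headline values: CONTROL 50%, SINGLE 27.78%,
separate cocktail 37.04% (ω=0) and 74.07% (ω=1), combined cocktail 27.78%
(ω=0) and 50% (ω=1).

Dominance thresholds are found by bisecting ω on the identity of the most
common strain at equilibrium (default bracket width 0.005). The combined
cocktail hands dominance from R3 to S at ω* ≈ 0.86 — exactly where the
sensitive strain's invasion condition βX̂ + σβc(1−X̂) = γ − G_S crosses —
and the separate cocktail hands it to the R1/R2 pair at ω* = 0.75.

## A structural identity, and what it implies for CYCLING/MIXING

On any bounded attractor where strain R1 persists, the time average of
d(ln R1)/dt vanishes, so

```
β(1−c)·⟨X⟩ = γ − ⟨G₁⟩_weighted + σβc·⟨S⟩ .
```

Under CYCLING, G₁ is an exogenous square wave alternating 0 and φ_min over
equal half-cycles (⟨G₁⟩ = φ_min/2) and S, R3 die out at strong tradeoff, so
the cycle-averaged X̂ is **pinned at (γ − φ_min/2)/(β(1−c)) = 41.67% for
every period π**. Under MIXING the clearance term is an occupancy-weighted
average across arms that is strictly less negative than φ_min/2 (R1 piles
up in whichever arm is not dosing drug A at the moment the arms swap), so
X̂_MIXING < X̂_CYCLING always — at π = 50 and ω = 1 the model gives
MIXING 37.6% and CYCLING 41.7%, with dominance thresholds 0.52 and 0.67.
This ordering is a theorem of the closed mass-action structure, not an
artifact of the arm reconstruction; re-randomizing patients across arms at
each boundary was also implemented and gives 37.3%, not more.

Two further consequences:

* The R1/R2 split at the CYCLING equilibrium is initial-condition
  dependent (the mirror strain is exactly neutral), so dominance is
  reported as whichever of R1/R2 leads, possibly both.
* At very long periods (π ≈ 50000) the off-drug strain must survive decay
  by factors like e^(−0.23·50000), far below the smallest subnormal
  float64. The compartment is flushed to exact zero, cannot regrow in a
  closed system, and the ward ends fully uninfected — a floating-point
  extinction effect, not a property of the exact ODE (which stays pinned at
  41.67% at every finite π).

## Parameters that matter

| parameter | meaning | default |
|---|---|---|
| β | infection rate (1/time) | 1.0 |
| σ | superinfection factor (–) | 0.25 |
| γ | immune clearance rate (1/time) | 0.25 |
| c | resistance cost (–) | 0.1 |
| φ_max / φ_min | drug-free / saturated growth (1/time) | 0.25 / −0.25 |
| k | Hill exponent (–) | 1 |
| MIC schema | R1, R2 vs own drug; others at floor | 240 / 1e-6 |
| dose budget | per patient, at all times | 240 |
| π | cycling/mixing period (time) | scenario-specific |

## Known limitations

* Strains are present from t = 0; there is no mutational origination of
  resistance, no epistasis between resistance mutations, and no
  patient-level stochasticity.
* The two cocktail forms bracket additive and suppressive drug
  interactions; synergy (which can accelerate resistance evolution) is out
  of scope.
* The closed ward ignores admission/discharge; with high patient turnover
  the pinning identity above no longer holds and cycling/mixing rankings
  can change.
* Results are equilibrium (or cycle-mean) properties; transient advantages
  of one strategy over another are not scored.
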