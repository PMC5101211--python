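# Methods

## Model and assumptions

The package models T-cell receptor (TCR) ligand discrimination as a
mass-action kinetic-proofreading chain. Free pMHC ligands P and free
receptors T associate at rate k_on·P·T into the initial complex C₀.
Each complex Cᵢ (i < N) either advances to C_{i+1} at the propagation
rate k_p(i) or dissociates at k_off(i); dissociation returns the
receptor to its unmodified state, so both molecules re-enter the free
pools. The terminal complex C_N only dissociates (no propagation out),
and its abundance is the signaling response. Amounts are molecule
counts per cell; there is no spatial structure, no receptor turnover,
no stochasticity, and one ligand species per solve.

The distinguishing assumption is that k_off(i) and k_p(i) are functions
of chain position: foreign (agonist) ligands stabilize their complexes
and accelerate propagation as proofreading progresses, self ligands do
the opposite. Profiles are materialized as explicit sequences
(`RateSchedule`) so measured or custom profiles are handled identically
to the built-in families.

## Steady state and the step-ratio convention

The closed-form steady state follows from the balance of each
intermediate complex. Because Cᵢ (1 ≤ i ≤ N−1) drains through *both*
k_off(i) and k_p(i), the step ratio is

    alpha_i = k_p(i−1) / (k_p(i) + k_off(i)).

An alternative convention with denominator k_p(i−1) + k_off(i) is
retained behind `recursion="printed"` for comparison; the two coincide
whenever k_p is constant, and only the mass-action form agrees with the
long-time limit of the ODE integrator (tested on randomized chains) —
that agreement is the decisive argument for the default. A rate system
assembled from the alternative convention is not even
conservation-consistent, so it is offered purely as a documented
algebraic variant, never integrated.

The occupancy C_T is the smaller root of
C_T² − (T_T+P_T+ε)C_T + T_T·P_T = 0, computed in the
cancellation-safe form 2·T_T·P_T/(S+√(S²−4·T_T·P_T)); the smaller root
is the physical one (C_T ≤ min(T_T, P_T)). The discriminant is provably
non-negative for valid inputs and is asserted, not re-checked.

## Sensitivity thresholds

μ, δ and ε do not depend on P_T, so the minimum ligand number for a
target terminal response solves the quadratic exactly:
C_T\* = target/δ and P_T_min = C_T\*(T_T+ε−C_T\*)/(T_T−C_T\*). When
C_T\* ≥ T_T even saturating every receptor cannot produce the target
and the threshold is reported as unreachable (rendered `>10^9` in
tabular output, matching the convention of the reference analyses).
Thresholds are real numbers — the deterministic model does not
quantize ligands — and the default target is one terminal complex per
cell, the conventional criterion for a productive response.

## Kinetics

Time courses integrate the N+3 state variables (P, T, C₀…C_N) with
LSODA (adaptive, stiff-capable) at rtol 1e−8 / atol 1e−10, with dense
interpolation between requested output points. The initial condition is
first contact: everything free, no complexes. Two exact conservation
laws (P+ΣCᵢ and T+ΣCᵢ) are monitored in tests at 1e−8 relative.

Time-resolved discrimination compares the productive fractions
C_N(t)/P_T of two ligands at a threshold time (default 10 s). It is
evaluated at P_T = 100 per cell: well below the occupancy scale
ε (~5×10³–3×10⁴ for the canonical chains) the response is linear in
P_T, making the ratio insensitive to the exact ligand count. Linearity
is tested across three decades of P_T chosen below ε (deviation
≤ 0.1%); at P_T = 10³ the exact occupancy correction of the binding
quadratic already contributes ~1%, which is a property of the model,
not of the integrator.

## Parameters

Defaults follow the standard per-cell parameterization of this
literature: T_T = 2×10⁴ receptors, k_on = 5×10⁻⁵ (molecule·s)⁻¹,
k_p(0) = 1 s⁻¹, k_off(0) = 1/τ with τ the C₀ lifetime (2 s for the
canonical equal-lifetime ligand pair). Saturating-response tables use
P_T = 10⁷. The canonical discrimination pair uses hyperbolic profiles
with shape r = 2.5/0.5 (foreign k_off/k_p) and 0.5/2.5 (self); the
model-comparison chains use geometric k_off with r = 0.95 (foreign) /
1.05 (self) paired with geometric k_p r = 1.05 / 0.95 at N = 20. The
McKeithan baseline uses c = 0.2 for its terminal-step stabilization
unless overridden.

The induced-rebinding baseline folds rebinding into effective
off-rates k_off·λ/(λ+ρᵢ) — the escape probability of a just-released
ligand that rebinds at ρᵢ while its signaling state decays at
λ = 10⁴ s⁻¹. The default ρ profile is 10³ s⁻¹ up to position 21,
ramping log-linearly (the rates span four decades) to 10⁷ s⁻¹ at
position 25. This effective-rate reduction reproduces both qualitative
regimes — near-classic behavior at N = 20 (within a few fold; the 9%
per-rate attenuation still compounds over the chain) and
orders-of-magnitude sensitivity gain with lost specificity at N = 25 —
but is an approximation, not a re-derivation of the full rebinding
state space.

## Numerical choices

- Chains of length N = 1 use the empty-product convention γ₀ = 1.
- P_T = 0 short-circuits to the zero solution.
- The ODE-vs-closed-form cross-check runs chains of N ≤ 6 with rates in
  [0.2, 4] s⁻¹ to a horizon of 60 slowest-rate time constants,
  agreeing at 1e−5 relative; randomized cases are seeded for
  reproducibility.
- Frozen expected values in the tests were computed with an independent
  exact-rational solver (sympy matrix solve of the balance equations
  plus the binding quadratic), not with the implementation's recursion.

## Known limitations

- Deterministic mass action only: no stochastic (Gillespie) dynamics,
  no cell-to-cell variability, no spatial effects or synapse geometry.
- One ligand species per solve; no competition between ligands.
- The rebinding baseline is an effective-rate approximation (above).
- The time-resolved discrimination ratios depend on the full transient
  of the chain and therefore on the exact kinetic scheme; the
  steady-state quantities are scheme-independent given the rates.
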