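# Methods

## Scope and assumptions

The package operates on time-homogeneous Markov chains over a finite
state space Ω of n ≥ 2 labeled states, whose dynamics are given
exhaustively by a row-stochastic transition probability matrix (TPM).
Matrix entries are read as interventional probabilities `P(e | do(c))`:
the cause is imposed, not observed, so the TPM *is* the causal model.
There is no estimation step — all quantities are computed from known
probabilities. Structural causal models with exogenous noise variables
are out of scope; the probability-of-necessity/sufficiency family is
included only through its simplified expressions, which under exogeneity
and monotonicity coincide with the Eells, Lewis and Cheng measures (the
package asserts those aliases bitwise).

State labels may optionally be fixed-width binary strings. All
Hamming-based constructions (local intervention balls, closest possible
worlds, bit flips) require them; the bit-flip measure further requires
the full hypercube so that every single-bit perturbation of a state is
itself a state. Bits are indexed most-significant-first.

## Causal primitives and measure conventions

With `s = P(e|c)`, `q = P(e|C\c)`, `v = 1 − q`, `m = P(e|C)`:

| measure | value | flagged cases |
|---|---|---|
| galton | `P_C(c)(1−P_C(c))(s+v−1)` | — |
| eells (= pearl_pns) | `s+v−1` | — |
| suppes | `s−m` | — |
| cheng (= pearl_ps) | `(s+v−1)/v` | undefined at v=0 |
| good | `log₂(v/(1−s))` | +∞ at s=1; −∞ at v=0; undefined at both |
| lewis (= pearl_pn) | `(s+v−1)/s` | −∞ at s=0<q; undefined at s=q=0 |
| lewis_cpw | `(s−P(e|c̄))/s`, c̄ = nearest state | ties averaged |
| bit_flip | `(1/N)Σᵢ Σₑ' P(e'|c[i]) D_H(e,e')` | no P_C used |
| effect information | `log₂(s/m)` | ±∞ at s=0 or m=0 |

System level: `EI = Σ P_C(c)P(e|c) ei(c,e) = log₂ n (det − deg)` and
`eff = EI/log₂ n`. Entropies are in bits with `0·log₂(1/0) = 0`.
Transition-level determinism/degeneracy coefficients at zero probability
are −∞ by convention (returned flagged rather than raised) so that
system-level averages, which weight them by zero, stay finite; the
averages skip zero-weight terms. Negative measure values (preventive
causes) are reported as-is, never clamped.

Expectations weight transitions by a joint `P(c,e) = P_w(c)P(e|c)`. The
default `P_w` is the stationary distribution (the convention for
system-level summaries here); the effective-information convention
(`P_w` = the intervention distribution itself) and custom vectors are
selectable through `ExpectationPolicy`. Undefined (0/0) terms are
excluded from expectations with a logged warning; included infinities
propagate, and a +∞/−∞ clash renders the expectation undefined. A
consequence worth knowing: the Lewis average `E[(s−q)/s]` telescopes to
exactly 0 only when every row has full support. On the bipartite model
(whose cross-group entries are structurally zero) the skipped terms
break the telescope and the average is positive; on the noisy NAND model
(strictly positive rows) it is 0 to machine precision.

## Intervention distributions

- **maxent** — uniform `1/n`; the exhaustive, unbiased probe.
- **observational** — the stationary fixed point π = πT, computed by
  averaged power iteration `μ ← (μ + μT)/2` from the uniform start,
  tolerance 1e−12 on `max|μT − μ|`, cap 10⁵ iterations (failure raises
  with the residual). Averaging the iterate with its image maps every
  eigenvalue λ of T to (1+λ)/2, so only the stationary subspace
  survives: period-2 oscillation (the bipartite chain) is damped
  geometrically, and for reducible chains with several fixed points the
  limit is the projection of the uniform start onto the stationary
  subspace — the same point the Cesàro average of the plain iteration
  reaches, reported in the distribution's metadata as the
  `uniform-cesaro` convention since the choice among multiple fixed
  points is a convention, not a theorem.
- **local(center, Δ)** — uniform on the Hamming ball
  `{s : D_H(s, center) ≤ Δ}`, center included. Default Δ = 1: the
  minimal non-degenerate neighborhood, one flip around the actual state.
  In per-transition measures and in expectations the ball is re-centered
  on each cause under scrutiny.

Excluding a cause with `P_C(c) = 0` is a no-op (renormalization by 1);
excluding one with `P_C(c) = 1` has no counterfactual mass and raises.

## Model systems

**Bipartite chain** (defaults n_a = n_b = 8, 4-bit labels; group A counts
up from 0000, group B counts down from 1111). Every A-state transitions
only into B and vice versa. `dilution` d ∈ [0,1] sets the main-target
mass `d + (1−d)/n_opp` against `(1−d)/n_opp` elsewhere in the opposite
group (d=1 deterministic, d=0 uniform-within-group). `rewiring`
g ∈ [0,1] reduces the number of distinct main targets to
`t = max(1, round((1−g)·n_src))`, assigned round-robin onto the first t
opposite-group states (g=0 bijective, g=1 fully convergent). At g=0 the
main map is the bitwise complement (0000 → 1111). The two-group
coarse-graining yields the macro TPM [[0,1],[1,0]] for *every* (d,g) —
this is the model's point: microscale noise varies freely under a fixed,
perfectly deterministic, non-degenerate macroscale. The asymmetric
variant (n_a ≠ n_b) uses the same generator.

**Noisy NAND network** (defaults 2 gates, noise 0.1). Each gate outputs
the NAND of the full previous gate vector — its own value included, which
is what makes two gates bistable (11 → 00, everything else → 11) and
matches the generated probability P(00|11) = 1 − noise. Noise is applied
at the state level: the logical target keeps `1 − noise`, the remaining
mass spreads uniformly over the other `2^n − 1` states. (Independent
per-gate flips would give P(00|11) = (1−noise)² instead.) Macroscale:
all-ON ↦ ON, everything else ↦ OFF. Degeneracy grows with the gate
count, determinism falls with noise — unlike the bipartite model, the
macro TPM is *not* fixed under these changes.

Both generators are deterministic functions of their spec. What they
emulate is noise structure (indeterminism vs. convergence), not any
empirical system: passing tests show the measures behave lawfully under
controlled uncertainty, not that any real system is causally emergent.

## Coarse-graining and causal emergence

A coarse-graining is a total, single-valued map h (supervenience by
construction). The macro TPM blends the micro rows of each group with
per-group aggregation weights — an intervention distribution restricted
and renormalized within the group, uniform by default (and uniform as
fallback for zero-mass groups). For the bipartite family the result is
weight-independent; `supervenience_check` quantifies this as the largest
within-group disagreement of induced macro rows, so a zero residual
certifies that the macroscale is well-defined regardless of the
aggregation convention. For general TPMs the residual can be positive
and the default is an explicit convention, recorded in the report.

`CE = CS_macro − CS_micro` per transition (the macro transition is the
h-image of the micro one) or in expectation. ±∞ propagates through the
subtraction — a −∞ micro value (preventive cause under a log measure)
against a finite macro value yields CE = +∞ — while ∞−∞ and undefined
inputs are flagged undefined, never silently NaN.

Macro state labels carry no bit structure, so Hamming-based
constructions at the macroscale use fresh minimal-width binary codes in
macrostate order. With two macrostates this makes the local intervention
coincide with maxent (the only counterfactual of one state is the
other), and gives the macro bit-flip measure the value 1 on a
deterministic flip-flop. A consequence, reproducible analytically: on
the symmetric bipartite grid the micro bit-flip value of a main
transition is `(7−3d)/4 ≥ 1` and of the first secondary transition
`(7−d)/4 ≥ 1.5`, so bit-flip CE never exceeds 0 there (it peaks at
exactly 0 at full dilution). Bit-flip does exhibit positive CE in the
NAND system (micro ≈ 0.13 vs macro ≈ 0.97 for the recovery transition
00 → 11 at noise 0.1). This is the expected behavior of a label-bound
measure that is not grounded in the causal primitives; any alternative
macro label geometry (e.g. inheriting micro representatives) would be an
equally arbitrary convention and is not implemented.

**Sweeps** cover an 11×11 (d,g) grid × three scopes (main transition,
secondary transition, expectation) for the eight primitive-based
per-transition measures by default (bit-flip is available on request),
emitting one tidy row per cell. The cross-measure summary normalizes
each measure's finite CE values by the measure's maximum |CE| over the
grid and averages across measures per cell; infinite and undefined cells
stay out of both the normalizer and the average. On this summary the
noisy/degenerate corner (d=0, g=1) scores distinctly higher than the
deterministic/non-degenerate corner (d=1, g=0), where causal reduction
dominates (for effective information under maxent the reduction at
(1,0) is exactly `1 − log₂ 16 = −3` bits).

## Numerical choices

- Probability validation tolerance 1e−9 on row sums and weight vectors;
  inputs within tolerance are renormalized once and trusted thereafter,
  larger violations are rejected naming the offending row.
- Stationary solve: tolerance 1e−12, max 10⁵ iterations (see above).
- Closest-possible-world ties (several equidistant neighbors) average
  the measure over all minimizers, preserving label-permutation
  invariance; a −∞ branch dominates the average.
- Main/secondary transition labels are structural (from the generator's
  target map). At d = 0 every transition ties, so the strict API refuses
  to name a main transition; sweeps use the structural map throughout.
- Undefined values serialize as empty cells plus a `defined=False`
  column; infinities as `"inf"`/`"-inf"`.

Problem sizes throughout the test suite and reference scripts are the
study defaults: 16-state bipartite models, 2–3-gate NAND networks,
random 3–8-state chains for oracle comparisons, and the full 11×11
parameter grid for sweeps.

## Known limitations

- No search over candidate coarse-grainings, no apportioning of CE
  across scales, no black-boxing: a single user-supplied macroscale is
  scored against its microscale.
- No estimation from sampled trajectories or partial observability —
  exact TPMs only — and no confidence statements.
- Mutual-information-style "information flow" measures are deliberately
  absent; effective information under the observational distribution
  already reduces to the mutual information of the stationary joint
  (asserted in the tests), and that special case is the known blind spot
  where macroscale gains vanish.
- The Lewis measure's expectation identity (zero average) and the
  bit-flip measure's macro-label sensitivity, both discussed above, make
  those two the least comparable members of the catalogue; they are kept
  because the catalogue aims at coverage of the literature, not at
  endorsement.
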