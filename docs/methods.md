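# Methods

## Model

A probabilistic linguistic fuzzy cognitive map is a directed graph
G = (C, E, X, f): concept nodes C with PLTS-valued states, edges E with
PLTS-valued influence weights, a state mapping X, and a threshold f.  States
live on a symmetric state scale (default granularity τ = 5, eleven terms);
weights on a weight scale (default τ = 3, from "very strong negative" to
"very strong positive" impact).  Exactly one node is the outcome; the rest
are candidate factors.  Self-edges are excluded — each node's own state
enters its update explicitly.

All computation happens in membership space through the affine bijection
g(α) = (α + τ)/(2τ) and its inverse g⁻¹(η) = (2η − 1)τ.  Memberships
combine with the probabilistic sum / algebraic product pair; probabilities
multiply across Cartesian pairings, and the duplicate memberships those
pairings can produce are merged by summing probability (bounding growth
while preserving the distribution).

## Alignment

Before iterating, every PLTS is expanded to a common position template: the
ascending union of all term indices appearing in any state or weight.

* **States** are term-aligned: probability zero at absent template
  positions, membership g(template term) on the state scale.  Every node
  therefore starts from the same membership row (the case-study template
  (s−3, s0, s3) maps to (0.2, 0.5, 0.8)), and node trajectories differ only
  through incidence and edge content.
* **Weights** are padded positionally to the template length by
  zero-probability copies of their smallest term, and position k of a
  weight pairs with position k of the source state.  A weight's membership
  at a position is g of its *own* padded term on the weight scale, not of
  the template term.

The weight convention is a deliberate design choice.  The alternative —
term-aligning weights too — forces every edge's membership at the lowest
template position to g(−τ_w) = 0, so that position updates as
x ← tanh(x), which decays only algebraically at λ = 1: the flagship
configuration would never reach a 1e-6 fixed point.  Positional pairing
instead lets a "very strong positive" singleton weight exert full influence
at every position, reproduces the saturation pattern expected of strongly
driven maps, and keeps λ = 1 dynamics geometrically convergent wherever a
node has at least one positive driver.

## Iteration

Per node i and position k, with incoming edges j → i:

    a_i^k   = 1 − ∏_j (1 − η_j^k · w_ji^k)          (membership aggregate)
    η_i^k   ← f(η_i^k + a_i^k − η_i^k a_i^k)
    b_i^k   = 1 − ∏_j (1 − p_j^k · q_ji^k)          (probability aggregate)
    p_i^k   ← f(p_i^k + b_i^k − p_i^k b_i^k), row renormalized to sum 1

with f(x) = tanh(λx).  The threshold is applied to the probability channel
before renormalization by default (`prob_apply_threshold`; the alternative
of skipping f there is a configuration flag, since steady probability rows
cannot discriminate the two).  Applying f to inputs in [0, 1] keeps every
membership in [0, tanh λ] after the first step; probability rows sum to one
at every recorded step by construction.  Because the membership update never
reads probabilities, two maps identical up to probabilities have bit-equal
membership histories — the exact sense in which the probability-free
(hesitant) degenerate model "iterates identically".

**Terminal classification.**  Fixed point: max-norm change across both
channels ≤ tol (default 1e-6).  Limit cycle: the state recurs within a
sliding window (default 50 steps) at the same tolerance, with the recurrence
distance reported as cycle length.  Chaotic: the cap is hit (default
max_iter = 2000; measured convergence at λ = 1 typically takes 600–1100
steps because the renormalized probability channel contracts slowly near
its fixed point, so 500 would misclassify healthy runs).  The tanh update
itself was never observed to cycle (randomized search over thousands of
small maps); the limit-cycle path is exercised through the pluggable
threshold hook, and genuinely arises in the signed crisp baseline.

**Numerical conventions.**  Probability sums are validated at 1e-9;
transformation round trips hold to 1e-12; Cartesian-operator merging keys
memberships at 12 decimals.  Iteration-produced PLTSs keep *all* template
positions: coincident term values (distinct positions saturating to the
same tanh fixed point, bit-identically) are not merged and not re-sorted,
because merging or reordering tied positions misaligns probabilities across
nodes and corrupts distances precisely in the saturated regime; ascending
order is validated with a 1e-9 slack for ulp-level rounding on plateaus.
Term distinctness is enforced where users supply PLTSs (parser, pooling);
continuous term indices are permitted in iteration outputs, since the score
and the inverse transformation are naturally real-valued.

## Ranking and similarity

At a fixed point, memberships are mapped back through g⁻¹ (probabilities
from the final probability channel) into one steady PLTS per node.  The
distance between two PLTSs normalizes, pads to the common length l, aligns
positions in ascending term order, scalarizes each position as
membership × probability, and takes the root-mean-square difference; the
similarity recalibrates the distance through a decreasing Z mapping,
S = (Z(d) − Z(1))/(Z(0) − Z(1)), for Z ∈ {1−t, (1−t)/(1+t), 1−t·e^{t−1},
1−t²}.  S lies in [0, 1], is symmetric, equals 1 iff d = 0 and 0 iff d = 1
(for extreme single-term PLTSs, the complement relation).  Because every Z
form is strictly decreasing, rank vectors are invariant to the Z choice;
ties receive mean ranks, and first-level groups score by the mean rank of
members (lower = more influential).

The membership × probability scalarization inside the distance is a
convention (the position-wise scalar is not otherwise pinned down); it is
applied after normalization and padding, uniformly in the main method,
while the hesitant baseline drops the probability factor and the crisp
baseline compares scalar activations directly.

## Baselines

* **Hesitant (probability-free)**: iterates the membership channel alone —
  implemented as an independent loop so its bit-identity with the full
  engine's membership channel is a checkable property, not a tautology —
  and measures similarity on steady membership vectors with uniform
  position weights.
* **Classical crisp map**: states defuzzify by score followed by g
  (unsigned, [0, 1]); weights by score divided by τ_w (signed, [−1, 1]);
  update x_i ← tanh(λ(x_i + Σ_j x_j w_ji)); similarity from |x_i − x_R|,
  clipped to [0, 1] before the Z mapping (mixed-sign steady activations can
  otherwise exceed unit distance).  With signed weights this system can
  genuinely oscillate — negative feedback loops produce limit cycles on
  some random matrices — which the nonnegative two-channel model avoids.

## Sensitivity

The Z sweep reuses one fixed point across the four Z forms and reports a
rank-agreement flag.  The λ sweep re-runs the full pipeline per steepness
value (default grid 2, 3, 4, 6, 8, 10) and reports the similarity spread
(max − min).  Steeper thresholds saturate activations and typically shrink
the spread toward zero; on maps with structurally inactive probability
positions (a position with zero initial probability and no incoming
probability mass stays at zero) a similarity floor persists and the spread
plateaus instead — the shrinkage is a property of fully activating maps,
not of the method as such.  As λ → 0 all activations collapse toward zero
and every similarity tends to 1 (no discrimination).

## Synthetic generator

The seeded generator emulates the *shape* of expert-elicited health maps:
factor nodes plus one outcome; three-term states (s−3, s0, s3) on the τ = 5
scale with Dirichlet-distributed probabilities (survey-proportion-like,
concentration 1 = uniform on the simplex); edge weights as contiguous runs
of one to three terms on one side of the weight scale (a pooled panel
rarely spreads mass across both signs), with a configurable negative share
(default 0.3, minority-negative as in health determinant maps); directed
density 0.3 by default; and at least one positive-leaning incoming edge per
node, as in elicited maps where every concept has a reinforcing driver
(this also keeps λ = 1 dynamics away from the pure-decay regime).  It does
*not* emulate: correlated edge structure (hierarchies of first-level
groups), expert disagreement patterns, or calibrated effect sizes — so
passing tests demonstrate mechanical correctness and invariants on random
structures, not predictive validity on real panels.

## Known limitations

* The expert-elicited connection matrix of the packaged case study is not
  redistributable; without it the fixture supports algebra and
  defuzzification, and full-pipeline behaviour is validated on synthetic
  matrices supplied through the same CSV dialect.
* Linguistic hedges ("at least medium") are out of scope; only explicit
  term:probability sets are parsed.
* Only the Euclidean-style PLTS distance is implemented (no Hamming or
  Hausdorff variants), and no weight-learning algorithms are provided.
* At λ = 1 a node position with no positive incoming influence decays as
  tanh(x) — algebraically slowly; such maps legitimately classify as
  non-convergent at practical caps.
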