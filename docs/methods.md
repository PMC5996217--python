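# Methods

## Model

Policies are decision-making units. For policy *o* with input vector
`x_o ≥ 0` and output vector `y_o ≥ 0`, the standard score is the optimum of
the input-oriented radial envelopment LP; under variable returns to scale
(VRS) the composite weights λ are convex (Σλ = 1), under constant returns
to scale (CRS) the convexity row is dropped. Only the input orientation is
implemented: it is the orientation consistent with the published score
tables this package reproduces, and the one that reads naturally for
policy-making ("by how much could this policy's resource use shrink?").
Output-oriented and slack-based (SBM) variants, weight restrictions and
bootstrap intervals are out of scope.

The multiplier-form weights u (outputs) and v (inputs) are recovered as the
duals of the envelopment constraints and reported non-negatively. No
non-Archimedean ε-perturbation and no second-phase slack maximization is
applied: the radial θ alone is contractual, matching the single radial
scores of the published tables. λ and the duals are reported as the solver
returns them; under degeneracy alternative optimal bases exist and only θ
is guaranteed.

### Signed outcomes

An outcome column may be negative for some policies (financial risk
*created* rather than averted, a negative equity score). Each cell is split:
`max(v, 0)` stays in that outcome's output column, `max(−v, 0)` goes to an
adverse-part input column. The adverse column is created only when at least
one policy is negative in the outcome — an all-zero input column is inert in
the radial model. Zero splits to (0, 0); no column is forced nonzero. No
linear translation of negative data is ever applied: shifting every
policy's financial-risk outcome until the worst is zero would assert that
patients are indifferent between "this policy impoverishes nobody" and
"every other policy impoverishes even fewer", which is not a defensible
reading of the data. Column order is deterministic (resource inputs, then
adverse parts in outcome order) so LP bases and duals are reproducible.

When the evaluated policy has a zero entry in an input column — typical for
adverse-part columns — the constraint degenerates to `Σ λ_k x_kj ≤ 0` and is
enforced: composites may not use policies that produce that adverse outcome.
This is what makes an adverse-free policy hard to imitate, and it is
deliberately kept active in the fallback's first stage too (see below).

### Superefficiency and the infeasibility fallback

The rank-capable score excludes the evaluated policy from its own reference
set; scores above 1 measure the margin by which the rest of the set fails
to match it. Under VRS the excluded program can be infeasible — exactly when
the policy holds an output level (or an adverse-free profile) outside the
convex hull of the others. Such a policy is on the frontier by definition
(its standard score is 1), and is scored lexicographically in two stages:

1. maximize the output-retention factor `s ∈ (0, 1]` subject to
   `Σ λ y_kr ≥ s y_or`, convexity, and the zero-input rows of the evaluated
   policy (`Σ λ x_kj ≤ 0` where `x_oj = 0`); radial input rows with
   `x_oj > 0` are dropped in this stage;
2. with `s*` fixed, minimize θ subject to all input rows and
   `Σ λ y_kr ≥ s* y_or`;
3. score `θ* + 1/s*`.

A retention shortfall (s* < 1) inflates the score through `1/s*`, mirroring
how an input margin inflates θ for feasible superefficient policies; the
score always exceeds 1. The two stages are solved in that order because a
single LP cannot trade off s against θ without an arbitrary weighting. The
fallback runs only on solver-certified infeasibility, never on
large-but-feasible scores. If even stage 1 is infeasible (the zero-input
rows exclude every reference policy), the policy is reported non-rankable
and placed last with an explicit flag.

One published fallback value (6.59 for the all-three policy combination in
the surgical-access example) is consistent with `1 + 1/s*` rather than
`θ* + 1/s*` (≈ 6.15); the formulation above is retained because it
reproduces the other three published fallback scores (2.36, 2.75, 4.82),
and the discrepant value is documented in the exclusion tests rather than
targeted.

### Cost-effectiveness baseline

`cea_frontier` projects the table on one (cost, effect) pair: pairwise
dominance first (cost ≤, effect ≥, one strict; identical pairs resolve
against the later row), then ICERs along the cost-ordered survivors with a
do-nothing origin at (0, 0). A non-increasing ICER step marks the
*intermediate* policy extended-dominated (a mix of its neighbours buys
effect more cheaply), and the walk iterates to a fixed point, after which
the ICER sequence is strictly increasing. Published tables sometimes quote
an ICER against a predecessor that extended dominance would remove; the
`previous-survivor` comparator convention reproduces that reading, while
`frontier` (the default) chains through frontier policies only. DEA and
frontier computations are independent: dominated policies keep well-defined
superefficiency scores.

Monetary columns published in thousands carry their scale as table
metadata; radial scores are scale-invariant, so the scale is applied only
when ICERs are displayed in absolute dollars.

## Numerical choices

LPs are solved with HiGHS via `scipy.optimize.linprog` (deterministic,
single-threaded); solver-certified infeasibility is distinguished from
numerical failure, which raises. Scores are kept at full precision and
rounded to two decimals only in reports; ranks are computed on unrounded
scores, with ties broken by lower total resource input, then by name. An
optimal stage-1 retention below 1e-9 is treated as non-rankable rather than
scored (1/s would be numerically meaningless). The test oracle enumerates
all basic solutions of the envelopment program (subsets of active
constraints of full cardinality), checks feasibility with a data-scaled
tolerance, and takes the vertex minimum; it is restricted to ≤ 6 reference
policies and ≤ 5 total columns.

## Synthetic data

The generator emulates the structure of published extended
cost-effectiveness league tables: strictly positive costs drawn uniformly
from (100, 10 000) US$, outcome magnitudes uniform in (1, 1000), and each
outcome cell negated independently with probability `neg_fraction`
(default 0.2, matching the minority-adverse pattern of the bundled
examples: 3 of 12 and 7 of 36 cells). It does not emulate correlation
between cost and effect, shared cost structure between policy combinations
(the bundled fixtures contain policy bundles whose costs are sub-additive),
or heavy-tailed outcome distributions; passing property tests on synthetic
tables therefore demonstrates correctness of the optimization and the
split, not realism of any particular policy mix. With `plant_dominator`,
the last policy strictly dominates all others (0.9× every cost minimum,
1.1× every benefit maximum) and one random policy is kept adverse-free so
the dominator always has a feasible stage-1 composite and is rankable.

## Problem sizes

Every bundled program has at most 10 variables and 12 constraints; the full
test suite solves a few thousand such LPs plus ~400 vertex enumerations of
≤ 7-variable systems, and the acceptance script solves 22 LPs. These sizes
are the published case studies' own (6–9 policies); the method itself has
no intrinsic size limit beyond LP tractability.

## Known limitations

- Only quantified attributes enter the analysis; qualitative attributes
  (e.g. verbal equity descriptions) must be quantified upstream or omitted,
  and the bundled three-policy illustration omits its qualitative equity
  attribute for exactly that reason.
- The superefficiency score of a fallback-cased policy is not on the same
  scale as a feasible θ; both exceed 1 and rank usefully, but the two
  families should not be compared as cardinal magnitudes.
- λ and dual weights under degenerate optima are solver-dependent.
- Two rows of one published table print 1.00 although strictly dominated in
  the printed data; no radial model reproduces them, and the exclusion
  tests document the contradiction.
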