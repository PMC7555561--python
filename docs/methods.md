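# Methods

## Model

`rlca` fits exploratory latent class models (LCMs) to wide-format categorical
item responses.  For I items with categories `0..K_i` and C latent classes,
items are conditionally independent given class membership U:

    P(X = x) = Σ_c p_c Π_i P(X_i = x_i | U = c).

Item response probabilities are parameterized by multinomial logits
`γ_ikc = log(p_ikc / p_i0c)` with the reference category 0 fixed at zero, and
class probabilities by logits `δ_c` with `δ_1 = 0`.  Dichotomous items are the
`K_i = 1` case; there, category 1 is conventionally the correct response and
`γ_i1c` its log-odds.  The raw parameter dimension is
`Σ_i K_i·C + C − 1`.

By convention, category 0 of a polytomous multiple-choice item is the correct
option and categories `1..K_i` the distractors ordered by attractiveness
(selection frequency); the `io` recoding utilities produce exactly this
coding from raw option codes.

## Fused regularization

Exploratory LCMs are heavily parameterized, and estimates are unstable at
realistic sample sizes.  The regularized LCM (RLCM) subtracts from the
log-likelihood a penalty on pairwise differences of item logits,

    ℓ(γ, δ) − N Σ_i Pen(γ_i; λ),

so that parameters whose differences are driven to zero merge into shared
values.  Penalizing all pairwise differences (fused regularization) extends
naturally to polytomous items, where five fusion strategies are available:

- `fused_classes` (λ1): per category, all class pairs — merges classes that
  behave alike on a category;
- `fused_categories` (λ2): per class, all category pairs — merges distractors
  that behave alike within a class;
- `fused_both` (λ1, λ2): the sum of the two, searched on a 2-D grid;
- `group_categories` (λ2): penalty on the Euclidean norm of the whole
  difference vector of two category rows, so two distractors merge across
  *all* classes or not at all;
- `group_classes` (λ1): the same block decision for two class columns.

λ1 always denotes class-fusion strength and λ2 category-fusion strength,
for grouped as well as element-wise fusion.

Penalty families: LASSO `λ|x|`, MCP `λ|x| − x²/(2a)` for `|x| ≤ aλ` then
constant `aλ²/2`, and SCAD (linear to λ, quadratic blend to `aλ`, constant
`(a+1)λ²/2` beyond).  Defaults `a = 3` (MCP) and `a = 3.7` (SCAD) are the
conventional choices.  MCP/SCAD plateau beyond a threshold, so large,
genuinely distinct differences are not shrunk — the reason they are
preferred here over LASSO.  The penalty acts on the logit scale: differences
between extreme probabilities count for more than on the probability scale,
which is intentional, since the logits are what the optimizer moves.

## Estimation

A penalized EM algorithm maximizes the objective:

- E-step: posterior class memberships by Bayes' rule, computed on the table
  of unique response patterns (all sufficient statistics depend on the data
  only through pattern counts, making iteration cost independent of N for
  discrete data).
- M-step, class part: closed form, `p_c` = mean posterior.
- M-step, item part: separates over items because the penalty is item-wise.
  Each item's posterior-weighted multinomial log-likelihood minus `N·Pen` is
  maximized by L-BFGS-B with an analytic gradient.  With no active penalty
  the closed-form weighted-frequency solution is used instead.

The penalty is non-differentiable at fused points; `|x|` is replaced by
`sqrt(x² + ε)`.  The fit runs a main phase at ε = 1e-4 and a refinement
phase at ε = 1e-6; in practice fused logit differences end below 1e-4 while
distinct ones stay above 0.1, so fusion is numerically unambiguous.  The
smoothed penalized objective is non-decreasing across EM iterations within
each phase (asserted to 1e-6 slack in the tests).

Mixture likelihoods have multiple maxima, so unpenalized fits default to 10
random starts (γ drawn uniformly in ±logit(0.8), δ at uniform).  Convergence:
successive smoothed objectives within 1e-6 *and* max |Δγ| below 1e-4, with a
500-iteration cap.  Classes whose probability collapses below 1e-6 are
floored with a warning.  Probabilities are clamped to [1e-12, 1−1e-12]
before logs, since regularized fits can push logits to large magnitudes.

Label switching: for comparison against a generating design, class labels
are matched by the permutation minimizing the total absolute difference of
probability tables (exhaustive, C ≤ 8).

## Model selection

The effective dimension of a regularized fit counts fused parameters once:
per item, parameters are grouped by the transitive closure of "penalized
pairwise difference below `fuse_tol`" (default 0.01 on the logit scale,
applied after refinement; single linkage so a chain a≈b≈c is one group).
`n_params = Σ_i #groups + (C − 1)`; `n_regularized` is the number of item
parameters merged away.  With no active penalty the raw count is reported —
equality of unpenalized estimates is a measure-zero event and exploratory
models are conventionally counted by their raw dimension.

AIC = −2ℓ + 2k and BIC = −2ℓ + k log N use this count.  λ is selected by
minimizing a criterion over a grid (default `0.01, 0.02, …, 0.30`,
extensible; 2-D Cartesian grids for `fused_both`).  The path is traversed
from small to large λ, each point warm-started from the previous solution;
the path root is the multi-start unpenalized fit.  One warm start per grid
point is the default (`starts_per_point`): path following from the root is
the standard approach and additional cold starts at large λ converge slowly
while rarely improving the path solution.  Non-converged points are flagged
and excluded from best-by-criterion selection.  `regularization_path`
extracts fitted probabilities per λ for plotting; merge events appear as
columns coinciding.

## Partial order of classes

From an `(I × C)` table of correct-response probabilities, class c is below
class d if `p_ic ≤ p_id` for all items; with tolerance ι, if at most ι items
violate the inequality.  Exact ties satisfy the weak inequality in both
directions, so exactly tied classes are mutually comparable — documented
rather than broken arbitrarily.  At ι = 0 the relation is a genuine partial
order; at ι > 0 transitivity can fail, in which case the report warns and
emits the transitive reduction of the raw strict relation.  For polytomous
fits the order is computed on category-0 (correct-response) probabilities by
convention.  `class_summary` reports the per-class mean correct probability
as a proficiency ranking.

## Synthetic data

`fixture_design` bundles the two study designs used throughout the tests:
12 dichotomous items (4 classes, class probabilities 0.30/0.20/0.10/0.40,
six item-parameter rows duplicated to twelve items, 22 of 48 item
parameters redundant by design) and 12 four-category items with equality
structure across both classes and categories.  `simulate` draws class
membership and responses from one integer seed.  The generator reproduces
exactly the multinomial mixture the model assumes — no misfit, no missing
data, no local dependence — so passing recovery tests demonstrates correct
estimation under ideal conditions, not robustness on real data.

`datasets.synthetic_spm_ls_raw` is a synthetic stand-in for the raw SPM-LS
responses (which must be downloaded separately): per-item option frequencies
match the published percentage table deterministically, but the person-level
dependence structure does not, so it exercises recoding/frequency logic
only.

## Replication studies and problem sizes

The acceptance script and the heavier tests replicate the simulated-data
analyses at N = 1000, C = 4: exploratory fits over several seeds; an MCP
fused-class search over λ ∈ {0.01, …, 1.00} (dichotomous); and a
fused-categories search over λ2 ∈ {0.01, …, 0.60} (polytomous).  The test
suite uses slightly coarsened grids (steps 0.02–0.05, and a 0.1-step 2-D
grid for `fused_both`) — grid resolution beyond that does not change which
fusion structure is selected.

One replication finding is worth flagging: on data simulated from the
polytomous design, the two-direction fused penalty (`fused_both`)
consistently attains a *lower* BIC than category-only fusion across seeds.
The design genuinely contains equality structure in both directions and the
2-D search space essentially nests the category-only fits, so this is the
expected behavior of the method; the corresponding ranking assertion in the
acceptance tests documents the discrepancy with the original report rather
than hiding it.

## Limitations

- Missing responses are rejected, not imputed.
- No standard errors or inference on fused parameters.
- Exhaustive label matching limits truth comparison to C ≤ 8.
- 2-D grids are full Cartesian products; no adaptive refinement.
- Identifiability of the restricted models induced by fusion is assumed,
  not verified.
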