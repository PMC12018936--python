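# Methods

This note documents the models, conventions and numerical choices behind
`paleocroc`, in the spirit of a package methods appendix: what is assumed,
what is configurable, and what the tests do and do not demonstrate.

## Parsimony scoring

Tree length is the generalized Sankoff dynamic program.  Each character has
a step-cost matrix: unordered characters cost 1 between any two distinct
states (Fitch); ordered morphocline characters cost `|i − j|` along the
integer cline (Wagner).  Costs are symmetric, zero on the diagonal, and
ordered costs satisfy the triangle equality along the cline, so the
dynamic program is exact.

* **Missing and inapplicable cells** (`?`, `-`) enter the tip pass with
  cost 0 for every state: they contribute nothing to the length anywhere on
  the tree.  Inapplicable scores are deliberately not given a separate
  reductive coding; they are treated as missing, the standard practice.
* **Polymorphic/ambiguous scores** `[ij]` cost 0 for member states and are
  otherwise excluded — polymorphism-as-uncertainty, not as "requires all".
* **Polytomies** are scored as hard polytomies (the sum over all children of
  a node); consensus trees are scored for reporting only, search operates on
  binary trees.
* **Ancestral states** are full MPR sets: a state belongs to a node's set
  iff some minimum-length labeling assigns it.  Computed by a down-pass plus
  an up-pass that prices each (node, state) pair against the rest of the
  tree; no ACCTRAN/DELTRAN resolution is imposed.  All arithmetic is int64,
  so equality tests are exact.

The test suite verifies lengths and MPR sets against exhaustive enumeration
of all internal labelings on random instances with up to 8 taxa, 6
characters and 4 states, including missing cells and polymorphism.

## Tree search and the molecular scaffold

The search is intentionally simple and fully reproducible: random-addition
starting trees (each taxon inserted at its best edge) followed by SPR (or
NNI) hill climbing, retaining every distinct equally best tree seen, capped
by `max_trees_retained`.  It is not a re-implementation of the
new-technology metaheuristics (sectorial search, ratchet, drift, fusing)
used for the published 128-taxon analysis; on fully enumerable tree spaces
(7 taxa, 945 topologies) it recovers the global optimum in ≥ 96% of random
instances with three replicates, which is the property the pipeline needs
at desk scale.  Because the count of equally parsimonious trees depends on
the retention cap and on zero-length-branch conventions, that count is a
setting, not a result.

The scaffold constraint keeps a backbone over the constrained (extant)
taxa: a candidate tree is admissible iff its restriction to those taxa
refines the backbone's rooted clades.  Constraint checks are applied during
stepwise addition (against the backbone restricted to the taxa present so
far) and to every rearrangement neighbour.

Determinism: replicate random streams are spawned per replicate index from
the master seed, so enlarging `n_replicates` extends, never perturbs, the
search; all ties (best insertion, best neighbour, output order) break by a
canonical lexicographic tree order.  Trees are rooted on a designated
outgroup (default: lexicographically first taxon).

## Minimum-branch-length calibration

Given first/last appearance dates (FAD/LAD, Ma) per tip, each tip is dated
by the configured rule — FAD by default, since first appearances are what
calibrate a clade's minimum age; LAD and midpoint are available.  Node ages
are then the unique pointwise-minimal solution of

* node age ≥ oldest descendant tip age, and
* parent age ≥ child age + `min_branch`,

computed in one postorder pass (`age(v) = max_child(age(c) + m)`), which a
constraint-propagation fixed point confirms on random trees.  The package
default `min_branch` is 5 Myr (the analysis setting; display trees
conventionally use 1 Myr).  Calibration is idempotent, keeps polytomies
as-is, and compares ages with a 1e-9 tolerance.

## Allometry and fossil imputation

The allometry is linear on log₁₀ scale: `log10 TL_cm = β₀ + β₁ log10 HW_cm`.
Base 10 is a convention of the body-size literature and is the package-wide
constant `LOG_BASE`.  Extant taxa with several specimens are averaged on
the log scale (symmetric treatment of multiplicative measurement error);
each fossil contributes the single head width of its designated specimen.

Residuals are Brownian on the time-calibrated tree under Pagel's λ: the
phylogenetic covariance (shared root-to-MRCA path length) has its
off-diagonal entries multiplied by λ ∈ [0, 1].  The covariance is scaled to
unit mean diagonal so σ² is a per-taxon residual variance regardless of
tree depth; all estimators and predictions are invariant to that scaling.
λ is estimated once by bounded 1-D profile maximum likelihood (with the
regression design profiled out) and then held fixed during sampling — a
plug-in treatment mirroring a signal value computed externally and handed
to the predictor.  Sampling λ is out of scope.

Fossil imputation is Gibbs sampling with conjugate conditionals: flat prior
on (β₀, β₁), inverse-gamma(0.001, 0.001) on σ².  Per iteration, β is drawn
from its GLS normal conditional, σ² from its inverse-gamma conditional, and
each fossil's log₁₀ TL from the Brownian kriging conditional
`x_f β + C_fo C_oo⁻¹(y − Xβ)` with variance `σ² (c_ff − C_fo C_oo⁻¹ C_of)`
(clamped at 0 against round-off).  Defaults: 10,000 iterations, 1,000
burn-in, thinning 10, seed mandatory.  Back-transformed draws give the
predictive mean and 2.5/97.5 percentiles in cm; an autocorrelation-based
effective sample size (initial-positive-sequence truncation) is reported
per taxon.

Numerical edges: polytomies in a prediction tree are resolved with
zero-length internal branches (logged); a singular extant covariance raises
an error suggesting a jitter argument rather than silently regularizing;
predictive variance for a fossil coincident with an extant tip is exactly
zero at λ = 1, and the sampler then returns that tip's value.

Interval calibration was checked by simulation: with 20 extant tips and the
generating λ supplied, 95% posterior intervals for the slope and 95%
predictive intervals for withheld fossil lengths cover the truth at 94–97%
over 200 replicates.

## Size classes, bins and reduction percentages

Total lengths are classified with upper-inclusive bounds — small (0, 150],
medium (150, 400], large (400, 700], gigantic (700, ∞) cm — because "about
1.5 m and lower" places 150 cm in the lower class; the same convention is
applied at every boundary.  For ancestral-state plotting, mean TL per taxon
(observed for extant taxa, predictive mean for fossils) is discretised into
fixed-width bins, 50 cm by default and configurable.

Ancestral bins are reconstructed by ordered parsimony (adjacent bins one
step apart), the binary osmoregulation character by Fitch parsimony with
`unknown` treated as missing.  Parsimony ASR uses topology only; the
"equal branch lengths" phrasing of display figures needs no special
handling.  Osmoregulation codings are an input table (salt-gland,
isotopic and occurrence evidence summarised per taxon by the user), not
package constants.

The reduction between an ancestral and a descendant bin is reported as a
(min, max) pair referenced to the *ancestral bin's upper bound*:
`min = (1 − upper_desc/upper_anc)·100`, `max = (1 − lower_desc/upper_anc)·100`.
This is the one convention that reproduces both published-style figures
from a 200–250 cm ancestor: at least 20% to a 150–200 cm bin and 40% to a
below-150 cm bin.  It is logged as a convention choice, not a claim about
any particular author's unstated formula.  Bins must be finite (the open
gigantic bin is rejected); a descendant extending above its ancestor clamps
the minimum to 0 with a note.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **Trees**: forward Gillespie birth–death (defaults 0.06/0.03 per Myr)
  run until the target extant count, with the present observed one
  exponential waiting time after the last event so the youngest cherry has
  positive length.  Extinct tips are kept as fossils; their FAD is the
  extinction time, with a short FAD–LAD observation window.
* **Characters**: continuous-time Markov jumps; unordered characters jump
  uniformly to another state, ordered characters step ±1 on the cline,
  matching the Wagner cost assumption.  Defaults: 56 characters over a
  ~25-tip tree (a quarter of the 128 × 219 study matrix), a quarter
  ordered, 25% missing cells and 2% polymorphic scores, rate 0.02/Myr.
* **Allometry**: per-taxon log₁₀ HW uniform on (4, 100) cm; residuals
  multivariate normal with λ-scaled tree covariance (defaults slope 0.95,
  intercept 1.05 — TL ≈ 11 × HW, crocodylian-like — σ² = 0.002, λ = 0.9);
  ~7 specimens per extant taxon with 0.02 log₁₀ measurement noise;
  fossil TL withheld and recorded as truth.

Random streams are per component (tree, matrix, traits), spawned from the
master seed, so one component's draw count never perturbs another.

What passing tests on these data do *not* show: the generator has no
character correlation or morphological integration, no rate heterogeneity
across characters or branches, no preservation biases in which taxa
fossilise, and uniform head-width sampling rather than the size
distribution of real faunas.  Results on real matrices depend on those
features.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
enumeration cross-checks at ≤ 8 taxa, search optimality on 7-taxon spaces
(945 topologies), calibration oracles on 10-tip trees, interval-calibration
simulations with 20 extant tips and ~2,000-iteration chains, and the full
pipeline on ~25-tip synthetic datasets.  The code paths are the same ones a
full-scale analysis uses; the 128 × 219 matrix dimensions are exercised in
the I/O round-trip test.

## Known limitations

* The search does not implement implied weighting, support values, or the
  published metaheuristics; exact most-parsimonious-tree counts are not
  reproducible quantities here.
* Only Brownian/λ residual models are provided (no OU or early-burst), and
  only head width as a predictor.
* mbl is the only calibration method (no cal3 or tip-dating, no node-age
  uncertainty).
* The TNT reader supports the `xread` block with numeric states 0–9 and
  ordered/unordered `ccode` directives; other commands are ignored with a
  warning, and interleaved blocks are not supported.
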