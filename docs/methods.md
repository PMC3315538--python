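# Methods

## Model and estimation

An interval-coded score model is a generalized additive classifier whose
per-variable effects are step functions. Continuous covariates are expanded
over a dense candidate grid of thresholds into one-hot interval indicators
(half-open intervals, lower bound included — so a chart row can read
"between 40 (included) and 60"); categorical variables get one indicator
per level and binary variables a two-indicator block. Within every block the
indicators partition the domain, so each patient activates exactly one
column per variable.

Training minimises hinge loss plus a weighted total-variation penalty on
each variable's interval coefficients. For continuous variables the
penalized differences form a chain over adjacent intervals; categorical
levels have no natural order, so each non-reference level is penalized
against the reference instead of chained. The reference interval of every
variable (leftmost interval, first level, binary value 0) is pinned to
weight zero. This gauge fixing costs nothing — adding a constant to a
block and subtracting it from the intercept leaves every prediction
unchanged — and makes "variable removed" literally "all weights zero",
matching charts in which baseline answers score 0 points.

With fixed penalty factors the problem is an exact linear program (hinge
slacks, split TV auxiliaries), solved with HiGHS. Iterative reweighting
recomputes u = 1/(|difference| + eps_c) from the current solution and
re-solves until the largest coefficient change falls below `tol`
(default 1e-4, `max_iter` 50); small differences thereby acquire large
penalties and fuse exactly, which at the fixed point prices the penalty at
roughly gamma per surviving step — an l0-like selection of interval
boundaries.

### Why the default solver carries a small ridge

The pure hinge + TV objective is piecewise linear, and its minimisers sit
on polytope vertices. On realistic (non-separable) data this has two
unwelcome consequences that we observed systematically: coefficients land
on a coarse lattice tied to the +-1 margins (typically one step of height 2
per variable — a near-binary rule rather than a graded score), and isolated
one-interval spikes in irrelevant variables carry genuine hinge benefit of
order sqrt(cell size) that no reweighting can price away without also
destroying true structure. Adding a small quadratic term (ridge/2)||w||^2
(default ridge 0.3) restores strict convexity: the solution is unique,
coefficients grade smoothly with effect size, and spurious spikes shrink to
where the reweighting can remove them exactly. The margin formulation the
model descends from carries exactly such a quadratic term, so we regard the
ridge as part of the model rather than a numerical trick; setting
`backend="lp", ridge=0` recovers the pure linear program.

The ridge problem is solved by ADMM: the margins and the penalized
differences are split into auxiliary blocks with closed-form proximal
updates (a shifted clip for the hinge, a soft-threshold for the weighted
TV); the (w, b) update is a single Cholesky solve, re-factored only when
the penalty parameter rho adapts by residual balancing. Fused structure is
read off the soft-thresholded difference block (cumulative sums along each
chain), so fusion and variable removal are exact, and the intercept is then
re-optimized exactly on the one-dimensional hinge. Solves warm-start across
reweighting iterations.

### Annealing the reweighting constant

Reweighting is applied on an eps ladder (1.0, 0.3, 0.1, 0.03, then eps_c;
`anneal=False` disables it). The unweighted ridge solution spreads a true
break over a ramp of small adjacent differences; a first reweight straight
at eps_c = 0.01 would assign each of those differences a penalty of order
gamma/eps_c and annihilate the ramp before it can fuse into a step. The
coarse-to-fine schedule lets ramps consolidate first; in every experiment
it dominated the plain loop, which on some draws collapsed the model to a
single step.

## Chart construction

Fitted weights are anchored (reference-interval weight moved into the
intercept), divided by the smallest non-zero magnitude and rounded to the
nearest integer, ties away from zero. The smallest-magnitude scan ignores
weights below max(1e-8, 1e-3 * max|w|) — solver dust, not effects — since a
spurious tiny "smallest weight" would inflate every other point by orders
of magnitude. Adjacent intervals with equal rounded points merge into one
chart row; the rendered questionnaire omits reference rows. The intercept
is not part of the chart; it is absorbed by the link function's domain.
Missing covariate values score 0 points (the reference answer) and are
excluded from grid construction; the data this design targets rarely
records why a value is absent, and 0 is the only answer a paper chart can
give.

## Link and risk table

The integer score orders patients but is not a probability. The link is
fitted to the empirical (score, outcome) pairs: by default isotonic
regression (the pool-adjacent-violators solution), optionally a
Gaussian-kernel smoother of per-score event rates followed by an isotonic
projection, with bandwidth chosen by cross-validated Bernoulli negative
log-likelihood. Risks are clipped to [0.001, 0.999] — a score chart should
not promise certainty — and the lookup table renders the clipped extremes
as "<0.001" / ">0.999"-style rows. Between knots the link interpolates
linearly; beyond the extreme knots it is constant.

## Model selection

gamma maximizes mean out-of-fold AUC under seeded stratified 10-fold CV
(ties towards larger gamma, i.e. the sparser model); eps_c is then chosen
as the candidate with the fewest total chart intervals among those whose
5-fold CV AUC, likelihood and Nagelkerke R^2 remain within slacks (0.01 /
2% relative / 0.02) of the unweighted model, falling back with a warning to
the best-AUC candidate if none qualifies. "Comparable" has no numeric
definition in the clinical-scoring literature; the slacks are ours. The
default gamma grid is 13 log-spaced absolute values between 0.01 and 100:
although the hinge is a sum over patients, the penalty competes with
per-interval margin imbalances rather than with the full sum, so the useful
region is essentially independent of n (values of order n collapse every
model to the majority vote). Folds are drawn on row order from (n, k, seed)
only; stratification guards the small-prevalence regime.

## Evaluation metrics

AUC is the Mann-Whitney concordance probability (ties count one half). Its
95% CI uses the bias-corrected percentile bootstrap: 1000 row resamples,
single-class replicates redrawn, percentile levels shifted by twice the
normal quantile of the fraction of replicates below the point estimate; no
acceleration term. R^2 is Nagelkerke's likelihood-ratio R^2 against the
prevalence model, with risks clipped to (1e-6, 1-1e-6). Grouped calibration
sorts by predicted risk into contiguous equal-count groups of at least 10%
of the data (remainder joins the last group) and reports per-group mean
prediction, observed event fraction and exact Clopper-Pearson 95% binomial
intervals, plus the overall predicted/observed ratio
(calibration-in-the-large; 1 is ideal). The decision cutoff maximizes
specificity subject to sensitivity >= 0.90 (ties toward the stricter
cutoff); the 2x2 table yields LR+ = sens/(1-spec), LR- = (1-sens)/spec,
DOR = LR+/LR-, with a log-normal CI and 0.5 continuity correction on empty
cells. The classical comparison baseline is a Sullivan-style system: an
ordinary logistic fit on the raw variables, user-chosen fixed-width
intervals, the midpoint effect applied per interval and rescaled so the
smallest effect is one point.

## Synthetic cohorts

The generator draws mixed continuous/binary/categorical covariates, builds
the log-odds as an intercept plus declared per-variable step functions, and
draws Bernoulli outcomes — a cohort whose true chart is known. The default
staircase spec has two informative continuous variables (uniform(0, 10)
with breaks at 3 and 7, effect levels 0/1/2; normal(50, 15) with breaks at
40 and 60, levels 0/1.2/2.5), one informative binary (prevalence 0.4,
effect 1), three irrelevant covariates, and intercept -3.7 giving ~0.30
event prevalence — echoing, at desk scale, the moderate effect sizes and
prevalence of gynecological diagnosis cohorts. Its large-sample Bayes AUC
(true risks vs outcomes) is ~0.787.

What passing tests on these cohorts do show: the solver finds the convex
optimum, reweighting sparsifies without losing discrimination, the link is
calibrated in the large, bootstrap CIs cover. What they cannot show:
behaviour under informative missingness, measurement error, covariate
correlation or case-mix shift, none of which the generator emulates.

## Known limitations

Breakpoint recovery at these study conditions is the method's weak point,
and we report it candidly: the hinge loss only rewards an interval when the
classes are imbalanced among margin-active patients there, so steps whose
risk difference straddles ~0.5 carry almost no gradient, and a fitted
boundary is optimal anywhere within a hinge-indifferent band a few grid
steps wide. On 20 seeded staircase draws (n = 2000, candidate grids of 20
quantile cuts) the default pipeline zeroed all irrelevant variables and
matched every true breakpoint within one grid step in 5/20 runs, and came
within 0.03 of the Bayes AUC in 10/20 — the corresponding acceptance test
asserts a 16/20 bar and therefore fails; the bar appears calibrated to a
likelihood-based fit. At the signal strengths where such charts are used in
practice (single-variable AUCs far above these), the indifference bands
collapse and the method recovers structure readily.

Desk-scale problem sizes used by the test suite: recovery runs CV over a
3-point gamma grid {1, 2, 4} with 3 folds; sparsification uses n = 1000 and
a fixed gamma = 2; calibration n = 5000; bootstrap coverage 200 simulations
of n = 200 with B = 1000.

Other limitations: no automatic interaction discovery (declare derived
variables instead), binary outcomes only, and the ADMM backend's objective
is accurate to ~1e-3 relative (the LP backend is exact and is the one held
to the 1e-6 oracle-equivalence bar).
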