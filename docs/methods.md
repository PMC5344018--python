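# Methods

This note records the models, estimators, numerical choices and
limitations behind renschkit, in the order the analysis runs.

## Trees

Trees are rooted phylogenies with branch lengths interpreted as durations
in million years (My). The package never rescales branch lengths: only
relative rates matter to every statistic computed here, so the dating
calibration is entirely upstream. dendropy provides parsing/serialization
(Newick and NEXUS) and the container; every node carries a stable string
id (tip label, or assigned `N<k>` for unlabeled internal nodes) so that
flat output tables can refer to nodes.

Polytomies are randomly resolved (seeded) into zero-length binary
branches. Zero-length branches are legal topology but are handled
specially downstream: they add nothing to any covariance, ancestral
estimates propagate across them unchanged, and rates in darwins are
undefined (not zero) on them.

## Brownian-motion ancestral reconstruction

Continuous traits are modelled by Brownian motion: independent increments
with zero mean and variance sigma^2 * t on a branch of duration t. This is
deliberately the simplest null model of homogeneous evolution.
Reconstruction is maximum likelihood / GLS on the fixed input tree:

- an upward (pruning) pass combines child estimates by inverse-variance
  weighting, accumulating corrected branch lengths;
- a downward pass folds the "rest of tree" pseudo-observation into each
  node, giving the marginal conditional expectation at every node. The
  root estimate equals the phylogenetic (GLS) mean
  (1' V^-1 x) / (1' V^-1 1).

The two-pass estimates equal a dense GLS solve
mu + C V^-1 (x - mu 1) with C the node-tip shared-path covariance; the
test suite and acceptance script verify this equivalence to 1e-8 on
batteries of random trees (observed agreement ~1e-14). The Brownian rate
is the ML estimator sigma^2 = (sum of squared standardized contrasts)/n;
95% node intervals are estimate ± 1.96 sqrt(sigma^2 * v_node) with v_node
the conditional variance factor from the downward pass. Tips are returned
exactly, with zero-width intervals.

Two caveats are properties of the model, not defects: BM reconstruction
shrinks ancestral values toward intermediate values, so per-branch changes
derived from it understate true rates; and the per-node intervals ignore
the uncertainty in sigma^2 itself.

## Fitch parsimony for binary characters

Secondary sexual characters coded 0/1 are reconstructed by Fitch
parsimony (downpass intersection/union, uppass MPR state sets). One
minimum-length labeling is produced by backtracking that keeps the
parent's state wherever the downpass set allows — i.e. changes are
delayed toward the tips (DELTRAN-style) — and per-branch gains (0→1) and
losses (1→0) are read off that labeling. Because most-parsimonious
reconstructions need not be unique, the result also reports the MPR set
of every node, the number of ambiguous nodes, and whether the root state
itself is ambiguous, rather than silently committing to one history.
Parsimony length is validated against exhaustive enumeration of all
internal labelings on small trees.

## Independent contrasts and RMA allometry

Contrasts follow Felsenstein's algorithm on a strictly binary tree.
Zero-length branches (polytomy inserts) receive a small additive constant
(1e-8 × tree depth) inside the variance terms only; each application is
logged. The allometry of male on female size uses log10 of both traits
(the conventional scale for allometric slopes) and through-origin RMA on
contrasts, with each x contrast positivized and the paired y contrast's
sign flipped accordingly — the standard convention that makes the
through-origin slope identifiable.

RMA (type II) slopes: sign(r) s_y/s_x, or sign(sum xy) sqrt(sum y^2 /
sum x^2) through the origin. R^2 is the squared (through-origin) Pearson
correlation and its p-value uses a t test with n−2 (n−1 through-origin)
degrees of freedom. Confidence intervals default to a seeded percentile
bootstrap over pairs with 1,999 replicates; an analytic interval
(slope × (sqrt(B+1) ± sqrt(B)), B = F_{1,df}(alpha) (1−r^2)/df) is
available. Simulation shows ~93% (bootstrap) and ~94.5% (analytic)
empirical coverage for nominal 95% at n = 59; the isometry decision
(is 1 inside the CI) is therefore mildly anticonservative, which is
acceptable for the strong effects this analysis targets.

## Blomberg's K

K = (MSE0/MSE) / [(tr V − n / 1'V^-1 1) / (n−1)], where MSE0 uses tip
deviations from the phylogenetic (GLS) mean and MSE is the GLS quadratic
form; the denominator is the expectation under BM on the given tree, so
K = 1 under Brownian motion, K < 1 means less signal, K > 1 more. The
implementation reproduces R picante's `Kcalc` to machine precision on
fixed cases (frozen in the tests). The permutation test shuffles tip
values (999 permutations by default, seeded) and reports the one-sided
proportion of permutations with an MSE0/MSE ratio at least as large as
observed, with the +1 correction. K is undefined for constant tip data
(the pipeline reports NaN and continues).

## Per-branch change and the 5% coding

For every branch, with parent and child values from the reconstruction:
change (final − initial), absolute change, and darwins
|ln(final/initial)| / duration. Darwins are only defined for strictly
positive trait values and positive durations; SSD (male − female, which
can be negative) is analysed via arithmetic change only, and undefined
rows are dropped from darwins summaries with a logged count.

Qualitative coding per branch: male or female change below 5% of the
branch's initial value is "=" (within measurement error); SSD change
below 5% of the total observed SSD range is "=". The SSD range defaults
to max − min of SSD over all reconstruction nodes (tips plus ancestors),
because the rule is applied to reconstructed branch changes; a tips-only
switch is provided. An "all changes" mode codes every branch by raw sign.
If the SSD range is exactly zero (perfectly coupled sexes) every SSD code
is "=". Branches where SSD changed and exactly one sex changed are
tallied and compared with an exact two-sided binomial test of equal
probabilities. Rate-difference regressions (male − female rate on each
sex's own rate, in darwins and in absolute change) are ordinary least
squares, since signed near-zero slopes are meaningful there; degenerate
fits (constant predictor or response) return NaN / flat fits instead of
raising.

## Box-counting fractal dimension

Outlines are binarized at 50% of the intensity range (configurable),
cropped, isotropically rescaled so the larger extent equals 2,000 px,
and centered on a 2,100 px canvas — the standard measurement geometry for
aedeagus outlines. Box counting uses origin-anchored grids with
power-of-two box sizes from 2 to canvas/4 and an OLS fit of log(count) on
log(size); the dimension is |slope|, and at least 4 scales are required.
Calibration is by analytic phantoms: a straight line (dimension 1), a
filled square (2), a circle outline (1) and a Koch curve
(log 4 / log 3 ≈ 1.2619); estimates land within 0.05 of the analytic
value for smooth shapes and within 0.1 for the Koch curve at 2,048 px.

Known limitation: upscaling thin (sub-pixel) structure by factors ≳2
during standardization thickens strokes and can move the estimate by
~0.05–0.06, so outlines should be captured near the target resolution.
Perimeter itself is consumed as a measured number per species (tracing
outlines from photographs is out of scope); perimeter/length is the
reported per-unit-length complexity.

## Synthetic data

The generators define the regime the package is tested under:

- Yule trees via exponential waiting times; n-tip trees get one extra
  waiting time after the n-th birth so pendant branches are strictly
  positive.
- Bivariate BM with per-branch increments drawn from covariance
  [[sm^2 t, r sm sf t], [r sm sf t, sf^2 t]] (exact Cholesky, valid at
  |r| = 1). Defaults emulate the study regime for a dimorphic beetle
  clade: 71 tips, sm/sf = 1.44, r = 0.9, root sizes 1.5/1.45 mm —
  chosen so the generating allometric slope sits in the empirically
  typical range (~1.4). True node values are always emitted.
- Binary characters evolve as a two-state Markov chain with gain/loss
  rates in events/My; the true event list is retained.

What the generators do not emulate: measurement error, intraspecific
variation, non-ultrametric sampling, rate heterogeneity across clades,
and any mechanistic model of sexual selection. Passing tests therefore
demonstrate correctness of the estimators under their own null model,
not robustness to those real-data complications.

## Problem sizes and determinism

Calibration tests use 100 replicates at 50–60 tips (slope recovery, K)
and 40–60 replicates at 150 tips (sigma^2 recovery, rate-ratio
recovery) — large enough that the Monte Carlo error is a few percent,
which is what the asserted bands allow. All stochastic steps take
explicit seeds; the pipeline derives independent named sub-seeds from one
master seed (recorded in its outputs), so a rerun with the same
configuration is byte-identical.
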