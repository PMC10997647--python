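# Methods

## Model

The core model is a Bayesian phylogenetic generalised least squares (PGLS)
regression with variable evolutionary rates. Residuals follow Brownian
motion on a rooted, time-calibrated tree (branch lengths in Myr): the
residual covariance of two species is σ² times the scaled path length they
share from the root, with Pagel's λ multiplying off-diagonal entries only
(λ = 1 full phylogenetic signal, λ = 0 a star phylogeny). Evolutionary tempo
may vary: a configuration of rate-scalar placements assigns a multiplier to
a single branch or to every branch of a clade (including its stem), and a
branch's effective scalar is the product of all placements covering it.

Species known from several localities are not reduced to a point estimate:
each carries a list of linked occurrence records (palaeolatitude, MAT, CMMT,
age from one locality), and the sampler resamples which record represents
the species, always jointly — a species' latitude and temperatures never
come from different localities. Hemisphere is recomputed from the currently
assigned record's sign, not fixed per species.

## Priors and proposals

The published analyses delegate sampler internals to closed-source
machinery, so the following are this package's own choices, fixed once:

* coefficients: independent N(0, 10²) — proper but vague next to slopes of
  order 10⁻², which keeps the implied Occam penalty in Bayes factors finite
  and honest;
* log σ²: uniform on [log 10⁻⁸, log 10⁸];
* λ: uniform on [0, 1], updated by a reflected random walk;
* number of scalar placements: Poisson(mean 1) truncated at 2n − 2; scalar
  values log-uniform on [10⁻³, 10³] — scale-free and spanning the >10×
  shifts the method is meant to detect; placements born from the prior,
  deleted uniformly, or modified by a log-normal step (sd 0.3);
* occurrence assignment: uniform over a species' linked records.

Proposals that would push any branch's effective scalar outside
[10⁻³, 10³] are rejected, not truncated. This conditions the placement
prior on the bound constraint; the prior-sampling test (likelihood power 0)
therefore compares the chain against an independent rejection sampler from
the same constrained prior, not against the unconstrained Poisson.

Coefficient, log-σ² and λ steps adapt toward ~0.3 acceptance during burn-in
(Robbins–Monro, decaying gain) and are frozen afterwards, so the recorded
portion of every chain is valid MCMC. Likelihood evaluations cache the
Cholesky factor of V and whitened copies of the response and design;
coefficient and σ² moves then cost O(np), and only λ or scalar moves pay
for a refactorisation.

Chain presets mirror the published run lengths (Mesozoic: 12.5M iterations,
2.5M burn-in, thin 1000; extant: 150M/100M/1000). The test suite uses
scaled-down chains (20k–120k iterations) and problem sizes (8–250 tips),
chosen as this package's own desk-scale study conditions.

## Model selection

Log marginal likelihoods are estimated by stepping-stone sampling: a ladder
0 = b₀ < … < b_K = 1 of likelihood powers (priors untempered), each stone
sampled by the same engine, initialised from the previous stone's final
state, with the first 20% of each stone discarded and proposal scales
re-adapted per stone (freezing them across stones left prior-scale steps in
posterior-scale stones and biased the estimate low). Stone k contributes
log (1/m) Σ exp[(b_{k+1} − b_k)(logL_j − max)] + (b_{k+1} − b_k)·max.
Spacing follows Beta(0.4, 1) quantiles, which concentrates stones near the
prior where the integrand changes fastest; a uniform ladder agrees within
Monte-Carlo error and both are available. Bayes factors are reported as
2·Δ log ML with BF > 2 as positive evidence. On a conjugate normal-mean
model with 50 observations, 30 stones × 4000 iterations reproduce the
closed-form log marginal likelihood to within 0.1.

The model ladder for the dinosaur-style analysis runs: focal predictor
only; +hemisphere; +period; +clade; +interactions with the focal predictor;
+tip age (a size-through-time, Cope's-rule term); +formation count;
+occurrence count — each as homogeneous-rate and variable-rates variants.
The mammaliaform preset keeps hemisphere, tip age and the two bias
covariates only (a two-species Triassic sample cannot support period-level
contrasts). Dummy coding uses k − 1 indicators with northern hemisphere,
Triassic and Ornithischia as zero-coded baselines.

## Summaries

p_MCMC is one-tailed as defined: the proportion of slope samples whose sign
opposes (or equals zero relative to) the posterior median's sign, 0.5 for a
median of exactly zero — its maximum. R² is whitened 1 − SSE/SST: response
and design are multiplied by the inverse Cholesky factor of V, SST is taken
about the GLS phylogenetic mean, and the statistic is evaluated per
posterior sample at that sample's coefficients. Evaluated away from the
optimum it can be negative; this is deliberate, since the posterior-median
R² of a weak regression is naturally below zero. Credible intervals are
equal-tailed quantiles (linear interpolation); effective sample sizes come
from arviz. Effect sizes on the log10 response scale convert to percent
change per predictor unit as (10^(βΔ) − 1)·100, reported to one decimal.

## Branch-wise changes

For the figure-style analysis, a univariate (intercept-only) variable-rates
run per trait yields a posterior of branch scalars; with fixed topology the
maximum-clade-credibility summary reduces to a per-branch statistic, taken
as the arithmetic mean (median available). Branch lengths are multiplied by
those consensus scalars, maximum-likelihood Brownian ancestral states are
computed on the scaled tree by two-pass message passing (the root state
equals the GLS phylogenetic mean; the implementation is cross-checked
against a joint-GLS conditional-expectation oracle and against
ape/phytools), and each branch's change is descendant state minus ancestor
state. Changes telescope exactly: they sum along any root-to-tip path to
(tip value − root state). Multi-occurrence species enter this deterministic
pipeline by their across-record mean; the stochastic treatment lives in the
sampler.

The change scatter anchors its least-squares trend at the origin (no
evolution in either trait). That trend's naive standard error understates
uncertainty, because changes share estimated ancestors; inference about the
trend therefore uses the through-origin regression of standardised
independent contrasts, which are independent under Brownian motion — the
contrast correlation is the inferential counterpart of the visual trend.
Point colouring by the ancestral change of either trait is an option rather
than a single hard-coded choice.

## Sampling-bias covariates

Nine 20° latitudinal zones partition [−90°, 90°] (half-open bins, top bin
closed so +90° is zone 8) and cross with the three Mesozoic periods
(ICS bounds: Triassic 251.9–201.4, Jurassic 201.4–145.0, Cretaceous
145.0–66.0 Ma; boundary ages go to the younger period; configurable).
Formation counts deduplicate formation identifiers within a cell over all
rows; occurrence counts first drop taxonomically unidentifiable records and
those not based on body fossils — the two stated exclusions apply to
occurrences only, since a formation exists in a cell regardless of how
identifiable its fossils are. Each species receives the counts of the cell
containing its mean palaeolatitude and mean age; a stated period label
takes precedence over the numeric age. Attachment is idempotent and
occurrence totals are conserved.

## Synthetic data

The generator module provides every structure the analyses assume: Brownian
motion on a given tree; correlated bivariate Brownian motion (positive
control; rate matrix Σ) and independent evolution (negative control);
clade-specific rate multipliers; and a Bergmann-type scenario in which
latitude evolves by Brownian motion (reflected into [−90°, 90°]) and size
is α + β·|latitude| plus phylogenetic noise split as λ-weighted Brownian
plus (1 − λ)-weighted independent components — so the marginal residual
covariance is σ²V(λ). A scenario may state its target variance explained
instead of σ², in which case the residual rate is derived from the realised
latitude spread. Random trees are Yule (pure birth, unit rate) rescaled to
a stated root height — deliberately plain, since tree shape is not what the
estimators under test are sensitive to. Multi-occurrence species draw
1 + Poisson extra records jittered by 2° of latitude, with temperatures
re-derived from the jittered latitude so records stay internally
consistent.

Local temperatures come from a deterministic latitudinal profile (linear
decline in |latitude| between an equatorial and a polar anchor, seasonality
offset growing poleward so CMMT ≤ MAT): the Triassic preset runs 30 °C at
the equator to 3 °C at the pole, the Cretaceous preset reaches −11 °C. The
profile emulates only the gross latitudinal structure of GCM-derived
temperature fields; it has no palaeogeography, no seasonal cycle beyond the
CMMT offset, and no spatial noise, so tests passing on it say nothing about
the fidelity of any climate model — temperatures in real analyses are input
columns.

What the generators do not emulate: fossil preservation and recovery
processes (bias covariates are tested on constructed tables), measurement
error in body-size proxies, topological uncertainty (one fixed tree per
scenario), and non-Brownian trait dynamics. Passing recovery tests
therefore demonstrates correctness of the estimators under their own
assumptions, not robustness to their violation.

## Numerical choices and degenerate inputs

Polytomies are kept at read time and resolved into zero-length bifurcations
(sorted-child-label order, hence reproducible) only inside covariance and
contrast computations; ancestral-state message passing handles
multifurcations natively. Zero-length branches are permitted; a singular
covariance gets a logged ridge of 10⁻¹⁰ × mean diagonal, never silently.
Rank-deficient designs are reported with the offending column names.
Taxon names match exactly after trimming and space/underscore unification —
no fuzzy matching, because a silent mismatch is worse than a hard failure.
A constant whitened response makes R² undefined and returns NaN. Same seed,
same configuration: bit-identical sample streams.

## Test problem sizes

Closed-form oracle equivalence runs 100 random trees of ≤10 taxa at 10⁻⁸.
Slope recovery uses 20 replicates of 128-tip trees with 50k-iteration
chains; 10× clade-shift detection uses 8 replicates of 64-tip trees with
40k iterations; stepping-stone calibration uses the 50-point conjugate
model and 10 null-model Bayes-factor replicates at 48 tips; the branch-
change controls use 250-tip trees. These sizes are the package's chosen
desk-scale study conditions; the full-scale presets remain available.

## Known limitations

Posterior equality with other variable-rates implementations is not
expected — proposal distributions and scalar priors differ and only
statistical behaviour (recovery, calibration, detection) is comparable.
The exact R² formula used by other software is unpublished; comparisons of
R² across packages are approximate. With few species (the 8-tip worked
example), the posterior-median R² sits well below the maximum-likelihood
R², and λ is weakly identified, so small-clade posterior medians can differ
noticeably from λ-fixed ML estimates. Generic tree editing (grafting
replacement taxa with tip-age constraints) is out of scope: trees are
pre-edited upstream, and this package only prunes.
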