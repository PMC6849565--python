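# Methods

This note records the models, conventions and default parameters behind
`traitsoil`, the choices made where the methodology was genuinely open, and
what the synthetic-data tests do and do not demonstrate.

## Trait table and functional-group classification

Six traits describe each species: canopy height (continuous, uniform units
within a table), perenniality (ordinal 1–5, annual → perennial), specific
leaf area (continuous, area/mass), root architectural class (ordinal 1–8,
fibrous/complex → tap-rooted/simple), rooting depth class (ordinal 1–3,
shallow → deep) and arbuscular-mycorrhizal affinity (ordinal 1–3).
Continuous traits must be strictly positive; ordinal codes must lie within
their declared bounds; duplicate species ids are rejected.

For clustering, continuous traits are z-scored and ordinal traits are
treated as numeric ranks and z-scored the same way, because Ward's
criterion assumes Euclidean geometry. Whether to standardize at all is a
genuine choice (classification protocols differ); z-scoring is the default
here because it stops the trait with the largest numeric range (usually
SLA or height) from dominating the dissimilarities. Missing trait values
are imputed by the across-species median and logged; a trait missing for
more than 30% of species is refused rather than imputed.

Divisive hierarchical clustering with Ward's distance is a contradictory
prescription — Ward linkage is agglomerative — so the default is
agglomerative Ward on the standardized matrix, with a DIANA-style divisive
algorithm (largest-diameter cluster split by a splinter group) available
via `method="diana"`. Group labels are renumbered by descending size with
ties broken by the lexicographically smallest member, and rows are sorted
by species id before any computation, so the partition is invariant to row
order.

The verification step refits the group labels with linear discriminant
analysis on the same standardized matrix and reports percent agreement.
Resubstitution agreement is reported by default (leave-one-out is
available via `cross_validate=True`); on clean synthetic syndromes both
are 100%. The discriminant is solved by least squares (`solver="lsqr"`)
because generated ordinal traits can be constant within a group, which
makes the within-class covariance singular and silently degrades the
default SVD solver.

## Community trait summaries

CWM = Σ pᵢtᵢ with pᵢ the relative percent cover among present species.
FDvar follows the Mason et al. (2003) functional-divergence definition:
ln x̄ = Σ pᵢ ln tᵢ, V = Σ pᵢ(ln tᵢ − ln x̄)², FDvar = (2/π)·arctan(5V).
This matches the index's documented anchors (0 when every present species
shares the trait value, approaching 1 as abundance-weighted log-trait
spread grows) and requires strictly positive trait values. Ordinal traits
enter as their numeric codes. Weighting is by percent cover only; biomass
weighting is out of scope.

Species present in a survey but missing from the trait table (or missing
the trait) are dropped from that trait's summary with a warning; the
retained share of cover is reported per subplot and values retaining less
than 80% of cover are flagged rather than suppressed. FDvar values are
logit-transformed before modelling with clipping at eps = 0.001.

Flux partitioning uses the convention that positive fluxes point to the
atmosphere: P_syn = NEE − R_eco, so P_syn is typically negative for net
photosynthetic uptake.

## Multifunctionality

Functions are clustered per time point on the distance 1 − |ρ| (Spearman
correlation across subplots). The correlation measure, linkage and cut are
not pinned down by the threshold-scoring literature; this implementation
uses Spearman (rank-based, consistent with the rank-based thresholding),
average linkage (the common choice for correlation distances) and a
dendrogram cut at 0.7, all configurable. Each function in a cluster of
size m among K clusters receives the global weight 1/(mK): weights are
equal within a cluster, cluster totals are equal, and the grand total is
exactly 1, which is the unique equal-within-cluster scheme under which the
score maximum is 1.

"Top 50% for that plot" is interpreted as: value ≥ the across-subplot
median of that function at that time point, computed separately per month;
ties pass. For a general threshold q the cutoff is the (1 − q) quantile.
Missing values score zero for that subplot without weight renormalization
(a conservative score) and are logged. Because passing depends only on a
subplot's rank among subplots, the score is invariant to monotone
increasing transforms of any single function — the property the test suite
verifies on random panels.

## Resistance and resilience

The Orwin & Wardle indices with D₀ = P₀ − C₀ (July drought minus July
control) and Dₓ = Pₓ − Cₓ (September):

    RS = 1 − 2|D₀| / (C₀ + |D₀|)        C₀ > 0 required
    RL = 2|D₀| / (|D₀| + |Dₓ|) − 1      |D₀| > 0 required

A published prose variant defines D₀ as the raw droughted value; that
reading breaks the [−1, 1] bounds and contradicts the index's source, so
it is offered only as `d0_convention="value"` (with a warning) for
reproduction attempts. Non-positive controls and zero initial impacts are
flagged (NaN) rather than dropped, so they remain visible. Averages across
functions are unweighted arithmetic means over available functions per
plot, computed on plot-level control/drought pairs (one control and one
droughted subplot per plot). One-sample t-tests against references 0 and 1
report degenerate zero-variance samples exactly ("all values equal
reference" / "all values equal non-reference constant") instead of
producing 0/0 statistics.

## Extreme-drought design

The extreme statistic is the annual maximum dry-spell length: the longest
run of days with rain < 1 mm inside the May 1 – August 31 window (both the
threshold and window configurable); this is a design choice, since drought
events can be defined many ways. Gumbel location/scale are fitted by
maximum likelihood by default, with the method-of-moments estimator
(β = s·√6/π, μ = m − γβ, Euler–Mascheroni γ) offered for very short
records such as a 10-year series. The T-year return level is
x_T = μ − β·ln(−ln(1 − 1/T)) and is rounded up to whole days for shelter
scheduling. MLE on 10⁵ simulated extremes recovers parameters within 1%;
10-point samples carry large sampling error, which is why the fitted
report includes n and method.

## Trait screening and model averaging

Stage one ranks predictors per function and time point (tree ensembles do
not accommodate repeated measures, so months are analysed separately) by
out-of-bag permutation importance: a bagged ensemble of regression trees
(default 1000; 300 in the recovery harness) grown on bootstrap samples
with p/3 candidate predictors per split, importance
100·(MSE_permuted − MSE_oob)/MSE_oob averaged over trees. Computing the
baseline on out-of-bag rather than training predictions matters: training
MSE of a deep tree is near zero, which inflates null importances
arbitrarily, whereas OOB importances fluctuate around zero for irrelevant
predictors. Correlated predictors share importance (dilution); this is
inherent to permutation importance and is surfaced by a dedicated test
rather than corrected. Predictors are z-scored and, by default, values
beyond 3 SD winsorized (removal is available). Soil moisture and the roof
treatment accompany the trait terms in the forest.

Stage two fits every subset of the screened traits (at most 10 terms,
2^p enumeration) as linear mixed models with random intercepts for block
and plot, estimated by maximum likelihood because AIC comparison across
fixed-effects structures is invalid under REML. Models with ΔAIC < 2 of
the best (strict inequality) are retained; Akaike weights are normalized
over the retained set; averaging is "full": a coefficient is zero in
models that exclude its term. The averaged standard error is the
unconditional Burnham–Anderson form Σ w_m·√(se_m² + (β_m − β̄)²). Singular
or non-converged fits are dropped with a logged reason. With no random
structure the machinery reduces to ordinary least squares, which the tests
exploit as an oracle.

The recovery harness (`recover_effects`) runs the whole chain on generated
data: it recomputes community summaries from the generated survey, screens
with the forest, carries the top five trait terms (of twelve) into the
enumeration, and keeps the roof treatment and its interaction with
rooting-depth divergence — the drought-response modifier the design
targets — in every candidate model, mirroring how identified interactions
are carried in repeated-measures protocols. Four traits is the selection
depth at which correlated-trait dilution stops costing detectability on
the generator's correlation structure while keeping the enumeration at 16
models.

## Synthetic experiment

The generator reproduces the field layout exactly: 6 blocks × 7 treatments
(every non-empty combination of three sown groups), each treatment once
per block in a randomized position, 42 plots, three roof subplots each
(unroofed control, perforated roofed control, full shelter), 126 subplots.

Three trait syndromes are generated (20 species each): group 1 tall,
deep-rooted, simple tap-rooted, with a wide spread of lifespans and
architectures; group 2 short, long-lived, shallow simple tap roots;
group 3 shallow complex fibrous architectures with low SLA. Within-group
noise defaults to 10% of the between-group spread per trait (with the
per-group widenings above), which makes the syndromes separable — Ward
clustering recovers the labels with adjusted Rand index 1.

Subplot composition is a Dirichlet draw (concentration 1) over the sown
groups' species pools, scaled to 80% total cover and held stable across
months. Soil-function values follow a linear model on the standardized
CWM/FDvar summaries: intercept 10, month effects +0.5/−0.5/+0.3
(May/July/September — July depressed), Gaussian noise SD 0.5, block and
plot random intercepts SD 0.3 each. Default trait effects encode the
directions of interest on the standardized scale: CWM height −0.5 on
mineralization, nitrification and NO₃-N; CWM SLA +0.5 on NO₃-N and PO₄-P;
CWM mycorrhizal affinity +0.5 on NH₄-N and R_eco; FDvar perenniality −0.3
on R_eco; FDvar height +0.3 on DOC. Sheltered subplots receive a drought
shift (−3 in July, −1.5 in September) damped by exp(−0.4·z) in the
standardized rooting-depth divergence, so depth-diverse communities resist
the drought better; shelters multiply July soil moisture by 1 − 0.34. All
randomness flows through one seed with per-stage sub-seeds, so a seed maps
to byte-identical outputs.

What the generator does **not** emulate: real cover distributions (no weed
pool by default, no zero-inflation or observer error), absolute function
units, non-linear or threshold trait–function relationships,
month-by-trait interactions other than the drought damping, and temporal
autocorrelation beyond the shared subplot composition. Passing recovery
tests therefore show that the pipeline's statistics behave as designed
under the declared linear noise model, not that field effects of this size
are always detectable.

## Problem sizes and numerics

The test suite runs the recovery experiment at 100 seeds for the sign of a
generated −0.5 standardized height effect (n = 126 subplots, noise SD 0.5)
and 100 seeds for null-interval calibration; the screening stage in that
harness uses 300 trees. Stability-index grids use 10⁴ random tuples;
Gumbel consistency uses 10⁵ draws. Weight sums are checked to 1e-12;
model-averaged OLS reductions to 1e-6. Degenerate inputs (empty
communities, constant functions, zero-variance samples, non-positive
controls, zero initial impacts) raise explicit errors or flags as
described above rather than propagating NaN.

## Known limitations

- DIANA splitting is greedy; for k > 2 its partitions can differ from the
  classical full-dendrogram construction on ambiguous data.
- Mixed-model AIC counts fixed effects plus variance components plus the
  residual variance; other software may count differently, shifting all
  AICs by a constant without affecting ΔAIC.
- Permutation importance dilutes over correlated predictors; summed
  importance of a duplicated predictor approximates the solo importance
  only loosely.
- The multifunctionality clustering (Spearman, average linkage, cut 0.7)
  is one reasonable convention among several; scores should be compared
  across studies only under a shared convention.
- Model-averaged intervals are approximate; under strong shrinkage their
  null coverage is conservative (above nominal).
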