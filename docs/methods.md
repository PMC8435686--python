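# Methods

This note documents the statistical procedures implemented in `phytodiv`,
their assumptions, the defaults that matter, and the design choices made
where the design was genuinely open.

## Data model

The central object is a binary feature table: samples × compounds with 0/1
presence calls and nested sample metadata (species > plant > organ, organ ∈
{leaf, seed, unripe_pulp, ripe_pulp}).  All analyses are presence/absence
based — with modest replication per species and ionization efficiency
varying widely across structurally diverse compounds, relative LC-MS ion
abundances are not comparable enough to support abundance-weighted
metrics.  A fragmentation-spectrum library (MGF) covers the subset of
compounds for which MS/MS spectra exist; all structural metrics restrict to
that subset (the pairwise similarity ε is undefined without a spectrum),
and the restriction is logged per sample.  A sample that loses all its
compounds under restriction aborts the analysis rather than being silently
dropped, because silent sample loss corrupts the design matrix.

## Spectral similarity, ε, and the molecular network

Pairwise compound similarity is a peak-matched cosine: candidate peak pairs
within `fragment_tol` (default 0.02 Da) are accepted greedily, best
|Δm/z| first with ties broken by the lower (m/z_a, m/z_b) pair, one-to-one.
The score is the dot product of transformed intensities over matched pairs,
normalized by each spectrum's intensity norm over *all* its peaks, so
unmatched peaks dilute the score; fewer than `min_matched_peaks` (default
6) matches scores 0.  The intensity transform defaults to square root
(common in molecular-networking practice) with `raw` available, since the
upstream networking platforms do not document a single choice.  Greedy
matching (rather than optimal assignment) is the de-facto standard, is
deterministic, and differs from the optimal matching only in contrived
tie-heavy cases.  Precursor-shift ("modified cosine") matching is
deliberately not used for ε: the structural-similarity matrix feeds sample
metrics, not analog library annotation.

The molecular network keeps compound pairs with ε ≥ `min_cosine` (default
0.7) when each endpoint ranks the other within its top-k neighbors
(default 1000); a connected-component size cap is not implemented (the
conventional "0" setting means unlimited).

## CSCS sample metrics

Binary CSCS similarity between samples A and B is the symmetric mean of
row/column maxima of ε over the two present-compound sets (formula in the
README); with ε the identity matrix it reduces *exactly* to Sørensen
similarity, which is enforced as a property test.  It is bounded in [0, 1],
symmetric, and 1 on identical samples, but the max-based aggregation does
not guarantee the triangle inequality, so 1 − CSCS is a dissimilarity, not
a metric — the downstream permutation methods only require symmetry.
CSCS(A, A) = 1 by construction (ε(i,i) = 1); whether the original
abundance-weighted form's self-similarity normalization should be retained
under binarization is ambiguous, and the bilinear abundance-weighted
variant is provided separately (`weighted_cscs`) for comparison rather than
silently mixed in.

Within-sample structural complexity is 1 minus the mean pairwise ε among a
sample's (spectra-bearing) compounds; samples with fewer than two such
compounds score 0 with a logged warning rather than erroring, since a
degenerate sample is a data property, not a usage error.

## PERMANOVA

From squared dissimilarities D², the Gower-centered matrix
G = −½·C·D²·C yields sums of squares as traces of projector products:
sequential (Type-I) SS in the order organ, species, organ×species, matching
the convention of the standard distance-based ANOVA implementations; the
term order is caller-controlled.  The permutation null relabels samples
(G is conjugated by the permutation); with a strata key, labels are
shuffled only within each stratum — plant identity as strata restricts
exchangeability to samples of the same individual.  p-values use
(1 + exceedances)/(1 + permutations), so 999 permutations give a floor of
0.001.  When the residual SS is numerically zero (duplicated points within
groups), the pseudo-F is reported as +∞ for any term with positive SS, and
permutations reproducing the exact partition tie with the observed
statistic — the floor still holds.  Negative term SS can occur for
interaction terms on non-Euclidean dissimilarities; this is a known
property of the decomposition and is reported as computed.  On Euclidean
distance matrices the decomposition equals the classical multivariate ANOVA
decomposition (oracle-tested).

Pairwise PERMANOVAs run one two-level test per unordered factor-level pair
on the corresponding sub-matrix; the adjustment defaults to Holm (the
correction used by common pairwise wrappers is undocumented, and Holm is
valid under arbitrary dependence), with Benjamini-Hochberg as an option.

## Beta-dispersion and variance partition

Dispersion embeds the distance matrix by principal coordinates, retaining
negative-eigenvalue axes as an imaginary block; the distance of a sample to
its group centroid is sqrt(max(0, d²_real − d²_imag)).  The group contrast
is a one-way F on these distances with a free-permutation p (999 default),
followed by Tukey HSD (studentized-range quantiles) and a compact letter
display built by insert-and-absorb over the significant-pair set with
deterministic letter ordering.  Centroids (not spatial medians) are used.
Per-organ variance partitioning is a one-factor PERMANOVA with species as
the factor; η²(species) = SS_species/SS_total and η²(residual) its
complement.

## Species-constrained rarefaction

Samples of the same species are statistically dependent, so accumulation
curves keep them contiguous: each bootstrap replicate draws a uniformly
random starting *sample*, appends its remaining species-mates in random
order, then draws the next sample uniformly among those remaining, and so
on.  (Drawing samples rather than species weights species by their
remaining sample count.)  With singleton species this reduces to classic
sample-based rarefaction, verified against exact enumeration of all
orderings on small tables.  Total richness per organ is the asymptote of
S(n) = Asym + (R0 − Asym)·exp(−exp(lrc)·n), fitted to *each replicate
curve* by nonlinear least squares (start: Asym₀ = 1.1 × final value,
R0₀ = first value, lrc₀ from a log-linear probe; bounded multi-start
fallback).  Fitting per replicate and averaging — rather than one fit to
the mean curve — yields the standard error of the estimate naturally; the
95% CI is the normal approximation.  Whether published SE/CI conventions
for this analysis derive from replicate fits or fit-parameter covariance is
typically unstated; the choice here is recorded in output metadata.  On an
already-saturated curve the fitted asymptote can dip slightly below the
observed richness; this is flagged (`estimate_below_observed`), not
clamped.  Individual non-converged fits are dropped and counted, and more
than 5% failures abort with diagnostics.

## Classification and Boruta

The organ classifier is a random forest (delegated to scikit-learn behind
a fit / OOB-predict / importance interface) with 2,000 trees and
floor(sqrt(p)) variables per split by default; confusion and error rates
are computed by this package exclusively from out-of-bag predictions.
Feature importance defaults to OOB permutation importance — per tree, each
feature's column is permuted within the tree's OOB samples and the drop in
that tree's OOB accuracy averaged over trees — with Gini (impurity)
importance as a faster option.  Permutation streams are keyed to feature
*names*, not column positions, so decisions survive column reordering.

The Boruta loop appends one shadow (independent row-permutation) per
undecided real feature each iteration, refits the forest, and scores a hit
for every real feature beating the maximum shadow importance.  Decisions
use a two-sided binomial test on accumulated hit counts at α = 0.01,
Bonferroni-adjusted across the features still undecided (the reference
algorithm's default); shadows are rebuilt from the shrinking undecided set.
Features undecided at the iteration cap (default 100) stay tentative.  A
small false-confirmation rate is inherent to all-relevant selection: a
noise feature chance-correlated with the finite labels carries genuine
in-sample signal.

## Mixed models

Alpha richness and structural complexity are modeled per sample with
organ, species and organ×species as fixed effects and plant identity as a
random intercept.  Fixed terms are tested by likelihood-ratio tests between
maximum-likelihood fits of nested models (ML, not REML, since REML
likelihoods are not comparable across fixed-effect structures), with df
equal to the difference in fixed-effect parameters.  When the plant
variance component is degenerate (boundary at zero, a common outcome in
small per-species subsets), both models of the pair fall back to the
boundary fit — an ordinary ML regression — with a warning, keeping the
likelihood comparison coherent.  Per-species follow-ups fit organ as the
only fixed effect; pairwise organ contrasts use Wald differences of the
fixed-effect estimates with a Tukey studentized-range adjustment at
large-sample (residual) degrees of freedom, a normal-approximation choice
recorded in the output, and are summarized as compact letter displays.

## Synthetic data generator

The generator emulates the sampling design of an organ-level comparative
survey: `n_species` = 12 species × 3 plants × 4 organs (one sample per
plant per organ — balanced by construction; real designs' occasional
second infructescence is noise, not structure).  Compounds comprise a
shared core (default 1,126), fruit-specific (92), leaf-specific (4) and
per-species pools (7 × 12), totaling 1,306 — the scale of a curated
LC-MS feature set.  Core occupancy is drawn once per species (probability
`p_core_present` = 0.9) and shared by that species' samples, which makes
species identity the dominant axis of compositional variance; organ signal
comes from the fruit-/leaf-specific pools (`organ_effect` = 0.8 presence
probability in their organ rows).  Presence noise is a symmetric per-cell
bit flip (`noise_rate` = 0.02) multiplied by `fruit_beta_inflation` = 2 in
the three fruit organs, the simplest mechanism giving controllably higher
fruit beta-dispersion.  Randomness is split into named sub-streams of one
seed so that, e.g., enlarging a compound pool never shifts the noise draws.

Spectra are organized in structural classes (default 20): each class owns
a backbone of fragment m/z values with class-level intensities; a
compound's spectrum takes `shared_backbone_fraction` (default 0.6) of its
8–15 peaks from the backbone and the rest as compound-unique peaks, with
intensities uniform on (0, 1] scaled to a max of 100 (cosine is
scale-invariant, so any positive scheme works; this one is fixed for
reproducibility).  Within-class cosine is therefore high and between-class
cosine near zero.

What the generator does **not** emulate: retention times, adducts,
in-source fragmentation, quantitative abundances, peak-picking artifacts,
or systematic differences *among* the three fruit organs — seed, unripe
and ripe pulp share one fruit pool and are statistically exchangeable.
Consequently, passing tests demonstrate correct statistical machinery and
recovery of planted structure, not performance on real data; in
particular, organ classification on synthetic data can separate leaf from
fruit perfectly but cannot distinguish fruit organs from each other, and
no attempt is made to reproduce dataset-specific published values (overall
OOB error, specific confirmed-feature lists, per-species χ², or per-organ
richness estimates), which depend on the original measurements.

## Problem sizes and determinism

Default analysis parameters follow the conventions above: 999 permutations
(floor p = 0.001), 5,000 rarefaction replicates, 2,000 classifier trees.
The test suite and examples run reduced designs (3–6 species, tens to a
few hundred compounds, tens to hundreds of replicates) chosen so each
check exercises the full code path at comfortable runtimes; statistical
assertions use tolerance bands sized to their Monte-Carlo error.  The
pipeline derives one seed per stage from a master seed by labeled hashing,
writes all artifacts with deterministic row/column ordering, and records
SHA-256 hashes in a manifest; reruns with an identical config are
byte-identical.

## Known limitations

- 1 − CSCS is not guaranteed metric; ordinations of it should use methods
  tolerant of non-metric dissimilarities (NMDS is the usual choice and is
  deliberately delegated to existing tools).
- The PERMANOVA strata restriction makes factors that are constant within
  strata (e.g., species when plants are strata) effectively tested against
  a null that only permutes within-plant structure; this mirrors the
  behavior of the standard implementations but the resulting p-values for
  such terms should be read with care.
- Tukey-adjusted LMM contrasts use a large-sample normal approximation
  rather than a small-sample degrees-of-freedom correction.
- The asymptotic-regression richness estimate is only as good as the
  model's fit to the accumulation curve; on nearly saturated curves it has
  a small downward bias (flagged in the result).
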