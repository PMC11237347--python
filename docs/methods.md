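# Methods

`streamofd` implements an occupancy-frequency-distribution (OFD) analysis for
stream insect metacommunities sampled on a nested survey design. This note
documents the statistical procedure, the choices the package makes where the
methodology leaves room, and what the synthetic data do and do not exercise.

## The pipeline

**Survey model.** Communities are observed as elementary sample units
(kick-net samples) collected from stream reaches over the four seasons of one
year. In the default design: 8 reaches, 4 seasons, 20 units per reach-season
(640 units). Reaches nest into 2 subbasins (3 reaches each), 2 basins (4
each) and one region (all 8). All downstream computation is presence/absence;
abundances are retained only for reporting.

**Dispersal groups from fuzzy-coded traits.** Trait affinities are coded
0-3 per trait category. Processing order: (1) category merging on raw codes
(merged affinity = maximum of the members), (2) standardization to
within-trait proportions summing to 1, (3) imputation of missing traits by
the mean profile of taxa sharing the lowest available taxonomic rank
(genus, then family, then superfamily; taxa with no donors are excluded from
clustering rather than filled from a global mean), (4) Gower dissimilarity
(mean over shared non-missing variables of range-normalized absolute
differences; zero-range variables contribute nothing), (5) agglomerative
Ward clustering. The number of groups defaults to k = 3 (the three dispersal
strategies of interest) but a within-cluster-sum-of-squares (WSS) curve with
an automatic knee suggestion (maximum second forward difference) is reported
so the choice can be audited. Groups are verified with ANOSIM (rank-based,
permutation p-value with the add-one estimator, so p is never 0) and
characterized by indicator analysis: for each trait category, the
point-biserial correlation against every non-empty proper subset of groups,
reporting the maximizing subset, with p-values from label permutations of
the subset-maximized statistic.

*Ward variant.* The package runs SciPy's `ward` linkage on the Gower
distances, which is the distance-based Ward update (the `ward.D2` convention
in the R ecosystem). The choice is justified when the Gower matrix is
Euclidean-embeddable, which holds for standardized proportions; the linkage
tie-break is SciPy's fixed candidate ordering, making clustering
deterministic.

*Point-biserial.* The plain (unequalized) correlation is used; group-size
equalization is not implemented because the group sizes here are similar and
the unequalized coefficient is the simplest published definition.

**Resampling.** An annually representative sample (ARS) pools one uniformly
drawn unit per season from one reach — the union of 4 units. A spatially
representative sample (SRS) is a fixed-size collection of ARSs at one
extent: 16 from a single reach (reach), 5 from each of 3 reaches (subbasin,
15 total — balanced deliberately instead of 16), 4 from each of 4 reaches
(basin) and 2 from each of the 8 reaches (region). Block selection (which
reach/subbasin/basin) is uniform over blocks. Sampling is with replacement
at both levels. ARSs with fewer than 10 taxa are unreliable for occupancy
shapes and are redrawn from the same reach (cap: 100 attempts), then dropped
with a logged shortfall; a config switch disables redrawing so the SRS
simply shrinks. The richness threshold applies to the whole-assemblage ARS,
before any dispersal-group split. Ensembles use one master seed with
per-(extent, SRS-index) substreams, so results are independent of iteration
order and reproducible bit-for-bit.

**RSOC multimodel inference.** For each SRS (per dispersal group), each
taxon's relative occupancy O_i is the fraction of the SRS's retained ARSs
containing it; taxa absent everywhere are dropped, the rest are ranked in
decreasing O_i (ties broken by taxon identifier). Five regression models are
fitted to (R_i, O_i) by Levenberg-Marquardt least squares (iteration cap
999, tolerances 1e-8, analytic Jacobians) from fixed published starting
values:

| model | equation | start | OFD pattern |
|---|---|---|---|
| exponential concave | y0 + a e^(-bR) | y0=0.01, a=1, b=0.01 | unimodal |
| power exponential | a R^b e^(-cR) | a=1, b=0.01, c=0.01 | bimodal if b>0 else unimodal |
| sigmoidal symmetric | a/(1+e^(-bR+c)) | a=1, b=-0.1, c=-1 | bimodal |
| sigmoidal asymmetric | a(1-e^(-bR^c)) | a=1, b=-1, c=-1 | bimodal |
| linear | aR + b | closed-form OLS | uniform/random |

The printed starting values for the power-exponential model label a
parameter `y0` that the equation does not contain; the package maps the
printed triple positionally onto (a, b, c). Starting values, tolerances and
the iteration cap are configurable.

Support is quantified by AICc for least squares, `n ln(RSS/n) + 2k +
2k(k+1)/(n-k-1)` with k counting the regression parameters plus one for the
residual variance (linear k=3, all others k=4). A fit needs S >= k+2 taxa so
the correction term stays defined; shorter curves skip the model. RSS is
floored at 1e-12 per point so an exact fit yields a finite AICc while still
dominating the weights. Non-convergent or non-finite fits are excluded and
the Akaike weights are renormalized over the converged set (equivalent to
assigning them infinite AICc); every exclusion is visible in the per-SRS
`converged_mask` column. Pattern probabilities sum weights by family, with
the power-exponential counted as bimodal only when its fitted exponent is
positive (only then does the curve have an inflection point).

Note a structural behavior of the candidate set: on strongly sigmoidal
curves the exponential-concave model sits on a flat ridge (b -> 0 trades off
against y0 and a) and often exhausts the iteration cap, and conversely the
sigmoidal asymmetric model often fails on concave curves. These exclusions
are the modal non-convergence events; the excluded model would have carried
negligible weight, so renormalization is benign.

**Aggregation.** Per (extent, group): means of the per-SRS pattern
probabilities, 95% confidence intervals as the 2.5/97.5 percentiles across
SRSs (a normal-approximation interval is available by option; "confidence
interval" is otherwise unspecified in the methodology), evidence ratios
computed from the *unrounded* mean weights for the pairs
bimodal/unimodal, unimodal/bimodal, random/bimodal and random/unimodal
(0/0-free: a zero numerator gives 0, a zero denominator with positive
numerator gives infinity), and the mean taxa number. OFD histograms bin
each taxon's O_i into 5 equal-width left-open right-closed classes over
(0, 1] — so O = 0.2 falls in the lowest class and O = 1 in the highest —
and average per-class counts over the ensemble.

## Synthetic data

The generator reproduces the survey design exactly and builds occupancy
structure mechanistically rather than sampling occupancies directly, so the
resampling and inference stages are exercised end to end. Per species:
core/satellite status ~ Bernoulli(p_core); a per-unit detection probability
from the status's Beta distribution (defaults: core Beta(20, 2), satellite
Beta(1, 30) — a visibly bimodal detection mixture); a uniformly chosen home
reach plus membership in every other reach with probability 1 - theta
(theta = spatial turnover, default 0.4, settable per dispersal group);
presence in a unit ~ Bernoulli(membership x detection x seasonal
multiplier); abundance, used only for reporting, 1 + Poisson(2). Default
species-pool sizes are 42/58/41 per group (matching the familiar group
sizes of the motivating system; not a claim of realism).

Trait tables come from three dispersal-strategy archetypes — an
aerial-active, long-lived, univoltine, small-bodied, low-fecundity strategy;
an active short-lived, semivoltine, larger-bodied strategy; and an
aerial-passive, very short-lived, multivoltine, drifting strategy — coded
over 8 traits / 24 categories, with each cell jittered by +-1 with
probability 0.1 and 2% of cells blanked to exercise imputation. Taxonomy is
fabricated with archetype-pure genera (~3 taxa) and families (~9 taxa) so
imputation donors exist.

Two named regimes document expected qualitative outcomes. `bimodal_reach`
(p_core 0.4, core Beta(25, 2), satellite Beta(1, 12), theta 0.15) keeps a
core plateau in reach-extent curves, so the bimodal family should dominate
there. `unimodal_region` (p_core 0.08, core Beta(15, 3), satellite
Beta(1.2, 16), theta 0.6) yields concavely decaying regional curves, so the
unimodal family should dominate at the region extent. The parameters were
chosen once from the design's occupancy arithmetic (an ARS detects a
species with probability 1-(1-p)^4; satellite-heavy regimes must still
clear the 10-taxon ARS floor), not tuned against any dataset.

What the synthetic data do *not* contain: seasonal phenology (multipliers
default to 1), spatial autocorrelation beyond the home-reach/turnover
dichotomy, abundance-driven detectability, taxonomic misassignment, or
habitat-heterogeneity gradients. Passing the synthetic-regime tests
therefore shows the pipeline recovers regimes its own generative assumptions
encode; it does not validate those assumptions against field data.

## Problem sizes

The test suite runs the regime-recovery ensembles at 1,000 SRSs per preset
and extent, the generating-model experiment at 200 replicates per model
(S = 25, noise sd 0.01), the ANOSIM null calibration at 1,000 datasets with
99 permutations each, and the trait-recovery check over 20 seeds. The
acceptance script uses 500-SRS ensembles per preset and extent. These sizes
give Monte-Carlo standard errors well inside the asserted margins. Full
10,000-SRS ensembles (the production default, `ResamplingConfig.n_srs`)
change the reported means by less than the widths of their confidence
intervals.

## Known limitations

- The field survey's deposited tables are not redistributed; field-data
  checks run only when the user fetches and converts the deposit (see
  `tests/test_acceptance.py::TestFieldDataReproduction`).
- The WSS knee heuristic (max second difference) is a tie-breakable
  convention; pin k when the curve is flat.
- The indicator-analysis permutation p-values test the subset-maximized
  statistic, which is conservative relative to testing a fixed subset.
- Occupancy ties are resolved by taxon identifier; this stabilizes runs but
  means rank order within a tie carries no information.
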