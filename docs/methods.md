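# Methods

## Problem and model

Two microbial taxa observed across a set of sites (lakes, soils, hosts) may
co-occur more or less often than chance. `guildnet` separates three causes of
such non-random association — shared environmental niches, shared dispersal
constraints, and potential biotic interaction — and assembles the residual
"interaction" pairs into a signed network whose modules are interpreted as
interacting guilds.

### Exact co-occurrence null

For a pair with occupancies `n_a`, `n_b` over `N` sites, under independent
placement the joint-presence count `J` is hypergeometric:

    P(J = j) = C(n_a, j) C(N - n_a, n_b - j) / C(N, n_b),
    j in [max(0, n_a + n_b - N), min(n_a, n_b)].

Both tails include the observed point mass (so `p_lt + p_gt >= 1` always); a
pair is *aggregated* when `p_gt < alpha`, *segregated* when `p_lt < alpha`,
*random* otherwise. The pmf is evaluated in log space (`gammaln`) and
renormalised, keeping normalisation error below 1e-12 up to `N = 10,000`.
Pairs with expected joint count `n_a n_b / N` below `min_expected` (default 1)
are reported but flagged untestable. The test conditions on the margins and is
exact; being discrete it is conservative, but note that with two tails at
`alpha = 0.05` each, the non-random rate under a true null approaches 10% for
species of intermediate occupancy, where the support is nearly continuous.

### Cause attribution

For each non-random pair two site groups are formed: *segregated* — allotypic
sites (only A vs only B); *aggregated* — sites with both species vs sites with
neither. Each of the nine environmental covariates is compared between groups
with a two-group one-way ANOVA (`df = (1, n-2)`); spatial segregation is
tested with a one-way MANOVA of the site coordinates using Pillai's trace,
which for two groups is exact and equivalent to Hotelling's T². Conventions:
zero within-group variance with equal means gives `p = 1`; with unequal means
`F = inf`, `p = 0`; a singular pooled covariance makes the MANOVA NA. A pair
is testable only when both groups have at least 3 sites (the two-response
MANOVA minimum, which subsumes the ANOVA's 2); untestable pairs form their own
category so they cannot inflate the interaction class.

Final cause: environment (some covariate significant), dispersal (MANOVA
significant), both, or — when nothing is significant — *interaction*. By
default no multiple-testing correction is applied across the nine covariates
or across pairs, mirroring the framework as commonly practised;
Benjamini–Hochberg is available per pair (`env_correction="bh"`) and across
pairs (`pair_correction="bh"`). Note that with nine simultaneous tests at
`alpha = 0.05`, a pair with no real environmental signal is falsely
"explained" with probability ~1 − 0.95⁹ ≈ 37%; the recovery benchmark
therefore runs with BH per pair, and users hunting interactions should too.

One caveat worth knowing: the group comparison is a mean-difference test, so a
niche centred at the middle of a covariate's range can be invisible (the
"both-present" and "both-absent" groups then share the same mean), even though
the niche genuinely drives the pair.

### Variable ranking

Per edge type, variables are ranked greedily by the number of not-yet-covered
pairs they explain (cumulative-coverage ranking), ties broken by variable
name; total and unique proportions and the dispersal-only share are reported.

### Signed network and guilds

Interaction-class pairs become edges weighted by
`s * (log10 alpha - log10 p)` with `s = +1` (co-occurrence, `p = p_gt`) or
`-1` (co-exclusion, `p = p_lt`): zero exactly at the significance boundary,
growing with the order-of-magnitude surplus of evidence. Underflowed p-values
are clamped at 1e-320 with a warning.

Guilds are found with the spinglass community algorithm in its negative-weight
variant (igraph), run per connected component with 25 seeded restarts; the
partition kept is the one maximising the signed modularity

    Q = w+/(w+ + w-) Q+  -  w-/(w+ + w-) Q-,

the weighted-Newman decomposition into positive and negative subgraphs.
Components with at most 8 nodes are instead partitioned by exhaustive
enumeration of set partitions against the same objective — exact,
deterministic, and immune to an annealing stall we observed on tiny graphs.

Module metrics follow common network practice: diameter on `|weight|`
distances but average path length in hops (these two conventions reproduce
diameters an order of magnitude above path lengths, as weighted evidence
accumulates along paths; both are switchable), clustering as mean local
transitivity excluding degree-<2 nodes, hub values as the principal
eigenvector of the `|weight|` adjacency (computed by dense symmetric
eigendecomposition for exact reproducibility, max-normalised, invariant to
weight rescaling), weighted degree as the signed strength. Disconnected pairs
are excluded from path statistics with a logged count.

### Guild statistics

Chi-square independence tests (no continuity correction) report Pearson
residuals and their percentage contribution to the total statistic (summing
to 100 whenever chi² > 0). Genus-level cause profiles are clustered with PAM
(k-medoids, greedy BUILD + full SWAP, Euclidean distance by default), choosing
`k` in 2..10 by maximum average silhouette; PAM is deterministic given the
feature matrix. Occupancy/abundance contrasts between interacting and
non-interacting taxa use the two-sided Wilcoxon rank-sum test, exact for
combined n <= 25 without ties, normal approximation with tie correction
otherwise.

## Synthetic metacommunity generator

No generative model accompanies the original analysis; every distributional
choice here is a stand-in built to plant known causes at realistic scale.

* **Sites** (default 224, mirroring an alpine lake district): coordinates
  uniform on a 100×100 landscape; each of the nine covariates (pH, DOC, NO₃,
  TP, SRP, DRSi, SO₄, water-renewal time, altitude; ranges in limnological
  units) is a linear spatial trend in a random direction plus
  Gaussian-bump-smoothed noise, rescaled into its declared range. Trend
  weights are fixed per variable (altitude 0.8, pH 0.6, nutrients 0.3–0.5),
  so environment and space are partially confounded — exactly the confounding
  attribution must untangle, and the reason dispersal-planted pairs
  legitimately also show environmental signal.
* **Species occurrence**: `P(present) = logistic(baseline_logit + niche -
  dispersal penalty)`. The niche term is `niche_height * (exp(-z²/2) - 1/2)`
  with `z` the covariate distance to the niche centre in units of
  `niche_width` — favoured inside the niche, penalised outside;
  `niche_height` defaults to 6 logits. The dispersal penalty is
  `(d / radius)²` from the dispersal centre. Interactions are applied by
  sequential conditional sampling: the later-listed member's logit is shifted
  by `sign × strength` at sites where the earlier member was realised
  (directed generation, undirected truth label).
* **Truth labels** per pair, priority interaction > dispersal > environment
  (recovery tests target the rarest class): interaction for planted pairs
  with positive strength; dispersal when centres lie within the smaller
  radius; environment when the same covariate is used with centres within the
  summed widths.
* **Counts**: per site, depth uniform over a range (default 5,000–20,000 to
  exercise rarefaction at 5,000), multinomial over present species with
  probabilities proportional to `mean_abundance` × lognormal(σ=0.5) noise.
  Empty sites yield all-zero columns with a warning.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific detection bias, temporal dynamics, indirect (chain) biotic
effects, and abundance-mediated interactions. Passing recovery tests
therefore show that the inference chain works when its assumptions hold, not
that real lakes satisfy them.

## Preprocessing

Rarefaction subsamples each site without replacement (multivariate
hypergeometric) to a fixed depth (default 5,000); shallower sites are dropped
with a warning rather than resampled. The occupancy filter keeps taxa present
in at least `ceil(fraction × n_sites)` sites (default 10%; for 240 sites that
is the conventional 24, and the boundary taxon is kept). Mean relative
abundance is annotated from pre-rarefaction proportions — the stage is not
universally standardised, so it is recorded in the output metadata.

## Problem sizes and numerics

Benchmarks run at sizes a laptop handles in seconds to minutes: null
calibration at 50 species × 300 sites (1,225 pairs); planted-cause recovery
over 50 independent 200-site metacommunities with 2 environment, 2 dispersal
and 2 facilitation pairs each (strength 4 logits); the guild toy is two
6-cliques of positive edges bridged by 4 negative edges, solved by annealing
and checked against exhaustive bipartition enumeration. The full demo
pipeline (224 sites × 150 species, ~11k pairs) completes in well under a
minute. Distributions are cached per occupancy pair; all randomness flows
from one root seed through `numpy.random.SeedSequence`, and reruns are
bit-identical (hub scores and small-component partitions are computed by
deterministic exact methods for precisely this reason).

## Known limitations

* Attribution inherits the mean-difference blindness noted above and assumes
  the measured covariates span the relevant environmental axes; unmeasured
  variables masquerade as interactions.
* The interaction class is a *residual*: it also absorbs model misfit and, at
  default settings (no multiple-testing correction), loses pairs to chance
  environmental "explanations".
* Spinglass annealing is stochastic; restarts plus the signed-Q selection make
  it reproducible per seed, but very flat objectives may still yield
  different partitions across seeds.
* The generator's interaction mechanism is a one-directional logit shift;
  symmetric or density-dependent interactions are out of scope.
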