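# Methods

## Community summaries

A survey consists of six transects per fragment. Botany (percent cover of
each vascular plant, bare ground and litter in a 1 × 5 m plot) is recorded
once per transect; leafhopper counts carry a sampling occasion (1–3).
Pooled abundance per fragment is the straight sum over transects and
occasions; species summing to zero are dropped. Relative cover of species
*s* on a transect is cover_s / (Σ plant covers + bare + litter), so the
per-transect fractions plus the bare/litter remainder sum to one.

**Mean-of-ratios.** Fragment-level relative cover is the arithmetic mean of
per-transect relative covers (absent species contribute zero), not the
ratio of summed covers. Computing the ratio per plot first respects the
plot as the observation unit and keeps transects with sparse vegetation
from dominating the denominator; the choice is pinned by tests. Plant
richness per fragment counts taxa with positive cover on at least one
transect (zero-cover records do not count). Degenerate transects (zero
total cover) are skipped with a warning; a fragment is rejected only when
every transect is degenerate. Missing occasions are treated as zero counts
with a logged warning rather than an error.

A leafhopper is a habitat specialist iff either of two conditions holds:
strict habitat requirements (warm, dry, short-sward calcareous grassland)
or a diet restricted to plants exclusive to it. Both flags ship in the diet
table; classification is their OR.

## Web assembly

Exclusion rules, in order: (1) taxa not identified to species level and
(2) taxa whose food plants are unknown at species or genus rank are dropped
globally; (3) taxa none of whose food plants was recorded in the fragment
are dropped per fragment. Every drop is logged with its specimen count, so
pooled = allocated + excluded holds exactly per fragment and study-wide.

Diet matching: species-rank entries match the exact taxon (names compared
after trimming and case-folding — no external taxonomic resolution);
genus-rank entries match **all** recorded congeners. Genus-rank knowledge is
treated as usable because diets unknown "at genus or species level" are
already excluded by rule 2; matching only the named species would make
genus-rank entries dead weight.

Allocation: one matched plant receives the full abundance; several share it
proportionally to their mean relative covers re-normalised over the matched
set only (the weights are relative to available food, not to the whole
sward). Allocations stay real-valued — integer rounding would break
conservation and the split is a model quantity, not a count. Allocation is
therefore invariant to rescaling all covers by a constant.

## Network indices

With p_ij = b_ij/B: interaction diversity H = −Σ p_ij ln p_ij (nats);
weighted generality G = Σ_j (b_+j/B) exp(H_j) where H_j is the entropy of
column j's proportions; vulnerability V is the row-wise mirror; weighted
linkage density LD = (G+V)/2. Effective numbers are base-invariant (base-2
entropies with 2^H give the same values), so the natural-log choice is
cosmetic. Empty cells contribute nothing (0·ln 0 := 0). All four indices
are invariant to scaling b and to row/column permutations; merging two
disjoint copies of a web leaves G, V, LD unchanged and raises H by ln 2 —
these invariants are enforced by property tests against plain-loop oracles.

## Connectivity

S_i = Σ_{j≠i, d_ij ≤ radius} exp(−α d_ij) · (area_scale · A_j)^β with
centroid Euclidean distances. Defaults: α = 0.001 m⁻¹ (decay length 1 km),
β = 0.5 (diminishing returns of patch area), radius = 2000 m. The index's
magnitude depends on the unit of area inside the kernel, which the
incidence-function literature leaves open; `area_scale` makes it explicit.
With areas kept in hectares (area_scale = 1) a single 4-ha neighbour at
1 km contributes e⁻¹·2 ≈ 0.74; the synthetic landscapes and the default
pipeline configuration use area_scale = 10⁴ (areas in m²), under which
2-km neighbourhoods of grassland patches produce indices on the familiar
20–849 scale. α and β are free configuration parameters throughout.

The design screen reports pairwise Spearman correlations (ties mid-ranked)
among size class (0/1), log₁₀ connectivity and % arable; a constant
variable yields NaN with a warning.

## Inference protocol

Responses: LD, G and H as Gaussian linear models; the specialist/generalist
species-richness ratio as a binomial GLM (logit link, successes = specialist
richness, trials = specialist + generalist richness in the web), fitted by
IRLS to tolerance 1e-8. Covariates: L (% arable), S (size class, small = 0 /
large = 1), C (connectivity, log₁₀-transformed for its non-linear effect),
their two-way interactions, and R (web plant + consumer richness) as a free
control covariate. Continuous covariates are standardised to [0,1] after
transformation.

All 36 submodels of the global model (18 marginality-respecting subsets of
the three mains and their interactions, doubled by R, including the null)
are fitted and ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with n = number
of fragments. For Gaussian fits the likelihood is the ML profile (variance
= RSS/n) and k counts intercept + slopes + the variance parameter — stated
explicitly because implementations differ and AICc values are otherwise not
comparable. The candidate set keeps ΔAICc strictly below 6; Akaike weights
exp(−Δ/2) are renormalised within it. AICc ties break by fewer terms, then
canonical term order, so output is deterministic.

Conditional averaging: each term is averaged over only the candidate models
containing it, with weights renormalised within that subset — avoiding the
shrinkage toward zero that full-model averaging imposes on rarely-selected
terms. The reported standard error combines within-model variance and
between-model spread, SE = Σ w̃_m √(se_m² + (β_m − β̄)²); CI95 = 1.96·SE;
significance stars use the two-sided normal z = β̄/SE at 0.05/0.01/0.001.
Importance is the integer count of candidate models containing the term,
not a weight sum. Binomial fits flagged for non-convergence or separation
(|β| > 15, SE > 50, or an IRLS failure) are excluded from ranking and
averaging with a warning.

For the binomial response the reported "R²" of the global model is the
squared Pearson correlation between observed proportions and fitted
probabilities — a deliberate, clearly-labelled analogue, since no single
pseudo-R² is canonical. VIFs (1/(1−R²) from regressing each main-effect
column on the others) are reported as a collinearity diagnostic.

## Synthetic studies

The generator emulates the study design rather than any particular dataset:

* **Landscape.** 28 focal fragments (14 small 0.06–0.60 ha, 14 large
  1.24–8.76 ha) on a 6-km grid (2-km neighbourhoods never overlap), each
  with a private Poisson-sized cluster of neighbour patches whose areas are
  scaled so computed connectivity is stratified log-uniformly across
  ≈ 20–849. Arable cover is uniform on 27–77%. The three design variables
  are rejection-sampled to pairwise |Spearman ρ| < 0.3, echoing the weak
  correlations of a well-balanced design.
* **Plants.** 167 taxa built from real grassland genera (several congeners
  per genus, so genus-rank matching is exercised); regional prevalence
  ~ Beta(0.9, 2.4), giving ≈ 45 species per fragment; per-transect covers
  log-normal around a species mean with 70% transect occupancy; ~35% of
  taxa flagged as calcareous-exclusive (the specialist diet pool).
* **Consumers.** 29 specialists + 38 generalists, plus 1 unidentified,
  4 diet-unknown and 4 restricted-diet taxa that exercise exclusion rules
  1–3 (together ≈ 5% of specimens). Diets are drawn prevalence-weighted
  within the class pool; monophagy probabilities 0.66 (specialists) and
  0.24 (generalists); 15% of polyphage entries are genus-rank.
* **Effect structure.** The truth is a logit-linear model for the expected
  specialist share of the community on the standardized covariate scale,
  with default coefficients matching the emulated study's averaged
  estimates (θ_S:C = 1.134, θ_S = −1.017, intercept ln(29/38), small L/C
  terms). Per fragment, specialist and generalist occupancy probabilities
  are tilted so the expected specialist richness share equals
  logistic(θ·x); normalising by the number of species whose food plants
  grow in the fragment keeps both the share and the mean richness (24
  species/fragment) on target despite the availability filter. Counts per
  present species are negative-binomial (means 15/6/9 for
  specialist/generalist/excluded taxa, dispersion 1.5 — overdispersed
  because clean Poisson counts are unrealistically well-behaved) and
  spread over the 6 × 3 transect–occasion grid by a Dirichlet-weighted
  multinomial (sweep-net catches are clumped).

A single integer seed drives a hierarchical seed tree (landscape / pools /
communities), so a study is fully reproducible and components can be
regenerated independently; `truth.json` records θ and the full
configuration. A hand-written 3-fragment fixture (`tiny_fixture`) covers
every assembler branch deterministically.

**What the generator does not emulate:** spatial autocorrelation of
vegetation, phenology across the three occasions (draws are independent),
detection error, taxonomic ambiguity beyond the single "sp." taxon, and
management differences between fragments. Passing tests therefore certify
the pipeline's arithmetic and its statistical behaviour under the assumed
data-generating model, not robustness to those field realities.

## Problem sizes and numerical choices

The packaged experiments use 28-fragment studies for end-to-end runs, 1000
random webs (≤ 6 × 6) for the metric-oracle comparison, and 100 replicates
of 200 fragments with a standardized S×C coefficient of 2 for parameter
recovery — sizes at which the recovery criterion (CI coverage ≥ 90%, sign
recovery ≥ 95%) is met with margin while a full run of suite plus
acceptance script stays under a minute of compute. The recovery experiment
drives the generator's occupancy model directly (design plus richness
counts) rather than assembling webs for every replicate: the binomial
richness-ratio model consumes exactly those counts, and the occupancy code
path is the one the community generator uses.

Tolerances: oracle equivalence for indices at 1e-10; OLS against normal
equations at 1e-8; IRLS tolerance 1e-8; conservation identities at 1e-9
(float allocation). Degenerate inputs: constant vectors cannot be
standardized (error); rank-deficient designs raise an error naming the
aliased columns; an all-excluded fragment raises an empty-web error rather
than emitting an empty matrix.

## Known limitations

* Exclusion rule 3 and allocation depend on mean relative cover being a
  fair availability proxy; no phenological matching between sampling
  occasion and plant cover is attempted.
* Conditional averaging reports Buckland-style unconditional SEs; these are
  known to be approximate when candidate sets are small and heterogeneous.
* The binomial "R²" is a convenience analogue and should not be compared
  against Gaussian R² values.
* Connectivity assumes planar centroid distances; no barriers or matrix
  permeability enter the kernel.
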