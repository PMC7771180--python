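# Methods

## The analysis model

The pipeline treats a metabarcoding diet study as a set of long-format
read-count records `(sample, run, BIN, reads)` plus design metadata. Runs
are the four primer × PCR-replicate combinations per sample; BINs are the
prey-item units. All ecological statistics operate on *merged sample
compositions* — the per-sample BIN sets (and summed reads) that remain after
filtering — so the filtering chain fully determines what the ecology sees.

### Filtering chain and its conventions

1. **Low-read removal.** A `(sample, run, BIN)` record is dropped iff
   `reads < min_reads` (default 2; a record with exactly `min_reads` reads is
   retained). The threshold is calibrated by filtering sweep-net molecular
   data at thresholds 1–5, collapsing BINs to order-level presence, and
   maximizing mean per-sample Jaccard similarity with the morphological
   order sets; ties break toward the smaller threshold (retains more data).
   Bray–Curtis on order proportions is selectable as the similarity.
2. **Blank rule.** For each BIN in a blank with read count `r_b`, sample
   records with `reads < 10 × r_b` are removed; equality retains. With
   multiple blanks in scope the maximum `r_b` is used (most conservative).
   Extraction blanks act within their extraction batch and sequencing blanks
   within their sequencing run (`scope="batch"`, the default); a study-wide
   `scope="global"` exists for studies without batch metadata. Extraction
   and sequencing rules are applied independently, in that order. Blanks
   carrying the same BIN in both roles are therefore handled by whichever
   rule fires; no cross-rule reconciliation is attempted.
3. **Replicate combination.** *Additive*: per sample × primer, union of the
   two replicates with reads summed. *Conservative*: a sample is dropped iff
   any of its four expected runs is missing or totals ≤ `min_run_reads`
   (default 100, strictly "more than"); run totals are evaluated after the
   low-read filter. For retained samples a BIN needs presence in both
   replicates of a primer. The conservative BIN set is provably a subset of
   the additive one; the suite checks this over 20 generated studies.
4. **Primer union.** Per-sample BIN presence is the union over primers;
   duplicated BINs collapse with reads summed (reads only matter to RRA).

Every removal is appended to an audit table `(rule, sample, run, BIN,
reads_removed, blank_reads)`; input = output + audit is tested, and each
rule is idempotent.

### Diet metrics

wPOO weights each sample equally and splits its unit mass over the items it
contains (presence-based, `1/n_s` per item; `n_s` counted at BIN level and
then collapsed to coarser levels, so order-level wPOO is the sum of its
BINs' contributions — aggregation commutes with normalization and needs no
renormalizing). POO and RRA follow their standard definitions. Levins'
`B_A` standardizes by `n` = the number of distinct BINs observed in the
focal diet; using all BINs in the study is selectable.

### Overlap and its null models

Pianka's `O_jk` is computed on wPOO vectors indexed on the union of BINs;
zero columns are retained because RA3 can move mass onto them (all resource
states are treated as usable). Null algorithms follow the co-occurrence
randomization family: RA1 (uniform resample), RA2 (uniform on the observed
support), RA3 (permute each row's values over all columns — the default, as
it retains each species' niche breadth), RA4 (permute nonzero values over
nonzero columns). Both tail probabilities are reported with the small-sample
`+1` correction, `p = (1 + #{null ≥ obs})/(n_iter + 1)`, ties counted in
both tails; "higher than null" claims read `p_high`. Defaults: 1,000 null
iterations, 999 ANOSIM permutations, average ranks on ANOSIM ties.

Stratified overlap pools each species' samples per stratum (broad:
allopatric/sympatric from the regional design; fine: allotopic/syntopic by
the 3 km rule within the sympatric region). Pairwise site overlap computes
`O_jk` between wPOO vectors of site pairs holding different species, within
each stratum; the resulting table is the response variable for downstream
model fits, which are out of scope here.

### Spatial classification

Distances are great-circle (haversine) on WGS84 decimal degrees with Earth
radius 6371.0088 km. A sympatric-region site is syntopic iff its distance to
any record of the other species is ≤ 3 km (boundary counts as syntopic, the
radius being a home-range-scale cutoff); otherwise allotopic. Swarming
sites, where bats congregate from far-away colonies, can be flagged
`excluded`, which removes their samples from both spatial scales.

### Functional classification and selection

Functional rules are keyed by taxon name; a BIN matches at species, then
family, then order rank — most specific wins — and unmatched BINs are
`unclassified`, excluded from denominators rather than forming a fourth
category. The per-sample "% not nocturnally volant" is count-based
(classified BINs in the non-volant or not-actively-volant categories over
classified BINs); an occurrence-weighted variant is selectable but coincides
with count-based weighting for equally weighted items.

The representativeness gate compares BIN sets: a site enters selection
analysis iff `|diet ∩ sweep| / |diet| ≥ 0.20` (boundary retains). Selection
is the simplex difference diet − availability at order or functional level,
so it sums to zero per site. Cross-site summaries use type-7 (linear
interpolation) quartiles and a percentile bootstrap (10,000 resamples of
sites with replacement) for the CI of the mean; flags are `over` if Q1 > 0
and `under` if Q3 < 0. The flag's specificity is intrinsically tied to the
number of retained sites: with few sites, quartile signs are driven by
small-sample sign coincidences, so the suite's specificity control runs at
20 single-species sites.

## The synthetic-data generator

The generator emulates the data structure the analysis assumes, not
sequences or phylogenies.

- **Prey pools.** Each species' pool holds `pool_size` BINs of which a
  fraction `pool_overlap` is shared; item scores are Gamma draws (shared
  items share one score, so `pool_overlap = 1` gives identical pools and
  unit true overlap). In syntopic sites, shared-item scores are multiplied
  by `1 − syntopic_shift`, diverging the species' utilization there.
  Ground-truth vectors per stratum (and sample-count-weighted mixtures for
  "sympatric" and "overall") are stored with their implied Pianka overlaps.
- **Samples.** A dropping sample draws weights `w ~ Dirichlet(α·p)` from its
  species-stratum vector; per run, reads are negative-binomial totals
  multinomially allocated over `w` after per-(primer, order) detection
  thinning (Bernoulli per sample × primer, shared across replicates) and
  whole-replicate dropout. Per-sample item counts are therefore emergent,
  not fixed. 1-read "noise" records from taxonomically foreign orders are
  injected at a configurable rate to exercise singleton removal.
- **Contamination.** Contaminant BINs live outside both pools. Blanks (one
  extraction blank per batch, one sequencing blank per run) carry
  `1 + Poisson` reads of every contaminant; samples receive geometric-tailed
  carry-over reads at a low rate, so both the removal branch and the ≥ 10×
  retention branch of the blank rule occur.
- **Sweeps and morphology.** Each site has an availability composition
  covering `sweep_coverage` of the local diet pool plus availability-only
  BINs. A sweep sample first draws its specimen pool (Poisson individuals,
  multinomial over the sample's weights); the morphology table records the
  complete order totals of those specimens, and molecular reads are
  generated from the same specimen composition — matching the field
  protocol, where every swept individual is identified morphologically and
  then pooled for sequencing. Orders in `blind_orders` have zero detection
  under both primers, so they appear morphologically but never molecularly.
  Setting `selection_bias_factor < 1` for one order under-represents it in
  availability (planting over-selection); `availability_mirrors_diet=True`
  sets availability equal to the site's diet truth (the specificity
  control).
- **Randomness.** A single seed drives hierarchical substreams (one per
  sample, sweep, blank and site), so enlarging a design does not perturb
  previously generated draws; the same config and seed reproduce the study
  exactly.

Defaults mirror a two-region, two-species field study: 39 sites across
allopatric/allotopic/syntopic strata, 5 dropping samples per site per
species present, ~900 BINs with ~500-BIN pools sharing 37 % (the share
implied by per-species and total BIN counts of that design), ~3,000 reads
per run, two primers with taxon-biased detection, 2 % replicate dropout, and
order weights echoing a moth/fly/spider-dominated insectivore diet.

### What the generator does and does not show

True prey-use vectors are the multinomial pool proportions. Occurrence-based
wPOO estimates a saturating transform of abundance: items common enough to
appear in nearly every sample are clipped at presence. In the sparse regime
(low per-sample Dirichlet concentration, samples holding a handful of
items), occurrence shares track pool proportions closely, and the suite's
parameter-recovery tests are run there (α = 2.5, 40 samples per species per
stratum recovers stratified `O_jk` within ±0.1 of truth). At the default
richer regime wPOO still orders strata correctly (the syntopic-divergence
sign test passes), but its absolute level is compressed relative to the
abundance-based truth. Passing tests therefore demonstrate correctness of
the estimators and the qualitative robustness of the spatial contrasts, not
that wPOO is an unbiased abundance estimator on real data — it is not, and
that limitation is inherent to occurrence metrics, not to this
implementation. The generator also omits real-data features such as
sequence-level error structure, index hopping, chimeras, phylogenetically
correlated detection bias, and within-site habitat heterogeneity.

## Numerical choices

Proportions live on [0, 1] (the CLI prints percentages). Simplex sums are
asserted to 1e−9; oracle comparisons to 1e−12. Pianka clips to [0, 1]
against floating-point drift and rejects zero vectors; degenerate null-model
matrices (a single usable resource state) raise. Empty or zero-read samples
are excluded from metrics with warnings, decrementing the sample count.
Quartiles use linear interpolation; ANOSIM ranks use average ties. Problem
sizes in the test suite and acceptance script (10–50 seeds, 100–1,000
randomization iterations, studies of 40–280 samples) were chosen as the
smallest designs at which the tested contrasts are statistically decidable.

## Known limitations

- The blank rule compares per-run read counts against the scoped maximum
  blank count; it does not model error rates per taxon (no model-based
  decontamination).
- ANOSIM permutations are vectorized over a dense pair mask, which is
  memory-heavy beyond a few thousand samples.
- The conservative replicate criterion requires exactly 2 primers × 2
  replicates; other run structures are accepted only by the additive path.
- Hurdle/linear/negative-binomial model fits on the exported per-sample and
  per-site-pair tables are deliberately left to downstream statistical
  tooling.
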