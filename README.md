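# trophiq

Diet analysis for DNA metabarcoding studies of trophic partitioning — built
around the question of how two cryptic, morphologically similar bat species
(*Myotis escalerai* and *M. crypticus*) divide prey resources where their
ranges overlap. The package takes BIN-level read-count tables (BINs —
Barcode Index Numbers — are the stable OTU-like prey-item units of the BOLD
system) and carries them through quality filtering, diet quantification,
niche-overlap testing and prey-selection analysis, stratified by
allopatry/sympatry at a broad (regional) and a fine (within-region, 3 km)
spatial scale. A synthetic-data generator produces complete studies with
known ground truth, so every stage has parameter-recovery tests and nothing
needs to be downloaded.

## What it computes

**Filtering** (per sample × sequencing run, two primers × two PCR
replicates): removal of low-read BIN records (default minimum 2 reads, i.e.
singleton removal, with the threshold calibrated against morphological
identification of sweep-net samples); removal of BINs found in
extraction/sequencing blanks from samples with fewer than 10× the blank's
reads; replicate combination under an *additive* (union) or *conservative*
(intersection, runs > 100 reads) criterion; primer union. Every removal is
logged to an audit table.

**Diet metrics.** For a set of samples, item proportions by

- wPOO (weighted percent of occurrence): `wPOO_i = (1/S) Σ_s x_is / n_s`,
  where `x_is` counts item *i*'s occurrences in sample *s* holding `n_s`
  items — an item found with 9 others contributes 1/10 of a sole item;
- POO: occurrences of *i* over all occurrences;
- RRA: mean per-sample read share of *i*;

at BIN, arthropod-order, or functional-category level, plus Levins' niche
breadth `B = 1/Σp_i²`, standardized `B_A = (B−1)/(n−1)`.

**Niche overlap.** Pianka's index
`O_jk = Σ p_ij p_ik / √(Σ p_ij² Σ p_ik²)` between the two species' pooled
wPOO vectors, tested against randomization nulls (RA1–RA4; default RA3,
which shuffles each species' utilization values across all resource states,
keeping niche breadth while scrambling resource identity). Jaccard distances
between samples feed an ANOSIM permutation test
(`R = (mean between-group rank − mean within-group rank)/(M/2)`). Overlap is
computed per stratum (allopatric/sympatric; allotopic/syntopic) and between
pairs of sites holding different species.

**Functional diet and selection.** BINs are classified non-volant / not
actively volant / nocturnally volant (most specific taxon rule wins), giving
per-sample percentages of not-nocturnally-volant prey. At sites where sweep
sampling covers ≥ 20 % of the diet BINs, selection = diet wPOO − availability
wPOO per order, summarized across sites by quartiles and a bootstrap CI of
the mean, flagging over-selected (Q1 > 0) and under-selected (Q3 < 0) prey.

## Worked example

```python
from trophiq import (GeneratorConfig, generate_study, filter_reads,
                     diet_by_group, stratified_overlap)

study = generate_study(GeneratorConfig(seed=11))
comp, audit, dropped = filter_reads(study.reads, study.metadata)

meta = study.metadata.set_index("sample_id")
drops = comp[comp.sample_id.map(meta.sample_type) == "dropping"]
diet = diet_by_group(drops, study.metadata, "bat_species",
                     level="order", taxonomy=study.taxonomy)
overlap = stratified_overlap(drops, study.metadata, scale="broad",
                             n_iter=1000, seed=11)
```

printing the top diet orders (% wPOO per species) and stratified overlap:

```
unit_id      crypticus  escalerai
Lepidoptera       23.7       26.1
Diptera           25.1       23.4
Araneae           17.8       19.5
Hemiptera          9.1        9.5

allopatric: O_jk = 0.34 (truth 0.38, p_high = 0.606)
sympatric:  O_jk = 0.20 (truth 0.21, p_high = 1.000)
```

Both species eat mostly moths, flies and spiders; the estimated Pianka
overlap per stratum lands close to the generator's ground truth, and
`p_high` gives the exact fraction of 1,000 RA3 null overlaps at or above the
observed value.

The same pipeline is scriptable from the shell:

```bash
trophiq simulate --config gen.yaml --seed 11 --out study/
trophiq filter --in study/ --out study/
trophiq overlap --in study/ --out study/ --scale fine --pairwise
trophiq selection --in study/ --out study/ --min-frac 0.2
```

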