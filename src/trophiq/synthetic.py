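"""Synthetic metabarcoding studies with known ground truth.

The generator emulates the statistical structure of a two-species bat-diet
metabarcoding study: each fecal ("dropping") sample draws a sparse per-sample
prey composition from its species' stratum-level prey pool (Dirichlet weights
around pool proportions), allocates sequencing reads per run by multinomial
sampling, thins detection per (primer, order) to mimic primer taxonomic bias,
drops whole PCR replicates at random, and injects low-level cross
contamination shared with extraction/sequencing blanks.  Vegetation-sweep
("sweeping") samples draw from a per-site availability composition that
covers a configurable fraction of the diet pool; morphological order counts
are taken from the same realized sweep composition, so orders invisible to
both primers ("primer-blind") remain visible morphologically.

Ground truth (pool proportion vectors per species and stratum, the Pianka
overlap they imply, the contaminant BIN set, the detection matrix, per-site
diet and availability vectors) is returned alongside the tables so every
downstream stage has parameter-recovery tests.

Randomness is hierarchical: one global seed spawns independent substreams per
sample, so enlarging the design does not perturb previously generated samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data_model import StudyTables, validate_study
from .overlap import pianka

SPECIES = ("escalerai", "crypticus")

#: arthropod orders and their approximate share of the prey pool
ORDER_WEIGHTS = {
    "Lepidoptera": 0.24, "Diptera": 0.24, "Araneae": 0.18, "Hemiptera": 0.10,
    "Coleoptera": 0.06, "Orthoptera": 0.05, "Neuroptera": 0.03,
    "Trichoptera": 0.03, "Blattodea": 0.02, "Ephemeroptera": 0.02,
    "Opiliones": 0.01, "Isopoda": 0.01, "Psocodea": 0.01,
}

#: orders used only for planted 1-read noise, foreign to every prey pool
NOISE_ORDERS = ("Zoraptera", "Embioptera", "Raphidioptera")

#: default primer taxonomic bias: (primer A prob, primer B prob) overrides
DEFAULT_DETECTION_BIAS = {
    "Coleoptera": (0.95, 0.45),
    "Orthoptera": (0.95, 0.50),
    "Neuroptera": (0.90, 0.40),
    "Trichoptera": (0.50, 0.90),
    "Blattodea": (0.60, 0.90),
}

PRIMERS = ("A", "B")
REPLICATES = ("1", "2")

_STRATA = ("allopatric_a", "allopatric_b", "allotopic_a", "allotopic_b", "syntopic")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters for :func:`generate_study`.

    Defaults mirror a two-species, two-region study: ~50 sites split between
    broad-scale allopatry and a sympatric region holding allotopic and
    syntopic locations, ~5 dropping samples per site per species present,
    ~3000 reads per sequencing run, two primers x two PCR replicates.
    """

    # design
    n_sites_allopatric_a: int = 13
    n_sites_allopatric_b: int = 13
    n_sites_allotopic_a: int = 7
    n_sites_allotopic_b: int = 7
    n_sites_syntopic: int = 8
    samples_per_site: int = 5
    # prey pools
    n_bins_total: int = 900
    pool_size: int = 500
    pool_overlap: float = 0.37
    pool_concentration: float = 1.0
    syntopic_shift: float = 0.6
    sample_alpha: float = 5.0
    # sequencing
    reads_per_run_mean: float = 3000.0
    reads_per_run_dispersion: float = 1.5
    detection_base: float = 0.9
    detection_bias: dict = field(default_factory=lambda: dict(DEFAULT_DETECTION_BIAS))
    blind_orders: tuple = ("Opiliones",)
    replicate_dropout: float = 0.02
    # contamination
    n_contaminants: int = 8
    blank_reads_mean: float = 15.0
    carryover_rate: float = 0.05
    carryover_mean: float = 60.0
    batch_size: int = 24
    n_sequencing_runs: int = 2
    # availability / sweeps
    n_sweep_samples_per_site: int = 1
    sweep_alpha: float = 30.0
    sweep_reads_mean: float = 5000.0
    sweep_coverage: float = 0.2
    availability_extra_bins: int = 60
    availability_concentration: float = 1.0
    availability_mirrors_diet: bool = False
    selection_bias_order: str | None = None
    selection_bias_factor: float = 1.0
    morph_individuals_mean: float = 174.0
    # planted noise (1-read error BINs from foreign orders)
    n_noise_bins: int = 30
    sweep_noise_rate: float = 2.0
    dropping_noise_rate: float = 1.0
    # functional structure
    functional_mixture: tuple = (0.20, 0.45, 0.35)
    families_per_order: int = 3
    seed: int = 0

    def noiseless(self, **overrides) -> "GeneratorConfig":
        """A copy with perfect detection and every noise source switched off."""
        clean = dict(
            detection_base=1.0, detection_bias={}, blind_orders=(),
            replicate_dropout=0.0, n_contaminants=0, carryover_rate=0.0,
            sweep_noise_rate=0.0, dropping_noise_rate=0.0,
        )
        clean.update(overrides)
        return replace(self, **clean)

    def validate(self) -> None:
        probs = [self.pool_overlap, self.syntopic_shift, self.detection_base,
                 self.replicate_dropout, self.carryover_rate, self.sweep_coverage]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("generator probabilities must lie in [0, 1]")
        shared = int(round(self.pool_overlap * self.pool_size))
        needed = 2 * self.pool_size - shared + self.n_contaminants
        if needed > self.n_bins_total:
            raise ValueError(
                f"infeasible config: pools + contaminants need {needed} BINs "
                f"but n_bins_total = {self.n_bins_total}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator."""

    bin_ids: list
    species: tuple
    strata_vectors: dict          # stratum -> species -> proportion vector
    true_overlaps: dict           # stratum -> Pianka index
    contaminant_bins: set
    detection: pd.DataFrame       # order x primer detection probabilities
    site_diet: dict               # site_id -> diet proportion vector
    site_availability: dict       # site_id -> availability proportion vector
    category_of_bin: pd.Series    # bin_id -> functional category (pool BINs)
    category_shares: dict         # species -> Series over categories
    pools: dict                   # species -> set of bin_ids
    seed: int


class SyntheticStudy(NamedTuple):
    reads: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    functional: pd.DataFrame
    morph: pd.DataFrame
    truth: SyntheticTruth

    @property
    def tables(self) -> StudyTables:
        return StudyTables(self.reads, self.metadata, self.taxonomy,
                           self.functional, self.morph)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                               spawn_key=tuple(int(k) for k in key))
    )


def true_overlap(truth: SyntheticTruth, stratum: str) -> float:
    """Pianka index of the two species' true proportion vectors in *stratum*."""
    if stratum not in truth.strata_vectors:
        raise KeyError(f"unknown stratum {stratum!r}; have {sorted(truth.strata_vectors)}")
    vecs = truth.strata_vectors[stratum]
    return pianka(vecs[truth.species[0]], vecs[truth.species[1]])


def _detection_table(cfg: GeneratorConfig) -> pd.DataFrame:
    orders = list(ORDER_WEIGHTS) + list(NOISE_ORDERS)
    det = pd.DataFrame(cfg.detection_base, index=orders, columns=list(PRIMERS), dtype=float)
    for order, (pa, pb) in cfg.detection_bias.items():
        if order in det.index:
            det.loc[order] = [pa, pb]
    for order in cfg.blind_orders:
        if order in det.index:
            det.loc[order] = 0.0
    return det


def _site_plan(cfg: GeneratorConfig) -> list[dict]:
    """Deterministic site layout: strata separated by >> 3 km, syntopic sites
    hosting both species at identical coordinates."""
    plan, idx = [], 0

    def add(stratum, n, species_list, lat0, lon0, dlon):
        nonlocal idx
        for i in range(n):
            plan.append(dict(site_id=f"S{idx:03d}", stratum=stratum,
                             species=species_list, lat=lat0, lon=lon0 + i * dlon))
            idx += 1

    add("allopatric_a", cfg.n_sites_allopatric_a, [SPECIES[0]], 37.5, -3.5, 0.2)
    add("allopatric_b", cfg.n_sites_allopatric_b, [SPECIES[1]], 43.3, -4.5, 0.2)
    add("allotopic_a", cfg.n_sites_allotopic_a, [SPECIES[0]], 42.0, -2.5, 0.2)
    add("allotopic_b", cfg.n_sites_allotopic_b, [SPECIES[1]], 42.4, -2.5, 0.2)
    add("syntopic", cfg.n_sites_syntopic, list(SPECIES), 42.8, -2.5, 0.2)
    return plan


_STRATUM_META = {
    "allopatric_a": ("andalusia", "allopatric", pd.NA),
    "allopatric_b": ("atlantic", "allopatric", pd.NA),
    "allotopic_a": ("larioja", "sympatric", "allotopic"),
    "allotopic_b": ("larioja", "sympatric", "allotopic"),
    "syntopic": ("larioja", "sympatric", "syntopic"),
}


def _negbin_total(rng: np.random.Generator, mean: float, k: float) -> int:
    lam = rng.gamma(shape=k, scale=mean / k)
    return int(rng.poisson(lam))


def _sample_weights(rng: np.random.Generator, p: np.ndarray, alpha: float) -> np.ndarray:
    """Sparse per-sample composition ~ Dirichlet(alpha * p)."""
    w = rng.gamma(shape=alpha * p)
    s = w.sum()
    return p if s <= 0 else w / s


def _emit_runs(rng, sample_id, weights, orders_of_bin, bin_ids, det, cfg,
               reads_mean, noise_rate, noise_indices, contaminant_idx, rows):
    """Generate the four runs of one sample; append (sample, run, bin, reads) rows."""
    detect = {}
    for primer in PRIMERS:
        probs = det[primer].reindex(orders_of_bin).to_numpy()
        detect[primer] = rng.random(len(weights)) < probs
    for primer in PRIMERS:
        w = weights * detect[primer]
        for rep in REPLICATES:
            run_id = primer + rep
            dropped = rng.random() < cfg.replicate_dropout
            if not dropped and w.sum() > 0:
                total = _negbin_total(rng, reads_mean, cfg.reads_per_run_dispersion)
                if total > 0:
                    counts = rng.multinomial(total, w / w.sum())
                    nz = np.nonzero(counts)[0]
                    for i in nz:
                        rows.append((sample_id, run_id, bin_ids[i], int(counts[i])))
            if noise_rate > 0 and len(noise_indices):
                k = rng.poisson(noise_rate)
                if k > 0:
                    pick = rng.choice(noise_indices, size=min(k, len(noise_indices)),
                                      replace=False)
                    for i in pick:
                        rows.append((sample_id, run_id, bin_ids[i], 1))
            for i in contaminant_idx:
                if rng.random() < cfg.carryover_rate:
                    reads = int(rng.geometric(1.0 / cfg.carryover_mean))
                    rows.append((sample_id, run_id, bin_ids[i], reads))


def generate_study(cfg: GeneratorConfig) -> SyntheticStudy:
    """Generate a complete synthetic study plus its ground truth.

    Same config and seed always produce identical outputs; per-sample
    substreams make the draw for sample *i* independent of how many other
    samples exist.
    """
    cfg.validate()
    seed = cfg.seed
    rng0 = _rng(seed, 0, 0)

    # --- taxonomy -----------------------------------------------------------
    n_real, n_noise = cfg.n_bins_total, cfg.n_noise_bins
    bin_ids = [f"BIN{i:05d}" for i in range(n_real + n_noise)]
    order_names = list(ORDER_WEIGHTS)
    order_p = np.array(list(ORDER_WEIGHTS.values()), dtype=float)
    order_p /= order_p.sum()
    real_orders = rng0.choice(order_names, size=n_real, p=order_p)
    noise_orders = rng0.choice(NOISE_ORDERS, size=n_noise)
    orders_of_bin = np.concatenate([real_orders, noise_orders])
    families = np.array([
        f"{o}_fam{rng0.integers(1, cfg.families_per_order + 1)}" for o in orders_of_bin
    ])
    taxonomy = pd.DataFrame({
        "bin_id": bin_ids,
        "order_name": orders_of_bin,
        "family_name": families,
        "species_name": [f"sp_{b}" for b in bin_ids],
    })

    # --- functional table (family-level rules; noise families unclassified) --
    real_families = sorted(set(families[:n_real]))
    mixture = np.asarray(cfg.functional_mixture, dtype=float)
    mixture = mixture / mixture.sum()
    categories = ("non_volant", "not_actively_volant", "nocturnally_volant")
    fam_cat = {}
    for fam in real_families:
        order = fam.rsplit("_fam", 1)[0]
        if order in ("Araneae", "Isopoda", "Opiliones"):
            fam_cat[fam] = "non_volant"
        else:
            fam_cat[fam] = str(rng0.choice(categories, p=mixture))
    functional = pd.DataFrame({
        "taxon_key": list(fam_cat), "category": [fam_cat[f] for f in fam_cat],
    })

    # --- pools and contaminants ---------------------------------------------
    shared_n = int(round(cfg.pool_overlap * cfg.pool_size))
    uniq_n = cfg.pool_size - shared_n
    perm = rng0.permutation(n_real)
    shared = perm[:shared_n]
    uniq_a = perm[shared_n:shared_n + uniq_n]
    uniq_b = perm[shared_n + uniq_n:shared_n + 2 * uniq_n]
    used = shared_n + 2 * uniq_n
    contaminant_idx = perm[used:used + cfg.n_contaminants]
    avail_reserve = perm[used + cfg.n_contaminants:]
    pool_idx = {SPECIES[0]: np.concatenate([shared, uniq_a]),
                SPECIES[1]: np.concatenate([shared, uniq_b])}

    n_total = n_real + n_noise
    shared_scores = rng0.gamma(cfg.pool_concentration, size=shared_n)
    base = {}
    for sp, uniq in ((SPECIES[0], uniq_a), (SPECIES[1], uniq_b)):
        v = np.zeros(n_total)
        v[shared] = shared_scores
        v[uniq] = rng0.gamma(cfg.pool_concentration, size=len(uniq))
        base[sp] = v / v.sum()
    shifted = {}
    for sp in SPECIES:
        v = base[sp].copy()
        v[shared] *= (1.0 - cfg.syntopic_shift)
        s = v.sum()
        shifted[sp] = base[sp] if s <= 0 else v / s

    # --- expected sample counts per stratum, for mixture truth vectors -------
    n_allot = {SPECIES[0]: cfg.n_sites_allotopic_a * cfg.samples_per_site,
               SPECIES[1]: cfg.n_sites_allotopic_b * cfg.samples_per_site}
    n_syn = cfg.n_sites_syntopic * cfg.samples_per_site
    n_allop = {SPECIES[0]: cfg.n_sites_allopatric_a * cfg.samples_per_site,
               SPECIES[1]: cfg.n_sites_allopatric_b * cfg.samples_per_site}
    strata_vectors = {
        "allopatric": {sp: base[sp] for sp in SPECIES},
        "allotopic": {sp: base[sp] for sp in SPECIES},
        "syntopic": {sp: shifted[sp] for sp in SPECIES},
    }
    sympatric, overall = {}, {}
    for sp in SPECIES:
        w_allot, w_syn = n_allot[sp], n_syn
        if w_allot + w_syn > 0:
            sympatric[sp] = (w_allot * base[sp] + w_syn * shifted[sp]) / (w_allot + w_syn)
        else:
            sympatric[sp] = base[sp]
        tot = n_allop[sp] + w_allot + w_syn
        overall[sp] = ((n_allop[sp] + w_allot) * base[sp] + w_syn * shifted[sp]) / max(tot, 1)
    strata_vectors["sympatric"] = sympatric
    strata_vectors["overall"] = overall
    true_overlaps = {
        st: pianka(vecs[SPECIES[0]], vecs[SPECIES[1]])
        for st, vecs in strata_vectors.items()
    }

    det = _detection_table(cfg)
    noise_indices = np.arange(n_real, n_total)

    # --- category truth ------------------------------------------------------
    cat_of_bin = pd.Series(
        [fam_cat.get(f, "unclassified") for f in families[:n_real]],
        index=bin_ids[:n_real],
    )
    category_shares = {}
    for sp in SPECIES:
        v = overall[sp][:n_real]
        shares = pd.Series(0.0, index=list(categories))
        for cat in categories:
            shares[cat] = v[(cat_of_bin == cat).to_numpy()].sum()
        total = shares.sum()
        category_shares[sp] = shares / total if total > 0 else shares

    # --- samples -------------------------------------------------------------
    plan = _site_plan(cfg)
    rows: list[tuple] = []
    meta_rows: list[dict] = []
    sample_counter = 0
    stratum_vec = {"allopatric_a": base, "allopatric_b": base,
                   "allotopic_a": base, "allotopic_b": base, "syntopic": shifted}
    for site in plan:
        region, broad, fine = _STRATUM_META[site["stratum"]]
        vecs = stratum_vec[site["stratum"]]
        for sp in site["species"]:
            for _ in range(cfg.samples_per_site):
                sid = f"D{sample_counter:04d}"
                rng = _rng(seed, 1, sample_counter)
                w = _sample_weights(rng, vecs[sp], cfg.sample_alpha)
                _emit_runs(rng, sid, w, orders_of_bin, bin_ids, det, cfg,
                           cfg.reads_per_run_mean, cfg.dropping_noise_rate,
                           noise_indices, contaminant_idx, rows)
                meta_rows.append(dict(
                    sample_id=sid, sample_type="dropping", bat_species=sp,
                    site_id=site["site_id"], region_id=region, broad_class=broad,
                    fine_class=fine, longitude=site["lon"], latitude=site["lat"],
                ))
                sample_counter += 1

    # --- sweeps + availability + morphology ----------------------------------
    site_diet, site_availability = {}, {}
    morph_rows: list[tuple] = []
    sweep_counter = 0
    order_index = {o: i for i, o in enumerate(list(ORDER_WEIGHTS) + list(NOISE_ORDERS))}
    for site in plan:
        vecs = stratum_vec[site["stratum"]]
        d = np.mean([vecs[sp] for sp in site["species"]], axis=0)
        site_diet[site["site_id"]] = d
        rng_site = _rng(seed, 5, int(site["site_id"][1:]))
        if cfg.availability_mirrors_diet:
            q = d.copy()
        else:
            pool_union = np.unique(np.concatenate([pool_idx[sp] for sp in site["species"]]))
            k_cov = int(np.ceil(cfg.sweep_coverage * len(pool_union)))
            covered = rng_site.choice(pool_union, size=min(k_cov, len(pool_union)),
                                      replace=False)
            n_extra = min(cfg.availability_extra_bins, len(avail_reserve))
            extra = (rng_site.choice(avail_reserve, size=n_extra, replace=False)
                     if n_extra else np.array([], dtype=int))
            support = np.concatenate([covered, extra]).astype(int)
            q = np.zeros(n_total)
            q[support] = rng_site.gamma(cfg.availability_concentration, size=len(support))
            if cfg.selection_bias_order is not None:
                in_order = np.array([orders_of_bin[i] == cfg.selection_bias_order
                                     for i in range(n_total)])
                q[in_order] *= cfg.selection_bias_factor
            s = q.sum()
            q = d.copy() if s <= 0 else q / s
        site_availability[site["site_id"]] = q
        for _ in range(cfg.n_sweep_samples_per_site):
            swid = f"W{sweep_counter:04d}"
            rng = _rng(seed, 2, sweep_counter)
            w = _sample_weights(rng, q, cfg.sweep_alpha)
            # swept specimens: every individual is identified morphologically
            # and pooled for sequencing, so molecular reads derive from the
            # same specimen composition the morphology table counts
            n_ind = max(int(rng.poisson(cfg.morph_individuals_mean)), 1)
            spec_counts = rng.multinomial(n_ind, w)
            order_counts = np.zeros(len(order_index), dtype=int)
            for i in np.nonzero(spec_counts)[0]:
                order_counts[order_index[orders_of_bin[i]]] += spec_counts[i]
            for o, c in zip(order_index, order_counts):
                if c > 0:
                    morph_rows.append((swid, o, int(c)))
            w_mol = spec_counts / n_ind
            _emit_runs(rng, swid, w_mol, orders_of_bin, bin_ids, det, cfg,
                       cfg.sweep_reads_mean, cfg.sweep_noise_rate,
                       noise_indices, contaminant_idx, rows)
            meta_rows.append(dict(
                sample_id=swid, sample_type="sweeping", bat_species=pd.NA,
                site_id=site["site_id"], region_id=_STRATUM_META[site["stratum"]][0],
                broad_class=_STRATUM_META[site["stratum"]][1],
                fine_class=_STRATUM_META[site["stratum"]][2],
                longitude=site["lon"], latitude=site["lat"],
            ))
            sweep_counter += 1

    # --- batches, sequencing runs, blanks ------------------------------------
    meta = pd.DataFrame(meta_rows)
    n_samples = len(meta)
    batch_ids = [f"X{(i // cfg.batch_size) + 1:02d}" for i in range(n_samples)]
    meta["extraction_batch_id"] = batch_ids
    n_batches = (n_samples - 1) // cfg.batch_size + 1
    seqrun_of_batch = {
        f"X{b + 1:02d}": f"SEQ{(b % max(cfg.n_sequencing_runs, 1)) + 1}"
        for b in range(n_batches)
    }
    meta["sequencing_run_id"] = meta["extraction_batch_id"].map(seqrun_of_batch)

    blank_rows: list[dict] = []
    if cfg.n_contaminants > 0:
        for b in range(n_batches):
            bid = f"BLX{b + 1:02d}"
            rng = _rng(seed, 3, b)
            for primer in PRIMERS:
                for rep in REPLICATES:
                    for i in contaminant_idx:
                        reads = 1 + int(rng.poisson(max(cfg.blank_reads_mean - 1, 0)))
                        rows.append((bid, primer + rep, bin_ids[i], reads))
            blank_rows.append(dict(
                sample_id=bid, sample_type="blank_extraction", bat_species=pd.NA,
                site_id=pd.NA, region_id=pd.NA, broad_class=pd.NA, fine_class=pd.NA,
                extraction_batch_id=f"X{b + 1:02d}",
                sequencing_run_id=seqrun_of_batch[f"X{b + 1:02d}"],
                longitude=np.nan, latitude=np.nan,
            ))
        for r in range(cfg.n_sequencing_runs):
            bid = f"BLS{r + 1:02d}"
            rng = _rng(seed, 3, 10000 + r)
            for primer in PRIMERS:
                for rep in REPLICATES:
                    for i in contaminant_idx:
                        reads = 1 + int(rng.poisson(max(cfg.blank_reads_mean - 1, 0)))
                        rows.append((bid, primer + rep, bin_ids[i], reads))
            blank_rows.append(dict(
                sample_id=bid, sample_type="blank_sequencing", bat_species=pd.NA,
                site_id=pd.NA, region_id=pd.NA, broad_class=pd.NA, fine_class=pd.NA,
                extraction_batch_id=pd.NA, sequencing_run_id=f"SEQ{r + 1}",
                longitude=np.nan, latitude=np.nan,
            ))
    if blank_rows:
        meta = pd.concat([meta, pd.DataFrame(blank_rows)], ignore_index=True)

    reads = pd.DataFrame(rows, columns=["sample_id", "run_id", "bin_id", "reads"])
    # carry-over + noise can collide with a real record for the same key: sum
    reads = (reads.groupby(["sample_id", "run_id", "bin_id"], as_index=False)["reads"]
             .sum())
    morph = pd.DataFrame(morph_rows,
                         columns=["sweep_sample_id", "order_name", "individuals"])

    truth = SyntheticTruth(
        bin_ids=bin_ids, species=SPECIES, strata_vectors=strata_vectors,
        true_overlaps=true_overlaps,
        contaminant_bins={bin_ids[i] for i in contaminant_idx},
        detection=det, site_diet=site_diet, site_availability=site_availability,
        category_of_bin=cat_of_bin, category_shares=category_shares,
        pools={sp: {bin_ids[i] for i in pool_idx[sp]} for sp in SPECIES},
        seed=seed,
    )
    tables = validate_study(StudyTables(reads, meta, taxonomy, functional, morph))
    return SyntheticStudy(*tables, truth)
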