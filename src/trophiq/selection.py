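"""Functional volancy classification and prey selection versus availability.

Prey BINs are classified into three functional categories — non-volant,
not actively volant, nocturnally volant — reflecting their likelihood of
capture by gleaning versus aerial hawking.  Classification rules live in a
functional table keyed by taxon name; the most specific matching rank wins
(species > family > order fallback).

Selection compares per-site diet composition (pooled dropping samples,
wPOO) against per-site prey availability (pooled sweep samples, wPOO):
selection = diet - availability per arthropod order or functional category,
summing to zero within a site.  Sites enter only if availability sampling is
representative: at least ``min_frac`` (default 20%) of the site's diet BINs
were also found in its sweeping samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import FUNCTIONAL_CATEGORIES, TrophiqError
from .diet import compute_wpoo

logger = logging.getLogger("trophiq")

NOT_NOCTURNALLY_VOLANT = ("non_volant", "not_actively_volant")


def classify_bins(taxonomy: pd.DataFrame, functional: pd.DataFrame) -> pd.Series:
    """Map each BIN to its functional category; most specific rule wins.

    A BIN's species name is checked first, then its family, then its order;
    BINs matching no rule are labelled ``unclassified`` (and later excluded
    from functional proportions).  Conflicting rules for the same taxon key
    raise at table validation.
    """
    rule = functional.set_index("taxon_key")["category"]
    dup = rule.index[rule.index.duplicated()]
    if len(dup):
        raise TrophiqError(f"classify_bins: conflicting rules for taxa {sorted(set(dup))}")

    def lookup(row) -> str:
        for col in ("species_name", "family_name", "order_name"):
            key = row.get(col)
            if pd.notna(key) and key in rule.index:
                return rule[key]
        return "unclassified"

    out = pd.Series(
        [lookup(row) for _, row in taxonomy.iterrows()],
        index=taxonomy["bin_id"].to_numpy(), name="category",
    )
    n_unc = int((out == "unclassified").sum())
    if n_unc:
        logger.info("classify_bins: %d of %d BINs unclassified", n_unc, len(out))
    return out


@dataclass
class FunctionalDiet:
    """Functional diet of a sample set: category wPOO + per-sample response."""

    proportions: pd.Series        # wPOO over the three categories
    per_sample: pd.DataFrame      # sample_id, n_classified, pct_not_nocturnally_volant


def functional_diet(samples: pd.DataFrame, classification: pd.Series,
                    weighting: str = "count") -> FunctionalDiet:
    """Category-level wPOO plus the per-sample share of not nocturnally volant prey.

    The per-sample percentage is count-based by default: classified BINs in
    the non-volant or not-actively-volant categories divided by all
    classified BINs in the sample (``weighting='wpoo'`` uses within-sample
    occurrence shares instead, which coincides with count-based here since
    items weigh equally).  Unclassified BINs are excluded from denominators;
    samples with no classified BIN are excluded with a warning.
    """
    if weighting not in ("count", "wpoo"):
        raise TrophiqError(f"unknown weighting {weighting!r}")
    t = samples.assign(category=samples["bin_id"].map(classification)
                       .fillna("unclassified"))
    classified = t[t["category"] != "unclassified"]
    lost = set(t["sample_id"]) - set(classified["sample_id"])
    if lost:
        warnings.warn(f"functional_diet: excluding samples with no classified "
                      f"BIN: {sorted(lost)}", stacklevel=2)
    if classified.empty:
        raise TrophiqError("functional_diet: no classified BINs in any sample")
    props = compute_wpoo(classified, level="functional_category",
                         classification=classification)
    props = props.reindex(list(FUNCTIONAL_CATEGORIES), fill_value=0.0)
    per = (classified.assign(nnv=classified["category"].isin(NOT_NOCTURNALLY_VOLANT))
           .groupby("sample_id")
           .agg(n_classified=("bin_id", "nunique"), n_nnv=("nnv", "sum")))
    per["pct_not_nocturnally_volant"] = per["n_nnv"] / per["n_classified"]
    per = per.drop(columns="n_nnv").reset_index()
    return FunctionalDiet(proportions=props.rename("wPOO"), per_sample=per)


def site_bin_sets(samples: pd.DataFrame, meta: pd.DataFrame,
                  sample_type: str) -> dict[str, set]:
    """BIN sets pooled per site for the given sample type."""
    m = meta.set_index("sample_id")
    sub = samples[samples["sample_id"].map(m["sample_type"]) == sample_type]
    site = sub["sample_id"].map(m["site_id"])
    return {s: set(g["bin_id"]) for s, g in sub.groupby(site)}


def representativeness_filter(diet_sites: dict[str, set], sweep_sites: dict[str, set],
                              min_frac: float = 0.20,
                              ) -> tuple[list[str], pd.Series]:
    """Retain sites where availability sampling covers enough of the diet.

    Per site, fraction = |diet BINs also in sweeps| / |diet BINs|; a site is
    retained iff fraction >= ``min_frac`` (boundary retains).  Sites with no
    sweep data are excluded with a warning.
    """
    fractions = {}
    missing = sorted(set(diet_sites) - set(sweep_sites))
    if missing:
        warnings.warn(f"representativeness_filter: no sweep data for sites "
                      f"{missing}; excluded", stacklevel=2)
    for site, diet_bins in diet_sites.items():
        if site not in sweep_sites or not diet_bins:
            continue
        fractions[site] = len(diet_bins & sweep_sites[site]) / len(diet_bins)
    frac = pd.Series(fractions, dtype=float).sort_index()
    retained = sorted(frac.index[frac >= min_frac])
    return retained, frac


def selection_index(diet_site: pd.Series, avail_site: pd.Series) -> pd.DataFrame:
    """Per-item selection = diet wPOO - availability wPOO on the union of items.

    Both inputs are simplex vectors at the same level (order or functional
    category); the output rows sum to zero.
    """
    for name, v in (("diet", diet_site), ("availability", avail_site)):
        if not np.isclose(float(v.sum()), 1.0, atol=1e-6):
            raise TrophiqError(f"selection_index: {name} composition must sum to 1")
    idx = diet_site.index.union(avail_site.index)
    d = diet_site.reindex(idx, fill_value=0.0)
    a = avail_site.reindex(idx, fill_value=0.0)
    return pd.DataFrame({
        "item": idx, "diet_wpoo": d.to_numpy(), "availability_wpoo": a.to_numpy(),
        "selection": (d - a).to_numpy(),
    })


def site_selection_table(samples: pd.DataFrame, meta: pd.DataFrame,
                         taxonomy: pd.DataFrame, level: str = "order",
                         classification: pd.Series | None = None,
                         min_frac: float = 0.20, force: bool = False,
                         species: str | None = None) -> pd.DataFrame:
    """Per-site selection rows for every site passing the representativeness gate.

    Diet is the site's pooled dropping samples (optionally one bat species);
    availability the site's pooled sweeping samples; both as wPOO at order or
    functional-category level.  ``force=True`` bypasses the gate.
    """
    m = meta.set_index("sample_id")
    drops = samples[samples["sample_id"].map(m["sample_type"]) == "dropping"]
    if species is not None:
        drops = drops[drops["sample_id"].map(m["bat_species"]) == species]
    sweeps = samples[samples["sample_id"].map(m["sample_type"]) == "sweeping"]
    diet_sets = {s: set(g["bin_id"])
                 for s, g in drops.groupby(drops["sample_id"].map(m["site_id"]))}
    sweep_sets = {s: set(g["bin_id"])
                  for s, g in sweeps.groupby(sweeps["sample_id"].map(m["site_id"]))}
    retained, frac = representativeness_filter(diet_sets, sweep_sets, min_frac)
    sites = (sorted(set(diet_sets) & set(sweep_sets)) if force else retained)
    rows = []
    for site in sites:
        d_sub = drops[drops["sample_id"].map(m["site_id"]) == site]
        a_sub = sweeps[sweeps["sample_id"].map(m["site_id"]) == site]
        if d_sub.empty or a_sub.empty:
            continue
        d = compute_wpoo(d_sub, level=level, taxonomy=taxonomy,
                         classification=classification)
        a = compute_wpoo(a_sub, level=level, taxonomy=taxonomy,
                         classification=classification)
        tab = selection_index(d, a)
        tab.insert(0, "site_id", site)
        rows.append(tab)
    if not rows:
        return pd.DataFrame(columns=["site_id", "item", "diet_wpoo",
                                     "availability_wpoo", "selection"])
    return pd.concat(rows, ignore_index=True)


def selection_summary(rows: pd.DataFrame, n_boot: int = 10000,
                      seed: int | None = None) -> pd.DataFrame:
    """Cross-site quartiles, bootstrap CI of the mean, and over/under flags.

    Per item: Q1/median/Q3 of selection values across sites (linear
    interpolation), a percentile bootstrap 95% CI of the cross-site mean
    (resampling sites with replacement), and a flag — ``over`` if Q1 > 0,
    ``under`` if Q3 < 0, else ``neutral``.  With fewer than 3 sites the CI is
    suppressed with a warning.
    """
    rng = np.random.default_rng(seed)
    out = []
    for item, grp in rows.groupby("item"):
        v = grp["selection"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        if len(v) >= 3:
            idx = rng.integers(0, len(v), size=(n_boot, len(v)))
            means = v[idx].mean(axis=1)
            lo, hi = np.quantile(means, [0.025, 0.975])
        else:
            warnings.warn(f"selection_summary: <3 sites for {item!r}; CI suppressed",
                          stacklevel=2)
            lo = hi = np.nan
        flag = "over" if q1 > 0 else ("under" if q3 < 0 else "neutral")
        out.append((item, len(v), q1, med, q3, v.mean(), lo, hi, flag))
    return pd.DataFrame(out, columns=["item", "n_sites", "q1", "median", "q3",
                                      "mean", "ci_low", "ci_high", "flag"])
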