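"""Diet composition metrics: wPOO, POO, RRA; niche breadth; order richness.

All three metrics summarize a set of per-sample prey compositions into a
single proportion vector over items (BINs, arthropod orders, or functional
categories) that sums to 1:

- wPOO (weighted percent of occurrence): each sample contributes equally and
  splits its contribution evenly among the items it contains — a prey item
  found alongside 9 others contributes 1/10 of what it would as the sole
  item.  Occurrence-based, robust to read-count biology.
- POO (percent of occurrence): item occurrences divided by total occurrences
  over all items and samples.
- RRA (relative read abundance): mean across samples of per-sample read
  shares.

Niche breadth is Levins' reciprocal Simpson B = 1 / sum(p^2), standardized
to B_A = (B - 1) / (n - 1) on [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import TrophiqError

LEVELS = ("BIN", "order", "functional_category")


def _item_of(samples: pd.DataFrame, level: str, taxonomy: pd.DataFrame | None,
             classification: pd.Series | None) -> pd.Series:
    """Map each record's bin_id to the analysis item at the requested level."""
    if level == "BIN":
        return samples["bin_id"]
    if level == "order":
        if taxonomy is None:
            raise TrophiqError("order-level metrics need a taxonomy table")
        order_of = taxonomy.set_index("bin_id")["order_name"]
        items = samples["bin_id"].map(order_of)
        if items.isna().any():
            warnings.warn("some BINs lack an order; counted as 'unassigned'",
                          stacklevel=3)
            items = items.fillna("unassigned")
        return items
    if level == "functional_category":
        if classification is None:
            raise TrophiqError("functional-level metrics need a BIN classification")
        return samples["bin_id"].map(classification).fillna("unclassified")
    raise TrophiqError(f"unknown level {level!r}; use one of {LEVELS}")


def _drop_empty(samples: pd.DataFrame, what: str) -> pd.DataFrame:
    sizes = samples.groupby("sample_id").size()
    empty = set(sizes[sizes == 0].index)
    if empty:
        warnings.warn(f"{what}: excluding empty samples {sorted(empty)}", stacklevel=3)
    return samples[~samples["sample_id"].isin(empty)]


def compute_wpoo(samples: pd.DataFrame, level: str = "BIN",
                 taxonomy: pd.DataFrame | None = None,
                 classification: pd.Series | None = None) -> pd.Series:
    """Weighted percent of occurrence over a merged composition table.

    Per sample, each of its n_s distinct BINs contributes 1/n_s, aggregated
    to the requested level; the vector is the mean over samples and sums
    to 1.  Item weighting uses presence, not read shares.
    """
    samples = _drop_empty(samples, "compute_wpoo")
    if samples.empty:
        raise TrophiqError("compute_wpoo: no non-empty samples")
    n_items = samples.groupby("sample_id")["bin_id"].transform("nunique")
    item = _item_of(samples, level, taxonomy, classification)
    contrib = (samples.assign(item=item, contrib=1.0 / n_items)
               .groupby("item")["contrib"].sum())
    out = contrib / samples["sample_id"].nunique()
    return out.sort_index().rename("wPOO")


def compute_poo(samples: pd.DataFrame, level: str = "BIN",
                taxonomy: pd.DataFrame | None = None,
                classification: pd.Series | None = None) -> pd.Series:
    """Percent of occurrence: item occurrences / total occurrences.

    Presence-only — invariant to read counts.
    """
    samples = _drop_empty(samples, "compute_poo")
    if samples.empty:
        raise TrophiqError("compute_poo: no non-empty samples")
    item = _item_of(samples, level, taxonomy, classification)
    occ = (samples.assign(item=item)[["sample_id", "item"]].drop_duplicates()
           .groupby("item").size())
    return (occ / occ.sum()).sort_index().rename("POO")


def compute_rra(samples: pd.DataFrame, level: str = "BIN",
                taxonomy: pd.DataFrame | None = None,
                classification: pd.Series | None = None) -> pd.Series:
    """Relative read abundance: mean across samples of per-sample read shares."""
    if "reads" not in samples.columns:
        raise TrophiqError("compute_rra: composition table lacks read counts")
    totals = samples.groupby("sample_id")["reads"].transform("sum")
    zero = samples.loc[totals == 0, "sample_id"].unique()
    if len(zero):
        warnings.warn(f"compute_rra: excluding zero-read samples {sorted(zero)}",
                      stacklevel=2)
        samples = samples[~samples["sample_id"].isin(set(zero))]
        totals = samples.groupby("sample_id")["reads"].transform("sum")
    if samples.empty:
        raise TrophiqError("compute_rra: no samples with reads")
    item = _item_of(samples, level, taxonomy, classification)
    share = (samples.assign(item=item, share=samples["reads"] / totals)
             .groupby("item")["share"].sum())
    return (share / samples["sample_id"].nunique()).sort_index().rename("RRA")


METRICS = {"wPOO": compute_wpoo, "POO": compute_poo, "RRA": compute_rra}


def diet_composition(samples: pd.DataFrame, metric: str = "wPOO",
                     level: str = "BIN", taxonomy: pd.DataFrame | None = None,
                     classification: pd.Series | None = None) -> pd.Series:
    """Dispatch to one of the three diet metrics by name."""
    if metric not in METRICS:
        raise TrophiqError(f"unknown metric {metric!r}; use one of {sorted(METRICS)}")
    return METRICS[metric](samples, level=level, taxonomy=taxonomy,
                           classification=classification)


def diet_by_group(samples: pd.DataFrame, meta: pd.DataFrame, group_by: str,
                  metric: str = "wPOO", level: str = "BIN",
                  taxonomy: pd.DataFrame | None = None,
                  classification: pd.Series | None = None) -> pd.DataFrame:
    """Tidy per-group diet composition (unit_id, item, proportion).

    ``group_by`` is a metadata column (``bat_species``, ``site_id``, ...) or
    ``"species_x_stratum"`` for bat_species crossed with broad_class.
    """
    m = meta.set_index("sample_id")
    if group_by == "species_x_stratum":
        unit = m["bat_species"].astype(str) + ":" + m["broad_class"].astype(str)
    else:
        unit = m[group_by]
    rows = []
    for u, grp in samples.groupby(samples["sample_id"].map(unit)):
        comp = diet_composition(grp, metric=metric, level=level,
                                taxonomy=taxonomy, classification=classification)
        for item, p in comp.items():
            rows.append((u, item, p))
    return pd.DataFrame(rows, columns=["unit_id", "item", "proportion"])


@dataclass
class BreadthResult:
    """Levins' niche breadth B with its standardized form B_A."""

    b: float
    b_a: float
    n_items: int


def levins_breadth(p, n: int | None = None) -> BreadthResult:
    """Levins' breadth B = 1 / sum(p^2) with B_A = (B - 1) / (n - 1).

    *n* is the number of resource states used for standardization; by default
    the number of items with nonzero proportion.  B_A is 1 for uniform use of
    all n states, 0 for a single resource.
    """
    v = (p.to_numpy(dtype=float) if isinstance(p, pd.Series)
         else np.asarray(p, dtype=float))
    if v.sum() <= 0:
        raise TrophiqError("levins_breadth: proportions must sum to a positive value")
    if not np.isclose(v.sum(), 1.0, atol=1e-6):
        raise TrophiqError("levins_breadth: proportions must sum to 1")
    support = int(np.count_nonzero(v))
    n = support if n is None else int(n)
    if n < support:
        raise TrophiqError("levins_breadth: n smaller than the observed support")
    b = 1.0 / float((v * v).sum())
    if n == 1:
        warnings.warn("levins_breadth: single resource state; B_A defined as 0",
                      stacklevel=2)
        return BreadthResult(b=b, b_a=0.0, n_items=1)
    b_a = (b - 1.0) / (n - 1.0)
    return BreadthResult(b=b, b_a=float(np.clip(b_a, 0.0, 1.0)), n_items=n)


def bins_per_sample_by_order(sample: pd.DataFrame, taxonomy: pd.DataFrame,
                             order_name: str) -> int:
    """Number of a single sample's BINs assigned to *order_name*."""
    order_of = taxonomy.set_index("bin_id")["order_name"]
    orders = sample["bin_id"].map(order_of)
    if orders.isna().any():
        warnings.warn("bins_per_sample_by_order: BINs with missing order counted "
                      "as 'unassigned'", stacklevel=2)
        orders = orders.fillna("unassigned")
    return int((orders == order_name).sum())


def order_richness_table(samples: pd.DataFrame, taxonomy: pd.DataFrame,
                         orders=None) -> pd.DataFrame:
    """Per-sample BIN counts by arthropod order (response for downstream GLMs).

    Returns one row per sample with one column per order (all orders observed
    unless *orders* restricts them).
    """
    order_of = taxonomy.set_index("bin_id")["order_name"]
    t = samples.assign(order=samples["bin_id"].map(order_of).fillna("unassigned"))
    wide = (t.groupby(["sample_id", "order"])["bin_id"].nunique()
            .unstack(fill_value=0))
    if orders is not None:
        wide = wide.reindex(columns=list(orders), fill_value=0)
    return wide.reset_index()


def major_orders(diet_by_species: pd.DataFrame, cutoff: float = 0.10) -> list[str]:
    """Orders reaching *cutoff* of the diet in at least one species.

    *diet_by_species* is a tidy (unit_id, item, proportion) table at order
    level, one unit per species.
    """
    wide = diet_by_species.pivot_table(index="item", columns="unit_id",
                                       values="proportion", fill_value=0.0)
    hit = (wide >= cutoff).any(axis=1)
    return sorted(wide.index[hit])
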