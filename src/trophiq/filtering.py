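"""Post-BIN quality filtering: singletons, blank contamination, replicate merging.

The filtering chain applied to a raw read-count table before ecological
analysis:

1. low-read removal — per (sample, run), drop BIN records below a minimum
   read count (default 2, i.e. singleton removal), with the threshold
   calibrated against morphological identification of sweep samples;
2. blank-based contamination removal — BINs present in extraction or
   sequencing blanks are dropped from samples in the same scope whose read
   counts are less than ``factor`` (default 10) times the blank's;
3. replicate combination — either *additive* (union of the two PCR
   replicates per primer, reads summed) or *conservative* (intersection of
   replicates, samples with any run at or below a minimum read total
   dropped);
4. primer union — compositions of the two primers merged per sample.

Every removal is appended to a :data:`FilterAudit` table (rule, sample, run,
BIN, reads removed) so a filtered dataset can be reconciled with its input.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .data_model import BLANK_TYPES, TrophiqError, run_structure

logger = logging.getLogger("trophiq")

AUDIT_COLUMNS = ["rule", "sample_id", "run_id", "bin_id", "reads_removed", "blank_reads"]


def _audit(removed: pd.DataFrame, rule: str, blank_reads=None) -> pd.DataFrame:
    out = removed[["sample_id", "run_id", "bin_id"]].copy()
    out.insert(0, "rule", rule)
    out["reads_removed"] = removed["reads"].to_numpy()
    out["blank_reads"] = (np.asarray(blank_reads, dtype=float)
                          if blank_reads is not None else np.nan)
    return out[AUDIT_COLUMNS]


def empty_audit() -> pd.DataFrame:
    return pd.DataFrame(columns=AUDIT_COLUMNS)


def remove_low_read_bins(table: pd.DataFrame, min_reads: int = 2,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop (sample, run, bin) records with fewer than *min_reads* reads.

    ``min_reads`` is the minimum count needed to retain a record; the default
    of 2 removes exactly the singletons (1-read records, likely PCR or
    sequencing errors).  ``min_reads = 1`` is the identity.
    """
    if min_reads < 1:
        raise TrophiqError("min_reads must be >= 1")
    keep = table["reads"] >= min_reads
    removed = table[~keep]
    audit = _audit(removed, "singleton") if len(removed) else empty_audit()
    if len(removed):
        logger.info("remove_low_read_bins: removed %d records below %d reads",
                    len(removed), min_reads)
    return table[keep].reset_index(drop=True), audit


def calibrate_min_read_threshold(sweep_table: pd.DataFrame, taxonomy: pd.DataFrame,
                                 morph: pd.DataFrame,
                                 thresholds=range(1, 6),
                                 similarity: str = "jaccard",
                                 ) -> tuple[int, dict[int, float]]:
    """Choose the low-read threshold maximizing molecular/morphological agreement.

    For each candidate threshold, sweep-sample molecular data are filtered,
    BINs collapsed to order-level presence, and compared with the
    morphological order set of the same sample by mean per-sample Jaccard
    similarity (or Bray-Curtis on order proportions with
    ``similarity='braycurtis'``).  Ties break toward the smaller threshold,
    which retains more data.
    """
    thresholds = sorted(int(t) for t in thresholds)
    order_of = taxonomy.set_index("bin_id")["order_name"]
    morph_orders = (morph[morph["individuals"] > 0]
                    .groupby("sweep_sample_id")["order_name"].agg(set))
    common = sorted(set(sweep_table["sample_id"]) & set(morph_orders.index))
    if not common:
        raise TrophiqError("calibrate_min_read_threshold: no samples shared "
                           "between molecular and morphological tables")
    sweep = sweep_table[sweep_table["sample_id"].isin(common)].copy()
    sweep["order_name"] = sweep["bin_id"].map(order_of)
    morph_counts = (morph.groupby(["sweep_sample_id", "order_name"])["individuals"]
                    .sum())
    scores: dict[int, float] = {}
    for t in thresholds:
        sub = sweep[sweep["reads"] >= t]
        sims = []
        for sid in common:
            mol = set(sub.loc[sub["sample_id"] == sid, "order_name"].dropna())
            mor = morph_orders.get(sid, set())
            if similarity == "jaccard":
                union = mol | mor
                sims.append(1.0 if not union else len(mol & mor) / len(union))
            elif similarity == "braycurtis":
                mol_reads = (sub[sub["sample_id"] == sid]
                             .groupby("order_name")["reads"].sum())
                mor_ind = morph_counts.loc[sid] if sid in morph_counts.index.get_level_values(0) else pd.Series(dtype=float)
                idx = mol_reads.index.union(mor_ind.index)
                a = (mol_reads / max(mol_reads.sum(), 1)).reindex(idx, fill_value=0.0)
                b = (mor_ind / max(mor_ind.sum(), 1)).reindex(idx, fill_value=0.0)
                sims.append(1.0 - 0.5 * float(np.abs(a - b).sum()))
            else:
                raise TrophiqError(f"unknown similarity {similarity!r}")
        scores[t] = float(np.mean(sims))
    best = max(scores.values())
    chosen = min(t for t in thresholds if scores[t] == best)
    return chosen, scores


def filter_blank_contamination(table: pd.DataFrame, meta: pd.DataFrame,
                               factor: float = 10.0, scope: str = "batch",
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove blank-borne BINs from samples with near-blank read counts.

    For each BIN present in a blank, with blank read count r_b (maximum over
    blanks and runs in scope), the BIN is removed from an in-scope sample run
    iff its reads are strictly less than ``factor * r_b``; records with at
    least ``factor * r_b`` reads are retained.  Extraction blanks act on
    their extraction batch and sequencing blanks on their sequencing run when
    ``scope='batch'``; ``scope='global'`` applies every blank study-wide.
    The two blank types are applied independently, in that order.
    """
    if factor <= 0:
        raise TrophiqError("factor must be positive")
    if scope not in ("batch", "global"):
        raise TrophiqError(f"unknown scope {scope!r}")
    m = meta.set_index("sample_id")
    stype = m["sample_type"]
    out = table.copy()
    audits = []
    rules = [("blank_extraction", "extraction_batch_id"),
             ("blank_sequencing", "sequencing_run_id")]
    for blank_type, group_col in rules:
        blank_ids = set(stype[stype == blank_type].index)
        if not blank_ids:
            warnings.warn(f"filter_blank_contamination: no {blank_type} blanks; "
                          f"rule skipped", stacklevel=2)
            continue
        sample_group = (m[group_col] if scope == "batch"
                        else pd.Series("__all__", index=m.index))
        blank_recs = out[out["sample_id"].isin(blank_ids)].copy()
        if blank_recs.empty:
            continue
        blank_recs["group"] = blank_recs["sample_id"].map(sample_group)
        # max blank read count per (group, bin): most conservative
        rb = (blank_recs.dropna(subset=["group"])
              .groupby(["group", "bin_id"])["reads"].max())
        is_sample = ~out["sample_id"].map(stype).isin(BLANK_TYPES)
        grp = out["sample_id"].map(sample_group)
        key = pd.MultiIndex.from_arrays([grp, out["bin_id"]])
        thresh = pd.Series(rb.reindex(key).to_numpy(), index=out.index)
        remove = is_sample & thresh.notna() & (out["reads"] < factor * thresh)
        if remove.any():
            audits.append(_audit(out[remove], blank_type,
                                 blank_reads=thresh[remove].to_numpy()))
            logger.info("filter_blank_contamination: %s removed %d records",
                        blank_type, int(remove.sum()))
        out = out[~remove]
    audit = (pd.concat(audits, ignore_index=True) if audits else empty_audit())
    return out.reset_index(drop=True), audit


def combine_replicates_additive(table: pd.DataFrame) -> pd.DataFrame:
    """Per sample x primer, union of the two PCR replicates with reads summed.

    Returns a composition table (sample_id, primer_id, bin_id, reads).
    """
    t = run_structure(table)
    return (t.groupby(["sample_id", "primer_id", "bin_id"], as_index=False)["reads"]
            .sum())


def combine_replicates_conservative(table: pd.DataFrame, min_run_reads: int = 100,
                                    ) -> tuple[pd.DataFrame, set, pd.DataFrame]:
    """Intersection of PCR replicates per primer, dropping low-yield samples.

    A sample is dropped iff any of its four expected runs (2 primers x 2
    replicates) is missing or has a read total at or below ``min_run_reads``
    (the requirement is strictly "more than"), since a failed run would void
    the replicate intersection for that primer.  For retained samples, a BIN
    is kept per primer iff present in both replicates; reads are summed.
    Returns (composition, dropped sample ids, audit of consensus removals).
    """
    t = run_structure(table)
    primers = sorted(t["primer_id"].unique())
    reps = sorted(t["replicate_id"].unique())
    if len(primers) != 2 or len(reps) != 2:
        raise TrophiqError(
            "combine_replicates_conservative: run structure must enumerate exactly "
            f"2 primers x 2 replicates; found primers={primers}, replicates={reps}"
        )
    expected_runs = [p + r for p in primers for r in reps]
    run_totals = t.groupby(["sample_id", "run_id"])["reads"].sum().unstack(fill_value=0)
    run_totals = run_totals.reindex(columns=expected_runs, fill_value=0)
    ok = (run_totals > min_run_reads).all(axis=1)
    dropped: set = set(run_totals.index[~ok])
    kept = t[~t["sample_id"].isin(dropped)]
    if dropped:
        logger.info("combine_replicates_conservative: dropped %d samples with a "
                    "run <= %d reads", len(dropped), min_run_reads)
    # per (sample, primer, bin): require presence in both replicates
    g = (kept.groupby(["sample_id", "primer_id", "bin_id"])
         .agg(n_reps=("replicate_id", "nunique"), reads=("reads", "sum"))
         .reset_index())
    consensus = g[g["n_reps"] >= 2][["sample_id", "primer_id", "bin_id", "reads"]]
    rejected = g[g["n_reps"] < 2]
    audit = (_audit(rejected.assign(run_id=rejected["primer_id"]),
                    "replicate_consensus")
             if len(rejected) else empty_audit())
    return consensus.reset_index(drop=True), dropped, audit


def merge_primers(per_primer: pd.DataFrame) -> pd.DataFrame:
    """Union of BIN compositions across primers per sample; reads summed.

    Duplicated BINs recovered by both primers collapse to one record (their
    reads summed — read counts matter only for RRA).  Returns (sample_id,
    bin_id, reads).
    """
    return (per_primer.groupby(["sample_id", "bin_id"], as_index=False)["reads"]
            .sum())


def primer_recovery_summary(per_primer: pd.DataFrame, taxonomy: pd.DataFrame,
                            ) -> pd.DataFrame:
    """Per arthropod order, BINs recovered by each primer exclusively or by both.

    A BIN counts as recovered by a primer if it appears in any sample under
    that primer.  Returns a tidy table (order_name, n_both, n_<p>_only ...,
    prop_both, prop_<p>_only ...); proportions sum to 1 within each order.
    """
    primers = sorted(per_primer["primer_id"].unique())
    if len(primers) != 2:
        raise TrophiqError(f"primer_recovery_summary: expected 2 primers, got {primers}")
    p1, p2 = primers
    by = per_primer.groupby("bin_id")["primer_id"].agg(set)
    order_of = taxonomy.set_index("bin_id")["order_name"]
    df = pd.DataFrame({
        "order_name": by.index.map(order_of),
        "which": [("both" if v == {p1, p2} else f"{next(iter(v))}_only") for v in by],
    })
    counts = (df.groupby(["order_name", "which"]).size().unstack(fill_value=0)
              .reindex(columns=["both", f"{p1}_only", f"{p2}_only"], fill_value=0))
    total = counts.sum(axis=1)
    out = counts.rename(columns={c: f"n_{c}" for c in counts.columns})
    for c in counts.columns:
        out[f"prop_{c}"] = counts[c] / total
    return out.reset_index()


def filter_reads(table: pd.DataFrame, meta: pd.DataFrame, *,
                 min_reads: int = 2, blank_factor: float = 10.0,
                 scope: str = "batch", replicate_mode: str = "additive",
                 min_run_reads: int = 100,
                 ) -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """Full filtering chain: singletons -> blanks -> replicates -> primer union.

    Returns (merged per-sample composition, audit table, dropped sample ids).
    Dropping and sweeping samples are both filtered; blank records are
    excluded from the returned composition.
    """
    t1, a1 = remove_low_read_bins(table, min_reads=min_reads)
    t2, a2 = filter_blank_contamination(t1, meta, factor=blank_factor, scope=scope)
    stype = meta.set_index("sample_id")["sample_type"]
    t2 = t2[~t2["sample_id"].map(stype).isin(BLANK_TYPES)]
    dropped: set = set()
    if replicate_mode == "additive":
        per_primer = combine_replicates_additive(t2)
        a3 = empty_audit()
    elif replicate_mode == "conservative":
        per_primer, dropped, a3 = combine_replicates_conservative(
            t2, min_run_reads=min_run_reads)
    else:
        raise TrophiqError(f"unknown replicate_mode {replicate_mode!r}")
    merged = merge_primers(per_primer)
    parts = [a for a in (a1, a2, a3) if len(a)]
    audit = pd.concat(parts, ignore_index=True) if parts else empty_audit()
    return merged, audit, dropped
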