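"""Niche overlap, randomization null models, Jaccard distances and ANOSIM.

Pianka's symmetric overlap index O_jk compares two resource-utilization
vectors; its significance is assessed against randomization null models in
the EcoSim tradition (RA1-RA4).  The default, RA3, shuffles each species'
utilization values among all resource states: niche breadth is retained while
which resources are used is scrambled.  Compositional distance between
samples uses the Jaccard index on BIN presence; ANOSIM tests whether
between-group rank distances exceed within-group ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_model import TrophiqError

logger = logging.getLogger("trophiq")

RA_ALGORITHMS = ("RA1", "RA2", "RA3", "RA4")


def _align_pair(p_j, p_k) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(p_j, pd.Series) or isinstance(p_k, pd.Series):
        p_j = pd.Series(p_j, dtype=float)
        p_k = pd.Series(p_k, dtype=float)
        idx = p_j.index.union(p_k.index)
        return (p_j.reindex(idx, fill_value=0.0).to_numpy(),
                p_k.reindex(idx, fill_value=0.0).to_numpy())
    return np.asarray(p_j, dtype=float), np.asarray(p_k, dtype=float)


def pianka(p_j, p_k) -> float:
    """Pianka's niche overlap O_jk = sum(p_j p_k) / sqrt(sum p_j^2 sum p_k^2).

    Accepts arrays (aligned positionally) or Series (aligned on the union of
    their indices, absent items counting as zero use).  Scale-invariant, so
    inputs need not be normalized.  Zero vectors raise.
    """
    a, b = _align_pair(p_j, p_k)
    if a.shape != b.shape:
        raise TrophiqError("pianka: vectors must share the same resource states")
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        raise TrophiqError("pianka: zero utilization vector")
    return float(np.clip((a * b).sum() / denom, 0.0, 1.0))


@dataclass
class OverlapResult:
    """Observed Pianka overlap with its randomization null distribution."""

    o_obs: float
    null_values: np.ndarray
    p_high: float          # Pr(null >= observed), small-sample corrected
    p_low: float           # Pr(null <= observed)
    algorithm: str
    n_iter: int
    seed: int | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"OverlapResult(O_jk={self.o_obs:.3f}, p_high={self.p_high:.4g}, "
                f"p_low={self.p_low:.4g}, {self.algorithm}, n_iter={self.n_iter})")


def _ra_nulls(matrix: np.ndarray, algorithm: str, n_iter: int,
              rng: np.random.Generator) -> np.ndarray:
    """Null utilization matrices, shape (n_iter, n_rows, n_cols)."""
    n_rows, n_cols = matrix.shape
    out = np.empty((n_iter, n_rows, n_cols))
    if algorithm == "RA3":
        # shuffle each row's values among all columns
        for r in range(n_rows):
            order = np.argsort(rng.random((n_iter, n_cols)), axis=1)
            out[:, r, :] = matrix[r][order]
    elif algorithm == "RA4":
        # shuffle each row's nonzero values among its nonzero columns
        out[:] = matrix[None, :, :]
        for r in range(n_rows):
            nz = np.nonzero(matrix[r])[0]
            if len(nz) > 1:
                order = np.argsort(rng.random((n_iter, len(nz))), axis=1)
                out[:, r, nz] = matrix[r][nz][order]
    elif algorithm == "RA1":
        # replace all utilizations with uniform random values
        out[:] = rng.random((n_iter, n_rows, n_cols))
    elif algorithm == "RA2":
        # replace nonzero utilizations with uniform random values, keep zeros
        out[:] = rng.random((n_iter, n_rows, n_cols))
        out *= (matrix != 0)[None, :, :]
    else:
        raise TrophiqError(f"unknown randomization algorithm {algorithm!r}")
    return out


def overlap_null_test(utilization, algorithm: str = "RA3", n_iter: int = 1000,
                      seed: int | None = None) -> OverlapResult:
    """Observed Pianka overlap of a 2 x m utilization matrix vs. an RA null.

    ``p_high`` is the fraction of null overlaps >= observed (ties included)
    with the +1 small-sample correction: (1 + #{null >= obs}) / (n_iter + 1);
    ``p_low`` likewise for the lower tail.
    """
    m = np.asarray(utilization, dtype=float)
    if m.ndim != 2 or m.shape[0] != 2:
        raise TrophiqError("overlap_null_test: utilization must be a 2 x m matrix")
    support = np.count_nonzero(m.sum(axis=0))
    if support <= 1:
        raise TrophiqError("overlap_null_test: degenerate matrix (single resource state)")
    if n_iter < 100:
        warnings.warn(f"overlap_null_test: n_iter = {n_iter} is very small",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    o_obs = pianka(m[0], m[1])
    nulls = _ra_nulls(m, algorithm, n_iter, rng)
    num = (nulls[:, 0, :] * nulls[:, 1, :]).sum(axis=1)
    den = np.sqrt((nulls[:, 0, :] ** 2).sum(axis=1) * (nulls[:, 1, :] ** 2).sum(axis=1))
    ok = den > 0
    null_values = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    eps = 1e-12
    p_high = (1.0 + np.sum(null_values >= o_obs - eps)) / (n_iter + 1.0)
    p_low = (1.0 + np.sum(null_values <= o_obs + eps)) / (n_iter + 1.0)
    return OverlapResult(o_obs=o_obs, null_values=null_values,
                         p_high=float(p_high), p_low=float(p_low),
                         algorithm=algorithm, n_iter=n_iter, seed=seed)


# -- Jaccard distance ---------------------------------------------------------

def jaccard_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distance on BIN presence between samples.

    *samples* is a merged composition table (sample_id, bin_id[, reads]).
    d(s, t) = 1 - |s n t| / |s u t|.  Empty samples are excluded with a
    warning.  Returns a symmetric DataFrame with zero diagonal.
    """
    pres = pd.crosstab(samples["sample_id"], samples["bin_id"]) > 0
    sizes = pres.sum(axis=1)
    empty = sizes[sizes == 0].index
    if len(empty):
        warnings.warn(f"jaccard_matrix: excluding empty samples {list(empty)}",
                      stacklevel=2)
        pres = pres.loc[sizes > 0]
    if len(pres) < 2:
        raise TrophiqError("jaccard_matrix: need at least 2 non-empty samples")
    x = pres.to_numpy(dtype=float)
    inter = x @ x.T
    size = x.sum(axis=1)
    union = size[:, None] + size[None, :] - inter
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pres.index, columns=pres.index)


# -- ANOSIM -------------------------------------------------------------------

@dataclass
class AnosimResult:
    """ANOSIM R statistic with permutation p-value."""

    r: float
    p: float
    n_perm: int
    seed: int | None


def _anosim_r(ranks: np.ndarray, within: np.ndarray, m_half: float) -> float:
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / m_half)


def anosim(dist, groups, n_perm: int = 999, seed: int | None = None) -> AnosimResult:
    """ANOSIM on a distance matrix: R = (mean between-rank - mean within-rank) / (M/2).

    Off-diagonal distances are ranked once (average ranks on ties);
    significance comes from permuting group labels.  Requires >= 2 groups
    with >= 2 members each.
    """
    if isinstance(dist, pd.DataFrame):
        labels = pd.Series(groups)
        if not labels.index.equals(dist.index):
            labels = labels.reindex(dist.index)
        d = dist.to_numpy(dtype=float)
        g = labels.to_numpy()
    else:
        d = np.asarray(dist, dtype=float)
        g = np.asarray(groups)
    n = d.shape[0]
    if d.shape != (n, n) or len(g) != n:
        raise TrophiqError("anosim: distance matrix and groups are inconsistent")
    uniq, counts = np.unique(g, return_counts=True)
    if len(uniq) < 2:
        raise TrophiqError("anosim: need at least two groups")
    if (counts < 2).any():
        raise TrophiqError("anosim: every group needs at least 2 members")
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu])
    m = len(ranks)
    m_half = m / 2.0
    same = g[iu[0]] == g[iu[1]]
    r_obs = _anosim_r(ranks, same, m_half)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(g) for _ in range(n_perm)])
    within_perm = perms[:, iu[0]] == perms[:, iu[1]]      # (n_perm, m)
    w_sum = within_perm.sum(axis=1).astype(float)
    rank_sum_within = within_perm @ ranks
    r_w = rank_sum_within / w_sum
    r_b = (ranks.sum() - rank_sum_within) / (m - w_sum)
    r_perm = (r_b - r_w) / m_half
    p = (1.0 + np.sum(r_perm >= r_obs - 1e-12)) / (n_perm + 1.0)
    return AnosimResult(r=r_obs, p=float(p), n_perm=n_perm, seed=seed)


# -- stratified and pairwise overlap ------------------------------------------

def _strata_masks(meta: pd.DataFrame, scale: str) -> dict[str, pd.Series]:
    drops = (meta["sample_type"] == "dropping") & (meta["broad_class"] != "excluded")
    if scale == "broad":
        return {
            "allopatric": drops & (meta["broad_class"] == "allopatric"),
            "sympatric": drops & (meta["broad_class"] == "sympatric"),
        }
    if scale == "fine":
        return {
            "allotopic": drops & (meta["fine_class"] == "allotopic"),
            "syntopic": drops & (meta["fine_class"] == "syntopic"),
        }
    raise TrophiqError(f"unknown scale {scale!r}; use 'broad' or 'fine'")


def _pooled_wpoo(samples: pd.DataFrame, sample_ids) -> pd.Series:
    """wPOO vector over BINs for the given samples of a composition table."""
    sub = samples[samples["sample_id"].isin(set(sample_ids))]
    if sub.empty:
        return pd.Series(dtype=float)
    n_items = sub.groupby("sample_id")["bin_id"].transform("nunique")
    contrib = 1.0 / n_items
    s = sub.assign(contrib=contrib).groupby("bin_id")["contrib"].sum()
    return s / sub["sample_id"].nunique()


def stratified_overlap(samples: pd.DataFrame, meta: pd.DataFrame,
                       scale: str = "broad", algorithm: str = "RA3",
                       n_iter: int = 1000, seed: int | None = None,
                       ) -> dict[str, OverlapResult]:
    """Per-stratum species overlap with its randomization null.

    For each stratum at the requested spatial scale, the two species' samples
    are pooled into wPOO vectors over the union of BINs and tested with
    :func:`overlap_null_test`.  Strata missing a species are skipped with a
    warning.
    """
    masks = _strata_masks(meta, scale)
    species = sorted(meta.loc[meta["sample_type"] == "dropping", "bat_species"]
                     .dropna().unique())
    out: dict[str, OverlapResult] = {}
    for i, (stratum, mask) in enumerate(masks.items()):
        vectors = {}
        for sp in species:
            ids = meta.loc[mask & (meta["bat_species"] == sp), "sample_id"]
            v = _pooled_wpoo(samples, ids)
            if len(v):
                vectors[sp] = v
        if len(vectors) < 2:
            warnings.warn(f"stratified_overlap: stratum {stratum!r} lacks both "
                          f"species; skipped", stacklevel=2)
            continue
        union = vectors[species[0]].index.union(vectors[species[1]].index)
        matrix = np.vstack([vectors[sp].reindex(union, fill_value=0.0).to_numpy()
                            for sp in species[:2]])
        sub_seed = None if seed is None else (seed + i)
        out[stratum] = overlap_null_test(matrix, algorithm=algorithm,
                                         n_iter=n_iter, seed=sub_seed)
    return out


def pairwise_site_overlap(samples: pd.DataFrame, meta: pd.DataFrame,
                          scale: str = "broad") -> pd.DataFrame:
    """Pianka overlap between pairs of sites holding different species.

    Diet composition is pooled per (site, species) into a wPOO vector; within
    each stratum of the requested scale, every ordered pair (site with
    species j, different site with species k) yields one overlap value.
    Returns columns site_j, site_k, contrast, o_jk; the exported table is the
    response variable for downstream model fits.
    """
    masks = _strata_masks(meta, scale)
    species = sorted(meta.loc[meta["sample_type"] == "dropping", "bat_species"]
                     .dropna().unique())
    if len(species) != 2:
        raise TrophiqError(f"pairwise_site_overlap: expected 2 species, got {species}")
    sp_j, sp_k = species
    rows = []
    for stratum, mask in masks.items():
        site_vecs: dict[str, dict[str, pd.Series]] = {sp: {} for sp in species}
        sub = meta[mask]
        for (site, sp), grp in sub.groupby(["site_id", "bat_species"]):
            v = _pooled_wpoo(samples, grp["sample_id"])
            if len(v):
                site_vecs[sp][site] = v
        for site_a, va in site_vecs[sp_j].items():
            for site_b, vb in site_vecs[sp_k].items():
                if site_a == site_b:
                    continue
                rows.append((site_a, site_b, stratum, pianka(va, vb)))
    return pd.DataFrame(rows, columns=["site_j", "site_k", "contrast", "o_jk"])
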