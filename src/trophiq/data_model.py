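"""Domain tables, readers/writers, validation, and spatial sympatry classification.

The pipeline's universal input is a long-format read-count table: one row per
(sample, sequencing run, BIN) with a non-negative read count.  Runs are the
four primer x PCR-replicate combinations each sample is sequenced under.
Sample metadata carries the study design (bat species, site, region,
allopatry/sympatry class at broad and fine spatial scales); BIN taxonomy maps
prey items to arthropod orders/families/species.

All tables are plain :class:`pandas.DataFrame` objects with the column sets
declared below; ``validate_*`` functions enforce the invariants and raise
:class:`ValidationError` naming the offending rows.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger("trophiq")

# -- column contracts ---------------------------------------------------------

READ_COLUMNS = ["sample_id", "run_id", "bin_id", "reads"]
META_COLUMNS = [
    "sample_id", "sample_type", "bat_species", "site_id", "region_id",
    "broad_class", "fine_class", "extraction_batch_id", "sequencing_run_id",
    "longitude", "latitude",
]
TAXONOMY_COLUMNS = ["bin_id", "order_name", "family_name", "species_name"]
FUNCTIONAL_COLUMNS = ["taxon_key", "category"]
MORPH_COLUMNS = ["sweep_sample_id", "order_name", "individuals"]

SAMPLE_TYPES = {"dropping", "sweeping", "blank_extraction", "blank_sequencing"}
BLANK_TYPES = {"blank_extraction", "blank_sequencing"}
BROAD_CLASSES = {"allopatric", "sympatric", "excluded"}
FINE_CLASSES = {"allotopic", "syntopic"}
FUNCTIONAL_CATEGORIES = ("non_volant", "not_actively_volant", "nocturnally_volant")

EARTH_RADIUS_KM = 6371.0088

_RUN_ID_RE = re.compile(r"^(?P<primer>.*?)(?P<replicate>\d+)$")


class TrophiqError(Exception):
    """Base class for all package errors."""


class ValidationError(TrophiqError):
    """A table violates its declared invariants."""


class StudyTables(NamedTuple):
    """The five input tables of a study, cross-validated."""

    reads: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    functional: pd.DataFrame
    morph: pd.DataFrame


def split_run_id(run_id: str) -> tuple[str, str]:
    """Split a run identifier into (primer_id, replicate_id).

    Run identifiers are free strings ending in the replicate number, e.g.
    ``"A1"`` -> ``("A", "1")`` or ``"ZBJ2"`` -> ``("ZBJ", "2")``.
    """
    m = _RUN_ID_RE.match(str(run_id))
    if not m or not m.group("primer"):
        raise ValidationError(
            f"run_id {run_id!r} does not follow '<primer><replicate>' form"
        )
    return m.group("primer"), m.group("replicate")


def run_structure(reads: pd.DataFrame) -> pd.DataFrame:
    """Return *reads* with ``primer_id`` and ``replicate_id`` columns added."""
    out = reads.copy()
    runs = out["run_id"].astype(str).unique()
    mapping = {r: split_run_id(r) for r in runs}
    out["primer_id"] = out["run_id"].map(lambda r: mapping[str(r)][0])
    out["replicate_id"] = out["run_id"].map(lambda r: mapping[str(r)][1])
    return out


# -- validation ---------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{table}: missing columns {missing}")


def validate_read_table(reads: pd.DataFrame, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    _require_columns(reads, READ_COLUMNS, "read table")
    out = reads.copy()
    out["reads"] = pd.to_numeric(out["reads"], errors="raise")
    neg = out.index[out["reads"] < 0]
    if len(neg):
        raise ValidationError(f"read table: negative reads at rows {list(neg[:10])}")
    if (out["reads"] % 1 != 0).any():
        raise ValidationError("read table: non-integer read counts")
    out["reads"] = out["reads"].astype(np.int64)
    dup = out.duplicated(subset=["sample_id", "run_id", "bin_id"])
    if dup.any():
        rows = out.loc[dup, ["sample_id", "run_id", "bin_id"]].head(10)
        raise ValidationError(f"read table: duplicate (sample, run, bin) keys:\n{rows}")
    if metadata is not None:
        known = set(metadata["sample_id"])
        unknown = sorted(set(out["sample_id"]) - known)
        if unknown:
            raise ValidationError(f"read table: sample_ids missing from metadata: {unknown[:10]}")
    return out


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    _require_columns(metadata, [c for c in META_COLUMNS if c not in ("longitude", "latitude")], "metadata")
    out = metadata.copy()
    for c in ("longitude", "latitude"):
        if c not in out.columns:
            out[c] = np.nan
    dup = out.duplicated(subset=["sample_id"])
    if dup.any():
        raise ValidationError(f"metadata: duplicate sample_ids {sorted(out.loc[dup, 'sample_id'])[:10]}")
    bad_type = sorted(set(out["sample_type"]) - SAMPLE_TYPES)
    if bad_type:
        raise ValidationError(f"metadata: unknown sample_type values {bad_type}")
    blanks = out["sample_type"].isin(BLANK_TYPES)
    bad_blank = out.loc[blanks & out["bat_species"].notna(), "sample_id"]
    if len(bad_blank):
        raise ValidationError(f"metadata: blanks with bat_species set: {list(bad_blank)[:10]}")
    fine = out["fine_class"].notna() & (out["fine_class"] != "NA")
    bad_fine = out.loc[fine & (out["broad_class"] != "sympatric"), "sample_id"]
    if len(bad_fine):
        raise ValidationError(
            f"metadata: fine_class set outside sympatric broad_class: {list(bad_fine)[:10]}"
        )
    return out


def validate_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    _require_columns(taxonomy, ["bin_id", "order_name"], "taxonomy")
    out = taxonomy.copy()
    for c in ("family_name", "species_name"):
        if c not in out.columns:
            out[c] = pd.NA
    dup = out.duplicated(subset=["bin_id"])
    if dup.any():
        raise ValidationError(f"taxonomy: duplicate bin_ids {sorted(out.loc[dup, 'bin_id'])[:10]}")
    empty = out["order_name"].isna() | (out["order_name"].astype(str).str.len() == 0)
    if empty.any():
        raise ValidationError(f"taxonomy: empty order_name for bins {list(out.loc[empty, 'bin_id'])[:10]}")
    return out


def validate_functional(functional: pd.DataFrame) -> pd.DataFrame:
    _require_columns(functional, FUNCTIONAL_COLUMNS, "functional table")
    out = functional.copy()
    bad = sorted(set(out["category"]) - set(FUNCTIONAL_CATEGORIES))
    if bad:
        raise ValidationError(f"functional table: unknown categories {bad}")
    conflicts = out.groupby("taxon_key")["category"].nunique()
    conflicts = conflicts[conflicts > 1]
    if len(conflicts):
        raise ValidationError(
            f"functional table: conflicting categories for taxa {list(conflicts.index)[:10]}"
        )
    return out.drop_duplicates(subset=["taxon_key"])


def validate_morph(morph: pd.DataFrame) -> pd.DataFrame:
    _require_columns(morph, MORPH_COLUMNS, "morphology table")
    out = morph.copy()
    out["individuals"] = pd.to_numeric(out["individuals"], errors="raise")
    if (out["individuals"] < 0).any():
        rows = out.index[out["individuals"] < 0]
        raise ValidationError(f"morphology table: negative counts at rows {list(rows[:10])}")
    out["individuals"] = out["individuals"].astype(np.int64)
    return out


def validate_study(tables: StudyTables) -> StudyTables:
    """Cross-validate the five study tables; returns normalized copies."""
    meta = validate_metadata(tables.metadata)
    reads = validate_read_table(tables.reads, meta)
    taxonomy = validate_taxonomy(tables.taxonomy)
    functional = validate_functional(tables.functional)
    morph = validate_morph(tables.morph)
    unknown_bins = sorted(set(reads["bin_id"]) - set(taxonomy["bin_id"]))
    if unknown_bins:
        raise ValidationError(f"read table: bin_ids missing from taxonomy: {unknown_bins[:10]}")
    return StudyTables(reads, meta, taxonomy, functional, morph)


# -- I/O ----------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a UTF-8 delimiter-separated table (tab default, comma auto-detected)."""
    path = Path(path)
    if not path.exists():
        raise TrophiqError(f"no such file: {path}")
    return pd.read_csv(path, sep=_detect_sep(path))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 TSV with a single header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tables(paths: Mapping[str, str | Path]) -> StudyTables:
    """Load and cross-validate the five study tables.

    Parameters
    ----------
    paths
        Mapping with keys ``reads``, ``metadata``, ``taxonomy``, ``functional``
        and ``morph``, each pointing at a delimiter-separated text file.
    """
    required = {"reads", "metadata", "taxonomy", "functional", "morph"}
    missing = required - set(paths)
    if missing:
        raise TrophiqError(f"read_tables: missing paths for {sorted(missing)}")
    raw = StudyTables(*(read_table(paths[k]) for k in
                        ("reads", "metadata", "taxonomy", "functional", "morph")))
    return validate_study(raw)


def write_tables(tables: StudyTables, outdir: str | Path) -> dict[str, Path]:
    """Write the five study tables into *outdir* as TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = {
        "reads": tables.reads, "metadata": tables.metadata,
        "taxonomy": tables.taxonomy, "functional": tables.functional,
        "morph": tables.morph,
    }
    paths = {}
    for key, df in names.items():
        paths[key] = outdir / f"{key}.tsv"
        write_table(df, paths[key])
    return paths


# -- spatial classification ---------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between WGS84 decimal-degree points.

    Vectorized over any broadcastable combination of coordinate arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def classify_fine_scale(metadata: pd.DataFrame, radius_km: float = 3.0) -> pd.DataFrame:
    """Label sympatric-region sites syntopic/allotopic by proximity to the other species.

    A site in the sympatric region is *syntopic* iff its great-circle distance
    to any record (sample) of the other bat species is <= ``radius_km``
    (boundary counts as syntopic); otherwise *allotopic*.  Records of either
    species anywhere in the study count as presence records.  Returns a copy
    of *metadata* with ``fine_class`` filled for sympatric dropping samples.
    """
    if radius_km <= 0:
        raise TrophiqError("radius_km must be positive")
    meta = metadata.copy()
    drops = meta[(meta["sample_type"] == "dropping") & meta["bat_species"].notna()]
    symp = drops[drops["broad_class"] == "sympatric"]
    no_coords = symp[symp["longitude"].isna() | symp["latitude"].isna()]
    if len(no_coords):
        sites = sorted(no_coords["site_id"].unique())
        raise ValidationError(
            f"classify_fine_scale: missing coordinates for sympatric sites {sites}"
        )
    species = sorted(drops["bat_species"].dropna().unique())
    if len(species) != 2:
        raise TrophiqError(f"classify_fine_scale: expected 2 species, found {species}")
    site_class: dict[tuple[str, str], str] = {}
    for sp in species:
        other = [s for s in species if s != sp][0]
        other_recs = drops[drops["bat_species"] == other]
        own_sites = symp[symp["bat_species"] == sp][
            ["site_id", "longitude", "latitude"]].drop_duplicates("site_id")
        for _, row in own_sites.iterrows():
            if len(other_recs) == 0:
                site_class[(row["site_id"], sp)] = "allotopic"
                continue
            d = haversine_km(row["longitude"], row["latitude"],
                             other_recs["longitude"].values, other_recs["latitude"].values)
            site_class[(row["site_id"], sp)] = (
                "syntopic" if float(np.min(d)) <= radius_km else "allotopic"
            )
    is_symp_drop = (
        (meta["sample_type"] == "dropping")
        & meta["bat_species"].notna()
        & (meta["broad_class"] == "sympatric")
    )
    meta.loc[is_symp_drop, "fine_class"] = [
        site_class[(row["site_id"], row["bat_species"])]
        for _, row in meta.loc[is_symp_drop].iterrows()
    ]
    return meta


def exclude_swarming(metadata: pd.DataFrame, site_ids: Iterable[str]) -> pd.DataFrame:
    """Flag the given sites ``broad_class = excluded`` (e.g. swarming locations).

    Excluded samples drop out of both broad- and fine-scale analyses; their
    ``fine_class`` is cleared.  Unknown site ids raise.
    """
    site_ids = set(site_ids)
    meta = metadata.copy()
    known = set(meta["site_id"].dropna())
    unknown = sorted(site_ids - known)
    if unknown:
        raise TrophiqError(f"exclude_swarming: unknown site_ids {unknown}")
    if not site_ids:
        return meta
    mask = meta["site_id"].isin(site_ids)
    meta.loc[mask, "broad_class"] = "excluded"
    meta.loc[mask, "fine_class"] = pd.NA
    logger.info("exclude_swarming: flagged %d samples at sites %s",
                int(mask.sum()), sorted(site_ids))
    return meta
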