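"""Reading, validation and normalization of occurrence and backbone tables.

Input dialect: UTF-8 tab-separated with a Darwin-Core-term header row.
Occurrence columns: scientificName, taxonRank, class, order, year, month,
decimalLatitude, decimalLongitude, basisOfRecord, issue.  Backbone columns:
scientificName, class, order, taxonomicStatus.

Normalization attaches to each record an origin category (Specimen /
Observation / Unknown from basisOfRecord), completeness flags (time_issue
when year or month is absent, space_issue when coordinates are absent or a
geospatial issue is flagged) and a species-precision flag (identified at
species rank or below).  Unparseable year/month/coordinate values are
treated as absent — they trip the corresponding issue flag instead of
dropping the row, so the completeness accounting still sees them.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceRecord",
    "BackboneEntry",
    "ReadTally",
    "classify_basis",
    "flag_completeness",
    "flag_precision",
    "normalize_lon",
    "read_occurrences",
    "read_occurrences_frame",
    "read_backbone",
    "count_known_species",
    "OCCURRENCE_COLUMNS",
    "BACKBONE_COLUMNS",
]

OCCURRENCE_COLUMNS = [
    "scientificName",
    "taxonRank",
    "class",
    "order",
    "year",
    "month",
    "decimalLatitude",
    "decimalLongitude",
    "basisOfRecord",
    "issue",
]
BACKBONE_COLUMNS = ["scientificName", "class", "order", "taxonomicStatus"]

#: Mandatory occurrence headers; absence is a hard error.
MANDATORY_COLUMNS = ("class", "basisOfRecord")

# basisOfRecord vocabularies, matched case-insensitively with separators
# (space/underscore/hyphen) stripped.
_SPECIMEN_BASES = {
    "fossilspecimen",
    "livingspecimen",
    "materialsample",
    "preservedspecimen",
}
_OBSERVATION_BASES = {
    "humanobservation",
    "machineobservation",
    "observation",
    "literature",
}

_PRECISE_RANKS = {"species", "subspecies", "variety", "form"}

_SEP_RE = re.compile(r"[\s_\-]+")


def classify_basis(basis_raw: str | None) -> str:
    """Map a raw basisOfRecord string to Specimen / Observation / Unknown.

    Total function: any unmatched value, including empty or missing,
    yields ``"Unknown"``.
    """
    if basis_raw is None or (isinstance(basis_raw, float) and np.isnan(basis_raw)):
        return "Unknown"
    key = _SEP_RE.sub("", str(basis_raw).strip().lower())
    if key in _SPECIMEN_BASES:
        return "Specimen"
    if key in _OBSERVATION_BASES:
        return "Observation"
    return "Unknown"


def flag_precision(taxon_rank: str | None, species: str | None) -> bool:
    """True iff the record is identified at species rank or below."""
    if not species or (isinstance(species, float) and np.isnan(species)):
        return False
    if taxon_rank is None or (isinstance(taxon_rank, float) and np.isnan(taxon_rank)):
        return False
    return str(taxon_rank).strip().lower() in _PRECISE_RANKS


def normalize_lon(lon: float) -> float:
    """Wrap a longitude into [-180, 180)."""
    return ((lon + 180.0) % 360.0) - 180.0


@dataclass(frozen=True)
class OccurrenceRecord:
    """One normalized occurrence."""

    class_name: str
    order_name: str
    species: str
    taxon_rank: str
    year: int | None
    month: int | None
    lat: float | None
    lon: float | None
    basis: str
    geo_issue: bool
    origin: str
    time_issue: bool
    space_issue: bool
    species_precise: bool


@dataclass(frozen=True)
class BackboneEntry:
    """One taxonomic-backbone name with its status."""

    species: str
    class_name: str
    order_name: str
    status: str


@dataclass
class ReadTally:
    """Bookkeeping for a table read; malformed values are never silent."""

    n_rows: int = 0
    n_records: int = 0
    n_skipped: int = 0
    n_bad_year: int = 0
    n_bad_month: int = 0
    n_bad_coord: int = 0
    n_no_class: int = 0
    details: dict = field(default_factory=dict)


def flag_completeness(
    year: int | None,
    month: int | None,
    lat: float | None,
    lon: float | None,
    geo_issue: bool,
) -> tuple[bool, bool]:
    """Derive (time_issue, space_issue) from the normalized fields."""
    time_issue = year is None or month is None
    space_issue = lat is None or lon is None or bool(geo_issue)
    return time_issue, space_issue


def _to_num(series: pd.Series) -> pd.Series:
    return pd.to_numeric(series, errors="coerce")


def read_occurrences_frame(
    path: str | Path,
    schema: dict[str, str] | None = None,
    geo_issue_flags: list[str] | None = None,
) -> tuple[pd.DataFrame, ReadTally]:
    """Read an occurrence table into a normalized DataFrame plus a tally.

    ``schema`` optionally remaps Darwin-Core header variants, as a mapping
    from the canonical column name to the header actually present in the
    file.  ``geo_issue_flags`` restricts which values of the ``issue``
    column count as geospatial issues; by default any non-empty value does.

    The returned frame has columns: class_name, order_name, species,
    taxon_rank, year, month, lat, lon, basis, geo_issue, origin,
    time_issue, space_issue, species_precise.  year/month are nullable
    integers; lat/lon are floats with NaN for absent.
    """
    schema = schema or {}
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    tally = ReadTally(n_rows=len(raw))

    colmap = {canon: schema.get(canon, canon) for canon in OCCURRENCE_COLUMNS}
    missing = [colmap[c] for c in MANDATORY_COLUMNS if colmap[c] not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")

    def col(canon: str) -> pd.Series:
        name = colmap[canon]
        if name in raw.columns:
            return raw[name]
        return pd.Series([""] * len(raw), index=raw.index, dtype=str)

    df = pd.DataFrame(index=raw.index)
    df["class_name"] = col("class").str.strip()
    df["order_name"] = col("order").str.strip()
    df["species"] = col("scientificName").str.strip()
    df["taxon_rank"] = col("taxonRank").str.strip()

    year_raw, month_raw = col("year"), col("month")
    year = _to_num(year_raw)
    month = _to_num(month_raw)
    tally.n_bad_year = int(((year_raw.str.strip() != "") & year.isna()).sum())
    tally.n_bad_month = int(((month_raw.str.strip() != "") & month.isna()).sum())
    month = month.where((month >= 1) & (month <= 12))
    df["year"] = year.round().astype("Int64")
    df["month"] = month.round().astype("Int64")

    lat = _to_num(col("decimalLatitude"))
    lon = _to_num(col("decimalLongitude"))
    bad_range = (lat < -90) | (lat > 90)
    tally.n_bad_coord = int(bad_range.fillna(False).sum())
    lat = lat.where(~bad_range.fillna(False))
    lon = lon.where(lat.notna())
    lon = ((lon + 180.0) % 360.0) - 180.0
    df["lat"] = lat
    df["lon"] = lon

    df["basis"] = col("basisOfRecord").str.strip()
    issue = col("issue").str.strip()
    if geo_issue_flags is None:
        df["geo_issue"] = issue != ""
    else:
        wanted = {f.strip().lower() for f in geo_issue_flags}
        df["geo_issue"] = issue.str.lower().apply(
            lambda v: any(tok.strip() in wanted for tok in v.split(";")) if v else False
        )

    df["origin"] = df["basis"].map(classify_basis)
    df["time_issue"] = df["year"].isna() | df["month"].isna()
    df["space_issue"] = df["lat"].isna() | df["lon"].isna() | df["geo_issue"]
    rank_lc = df["taxon_rank"].str.lower()
    df["species_precise"] = rank_lc.isin(_PRECISE_RANKS) & (df["species"] != "")
    # species field only meaningful at species rank or lower
    df.loc[~df["species_precise"], "species"] = ""

    tally.n_no_class = int((df["class_name"] == "").sum())
    tally.n_records = len(df)
    if tally.n_bad_year or tally.n_bad_month or tally.n_bad_coord:
        logger.warning(
            "lenient parse: %d bad years, %d bad months, %d out-of-range coords "
            "mapped to absent",
            tally.n_bad_year,
            tally.n_bad_month,
            tally.n_bad_coord,
        )
    return df, tally


def iter_records(df: pd.DataFrame) -> Iterator[OccurrenceRecord]:
    """Yield :class:`OccurrenceRecord` objects from a normalized frame."""
    for row in df.itertuples(index=False):
        yield OccurrenceRecord(
            class_name=row.class_name,
            order_name=row.order_name,
            species=row.species,
            taxon_rank=row.taxon_rank,
            year=None if pd.isna(row.year) else int(row.year),
            month=None if pd.isna(row.month) else int(row.month),
            lat=None if pd.isna(row.lat) else float(row.lat),
            lon=None if pd.isna(row.lon) else float(row.lon),
            basis=row.basis,
            geo_issue=bool(row.geo_issue),
            origin=row.origin,
            time_issue=bool(row.time_issue),
            space_issue=bool(row.space_issue),
            species_precise=bool(row.species_precise),
        )


def read_occurrences(
    path: str | Path,
    schema: dict[str, str] | None = None,
    geo_issue_flags: list[str] | None = None,
) -> tuple[list[OccurrenceRecord], ReadTally]:
    """Read an occurrence table into a list of records plus a tally."""
    df, tally = read_occurrences_frame(path, schema=schema, geo_issue_flags=geo_issue_flags)
    return list(iter_records(df)), tally


def read_backbone(path: str | Path) -> list[BackboneEntry]:
    """Read a backbone table (scientificName, class, order, taxonomicStatus)."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("scientificName", "class", "taxonomicStatus") if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory backbone columns: {missing}")
    orders = raw["order"] if "order" in raw.columns else [""] * len(raw)
    entries = []
    for name, cls, order, status in zip(
        raw["scientificName"], raw["class"], orders, raw["taxonomicStatus"]
    ):
        status = status.strip().lower()
        if status not in {"accepted", "doubtful", "synonym"}:
            raise ValueError(f"unknown taxonomicStatus {status!r}")
        entries.append(
            BackboneEntry(
                species=name.strip(),
                class_name=cls.strip(),
                order_name=order.strip(),
                status=status,
            )
        )
    return entries


def backbone_frame(entries: list[BackboneEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [e.species for e in entries],
            "class_name": [e.class_name for e in entries],
            "order_name": [e.order_name for e in entries],
            "status": [e.status for e in entries],
        }
    )


def count_known_species(entries: list[BackboneEntry], class_name: str) -> int:
    """Distinct non-synonym species names of one class.

    Returns 0 (with a logged warning) for a class absent from the backbone.
    """
    names = {
        e.species for e in entries if e.class_name == class_name and e.status != "synonym"
    }
    if not names:
        logger.warning("class %r not found in backbone; N = 0", class_name)
    return len(names)
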