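"""Per-taxon sampling-bias statistics and ideal-sampling deviations.

Conventions: the median of an even-length sample is the mean of the two
central order statistics; the MAD is the raw median of absolute deviations
from the median (no normal-consistency scaling).  Species identity is the
exact name string within a taxon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import grid
from .ingest import BackboneEntry

logger = logging.getLogger(__name__)

__all__ = [
    "ClassSummary",
    "BiasDeviation",
    "median",
    "mad",
    "summarize",
    "ideal_sampling",
    "deviation",
    "deviations_from_summaries",
    "temporal_deviations",
    "occurrence_class_histogram",
    "weighted_precision",
    "share_of_total",
]

DEFAULT_CHECKPOINTS = (1956, 1966, 1976, 1986, 1996, 2006)

#: Threshold for a "decently sampled" species: at least this many
#: occurrences (or spatially distinct occurrences for the ``d`` variant).
DECENT_THRESHOLD = 20


def median(values: Sequence[float] | np.ndarray) -> float:
    """Median; even length averages the two central order statistics."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan")
    return float(np.median(arr))


def mad(values: Sequence[float] | np.ndarray) -> float:
    """Unscaled median absolute deviation from the median."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return float("nan")
    return float(np.median(np.abs(arr - np.median(arr))))


@dataclass
class ClassSummary:
    """All per-taxon statistics of the summary report."""

    taxon: str
    nb_occ: int = 0
    n_gt1: int = 0
    N: int = 0
    med_sp: float = float("nan")
    mad: float = float("nan")
    precision: float = float("nan")
    p_gt1: float = float("nan")
    p_gt20: float = float("nan")
    p_gt20d: float = float("nan")
    o_spec: float = float("nan")
    o_obs: float = float("nan")
    o_unk: float = float("nan")
    p_time: float = float("nan")
    p_space: float = float("nan")


@dataclass
class BiasDeviation:
    """Ideal sampling I and signed deviation for one taxon at a checkpoint."""

    taxon: str
    checkpoint: int | str
    nb_occ: int
    I: float
    D: float
    sign: str
    d_norm: float = float("nan")


def ideal_sampling(NB_occ: float, N: float, N_tot: float) -> float:
    """Occurrence count a taxon would have under proportional sampling."""
    if N_tot <= 0:
        raise ValueError("N_tot must be positive")
    if not (0 <= N <= N_tot):
        raise ValueError("N must lie in [0, N_tot]")
    return NB_occ * (N / N_tot)


def deviation(nb_occ: float, ideal: float) -> float:
    return nb_occ - ideal


def _sign(d: float) -> str:
    if d > 0:
        return "over"
    if d < 0:
        return "under"
    return "balanced"


def _species_counts(df: pd.DataFrame) -> pd.Series:
    """Occurrences per species, species-precise records only."""
    precise = df[df["species_precise"] & (df["species"] != "")]
    return precise.groupby("species").size()


def summarize(
    records: pd.DataFrame,
    backbone: Iterable[BackboneEntry],
    level: str = "class",
    cell_size: float = grid.DEFAULT_CELL_SIZE_M,
    taxa: Sequence[str] | None = None,
) -> list[ClassSummary]:
    """Compute all per-taxon summary statistics at class or order level.

    Records with an empty taxon field at the requested level are excluded
    from the summaries (with a logged tally).  ``taxa`` restricts the
    output to the given taxon names; by default all observed taxa are
    summarized, ordered by descending occurrence count.
    """
    if level not in ("class", "order"):
        raise ValueError("level must be 'class' or 'order'")
    key = "class_name" if level == "class" else "order_name"
    df = records
    n_empty = int((df[key] == "").sum())
    if n_empty:
        logger.info("%d records without %s affiliation excluded from summaries", n_empty, level)
    df = df[df[key] != ""]

    backbone = list(backbone)
    bb_key = "class_name" if level == "class" else "order_name"
    known: dict[str, set[str]] = {}
    for e in backbone:
        if e.status == "synonym":
            continue
        taxon = getattr(e, bb_key)
        if taxon:
            known.setdefault(taxon, set()).add(e.species)

    if taxa is None:
        taxa = list(df.groupby(key).size().sort_values(ascending=False).index)

    out = []
    for taxon in taxa:
        sub = df[df[key] == taxon]
        nb_occ = len(sub)
        counts = _species_counts(sub)
        n_gt1 = int(len(counts))
        n_gt20 = int((counts >= DECENT_THRESHOLD).sum())
        N = len(known.get(taxon, ()))

        # distinct-cell counts for species that could plausibly pass the
        # threshold; records lacking coordinates excluded before counting
        n_gt20d = 0
        candidates = counts[counts >= DECENT_THRESHOLD].index
        if len(candidates) > 0:
            spatial = sub[
                sub["species"].isin(candidates) & sub["lat"].notna() & sub["lon"].notna()
            ]
            for _, sp_df in spatial.groupby("species"):
                if (
                    grid.count_distinct_cells(
                        sp_df["lat"].to_numpy(), sp_df["lon"].to_numpy(), cell_size
                    )
                    >= DECENT_THRESHOLD
                ):
                    n_gt20d += 1

        s = ClassSummary(taxon=taxon, nb_occ=nb_occ, n_gt1=n_gt1, N=N)
        if nb_occ:
            s.precision = float(sub["species_precise"].mean())
            s.o_spec = float((sub["origin"] == "Specimen").mean())
            s.o_obs = float((sub["origin"] == "Observation").mean())
            s.o_unk = float((sub["origin"] == "Unknown").mean())
            s.p_time = float(sub["time_issue"].mean())
            s.p_space = float(sub["space_issue"].mean())
        if n_gt1:
            s.med_sp = median(counts.to_numpy())
            s.mad = mad(counts.to_numpy())
        if N > 0:
            s.p_gt1 = n_gt1 / N
            s.p_gt20 = n_gt20 / N
            s.p_gt20d = n_gt20d / N
        out.append(s)
    return out


def deviations_from_summaries(summaries: Sequence[ClassSummary]) -> list[BiasDeviation]:
    """Signed deviations from ideal sampling over a set of taxa ("all" state)."""
    NB_occ = sum(s.nb_occ for s in summaries)
    N_tot = sum(s.N for s in summaries)
    out = []
    for s in summaries:
        ideal = ideal_sampling(NB_occ, s.N, N_tot)
        d = deviation(s.nb_occ, ideal)
        out.append(
            BiasDeviation(
                taxon=s.taxon,
                checkpoint="all",
                nb_occ=s.nb_occ,
                I=ideal,
                D=d,
                sign=_sign(d),
                d_norm=d / NB_occ if NB_occ else float("nan"),
            )
        )
    return out


def temporal_deviations(
    records: pd.DataFrame,
    backbone: Iterable[BackboneEntry],
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    export_year: int = 2016,
    taxa: Sequence[str] | None = None,
) -> list[BiasDeviation]:
    """Deviation from ideal sampling at decadal checkpoints.

    Excludes records without a collection year and records from the last
    10 years before ``export_year`` (integration lag).  At each checkpoint
    the per-class occurrence count is the cumulative count of records with
    ``year <= checkpoint``; known-species counts N are held at their
    present-day backbone values.
    """
    backbone = list(backbone)
    df = records[records["class_name"] != ""]
    dated = df[df["year"].notna()]
    dated = dated[dated["year"] <= export_year - 10]

    if taxa is None:
        taxa = sorted(df["class_name"].unique())
    counts_by_class: dict[str, set] = {}
    for e in backbone:
        if e.status == "synonym" or not e.class_name:
            continue
        counts_by_class.setdefault(e.class_name, set()).add(e.species)
    N = {t: len(counts_by_class.get(t, ())) for t in taxa}
    N_tot = sum(N.values())

    out = []
    for cp in checkpoints:
        upto = dated[dated["year"] <= cp]
        nb = upto.groupby("class_name").size()
        NB_occ = int(nb.sum())
        for taxon in taxa:
            n_occ = int(nb.get(taxon, 0))
            ideal = ideal_sampling(NB_occ, N[taxon], N_tot) if N_tot else 0.0
            d = deviation(n_occ, ideal)
            out.append(
                BiasDeviation(
                    taxon=taxon,
                    checkpoint=int(cp),
                    nb_occ=n_occ,
                    I=ideal,
                    D=d,
                    sign=_sign(d),
                    d_norm=d / NB_occ if NB_occ else 0.0,
                )
            )
    return out


def occurrence_class_histogram(
    species_counts: Sequence[float] | np.ndarray,
) -> tuple[float, float, float]:
    """Proportions of recorded species with 1, 2-19 and >=20 occurrences."""
    arr = np.asarray(species_counts, dtype=float)
    arr = arr[arr >= 1]
    if arr.size == 0:
        raise ValueError("no species with at least one occurrence")
    n = arr.size
    p1 = float((arr == 1).sum() / n)
    p20 = float((arr >= DECENT_THRESHOLD).sum() / n)
    pmid = float(((arr >= 2) & (arr < DECENT_THRESHOLD)).sum() / n)
    return p1, pmid, p20


def weighted_precision(
    summaries: Sequence[ClassSummary], exclude: Iterable[str] = ()
) -> float:
    """Occurrence-weighted mean taxonomic precision over non-excluded taxa."""
    excl = set(exclude)
    rows = [s for s in summaries if s.taxon not in excl]
    total = sum(s.nb_occ for s in rows)
    if total == 0:
        raise ValueError("no occurrences in selection")
    return sum(s.nb_occ * s.precision for s in rows) / total


def share_of_total(
    summaries: Sequence[ClassSummary], taxon: str, reference_total: float
) -> float:
    """Share of a reference total held by one taxon's occurrence count."""
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    for s in summaries:
        if s.taxon == taxon:
            return s.nb_occ / reference_total
    raise KeyError(taxon)


def summaries_frame(summaries: Sequence[ClassSummary]) -> pd.DataFrame:
    """Tabular view of summaries for report writing."""
    return pd.DataFrame([vars(s) for s in summaries])


def deviations_frame(devs: Sequence[BiasDeviation]) -> pd.DataFrame:
    return pd.DataFrame([vars(d) for d in devs])
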