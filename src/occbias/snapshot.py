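"""Published per-class summary statistics of the June 2016 GBIF snapshot.

The bundled table holds the class-level statistics published for the GBIF
occurrence snapshot of June 2016 (snapshot doi:10.15468/dl.hqesx6, backbone
doi:10.15468/39omei): occurrence totals in millions, recorded-species
totals in thousands, per-species median/MAD and taxonomic precision for
the 24 classes that exceeded one million occurrences, plus the 24-class
and whole-GBIF totals.  These serve as reference inputs for headline
coverage and precision statistics; they are data, not code defaults.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import ClassSummary

__all__ = [
    "load_table",
    "class_summaries",
    "totals",
    "SPECIES_HISTOGRAM_COUNTS",
]

#: Published counts of recorded species with exactly 1, 2-19 and >=20
#: occurrences across the 24 selected classes (June 2016 snapshot).
SPECIES_HISTOGRAM_COUNTS = (212_911, 446_643, 353_843)

_TOTAL_ROWS = ("TOTAL_24_CLASSES", "TOTAL_GBIF")


def load_table() -> pd.DataFrame:
    """Raw bundled table, including the two totals rows."""
    ref = resources.files("occbias.data") / "gbif_2016_class_summary.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def class_summaries() -> list[ClassSummary]:
    """The 24 class rows as :class:`ClassSummary` objects.

    ``nb_occ`` is in millions of occurrences and ``n_gt1`` in thousands of
    species, as published; callers that mix these with absolute counts
    must rescale.
    """
    df = load_table()
    out = []
    for row in df.itertuples(index=False):
        if row[0] in _TOTAL_ROWS:
            continue
        out.append(
            ClassSummary(
                taxon=row[0],
                nb_occ=row.nb_occ_millions,
                n_gt1=row.species_thousands,
                med_sp=float(row.med_sp),
                mad=float(row.mad),
                precision=float(row.precision),
            )
        )
    return out


def totals() -> dict[str, dict[str, float]]:
    """Occurrence/species totals for the 24-class subset and whole GBIF."""
    df = load_table().set_index("class")
    out = {}
    for key, label in (("selected", "TOTAL_24_CLASSES"), ("gbif", "TOTAL_GBIF")):
        row = df.loc[label]
        out[key] = {
            "nb_occ_millions": float(row.nb_occ_millions),
            "species_thousands": float(row.species_thousands),
            "precision": float(row.precision),
        }
    return out
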