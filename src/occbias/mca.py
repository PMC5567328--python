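"""Multiple correspondence analysis with rare-category ventilation.

MCA is computed as the correspondence analysis of the complete disjunctive
(indicator) table: centre by category masses, scale, then a singular value
decomposition of the standardized residuals.  Row (occurrence) scores are
retained so taxon barycentres can be placed at the average position of
their occurrences.  Axis orientation is fixed by making the
largest-magnitude category loading on each axis positive, which makes
results deterministic given the sampling seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

logger = logging.getLogger(__name__)

__all__ = [
    "YEAR_BINS",
    "McaResult",
    "year_bin",
    "completeness_category",
    "build_mca_table",
    "ventilate",
    "fit_mca",
    "class_barycentres",
]

YEAR_BINS = (
    "<1900",
    "1900-1949",
    "1950-1974",
    "1975-1999",
    "2000-2004",
    "2005-2009",
    "2010-2014",
    ">=2015",
    "Unknown Year",
)

_YEAR_EDGES = (1900, 1950, 1975, 2000, 2005, 2010, 2015)


def year_bin(year: float | None) -> str:
    """Categorize a collection year into the eight intervals + Unknown."""
    if year is None or (isinstance(year, float) and np.isnan(year)) or pd.isna(year):
        return "Unknown Year"
    y = int(year)
    if y < 1900:
        return "<1900"
    if y < 1950:
        return "1900-1949"
    if y < 1975:
        return "1950-1974"
    if y < 2000:
        return "1975-1999"
    if y < 2005:
        return "2000-2004"
    if y < 2010:
        return "2005-2009"
    if y < 2015:
        return "2010-2014"
    return ">=2015"


def completeness_category(time_issue: bool, space_issue: bool) -> str:
    if time_issue and space_issue:
        return "Both issues"
    if time_issue:
        return "Temporal issue"
    if space_issue:
        return "Spatial issues"
    return "No issue"


def build_mca_table(records: pd.DataFrame) -> pd.DataFrame:
    """Categorical table (class, year_bin, origin, completeness) per record."""
    df = records[records["class_name"] != ""]
    out = pd.DataFrame(index=df.index)
    out["class"] = df["class_name"]
    out["year_bin"] = df["year"].map(year_bin)
    out["origin"] = df["origin"]
    out["completeness"] = [
        completeness_category(t, s) for t, s in zip(df["time_issue"], df["space_issue"])
    ]
    return out.reset_index(drop=True)


def ventilate(
    table: pd.DataFrame,
    threshold: float = 0.005,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Reassign rows of rare categories among the remaining categories.

    For each variable, every category held by fewer than ``threshold`` of
    the rows has its rows randomly redistributed over the variable's
    non-rare categories with probabilities proportional to their
    frequencies, repeating until no category is rare.  A variable that
    collapses to a single category is dropped with a warning.  Row count
    is preserved exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    drop: list[str] = []
    for col in out.columns:
        for _ in range(100):
            counts = out[col].value_counts()
            if len(counts) <= 1:
                break
            rare = counts[counts < threshold * n]
            if rare.empty:
                break
            keep = counts[counts >= threshold * n]
            if keep.empty:
                # everything rare: collapse to the modal category
                out[col] = counts.index[0]
                break
            mask = out[col].isin(rare.index)
            probs = keep / keep.sum()
            out.loc[mask, col] = rng.choice(
                keep.index.to_numpy(), size=int(mask.sum()), p=probs.to_numpy()
            )
        if out[col].nunique() <= 1:
            logger.warning("variable %r collapsed to one category; dropped", col)
            drop.append(col)
    return out.drop(columns=drop)


@dataclass
class McaResult:
    eigenvalues: np.ndarray  # non-increasing, in [0, 1]
    inertia_share: np.ndarray
    category_coords: pd.DataFrame  # index (variable, category), columns axis1..axisK
    row_coords: np.ndarray  # n x K principal coordinates
    J: int
    Q: int
    variables: list[str]


def fit_mca(table: pd.DataFrame, n_axes: int | None = None) -> McaResult:
    """Fit MCA on a table of categorical variables (one row per occurrence)."""
    for col in table.columns:
        if table[col].nunique() <= 1:
            raise ValueError(
                f"variable {col!r} is constant; ventilate or drop it before fitting"
            )
    n = len(table)
    Q = table.shape[1]
    dummies = pd.get_dummies(table.astype(str), prefix_sep="\x00")
    Z = dummies.to_numpy(dtype=float)
    J = Z.shape[1]

    P = Z / (n * Q)
    r = np.full(n, 1.0 / n)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = linalg.svd(S, full_matrices=False)

    eig_full = sv**2
    keep = min(J - Q, 10) if n_axes is None else n_axes
    keep = max(1, min(keep, len(sv)))
    sv = sv[:keep]
    U = U[:, :keep]
    V = Vt[:keep].T

    col_coords = (V * sv) / np.sqrt(c)[:, None]
    row_coords = (U * sv) / np.sqrt(r)[:, None]

    # orientation: largest-magnitude category loading positive per axis
    for k in range(keep):
        j = int(np.argmax(np.abs(col_coords[:, k])))
        if col_coords[j, k] < 0:
            col_coords[:, k] *= -1
            row_coords[:, k] *= -1

    idx = pd.MultiIndex.from_tuples(
        [tuple(name.split("\x00", 1)) for name in dummies.columns],
        names=["variable", "category"],
    )
    coords = pd.DataFrame(
        col_coords, index=idx, columns=[f"axis{k + 1}" for k in range(keep)]
    )
    total_inertia = J / Q - 1.0
    return McaResult(
        eigenvalues=eig_full,
        inertia_share=eig_full / total_inertia,
        category_coords=coords,
        row_coords=row_coords,
        J=J,
        Q=Q,
        variables=list(table.columns),
    )


def class_barycentres(result: McaResult, classes: pd.Series | np.ndarray) -> pd.DataFrame:
    """Average row-score position of each class's occurrences."""
    classes = np.asarray(classes)
    if len(classes) != result.row_coords.shape[0]:
        raise ValueError("classes length does not match fitted rows")
    df = pd.DataFrame(
        result.row_coords,
        columns=[f"axis{k + 1}" for k in range(result.row_coords.shape[1])],
    )
    df["class"] = classes
    return df.groupby("class").mean()
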