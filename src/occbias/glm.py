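"""Negative-binomial models of occurrence counts vs interest and research.

The model is identical for every taxon: a log-link NB2 regression of the
per-species occurrence count on the transformed public-interest covariate,
the transformed research covariate and their interaction, with the
dispersion estimated by maximum likelihood.  Species selection (best
represented vs random) and the Q3 + 4*IQR outlier exclusion are applied
before fitting; outlier thresholds are computed once on the selected set,
jointly for the occurrence and interest variables, in a single pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierRule",
    "GlmFit",
    "select_species",
    "outlier_threshold",
    "remove_outliers",
    "fit_nb_glm",
    "residual_diagnostics",
]

TERMS = ("intercept", "interest", "research", "interaction")


@dataclass(frozen=True)
class OutlierRule:
    """Exclusion above Q3 + multiplier * IQR (linear-interpolation quartiles)."""

    multiplier: float = 4.0


def select_species(
    table: pd.DataFrame,
    mode: str,
    n_target: int = 1000,
    seed: int | None = None,
    count_col: str = "occurrences",
) -> pd.DataFrame:
    """Select species rows for modelling.

    ``mode='best'`` takes the top ``n_target`` by occurrence count with a
    deterministic tie-break (count descending, then species name
    ascending); ``mode='random'`` draws uniformly without replacement.
    When fewer than ``n_target`` species exist, all are taken.
    """
    if mode not in ("best", "random"):
        raise ValueError("mode must be 'best' or 'random'")
    if len(table) <= n_target:
        return table.copy()
    if mode == "best":
        ordered = table.sort_values(
            [count_col, "species"], ascending=[False, True], kind="mergesort"
        )
        return ordered.head(n_target).copy()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(table), size=n_target, replace=False)
    return table.iloc[np.sort(idx)].copy()


def outlier_threshold(values: np.ndarray, rule: OutlierRule = OutlierRule()) -> float:
    """Q3 + multiplier * IQR with linear-interpolation quantiles."""
    q1, q3 = np.quantile(np.asarray(values, dtype=float), [0.25, 0.75])
    return float(q3 + rule.multiplier * (q3 - q1))


def remove_outliers(
    table: pd.DataFrame,
    rule: OutlierRule = OutlierRule(),
    count_col: str = "occurrences",
    interest_col: str = "interest_keyword",
) -> pd.DataFrame:
    """Drop species whose occurrence or interest count exceeds its threshold.

    Thresholds come from the selected set before any exclusion; the rule is
    applied in one pass (no re-iteration), and a species is dropped when
    EITHER variable strictly exceeds its own threshold.
    """
    if not np.isfinite(rule.multiplier):
        return table.copy()
    t_occ = outlier_threshold(table[count_col].to_numpy(), rule)
    t_int = outlier_threshold(table[interest_col].to_numpy(), rule)
    keep = (table[count_col] <= t_occ) & (table[interest_col] <= t_int)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("outlier rule removed %d of %d species", dropped, len(table))
    return table[keep].copy()


@dataclass
class GlmFit:
    """One fitted negative-binomial model."""

    n_species_used: int
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    signs: dict[str, str]
    dispersion: float  # k such that var = m + m^2/k
    alpha: float  # statsmodels NB2 alpha = 1/k
    converged: bool
    fitted: np.ndarray = field(repr=False, default=None)
    deviance_residuals: np.ndarray = field(repr=False, default=None)
    conf_int: dict[str, tuple[float, float]] = field(default_factory=dict)

    def significant(self, term: str, threshold: float = 0.05) -> bool:
        return self.pvalues[term] < threshold


def _design(
    table: pd.DataFrame, interest_col: str, transform: str
) -> tuple[np.ndarray, np.ndarray]:
    if transform == "log1p":
        t = np.log1p
    elif transform == "identity":
        t = np.asarray
    else:
        raise ValueError("transform must be 'log1p' or 'identity'")
    x_i = t(table[interest_col].to_numpy(dtype=float))
    x_r = t(table["research"].to_numpy(dtype=float))
    X = np.column_stack([np.ones(len(table)), x_i, x_r, x_i * x_r])
    y = table["occurrences"].to_numpy(dtype=float)
    return y, X


def fit_nb_glm(
    table: pd.DataFrame,
    interest_col: str = "interest_keyword",
    transform: str = "log1p",
    min_species: int = 30,
) -> GlmFit:
    """Fit the NB2 regression with Wald per-coefficient p-values.

    Requires at least ``min_species`` retained species.  Non-convergence
    is flagged on the returned fit, never silently ignored.
    """
    if len(table) < min_species:
        raise ValueError(f"need at least {min_species} species, got {len(table)}")
    y, X = _design(table, interest_col, transform)
    if y.var() <= y.mean():
        logger.info("response variance <= mean; overdispersion assumption weak")
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    with np.errstate(all="ignore"):
        try:
            res = model.fit(disp=0, maxiter=500, method="bfgs")
        except Exception:  # pragma: no cover - optimizer pathologies
            res = model.fit(disp=0, maxiter=500, method="nm")
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        logger.warning("NB fit did not converge (n=%d)", len(table))

    params = np.asarray(res.params)
    pvals = np.asarray(res.pvalues)
    alpha = float(params[-1])
    ci = np.asarray(res.conf_int())
    coefficients = {t: float(params[i]) for i, t in enumerate(TERMS)}
    pvalues = {t: float(pvals[i]) for i, t in enumerate(TERMS)}
    signs = {t: ("+" if coefficients[t] >= 0 else "-") for t in TERMS}
    conf = {t: (float(ci[i, 0]), float(ci[i, 1])) for i, t in enumerate(TERMS)}

    mu = np.exp(X @ params[:-1])
    resid = _nb_deviance_residuals(y, mu, alpha)
    return GlmFit(
        n_species_used=len(table),
        coefficients=coefficients,
        pvalues=pvalues,
        signs=signs,
        dispersion=float(1.0 / alpha) if alpha > 0 else float("inf"),
        alpha=alpha,
        converged=converged,
        fitted=mu,
        deviance_residuals=resid,
        conf_int=conf,
    )


def _nb_deviance_residuals(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    alpha = max(alpha, 1e-12)
    with np.errstate(all="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        term2 = (y + 1.0 / alpha) * np.log((1.0 + alpha * y) / (1.0 + alpha * mu))
        dev = 2.0 * (term1 - term2)
    dev = np.maximum(dev, 0.0)
    return np.sign(y - mu) * np.sqrt(dev)


def residual_diagnostics(fit: GlmFit) -> dict:
    """Residual-vs-fitted payload with a linear trend flag.

    The trend statistic is the slope of |deviance residual| on the fitted
    mean (simple regression) with its p-value, for automated screening of
    residual heterogeneity.
    """
    fitted = fit.fitted
    resid = fit.deviance_residuals
    slope, intercept, r, p, se = sps.linregress(fitted, np.abs(resid))
    return {
        "fitted": fitted,
        "residuals": resid,
        "trend_slope": float(slope),
        "trend_pvalue": float(p),
        "n": len(fitted),
    }
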