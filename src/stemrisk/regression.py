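"""Cross-site trend analyses of the mutagen-attributable cancer fraction.

Given per-site conditional probabilities Pr_M (that a cancer carries at
least one mutagen-induced mutation, computed from the exact stem-lineage
recurrence), this module fits the ordinary-least-squares trends used to
probe whether Pr_M tracks tissue proliferative activity or measured
mutagen-specific risk:

* Pr_M on log10(cumulative stem-cell divisions),
* radiation-exposure-induced cancer risk (REIC) on Pr_M,
* smoking-associated mortality-rate difference on Pr_M.

Each fit reports the slope F-test p-value, R^2, Pearson and Spearman
correlations, and the fit repeated after a single-pass removal of
high-leverage sites (Cook's distance above 4 / (n - p - 1), p = 2 fitted
parameters).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import wu

__all__ = [
    "SiteObservation",
    "TrendResult",
    "fit_trend",
    "compute_pr_m",
    "run_paper_regressions",
]

logger = logging.getLogger(__name__)

#: number of fitted parameters (intercept + slope) in every trend model
_N_PARAMS = 2


@dataclass(frozen=True)
class SiteObservation:
    """One cancer site's model output and external covariates.

    Any covariate may be missing (None); sites with a missing covariate are
    dropped from the corresponding regression only.
    """

    site: str
    pr_m: float
    log10_divisions: Optional[float] = None
    reic: Optional[float] = None
    sm_diff: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pr_m <= 1.0 or math.isnan(self.pr_m):
            raise ValueError(f"pr_m out of [0, 1] for {self.site!r}: {self.pr_m!r}")
        if self.log10_divisions is not None and not math.isfinite(self.log10_divisions):
            raise ValueError(f"log10_divisions not finite for {self.site!r}")


@dataclass(frozen=True)
class TrendResult:
    """OLS trend fit with influence diagnostics."""

    intercept: float
    slope: float
    p_trend: float
    r_squared: float
    pearson_r: float
    spearman_rho: float
    n: int
    removed: tuple = ()
    p_trend_after_removal: float = float("nan")
    slope_se: float = float("nan")


def _ols(y: np.ndarray, x: np.ndarray):
    model = sm.OLS(y, sm.add_constant(x))
    return model.fit()


def fit_trend(
    y: Sequence[float],
    x: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> TrendResult:
    """Fit y = a0 + a1 x by OLS with an F-test for the slope.

    High-leverage points (Cook's distance > 4 / (n - p - 1)) are removed in
    a single pass and the model refit once; ``removed`` lists their labels
    (or indices).  Requires at least three complete pairs and non-degenerate
    x.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D arrays of equal length")
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if labels is None:
        labels = [str(i) for i in np.nonzero(keep)[0]]
    else:
        labels = [l for l, k in zip(labels, keep) if k]
    n = len(y)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0.0:
        raise ValueError("independent variable has zero variance")

    res = _ols(y, x)
    pearson_r, _ = stats.pearsonr(x, y)
    spearman_rho, _ = stats.spearmanr(x, y)

    cooks = res.get_influence().cooks_distance[0]
    threshold = 4.0 / (n - _N_PARAMS - 1) if n > _N_PARAMS + 1 else math.inf
    flagged = np.nonzero(cooks > threshold)[0]
    removed = tuple(labels[i] for i in flagged)

    p_after = float("nan")
    if flagged.size:
        keep2 = np.setdiff1d(np.arange(n), flagged)
        if keep2.size >= 3 and np.ptp(x[keep2]) > 0.0:
            p_after = float(_ols(y[keep2], x[keep2]).f_pvalue)
        else:
            logger.warning("too few points after Cook's-distance removal; p undefined")
    else:
        p_after = float(res.f_pvalue)

    return TrendResult(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        p_trend=float(res.f_pvalue),
        r_squared=float(res.rsquared),
        pearson_r=float(pearson_r),
        spearman_rho=float(spearman_rho),
        n=n,
        removed=removed,
        p_trend_after_removal=p_after,
        slope_se=float(res.bse[1]),
    )


def compute_pr_m(
    site_table: pd.DataFrame,
    k: int,
    u_s: float,
    u_m: float,
    onset_fraction: float = 1.0 / 3.0,
) -> pd.Series:
    """Pr_M per site from the exact recurrence, indexed like ``site_table``.

    ``site_table`` needs integer columns ``n1`` and ``n2``.
    """
    out = []
    for _, row in site_table.iterrows():
        config = wu.WuConfig(int(row["n1"]), int(row["n2"]), k)
        schedule = wu.RateSchedule.constant(config.n_divisions, u_s, u_m, onset_fraction)
        out.append(wu.pr_mutagen(config, schedule))
    return pd.Series(out, index=site_table.index, name="pr_m")


_OUTCOMES = {
    # regression name -> (dependent attr, independent attr)
    "pr_m_vs_log10_divisions": ("pr_m", "log10_divisions"),
    "reic_vs_pr_m": ("reic", "pr_m"),
    "sm_diff_vs_pr_m": ("sm_diff", "pr_m"),
}


def run_paper_regressions(observations: Sequence[SiteObservation]) -> pd.DataFrame:
    """All three cross-site trend fits, one row per regression.

    Regressions whose covariate is missing for every site are skipped with
    a logged warning; sites missing a covariate are dropped from that
    regression only.
    """
    rows = []
    for name, (dep, ind) in _OUTCOMES.items():
        y, x, labels = [], [], []
        for obs in observations:
            yv = getattr(obs, dep)
            xv = getattr(obs, ind)
            if yv is None or xv is None:
                continue
            y.append(yv)
            x.append(xv)
            labels.append(obs.site)
        if len(y) < 3:
            logger.warning("skipping %s: only %d complete sites", name, len(y))
            continue
        try:
            result = fit_trend(y, x, labels)
        except ValueError as exc:
            logger.warning("skipping %s: %s", name, exc)
            continue
        rows.append(
            {
                "regression": name,
                "n": result.n,
                "intercept": result.intercept,
                "slope": result.slope,
                "p_trend": result.p_trend,
                "p_trend_after_removal": result.p_trend_after_removal,
                "r_squared": result.r_squared,
                "pearson_r": result.pearson_r,
                "spearman_rho": result.spearman_rho,
                "removed": ";".join(result.removed),
            }
        )
    return pd.DataFrame(rows)
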