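"""Shared statistical primitives: multiple-testing corrections and the
empirical-Bayes variance squeeze used by the moderated methylation tests."""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down FWER adjustment; NaNs propagate."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="holm")[1]
    return out


def bonferroni_adjust(p: np.ndarray) -> np.ndarray:
    return np.minimum(np.asarray(p, dtype=float) * np.isfinite(p).size, 1.0)


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction on a 2x2 table.

    Returns (statistic, p).  A zero margin leaves the statistic
    undefined; (nan, nan) is returned.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return float("nan"), float("nan")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed sample variances.

    Fits ``s2 ~ s0^2 * F(df, df0)`` via the method of moments on
    log-variances, returning (df0, s0^2); df0 = inf when the observed
    spread is no larger than expected under a single common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) if len(e) > 1 else 0.0
    e_var -= special.polygamma(1, df / 2.0)
    if e_var > 0:
        df0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = np.exp(e_mean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0))
    else:
        df0 = np.inf
        s0_sq = np.exp(e_mean)
    return float(df0), float(s0_sq)


def squeeze_var(
    s2: np.ndarray, df: float | np.ndarray, prior_df: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Shrink per-feature variances toward a common prior.

    Returns (posterior variances, prior df, prior variance).  ``df`` may
    vary per feature (the prior is then moment-fitted at the median df).
    With ``prior_df`` given, only the prior variance is estimated; with
    prior_df == 0 the variances are returned unshrunk.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    df_fit = float(np.median(df)) if df.ndim else float(df)
    df0, s0_sq = fit_f_dist(s2, df_fit)
    if prior_df is not None:
        df0 = prior_df
    if np.isinf(df0):
        post = np.full_like(s2, s0_sq)
    elif df0 == 0:
        post = s2.copy()
    else:
        post = (df0 * s0_sq + df * s2) / (df0 + df)
    return post, float(df0), float(s0_sq)
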