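"""Differential expression across brain development.

The study design crosses four ages (1, 20, 65 dph, adult) with sex, three
pooled replicates per cell.  Counts are TMM-normalised, low-expression
genes removed, and every gene is fitted with a negative-binomial GLM on
the 8-level age x sex group factor.  Testing is stagewise: an omnibus
likelihood-ratio test screens genes over all five contrasts of interest
(the average age effect of 20 dph/65 dph/adult vs 1 dph, and the M-F sex
effect at each age) with BH FDR control, and per-contrast post-hoc tests
are then confirmed within each screened gene under family-wise error
control (Holm).

Developmental trajectories are additionally classified into the 27
H/E/L pattern codes: a gene's expression at 20 dph, 65 dph and adult is
called Higher/Lower than at 1 dph when the group-mean log-cpm differs by
more than 1.65 within-group standard deviations (one-sided normal tail
of about 5%), else Equal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._nbglm import dispersion_mle, fit_nb_glm
from ._stats import bh_adjust, holm_adjust
from .core import AGES, SEXES, ExpressionMatrix, SampleDesign

GROUPS = tuple(f"{age}.{sex}" for age in AGES for sex in SEXES)
CONTRAST_NAMES = ("age", "sex_d1", "sex_d20", "sex_d65", "sex_adult")


# ---------------------------------------------------------------------------
# normalisation


def _quantile_factor(counts: np.ndarray, lib_size: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib_size


def _tmm_pair(
    obs: np.ndarray,
    lib_obs: float,
    ref: np.ndarray,
    lib_ref: float,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    precision_weights: bool = True,
) -> float:
    """TMM scaling factor of one sample against the reference.

    The gene-wise log-ratios M are trimmed 30% from each tail, the
    average log-abundances A 5% from each tail, and the surviving M
    values averaged with inverse delta-method variance weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        pr_obs = obs / lib_obs
        pr_ref = ref / lib_ref
        m = np.log2(pr_obs / pr_ref)
        a = 0.5 * (np.log2(pr_obs) + np.log2(pr_ref))
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    ok = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[ok], a[ok], v[ok]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    if precision_weights:
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(m[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def normalize_counts(x: ExpressionMatrix) -> ExpressionMatrix:
    """Compute TMM normalisation factors (geometric mean rescaled to 1).

    The reference sample is the one whose library-size-scaled upper
    quartile is closest to the mean upper quartile across samples.
    """
    counts = x.counts.to_numpy(dtype=float)
    lib = x.lib_size.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    f75 = _quantile_factor(counts, lib)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(counts[:, j], lib[j], counts[:, ref_idx], lib[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return ExpressionMatrix(
        counts=x.counts,
        lib_size=x.lib_size,
        norm_factor=pd.Series(factors, index=x.counts.columns),
    )


def log_cpm(x: ExpressionMatrix, prior_count: float = 2.0) -> pd.DataFrame:
    """log2 counts per million with a library-size-scaled prior count.

    The prior stabilises low counts: each sample's prior is scaled by its
    effective library size relative to the mean, and the library size is
    augmented by twice the scaled prior before the cpm is formed.
    """
    lib = x.effective_lib_size.to_numpy(dtype=float)
    prior_scaled = lib / lib.mean() * prior_count
    denom = lib + 2.0 * prior_scaled
    arr = (x.counts.to_numpy(dtype=float) + prior_scaled[None, :]) / denom[None, :] * 1e6
    return pd.DataFrame(np.log2(arr), index=x.counts.index, columns=x.counts.columns)


def filter_low_expression(
    x: ExpressionMatrix, min_cpm: float = 1.0, max_low_samples: int = 21
) -> ExpressionMatrix:
    """Drop genes with cpm below ``min_cpm`` in more than ``max_low_samples``
    samples (default: removed when cpm < 1 in 22 or more of 24 samples)."""
    cpm = x.cpm(use_norm_factors=False)
    n_low = (cpm < min_cpm).sum(axis=1)
    keep = n_low <= max_low_samples
    return ExpressionMatrix(
        counts=x.counts.loc[keep],
        lib_size=x.lib_size,
        norm_factor=x.norm_factor,
    )


# ---------------------------------------------------------------------------
# stagewise differential expression


def group_design(design: SampleDesign) -> tuple[np.ndarray, list[str]]:
    """Indicator (samples x groups) design matrix on the age x sex factor."""
    labels = design.group_labels().to_numpy()
    groups = [g for g in GROUPS if g in set(labels)]
    X = np.column_stack([(labels == g).astype(float) for g in groups])
    return X, groups


def contrast_matrix(groups: list[str]) -> tuple[np.ndarray, list[str]]:
    """The five tested contrasts on the group-mean parameterisation.

    Age: mean(d20, d65, adult) - d1, averaged over sexes.  Sex: M - F at
    each age separately.
    """
    idx = {g: i for i, g in enumerate(groups)}
    rows, names = [], []
    age_row = np.zeros(len(groups))
    for sex in SEXES:
        age_row[idx[f"d1.{sex}"]] -= 1.0 / 2.0
        for age in ("d20", "d65", "adult"):
            age_row[idx[f"{age}.{sex}"]] += 1.0 / 6.0
    rows.append(age_row)
    names.append("age")
    for age in AGES:
        row = np.zeros(len(groups))
        row[idx[f"{age}.M"]] = 1.0
        row[idx[f"{age}.F"]] = -1.0
        rows.append(row)
        names.append(f"sex_{age}")
    return np.vstack(rows), names


@dataclass
class DEResult:
    """Per-gene stagewise differential-expression results.

    ``table`` columns: log2 fold changes per contrast, the omnibus LRT
    p-value and BH FDR, within-gene Holm-adjusted stage-2 p-values (NaN
    for genes failing the screen), the shrunk dispersion, and fit flags.
    """

    table: pd.DataFrame
    screen_fdr: float
    contrasts: list[str] = field(default_factory=lambda: list(CONTRAST_NAMES))

    def screened(self) -> pd.Index:
        return self.table.index[self.table["omnibus_fdr"] < self.screen_fdr]

    def significant(self, contrast: str, alpha: float = 0.05) -> pd.Index:
        col = f"stage2_p_{contrast}"
        mask = self.table[col] < alpha
        return self.table.index[mask.fillna(False)]

    def age_de_genes(self, alpha: float = 0.05) -> pd.Index:
        return self.significant("age", alpha)

    def any_de_genes(self, alpha: float = 0.05) -> pd.Index:
        cols = [f"stage2_p_{c}" for c in self.contrasts]
        mask = (self.table[cols] < alpha).any(axis=1)
        return self.table.index[mask]


def estimate_dispersions(
    x: ExpressionMatrix,
    design: SampleDesign,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-gene NB dispersions shrunk toward a smoothed mean-dispersion trend.

    Per-gene adjusted-profile-likelihood MLEs are computed first, a
    lowess curve of log-dispersion against average log-cpm provides the
    trend, and each gene's log-dispersion is averaged with the trend
    using ``prior_df`` pseudo-degrees of freedom against the residual
    degrees of freedom.  prior_df -> inf returns the trend; prior_df = 0
    the raw MLEs.
    """
    X, groups = group_design(design)
    offset = np.log(x.effective_lib_size.to_numpy(dtype=float))
    counts = x.counts.to_numpy(dtype=float)
    n, p = X.shape
    resid_df = n - p
    mle = np.array([dispersion_mle(counts[i], X, offset) for i in range(counts.shape[0])])
    ave_logcpm = log_cpm(x).mean(axis=1).to_numpy()
    log_mle = np.log(np.maximum(mle, 1e-8))
    if len(mle) >= 10:
        sm = lowess(log_mle, ave_logcpm, frac=0.5, it=3, return_sorted=False)
        trend = np.exp(sm)
    else:
        trend = np.full_like(mle, np.exp(log_mle.mean()))
    trend = np.maximum(trend, 1e-6)
    if np.isinf(prior_df):
        shrunk = trend.copy()
    else:
        w = prior_df / (prior_df + resid_df)
        shrunk = np.exp(w * np.log(trend) + (1 - w) * log_mle)
    return pd.DataFrame(
        {"dispersion_mle": mle, "dispersion_trend": trend, "dispersion": shrunk},
        index=x.counts.index,
    )


def fit_stagewise_de(
    x: ExpressionMatrix,
    design: SampleDesign,
    screen_fdr: float = 0.05,
    prior_df: float = 10.0,
    dispersions: pd.Series | None = None,
) -> DEResult:
    """Stagewise omnibus + post-hoc differential expression testing.

    Stage 1 screens genes with a 5-df likelihood-ratio test of all
    contrasts jointly (BH FDR across genes); stage 2 reports Wald tests
    per contrast, Holm-adjusted within each screened gene so the
    family-wise error is controlled per post-hoc family.
    """
    X, groups = group_design(design)
    C, names = contrast_matrix(groups)
    from scipy.linalg import null_space

    N = null_space(C)  # basis of {beta : C beta = 0}
    X_reduced = X @ N
    offset = np.log(x.effective_lib_size.to_numpy(dtype=float))
    counts = x.counts.to_numpy(dtype=float)
    if dispersions is None:
        disp = estimate_dispersions(x, design, prior_df=prior_df)["dispersion"].to_numpy()
    else:
        disp = dispersions.reindex(x.counts.index).to_numpy(dtype=float)

    n_genes = counts.shape[0]
    logfc = np.zeros((n_genes, len(names)))
    wald_p = np.zeros((n_genes, len(names)))
    omnibus_p = np.zeros(n_genes)
    flags = np.zeros(n_genes, dtype=bool)
    for i in range(n_genes):
        y = counts[i]
        full = fit_nb_glm(y, X, offset, disp[i])
        red = fit_nb_glm(y, X_reduced, offset, disp[i])
        lr = max(2.0 * (full.llf - red.llf), 0.0)
        omnibus_p[i] = stats.chi2.sf(lr, C.shape[0])
        est = C @ full.beta
        var = np.einsum("ij,jk,ik->i", C, full.cov, C)
        z = est / np.sqrt(np.maximum(var, 1e-300))
        wald_p[i] = 2.0 * stats.norm.sf(np.abs(z))
        logfc[i] = est / np.log(2.0)
        flags[i] = full.stabilized or red.stabilized

    omnibus_fdr = bh_adjust(omnibus_p)
    stage2 = np.full_like(wald_p, np.nan)
    screened = omnibus_fdr < screen_fdr
    for i in np.where(screened)[0]:
        stage2[i] = holm_adjust(wald_p[i])

    table = pd.DataFrame(index=x.counts.index)
    for j, name in enumerate(names):
        table[f"logFC_{name}"] = logfc[:, j]
    table["omnibus_p"] = omnibus_p
    table["omnibus_fdr"] = omnibus_fdr
    for j, name in enumerate(names):
        table[f"stage2_p_{name}"] = stage2[:, j]
    table["dispersion"] = disp
    table["stabilized"] = flags
    return DEResult(table=table, screen_fdr=screen_fdr, contrasts=names)


# ---------------------------------------------------------------------------
# developmental pattern classification


@dataclass(frozen=True)
class PatternConfig:
    threshold_sd: float = 1.65  # one-sided normal tail of about 5%
    reference_age: str = "d1"
    pool_sexes: bool = True

    def __post_init__(self):
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")


def pattern_alphabet() -> tuple[list[str], list[str]]:
    """All 27 H/E/L trajectory codes and the 12 reported pattern groups."""
    alphabet = ["".join(p) for p in itertools.product("LEH", repeat=3)]
    selected = [
        "LEE", "ELE", "EEL", "HEE", "EHE", "EEH",  # change at one time point
        "LLE", "HHE",                              # at 20 and 65 dph
        "LLL", "HHH",                              # from 20 dph onwards
        "ELL", "EHH",                              # from 65 dph onwards
    ]
    return alphabet, selected


@dataclass
class PatternAssignment:
    table: pd.DataFrame  # index gene_id; pattern, selected, sd, flagged

    def genes_with_pattern(self, code: str) -> pd.Index:
        return self.table.index[self.table["pattern"] == code]


def classify_patterns(
    logcpm: pd.DataFrame,
    design: SampleDesign,
    cfg: PatternConfig = PatternConfig(),
) -> PatternAssignment:
    """Classify each gene's trajectory relative to 1 dph.

    The per-gene noise scale is the pooled within-group (age x sex)
    standard deviation of log-cpm.  At 20 dph, 65 dph and adult the
    sexes-pooled mean is compared with the 1 dph mean: Higher (H) or
    Lower (L) when the difference exceeds ``threshold_sd`` noise SDs,
    else Equal (E).  Constant genes (zero SD) are labelled EEE and
    flagged.
    """
    labels = design.group_labels().reindex(logcpm.columns)
    arr = logcpm.to_numpy(dtype=float)
    n, _ = arr.shape
    ss_within = np.zeros(n)
    n_obs = 0
    n_groups = 0
    for g, cols in pd.Series(range(len(labels)), index=labels.values).groupby(level=0):
        j = cols.to_numpy()
        if len(j) < 2:
            raise ValueError(f"group {g} has fewer than 2 replicates")
        sub = arr[:, j]
        ss_within += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_obs += len(j)
        n_groups += 1
    sd = np.sqrt(ss_within / (n_obs - n_groups))

    sample_meta = design.table.set_index("sample_id").reindex(logcpm.columns)
    age_of = sample_meta["age"]
    if cfg.pool_sexes:
        keep = np.ones(len(logcpm.columns), dtype=bool)
    else:
        keep = (sample_meta["sex"] == "M").to_numpy()  # classify on males only
    means = {
        age: arr[:, ((age_of == age).to_numpy() & keep)].mean(axis=1) for age in AGES
    }

    ref = means[cfg.reference_age]
    thr = cfg.threshold_sd * sd
    codes = np.empty(n, dtype=object)
    flagged = sd == 0
    letters = []
    for age in ("d20", "d65", "adult"):
        diff = means[age] - ref
        lev = np.where(diff > thr, "H", np.where(diff < -thr, "L", "E"))
        lev = np.where(flagged, "E", lev)
        letters.append(lev)
    codes = np.char.add(np.char.add(letters[0], letters[1]), letters[2])
    _, selected = pattern_alphabet()
    table = pd.DataFrame(
        {
            "pattern": codes,
            "selected": np.isin(codes, selected),
            "sd": sd,
            "flagged": flagged,
        },
        index=logcpm.index,
    )
    return PatternAssignment(table)
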