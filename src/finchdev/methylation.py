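"""Differential DNA methylation from (ox)RRBS cytosine counts.

Per-cytosine methylation fractions beta = meth/total are transformed to
M-values, M = log2((beta + a) / (1 - beta + a)) with offset a = 0.01,
which behave better under linear modelling than the bounded beta scale.
Sites are quality-filtered (mean coverage >= 5x per sample and >= 6
methylated reads summed over samples), fitted per cytosine by ordinary
least squares on the same 8-level age x sex group factor as expression,
and the residual variances are shrunk by empirical Bayes toward a common
prior, giving moderated t/F statistics with augmented degrees of
freedom.  Hydroxymethylation (5hmC) is estimated descriptively by
subtracting oxRRBS (5mC only) from RRBS (5mC + 5hmC) methylation
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, holm_adjust, squeeze_var
from .core import GeneAnnotation, MethylationMatrix, SampleDesign
from .expression import CONTRAST_NAMES, contrast_matrix, group_design


@dataclass(frozen=True)
class MethylConfig:
    alpha: float = 0.01  # M-value offset
    min_mean_coverage: float = 5.0
    min_total_meth: int = 6
    screen_fdr: float = 0.05
    prior_df: float | None = None  # None: estimate from the data
    min_samples: int | None = None  # None: require coverage in all samples

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_up: int = 2000
    promoter_down: int = 500

    def __post_init__(self):
        if self.promoter_up < 0 or self.promoter_down < 0:
            raise ValueError("promoter extents must be non-negative")


# ---------------------------------------------------------------------------
# beta / M values


def compute_m_values(
    m: MethylationMatrix, cfg: MethylConfig = MethylConfig()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site, per-sample beta and M matrices.

    Entries with zero total coverage are missing (NaN), never 0/0.
    """
    meth = m.meth.to_numpy(dtype=float)
    total = m.total.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(total > 0, meth / np.where(total > 0, total, 1), np.nan)
    mval = np.log2((beta + cfg.alpha) / (1.0 - beta + cfg.alpha))
    beta_df = pd.DataFrame(beta, index=m.sites, columns=m.meth.columns)
    m_df = pd.DataFrame(mval, index=m.sites, columns=m.meth.columns)
    return beta_df, m_df


def filter_cytosines(m: MethylationMatrix, cfg: MethylConfig = MethylConfig()) -> MethylationMatrix:
    """Quality filter: retain sites with mean total coverage >= 5x per
    sample and >= 6 methylated reads summed over all samples."""
    mean_cov = m.total.mean(axis=1)
    sum_meth = m.meth.sum(axis=1)
    keep = (mean_cov >= cfg.min_mean_coverage) & (sum_meth >= cfg.min_total_meth)
    return m.subset_sites(keep.to_numpy())


# ---------------------------------------------------------------------------
# moderated differential methylation


@dataclass
class DMResult:
    """Per-cytosine moderated test results.

    ``table`` holds group-mean betas, per-contrast log2FC on the M scale,
    moderated t p-values, the omnibus moderated F with BH FDR, and
    stage-2 Holm-adjusted per-contrast p-values for screened sites.
    """

    table: pd.DataFrame
    m_values: pd.DataFrame
    screen_fdr: float
    prior_df: float
    prior_var: float
    contrasts: list[str] = field(default_factory=lambda: list(CONTRAST_NAMES))

    def significant_sites(self, contrast: str | None = None, alpha: float = 0.05) -> pd.Index:
        if contrast is None:
            return self.table.index[self.table["omnibus_fdr"] < self.screen_fdr]
        mask = (self.table[f"stage2_p_{contrast}"] < alpha).fillna(False)
        return self.table.index[mask]

    def subset_fdr(self, subset: pd.Index | np.ndarray) -> pd.Series:
        """Recompute BH q-values on a subset of sites (e.g. CpGs falling
        in differentially expressed genes)."""
        p = self.table.loc[subset, "omnibus_p"]
        return pd.Series(bh_adjust(p.to_numpy()), index=p.index)


def fit_moderated_dm(
    m: MethylationMatrix,
    design: SampleDesign,
    cfg: MethylConfig = MethylConfig(),
) -> DMResult:
    """Moderated-variance differential methylation on M-values.

    Complete-case per site: sites covered in fewer than ``min_samples``
    samples (default: all) are dropped.  Each site is fitted by OLS on
    the group factor; residual variances are squeezed toward an
    inverse-gamma prior fitted by moments on the log variances, and the
    omnibus moderated F over the five contrasts is BH-adjusted across
    sites.  Per-contrast moderated t tests are Holm-adjusted within each
    screened site.
    """
    beta_df, m_df = compute_m_values(m, cfg)
    min_samples = cfg.min_samples if cfg.min_samples is not None else design.n_samples
    covered = m_df.notna().sum(axis=1) >= min_samples
    m_df = m_df.loc[covered.to_numpy()]
    beta_df = beta_df.loc[covered.to_numpy()]
    if len(m_df) == 0:
        raise ValueError("no sites covered in the required number of samples")

    X, groups = group_design(design)
    C, names = contrast_matrix(groups)
    Y = m_df.to_numpy(dtype=float)
    n, p = X.shape
    n_con = C.shape[0]
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")
    n_sites = Y.shape[0]

    B = np.full((n_sites, p), np.nan)
    s2 = np.full(n_sites, np.nan)
    df_resid = np.full(n_sites, np.nan)
    cvar = np.full((n_sites, n_con), np.nan)  # per-contrast unit variances
    quad = np.full(n_sites, np.nan)  # omnibus quadratic forms / s2

    complete = ~np.isnan(Y).any(axis=1)
    XtX_inv = np.linalg.inv(X.T @ X)
    proj = XtX_inv @ X.T
    Bc = Y[complete] @ proj.T
    resid = Y[complete] - Bc @ X.T
    B[complete] = Bc
    df_resid[complete] = n - p
    s2[complete] = (resid**2).sum(axis=1) / (n - p)
    cvar[complete] = np.einsum("ij,jk,ik->i", C, XtX_inv, C)[None, :]
    Vinv_c = np.linalg.inv(C @ XtX_inv @ C.T)
    est_c = Bc @ C.T
    quad[complete] = np.einsum("ij,jk,ik->i", est_c, Vinv_c, est_c)

    # complete-case per site: incomplete sites are fitted on their covered
    # samples, provided every group is still represented
    keep_mask = complete.copy()
    for i in np.where(~complete)[0]:
        obs = ~np.isnan(Y[i])
        Xs = X[obs]
        if (Xs.sum(axis=0) == 0).any() or obs.sum() - p <= 0:
            continue
        XtX_inv_s = np.linalg.inv(Xs.T @ Xs)
        b = XtX_inv_s @ Xs.T @ Y[i, obs]
        r = Y[i, obs] - Xs @ b
        B[i] = b
        df_resid[i] = obs.sum() - p
        s2[i] = (r**2).sum() / df_resid[i]
        cvar[i] = np.einsum("ij,jk,ik->i", C, XtX_inv_s, C)
        est_i = C @ b
        quad[i] = est_i @ np.linalg.solve(C @ XtX_inv_s @ C.T, est_i)
        keep_mask[i] = True

    m_df = m_df.loc[keep_mask]
    beta_df = beta_df.loc[keep_mask]
    B, s2, df_resid = B[keep_mask], s2[keep_mask], df_resid[keep_mask]
    cvar, quad = cvar[keep_mask], quad[keep_mask]

    s2_post, df0, s0_sq = squeeze_var(s2, df_resid, prior_df=cfg.prior_df)
    df_total = df_resid + (df0 if np.isfinite(df0) else 1e12)

    est = B @ C.T  # sites x contrasts
    tstat = est / np.sqrt(s2_post[:, None] * cvar)
    t_p = 2.0 * stats.t.sf(np.abs(tstat), df_total[:, None])

    F = quad / (n_con * s2_post)
    omnibus_p = stats.f.sf(F, n_con, df_total)
    omnibus_fdr = bh_adjust(omnibus_p)

    stage2 = np.full_like(t_p, np.nan)
    for i in np.where(omnibus_fdr < cfg.screen_fdr)[0]:
        stage2[i] = holm_adjust(t_p[i])

    table = pd.DataFrame(index=m_df.index)
    labels = design.group_labels().reindex(m_df.columns)
    beta_arr = beta_df.to_numpy()
    with np.errstate(invalid="ignore"):
        for g in groups:
            cols = (labels == g).to_numpy()
            table[f"beta_{g}"] = np.nanmean(beta_arr[:, cols], axis=1)
    table["beta_mean"] = beta_df.mean(axis=1)
    for j, name in enumerate(names):
        table[f"logFC_{name}"] = est[:, j]
    table["F"] = F
    table["omnibus_p"] = omnibus_p
    table["omnibus_fdr"] = omnibus_fdr
    for j, name in enumerate(names):
        table[f"t_p_{name}"] = t_p[:, j]
        table[f"stage2_p_{name}"] = stage2[:, j]
    table["s2"] = s2
    table["s2_post"] = s2_post
    return DMResult(
        table=table,
        m_values=m_df,
        screen_fdr=cfg.screen_fdr,
        prior_df=df0,
        prior_var=s0_sq,
        contrasts=names,
    )


# ---------------------------------------------------------------------------
# hydroxymethylation by subtraction


def subtract_hydroxymethylation(
    rrbs: MethylationMatrix, oxrrbs: MethylationMatrix
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Estimate per-site, per-sample 5hmC fractions.

    RRBS reads 5mC + 5hmC; oxRRBS reads 5mC only, so the
    hydroxymethylation fraction is h = beta_rrbs - beta_oxrrbs, computed
    on the beta scale because coverage differs between assays.  Negative
    estimates (sampling noise) are clipped to 0 and flagged.  Returns
    (h, clipped flags, number of unmatched sites dropped).
    """
    common = rrbs.sites.intersection(oxrrbs.sites)
    if len(common) == 0:
        raise ValueError("no overlapping sites between RRBS and oxRRBS")
    n_dropped = (len(rrbs.sites) - len(common)) + (len(oxrrbs.sites) - len(common))
    beta_r, _ = compute_m_values(MethylationMatrix(rrbs.meth.loc[common], rrbs.total.loc[common], "rrbs"))
    beta_o, _ = compute_m_values(
        MethylationMatrix(oxrrbs.meth.loc[common], oxrrbs.total.loc[common], "oxrrbs")
    )
    h = beta_r - beta_o
    clipped = h < 0
    h = h.clip(lower=0.0)
    return h, clipped, n_dropped


# ---------------------------------------------------------------------------
# genomic annotation of cytosines


def annotate_cytosines(
    sites: pd.MultiIndex | pd.DataFrame,
    genes: GeneAnnotation,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Assign each cytosine to promoter / genic / intergenic space.

    A site inside any promoter window ([TSS-2000, TSS+500) strand-
    oriented) is "promoter" regardless of gene bodies; otherwise a site
    inside any gene body is "genic"; otherwise "intergenic".  All
    overlapping gene ids are recorded and a unique-gene flag is set when
    exactly one gene is involved.
    """
    if isinstance(sites, pd.DataFrame):
        site_df = sites[["chrom", "pos"]].copy()
        index = sites.index
    else:
        site_df = pd.DataFrame(
            {"chrom": sites.get_level_values("chrom"), "pos": sites.get_level_values("pos")}
        )
        index = sites
    prom = genes.promoters(cfg.promoter_up, cfg.promoter_down)
    body = genes.table[["chrom", "start", "end"]]

    ann = []
    by_chrom_prom = {c: t for c, t in prom.groupby("chrom")}
    by_chrom_body = {c: t for c, t in body.groupby("chrom")}
    for chrom, pos in zip(site_df["chrom"], site_df["pos"]):
        pos = int(pos)
        pgenes: list[str] = []
        t = by_chrom_prom.get(chrom)
        if t is not None:
            hit = (t["start"] <= pos) & (pos < t["end"])
            pgenes = list(t.index[hit])
        ggenes: list[str] = []
        t = by_chrom_body.get(chrom)
        if t is not None:
            hit = (t["start"] <= pos) & (pos < t["end"])
            ggenes = list(t.index[hit])
        if pgenes:
            region = "promoter"
            gene_ids = sorted(set(pgenes) | set(ggenes))
        elif ggenes:
            region = "genic"
            gene_ids = sorted(set(ggenes))
        else:
            region = "intergenic"
            gene_ids = []
        ann.append((region, ",".join(gene_ids), len(gene_ids) == 1))
    out = pd.DataFrame(ann, columns=["region", "gene_ids", "unique_gene"], index=index)
    return out
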