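"""Integration of expression and methylation results.

Two questions: (i) how strongly is expression coupled to methylation —
answered by a linear mixed model of log-cpm on the per-(gene, sample)
mean M-value with crossed random intercepts for gene and sample; and
(ii) is differential methylation concentrated in differentially
expressed genes — answered by chi-squared tests on site counts, plus
the fraction of DE genes carrying at least one DM cytosine and the
TF vs non-TF contrast of that fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._stats import chi2_2x2
from .core import GeneAnnotation


# ---------------------------------------------------------------------------
# crossed random-intercept mixed model


@dataclass
class MixedFit:
    """REML fit of y = a + b x + u_row + v_col + e with crossed random
    intercepts u (e.g. gene) and v (e.g. sample)."""

    intercept: float
    slope: float
    slope_se: float
    slope_p: float
    var_row: float
    var_col: float
    var_resid: float
    n_obs: int
    n_rows: int
    n_cols: int
    singular: bool
    converged: bool


def fit_crossed_mixed_model(
    y: np.ndarray,
    x: np.ndarray,
    row: np.ndarray,
    col: np.ndarray,
    tol: float = 1e-8,
) -> MixedFit:
    """REML for a two-way crossed random-intercept model.

    The profiled REML criterion is optimised over the two variance
    ratios; the marginal covariance is inverted through the Woodbury
    identity on the (rows + cols)-dimensional random-effect space, so
    the fit scales with the number of levels, not observations.
    Variance components estimated at the boundary (ratio ~ 0) flag the
    fit as singular.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    row_codes, row_levels = pd.factorize(row)
    col_codes, col_levels = pd.factorize(col)
    n = len(y)
    q1, q2 = len(row_levels), len(col_levels)
    if q1 < 2 or q2 < 2:
        raise ValueError("need at least 2 row and 2 column levels")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; slope undefined")
    X = np.column_stack([np.ones(n), x])
    p = 2

    Zr = np.zeros((n, q1))
    Zr[np.arange(n), row_codes] = 1.0
    Zc = np.zeros((n, q2))
    Zc[np.arange(n), col_codes] = 1.0
    # sufficient cross-products for the Woodbury inversion
    ZtZ = np.block(
        [
            [np.diag(np.bincount(row_codes, minlength=q1)).astype(float), Zr.T @ Zc],
            [Zc.T @ Zr, np.diag(np.bincount(col_codes, minlength=q2)).astype(float)],
        ]
    )
    Z = np.concatenate([Zr, Zc], axis=1)
    Zty = Z.T @ y
    ZtX = Z.T @ X
    ZtYX = np.column_stack([Zty, ZtX])
    YX = np.column_stack([y, X])

    def reml_pieces(log_g):
        g1, g2 = np.exp(log_g)
        d = np.concatenate([np.full(q1, g1), np.full(q2, g2)])
        A = np.eye(q1 + q2) + ZtZ * d[None, :]  # I + Z'Z D
        # Woodbury: K^-1 M = M - Z D (I + Z'Z D)^-1 Z' M
        Kinv_YX = YX - (Z * d[None, :]) @ np.linalg.solve(A, ZtYX)
        Kinv_y, Kinv_X = Kinv_YX[:, 0], Kinv_YX[:, 1:]
        XtKX = X.T @ Kinv_X
        beta = np.linalg.solve(XtKX, X.T @ Kinv_y)
        r_Kinv_r = float(y @ Kinv_y - (X.T @ Kinv_y) @ beta)
        rss = max(r_Kinv_r, 1e-300)
        _, logdet_K = np.linalg.slogdet(A)
        _, logdet_XtKX = np.linalg.slogdet(XtKX)
        crit = logdet_K + (n - p) * np.log(rss) + logdet_XtKX
        return crit, beta, rss, XtKX

    def objective(log_g):
        return reml_pieces(log_g)[0]

    res = optimize.minimize(
        objective,
        x0=np.log([0.5, 0.5]),
        method="Nelder-Mead",
        options={"xatol": tol, "fatol": tol, "maxiter": 2000},
    )
    log_g = res.x
    crit, beta, rss, XtKX = reml_pieces(log_g)
    g1, g2 = np.exp(log_g)
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtKX)
    se = float(np.sqrt(cov_beta[1, 1]))
    zstat = beta[1] / se
    pval = 2.0 * stats.norm.sf(abs(zstat))
    singular = bool(min(g1, g2) < 1e-6)
    return MixedFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        slope_se=se,
        slope_p=float(pval),
        var_row=float(g1 * sigma2),
        var_col=float(g2 * sigma2),
        var_resid=float(sigma2),
        n_obs=n,
        n_rows=q1,
        n_cols=q2,
        singular=singular,
        converged=bool(res.success),
    )


@dataclass
class AssociationFit:
    region: str
    context: str
    slope: float
    se: float
    p: float
    n_genes: int
    n_samples: int
    singular: bool


def gene_sample_mean_m(
    m_values: pd.DataFrame,
    annotation: pd.DataFrame,
    region: str,
    context: str,
) -> pd.DataFrame:
    """Per-(gene, sample) mean M-value over a gene's cytosines in one
    region class, using only uniquely annotated sites."""
    ctx = m_values.index.get_level_values("context") == context
    ann = annotation.loc[m_values.index]
    keep = ctx & (ann["region"] == region).to_numpy() & ann["unique_gene"].to_numpy()
    sub = m_values.loc[keep]
    genes = ann.loc[keep, "gene_ids"].to_numpy()
    sub = sub.copy()
    sub.index = pd.Index(genes, name="gene_id")
    return sub.groupby(level=0).mean()


def methylation_expression_mixed_model(
    logcpm: pd.DataFrame,
    m_values: pd.DataFrame,
    annotation: pd.DataFrame,
    regions: tuple[str, ...] = ("promoter", "genic"),
    contexts: tuple[str, ...] = ("CpG", "CpH"),
    genes: pd.Index | None = None,
) -> list[AssociationFit]:
    """Mixed-model association between log-cpm and mean M-values.

    For each (region, context): response log-cpm per (gene, sample),
    fixed-effect covariate the mean M-value of the gene's uniquely
    annotated cytosines in that region class, random intercepts for gene
    and sample (REML).  Gene-sample cells without a covered cytosine are
    dropped.  ``genes`` restricts the analysis (e.g. to age-DE genes).
    """
    fits = []
    for region in regions:
        for context in contexts:
            mm = gene_sample_mean_m(m_values, annotation, region, context)
            common = mm.index.intersection(logcpm.index)
            if genes is not None:
                common = common.intersection(genes)
            if len(common) < 2:
                continue
            mm = mm.loc[common, logcpm.columns]
            expr = logcpm.loc[common]
            long = pd.DataFrame(
                {
                    "y": expr.to_numpy().ravel(),
                    "x": mm.to_numpy().ravel(),
                    "gene": np.repeat(common.to_numpy(), expr.shape[1]),
                    "sample": np.tile(expr.columns.to_numpy(), len(common)),
                }
            ).dropna()
            fit = fit_crossed_mixed_model(
                long["y"].to_numpy(),
                long["x"].to_numpy(),
                long["gene"].to_numpy(),
                long["sample"].to_numpy(),
            )
            fits.append(
                AssociationFit(
                    region=region,
                    context=context,
                    slope=fit.slope,
                    se=fit.slope_se,
                    p=fit.slope_p,
                    n_genes=len(common),
                    n_samples=expr.shape[1],
                    singular=fit.singular,
                )
            )
    return fits


# ---------------------------------------------------------------------------
# DM-in-DE enrichment


@dataclass
class DmDeEnrichment:
    chi2: float
    p: float
    table: np.ndarray  # (DM yes/no) x (DE gene / non-DE gene) site counts
    pct_de_genes_with_dm: dict[str, float]  # per region class
    tf_chi2: float
    tf_p: float
    tf_fraction: float  # DE TF genes with >= 1 DM site
    non_tf_fraction: float


def dm_in_de_enrichment(
    dm_table: pd.DataFrame,
    annotation: pd.DataFrame,
    de_genes: pd.Index,
    universe: pd.Index,
    genes: GeneAnnotation,
    dm_significant: pd.Index | None = None,
    unit: str = "site",
) -> DmDeEnrichment:
    """Test whether DM cytosines concentrate in DE genes.

    ``dm_table`` is the DMResult table; ``annotation`` the per-site
    region/gene assignment; ``universe`` the genes with both expression
    and methylation coverage.  The default counting unit is the
    cytosine: a 2x2 chi-squared of (site DM vs not) x (site in DE vs
    non-DE gene), over uniquely annotated promoter/genic sites in the
    universe.  Also reported: the percentage of DE genes with >= 1 DM
    site per region class, and the TF vs non-TF contrast among DE genes.
    """
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    ann = annotation.loc[dm_table.index]
    in_gene = ann["unique_gene"] & ann["region"].isin(["promoter", "genic"])
    sites = ann.loc[in_gene]
    site_gene = sites["gene_ids"]
    in_universe = site_gene.isin(universe)
    sites = sites.loc[in_universe]
    site_gene = site_gene.loc[in_universe]

    if dm_significant is None:
        dm_flag = dm_table.loc[sites.index, "omnibus_fdr"] < 0.05
    else:
        dm_flag = pd.Series(sites.index.isin(dm_significant), index=sites.index)
    de_flag = site_gene.isin(de_genes)

    if unit == "gene":
        per_gene = pd.DataFrame({"gene": site_gene, "dm": dm_flag}).groupby("gene")["dm"].any()
        dm_vec = per_gene.to_numpy()
        de_vec = per_gene.index.isin(de_genes)
    else:
        dm_vec = dm_flag.to_numpy()
        de_vec = de_flag.to_numpy()
    table = np.array(
        [
            [np.sum(dm_vec & de_vec), np.sum(dm_vec & ~de_vec)],
            [np.sum(~dm_vec & de_vec), np.sum(~dm_vec & ~de_vec)],
        ],
        dtype=float,
    )
    chi2, p = chi2_2x2(table)

    pct = {}
    for region in ("promoter", "genic"):
        reg_genes = site_gene[(sites["region"] == region).to_numpy() & dm_flag.to_numpy()]
        covered = site_gene[(sites["region"] == region).to_numpy()]
        de_covered = pd.Index(covered.unique()).intersection(de_genes)
        if len(de_covered):
            n_with = len(pd.Index(reg_genes.unique()).intersection(de_genes))
            pct[region] = 100.0 * n_with / len(de_covered)
        else:
            pct[region] = float("nan")

    # TF vs non-TF: among DE genes with methylation coverage, does the
    # >=1-DM-site fraction differ by transcription-factor status?
    gene_dm = pd.DataFrame({"gene": site_gene, "dm": dm_flag.to_numpy()}).groupby("gene")["dm"].any()
    de_covered_genes = gene_dm.index.intersection(de_genes)
    is_tf = genes.table["is_tf"].reindex(de_covered_genes).fillna(False).astype(bool)
    has_dm = gene_dm.loc[de_covered_genes]
    tf_table = np.array(
        [
            [np.sum(has_dm & is_tf), np.sum(~has_dm & is_tf)],
            [np.sum(has_dm & ~is_tf), np.sum(~has_dm & ~is_tf)],
        ],
        dtype=float,
    )
    tf_chi2, tf_p = chi2_2x2(tf_table)
    tf_n = max(int(is_tf.sum()), 1)
    non_tf_n = max(int((~is_tf).sum()), 1)
    return DmDeEnrichment(
        chi2=chi2,
        p=p,
        table=table,
        pct_de_genes_with_dm=pct,
        tf_chi2=tf_chi2,
        tf_p=tf_p,
        tf_fraction=float(np.sum(has_dm & is_tf)) / tf_n,
        non_tf_fraction=float(np.sum(has_dm & ~is_tf)) / non_tf_n,
    )
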