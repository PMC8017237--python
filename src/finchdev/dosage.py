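"""Z-chromosome dosage-compensation analysis.

Birds compensate Z-gene dosage only partially: males are ZZ, females
ZW, so an uncompensated Z gene shows a male:female expression ratio near
2 and a fully compensated one near 1.  Per developmental stage, each
gene's M:F ratio of mean cpm is computed; the 95% quantile of the
autosomal ratio distribution (autosomes are not dosage-affected) serves
as the compensation cutoff, and Z-linked genes are classified as
compensated from birth (ratio below cutoff at 1 dph and adult),
acquiring compensation (above at 1 dph, below at adult), or never
compensated (above at both).  Unplaced "_random" fragments count with
their parent chromosome class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from ._stats import bonferroni_adjust, chi2_2x2
from .core import AGES, ExpressionMatrix, GeneAnnotation, SampleDesign


@dataclass(frozen=True)
class DosageConfig:
    quantile: float = 0.95
    epsilon: float = 1e-6  # zero-denominator guard on female means
    n_bins: int = 1000
    per_age_cutoff: bool = True  # cutoff from each age's autosomal ratios

    def __post_init__(self):
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")


CLASSES = ("from_birth", "acquired", "never")


def mf_ratios(
    x: ExpressionMatrix,
    design: SampleDesign,
    genes: GeneAnnotation,
    cfg: DosageConfig = DosageConfig(),
) -> pd.DataFrame:
    """Per-gene, per-age male:female ratios of mean cpm.

    Returns a table indexed by gene with one ratio column per age, the
    chromosome class (random fragments folded into their parent class),
    and a flag for genes whose female mean was zero at some age.
    """
    cpm = x.cpm()
    out = pd.DataFrame(index=cpm.index)
    guarded = np.zeros(len(cpm), dtype=bool)
    for age in AGES:
        males = design.samples_where(age=age, sex="M")
        females = design.samples_where(age=age, sex="F")
        if not males or not females:
            raise ValueError(f"age {age} lacks one sex")
        m_mean = cpm[males].mean(axis=1)
        f_mean = cpm[females].mean(axis=1)
        guarded |= (f_mean == 0).to_numpy()
        out[f"ratio_{age}"] = m_mean / (f_mean + cfg.epsilon)
    cls = genes.table["chrom_class"].reindex(cpm.index)
    out["chrom_class"] = cls.replace({"random_autosome": "autosome", "random_Z": "Z"})
    out["zero_female_mean"] = guarded
    return out


@dataclass
class DosageClassification:
    table: pd.DataFrame  # Z genes: ratios, class
    cutoff: dict[str, float]  # per age (or the same pooled value per age)
    counts: dict[str, int] = field(default_factory=dict)

    def genes_in_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["dosage_class"] == cls]


def classify_dosage(
    ratios: pd.DataFrame,
    cfg: DosageConfig = DosageConfig(),
) -> DosageClassification:
    """Three-way dosage classification of Z-linked genes.

    The cutoff is the linear-interpolation ``cfg.quantile`` quantile of
    the autosomal ratio distribution, by default computed separately for
    the 1 dph and adult conditions; genes with zero expression in both
    sexes at either decision age are unclassifiable and excluded.
    """
    auto = ratios[ratios["chrom_class"] == "autosome"]
    z = ratios[ratios["chrom_class"] == "Z"].copy()
    if len(auto) < 20:
        raise ValueError("need >= 20 autosomal genes for a stable quantile")
    if len(z) == 0:
        raise ValueError("no Z-linked genes")
    ages_used = ("d1", "adult")
    if cfg.per_age_cutoff:
        cutoff = {
            age: float(np.quantile(auto[f"ratio_{age}"], cfg.quantile)) for age in ages_used
        }
    else:
        pooled = np.concatenate([auto[f"ratio_{age}"].to_numpy() for age in ages_used])
        c = float(np.quantile(pooled, cfg.quantile))
        cutoff = {age: c for age in ages_used}
    hi_d1 = z["ratio_d1"] >= cutoff["d1"]
    hi_adult = z["ratio_adult"] >= cutoff["adult"]
    cls = np.where(
        ~hi_d1 & ~hi_adult,
        "from_birth",
        np.where(hi_d1 & ~hi_adult, "acquired", np.where(hi_d1 & hi_adult, "never", "other")),
    )
    z["dosage_class"] = cls
    # ratio below cutoff at 1 dph but above at adult does not fit the
    # three-way scheme; kept in the table as "other", not counted
    counts = {c: int((cls == c).sum()) for c in CLASSES}
    return DosageClassification(table=z, cutoff=cutoff, counts=counts)


def ratio_distribution(
    ratios: pd.DataFrame,
    cfg: DosageConfig = DosageConfig(),
    lowess_frac: float = 0.1,
) -> pd.DataFrame:
    """Binned M:F ratio distributions per chromosome class and age.

    1,000 equal-width bins span the observed ratio range; the percentage
    of genes per bin is reported raw and lowess-smoothed.
    """
    rows = []
    for age in AGES:
        col = f"ratio_{age}"
        lo, hi = ratios[col].min(), ratios[col].max()
        edges = np.linspace(lo, hi, cfg.n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for cls, sub in ratios.groupby("chrom_class"):
            vals = sub[col].to_numpy()
            if len(vals) == 0:
                continue
            counts, _ = np.histogram(vals, bins=edges)
            pct = 100.0 * counts / len(vals)
            if hi > lo:
                smooth = lowess(pct, centers, frac=lowess_frac, it=0, return_sorted=False)
            else:  # degenerate range: nothing to smooth
                smooth = pct.copy()
            df = pd.DataFrame(
                {
                    "age": age,
                    "chrom_class": cls,
                    "bin_center": centers,
                    "pct": pct,
                    "pct_smooth": smooth,
                }
            )
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


@dataclass
class DosageGroupStats:
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame  # pairwise class comparisons
    z_fraction_tests: pd.DataFrame  # pairwise ages, chi2 on Z fraction of sex-DE genes
    direction_tests: pd.DataFrame  # pairwise ages, chi2 on male- vs female-biased rates


def dosage_group_stats(
    logcpm: pd.DataFrame,
    classification: DosageClassification,
    sex_de_by_age: dict[str, pd.Index] | None = None,
    gene_classes: pd.Series | None = None,
    direction_by_age: dict[str, pd.Series] | None = None,
) -> DosageGroupStats:
    """Compare expression across dosage classes and sex-DE composition
    across ages.

    ANOVA with Tukey post-hoc on per-gene mean log-cpm across the three
    dosage classes.  If per-age sex-DE gene sets are given (with
    ``gene_classes`` mapping every tested gene to Z/autosome), all six
    pairwise ages are compared by chi-squared on the Z-linked fraction
    of sex-DE genes, Bonferroni-corrected; ``direction_by_age`` (per-age
    male/female overexpression labels) is tested analogously.
    """
    tab = classification.table
    groups = []
    labels = []
    for cls in CLASSES:
        ids = tab.index[tab["dosage_class"] == cls].intersection(logcpm.index)
        if len(ids) < 2:
            raise ValueError(f"dosage class {cls!r} has fewer than 2 genes")
        vals = logcpm.loc[ids].mean(axis=1).to_numpy()
        groups.append(vals)
        labels.extend([cls] * len(vals))
    f_stat, p = stats.f_oneway(*groups)
    tk = pairwise_tukeyhsd(np.concatenate(groups), np.array(labels))
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    def _pairwise(per_age_tables: dict[str, np.ndarray]) -> pd.DataFrame:
        pairs = [(a1, a2) for i, a1 in enumerate(AGES) for a2 in AGES[i + 1 :]]
        rows = []
        for a1, a2 in pairs:
            t = np.vstack([per_age_tables[a1], per_age_tables[a2]])
            c, pv = chi2_2x2(t)
            rows.append({"age_1": a1, "age_2": a2, "chi2": c, "p": pv})
        out = pd.DataFrame(rows)
        raw = out["p"].to_numpy()
        out["p_bonferroni"] = np.minimum(raw * len(pairs), 1.0)
        return out

    z_tests = pd.DataFrame()
    dir_tests = pd.DataFrame()
    if sex_de_by_age is not None and gene_classes is not None:
        per_age = {}
        for age in AGES:
            de = sex_de_by_age.get(age, pd.Index([]))
            on_z = gene_classes.reindex(de).isin(["Z", "random_Z"]).sum()
            per_age[age] = np.array([on_z, len(de) - on_z], dtype=float)
        z_tests = _pairwise(per_age)
    if direction_by_age is not None:
        per_age = {}
        for age in AGES:
            d = direction_by_age.get(age, pd.Series(dtype=object))
            per_age[age] = np.array([(d == "M").sum(), (d == "F").sum()], dtype=float)
        dir_tests = _pairwise(per_age)
    return DosageGroupStats(
        anova_f=float(f_stat),
        anova_p=float(p),
        tukey=tukey,
        z_fraction_tests=z_tests,
        direction_tests=dir_tests,
    )
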