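"""Synthetic datasets with the statistical structure the pipeline assumes.

Every downstream stage is testable without any external download: the
generator draws negative-binomial counts with age x sex group structure,
binomial methylation counts with age trends and a hydroxymethylation
fraction, autosome/Z chromosome assignment with configurable
dosage-compensation classes, and promoter sequences with planted motif
occurrences — each with ground-truth labels.

One global seed fully determines the output; per-stage child streams are
spawned deterministically (genes, expression, methylation, promoters) so
stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AGES,
    ExpressionMatrix,
    GeneAnnotation,
    MethylationMatrix,
    PWM,
    SampleDesign,
    chrom_class_of,
)
from .expression import pattern_alphabet

_AGE_INDEX = {age: i for i, age in enumerate(AGES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults mirror the study design where it
    states a value, otherwise hold plausible magnitudes for brain
    RNA-seq/RRBS (dispersion, coverage), which are knobs, not claims."""

    n_genes: int = 1000
    n_cpg_per_gene: int = 5
    n_cph_per_gene: int = 2
    seed: int = 0
    nb_dispersion: float = 0.05
    baseline_logcpm_range: tuple[float, float] = (1.0, 9.0)
    pattern_assignments: dict[str, str] | None = None
    effect_size_sd_units: float = 3.0
    dosage_class_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "from_birth": 0.015,
            "acquired": 0.065,
            "never": 0.020,
            "autosomal_null": 0.900,
        }
    )
    meth_age_slope: float = 0.5  # logit shift per age step at DM sites
    dm_fraction: float = 0.3  # fraction of CpG sites carrying the age trend
    cpg_beta_params: tuple[float, float] = (5.0, 2.0)  # high CpG methylation
    cph_beta_params: tuple[float, float] = (1.5, 8.0)  # low CpH methylation
    hmc_fraction: float = 0.1  # 5hmC as a fraction of total methylation
    coverage_mean: float = 20.0
    mean_lib_size: float = 1.0e7
    tf_fraction: float = 0.08
    planted_motif: str | None = None
    promoter_length: int = 2500  # the -2,000/+500 TSS window
    background_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        total = sum(self.dosage_class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("dosage_class_fractions must sum to 1")
        if not 0 <= self.hmc_fraction < 1:
            raise ValueError("hmc_fraction must be in [0, 1)")
        if self.pattern_assignments:
            alphabet, _ = pattern_alphabet()
            bad = set(self.pattern_assignments.values()) - set(alphabet)
            if bad:
                raise ValueError(f"pattern code(s) not in the 27-pattern alphabet: {sorted(bad)}")


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    return {
        name: np.random.default_rng(ss)
        for name, ss in zip(("genes", "expression", "methylation", "promoters"), children)
    }


# ---------------------------------------------------------------------------
# gene models


GENE_LENGTH = 5000
GENE_SPACING = 20000


def simulate_genes(config: SimulationConfig) -> tuple[GeneAnnotation, pd.DataFrame]:
    """Gene coordinates, chromosomes and dosage-class ground truth.

    Z-class genes go to chromosome Z (a tenth to the unplaced Z_random
    fragment), autosomal genes round-robin over chromosomes 1-5 (again a
    tenth to unplaced fragments); genes are laid head-to-tail with
    alternating strand.  Returns (annotation, truth) where truth maps
    each gene to its dosage class and TF flag.
    """
    rng = _child_rngs(config.seed)["genes"]
    classes = list(config.dosage_class_fractions)
    probs = np.array([config.dosage_class_fractions[c] for c in classes])
    dosage = rng.choice(classes, size=config.n_genes, p=probs)
    is_tf = rng.random(config.n_genes) < config.tf_fraction
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    autosomes = ["1", "2", "3", "4", "5"]
    chrom = []
    auto_counter = 0
    for i in range(config.n_genes):
        unplaced = rng.random() < 0.1
        if dosage[i] == "autosomal_null":
            base = autosomes[auto_counter % len(autosomes)]
            auto_counter += 1
        else:
            base = "Z"
        chrom.append(f"{base}_random" if unplaced else base)
    offsets: dict[str, int] = {}
    rows = []
    for i, gid in enumerate(gene_ids):
        start = offsets.get(chrom[i], 10000)
        end = start + GENE_LENGTH
        offsets[chrom[i]] = start + GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        tss = start if strand == "+" else end - 1
        rows.append(
            {
                "gene_id": gid,
                "chrom": chrom[i],
                "start": start,
                "end": end,
                "strand": strand,
                "tss": tss,
                "chrom_class": chrom_class_of(chrom[i]),
                "is_tf": bool(is_tf[i]),
            }
        )
    genes = GeneAnnotation(pd.DataFrame(rows).set_index("gene_id"))
    truth = pd.DataFrame({"dosage_class": dosage, "is_tf": is_tf}, index=genes.gene_ids)
    return genes, truth


# ---------------------------------------------------------------------------
# expression


def _sex_log2_ratio(dosage_class: str, age_idx: int) -> float:
    """True male:female log2 mean ratio per dosage class and age.

    Uncompensated Z genes sit at ratio 2 throughout; acquiring genes
    interpolate linearly in log-ratio from 2 at 1 dph to 1 at adult;
    compensated-from-birth and autosomal genes sit at 1.
    """
    if dosage_class == "never":
        return 1.0
    if dosage_class == "acquired":
        return 1.0 - age_idx / (len(AGES) - 1)
    return 0.0


def simulate_expression(
    config: SimulationConfig,
    design: SampleDesign,
    genes: GeneAnnotation | None = None,
    gene_truth: pd.DataFrame | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted age patterns and sex effects.

    Group means start from a uniform baseline log2-cpm; genes with an
    assigned H/E/L pattern are shifted at the flagged time points by
    ``effect_size_sd_units`` within-group standard deviations (of log2
    counts, from the NB mean-variance function); Z genes get the
    dosage-class male:female ratio.  Counts are drawn per sample from
    NB(mean, dispersion).  Returns the matrix and per-gene truth
    (pattern, dosage_class, sex_effect).
    """
    if genes is None or gene_truth is None:
        genes, gene_truth = simulate_genes(config)
    rng = _child_rngs(config.seed)["expression"]
    n = config.n_genes
    lo, hi = config.baseline_logcpm_range
    base_log2cpm = rng.uniform(lo, hi, size=n)
    lib_sizes = config.mean_lib_size * rng.uniform(0.85, 1.15, size=design.n_samples)

    patterns = pd.Series("EEE", index=genes.gene_ids)
    if config.pattern_assignments:
        for gid, code in config.pattern_assignments.items():
            patterns.loc[gid] = code
    # replicate SD of log2 counts under the NB at the baseline mean
    base_mu = 2.0**base_log2cpm * config.mean_lib_size / 1e6
    sd_log2 = np.sqrt(1.0 / base_mu + config.nb_dispersion) / np.log(2.0)
    shift = config.effect_size_sd_units * sd_log2

    dosage = gene_truth["dosage_class"].reindex(genes.gene_ids).to_numpy()
    pattern_arr = patterns.to_numpy()
    level_shift = {"H": 1.0, "E": 0.0, "L": -1.0}

    counts = np.zeros((n, design.n_samples), dtype=np.int64)
    meta = design.table
    for j in range(design.n_samples):
        age = meta["age"].iloc[j]
        sex = meta["sex"].iloc[j]
        a = _AGE_INDEX[age]
        log2mu = base_log2cpm.copy()
        if a > 0:  # pattern codes index d20/d65/adult relative to d1
            lev = np.array([level_shift[p[a - 1]] for p in pattern_arr])
            log2mu = log2mu + lev * shift
        ratio = np.array([_sex_log2_ratio(d, a) for d in dosage])
        # split the ratio symmetrically: males up, females down by half
        log2mu = log2mu + (0.5 if sex == "M" else -0.5) * ratio
        mu = 2.0**log2mu * lib_sizes[j] / 1e6
        r = 1.0 / config.nb_dispersion
        counts[:, j] = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=genes.gene_ids, columns=design.sample_ids)
    x = ExpressionMatrix(counts=counts_df, lib_size=counts_df.sum(axis=0))
    truth = pd.DataFrame(
        {
            "pattern": pattern_arr,
            "dosage_class": dosage,
            "sex_effect": np.isin(dosage, ["never", "acquired"]),
            "is_tf": gene_truth["is_tf"].reindex(genes.gene_ids).to_numpy(),
        },
        index=genes.gene_ids,
    )
    return x, truth


# ---------------------------------------------------------------------------
# methylation


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    config: SimulationConfig,
    design: SampleDesign,
    genes: GeneAnnotation,
) -> tuple[MethylationMatrix, MethylationMatrix, pd.DataFrame]:
    """Binomial methylation counts for the RRBS and oxRRBS assays.

    CpG sites are placed in each gene's promoter window, CpH sites in
    the gene body, with CpH baseline methylation well below CpG levels
    (as in neural tissue).  A ``dm_fraction`` of CpG sites carries an
    age trend of ``meth_age_slope`` logits per age step.  Total counts
    are Poisson(coverage_mean); RRBS success probability is the total
    methylation level, oxRRBS reads only true 5mC, i.e. a fraction
    (1 - hmc_fraction) of it.  Returns (rrbs, oxrrbs, per-site truth).
    """
    rng = _child_rngs(config.seed)["methylation"]
    prom = genes.promoters()
    rows = []
    for gid, g in genes.table.iterrows():
        p = prom.loc[gid]
        cpg_pos = np.sort(
            rng.choice(np.arange(p["start"], p["end"]), size=config.n_cpg_per_gene, replace=False)
        )
        for pos in cpg_pos:
            rows.append((g["chrom"], int(pos), "+", "CpG", gid))
        if config.n_cph_per_gene > 0:
            cph_pos = np.sort(
                rng.choice(
                    np.arange(g["start"], g["end"]), size=config.n_cph_per_gene, replace=False
                )
            )
            for pos in cph_pos:
                rows.append((g["chrom"], int(pos), "+", "CpH", gid))
    site_df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "gene_id"])
    site_df = site_df.drop_duplicates(subset=["chrom", "pos", "strand", "context"])
    n_sites = len(site_df)
    is_cpg = (site_df["context"] == "CpG").to_numpy()

    base_beta = np.where(
        is_cpg,
        rng.beta(*config.cpg_beta_params, size=n_sites),
        rng.beta(*config.cph_beta_params, size=n_sites),
    )
    base_beta = np.clip(base_beta, 0.02, 0.98)
    dm_flag = is_cpg & (rng.random(n_sites) < config.dm_fraction) & (config.meth_age_slope != 0)

    index = pd.MultiIndex.from_frame(site_df[["chrom", "pos", "strand", "context"]])
    ages = design.table["age"].map(_AGE_INDEX).to_numpy()
    beta_by_age = np.empty((n_sites, len(AGES)))
    for a in range(len(AGES)):
        logit_b = _logit(base_beta) + np.where(dm_flag, config.meth_age_slope * a, 0.0)
        beta_by_age[:, a] = _expit(logit_b)

    def draw(assay_scale: float) -> tuple[pd.DataFrame, pd.DataFrame]:
        total = rng.poisson(config.coverage_mean, size=(n_sites, design.n_samples))
        prob = beta_by_age[:, ages] * assay_scale
        meth = rng.binomial(total, prob)
        meth_df = pd.DataFrame(meth, index=index, columns=design.sample_ids)
        total_df = pd.DataFrame(total, index=index, columns=design.sample_ids)
        return meth_df, total_df

    rrbs_meth, rrbs_total = draw(1.0)
    ox_meth, ox_total = draw(1.0 - config.hmc_fraction)
    rrbs = MethylationMatrix(rrbs_meth, rrbs_total, "rrbs")
    oxrrbs = MethylationMatrix(ox_meth, ox_total, "oxrrbs")
    truth = pd.DataFrame(
        {
            "gene_id": site_df["gene_id"].to_numpy(),
            "dm_flag": dm_flag,
            "true_hmc": np.where(is_cpg, config.hmc_fraction * base_beta, 0.0),
            **{f"true_beta_{age}": beta_by_age[:, a] for age, a in _AGE_INDEX.items()},
        },
        index=index,
    )
    return rrbs, oxrrbs, truth


# ---------------------------------------------------------------------------
# promoter sequences


def simulate_promoters(
    config: SimulationConfig,
    genes: GeneAnnotation,
    motif: PWM | None = None,
    positive_genes: pd.Index | None = None,
) -> tuple[dict[str, str], pd.Series]:
    """Promoter sequences with planted motif occurrences.

    Background bases are i.i.d. from ``background_freqs``; each
    motif-positive gene receives one exact consensus occurrence at a
    random position.  Returns ({gene_id: sequence}, truth labels).
    """
    rng = _child_rngs(config.seed)["promoters"]
    L = config.promoter_length
    bases = np.array(list("ACGT"))
    freqs = np.asarray(config.background_freqs, dtype=float)
    freqs = freqs / freqs.sum()
    if motif is not None and motif.length > L:
        raise ValueError("motif longer than promoter")
    positive = pd.Series(False, index=genes.gene_ids)
    if positive_genes is not None:
        positive.loc[positive_genes] = True
    seqs = {}
    for gid in genes.gene_ids:
        seq = rng.choice(bases, size=L, p=freqs)
        if motif is not None and positive.loc[gid]:
            start = int(rng.integers(0, L - motif.length + 1))
            seq[start : start + motif.length] = list(motif.consensus())
        seqs[gid] = "".join(seq)
    return seqs, positive


# ---------------------------------------------------------------------------
# coupled expression-methylation (mixed-model ground truth)


def simulate_coupled_methylation_expression(
    design: SampleDesign,
    n_genes: int = 500,
    slope: float = -0.04,
    seed: int = 0,
    gene_sd: float = 2.0,
    sample_sd: float = 0.2,
    resid_sd: float = 0.3,
    m_gene_sd: float = 1.5,
    m_within_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression coupled to methylation with a known mixed-model slope.

    Per (gene, sample): mean M-value = gene baseline + within-gene noise;
    log-cpm = 6 + slope * M + gene intercept + sample intercept + noise.
    Returns (logcpm, M) gene x sample frames; the generating slope, gene/
    sample intercept SDs and residual SD are exactly the crossed
    random-intercept model the integration module fits.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    n_s = design.n_samples
    m_gene = 1.5 + m_gene_sd * rng.standard_normal(n_genes)
    M = m_gene[:, None] + m_within_sd * rng.standard_normal((n_genes, n_s))
    u = gene_sd * rng.standard_normal(n_genes)
    v = sample_sd * rng.standard_normal(n_s)
    y = 6.0 + slope * M + u[:, None] + v[None, :] + resid_sd * rng.standard_normal((n_genes, n_s))
    cols = design.sample_ids
    return (
        pd.DataFrame(y, index=gene_ids, columns=cols),
        pd.DataFrame(M, index=gene_ids, columns=cols),
    )


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedDataset:
    genes: GeneAnnotation
    expression: ExpressionMatrix
    gene_truth: pd.DataFrame
    rrbs: MethylationMatrix
    oxrrbs: MethylationMatrix
    site_truth: pd.DataFrame
    promoters: dict[str, str]
    motif_truth: pd.Series


def simulate_dataset(
    config: SimulationConfig,
    design: SampleDesign,
    motif: PWM | None = None,
    motif_positive_genes: pd.Index | None = None,
) -> SimulatedDataset:
    """Generate a complete, mutually consistent synthetic study."""
    genes, gclass = simulate_genes(config)
    expr, gene_truth = simulate_expression(config, design, genes, gclass)
    rrbs, oxrrbs, site_truth = simulate_methylation(config, design, genes)
    promoters, motif_truth = simulate_promoters(config, genes, motif, motif_positive_genes)
    return SimulatedDataset(
        genes=genes,
        expression=expr,
        gene_truth=gene_truth,
        rrbs=rrbs,
        oxrrbs=oxrrbs,
        site_truth=site_truth,
        promoters=promoters,
        motif_truth=motif_truth,
    )
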