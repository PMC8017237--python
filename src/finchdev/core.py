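"""Core containers shared across the pipeline.

All genomic coordinates are held internally as 0-based half-open
intervals; conversion from 1-based inclusive GTF coordinates happens
exactly once, on read (see :mod:`finchdev.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Ordered developmental stages (days post hatching; "adult" > 65 dph).
AGES = ("d1", "d20", "d65", "adult")
SEXES = ("M", "F")

#: Chromosome classes used by the dosage-compensation analysis.  Scaffolds
#: whose precise location is unknown carry a "_random" suffix in the
#: annotation and are folded into their parent class.
CHROM_CLASSES = ("autosome", "Z", "W", "random_autosome", "random_Z")


def chrom_class_of(chrom: str) -> str:
    """Map a chromosome name to its dosage class.

    ``"Z"`` and ``"Z_random"`` are Z-linked, ``"W"`` is W-linked, anything
    else is autosomal; a ``"_random"`` suffix marks unplaced fragments.
    """
    base, _, suffix = chrom.partition("_")
    random = suffix == "random"
    if base == "Z":
        return "random_Z" if random else "Z"
    if base == "W":
        return "W"
    return "random_autosome" if random else "autosome"


@dataclass(frozen=True)
class SampleDesign:
    """Age x sex x pool factor table aligned to every data matrix.

    The full study design has 24 samples: 4 ages x 2 sexes x 3 pools,
    each pool an RNA mix of three birds.
    """

    table: pd.DataFrame  # columns: sample_id, age, sex, pool

    def __post_init__(self):
        t = self.table
        for col in ("sample_id", "age", "sex"):
            if col not in t.columns:
                raise ValueError(f"design table lacks column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        bad_age = set(t["age"]) - set(AGES)
        if bad_age:
            raise ValueError(f"unknown age level(s): {sorted(bad_age)}")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex level(s): {sorted(bad_sex)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def group_labels(self) -> pd.Series:
        """Per-sample ``age.sex`` labels (8 levels in the full design)."""
        lab = self.table["age"].astype(str) + "." + self.table["sex"].astype(str)
        lab.index = self.table["sample_id"]
        return lab

    def samples_where(self, age: str | None = None, sex: str | None = None) -> list[str]:
        t = self.table
        keep = pd.Series(True, index=t.index)
        if age is not None:
            keep &= t["age"] == age
        if sex is not None:
            keep &= t["sex"] == sex
        return list(t.loc[keep, "sample_id"])


def default_design(n_pools: int = 3) -> SampleDesign:
    """The full 4 ages x 2 sexes x ``n_pools`` design (24 samples)."""
    rows = [
        {"sample_id": f"{age}_{sex}_{p + 1}", "age": age, "sex": sex, "pool": p + 1}
        for age in AGES
        for sex in SEXES
        for p in range(n_pools)
    ]
    return SampleDesign(pd.DataFrame(rows))


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts with library sizes and TMM factors."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    lib_size: pd.Series  # per-sample raw totals
    norm_factor: pd.Series | None = None  # per-sample TMM factors (default 1)

    def __post_init__(self):
        if self.norm_factor is None:
            self.norm_factor = pd.Series(1.0, index=self.counts.columns)
        self.lib_size = self.lib_size.reindex(self.counts.columns)
        self.norm_factor = self.norm_factor.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.norm_factor

    def cpm(self, use_norm_factors: bool = True) -> pd.DataFrame:
        """Counts per million mapped reads (optionally TMM-adjusted)."""
        lib = self.effective_lib_size if use_norm_factors else self.lib_size
        return self.counts.div(lib, axis=1) * 1e6

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return replace(self, counts=self.counts.loc[gene_ids])


@dataclass
class MethylationMatrix:
    """Per-cytosine (methylated, total) read counts for one assay.

    Rows are keyed by (chrom, pos, strand, context) where ``pos`` is the
    0-based genomic position of the cytosine, ``context`` is CpG or CpH;
    columns are samples aligned to the design.
    """

    meth: pd.DataFrame  # sites x samples methylated read counts
    total: pd.DataFrame  # sites x samples total read counts
    assay: str  # "rrbs" (5mC + 5hmC) or "oxrrbs" (5mC only)

    INDEX_NAMES = ("chrom", "pos", "strand", "context")

    def __post_init__(self):
        if self.assay not in ("rrbs", "oxrrbs"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if not self.meth.index.equals(self.total.index):
            raise ValueError("meth/total site indices differ")
        if (self.meth.to_numpy() > self.total.to_numpy()).any():
            raise ValueError("methylated count exceeds total count")

    @property
    def sites(self) -> pd.MultiIndex:
        return self.meth.index

    @property
    def n_sites(self) -> int:
        return len(self.meth)

    def subset_sites(self, mask) -> "MethylationMatrix":
        return MethylationMatrix(self.meth.loc[mask], self.total.loc[mask], self.assay)


@dataclass
class GeneAnnotation:
    """Gene coordinates (0-based half-open), strand-aware TSS, chromosome
    class and transcription-factor flag, one row per gene."""

    table: pd.DataFrame  # index gene_id; chrom, start, end, strand, tss,
    # chrom_class, is_tf

    def __post_init__(self):
        t = self.table
        if (t["start"] > t["end"]).any():
            raise ValueError("gene with start > end")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("gene without valid strand")
        if "chrom_class" not in t.columns:
            t["chrom_class"] = [chrom_class_of(c) for c in t["chrom"]]
        if "is_tf" not in t.columns:
            t["is_tf"] = False

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def promoters(self, upstream: int = 2000, downstream: int = 500) -> pd.DataFrame:
        """Strand-oriented promoter windows [TSS-upstream, TSS+downstream),
        0-based half-open, clamped at the chromosome start."""
        t = self.table
        plus = t["strand"] == "+"
        start = np.where(plus, t["tss"] - upstream, t["tss"] - downstream + 1)
        end = np.where(plus, t["tss"] + downstream, t["tss"] + upstream + 1)
        out = pd.DataFrame(
            {"chrom": t["chrom"], "start": np.maximum(start, 0), "end": end},
            index=t.index,
        )
        return out

    def z_linked(self) -> pd.Index:
        mask = self.table["chrom_class"].isin(["Z", "random_Z"])
        return self.table.index[mask]

    def autosomal(self) -> pd.Index:
        mask = self.table["chrom_class"].isin(["autosome", "random_autosome"])
        return self.table.index[mask]


@dataclass
class PWM:
    """Position weight matrix with background model.

    ``probs`` is a 4 x L column-stochastic matrix over (A, C, G, T) after
    pseudocount regularisation of the raw counts.
    """

    motif_id: str
    probs: np.ndarray  # 4 x L, columns sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1

    ALPHABET = "ACGT"

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise ValueError("PWM must be a 4 x L matrix with L >= 1")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        rc = self.probs[::-1, ::-1].copy()
        bg = self.background[::-1].copy()
        return PWM(self.motif_id, rc, bg, self.pseudocount)

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.motif_id, self.probs, np.asarray(background, float), self.pseudocount)


def pwm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> PWM:
    """Build a PWM from a 4 x L count/frequency matrix.

    Pseudocounts are distributed by the background composition, then each
    column is normalised to a probability vector.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("PFM must have exactly 4 rows (A, C, G, T)")
    if (counts < 0).any():
        raise ValueError("PFM entries must be non-negative")
    if background is None:
        background = np.full(4, 0.25)
    colsums = counts.sum(axis=0)
    if pseudocount == 0 and (colsums == 0).any():
        raise ValueError(f"motif {motif_id!r}: column sums to zero")
    padded = counts + pseudocount * background[:, None]
    probs = padded / padded.sum(axis=0, keepdims=True)
    return PWM(motif_id, probs, np.asarray(background, float), pseudocount)
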