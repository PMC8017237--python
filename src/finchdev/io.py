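"""Readers and writers for the formats the pipeline touches.

Counts and cytosine reports are plain TSV; gene models come from GTF
(1-based inclusive, converted to the internal 0-based half-open
convention exactly once, here); motifs from JASPAR ``.pfm`` or MEME
minimal files via Bio.motifs; promoter/genome sequences from FASTA via
Bio.SeqIO.  The bedGraph writer implements the signed-significance
convention used for browser tracks: significant cytosines carry their
methylation fraction as a positive value, non-significant ones as a
negative value.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO, motifs

from .core import (
    ExpressionMatrix,
    GeneAnnotation,
    MethylationMatrix,
    PWM,
    SampleDesign,
    chrom_class_of,
    pwm_from_counts,
)

# ---------------------------------------------------------------------------
# sample design


def read_design(path: str | os.PathLike) -> SampleDesign:
    """Read a design TSV with columns sample_id, age, sex, pool."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleDesign(table)


def write_design(design: SampleDesign, path: str | os.PathLike) -> None:
    design.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression counts


def read_counts(path: str | os.PathLike, design: SampleDesign) -> ExpressionMatrix:
    """Read a gene x sample count TSV and align it to the design.

    The first column holds gene identifiers; remaining columns must cover
    every sample in the design.  Library size is the raw column sum.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [s for s in design.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"count table lacks sample column(s): {missing}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    df = df[design.sample_ids]
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric count value")
    if (arr < 0).any():
        raise ValueError("negative count value")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("non-integer count value")
    counts = df.astype(np.int64)
    return ExpressionMatrix(counts=counts, lib_size=counts.sum(axis=0))


def write_counts(x: ExpressionMatrix, path: str | os.PathLike) -> None:
    out = x.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# cytosine reports

_CONTEXTS = ("CpG", "CpH")


def read_cytosine_report(
    path: str | os.PathLike, design: SampleDesign, assay: str
) -> MethylationMatrix:
    """Read a long-format per-cytosine report into a MethylationMatrix.

    Expected columns: chrom, pos (0-based cytosine position), strand,
    context (CpG/CpH), sample_id, meth, total — one row per site x sample.
    Sites absent in a sample get zero counts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    bad_ctx = set(df["context"]) - set(_CONTEXTS)
    if bad_ctx:
        raise ValueError(f"unknown context token(s): {sorted(bad_ctx)}")
    if (df["meth"] > df["total"]).any():
        row = df[df["meth"] > df["total"]].iloc[0]
        raise ValueError(
            f"meth > total at {row['chrom']}:{row['pos']} sample {row['sample_id']}"
        )
    unknown = set(df["sample_id"]) - set(design.sample_ids)
    if unknown:
        raise ValueError(f"sample(s) not in design: {sorted(unknown)}")
    key = ["chrom", "pos", "strand", "context"]
    if df.duplicated(subset=key + ["sample_id"]).any():
        raise ValueError("duplicate (site, sample) row in cytosine report")
    meth = (
        df.pivot_table(index=key, columns="sample_id", values="meth", fill_value=0)
        .reindex(columns=design.sample_ids, fill_value=0)
        .astype(np.int64)
    )
    total = (
        df.pivot_table(index=key, columns="sample_id", values="total", fill_value=0)
        .reindex(columns=design.sample_ids, fill_value=0)
        .astype(np.int64)
    )
    meth.columns.name = None
    total.columns.name = None
    return MethylationMatrix(meth=meth, total=total, assay=assay)


def write_cytosine_report(m: MethylationMatrix, path: str | os.PathLike) -> None:
    """Write the long-format cytosine report (inverse of the reader).

    Only (site, sample) cells with non-zero total coverage are emitted;
    uncovered cells are implicit zeros.
    """
    meth_long = m.meth.stack()
    total_long = m.total.stack()
    df = pd.DataFrame({"meth": meth_long, "total": total_long}).reset_index()
    df.columns = ["chrom", "pos", "strand", "context", "sample_id", "meth", "total"]
    df = df[df["total"] > 0]
    df = df[["chrom", "pos", "strand", "context", "sample_id", "meth", "total"]]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation (GTF)


def read_annotation(path: str | os.PathLike) -> GeneAnnotation:
    """Read gene features from a GTF into a GeneAnnotation.

    GTF coordinates are 1-based inclusive; they are converted here to
    0-based half-open.  The TSS is the first transcribed base: ``start``
    on the + strand, ``end`` on the - strand.  An optional ``is_tf``
    attribute ("1"/"0") marks transcription-factor genes.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    rows = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {feat.id} without strand")
        start0 = feat.start - 1  # GTF 1-based inclusive -> 0-based half-open
        end0 = feat.end
        tss = start0 if feat.strand == "+" else end0 - 1
        is_tf = feat.attributes.get("is_tf", ["0"])[0] in ("1", "true", "True")
        rows.append(
            {
                "gene_id": feat.id,
                "chrom": feat.seqid,
                "start": start0,
                "end": end0,
                "strand": feat.strand,
                "tss": tss,
                "chrom_class": chrom_class_of(feat.seqid),
                "is_tf": is_tf,
            }
        )
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    table = pd.DataFrame(rows).set_index("gene_id")
    return GeneAnnotation(table)


def write_annotation_gtf(genes: GeneAnnotation, path: str | os.PathLike) -> None:
    """Write gene features as GTF (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        for gid, row in genes.table.iterrows():
            attrs = f'gene_id "{gid}"; is_tf "{int(row["is_tf"])}";'
            fh.write(
                "\t".join(
                    [
                        str(row["chrom"]),
                        "finchdev",
                        "gene",
                        str(int(row["start"]) + 1),
                        str(int(row["end"])),
                        ".",
                        row["strand"],
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# motifs


def read_pfm(
    path: str | os.PathLike,
    fmt: str | None = None,
    pseudocount: float = 0.1,
    background: np.ndarray | None = None,
) -> list[PWM]:
    """Read position frequency matrices (JASPAR .pfm or MEME minimal).

    The format is sniffed from the first non-blank line unless given.
    Columns are normalised to probabilities after pseudocount addition.
    """
    path = str(path)
    if fmt is None:
        with open(path) as fh:
            first = next((ln for ln in fh if ln.strip()), "")
        fmt = "minimal" if first.startswith("MEME version") else "jaspar"
    with open(path) as fh:
        records = motifs.parse(fh, fmt)
    pwms = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in "ACGT"], dtype=float)
        pwms.append(
            pwm_from_counts(
                rec.matrix_id or rec.name or f"motif{len(pwms) + 1}",
                counts,
                pseudocount=pseudocount,
                background=background,
            )
        )
    if not pwms:
        raise ValueError(f"no motifs parsed from {path}")
    return pwms


def write_pfm_jaspar(pwms_counts: dict[str, np.ndarray], path: str | os.PathLike) -> None:
    """Write raw count matrices in JASPAR .pfm format."""
    with open(path, "w") as fh:
        for motif_id, counts in pwms_counts.items():
            counts = np.asarray(counts, dtype=float)
            fh.write(f">{motif_id} {motif_id}\n")
            for base, row in zip("ACGT", counts):
                vals = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read FASTA into an {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bedGraph

#: Magnitude emitted for a non-significant site with beta == 0 so the sign
#: still encodes non-significance.
BEDGRAPH_ZERO_SENTINEL = 0.001


def write_methylation_bedgraph(
    sites: pd.DataFrame,
    path: str | os.PathLike,
    track_name: str = "methylation",
) -> None:
    """Write scored cytosines as a signed-significance bedGraph track.

    ``sites`` needs columns chrom, pos (0-based), beta (mean methylation
    fraction in [0, 1]) and significant (bool).  Significant sites are
    written as +beta; non-significant sites as -max(beta, 0.001), so the
    sign of every value encodes its significance and a browser can colour
    the two classes differently.
    """
    beta = sites["beta"].to_numpy(dtype=float)
    if ((beta < 0) | (beta > 1)).any():
        raise ValueError("beta outside [0, 1]")
    sig = sites["significant"].to_numpy(dtype=bool)
    value = np.where(sig, beta, -np.maximum(beta, BEDGRAPH_ZERO_SENTINEL))
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, pos, v in zip(sites["chrom"], sites["pos"].astype(int), value):
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:g}\n")


def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, end, value = line.split()
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
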