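"""Transcription-factor binding-site scanning and enrichment.

Promoter sequences (or the 100-bp flanks of differentially methylated
CpGs) are scanned with position weight matrices using log2-odds scores
against a 0-order background.  Per-window p-values are exact: the null
distribution of the score is computed by dynamic programming over a
discretised score grid, and windows with p below the retention threshold
(default 1e-4) on either strand count as matches.  Per motif, a 2x2
Pearson chi-squared compares the fraction of foreground vs outgroup
sequences carrying at least one match, with BH correction across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, chi2_2x2
from .core import PWM

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class TFBSConfig:
    p_threshold: float = 1.0e-4  # FIMO's default retention threshold
    flank: int = 50  # nt each side of a cytosine
    bin_width: float = 1.0e-3  # log2-odds discretisation for the exact DP
    background: str = "seqs"  # "seqs" (0-order from scanned set) or "uniform"
    hit_mode: str = "binary"  # "binary": sequence with >=1 match; "counts"

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")


def encode_sequence(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3; any other character (N etc.) to -1."""
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid alphabet character(s): {sorted(bad)}")
    out = np.fromiter((_BASE_INDEX.get(c, -1) for c in seq), dtype=np.int64, count=len(seq))
    return out


def estimate_background(seqs: dict[str, str]) -> np.ndarray:
    """0-order nucleotide frequencies over a sequence set (N ignored).

    Frequencies are averaged with their reverse complement (A with T,
    C with G) so the null model is strand-symmetric and both strands of
    a scan share one score distribution.
    """
    counts = np.zeros(4)
    for s in seqs.values():
        enc = encode_sequence(s)
        counts += np.bincount(enc[enc >= 0], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    counts = 0.5 * (counts + counts[::-1])
    return counts / counts.sum()


class ScoreDistribution:
    """Exact null distribution of a PWM's log2-odds score.

    Per-position scores are discretised to an integer grid of width
    ``bin_width``; the distribution of the window score under the
    0-order background follows by convolution across positions, and the
    p-value of a score is the upper tail mass.
    """

    def __init__(self, pwm: PWM, bin_width: float = 1.0e-3):
        probs = np.maximum(pwm.probs, 1e-300)
        bg = np.maximum(pwm.background, 1e-300)
        lod = np.log2(probs / bg[:, None])  # 4 x L
        self.int_scores = np.round(lod / bin_width).astype(np.int64)  # 4 x L
        self.bin_width = bin_width
        self.background = bg / bg.sum()
        L = pwm.length
        mins = self.int_scores.min(axis=0)
        spans = self.int_scores.max(axis=0) - mins
        dist = np.zeros(int(spans.sum()) + 1)
        dist[0] = 1.0
        used = 0
        for j in range(L):
            new = np.zeros(used + int(spans[j]) + 1)
            for b in range(4):
                off = self.int_scores[b, j] - mins[j]
                new[off : off + used + 1] += self.background[b] * dist[: used + 1]
            used += int(spans[j])
            dist = new
        self.offset = int(mins.sum())  # integer score of dist[0]
        self.dist = dist
        # upper-tail p-values: p[k] = P(score_int >= offset + k)
        self.tail = np.cumsum(dist[::-1])[::-1]

    @property
    def total_probability(self) -> float:
        return float(self.dist.sum())

    def score_word(self, word: np.ndarray) -> int:
        """Integer score of an encoded word of the motif's length."""
        return int(self.int_scores[word, np.arange(len(word))].sum())

    def pvalue(self, int_score: int) -> float:
        k = int_score - self.offset
        if k < 0:
            return 1.0
        if k >= len(self.tail):
            return 0.0
        return float(self.tail[k])

    def score_threshold(self, p_threshold: float) -> int:
        """Smallest integer score whose p-value is below the threshold."""
        below = np.nonzero(self.tail < p_threshold)[0]
        if len(below) == 0:
            return self.offset + len(self.tail)  # unattainable
        return self.offset + int(below[0])


def scan_sequences(
    seqs: dict[str, str],
    pwm: PWM,
    cfg: TFBSConfig = TFBSConfig(),
    background: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Scan sequences with one PWM on both strands.

    Returns per sequence a table of matches (0-based window start on the
    forward strand, strand, log2-odds score, exact p-value).  Windows
    containing N are skipped; motifs longer than a sequence simply yield
    no matches there.
    """
    if background is None:
        if cfg.background == "seqs":
            background = estimate_background(seqs)
        else:
            background = np.full(4, 0.25)
    fwd = pwm.with_background(background)
    rev = fwd.reverse_complement().with_background(background)
    dists = {"+": ScoreDistribution(fwd, cfg.bin_width), "-": ScoreDistribution(rev, cfg.bin_width)}
    L = pwm.length
    out = {}
    for name, seq in seqs.items():
        enc = encode_sequence(seq)
        rows = []
        n_win = len(enc) - L + 1
        if n_win > 0:
            valid = np.ones(n_win, dtype=bool)
            bad = np.nonzero(enc < 0)[0]
            for b in bad:
                lo = max(0, b - L + 1)
                valid[lo : b + 1] = False
            for strand, dist in dists.items():
                scores = np.zeros(n_win, dtype=np.int64)
                enc_safe = np.where(enc < 0, 0, enc)
                for j in range(L):
                    scores += dist.int_scores[enc_safe[j : j + n_win], j]
                thr = dist.score_threshold(cfg.p_threshold)
                hits = np.nonzero(valid & (scores >= thr))[0]
                for i in hits:
                    rows.append(
                        (
                            int(i),
                            strand,
                            scores[i] * cfg.bin_width,
                            dist.pvalue(int(scores[i])),
                        )
                    )
        out[name] = pd.DataFrame(rows, columns=["position", "strand", "score", "p"])
    return out


# ---------------------------------------------------------------------------
# enrichment


def _hit_counts(matches: dict[str, pd.DataFrame], mode: str) -> tuple[int, int]:
    if mode == "binary":
        hits = sum(1 for df in matches.values() if len(df) > 0)
    else:
        hits = sum(len(df) for df in matches.values())
    return hits, len(matches)


def motif_enrichment(
    fg: dict[str, str],
    bg: dict[str, str],
    pwms: list[PWM],
    cfg: TFBSConfig = TFBSConfig(),
) -> pd.DataFrame:
    """Per-motif chi-squared enrichment of foreground vs outgroup.

    Each motif contributes a 2x2 table of (sequence has >= 1 match vs
    not) x (foreground vs outgroup); Pearson chi-squared without
    continuity correction, BH-adjusted across motifs.  A zero margin
    leaves the statistic undefined (NaN with a reason).
    """
    if not fg or not bg:
        raise ValueError("foreground and outgroup must both be non-empty")
    overlap = set(fg) & set(bg)
    if overlap:
        raise ValueError(f"foreground and outgroup share sequence(s): {sorted(overlap)[:3]}")
    background = (
        estimate_background({**fg, **bg}) if cfg.background == "seqs" else np.full(4, 0.25)
    )
    rows = []
    for pwm in pwms:
        fg_matches = scan_sequences(fg, pwm, cfg, background=background)
        bg_matches = scan_sequences(bg, pwm, cfg, background=background)
        fg_hits, fg_total = _hit_counts(fg_matches, cfg.hit_mode)
        bg_hits, bg_total = _hit_counts(bg_matches, cfg.hit_mode)
        table = np.array(
            [[fg_hits, fg_total - fg_hits], [bg_hits, bg_total - bg_hits]], dtype=float
        )
        chi2, p = chi2_2x2(table)
        # Haldane-corrected proportions keep the fold change finite
        pf = (fg_hits + 0.5) / (fg_total + 1.0)
        pb = (bg_hits + 0.5) / (bg_total + 1.0)
        rows.append(
            {
                "motif_id": pwm.motif_id,
                "fg_hits": fg_hits,
                "fg_total": fg_total,
                "bg_hits": bg_hits,
                "bg_total": bg_total,
                "log2_fc": np.log2(pf / pb),
                "chi2": chi2,
                "p": p,
                "note": "" if np.isfinite(chi2) else "zero margin",
            }
        )
    out = pd.DataFrame(rows).set_index("motif_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def extract_flanks(
    sites: pd.DataFrame,
    genome: dict[str, str],
    flank: int = 50,
) -> tuple[dict[str, str], pd.Series]:
    """Extract [pos-flank, pos+flank) windows around cytosines.

    ``sites`` needs chrom and pos (0-based) columns.  Windows are
    truncated at chromosome ends; truncation is flagged.  Sites on
    chromosomes absent from the genome raise.
    """
    seqs: dict[str, str] = {}
    truncated = {}
    for i, (chrom, pos) in enumerate(zip(sites["chrom"], sites["pos"])):
        if chrom not in genome:
            raise ValueError(f"site on unknown chromosome {chrom!r}")
        ref = genome[chrom]
        lo = max(0, int(pos) - flank)
        hi = min(len(ref), int(pos) + flank)
        name = f"{chrom}:{int(pos)}#{i}"
        seqs[name] = ref[lo:hi]
        truncated[name] = (hi - lo) < 2 * flank
    return seqs, pd.Series(truncated)


def cpg_flank_enrichment(
    dm_sites: pd.DataFrame,
    non_dm_sites: pd.DataFrame,
    genome: dict[str, str],
    pwms: list[PWM],
    cfg: TFBSConfig = TFBSConfig(),
) -> pd.DataFrame:
    """Motif enrichment in flanks of differentially methylated CpGs.

    The 100-bp windows (50 bp each side) around DM promoter CpGs form
    the foreground; flanks of non-DM promoter CpGs are the outgroup.
    """
    fg, _ = extract_flanks(dm_sites, genome, cfg.flank)
    bg, _ = extract_flanks(non_dm_sites, genome, cfg.flank)
    bg = {f"bg|{k}": v for k, v in bg.items()}
    fg = {f"fg|{k}": v for k, v in fg.items()}
    return motif_enrichment(fg, bg, pwms, cfg)
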