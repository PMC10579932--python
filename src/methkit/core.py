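"""Context classification and methylation-level arithmetic.

The central quantity throughout is the *weighted methylation level*

    Rm = Nm / (Nm + Nnm)

where Nm is the pooled count of reads supporting methylation and Nnm the
pooled count of reads supporting non-methylation, summed over every covered
cytosine of one sequence context (CG, CHG or CHH; H = A, C or T) inside a
region.  Pooling read counts — rather than averaging per-site fractions —
weights each site by its coverage and makes the level exactly additive over
disjoint intervals.

This module also provides the gene-feature decomposition (upstream 2 kb,
first/internal/last exon, first/internal intron, downstream 2 kb, promoter,
gene body), the 7-mer sequence-preference table, the per-site
degree-of-difference score log2(Rm1)/log2(Rm2), genome-wide context
proportions, and row normalisation for time-course feature tracks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONTEXTS, GeneModel, GenomicInterval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Feature labels produced by :func:`partition_gene`, in 5'→3' display order.
GENE_FEATURES = (
    "upstream",
    "first_exon",
    "first_intron",
    "internal_exon",
    "internal_intron",
    "last_exon",
    "downstream",
)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RegionMethylation:
    """Pooled methylation counts and weighted level for one region × context.

    ``level`` is ``None`` when the region contains no covered site of the
    requested context (undefined rather than zero).
    """

    interval: GenomicInterval
    context: str
    n_sites: int
    n_meth: int
    n_unmeth: int

    @property
    def level(self) -> float | None:
        total = self.n_meth + self.n_unmeth
        if total == 0:
            return None
        return self.n_meth / total


@dataclass(frozen=True)
class DifferenceScore:
    """Degree-of-difference between two methylation levels.

    ``score = log2(Rm1) / log2(Rm2)`` with any zero input replaced by 0.001
    before the logs.  When the denominator level equals 1 after substitution
    (log2 = 0) the score is flagged infinite rather than raising.
    """

    rm1: float
    rm2: float
    score: float

    @property
    def finite(self) -> bool:
        return math.isfinite(self.score)


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def classify_context(
    genome: Mapping[str, str], chrom: str, pos: int, strand: str
) -> str | None:
    """Classify the sequence context of the cytosine at (chrom, pos, strand).

    ``pos`` is 1-based.  The context is read 3' of the cytosine on its own
    strand: CG if the next base is G, else CHG if the base after that is G,
    else CHH.  Returns ``None`` (undefined) when a needed base is N or lies
    beyond the contig end.  Raises ``ValueError`` if the base at the given
    position is not a cytosine on the given strand.
    """
    seq = genome[chrom]
    i = pos - 1
    if i < 0 or i >= len(seq):
        raise ValueError(f"position {chrom}:{pos} outside contig")
    base = seq[i].upper()
    if strand == "+":
        if base != "C":
            raise ValueError(f"{chrom}:{pos}+ is {base}, not C")
        b1 = seq[i + 1].upper() if i + 1 < len(seq) else None
        b2 = seq[i + 2].upper() if i + 2 < len(seq) else None
    elif strand == "-":
        if base != "G":
            raise ValueError(f"{chrom}:{pos}- is not a minus-strand C")
        b1 = seq[i - 1].upper().translate(_COMPLEMENT) if i - 1 >= 0 else None
        b2 = seq[i - 2].upper().translate(_COMPLEMENT) if i - 2 >= 0 else None
    else:
        raise ValueError(f"invalid strand {strand!r}")

    if b1 is None or b1 == "N":
        return None
    if b1 == "G":
        return "CG"
    if b2 is None or b2 == "N":
        return None
    if b2 == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# region-level arithmetic
# ---------------------------------------------------------------------------

def _in_interval_mask(
    calls: pd.DataFrame, interval: GenomicInterval
) -> pd.Series:
    # 1-based pos p lies in the 0-based half-open [start, end) iff
    # start + 1 <= p <= end.
    return (
        (calls["chrom"] == interval.chrom)
        & (calls["pos"] >= interval.start + 1)
        & (calls["pos"] <= interval.end)
    )


def region_level(
    calls: pd.DataFrame, interval: GenomicInterval, context: str
) -> RegionMethylation:
    """Pool read counts of one context over an interval.

    A zero-coverage interval yields ``n_sites=0`` and an undefined level.
    """
    sub = calls[_in_interval_mask(calls, interval) & (calls["context"] == context)]
    n_meth = int(sub["n_meth"].sum())
    n_total = int(sub["n_total"].sum())
    return RegionMethylation(
        interval=interval,
        context=context,
        n_sites=len(sub),
        n_meth=n_meth,
        n_unmeth=n_total - n_meth,
    )


def pooled_level(
    calls: pd.DataFrame, intervals: Sequence[GenomicInterval], context: str
) -> RegionMethylation:
    """Pool counts over a set of intervals, counting shared sites once.

    Overlapping intervals (e.g. the same feature from two gene models) are
    merged per chromosome before pooling so no site is double-counted.
    """
    merged = merge_intervals(intervals)
    sub = calls[calls["context"] == context]
    n_sites = n_meth = n_total = 0
    for chrom, grp in sub.groupby("chrom", sort=False):
        ivs = [iv for iv in merged if iv.chrom == chrom]
        if not ivs:
            continue
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos = grp["pos"].to_numpy()[order]
        cm = np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy()[order])])
        ct = np.concatenate([[0], np.cumsum(grp["n_total"].to_numpy()[order])])
        for iv in ivs:
            i = np.searchsorted(pos, iv.start + 1, side="left")
            j = np.searchsorted(pos, iv.end, side="right")
            n_sites += int(j - i)
            n_meth += int(cm[j] - cm[i])
            n_total += int(ct[j] - ct[i])
    span = merged[0] if merged else GenomicInterval("NA", 0, 1)
    return RegionMethylation(span, context, n_sites, n_meth, n_total - n_meth)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals per chromosome."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return out


# ---------------------------------------------------------------------------
# gene feature partition
# ---------------------------------------------------------------------------

def partition_gene(
    gene: GeneModel, flank: int = 2000, chrom_len: int | None = None
) -> dict[str, list[GenomicInterval]]:
    """Decompose a transcript into labelled features.

    With E exons: ``first_exon`` is exon 1 (transcription order),
    ``last_exon`` exon E (only when E ≥ 2), ``internal_exon`` exons 2..E−1;
    of the E−1 introns, intron 1 is ``first_intron`` and introns 2..E−1 are
    ``internal_intron``.  ``upstream``/``downstream`` are the *flank*-bp
    regions 5' of the TSS and 3' of the transcript end in transcription
    orientation, clipped at contig bounds.  ``promoter`` is an alias of
    ``upstream`` and ``gene_body`` spans TSS to transcript end.

    Returns a dict mapping feature label to a (possibly empty) list of
    intervals in plus-strand coordinates.
    """
    exons = gene.exons
    if not exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    feats: dict[str, list[GenomicInterval]] = {k: [] for k in GENE_FEATURES}
    chrom = gene.chrom

    feats["first_exon"] = [exons[0]]
    if len(exons) >= 2:
        feats["last_exon"] = [exons[-1]]
    feats["internal_exon"] = list(exons[1:-1])

    # introns between consecutive exons in transcription order
    introns = []
    for a, b in zip(exons, exons[1:]):
        lo, hi = (a.end, b.start) if a.start < b.start else (b.end, a.start)
        introns.append(GenomicInterval(chrom, lo, hi, gene.strand, "intron"))
    if introns:
        feats["first_intron"] = [introns[0]]
        feats["internal_intron"] = introns[1:]

    start, end = gene.start, gene.end
    if gene.strand == "+":
        up = (max(0, start - flank), start)
        down = (end, end + flank)
    else:
        up = (end, end + flank)
        down = (max(0, start - flank), start)
    if chrom_len is not None:
        up = (up[0], min(up[1], chrom_len))
        down = (down[0], min(down[1], chrom_len))
    if up[0] < up[1]:
        feats["upstream"] = [GenomicInterval(chrom, up[0], up[1], gene.strand, "upstream")]
    if down[0] < down[1]:
        feats["downstream"] = [GenomicInterval(chrom, down[0], down[1], gene.strand, "downstream")]

    feats["promoter"] = list(feats["upstream"])
    feats["gene_body"] = [GenomicInterval(chrom, start, end, gene.strand, "gene_body")]
    return feats


def feature_profile(
    calls_by_group: Mapping[str, pd.DataFrame],
    partitions: Sequence[Mapping[str, Sequence[GenomicInterval]]],
    tracks: Mapping[str, Sequence[GenomicInterval]] | None = None,
    context: str = "CG",
) -> pd.DataFrame:
    """Weighted methylation level per feature × sample group.

    ``partitions`` is one :func:`partition_gene` result per gene; ``tracks``
    adds extra genome-wide element classes (e.g. repeats, CpG islands,
    mRNA).  Counts are pooled over all intervals of a label genome-wide
    (weighted pooling, not a mean of per-gene means).  Cells with no covered
    site are NaN.
    """
    if not calls_by_group:
        raise ValueError("at least one sample group is required")
    labels: dict[str, list[GenomicInterval]] = {k: [] for k in GENE_FEATURES}
    for part in partitions:
        for label, ivs in part.items():
            if label in ("promoter", "gene_body"):
                continue
            if label not in labels:
                raise ValueError(f"unknown feature label {label!r}")
            labels[label].extend(ivs)
    for label, ivs in (tracks or {}).items():
        labels[label] = list(ivs)

    rows = {}
    for label, ivs in labels.items():
        row = {}
        for group, calls in calls_by_group.items():
            if not ivs:
                row[group] = np.nan
                continue
            pooled = pooled_level(calls, ivs, context)
            row[group] = np.nan if pooled.level is None else pooled.level
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(calls_by_group)]


def normalize_track(values: Sequence[float]) -> tuple[np.ndarray, bool]:
    """Normalise one feature's levels across time points to fractions.

    Each value is divided by the row sum so the output sums to 1.  Returns
    ``(fractions, defined)``; an all-zero row comes back unchanged with
    ``defined=False``.  Negative input raises ``ValueError``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one time point")
    if (arr < 0).any():
        raise ValueError("negative methylation level in track")
    total = arr.sum()
    if total == 0:
        return arr.copy(), False
    return arr / total, True


# ---------------------------------------------------------------------------
# k-mer sequence preference
# ---------------------------------------------------------------------------

def kmer_preference(
    calls: pd.DataFrame,
    genome: Mapping[str, str],
    k: int = 7,
    center: int = 4,
    statistic: str = "weighted",
    min_coverage: int = 4,
) -> tuple[pd.DataFrame, int]:
    """Methylation preference of the k-mer flanking each covered cytosine.

    For every covered site the *k*-mer read on the site's own strand, with
    the cytosine at 1-based position *center* (default: 3 bases 5', the C,
    3 bases 3'), is looked up in the genome.  Sites whose flanks run off the
    contig or contain N are excluded and tallied.

    ``statistic`` selects the per-k-mer level: ``"weighted"`` pools read
    counts (Nm/(Nm+Nnm)); ``"site_fraction"`` reports the fraction of sites
    methylated (≥1 methylated read at coverage ≥ *min_coverage*).

    Returns ``(table, n_excluded)`` where the table has columns
    kmer/context/n_sites/level sorted by (context, kmer).
    """
    if not 1 <= center <= k:
        raise ValueError("center must lie within the k-mer")
    if statistic not in ("weighted", "site_fraction"):
        raise ValueError(f"unknown statistic {statistic!r}")
    left = center - 1
    right = k - center

    kmers = np.empty(len(calls), dtype=object)
    keep = np.zeros(len(calls), dtype=bool)
    seqs = {c: genome[c] for c in calls["chrom"].unique()}
    for idx, (chrom, pos, strand) in enumerate(
        zip(calls["chrom"], calls["pos"], calls["strand"])
    ):
        seq = seqs[chrom]
        i = pos - 1
        if strand == "+":
            lo, hi = i - left, i + right + 1
        else:
            lo, hi = i - right, i + left + 1
        if lo < 0 or hi > len(seq):
            continue
        mer = seq[lo:hi]
        if strand == "-":
            mer = revcomp(mer)
        if "N" in mer:
            continue
        if mer[center - 1] != "C":
            raise ValueError(
                f"call at {chrom}:{pos}{strand} is not a cytosine in the genome"
            )
        kmers[idx] = mer
        keep[idx] = True

    n_excluded = int((~keep).sum())
    sub = calls.loc[keep].copy()
    sub["kmer"] = kmers[keep]
    if statistic == "weighted":
        grouped = sub.groupby(["kmer", "context"], sort=True).agg(
            n_sites=("pos", "size"),
            n_meth=("n_meth", "sum"),
            n_total=("n_total", "sum"),
        )
        grouped["level"] = grouped["n_meth"] / grouped["n_total"]
        table = grouped.reset_index()[["kmer", "context", "n_sites", "level"]]
    else:
        sub["is_meth"] = (sub["n_meth"] >= 1) & (sub["n_total"] >= min_coverage)
        grouped = sub.groupby(["kmer", "context"], sort=True).agg(
            n_sites=("pos", "size"), level=("is_meth", "mean")
        )
        table = grouped.reset_index()
    table = table.sort_values(["context", "kmer"], kind="stable").reset_index(drop=True)
    return table, n_excluded


# ---------------------------------------------------------------------------
# degree of difference
# ---------------------------------------------------------------------------

ZERO_SUBSTITUTE = 0.001


def degree_of_difference(rm1: float, rm2: float) -> DifferenceScore:
    """Per-region comparison score log2(Rm1)/log2(Rm2).

    ``rm1`` is the control-group level, ``rm2`` the comparison group.  A
    zero input is replaced by 0.001 before taking logs.  When the
    denominator level is 1 (log2 = 0) the score is +/-inf and flagged via
    :attr:`DifferenceScore.finite`.
    """
    for v in (rm1, rm2):
        if not 0 <= v <= 1:
            raise ValueError(f"methylation level {v} outside [0, 1]")
    a = rm1 if rm1 > 0 else ZERO_SUBSTITUTE
    b = rm2 if rm2 > 0 else ZERO_SUBSTITUTE
    num = math.log2(a)
    den = math.log2(b)
    if den == 0:
        score = math.inf if num != 0 else 1.0
    else:
        score = num / den
    return DifferenceScore(rm1=rm1, rm2=rm2, score=score)


# ---------------------------------------------------------------------------
# context proportions
# ---------------------------------------------------------------------------

def context_proportions(
    calls: pd.DataFrame, min_coverage: int = 4, min_meth: int = 1
) -> pd.Series | None:
    """Shares of mCG/mCHG/mCHH among methylated sites, in percent.

    A site counts as methylated when it has at least ``min_meth`` methylated
    reads at coverage ≥ ``min_coverage`` (the rule is a convention, not a
    statistical test — pluggable via the two thresholds).  Returns a Series
    indexed CG/CHG/CHH summing to 100, or ``None`` when no site qualifies.
    """
    meth = calls[(calls["n_total"] >= min_coverage) & (calls["n_meth"] >= min_meth)]
    if meth.empty:
        return None
    counts = meth["context"].value_counts().reindex(list(CONTEXTS), fill_value=0)
    return 100.0 * counts / counts.sum()


# ---------------------------------------------------------------------------
# chromosome methylation map
# ---------------------------------------------------------------------------

def chromosome_map(
    calls: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    context: str = "CG",
    window: int = 10_000,
    scale: float = 20.0,
) -> pd.DataFrame:
    """Per-tile weighted levels for chromosome-scale methylation maps.

    The genome is tiled into non-overlapping *window*-bp tiles and the
    weighted level of each tile is rendered on a 0–``scale`` colour scale
    (level × scale; presentational only).  Tiles without coverage get NaN.
    Returns a frame with chrom/start/end/value suitable for
    :func:`methkit.io.write_track` after dropping NaN rows.
    """
    sub = calls[calls["context"] == context]
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_win = -(-size // window)
        cc = sub[sub["chrom"] == chrom]
        win = (cc["pos"].to_numpy() - 1) // window
        meth = np.bincount(win, weights=cc["n_meth"].to_numpy(), minlength=n_win)
        total = np.bincount(win, weights=cc["n_total"].to_numpy(), minlength=n_win)
        with np.errstate(invalid="ignore"):
            level = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
        for w in range(n_win):
            rows.append(
                (chrom, w * window, min((w + 1) * window, size), level[w] * scale)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
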