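"""Windowed two-group DMR detection with iterative merging.

The genome is tiled into non-overlapping windows (default 1 kb).  A window
is a putative differentially methylated region (DMR) between two sample
groups when, for one context, it has at least ``min_sites`` covered
cytosines in *each* group, at least a ``min_fold`` change in weighted
methylation level, a two-sided Fisher exact P below ``alpha`` on the pooled
2×2 read-count table, and neither group is hypomethylated (both weighted
levels ≥ ``floor``; an "either" reading of that rule is available).

Neighbouring passing windows (same chromosome, context and direction of
change, gap ≤ ``max_gap``) are *interdependent* when the pooled counts over
the whole span — from the beginning of the upstream region to the end of
the downstream one — still satisfy the fold, P and floor criteria; such
pairs are combined into one continuous DMR.  Merging is repeated
left-to-right until a full pass makes no change, so the final DMR set is a
fixed point: no neighbouring pair in it satisfies the merge criterion.

No multiple-testing correction is applied by default (raw P < alpha);
Benjamini–Hochberg adjustment is available as an option for users who want
it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import GeneModel, GenomicInterval

#: relative tolerance when comparing table probabilities to the observed one
#: in the two-sided Fisher test (absorbs floating-point noise in ties)
_FISHER_REL_TOL = 1e-7

WINDOW_COLUMNS = [
    "chrom", "start", "end", "context",
    "n_sites_1", "n_sites_2", "Nm1", "Nnm1", "Nm2", "Nnm2",
    "Rm1", "Rm2", "fold", "p", "eligible", "passed",
]

DMR_COLUMNS = [
    "chrom", "start", "end", "context", "direction",
    "n_sites_1", "n_sites_2", "Nm1", "Nnm1", "Nm2", "Nnm2",
    "Rm1", "Rm2", "fold", "p", "merged_from",
]


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for the 2×2 table [[a, b], [c, d]].

    Rows are groups, columns (methylated, unmethylated) pooled read counts.
    The P-value is the sum of hypergeometric probabilities of all tables
    with the same margins whose probability is ≤ that of the observed table
    (within a relative tolerance of 1e-7).  An all-zero margin yields P = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in 2x2 table")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(r2 + 1) - gammaln(c1 - support + 1)
        - gammaln(r2 - c1 + support + 1)
    )
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    p_obs = pmf[a - lo]
    p = pmf[pmf <= p_obs * (1.0 + _FISHER_REL_TOL)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# per-(chrom, context) count index for fast span queries
# ---------------------------------------------------------------------------

class _CallIndex:
    """Sorted positions + cumulative counts of one group's calls."""

    def __init__(self, calls: pd.DataFrame):
        self._by_key: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for (chrom, context), sub in calls.groupby(["chrom", "context"], sort=False):
            sub = sub.sort_values("pos", kind="stable")
            pos = sub["pos"].to_numpy()
            cm = np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy())])
            ct = np.concatenate([[0], np.cumsum(sub["n_total"].to_numpy())])
            self._by_key[(chrom, context)] = (pos, cm, ct)

    def span(self, chrom: str, context: str, start: int, end: int):
        """(n_sites, n_meth, n_unmeth) over 0-based half-open [start, end)."""
        entry = self._by_key.get((chrom, context))
        if entry is None:
            return 0, 0, 0
        pos, cm, ct = entry
        i = np.searchsorted(pos, start + 1, side="left")
        j = np.searchsorted(pos, end, side="right")
        n_meth = int(cm[j] - cm[i])
        n_total = int(ct[j] - ct[i])
        return int(j - i), n_meth, n_total - n_meth


def _level(n_meth: int, n_unmeth: int) -> float:
    total = n_meth + n_unmeth
    return n_meth / total if total else np.nan


def _fold(rm1: float, rm2: float, floor: float) -> float:
    """Fold change between weighted levels with *floor* as pseudo-level.

    Flooring both levels at *floor* prevents division by zero while leaving
    genuine differences above the floor untouched.
    """
    lo = min(max(rm1, floor), max(rm2, floor))
    hi = max(max(rm1, floor), max(rm2, floor))
    return hi / lo


def _hypo_ok(rm1: float, rm2: float, floor: float, rule: str) -> bool:
    if rule == "both":
        return rm1 >= floor and rm2 >= floor
    if rule == "either":
        return rm1 >= floor or rm2 >= floor
    raise ValueError(f"unknown hypomethylation rule {rule!r}")


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------

def window_scan(
    calls_g1: pd.DataFrame,
    calls_g2: pd.DataFrame,
    context: str,
    window_bp: int = 1000,
    min_sites: int = 5,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    floor: float = 0.05,
    hypo_rule: str = "both",
    chrom_sizes: Mapping[str, int] | None = None,
    step: int | None = None,
) -> pd.DataFrame:
    """Scan the genome in windows and test each for differential methylation.

    Group 1 is the control.  Windows are non-overlapping ``window_bp`` tiles
    by default; passing ``step`` (e.g. ``window_bp // 2``) turns on a
    sliding scan.  Only windows covered in at least one group are returned.
    The Fisher P is computed for *eligible* windows (site filter met in both
    groups); ``passed`` additionally requires the fold, floor and alpha
    criteria.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step = step or window_bp
    c1 = calls_g1[calls_g1["context"] == context]
    c2 = calls_g2[calls_g2["context"] == context]

    if chrom_sizes is None:
        chrom_sizes = {}
        for df in (c1, c2):
            for chrom, sub in df.groupby("chrom"):
                size = int(sub["pos"].max())
                chrom_sizes[chrom] = max(size, chrom_sizes.get(chrom, 0))

    idx1, idx2 = _CallIndex(c1), _CallIndex(c2)
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size, step):
            end = min(start + window_bp, size)
            s1, m1, u1 = idx1.span(chrom, context, start, end)
            s2, m2, u2 = idx2.span(chrom, context, start, end)
            if s1 + s2 == 0:
                continue
            rm1, rm2 = _level(m1, u1), _level(m2, u2)
            eligible = s1 >= min_sites and s2 >= min_sites
            fold = _fold(rm1, rm2, floor) if eligible else np.nan
            p = fisher_exact_two_sided(m1, u1, m2, u2) if eligible else np.nan
            passed = bool(
                eligible
                and fold >= min_fold
                and p < alpha
                and _hypo_ok(rm1, rm2, floor, hypo_rule)
            )
            rows.append(
                (chrom, start, end, context, s1, s2, m1, u1, m2, u2,
                 rm1, rm2, fold, p, eligible, passed)
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


# ---------------------------------------------------------------------------
# interdependent-DMR merging
# ---------------------------------------------------------------------------

@dataclass
class _Region:
    chrom: str
    start: int
    end: int
    context: str
    direction: str
    n_sites_1: int
    n_sites_2: int
    Nm1: int
    Nnm1: int
    Nm2: int
    Nnm2: int
    Rm1: float
    Rm2: float
    fold: float
    p: float
    merged_from: int = 1


def _evaluate_span(
    idx1: _CallIndex,
    idx2: _CallIndex,
    chrom: str,
    context: str,
    start: int,
    end: int,
    min_sites: int,
    min_fold: float,
    alpha: float,
    floor: float,
    hypo_rule: str,
) -> tuple[_Region | None, bool]:
    """Pool counts over a span and test the DMR criteria on them."""
    s1, m1, u1 = idx1.span(chrom, context, start, end)
    s2, m2, u2 = idx2.span(chrom, context, start, end)
    rm1, rm2 = _level(m1, u1), _level(m2, u2)
    if np.isnan(rm1) or np.isnan(rm2):
        return None, False
    fold = _fold(rm1, rm2, floor)
    p = fisher_exact_two_sided(m1, u1, m2, u2)
    direction = "hyper" if rm2 >= rm1 else "hypo"
    region = _Region(
        chrom, start, end, context, direction,
        s1, s2, m1, u1, m2, u2, rm1, rm2, fold, p,
    )
    ok = (
        s1 >= min_sites
        and s2 >= min_sites
        and fold >= min_fold
        and p < alpha
        and _hypo_ok(rm1, rm2, floor, hypo_rule)
    )
    return region, ok


def merge_interdependent(
    windows: pd.DataFrame,
    calls_g1: pd.DataFrame,
    calls_g2: pd.DataFrame,
    max_gap: int = 1000,
    min_sites: int = 5,
    min_fold: float = 2.0,
    alpha: float = 0.05,
    floor: float = 0.05,
    hypo_rule: str = "both",
) -> pd.DataFrame:
    """Iteratively combine interdependent neighbouring DMRs.

    ``windows`` is the output of :func:`window_scan` (only rows with
    ``passed`` are used).  Two neighbouring DMRs — same chromosome, context
    and direction, consecutive in position, separated by at most ``max_gap``
    bp — are combined when the pooled counts over the full span, recomputed
    from the raw calls, still satisfy the fold, P and floor criteria.  The
    pass restarts after every merge and repeats to a fixed point, so the
    returned set is pairwise non-mergeable.  The operation is idempotent.
    """
    passing = windows[windows["passed"]] if "passed" in windows else windows
    idx1 = _CallIndex(calls_g1)
    idx2 = _CallIndex(calls_g2)

    groups: dict[tuple[str, str], list[_Region]] = {}
    for row in passing.itertuples(index=False):
        direction = getattr(row, "direction", None) or (
            "hyper" if row.Rm2 >= row.Rm1 else "hypo"
        )
        region = _Region(
            row.chrom, int(row.start), int(row.end), row.context, direction,
            int(row.n_sites_1), int(row.n_sites_2),
            int(row.Nm1), int(row.Nnm1), int(row.Nm2), int(row.Nnm2),
            float(row.Rm1), float(row.Rm2), float(row.fold), float(row.p),
            int(getattr(row, "merged_from", 1)),
        )
        groups.setdefault((row.chrom, row.context), []).append(region)

    criteria = dict(
        min_sites=min_sites, min_fold=min_fold, alpha=alpha,
        floor=floor, hypo_rule=hypo_rule,
    )

    final: list[_Region] = []
    for key in sorted(groups):
        items = sorted(groups[key], key=lambda r: r.start)
        merged_any = True
        while merged_any:
            merged_any = False
            for i in range(len(items) - 1):
                a, b = items[i], items[i + 1]
                if a.direction != b.direction or b.start - a.end > max_gap:
                    continue
                span, ok = _evaluate_span(
                    idx1, idx2, a.chrom, a.context, a.start, b.end, **criteria
                )
                if ok and span.direction == a.direction:
                    span.merged_from = a.merged_from + b.merged_from
                    items[i:i + 2] = [span]
                    merged_any = True
                    break  # restart the left-to-right pass
        final.extend(items)

    rows = [
        (r.chrom, r.start, r.end, r.context, r.direction,
         r.n_sites_1, r.n_sites_2, r.Nm1, r.Nnm1, r.Nm2, r.Nnm2,
         r.Rm1, r.Rm2, r.fold, r.p, r.merged_from)
        for r in sorted(final, key=lambda r: (r.chrom, r.start, r.context))
    ]
    return pd.DataFrame(rows, columns=DMR_COLUMNS)


# ---------------------------------------------------------------------------
# tallies and gene assignment
# ---------------------------------------------------------------------------

def count_dmrs(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Tally DMRs per context × direction (plus a total row)."""
    if dmrs.empty:
        return pd.DataFrame(columns=["context", "direction", "n"])
    tally = (
        dmrs.groupby(["context", "direction"], sort=True)
        .size()
        .reset_index(name="n")
    )
    return tally


def assign_dmgs(
    dmrs: pd.DataFrame,
    genes: Sequence[GeneModel],
    promoter_len: int = 2000,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assign DMRs to genes (DMG = DMR-associated gene).

    A gene is a *gene-body* DMG when ≥1 DMR overlaps its TSS-to-transcript-
    end span by at least 1 bp, and a *promoter* DMG when ≥1 DMR overlaps the
    ``promoter_len``-bp region immediately upstream of the TSS.  One gene
    may be both.  Returns the per-overlap record table and the tallies of
    distinct genes per location.
    """
    records = []
    for gene in genes:
        body = GenomicInterval(gene.chrom, gene.start, gene.end)
        if gene.strand == "+":
            p_start, p_end = max(0, gene.start - promoter_len), gene.start
        else:
            p_end = gene.end + promoter_len
            if chrom_sizes and gene.chrom in chrom_sizes:
                p_end = min(p_end, chrom_sizes[gene.chrom])
            p_start = gene.end
        promoter = (
            GenomicInterval(gene.chrom, p_start, p_end) if p_start < p_end else None
        )
        sub = dmrs[dmrs["chrom"] == gene.chrom]
        for row in sub.itertuples(index=False):
            for location, region in (("gene_body", body), ("promoter", promoter)):
                if region is None:
                    continue
                if row.start < region.end and row.end > region.start:
                    records.append(
                        (gene.gene_id, location, row.chrom, row.start, row.end,
                         row.context, row.direction, row.Rm1, row.Rm2, row.p)
                    )
    table = pd.DataFrame(
        records,
        columns=["gene_id", "location", "chrom", "start", "end",
                 "context", "direction", "Rm1", "Rm2", "p"],
    )
    tallies = {
        loc: int(table.loc[table["location"] == loc, "gene_id"].nunique())
        for loc in ("gene_body", "promoter")
    }
    return table, tallies


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED6: name=context:direction, score=-log10(p) capped at 100."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for row in dmrs.sort_values(["chrom", "start"]).itertuples(index=False):
            score = min(100.0, -np.log10(max(row.p, 1e-300)))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t"
                f"{row.context}:{row.direction}\t{score:.4g}\t.\n"
            )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional output column)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
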