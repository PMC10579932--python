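"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by the most direct method available —
exact enumeration, naive string scanning, direct recounting — with no code
shared with the implementation it checks.
"""

from __future__ import annotations

from math import comb

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher P by exact enumeration of all same-margin tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    denom = comb(n, c1)
    probs = [comb(r1, x) * comb(r2, c1 - x) / denom for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def context_scan(seq: str, pos: int, strand: str) -> str | None:
    """Context of the cytosine at 1-based pos by scanning the strand's own
    sequence (reverse complement of the whole contig for the minus strand)."""
    if strand == "-":
        s = revcomp(seq.upper())
        i = len(seq) - pos
    else:
        s = seq.upper()
        i = pos - 1
    assert s[i] == "C", "not a cytosine on the requested strand"
    tail = s[i + 1:i + 3]
    if len(tail) < 1 or tail[0] == "N":
        return None
    if tail[0] == "G":
        return "CG"
    if len(tail) < 2 or tail[1] == "N":
        return None
    if tail[1] == "G":
        return "CHG"
    return "CHH"


def kmer_recount(calls, genome, k: int = 7, center: int = 4):
    """Naive per-site recount of the k-mer preference table.

    Returns ({(kmer, context): (n_sites, n_meth, n_total)}, n_excluded).
    """
    left, right = center - 1, k - center
    table: dict[tuple[str, str], list[int]] = {}
    excluded = 0
    for row in calls.itertuples(index=False):
        seq = genome[row.chrom].upper()
        i = row.pos - 1
        if row.strand == "+":
            lo, hi = i - left, i + right + 1
        else:
            lo, hi = i - right, i + left + 1
        if lo < 0 or hi > len(seq):
            excluded += 1
            continue
        mer = seq[lo:hi]
        if row.strand == "-":
            mer = revcomp(mer)
        if "N" in mer:
            excluded += 1
            continue
        entry = table.setdefault((mer, row.context), [0, 0, 0])
        entry[0] += 1
        entry[1] += row.n_meth
        entry[2] += row.n_total
    return {k_: tuple(v) for k_, v in table.items()}, excluded


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric P(X >= k) by summing exact binomials."""
    denom = comb(N, n)
    return sum(
        comb(K, x) * comb(N - K, n - x)
        for x in range(k, min(K, n) + 1)
        if n - x <= N - K
    ) / denom
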