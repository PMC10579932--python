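"""Bisulfite-sequencing-PCR (BSP) clone analysis.

After bisulfite treatment, unmethylated cytosines read as T while
methylated cytosines remain C.  Sequencing ~10 cloned amplicons per sample
therefore reads out the methylation state of every CpG in the amplicon, one
molecule per clone.  This module re-implements the core of that clone
analysis: a bisulfite-aware global alignment of each clone against the
reference amplicon (a clone T opposite a reference C is a legitimate
conversion, not a mismatch), per-CpG methylation calls, a conversion-rate
QC based on non-CpG cytosines, and the clone × CpG "lollipop" matrix with
per-position summaries.

Only the top (primer-defined) strand is modelled: BSP primers select one
strand of the converted template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import revcomp

logger = logging.getLogger(__name__)

MISSING = "."


class CloneRejectedError(ValueError):
    """Clone could not be aligned confidently to the reference amplicon."""


@dataclass
class CloneRead:
    """One sequenced clone of a bisulfite-converted amplicon."""

    clone_id: str
    sequence: str
    conversion_rate: float | None = None
    qc_pass: bool | None = None


@dataclass
class CloneCalls:
    """Per-CpG methylation calls for one aligned clone."""

    clone_id: str
    calls: list[str]  # 'M', 'U' or '.' per reference CpG
    conversion_rate: float
    qc_pass: bool
    identity: float
    reverse_complemented: bool


@dataclass
class MethylationMatrix:
    """QC-passing clones × reference CpG positions.

    ``cpg_positions`` are 0-based offsets of the CpG cytosines in the
    reference amplicon; ``cells[i][j]`` is 'M', 'U' or '.' (missing);
    ``column_summary[j]`` is methylated/(methylated+unmethylated) over
    clones, NaN when no clone informs the position.
    """

    cpg_positions: list[int]
    clone_ids: list[str]
    cells: np.ndarray
    column_summary: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n_meth = (self.cells == "M").sum(axis=0)
        n_unmeth = (self.cells == "U").sum(axis=0)
        with np.errstate(invalid="ignore"):
            self.column_summary = np.where(
                n_meth + n_unmeth > 0,
                n_meth / np.maximum(n_meth + n_unmeth, 1),
                np.nan,
            )


def find_cpg_positions(reference: str) -> list[int]:
    """0-based positions of CpG cytosines on the top strand."""
    ref = reference.upper()
    return [i for i in range(len(ref) - 1) if ref[i] == "C" and ref[i + 1] == "G"]


# ---------------------------------------------------------------------------
# in-silico bisulfite conversion (simulator)
# ---------------------------------------------------------------------------

def bisulfite_convert(
    reference: str,
    pattern,
    conversion_rate: float = 1.0,
    n_clones: int = 10,
    seed: int = 0,
) -> tuple[list[CloneRead], np.ndarray]:
    """Simulate bisulfite-converted clones of an amplicon.

    ``pattern`` gives the methylation probability of each CpG (one value
    per CpG position).  Per clone, each CpG cytosine is methylated with its
    pattern probability; methylated Cs stay C, while unmethylated Cs and
    all non-CpG Cs convert C→T with probability ``conversion_rate``.

    Returns the clones and the planted truth matrix (clones × CpGs, True =
    methylated).  Deterministic under ``seed``.
    """
    if not 0 <= conversion_rate <= 1:
        raise ValueError("conversion_rate must lie in [0, 1]")
    ref = reference.upper()
    cpgs = find_cpg_positions(ref)
    pattern = np.asarray(pattern, dtype=float)
    if pattern.shape != (len(cpgs),):
        raise ValueError(
            f"pattern length {pattern.size} != number of CpGs {len(cpgs)}"
        )
    rng = np.random.default_rng(seed)
    cpg_set = set(cpgs)
    non_cpg_c = [i for i, b in enumerate(ref) if b == "C" and i not in cpg_set]

    clones = []
    truth = np.zeros((n_clones, len(cpgs)), dtype=bool)
    for ci in range(n_clones):
        seq = list(ref)
        meth = rng.random(len(cpgs)) < pattern
        truth[ci] = meth
        for j, i in enumerate(cpgs):
            if not meth[j] and rng.random() < conversion_rate:
                seq[i] = "T"
        for i in non_cpg_c:
            if rng.random() < conversion_rate:
                seq[i] = "T"
        clones.append(CloneRead(clone_id=f"clone_{ci + 1:03d}", sequence="".join(seq)))
    return clones, truth


# ---------------------------------------------------------------------------
# alignment and calling
# ---------------------------------------------------------------------------

def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = 1.0 if a == b else -1.0
    matrix["C", "T"] = 1.0  # reference C read as T: bisulfite conversion
    for x in "ACGTN":
        matrix["N", x] = 0.0
        matrix[x, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def _align_once(reference: str, query: str):
    """Best global alignment; returns (ref_index -> clone base map, identity)."""
    aligner = _aligner()
    alignment = aligner.align(reference, query)[0]
    indices = alignment.indices  # 2 × n_columns, -1 at gaps
    ref_to_base: dict[int, str] = {}
    matches = 0
    n_cols = indices.shape[1]
    for col in range(n_cols):
        ti, qi = indices[0, col], indices[1, col]
        if ti >= 0 and qi >= 0:
            rb, qb = reference[ti], query[qi]
            ref_to_base[int(ti)] = qb
            if rb == qb or (rb == "C" and qb == "T"):
                matches += 1
    identity = matches / n_cols if n_cols else 0.0
    return ref_to_base, identity


def align_and_call(
    reference: str,
    clone: CloneRead,
    min_conversion: float = 0.95,
    min_identity: float = 0.8,
) -> CloneCalls:
    """Align one clone to the reference amplicon and call its CpGs.

    The alignment is global with bisulfite-aware scoring (clone T opposite
    reference C at zero penalty).  If the direct-orientation identity is
    below 0.5 the reverse complement is tried and the better orientation
    kept.  At each reference CpG a clone C is called methylated, T
    unmethylated, anything else missing.  The conversion rate is the
    fraction of non-CpG reference cytosines read as T; ``qc_pass`` requires
    it to reach ``min_conversion``.  Raises :class:`CloneRejectedError`
    when the bisulfite-aware identity stays below ``min_identity``.
    """
    ref = reference.upper()
    seq = clone.sequence.upper()
    mapping, identity = _align_once(ref, seq)
    used_rc = False
    if identity < 0.5:
        rc_mapping, rc_identity = _align_once(ref, revcomp(seq))
        if rc_identity > identity:
            mapping, identity, used_rc = rc_mapping, rc_identity, True
    if identity < min_identity:
        raise CloneRejectedError(
            f"clone {clone.clone_id}: bisulfite-aware identity "
            f"{identity:.3f} < {min_identity}"
        )

    cpgs = set(find_cpg_positions(ref))
    calls = []
    for i in sorted(cpgs):
        base = mapping.get(i)
        if base == "C":
            calls.append("M")
        elif base == "T":
            calls.append("U")
        else:
            calls.append(MISSING)

    converted = unconverted = 0
    for i, b in enumerate(ref):
        if b == "C" and i not in cpgs:
            base = mapping.get(i)
            if base == "T":
                converted += 1
            elif base == "C":
                unconverted += 1
    rate = converted / (converted + unconverted) if converted + unconverted else 1.0

    clone.conversion_rate = rate
    clone.qc_pass = rate >= min_conversion
    return CloneCalls(
        clone_id=clone.clone_id,
        calls=calls,
        conversion_rate=rate,
        qc_pass=rate >= min_conversion,
        identity=identity,
        reverse_complemented=used_rc,
    )


def build_matrix(
    reference: str,
    clones: list[CloneRead],
    min_conversion: float = 0.95,
    apply_qc: bool = True,
) -> MethylationMatrix:
    """Clone × CpG methylation matrix over QC-passing clones.

    Clones that fail alignment are skipped with a warning; clones below the
    conversion threshold are dropped when ``apply_qc`` is set.  Raises
    ``ValueError`` when no clone survives.  Rows are ordered by clone id.
    """
    results = []
    for clone in clones:
        try:
            res = align_and_call(reference, clone, min_conversion=min_conversion)
        except CloneRejectedError as exc:
            logger.warning("%s", exc)
            continue
        if apply_qc and not res.qc_pass:
            logger.warning(
                "clone %s failed conversion QC (%.3f < %.3f)",
                clone.clone_id, res.conversion_rate, min_conversion,
            )
            continue
        results.append(res)
    if not results:
        raise ValueError("no clone passed alignment and conversion QC")
    results.sort(key=lambda r: r.clone_id)
    cpgs = find_cpg_positions(reference.upper())
    cells = np.array([r.calls for r in results], dtype="<U1")
    return MethylationMatrix(
        cpg_positions=cpgs,
        clone_ids=[r.clone_id for r in results],
        cells=cells,
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def render_lollipop(matrix: MethylationMatrix) -> str:
    """Plain-text lollipop rendering: ● methylated, ○ unmethylated, · missing."""
    glyph = {"M": "●", "U": "○", MISSING: "·"}
    width = max((len(c) for c in matrix.clone_ids), default=0)
    lines = []
    for cid, row in zip(matrix.clone_ids, matrix.cells):
        lines.append(f"{cid:<{width}}  " + " ".join(glyph[c] for c in row))
    summary = " ".join(
        " -" if np.isnan(v) else f"{int(round(100 * v)):2d}"
        for v in matrix.column_summary
    )
    lines.append(f"{'%meth':<{width}}  {summary}")
    return "\n".join(lines)


def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write the clone × CpG matrix as TSV (values M/U/.)."""
    with open(path, "w") as fh:
        header = "clone_id\t" + "\t".join(
            f"cpg_{p + 1}" for p in matrix.cpg_positions
        )
        fh.write(header + "\n")
        for cid, row in zip(matrix.clone_ids, matrix.cells):
            fh.write(cid + "\t" + "\t".join(row) + "\n")
        fh.write(
            "column_summary\t"
            + "\t".join(
                "NA" if np.isnan(v) else f"{v:.4f}" for v in matrix.column_summary
            )
            + "\n"
        )
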