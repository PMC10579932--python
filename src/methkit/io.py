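"""Readers and writers for the text formats the pipeline touches.

Coordinate conventions, applied strictly:

* per-cytosine call files are 1-based (CGmap-style TSV);
* BED and bedGraph files are 0-based half-open;
* the in-memory :class:`GenomicInterval` is 0-based half-open.

All readers validate records against the type invariants and raise
:class:`MalformedRecordError` (with the offending line number) rather than
silently coercing bad input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: Columns of a validated call table, in file order. ``n_unmeth`` is derived
#: on read as ``n_total - n_meth``.
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]


class MalformedRecordError(ValueError):
    """A record in an input file violates a type invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A transcript: exons in transcription order plus the TSS.

    ``exons`` are 0-based half-open intervals; ``exons[0]`` is the 5'-most
    exon on the transcript's own strand.  ``tss`` is the 1-based transcribed
    5' end (feature start on ``+``, feature end on ``-``).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    tss: int = 1

    @property
    def start(self) -> int:
        """0-based start of the transcript span."""
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        """0-based exclusive end of the transcript span."""
        return max(e.end for e in self.exons)


# ---------------------------------------------------------------------------
# per-cytosine call tables
# ---------------------------------------------------------------------------

def read_calls(path: str | Path) -> pd.DataFrame:
    """Read a per-cytosine methylation call table.

    The file is tab-separated with one cytosine per line::

        chrom  pos  strand  context  n_meth  n_total

    where ``pos`` is 1-based, ``context`` is CG/CHG/CHH and
    ``n_total = n_meth + n_unmeth``.  Lines starting with ``#`` are comments.

    Returns a DataFrame with columns ``chrom, pos, strand, context, n_meth,
    n_total, n_unmeth`` sorted by (chrom, pos).  An empty file yields an
    empty frame.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=CALL_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
            },
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CALL_COLUMNS)
    if df.empty:
        out = df.copy()
        out["n_unmeth"] = pd.Series(dtype=int)
        return out.astype(
            {"pos": int, "n_meth": int, "n_total": int, "n_unmeth": int},
            errors="ignore",
        )

    bad = pd.Series(False, index=df.index)
    for col in ("pos", "n_meth", "n_total"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad |= vals.isna()
        df[col] = vals
    bad |= ~df["context"].isin(CONTEXTS)
    bad |= ~df["strand"].isin(["+", "-"])
    bad |= df["pos"] < 1
    bad |= df["n_meth"] < 0
    bad |= df["n_meth"] > df["n_total"]
    if bad.any():
        _raise_with_line_number(path, int(bad.idxmax()))

    df = df.astype({"pos": int, "n_meth": int, "n_total": int})
    df["n_unmeth"] = df["n_total"] - df["n_meth"]
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _raise_with_line_number(path: Path, record_index: int) -> None:
    """Re-scan *path* to map a record index to a 1-based file line number."""
    seen = -1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            seen += 1
            if seen == record_index:
                raise MalformedRecordError(
                    f"{path}, line {lineno}: malformed call record: {line.rstrip()!r}"
                )
    raise MalformedRecordError(f"{path}: malformed call record #{record_index}")


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call table in the format :func:`read_calls` accepts."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CALL_COLUMNS) + "\n")
        calls[CALL_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read transcript models from a GFF3 file.

    One :class:`GeneModel` is produced per mRNA feature.  Exons are converted
    to 0-based half-open intervals and ordered in transcription order (index
    0 is the 5'-most exon, so the order is reversed for minus-strand
    transcripts).  Exons without a resolvable mRNA parent are skipped with a
    logged warning; overlapping exons within one transcript are an error.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except EmptyInputError:
        return []

    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or not any(p in mrna_ids for p in parents):
            logger.warning("exon %s at %s:%d-%d has no mRNA parent; skipped",
                           exon.id, exon.seqid, exon.start, exon.end)

    models = []
    for mrna in db.features_of_type("mRNA"):
        exons = sorted(
            db.children(mrna, featuretype="exon"), key=lambda f: f.start
        )
        ivals = [
            GenomicInterval(mrna.seqid, e.start - 1, e.end, mrna.strand, "exon")
            for e in exons
        ]
        for a, b in zip(ivals, ivals[1:]):
            if b.start < a.end:
                raise MalformedRecordError(
                    f"{path}: overlapping exons in transcript {mrna.id}"
                )
        if mrna.strand == "-":
            ivals = ivals[::-1]
            tss = mrna.end
        else:
            tss = mrna.start
        models.append(
            GeneModel(
                gene_id=mrna.id,
                chrom=mrna.seqid,
                strand=mrna.strand,
                exons=ivals,
                tss=tss,
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.gene_id))
    return models


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene + mRNA + exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda m: (m.chrom, m.start, m.gene_id)):
            start, end = g.start + 1, g.end
            fh.write(
                f"{g.chrom}\tmethkit\tgene\t{start}\t{end}\t.\t{g.strand}\t."
                f"\tID=gene:{g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tmethkit\tmRNA\t{start}\t{end}\t.\t{g.strand}\t."
                f"\tID={g.gene_id};Parent=gene:{g.gene_id}\n"
            )
            for i, e in enumerate(sorted(g.exons, key=lambda x: x.start), 1):
                fh.write(
                    f"{g.chrom}\tmethkit\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def write_regions(regions: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (0-based half-open), sorted by (chrom, start)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for iv in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t"
                f"{iv.strand}\n"
            )


def read_regions(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file into a list of :class:`GenomicInterval`.

    Only the first six columns are used; missing name/strand default to
    ``''``/``'.'``.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise MalformedRecordError(f"{path}, line {lineno}: short BED line")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, label))
            except ValueError as exc:
                raise MalformedRecordError(f"{path}, line {lineno}: {exc}") from exc
    return sorted(out, key=lambda r: (r.chrom, r.start, r.end))


def write_track(track: pd.DataFrame, path: str | Path) -> None:
    """Write a bedGraph file from a frame with chrom/start/end/value columns."""
    track = track.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="methkit"\n')
        for row in track.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:g}\n")


def read_track(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph file written by :func:`write_track`."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "track", "browser")) or not line.strip():
                continue
            chrom, start, end, value = line.split("\t")
            rows.append((chrom, int(start), int(end), float(value)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into a dict of upper-case sequences.

    Uses pyfaidx for parsing; the genomes this pipeline handles are small
    enough to hold in memory, which keeps downstream vectorised scans simple.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
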