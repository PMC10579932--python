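"""Synthetic methylome generator with known ground truth.

Produces every input the pipeline needs — a random genome with gene models,
CpG-island and repeat tracks, grouped per-cytosine bisulfite call tables
with planted DMRs, synthetic gene→term maps, and BSP clone reads — entirely
in silico, so the full analysis can be exercised and scored without any
sequencing data.

The methylome model is deliberately simple but mirrors the mosaic
methylation landscape of a bivalve genome:

* each cytosine site is either methylated or not; the probability that a
  site is methylated depends on its sequence context (CG/CHG/CHH) and on
  the genomic feature it falls in (gene body and repeats high, promoter and
  CpG island low for CG; uniformly rare for CHG/CHH);
* a methylated site has a true per-read methylation level of
  ``meth_level`` (default 0.8, allowing for incomplete clonal methylation),
  an unmethylated site a level of ``unmeth_level`` (default 0, i.e.
  complete bisulfite conversion);
* the methylation *state* of each background site is drawn once and shared
  by all sample groups — the groups are the same animals — so between-group
  differences outside planted DMRs come only from read sampling;
* inside a planted DMR, every site of the DMR's context gets a flat
  group-specific true level (e.g. 0.3 in the control vs 0.7 post-graft),
  which makes the region's pooled weighted level equal the planted value;
* per group, each site's coverage is Poisson(``coverage``) and the
  methylated-read count Binomial(coverage, true level).

Everything is deterministic under ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bsp as bsp_mod
from .io import (
    GeneModel,
    GenomicInterval,
    write_calls,
    write_fasta,
    write_gff3,
    write_regions,
)

CONTEXT_CODES = {"CG": 0, "CHG": 1, "CHH": 2}
CONTEXT_NAMES = np.array(["CG", "CHG", "CHH"])

#: genomic feature classes used by the methylation baseline
FEATURES = ("intergenic", "repeat", "gene_body", "upstream", "cpg_island")
FEATURE_CODES = {name: i for i, name in enumerate(FEATURES)}

#: Probability that a cytosine site is methylated, per context × feature.
#: CG methylation is high in gene bodies and repeats, intermediate in plain
#: intergenic sequence and nearly absent in promoters and CpG islands;
#: CHG/CHH methylation is rare everywhere.  With these defaults the share
#: of methylated sites splits roughly 91% / 2% / 7% across mCG/mCHG/mCHH.
DEFAULT_CONTEXT_LEVELS: dict[str, dict[str, float]] = {
    "CG": {
        "intergenic": 0.60,
        "repeat": 0.70,
        "gene_body": 0.70,
        "upstream": 0.05,
        "cpg_island": 0.05,
    },
    "CHG": {f: 0.014 for f in FEATURES},
    "CHH": {f: 0.011 for f in FEATURES},
}


@dataclass(frozen=True)
class PlantedDMR:
    """Ground-truth differentially methylated region."""

    interval: GenomicInterval
    context: str
    levels: dict[str, float]  # group label -> flat true level inside the DMR


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the default desk-scale study: a 2 × 500 kb genome at
    35% GC carrying 40 four-exon genes, one CpG island per promoter, 10%
    annotated repeats, two sample groups (a pre-grafting control and one
    post-grafting group) sequenced at 30× mean Poisson coverage, and 20
    planted 1 kb CG DMRs at weighted level 0.3 (control) vs 0.7.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 500_000
    gc_content: float = 0.35
    n_genes: int = 40
    exons_per_gene: int = 4
    exon_len: int = 300
    intron_len: int = 500
    flank: int = 2000
    cpg_island_density: float = 1.0  # islands per gene, placed in promoters
    cpg_island_len: int = 600
    repeat_fraction: float = 0.10
    repeat_unit: int = 2000
    groups: tuple[str, ...] = ("control", "graft")
    control: str = "control"
    coverage: float = 30.0
    meth_level: float = 0.8
    unmeth_level: float = 0.0
    context_levels: dict = field(
        default_factory=lambda: {
            c: dict(v) for c, v in DEFAULT_CONTEXT_LEVELS.items()
        }
    )
    n_planted_dmrs: int = 20
    dmr_len: int = 1000
    dmr_context: str = "CG"
    dmr_level_control: float = 0.3
    dmr_level_case: float = 0.7
    n_terms: int = 24

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    def validate(self) -> list[str]:
        problems = []
        if not 0 < self.gc_content < 1:
            problems.append("gc_content must lie in (0, 1)")
        if self.coverage <= 0:
            problems.append("coverage must be positive")
        if self.control not in self.groups:
            problems.append(f"control group {self.control!r} not in groups")
        for ctx, table in self.context_levels.items():
            for feat, p in table.items():
                if not 0 <= p <= 1:
                    problems.append(f"context_levels[{ctx}][{feat}] outside [0, 1]")
        for name, v in (
            ("meth_level", self.meth_level),
            ("unmeth_level", self.unmeth_level),
            ("dmr_level_control", self.dmr_level_control),
            ("dmr_level_case", self.dmr_level_case),
        ):
            if not 0 <= v <= 1:
                problems.append(f"{name} outside [0, 1]")
        return problems


@dataclass
class SimulatedGenome:
    """Genome, annotation and tracks produced by :func:`simulate_genome`."""

    seqs: dict[str, str]
    genes: list[GeneModel]
    cpg_islands: list[GenomicInterval]
    repeats: list[GenomicInterval]
    gene_terms: list[tuple[str, str]]
    term_names: list[tuple[str, str, str]]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """IID random sequence at the requested GC content."""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _cpg_rich_sequence(rng: np.random.Generator, length: int) -> str:
    """CG-enriched sequence for CpG islands (frequent CpG dinucleotides)."""
    out: list[str] = []
    bases = list("ACGT")
    p = [0.2, 0.3, 0.3, 0.2]
    while len(out) < length:
        if rng.random() < 0.25:
            out.extend("CG")
        else:
            out.append(str(rng.choice(bases, p=p)))
    return "".join(out[:length])


def _context_codes(seq_u8: np.ndarray, idx: np.ndarray, strand: str) -> np.ndarray:
    """Vectorised context classification; -1 marks undefined (edge or N).

    Must agree base-for-base with :func:`methkit.core.classify_context`
    (cross-checked in the test suite).
    """
    C, G, N = ord("C"), ord("G"), ord("N")
    n = len(seq_u8)
    padded = np.full(n + 4, N, dtype=np.uint8)
    padded[2:-2] = seq_u8
    pidx = idx + 2
    if strand == "+":
        b1_is_g = padded[pidx + 1] == G
        b1_is_n = padded[pidx + 1] == N
        b2_is_g = padded[pidx + 2] == G
        b2_is_n = padded[pidx + 2] == N
    else:
        # minus-strand 3' neighbours are the complements of plus bases to
        # the left; complement == G iff the plus base is C
        b1_is_g = padded[pidx - 1] == C
        b1_is_n = padded[pidx - 1] == N
        b2_is_g = padded[pidx - 2] == C
        b2_is_n = padded[pidx - 2] == N
    codes = np.full(len(idx), 2, dtype=np.int8)  # CHH unless shown otherwise
    codes[b2_is_g] = 1
    codes[b2_is_n] = -1
    codes[b1_is_g] = 0
    codes[b1_is_n] = -1
    return codes


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulatedGenome:
    """Generate the genome, gene models, tracks and term maps.

    Genes are placed on a regular per-chromosome grid (jittered within each
    slot) so they never overlap; a CG-enriched CpG island is written into
    the promoter of each island-bearing gene; repeats fill intergenic space
    up to ``repeat_fraction``.  Raises ``ValueError`` when genes cannot be
    placed without overlap at the requested density.  Deterministic under
    the config seed; when ``outdir`` is given, writes genome.fa, genes.gff3,
    cpg_islands.bed, repeats.bed, gene_terms.tsv and term_names.tsv.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {c: list(random_sequence(rng, config.chrom_len, config.gc_content))
            for c in chroms}

    # distribute genes over chromosomes as evenly as possible
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    gene_len = (
        config.exons_per_gene * config.exon_len
        + (config.exons_per_gene - 1) * config.intron_len
    )
    margin = config.flank + config.cpg_island_len + 200
    genes: list[GeneModel] = []
    gid = 0
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        if n_on_chrom == 0:
            continue
        slot = config.chrom_len // n_on_chrom
        lo, hi = margin, slot - gene_len - margin
        if hi <= lo:
            raise ValueError(
                f"cannot place {n_on_chrom} non-overlapping genes of "
                f"{gene_len} bp (+{margin} bp margins) on a "
                f"{config.chrom_len} bp chromosome"
            )
        for s in range(n_on_chrom):
            gid += 1
            start = s * slot + int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = []
            pos = start
            for _ in range(config.exons_per_gene):
                exons.append(
                    GenomicInterval(chrom, pos, pos + config.exon_len, strand, "exon")
                )
                pos += config.exon_len + config.intron_len
            if strand == "-":
                exons = exons[::-1]
            tss = start + 1 if strand == "+" else exons[0].end
            genes.append(GeneModel(f"g{gid:04d}", chrom, strand, exons, tss))

    # CpG islands in promoters: CG-enriched sequence immediately 5' of TSS
    n_islands = int(round(config.cpg_island_density * len(genes)))
    island_genes = list(rng.choice(len(genes), size=min(n_islands, len(genes)),
                                   replace=False))
    islands: list[GenomicInterval] = []
    for i in sorted(island_genes):
        g = genes[i]
        if g.strand == "+":
            s, e = g.start - config.cpg_island_len, g.start
        else:
            s, e = g.end, g.end + config.cpg_island_len
        s = max(0, s)
        e = min(config.chrom_len, e)
        if s >= e:
            continue
        seqs[g.chrom][s:e] = list(_cpg_rich_sequence(rng, e - s))
        islands.append(GenomicInterval(g.chrom, s, e, ".", "cpg_island"))

    # repeats fill intergenic gaps up to the requested genome fraction
    repeats: list[GenomicInterval] = []
    for chrom in chroms:
        blocked = [
            (max(0, g.start - margin), min(config.chrom_len, g.end + margin))
            for g in genes if g.chrom == chrom
        ]
        blocked.sort()
        gaps, cursor = [], 0
        for s, e in blocked + [(config.chrom_len, config.chrom_len)]:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        target = int(config.repeat_fraction * config.chrom_len)
        placed = 0
        for gs, ge in gaps:
            pos = gs + 500
            while placed < target and pos + config.repeat_unit + 500 <= ge:
                repeats.append(
                    GenomicInterval(chrom, pos, pos + config.repeat_unit, ".", "repeat")
                )
                placed += config.repeat_unit
                pos += config.repeat_unit + 1000
            if placed >= target:
                break

    # synthetic annotation terms: each gene carries 1-4 of n_terms terms
    term_ids = [f"T{i + 1:04d}" for i in range(config.n_terms)]
    term_names = [
        (tid, f"synthetic term {tid}", ["GO-BP", "GO-MF", "GO-CC", "KEGG"][i % 4])
        for i, tid in enumerate(term_ids)
    ]
    gene_terms = []
    for g in genes:
        k = int(rng.integers(1, 5))
        for t in rng.choice(config.n_terms, size=k, replace=False):
            gene_terms.append((g.gene_id, term_ids[int(t)]))

    genome = SimulatedGenome(
        seqs={c: "".join(s) for c, s in seqs.items()},
        genes=genes,
        cpg_islands=islands,
        repeats=repeats,
        gene_terms=gene_terms,
        term_names=term_names,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome.seqs, outdir / "genome.fa")
        write_gff3(genome.genes, outdir / "genes.gff3")
        write_regions(genome.cpg_islands, outdir / "cpg_islands.bed")
        write_regions(genome.repeats, outdir / "repeats.bed")
        with open(outdir / "gene_terms.tsv", "w") as fh:
            fh.write("#gene_id\tterm_id\n")
            for gene_id, term_id in gene_terms:
                fh.write(f"{gene_id}\t{term_id}\n")
        with open(outdir / "term_names.tsv", "w") as fh:
            fh.write("#term_id\tname\tnamespace\n")
            for tid, name, ns in term_names:
                fh.write(f"{tid}\t{name}\t{ns}\n")
    return genome


# ---------------------------------------------------------------------------
# planted DMRs
# ---------------------------------------------------------------------------

def plant_dmrs(
    genome: SimulatedGenome, config: SimulationConfig, rng: np.random.Generator
) -> list[PlantedDMR]:
    """Choose ground-truth DMR intervals on a window-aligned grid.

    Candidate tiles of ``dmr_len`` bp (excluding chromosome ends) are
    shuffled and accepted greedily with at least ``2 * dmr_len`` bp between
    accepted tiles, so distinct planted DMRs are never merged by the
    default caller settings and remain individually scorable.
    """
    levels = {
        g: (config.dmr_level_control if g == config.control else config.dmr_level_case)
        for g in config.groups
    }
    candidates = []
    for chrom, size in genome.chrom_sizes.items():
        n_tiles = size // config.dmr_len
        for t in range(1, n_tiles - 1):
            candidates.append((chrom, t * config.dmr_len))
    order = rng.permutation(len(candidates))
    accepted: list[tuple[str, int]] = []
    for oi in order:
        chrom, start = candidates[int(oi)]
        if any(
            c == chrom and abs(start - s) < 3 * config.dmr_len
            for c, s in accepted
        ):
            continue
        accepted.append((chrom, start))
        if len(accepted) == config.n_planted_dmrs:
            break
    if len(accepted) < config.n_planted_dmrs:
        raise ValueError("genome too small for the requested number of planted DMRs")
    accepted.sort()
    return [
        PlantedDMR(
            GenomicInterval(chrom, start, start + config.dmr_len, ".", "planted"),
            config.dmr_context,
            dict(levels),
        )
        for chrom, start in accepted
    ]


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylome(
    genome: SimulatedGenome,
    config: SimulationConfig,
    outdir: str | Path | None = None,
    planted: Sequence[PlantedDMR] | None = None,
) -> tuple[dict[str, pd.DataFrame], list[PlantedDMR]]:
    """Simulate grouped per-cytosine call tables over a simulated genome.

    Returns ``(calls_by_group, planted_dmrs)``.  When ``outdir`` is given,
    writes one ``calls_<group>.tsv`` per group plus the ground-truth
    ``planted_dmrs.tsv``/``.bed`` and the baseline table as JSON.
    """
    ss = np.random.SeedSequence([config.seed, 2])
    plant_rng, state_rng, *group_rngs = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(config.groups))
    ]
    if planted is None:
        planted = (
            plant_dmrs(genome, config, plant_rng) if config.n_planted_dmrs else []
        )
    for dmr in planted:
        iv = dmr.interval
        size = genome.chrom_sizes.get(iv.chrom)
        if size is None or iv.end > size:
            raise ValueError(f"planted DMR {iv} outside the genome")

    lut = np.zeros((3, len(FEATURES)))
    for ctx, ci in CONTEXT_CODES.items():
        for feat, fi in FEATURE_CODES.items():
            lut[ci, fi] = config.context_levels[ctx][feat]

    calls_by_group: dict[str, list[pd.DataFrame]] = {g: [] for g in config.groups}
    for chrom in sorted(genome.seqs):
        seq_u8 = np.frombuffer(genome.seqs[chrom].encode(), dtype=np.uint8)
        size = len(seq_u8)

        feat = np.zeros(size, dtype=np.int8)
        for r in genome.repeats:
            if r.chrom == chrom:
                feat[r.start:r.end] = FEATURE_CODES["repeat"]
        for g in genome.genes:
            if g.chrom == chrom:
                feat[g.start:g.end] = FEATURE_CODES["gene_body"]
                if g.strand == "+":
                    feat[max(0, g.start - config.flank):g.start] = FEATURE_CODES["upstream"]
                else:
                    feat[g.end:min(size, g.end + config.flank)] = FEATURE_CODES["upstream"]
        for isl in genome.cpg_islands:
            if isl.chrom == chrom:
                feat[isl.start:isl.end] = FEATURE_CODES["cpg_island"]

        site_pos: list[np.ndarray] = []
        site_strand: list[np.ndarray] = []
        site_ctx: list[np.ndarray] = []
        for strand, base in (("+", ord("C")), ("-", ord("G"))):
            idx = np.flatnonzero(seq_u8 == base)
            codes = _context_codes(seq_u8, idx, strand)
            keep = codes >= 0
            site_pos.append(idx[keep])
            site_strand.append(np.full(keep.sum(), strand, dtype="<U1"))
            site_ctx.append(codes[keep])
        pos0 = np.concatenate(site_pos)
        strands = np.concatenate(site_strand)
        ctx = np.concatenate(site_ctx)
        order = np.argsort(pos0, kind="stable")
        pos0, strands, ctx = pos0[order], strands[order], ctx[order]

        prob = lut[ctx, feat[pos0]]
        state = state_rng.random(len(pos0)) < prob
        base_level = np.where(state, config.meth_level, config.unmeth_level)

        for group, rng_g in zip(config.groups, group_rngs):
            level = base_level.copy()
            for dmr in planted:
                if dmr.interval.chrom != chrom:
                    continue
                mask = (
                    (ctx == CONTEXT_CODES[dmr.context])
                    & (pos0 >= dmr.interval.start)
                    & (pos0 < dmr.interval.end)
                )
                level[mask] = dmr.levels[group]
            cov = rng_g.poisson(config.coverage, len(pos0))
            n_meth = rng_g.binomial(cov, level)
            covered = cov > 0
            calls_by_group[group].append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos0[covered] + 1,
                        "strand": strands[covered],
                        "context": CONTEXT_NAMES[ctx[covered]],
                        "n_meth": n_meth[covered],
                        "n_total": cov[covered],
                    }
                )
            )

    out: dict[str, pd.DataFrame] = {}
    for group, frames in calls_by_group.items():
        df = pd.concat(frames, ignore_index=True)
        df["n_unmeth"] = df["n_total"] - df["n_meth"]
        out[group] = df

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for group, df in out.items():
            write_calls(df, outdir / f"calls_{group}.tsv")
        planted_table(planted, config.groups).to_csv(
            outdir / "planted_dmrs.tsv", sep="\t", index=False
        )
        write_regions([d.interval for d in planted], outdir / "planted_dmrs.bed")
        with open(outdir / "baseline_levels.json", "w") as fh:
            json.dump(config.context_levels, fh, indent=2)
    return out, list(planted)


def planted_table(
    planted: Sequence[PlantedDMR], groups: Sequence[str]
) -> pd.DataFrame:
    """Ground-truth DMR table with one level column per group."""
    rows = []
    for d in planted:
        row = {
            "chrom": d.interval.chrom,
            "start": d.interval.start,
            "end": d.interval.end,
            "context": d.context,
        }
        for g in groups:
            row[f"level_{g}"] = d.levels[g]
        rows.append(row)
    return pd.DataFrame(rows)


def score_dmr_calls(
    called: pd.DataFrame, planted: Sequence[PlantedDMR]
) -> dict[str, float]:
    """Overlap-based sensitivity and precision of a called DMR set.

    A planted DMR is recovered when ≥1 called DMR of the same context
    overlaps it; a called DMR is a true positive when it overlaps ≥1
    planted DMR of its context.
    """
    def overlaps(row, dmr: PlantedDMR) -> bool:
        return (
            row.chrom == dmr.interval.chrom
            and row.context == dmr.context
            and row.start < dmr.interval.end
            and row.end > dmr.interval.start
        )

    rows = list(called.itertuples(index=False))
    recovered = sum(
        1 for d in planted if any(overlaps(r, d) for r in rows)
    )
    true_pos = sum(
        1 for r in rows if any(overlaps(r, d) for d in planted)
    )
    sensitivity = recovered / len(planted) if planted else float("nan")
    precision = true_pos / len(rows) if rows else float("nan")
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_planted": len(planted),
        "n_called": len(rows),
    }


# ---------------------------------------------------------------------------
# BSP simulation
# ---------------------------------------------------------------------------

def simulate_bsp(
    reference: str,
    pattern: Sequence[float],
    n_clones: int = 10,
    conversion_rate: float = 1.0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[bsp_mod.CloneRead], np.ndarray]:
    """Simulate BSP clones for an amplicon and write FASTA + truth table.

    Delegates the conversion chemistry to
    :func:`methkit.bsp.bisulfite_convert`; the default of 10 clones mirrors
    typical clone-sequencing depth per subject.
    """
    clones, truth = bsp_mod.bisulfite_convert(
        reference, pattern, conversion_rate=conversion_rate,
        n_clones=n_clones, seed=seed,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "clones.fasta", "w") as fh:
            for clone in clones:
                fh.write(f">{clone.clone_id}\n{clone.sequence}\n")
        with open(outdir / "reference.fasta", "w") as fh:
            fh.write(f">amplicon\n{reference}\n")
        cpgs = bsp_mod.find_cpg_positions(reference)
        with open(outdir / "clone_truth.tsv", "w") as fh:
            fh.write("clone_id\t" + "\t".join(f"cpg_{p + 1}" for p in cpgs) + "\n")
            for clone, row in zip(clones, truth):
                fh.write(
                    clone.clone_id + "\t"
                    + "\t".join("M" if m else "U" for m in row) + "\n"
                )
    return clones, truth


def config_to_dict(config: SimulationConfig) -> dict:
    """JSON-serialisable form of a config (for run summaries and hashing)."""
    d = asdict(config)
    d["groups"] = list(config.groups)
    return d


def config_from_dict(data: Mapping) -> SimulationConfig:
    """Build a config from a plain mapping (TOML/YAML section)."""
    data = dict(data)
    if "groups" in data:
        data["groups"] = tuple(data["groups"])
    return SimulationConfig(**data)
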