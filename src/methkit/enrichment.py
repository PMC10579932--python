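"""Hypergeometric over-representation analysis of DMG sets.

Given a set of DMR-associated genes (DMGs), a universe of background genes
and a gene→term annotation map (GO or KEGG supplied as plain TSV files),
each term is tested for over-representation with the upper tail of the
hypergeometric distribution:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the universe genes annotated to the term,
n the DMG set size and k the DMGs annotated to the term.  Terms with raw
p < 0.05 are flagged significant; a Benjamini–Hochberg adjusted column is
emitted alongside for users who want it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

NAMESPACES = ("GO-BP", "GO-MF", "GO-CC", "KEGG")


@dataclass
class TermMapping:
    """One annotation term and the genes it covers."""

    term_id: str
    term_name: str = ""
    namespace: str = ""
    genes: set[str] = field(default_factory=set)


def read_term_mapping(
    mapping_path: str | Path, names_path: str | Path | None = None
) -> dict[str, TermMapping]:
    """Read a two-column gene→term TSV, optionally with a description table.

    ``mapping_path`` holds ``gene_id<TAB>term_id`` rows; ``names_path``
    (optional) holds ``term_id<TAB>name[<TAB>namespace]`` rows.  Lines
    starting with '#' are comments.
    """
    mappings: dict[str, TermMapping] = {}
    with open(mapping_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            gene_id, term_id = line.rstrip("\n").split("\t")[:2]
            mappings.setdefault(term_id, TermMapping(term_id)).genes.add(gene_id)
    if names_path is not None:
        with open(names_path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                term_id = fields[0]
                if term_id in mappings:
                    mappings[term_id].term_name = fields[1] if len(fields) > 1 else ""
                    mappings[term_id].namespace = fields[2] if len(fields) > 2 else ""
    return mappings


def enrich(
    dmg_genes: Iterable[str],
    mappings: Mapping[str, TermMapping],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a DMG set.

    The universe defaults to all genes appearing in any mapping.  DMG genes
    absent from the universe are an error (listed in the message).  Terms
    with no universe gene are skipped.  Results are sorted by (p, term_id)
    for determinism and carry a Benjamini–Hochberg adjusted column.
    """
    if not mappings:
        raise ValueError("empty term mapping")
    dmg = set(dmg_genes)
    if universe is None:
        uni: set[str] = set()
        for term in mappings.values():
            uni |= term.genes
    else:
        uni = set(universe)
    missing = sorted(dmg - uni)
    if missing:
        raise ValueError(
            f"{len(missing)} DMG gene(s) absent from the universe: "
            + ", ".join(missing[:10])
            + ("..." if len(missing) > 10 else "")
        )

    N, n = len(uni), len(dmg)
    rows = []
    for term_id in sorted(mappings):
        term = mappings[term_id]
        term_genes = term.genes & uni
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & dmg)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            (term_id, term.term_name, term.namespace, k, n, K, N, p)
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "namespace", "k", "n", "K", "N", "p"]
    )
    if not table.empty:
        from .dmr import bh_adjust

        table["p_bh"] = bh_adjust(table["p"])
        table["significant"] = table["p"] < alpha
        table = table.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    return table
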