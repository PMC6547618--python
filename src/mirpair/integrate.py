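"""Anticorrelated miRNA-gene pairing and hallmark-style gene-set enrichment.

A regulatory pair requires three things at once: both the miRNA and the gene
are differentially expressed, their tumor-vs-normal directions are opposite,
and the relation is supported by the compiled target map.  Enrichment is
one-sided over-representation (upper-tail hypergeometric) of a directional
query against each gene set, BH-corrected within the query's direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import TargetMap
from .de import bh_fdr

__all__ = [
    "RegulatoryPair",
    "anticorrelated_pairs",
    "pair_summary",
    "hypergeometric_enrich",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class RegulatoryPair:
    """An anticorrelated DEmiR-DEG relation supported by the target map."""

    mirna_id: str
    mirna_direction: str
    gene_id: str
    gene_direction: str
    provenance: str

    def __post_init__(self) -> None:
        if self.mirna_direction == self.gene_direction:
            raise ValueError("pair directions must be opposite")


def anticorrelated_pairs(
    demir_directions: Mapping[str, str],
    deg_directions: Mapping[str, str],
    targets: TargetMap,
) -> list[RegulatoryPair]:
    """Cross-join DEmiRs x DEGs filtered to opposite direction + target support.

    ``demir_directions`` / ``deg_directions`` map feature id to "up"/"down"
    in tumor.  A (miRNA, gene) appearing under several provenances yields one
    pair per provenance, so the evidence trail survives the join.
    """
    pairs: list[RegulatoryPair] = []
    for rel in sorted(
        targets.relations, key=lambda r: (r.mirna_id, r.gene_id, r.provenance)
    ):
        mdir = demir_directions.get(rel.mirna_id)
        gdir = deg_directions.get(rel.gene_id)
        if mdir is None or gdir is None or mdir == gdir:
            continue
        pairs.append(
            RegulatoryPair(rel.mirna_id, mdir, rel.gene_id, gdir, rel.provenance)
        )
    return pairs


def pair_summary(pairs: Sequence[RegulatoryPair]) -> dict[str, int]:
    """Distinct-entity tallies of a pair list."""
    keys = {(p.mirna_id, p.gene_id) for p in pairs}
    mirnas = {p.mirna_id: p.mirna_direction for p in pairs}
    genes = {p.gene_id: p.gene_direction for p in pairs}
    return {
        "n_pairs": len(keys),
        "n_mirnas": len(mirnas),
        "n_mirnas_up": sum(1 for d in mirnas.values() if d == "up"),
        "n_mirnas_down": sum(1 for d in mirnas.values() if d == "down"),
        "n_genes": len(genes),
        "n_genes_up": sum(1 for d in genes.values() if d == "up"),
        "n_genes_down": sum(1 for d in genes.values() if d == "down"),
    }


def pairs_to_frame(pairs: Sequence[RegulatoryPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.mirna_id, p.mirna_direction, p.gene_id, p.gene_direction, p.provenance)
            for p in pairs
        ],
        columns=["mirna_id", "mirna_dir", "gene_id", "gene_dir", "provenance"],
    )


def hypergeometric_enrich(
    query: Iterable[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Iterable[str],
    query_direction: str = "up",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    With universe size N, set size K (after intersecting the set with the
    universe), query size n and overlap k, p = P(X >= k) for X
    hypergeometric(N, K, n).  BH correction spans all sets tested here (one
    query direction = one BH family); rows come back sorted by q then p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(query & members)
        K, n, N = len(members), len(query), len(universe)
        # P(X >= k) == sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, min(max(p, 0.0), 1.0)))
    df = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p"]
    )
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    df["query_direction"] = query_direction
    return df.sort_values(["q", "p", "set_name"], kind="stable").reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT reader: tab-separated set name, description, members; CRLF tolerated."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
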