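"""Over-representation statistics for a gene set against term annotations.

Hypergeometric upper-tail p-values per term, Benjamini-Hochberg adjustment
across tested terms, one-sided (enrichment only). The universe is the set of
annotated genes supplied, not a genome size.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["TermMap", "EnrichmentResult", "enrich", "read_term_map_tsv"]


@dataclass
class TermMap:
    """term id -> annotated gene set, with the annotation universe."""

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("annotation universe is empty")
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has no genes")
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} contains genes outside the universe")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   labels: Mapping[str, str] | None = None) -> "TermMap":
        """Build from (gene, term) pairs; the universe is all genes seen."""
        terms: dict[str, set[str]] = {}
        universe: set[str] = set()
        for gene, term in pairs:
            universe.add(gene)
            terms.setdefault(term, set()).add(gene)
        return cls(terms={t: frozenset(g) for t, g in terms.items()},
                   universe=frozenset(universe), labels=dict(labels or {}))


def read_term_map_tsv(path: str | Path, labels: Mapping[str, str] | None = None) -> TermMap:
    """Read a two-column gene<TAB>term annotation file."""
    pairs: list[tuple[str, str]] = []
    with open(path, newline="") as handle:
        for row_number, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: row {row_number} must have exactly 2 columns")
            pairs.append((row[0], row[1]))
    if not pairs:
        raise ValueError(f"{path}: no annotations")
    return TermMap.from_pairs(pairs, labels=labels)


@dataclass
class EnrichmentResult:
    """Per-term results, sorted by ascending p-value."""

    table: pd.DataFrame
    n_query_used: int
    n_query_dropped: int
    fdr_threshold: float

    @property
    def significant_terms(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def enrich(query: Iterable[str], terms: TermMap, fdr_threshold: float = 0.05) -> EnrichmentResult:
    """Hypergeometric over-representation test with BH adjustment.

    Query genes outside the universe are dropped (with a warning). Terms are
    tested only when they overlap the query; the number of tested terms is
    the BH family size.
    """
    query_set = frozenset(query)
    if not query_set:
        raise ValueError("empty query gene set")
    used = query_set & terms.universe
    dropped = len(query_set) - len(used)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) outside the annotation universe were dropped")
    if not used:
        raise ValueError("no query genes inside the annotation universe")

    population = len(terms.universe)
    draws = len(used)
    rows = []
    for term, genes in terms.terms.items():
        overlap = len(genes & used)
        if overlap < 1:
            continue
        # upper tail P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, population, len(genes), draws))
        rows.append((term, terms.labels.get(term, ""), overlap, len(genes), min(p, 1.0)))
    if not rows:
        raise ValueError("no term overlaps the query")

    table = pd.DataFrame(rows, columns=["term", "label", "overlap", "term_size", "p_value"])
    table["fdr"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    table["significant"] = table["fdr"] < fdr_threshold
    table = table.sort_values(["p_value", "term"], kind="mergesort").set_index("term")
    return EnrichmentResult(table=table, n_query_used=len(used),
                            n_query_dropped=dropped, fdr_threshold=fdr_threshold)
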