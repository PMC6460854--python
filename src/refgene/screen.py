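"""Four-criterion reference-gene screen, CV ranking, and multi-dataset
core-set partitioning.

The screen works on replicate-averaged gene x condition TPM matrices.
Criteria are applied in a fixed cascade:

I.   expression observed in every condition (TPM strictly above a floor,
     default 0);
II.  sample SD of log2(TPM) across conditions strictly below a threshold
     (default 1);
III. no condition whose log2(TPM) deviates from the gene's mean by the
     deviation threshold or more (default 2);
IV.  mean log2(TPM) strictly above a floor (default 5).

Candidates are ranked by the coefficient of variation CV = sd/mean of
log2(TPM); the II/IV thresholds imply an analytic CV bound (default 0.2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import ExpressionMatrix

__all__ = [
    "ScreenCriteria",
    "ScreenResult",
    "CoreSetReport",
    "screen_dataset",
    "rank_by_cv",
    "core_set",
    "cv_bound_check",
    "percentage_of_total",
]

CASCADE_STEPS = ("I", "I-II", "I-III", "I-IV")


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the four screening criteria (all strict inequalities)."""

    min_tpm_exclusive: float = 0.0
    max_sd_log2: float = 1.0
    max_abs_deviation_log2: float = 2.0
    min_mean_log2_exclusive: float = 5.0

    def __post_init__(self) -> None:
        if self.min_tpm_exclusive < 0:
            raise ValueError("min_tpm_exclusive must be >= 0")
        for name in ("max_sd_log2", "max_abs_deviation_log2", "min_mean_log2_exclusive"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ScreenResult:
    """Per-gene screen outcome plus cascade counts.

    ``table`` is indexed by gene id with columns passes_I..passes_IV,
    mean_log2, sd_log2, max_abs_dev_log2, cv, candidate, and rank
    (1 = lowest CV among candidates; NaN for non-candidates). Genes failing
    criterion I have NaN log2 statistics.
    """

    table: pd.DataFrame
    cascade_counts: dict[str, int]
    n_genes: int
    criteria: ScreenCriteria

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])

    @property
    def n_candidates(self) -> int:
        return int(self.table["candidate"].sum())

    def cascade_percentages(self) -> dict[str, float]:
        """Cascade survivor counts as percentages of the full gene set."""
        return {
            step: percentage_of_total(count, self.n_genes)
            for step, count in self.cascade_counts.items()
        }

    def cascade_report(self) -> dict:
        """JSON-friendly cascade summary."""
        return {
            "n_genes": self.n_genes,
            "counts": dict(self.cascade_counts),
            "percentages": self.cascade_percentages(),
        }


def percentage_of_total(count: int, total: int) -> float:
    """100 * count / total, rounded to two decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def screen_dataset(matrix: ExpressionMatrix, criteria: ScreenCriteria | None = None) -> ScreenResult:
    """Apply the four-criterion cascade to a replicate-averaged matrix."""
    criteria = criteria or ScreenCriteria()
    if matrix.n_genes == 0:
        raise ValueError("empty expression matrix")
    if matrix.n_conditions < 2:
        raise ValueError(
            f"screening requires >=2 conditions, got {matrix.n_conditions}"
        )

    values = matrix.values
    passes_i = np.all(values > criteria.min_tpm_exclusive, axis=1)

    n_genes, n_conditions = values.shape
    mean_log2 = np.full(n_genes, np.nan)
    sd_log2 = np.full(n_genes, np.nan)
    max_abs_dev = np.full(n_genes, np.nan)
    cv = np.full(n_genes, np.nan)

    if passes_i.any():
        log2_vals = np.log2(values[passes_i])
        mean_log2[passes_i] = log2_vals.mean(axis=1)
        sd_log2[passes_i] = log2_vals.std(axis=1, ddof=1)
        max_abs_dev[passes_i] = np.abs(log2_vals - log2_vals.mean(axis=1, keepdims=True)).max(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv[passes_i] = sd_log2[passes_i] / mean_log2[passes_i]

    # strict inequalities throughout; genes failing I carry False downstream
    passes_ii = passes_i & (sd_log2 < criteria.max_sd_log2)
    passes_iii = passes_i & (max_abs_dev < criteria.max_abs_deviation_log2)
    passes_iv = passes_i & (mean_log2 > criteria.min_mean_log2_exclusive)
    candidate = passes_i & passes_ii & passes_iii & passes_iv

    cascade_counts = {
        "I": int(passes_i.sum()),
        "I-II": int((passes_i & passes_ii).sum()),
        "I-III": int((passes_i & passes_ii & passes_iii).sum()),
        "I-IV": int(candidate.sum()),
    }

    table = pd.DataFrame(
        {
            "passes_I": passes_i,
            "passes_II": passes_ii,
            "passes_III": passes_iii,
            "passes_IV": passes_iv,
            "mean_log2": mean_log2,
            "sd_log2": sd_log2,
            "max_abs_dev_log2": max_abs_dev,
            "cv": cv,
            "candidate": candidate,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )

    rank = pd.Series(np.nan, index=table.index)
    cand = table[table["candidate"]]
    if len(cand):
        order = cand.reset_index().sort_values(["cv", "gene"], kind="mergesort")["gene"]
        rank.loc[order] = np.arange(1, len(order) + 1, dtype=float)
    table["rank"] = rank

    return ScreenResult(table=table, cascade_counts=cascade_counts,
                        n_genes=n_genes, criteria=criteria)


def rank_by_cv(result: ScreenResult, top_k: int = 10) -> pd.DataFrame:
    """Top candidates ordered by ascending CV (ties: ascending gene id)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    cand = result.table[result.table["candidate"]]
    if cand.empty:
        raise ValueError("no candidate genes to rank")
    ordered = cand.reset_index().sort_values(["cv", "gene"], kind="mergesort")
    return ordered[["gene", "cv", "mean_log2"]].head(top_k).reset_index(drop=True)


@dataclass
class CoreSetReport:
    """Occupancy partition of k named gene-id sets (Venn arithmetic)."""

    set_names: list[str]
    region_counts: dict[str, int]
    union_size: int
    intersection_size: int
    shared_percentage: float
    core_genes: list[str] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "set_names": self.set_names,
            "region_counts": dict(self.region_counts),
            "union_size": self.union_size,
            "intersection_size": self.intersection_size,
            "shared_percentage": self.shared_percentage,
        }


def core_set(candidate_sets: Mapping[str, Iterable[str]]) -> CoreSetReport:
    """Partition >=2 named candidate sets into occupancy regions.

    ``shared_percentage`` is 100 * |intersection of all| / |union of all|,
    rounded to two decimals.
    """
    names = list(candidate_sets)
    if len(names) < 2:
        raise ValueError("core_set requires >=2 candidate sets")
    sets = {name: frozenset(candidate_sets[name]) for name in names}
    union = frozenset().union(*sets.values())
    intersection = frozenset.intersection(*sets.values()) if union else frozenset()

    region_counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = frozenset.intersection(*(sets[n] for n in combo))
            outside = frozenset().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else frozenset()
            region_counts["&".join(combo)] = len(inside - outside)

    shared = percentage_of_total(len(intersection), len(union)) if union else 0.0
    return CoreSetReport(
        set_names=names,
        region_counts=region_counts,
        union_size=len(union),
        intersection_size=len(intersection),
        shared_percentage=shared,
        core_genes=sorted(intersection),
    )


def cv_bound_check(criteria: ScreenCriteria | None = None) -> float:
    """Analytic supremum of CV for genes passing criteria II and IV.

    With sd(log2 TPM) < s and mean(log2 TPM) > m (m > 0), CV = sd/mean < s/m.
    Defaults give 1/5 = 0.2.
    """
    criteria = criteria or ScreenCriteria()
    if criteria.min_mean_log2_exclusive <= 0:
        raise ValueError("min_mean_log2_exclusive must be positive for the CV bound")
    return criteria.max_sd_log2 / criteria.min_mean_log2_exclusive
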