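"""Expression-stability statistics for candidate reference genes on Ct data.

Three methods are implemented on a gene x sample T matrix:

* geNorm: mean pairwise variation M of log2 expression ratios, with the
  stepwise exclusion ranking and the V(n/n+1) pairwise-variation series of
  normalization factors;
* a model-based (NormFinder-style) stability combining the gene x group
  interaction with within-group sampling error, or the SD of column-centered
  log-quantities when no groups are given;
* the comparative delta-Ct method: mean SD of per-sample Ct differences
  against every other gene.

Lower scores mean more stable throughout. The three per-method rankings are
combined by the geometric mean of ranks. Sample SD uses the n-1 denominator
everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import CtMatrix

__all__ = [
    "RelativeQuantityMatrix",
    "DilutionSeries",
    "EfficiencyFit",
    "StabilityReport",
    "ct_to_quantity",
    "amplification_efficiency",
    "genorm_m",
    "genorm_rank",
    "GenormRanking",
    "normfinder_stability",
    "deltact_stability",
    "comprehensive_rank",
    "stability_report",
    "collapse_technical_replicates",
]

METHODS = ("genorm", "normfinder", "deltact")


@dataclass
class RelativeQuantityMatrix:
    """Per-gene relative quantities Q in (0, 1]; the minimum-Ct sample is 1."""

    gene_ids: list[str]
    sample_ids: list[str]
    quantities: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.quantities = np.asarray(self.quantities, dtype=float)
        if self.quantities.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("quantities shape does not match gene and sample ids")
        if np.any(self.quantities <= 0) or np.any(self.quantities > 1 + 1e-9):
            raise ValueError("quantities must lie in (0, 1]")
        if not np.allclose(self.quantities.max(axis=1), 1.0):
            raise ValueError("per gene, the maximum quantity must equal 1")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.quantities, index=pd.Index(self.gene_ids, name="gene"),
                            columns=self.sample_ids)


def ct_to_quantity(ct: CtMatrix) -> RelativeQuantityMatrix:
    """Q(g, s) = (1 + E_g) ** (Ct_min(g) - Ct(g, s)); E defaults to 1."""
    eff = ct.efficiency_array()
    if np.any(eff <= -1):
        raise ValueError("amplification efficiency must be > -1")
    ct_min = ct.ct_values.min(axis=1, keepdims=True)
    quantities = (1.0 + eff)[:, None] ** (ct_min - ct.ct_values)
    return RelativeQuantityMatrix(gene_ids=ct.gene_ids, sample_ids=ct.sample_ids,
                                  quantities=quantities)


@dataclass
class DilutionSeries:
    """Standard-curve data: two-fold serial template inputs (ng) and Ct."""

    inputs_ng: np.ndarray
    ct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.inputs_ng = np.asarray(self.inputs_ng, dtype=float)
        if self.inputs_ng.size < 3:
            raise ValueError("a dilution series needs >=3 points")
        if np.any(self.inputs_ng <= 0):
            raise ValueError("template inputs must be positive")
        ratios = self.inputs_ng[:-1] / self.inputs_ng[1:]
        if not np.allclose(ratios, 2.0, rtol=1e-6):
            raise ValueError("inputs must be strictly decreasing by a factor of 2")
        if self.ct is not None:
            self.ct = np.asarray(self.ct, dtype=float)
            if self.ct.shape != self.inputs_ng.shape:
                raise ValueError("ct must have one value per dilution point")

    @classmethod
    def two_fold(cls, start_ng: float = 100.0, n_points: int = 8,
                 ct: Sequence[float] | None = None) -> "DilutionSeries":
        """Series halving from ``start_ng`` for ``n_points`` points."""
        inputs = start_ng / (2.0 ** np.arange(n_points))
        return cls(inputs_ng=inputs, ct=None if ct is None else np.asarray(ct, dtype=float))

    @property
    def lowest_input_ng(self) -> float:
        return float(self.inputs_ng.min())


@dataclass(frozen=True)
class EfficiencyFit:
    """Standard-curve fit: Ct = slope * log2(input) + intercept."""

    efficiency: float
    slope: float
    intercept: float
    r_squared: float


def amplification_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """OLS of Ct on log2(input); E = 2**(-1/slope) - 1 (E = 1 at slope -1)."""
    if series.ct is None:
        raise ValueError("dilution series has no Ct measurements")
    x = np.log2(series.inputs_ng)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in template inputs")
    fit = stats.linregress(x, series.ct)
    if fit.slope == 0:
        raise ValueError("zero slope: efficiency undefined")
    efficiency = 2.0 ** (-1.0 / fit.slope) - 1.0
    return EfficiencyFit(efficiency=float(efficiency), slope=float(fit.slope),
                         intercept=float(fit.intercept), r_squared=float(fit.rvalue ** 2))


def _log_quantities(q: RelativeQuantityMatrix) -> np.ndarray:
    if np.any(q.quantities <= 0):
        raise ValueError("quantities must be positive")
    return np.log2(q.quantities)


def genorm_m(q: RelativeQuantityMatrix) -> pd.Series:
    """geNorm stability M: mean over partners of sd(log2 pairwise ratio)."""
    if q.n_genes < 2:
        raise ValueError("geNorm M requires >=2 genes")
    if len(q.sample_ids) < 2:
        raise ValueError("geNorm M requires >=2 samples")
    log_q = _log_quantities(q)
    n = q.n_genes
    # V[j, k] = sd over samples of log2(Q_j / Q_k)
    diffs = log_q[:, None, :] - log_q[None, :, :]
    v = diffs.std(axis=2, ddof=1)
    m = (v.sum(axis=1)) / (n - 1)  # diagonal contributes 0
    return pd.Series(m, index=pd.Index(q.gene_ids, name="gene"), name="genorm_M")


@dataclass
class GenormRanking:
    """Stepwise geNorm output: ranks, exclusion order, V(n/n+1) series."""

    ranks: pd.Series
    exclusion_order: list[str]
    inclusion_order: list[str]
    initial_m: pd.Series
    pairwise_variation: dict[str, float]


def genorm_rank(q: RelativeQuantityMatrix) -> GenormRanking:
    """Iteratively drop the highest-M gene until two remain.

    The final pair is tied at average rank 1.5. V(n/n+1) is the sample SD of
    log2(NF_n / NF_{n+1}) where NF_n(s) is the geometric mean of the n
    top-ranked genes' quantities, for n = 2..k-1 along the inclusion order.
    """
    if q.n_genes < 3:
        raise ValueError("geNorm ranking requires >=3 genes")
    frame = q.to_frame()
    initial_m = genorm_m(q)

    remaining = list(q.gene_ids)
    exclusion_order: list[str] = []
    while len(remaining) > 2:
        sub = RelativeQuantityMatrix(
            gene_ids=remaining, sample_ids=q.sample_ids,
            quantities=_renormalize(frame.loc[remaining].to_numpy()))
        m = genorm_m(sub)
        worst_value = m.max()
        # deterministic tie-break: drop the lexicographically last gene
        worst = max(g for g in remaining if m[g] == worst_value)
        remaining.remove(worst)
        exclusion_order.append(worst)

    final_pair = sorted(remaining)
    inclusion_order = final_pair + list(reversed(exclusion_order))
    ranks = pd.Series(index=pd.Index(q.gene_ids, name="gene"), dtype=float, name="genorm_rank")
    ranks[final_pair] = 1.5
    for position, gene in enumerate(reversed(exclusion_order), start=3):
        ranks[gene] = float(position)

    log_q = np.log2(frame.loc[inclusion_order].to_numpy())
    pairwise_variation: dict[str, float] = {}
    for n in range(2, q.n_genes):
        log_nf_n = log_q[:n].mean(axis=0)
        log_nf_n1 = log_q[: n + 1].mean(axis=0)
        pairwise_variation[f"V{n}/{n + 1}"] = float(np.std(log_nf_n - log_nf_n1, ddof=1))

    return GenormRanking(ranks=ranks, exclusion_order=exclusion_order,
                         inclusion_order=inclusion_order, initial_m=initial_m,
                         pairwise_variation=pairwise_variation)


def _renormalize(quantities: np.ndarray) -> np.ndarray:
    # M is invariant under per-gene rescaling; rescale so the type invariant
    # (max = 1) holds after subsetting.
    return quantities / quantities.max(axis=1, keepdims=True)


def normfinder_stability(ct: CtMatrix, use_groups: bool | None = None) -> pd.Series:
    """Model-based stability on the log2-quantity scale y = -Ct * log2(1+E).

    Ungrouped: sample SD of the gene's column-centered y values. Grouped
    (requires >=2 groups, each with >=2 samples): per group, |interaction
    term| + sqrt(within-group variance / group size), averaged over groups.
    """
    if ct.n_genes < 3:
        raise ValueError("normfinder_stability requires >=3 genes")
    if ct.n_samples < 2:
        raise ValueError("normfinder_stability requires >=2 samples")
    grouped = ct.groups is not None if use_groups is None else use_groups
    if grouped and ct.groups is None:
        raise ValueError("grouped mode requested but the Ct matrix has no groups")

    eff = ct.efficiency_array()
    y = -ct.ct_values * np.log2(1.0 + eff)[:, None]
    z = y - y.mean(axis=0, keepdims=True)  # column-centered (per-sample gene mean removed)
    index = pd.Index(ct.gene_ids, name="gene")

    if not grouped:
        return pd.Series(z.std(axis=1, ddof=1), index=index, name="normfinder_stability")

    group_labels = [ct.groups[s] for s in ct.sample_ids]
    groups = list(dict.fromkeys(group_labels))
    if len(groups) < 2:
        raise ValueError("grouped mode requires >=2 groups")
    members = {g: [i for i, lbl in enumerate(group_labels) if lbl == g] for g in groups}
    small = [g for g, idx in members.items() if len(idx) < 2]
    if small:
        raise ValueError(
            f"group(s) {small} have fewer than 2 samples; rerun with use_groups=False"
        )

    # two-way table of group means and its interaction residual
    group_means = np.column_stack([y[:, members[g]].mean(axis=1) for g in groups])
    gene_mean = group_means.mean(axis=1, keepdims=True)
    group_mean = group_means.mean(axis=0, keepdims=True)
    grand_mean = group_means.mean()
    d = group_means - gene_mean - group_mean + grand_mean

    stability = np.zeros(ct.n_genes)
    for j, g in enumerate(groups):
        idx = members[g]
        var_within = z[:, idx].var(axis=1, ddof=1)
        stability += np.abs(d[:, j]) + np.sqrt(var_within / len(idx))
    stability /= len(groups)
    return pd.Series(stability, index=index, name="normfinder_stability")


def deltact_stability(ct: CtMatrix) -> pd.Series:
    """Comparative delta-Ct: mean over partners of sd(Ct_i - Ct_j) (cycles)."""
    if ct.n_genes < 2:
        raise ValueError("deltact_stability requires >=2 genes")
    if ct.n_samples < 2:
        raise ValueError("deltact_stability requires >=2 samples")
    values = ct.ct_values
    diffs = values[:, None, :] - values[None, :, :]
    sd = diffs.std(axis=2, ddof=1)
    stability = sd.sum(axis=1) / (ct.n_genes - 1)
    return pd.Series(stability, index=pd.Index(ct.gene_ids, name="gene"),
                     name="deltact_stability")


def comprehensive_rank(scores: pd.DataFrame) -> pd.DataFrame:
    """Combine per-method stability scores by geometric mean of ranks.

    ``scores`` must hold one column per method in :data:`METHODS`, indexed by
    gene. Each method is ranked ascending (rank 1 = most stable, ties get
    average ranks); the comprehensive score is the geometric mean of the three
    ranks and the final order is ascending score (ties by gene id).
    """
    missing_cols = [m for m in METHODS if m not in scores.columns]
    if missing_cols:
        raise ValueError(f"missing score column(s): {missing_cols}")
    for method in METHODS:
        col = scores[method]
        if col.isna().any():
            gene = col.index[col.isna()][0]
            raise ValueError(f"missing {method} score for gene {gene!r}")

    out = pd.DataFrame(index=scores.index)
    for method in METHODS:
        out[f"{method}_score"] = scores[method].astype(float)
        out[f"{method}_rank"] = scores[method].rank(method="average", ascending=True)
    rank_product = (out["genorm_rank"] * out["normfinder_rank"] * out["deltact_rank"])
    out["comprehensive_score"] = rank_product ** (1.0 / 3.0)
    order = out.reset_index().sort_values(
        ["comprehensive_score", out.index.name or "index"], kind="mergesort"
    ).set_index(out.index.name or "index").index
    final = pd.Series(np.arange(1, len(out) + 1, dtype=float), index=order)
    out["comprehensive_rank"] = final
    return out


@dataclass
class StabilityReport:
    """Joined stability table plus the geNorm stepwise diagnostics."""

    table: pd.DataFrame
    genorm: GenormRanking
    grouped: bool

    def ordered(self) -> pd.DataFrame:
        return self.table.sort_values("comprehensive_rank")


def stability_report(ct: CtMatrix, use_groups: bool | None = None) -> StabilityReport:
    """Run all three methods on one Ct matrix and combine their rankings."""
    quantities = ct_to_quantity(ct)
    m = genorm_m(quantities)
    genorm_stepwise = genorm_rank(quantities)
    nf = normfinder_stability(ct, use_groups=use_groups)
    dct = deltact_stability(ct)
    scores = pd.DataFrame({"genorm": m, "normfinder": nf, "deltact": dct})
    combined = comprehensive_rank(scores)
    combined = combined.rename(columns={
        "genorm_score": "genorm_M",
        "normfinder_score": "normfinder_stability",
        "deltact_score": "deltact_stability",
    })
    grouped = ct.groups is not None if use_groups is None else use_groups
    return StabilityReport(table=combined, genorm=genorm_stepwise, grouped=grouped)


def collapse_technical_replicates(ct_frame: pd.DataFrame,
                                  replicate_map: dict[str, str]) -> pd.DataFrame:
    """Average technical-replicate Ct columns (e.g. triplicate wells)."""
    unmapped = [c for c in ct_frame.columns if c not in replicate_map]
    if unmapped:
        raise ValueError(f"sample column(s) not in replicate map: {unmapped}")
    samples = list(dict.fromkeys(replicate_map[c] for c in ct_frame.columns))
    collapsed = {
        s: ct_frame[[c for c in ct_frame.columns if replicate_map[c] == s]].mean(axis=1)
        for s in samples
    }
    return pd.DataFrame(collapsed, index=ct_frame.index)[samples]
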