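"""Synthetic data generators with known ground truth.

Generates (a) expression matrices containing planted stable genes among
variable, stage-specific and silent genes, (b) Ct matrices linearly coupled
to log2(TPM) with additive cycle noise, and (c) truth-labeled FASTQ files for
exercising the read filter. All generators are deterministic given a seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .ingest import CtMatrix, ExpressionMatrix, FastqReadFilterParams, average_replicates

__all__ = [
    "ExpressionSimSpec",
    "CtSimSpec",
    "SimulatedExpression",
    "gen_expression",
    "gen_ct",
    "gen_fastq",
    "preset_spec",
    "PRESET_NAMES",
]

TRUTH_LABELS = ("stable", "variable", "stage_specific", "silent")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Composition and distribution parameters for a simulated matrix.

    Condition-level log2 expression is Normal(mean, sd) per gene archetype;
    replicate measurements add Normal(0, noise_sd_log2) on the log2 scale and
    are exponentiated to TPM. Stage-specific genes are expressed in a single
    condition; silent genes are zeroed in at least one condition.
    """

    n_stable: int = 50
    n_variable: int = 450
    n_stage_specific: int = 0
    n_silent: int = 0
    n_conditions: int = 10
    n_replicates: int = 3
    stable_mean_log2: float = 8.0
    stable_sd_log2: float = 0.2
    variable_mean_log2: float = 8.0
    variable_sd_log2: float = 2.0
    noise_sd_log2: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_stable, self.n_variable, self.n_stage_specific, self.n_silent)
        if any(c < 0 for c in counts):
            raise ValueError("gene counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("at least one gene is required")
        if self.n_conditions < 1:
            raise ValueError("at least one condition is required")
        if self.n_replicates < 1:
            raise ValueError("at least one replicate per condition is required")
        for name in ("stable_sd_log2", "variable_sd_log2", "noise_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_stable + self.n_variable + self.n_stage_specific + self.n_silent


#: Preset shapes mimicking a developmental series, a tissue panel, and a
#: gonadal time course.
_PRESETS = {
    "early": dict(n_conditions=7, n_replicates=1),
    "tissues": dict(n_conditions=11, n_replicates=3),
    "gonad": dict(n_conditions=8, n_replicates=3),
}
PRESET_NAMES = tuple(_PRESETS)


def preset_spec(name: str, **overrides) -> ExpressionSimSpec:
    """One of the three built-in dataset shapes ('early', 'tissues', 'gonad')."""
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    params = {**_PRESETS[name], **overrides}
    return ExpressionSimSpec(**params)


@dataclass
class SimulatedExpression:
    """Averaged matrix, replicate-level TPM, and per-gene truth labels."""

    matrix: ExpressionMatrix
    replicate_tpm: pd.DataFrame
    truth: pd.Series
    spec: ExpressionSimSpec


def gen_expression(spec: ExpressionSimSpec) -> SimulatedExpression:
    """Simulate a replicate-level TPM table and its replicate-averaged matrix."""
    rng = np.random.default_rng(spec.seed)
    gene_ids: list[str] = []
    labels: list[str] = []
    for prefix, label, count in (
        ("STB", "stable", spec.n_stable),
        ("VAR", "variable", spec.n_variable),
        ("SSP", "stage_specific", spec.n_stage_specific),
        ("SIL", "silent", spec.n_silent),
    ):
        gene_ids.extend(f"{prefix}{i:04d}" for i in range(count))
        labels.extend([label] * count)

    n_genes, n_cond = spec.n_genes, spec.n_conditions
    log2_level = np.empty((n_genes, n_cond))
    zero_mask = np.zeros((n_genes, n_cond), dtype=bool)
    row = 0
    for label in labels:
        if label == "stable":
            log2_level[row] = rng.normal(spec.stable_mean_log2, spec.stable_sd_log2, n_cond)
        elif label == "variable":
            log2_level[row] = rng.normal(spec.variable_mean_log2, spec.variable_sd_log2, n_cond)
        elif label == "stage_specific":
            log2_level[row] = rng.normal(spec.variable_mean_log2, spec.stable_sd_log2, n_cond)
            on = rng.integers(n_cond)
            zero_mask[row] = True
            zero_mask[row, on] = False
        else:  # silent: zero in a random non-empty subset of conditions
            log2_level[row] = rng.normal(spec.variable_mean_log2, spec.variable_sd_log2, n_cond)
            n_off = int(rng.integers(1, n_cond + 1))
            off = rng.choice(n_cond, size=n_off, replace=False)
            zero_mask[row, off] = True
        row += 1

    sample_ids: list[str] = []
    replicate_map: dict[str, str] = {}
    columns = []
    for c in range(n_cond):
        condition = f"C{c + 1:02d}"
        for r in range(spec.n_replicates):
            sample = f"{condition}_r{r + 1}"
            sample_ids.append(sample)
            replicate_map[sample] = condition
            noise = rng.normal(0.0, spec.noise_sd_log2, n_genes)
            tpm = np.exp2(log2_level[:, c] + noise)
            tpm[zero_mask[:, c]] = 0.0
            columns.append(tpm)

    replicate_tpm = pd.DataFrame(
        np.column_stack(columns), index=pd.Index(gene_ids, name="gene"), columns=sample_ids
    )
    matrix = average_replicates(replicate_tpm, replicate_map)
    truth = pd.Series(labels, index=pd.Index(gene_ids, name="gene"), name="truth")
    return SimulatedExpression(matrix=matrix, replicate_tpm=replicate_tpm,
                               truth=truth, spec=spec)


@dataclass(frozen=True)
class CtSimSpec:
    """Generative coupling Ct = slope * log2(TPM) + intercept + noise.

    ``spike_gene`` optionally designates one gene whose cycle noise is
    inflated by ``spike_noise_factor`` (a deliberately unstable control).
    """

    slope: float = -0.94
    intercept: float = 29.67
    ct_noise_sd: float = 0.2
    efficiency_range: tuple[float, float] = (1.0, 1.0)
    spike_gene: str | None = None
    spike_noise_factor: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("calibration slope must be negative")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        lo, hi = self.efficiency_range
        if not (0 < lo <= hi <= 1.2):
            raise ValueError("efficiency_range must lie in (0, 1.2] with lo <= hi")
        if self.spike_noise_factor <= 0:
            raise ValueError("spike_noise_factor must be positive")


def gen_ct(tpm_subset: ExpressionMatrix, spec: CtSimSpec) -> CtMatrix:
    """Simulate a Ct matrix from TPM values of selected genes.

    Values falling outside (0, 45] are clipped into range with a warning.
    """
    rng = np.random.default_rng(spec.seed)
    values = tpm_subset.values
    if np.any(values <= 0):
        raise ValueError("all TPM values must be positive to simulate Ct")
    if spec.spike_gene is not None and spec.spike_gene not in tpm_subset.gene_ids:
        raise KeyError(f"spike gene {spec.spike_gene!r} not in matrix")

    noise_sd = np.full(tpm_subset.n_genes, spec.ct_noise_sd)
    if spec.spike_gene is not None:
        noise_sd[tpm_subset.gene_ids.index(spec.spike_gene)] *= spec.spike_noise_factor

    ct = spec.slope * np.log2(values) + spec.intercept
    ct = ct + rng.normal(0.0, 1.0, ct.shape) * noise_sd[:, None]
    out_of_range = (ct <= 0) | (ct > 45)
    if out_of_range.any():
        warnings.warn(f"{int(out_of_range.sum())} simulated Ct value(s) clipped into (0, 45]")
        ct = np.clip(ct, 1e-6, 45.0)

    lo, hi = spec.efficiency_range
    if lo == hi:
        efficiencies = {g: lo for g in tpm_subset.gene_ids}
    else:
        draws = rng.uniform(lo, hi, tpm_subset.n_genes)
        efficiencies = dict(zip(tpm_subset.gene_ids, draws.tolist()))

    return CtMatrix(gene_ids=tpm_subset.gene_ids, sample_ids=tpm_subset.condition_labels,
                    ct_values=ct, efficiencies=efficiencies)


def gen_fastq(
    path: str | Path,
    n_reads: int = 1000,
    read_len: int = 50,
    fraction_with_n: float = 0.1,
    fraction_low_quality: float = 0.1,
    seed: int = 0,
    filter_params: FastqReadFilterParams | None = None,
) -> dict[str, int]:
    """Write a truth-labeled FASTQ file; returns expected filter counts.

    Clean reads are all-Q40 ACGT; 'N' reads carry a single N; low-quality
    reads carry exactly ``max_low_quality_positions + 1`` bases at one Phred
    point below the threshold, so the filter must drop them and only them.
    Read ids encode the category (keep_/N_/lowq_).
    """
    if not (0 <= fraction_with_n <= 1 and 0 <= fraction_low_quality <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if fraction_with_n + fraction_low_quality > 1:
        raise ValueError("category fractions must sum to <= 1")
    params = filter_params or FastqReadFilterParams()
    n_with_n = round(n_reads * fraction_with_n)
    n_low = round(n_reads * fraction_low_quality)
    n_keep = n_reads - n_with_n - n_low

    rng = np.random.default_rng(seed)
    categories = ["N"] * n_with_n + ["lowq"] * n_low + ["keep"] * n_keep
    rng.shuffle(categories)

    bases = np.array(list("ACGT"))
    q_high = chr(40 + 33)
    q_low = chr((params.low_quality_threshold - 1) + 33)
    n_bad_positions = params.max_low_quality_positions + 1
    if n_low > 0 and read_len < n_bad_positions:
        raise ValueError(
            f"read_len={read_len} cannot hold {n_bad_positions} low-quality positions"
        )

    with open(path, "w") as handle:
        for i, category in enumerate(categories):
            seq = "".join(rng.choice(bases, size=read_len))
            qual = q_high * read_len
            if category == "N":
                pos = int(rng.integers(read_len))
                seq = seq[:pos] + "N" + seq[pos + 1:]
            elif category == "lowq":
                positions = rng.choice(read_len, size=min(n_bad_positions, read_len),
                                       replace=False)
                qual_list = list(qual)
                for pos in positions:
                    qual_list[pos] = q_low
                qual = "".join(qual_list)
            handle.write(f"@{category}_{i}\n{seq}\n+\n{qual}\n")

    return {"kept": n_keep, "dropped_N": n_with_n, "dropped_quality": n_low,
            "total": n_reads}
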