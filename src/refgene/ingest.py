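"""Input handling: FASTQ quality filtering, counts-to-TPM conversion,
replicate averaging, and TSV I/O for expression and Ct matrices.

Expression values are handled on the linear TPM scale here; log transforms
happen downstream in :mod:`refgene.screen`.
"""

from __future__ import annotations

import csv
import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FastqParseError",
    "FastqReadFilterParams",
    "FilterCounts",
    "ExpressionMatrix",
    "CtMatrix",
    "filter_fastq",
    "filter_fastq_paired",
    "counts_to_tpm",
    "average_replicates",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_ct_tsv",
    "write_ct_tsv",
    "read_two_column_tsv",
]


class FastqParseError(ValueError):
    """Raised when a FASTQ stream cannot be parsed as 4-line records."""


@dataclass(frozen=True)
class FastqReadFilterParams:
    """Thresholds for the read-quality filter.

    A read is dropped if it contains any undetermined base ('N') or if
    strictly more than ``max_low_quality_positions`` bases have a Phred
    quality below ``low_quality_threshold``.
    """

    max_low_quality_positions: int = 10
    low_quality_threshold: int = 20
    reject_any_n: bool = True

    def __post_init__(self) -> None:
        if self.max_low_quality_positions < 0:
            raise ValueError("max_low_quality_positions must be non-negative")
        if not 0 <= self.low_quality_threshold <= 93:
            raise ValueError("low_quality_threshold must be in [0, 93]")


@dataclass(frozen=True)
class FilterCounts:
    """Partition of the input reads by filter outcome."""

    kept: int
    dropped_n: int
    dropped_quality: int

    @property
    def total(self) -> int:
        return self.kept + self.dropped_n + self.dropped_quality

    def to_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "dropped_N": self.dropped_n,
            "dropped_quality": self.dropped_quality,
            "total": self.total,
        }


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _fastq_format(phred_offset: int) -> str:
    if phred_offset == 33:
        return "fastq"
    if phred_offset == 64:
        return "fastq-illumina"
    raise ValueError(f"unsupported Phred offset {phred_offset}; use 33 or 64")


def _parse_fastq(handle: IO[str], fmt: str) -> Iterator[SeqRecord]:
    """Yield records, converting parser failures into indexed errors."""
    it = SeqIO.parse(handle, fmt)
    index = 0
    while True:
        try:
            record = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ record at index {index}: {exc}") from exc
        yield record
        index += 1


def _classify_read(record: SeqRecord, params: FastqReadFilterParams) -> str:
    seq = str(record.seq)
    quals = record.letter_annotations["phred_quality"]
    if len(quals) != len(seq):
        raise FastqParseError(
            f"record {record.id!r}: sequence and quality lengths differ "
            f"({len(seq)} vs {len(quals)})"
        )
    if params.reject_any_n and "N" in seq.upper():
        return "N"
    n_low = sum(q < params.low_quality_threshold for q in quals)
    if n_low > params.max_low_quality_positions:
        return "quality"
    return "keep"


def filter_fastq(
    in_path: str | Path,
    out_path: str | Path | None = None,
    params: FastqReadFilterParams | None = None,
    phred_offset: int = 33,
) -> FilterCounts:
    """Filter a FASTQ file, writing kept reads to ``out_path`` if given.

    Returns counts that partition the input: kept + dropped_N +
    dropped_quality equals the number of input reads.
    """
    params = params or FastqReadFilterParams()
    fmt = _fastq_format(phred_offset)
    kept = dropped_n = dropped_quality = 0
    out_handle = _open_maybe_gzip(out_path, "wt") if out_path is not None else None
    try:
        with _open_maybe_gzip(in_path) as handle:
            for record in _parse_fastq(handle, fmt):
                verdict = _classify_read(record, params)
                if verdict == "keep":
                    kept += 1
                    if out_handle is not None:
                        SeqIO.write(record, out_handle, fmt)
                elif verdict == "N":
                    dropped_n += 1
                else:
                    dropped_quality += 1
    finally:
        if out_handle is not None:
            out_handle.close()
    return FilterCounts(kept=kept, dropped_n=dropped_n, dropped_quality=dropped_quality)


def filter_fastq_paired(
    in_path_1: str | Path,
    in_path_2: str | Path,
    out_path_1: str | Path | None = None,
    out_path_2: str | Path | None = None,
    params: FastqReadFilterParams | None = None,
    phred_offset: int = 33,
) -> FilterCounts:
    """Paired-end filter: a pair is dropped when either mate fails.

    Counts are in read pairs; an 'N' in either mate takes precedence over
    the low-quality reason.
    """
    params = params or FastqReadFilterParams()
    fmt = _fastq_format(phred_offset)
    kept = dropped_n = dropped_quality = 0
    out1 = _open_maybe_gzip(out_path_1, "wt") if out_path_1 is not None else None
    out2 = _open_maybe_gzip(out_path_2, "wt") if out_path_2 is not None else None
    try:
        with _open_maybe_gzip(in_path_1) as h1, _open_maybe_gzip(in_path_2) as h2:
            it1, it2 = _parse_fastq(h1, fmt), _parse_fastq(h2, fmt)
            while True:
                r1 = next(it1, None)
                r2 = next(it2, None)
                if r1 is None and r2 is None:
                    break
                if r1 is None or r2 is None:
                    raise FastqParseError("paired FASTQ files have unequal read counts")
                v1, v2 = _classify_read(r1, params), _classify_read(r2, params)
                if v1 == "keep" and v2 == "keep":
                    kept += 1
                    if out1 is not None:
                        SeqIO.write(r1, out1, fmt)
                    if out2 is not None:
                        SeqIO.write(r2, out2, fmt)
                elif "N" in (v1, v2):
                    dropped_n += 1
                else:
                    dropped_quality += 1
    finally:
        for h in (out1, out2):
            if h is not None:
                h.close()
    return FilterCounts(kept=kept, dropped_n=dropped_n, dropped_quality=dropped_quality)


def counts_to_tpm(counts: pd.DataFrame, lengths: Sequence[float] | pd.Series) -> pd.DataFrame:
    """Convert raw counts (gene x sample) to TPM given per-gene lengths.

    Per sample: rate_i = count_i / length_i, TPM_i = 1e6 * rate_i / sum(rate).
    Every output column sums to 1e6.
    """
    if isinstance(lengths, pd.Series):
        missing = counts.index.difference(lengths.index)
        if len(missing):
            raise ValueError(f"missing lengths for genes: {sorted(missing)[:5]}")
        lengths = lengths.reindex(counts.index)
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != (counts.shape[0],):
        raise ValueError(
            f"lengths has {lengths.shape[0] if lengths.ndim else 0} entries "
            f"for {counts.shape[0]} genes"
        )
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive and finite")
    values = counts.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ValueError("counts must be non-negative and finite")
    rates = values / lengths[:, None]
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"sample(s) with all-zero counts, TPM undefined: {bad}")
    tpm = rates * 1e6 / totals
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


@dataclass
class ExpressionMatrix:
    """Gene x condition TPM values with replicate provenance."""

    gene_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray
    replicate_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.condition_labels = list(self.condition_labels)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene id: {dup!r}")
        if len(set(self.condition_labels)) != len(self.condition_labels):
            dup = _first_duplicate(self.condition_labels)
            raise ValueError(f"duplicate condition label: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.condition_labels)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_labels)} conditions"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TPM values must be finite")
        if np.any(self.values < 0):
            raise ValueError("TPM values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, replicate_map: dict[str, str] | None = None) -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index.astype(str)),
            condition_labels=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
            replicate_map=replicate_map,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene"),
                            columns=self.condition_labels)

    def subset(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        frame = self.to_frame()
        missing = [g for g in gene_ids if g not in frame.index]
        if missing:
            raise KeyError(f"gene(s) not in matrix: {missing[:5]}")
        return ExpressionMatrix.from_frame(frame.loc[list(gene_ids)], self.replicate_map)


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for item in items:
        if item in seen:
            return item
        seen.add(item)
    return ""


def average_replicates(tpm: pd.DataFrame, replicate_map: Mapping[str, str]) -> ExpressionMatrix:
    """Average biological-replicate columns on the linear TPM scale.

    Condition order follows first appearance in ``replicate_map``.
    """
    unmapped = [c for c in tpm.columns if c not in replicate_map]
    if unmapped:
        raise ValueError(f"sample column(s) not in replicate map: {unmapped}")
    conditions: list[str] = []
    for sample, condition in replicate_map.items():
        if condition not in conditions:
            conditions.append(condition)
    columns = {}
    for condition in conditions:
        samples = [s for s, c in replicate_map.items() if c == condition and s in tpm.columns]
        if not samples:
            raise ValueError(f"condition {condition!r} has no sample columns in the matrix")
        columns[condition] = tpm[samples].mean(axis=1)
    averaged = pd.DataFrame(columns, index=tpm.index)[conditions]
    return ExpressionMatrix.from_frame(averaged, replicate_map=dict(replicate_map))


@dataclass
class CtMatrix:
    """Gene x sample quantification-cycle (Ct) values.

    ``groups`` optionally maps every sample to a condition label;
    ``efficiencies`` optionally maps genes to amplification efficiency E
    (E = 1 means perfect doubling per cycle).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    ct_values: np.ndarray
    groups: dict[str, str] | None = None
    efficiencies: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.ct_values = np.asarray(self.ct_values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"duplicate gene id: {_first_duplicate(self.gene_ids)!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"duplicate sample id: {_first_duplicate(self.sample_ids)!r}")
        if self.ct_values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("ct_values shape does not match gene and sample ids")
        if not np.all(np.isfinite(self.ct_values)):
            raise ValueError("Ct values must be finite")
        if np.any(self.ct_values <= 0) or np.any(self.ct_values > 45):
            raise ValueError("Ct values must lie in (0, 45]")
        if self.groups is not None:
            uncovered = [s for s in self.sample_ids if s not in self.groups]
            if uncovered:
                raise ValueError(f"groups do not cover sample(s): {uncovered}")
        if self.efficiencies is not None:
            for gene, eff in self.efficiencies.items():
                if not (0 < eff <= 1.2):
                    raise ValueError(f"efficiency for {gene!r} must be in (0, 1.2], got {eff}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        groups: dict[str, str] | None = None,
        efficiencies: dict[str, float] | None = None,
    ) -> "CtMatrix":
        return cls(
            gene_ids=list(frame.index.astype(str)),
            sample_ids=list(frame.columns.astype(str)),
            ct_values=frame.to_numpy(dtype=float),
            groups=groups,
            efficiencies=efficiencies,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct_values, index=pd.Index(self.gene_ids, name="gene"),
                            columns=self.sample_ids)

    def efficiency_array(self) -> np.ndarray:
        """Per-gene efficiency vector, defaulting to 1.0 (perfect doubling)."""
        if self.efficiencies is None:
            return np.ones(self.n_genes)
        return np.array([self.efficiencies.get(g, 1.0) for g in self.gene_ids])


def _read_matrix_tsv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    path = Path(path)
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 2:
            raise ValueError(f"{path}: header must have a gene column and >=1 value column")
        labels = header[1:]
        gene_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for row_number, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: row {row_number} has {len(row)} fields, expected {len(header)}"
                )
            gene = row[0]
            if gene in seen:
                raise ValueError(f"{path}: duplicate gene id {gene!r} at row {row_number}")
            seen.add(gene)
            try:
                values = [float(cell) for cell in row[1:]]
            except ValueError:
                bad = next(c for c in row[1:] if not _is_number(c))
                raise ValueError(
                    f"{path}: non-numeric cell {bad!r} at row {row_number}"
                ) from None
            if any(not np.isfinite(v) for v in values):
                raise ValueError(f"{path}: non-finite value at row {row_number}")
            gene_ids.append(gene)
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return gene_ids, labels, np.array(rows, dtype=float)


def _is_number(cell: str) -> bool:
    try:
        float(cell)
    except ValueError:
        return False
    return np.isfinite(float(cell))


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a gene x condition TPM matrix from TSV (first column = gene id)."""
    gene_ids, labels, values = _read_matrix_tsv(path)
    return ExpressionMatrix(gene_ids=gene_ids, condition_labels=labels, values=values)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV that round-trips through :func:`read_expression_tsv`."""
    _write_matrix_tsv(matrix.gene_ids, matrix.condition_labels, matrix.values, path)


def read_ct_tsv(
    path: str | Path,
    groups: dict[str, str] | None = None,
    efficiencies: dict[str, float] | None = None,
) -> CtMatrix:
    """Read a gene x sample Ct matrix from TSV."""
    gene_ids, sample_ids, values = _read_matrix_tsv(path)
    return CtMatrix(gene_ids=gene_ids, sample_ids=sample_ids, ct_values=values,
                    groups=groups, efficiencies=efficiencies)


def write_ct_tsv(matrix: CtMatrix, path: str | Path) -> None:
    _write_matrix_tsv(matrix.gene_ids, matrix.sample_ids, matrix.ct_values, path)


def _write_matrix_tsv(gene_ids: Sequence[str], labels: Sequence[str],
                      values: np.ndarray, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", *labels])
        for gene, row in zip(gene_ids, values):
            writer.writerow([gene, *(repr(float(v)) for v in row)])


def read_two_column_tsv(path: str | Path) -> dict[str, str]:
    """Read an ordered key -> value map (e.g. sample -> condition) from TSV."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        for row_number, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(f"{path}: row {row_number} must have exactly 2 columns")
            key, value = row
            if key in mapping:
                raise ValueError(f"{path}: duplicate key {key!r} at row {row_number}")
            mapping[key] = value
    if not mapping:
        raise ValueError(f"{path}: no entries")
    return mapping
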