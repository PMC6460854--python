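"""Linear calibration between RT-qPCR Ct and RNA-Seq log2(TPM).

A single global ordinary-least-squares line is fitted over pooled
(gene, sample) pairs; known-unstable genes can be excluded by id.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CalibrationFit", "fit_ct_tpm", "predict_ct", "fit_from_pairs"]

PAIRS_COLUMNS = ("gene", "sample", "log2_tpm", "ct")


@dataclass(frozen=True)
class CalibrationFit:
    """Ct = slope * log2(TPM) + intercept."""

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("a calibration fit needs >=3 points")
        if abs(self.r_squared - self.pearson_r**2) > 1e-9:
            raise ValueError("r_squared must equal pearson_r**2")

    def to_dict(self) -> dict:
        return asdict(self)


def fit_ct_tpm(log2_tpm: Sequence[float], ct: Sequence[float]) -> CalibrationFit:
    """OLS of Ct on log2(TPM) with Pearson r and its two-sided p-value."""
    x = np.asarray(log2_tpm, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("log2_tpm and ct must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError(f"need >=3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log2(TPM): slope undefined")
    res = stats.linregress(x, y)
    # constant Ct: correlation undefined, report r = 0 (no linear relation)
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=r,
        r_squared=r**2,
        p_value=p,
        n_points=int(x.size),
    )


def predict_ct(fit: CalibrationFit, log2_tpm):
    """Predicted Ct = slope * log2_tpm + intercept (vectorized)."""
    x = np.asarray(log2_tpm, dtype=float)
    result = fit.slope * x + fit.intercept
    return float(result) if np.isscalar(log2_tpm) or x.ndim == 0 else result


def fit_from_pairs(pairs: pd.DataFrame, exclude: Iterable[str] = ()) -> CalibrationFit:
    """Fit from a long table with columns gene, sample, log2_tpm, ct.

    Rows whose gene is in ``exclude`` are dropped before fitting.
    """
    missing = [c for c in PAIRS_COLUMNS if c not in pairs.columns]
    if missing:
        raise ValueError(f"pairs table missing column(s): {missing}")
    excluded = set(exclude)
    kept = pairs[~pairs["gene"].isin(excluded)]
    if kept.empty:
        raise ValueError("no observations left after exclusion")
    return fit_ct_tpm(kept["log2_tpm"].to_numpy(), kept["ct"].to_numpy())
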