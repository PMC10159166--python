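"""Drift removal, windowing, IQR outlier filtering and 0-1 normalization.

Raw plant electrical recordings carry a slow drift that dominates the
stochastic response of interest; a zero-phase Butterworth high-pass
stands in for the study-specific optimal IIR design. Feature tables are
then cleaned with an interquartile-range rule and min-max scaled to
[0, 1] before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .features import FEATURE_NAMES


@dataclass(frozen=True)
class FilterConfig:
    """High-pass drift-removal filter (Butterworth, zero-phase)."""

    cutoff: float = 0.05  # Hz
    order: int = 2
    family: str = "butterworth"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.family != "butterworth":
            raise ValueError("only the butterworth family is supported")


@dataclass(frozen=True)
class OutlierConfig:
    """IQR band filter on feature columns.

    ``rule="as_printed"`` keeps values in ``(Q1 - n*IQR, Q1 + n*IQR)`` —
    the literal, asymmetric condition the methodology states, with Q1 on
    both bounds. ``rule="conventional"`` uses the standard
    ``(Q1 - n*IQR, Q3 + n*IQR)`` band.
    """

    n: float = 6.0
    rule: str = "as_printed"

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.rule not in ("as_printed", "conventional"):
            raise ValueError("rule must be 'as_printed' or 'conventional'")


def highpass_filter(samples: np.ndarray, fs: float,
                    cfg: FilterConfig = FilterConfig()) -> np.ndarray:
    """Zero-phase high-pass filtering of a voltage trace.

    Applies the Butterworth filter forward and backward (filtfilt) so the
    output has no phase distortion and the same length as the input.
    """
    samples = np.asarray(samples, float)
    if cfg.cutoff >= fs / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency fs/2")
    if samples.size < 3 * cfg.order:
        raise ValueError("input too short for the requested filter order")
    sos = signal.butter(cfg.order, cfg.cutoff, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, samples)


def segment(samples: np.ndarray, block_len: int) -> list[np.ndarray]:
    """Cut a trace into floor(N / block_len) non-overlapping blocks.

    The trailing remainder is discarded; a trace shorter than one block
    yields an empty list.
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    samples = np.asarray(samples, float)
    n_blocks = samples.size // block_len
    return [samples[i * block_len:(i + 1) * block_len].copy() for i in range(n_blocks)]


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in FEATURE_NAMES if c in table.columns]


def outlier_mask(table: pd.DataFrame, cfg: OutlierConfig = OutlierConfig()) -> np.ndarray:
    """Boolean keep-mask of the IQR rule; a row fails if ANY feature does.

    Quartiles use linear interpolation between order statistics. Rows
    containing non-finite feature values are always dropped (degenerate
    blocks flag themselves non-finite upstream).
    """
    cols = _feature_columns(table)
    if not cols or table.empty:
        raise ValueError("feature table is empty")
    values = table[cols].to_numpy(float)
    keep = np.all(np.isfinite(values), axis=1)
    finite = values[keep]
    if finite.size == 0:
        return keep
    q1 = np.percentile(finite, 25, axis=0)
    q3 = np.percentile(finite, 75, axis=0)
    iqr = q3 - q1
    for j, col in enumerate(cols):
        if iqr[j] == 0:
            warnings.warn(
                f"feature {col!r} has zero IQR; outlier band degenerates to equality",
                RuntimeWarning,
                stacklevel=2,
            )
    lower = q1 - cfg.n * iqr
    upper = (q1 if cfg.rule == "as_printed" else q3) + cfg.n * iqr
    with np.errstate(invalid="ignore"):
        inside = (values > lower) & (values < upper)
        # zero-IQR features degenerate to an equality band around Q1
        degenerate = iqr == 0
        if np.any(degenerate):
            inside[:, degenerate] = values[:, degenerate] == q1[degenerate]
    return keep & np.all(inside, axis=1)


def remove_outliers(table: pd.DataFrame,
                    cfg: OutlierConfig = OutlierConfig()) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop rows violating the IQR band; returns (filtered table, keep-mask)."""
    mask = outlier_mask(table, cfg)
    return table.loc[mask].reset_index(drop=True), mask


def retention_curve(table: pd.DataFrame, n_values,
                    rule: str = "as_printed") -> np.ndarray:
    """Fraction of rows retained by the IQR rule for each band width n."""
    fractions = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for n in n_values:
            mask = outlier_mask(table, OutlierConfig(n=n, rule=rule))
            fractions.append(mask.mean())
    return np.asarray(fractions)


def minmax_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Scale every feature column to [0, 1]: x' = (x - min) / (max - min).

    Labels and row order are untouched. A constant feature cannot be
    scaled and raises, naming the column.
    """
    out = table.copy()
    for col in _feature_columns(table):
        x = out[col].to_numpy(float)
        lo, hi = np.nanmin(x), np.nanmax(x)
        if hi <= lo:
            raise ValueError(f"feature {col!r} is constant; cannot min-max normalize")
        out[col] = (x - lo) / (hi - lo)
    out.attrs["normalized"] = True
    return out
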