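"""Comparator measures: spike counting, average power, Hurst exponent.

These are the three established single-trace measures against which
Markovian Entropy is benchmarked. Each consumes one trace and returns one
number (plus diagnostics).

Spike counting uses an amplitude-ratio onset rule: a spike starts at a time
point whose value reaches at least 150% of the previous point's value, and
persists while the trace stays at or above the value attained at the onset
point; excursions shorter than two time points are not counted.

Average power is the Parseval / time-domain form for discrete signals,
``(1/T) * sum x_t^2``.

The Hurst exponent is estimated by rescaled-range (R/S) analysis over a
randomly placed dyadic window pyramid: one 512-point window, its two
256-point halves, four 128-point quarters, ... down to 8-point windows,
with the OLS slope of log2(mean R/S) against log2(window size) as the
estimate. H ≈ 0.5 indicates a memoryless series, H > 0.5 persistence,
H < 0.5 antipersistence; estimates above 1 are flagged for exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trace_io import CalciumTrace

__all__ = [
    "SpikeParams",
    "SpikeCountResult",
    "HurstParams",
    "HurstResult",
    "ConstantSegmentError",
    "count_spikes",
    "average_power",
    "rescaled_range",
    "hurst_exponent",
]


class ConstantSegmentError(ValueError):
    """Raised when R/S is requested for a segment with no variance."""


@dataclass(frozen=True)
class SpikeParams:
    """Spike-detection thresholds.

    onset_ratio : minimum ratio of a point to its predecessor for that
        point to qualify as a spike onset (default 1.5, i.e. 150%).
    min_duration : minimum number of time points the trace must remain at
        or above the onset value for the excursion to count (default 2).
    """

    onset_ratio: float = 1.5
    min_duration: int = 2

    def __post_init__(self) -> None:
        if not self.onset_ratio > 1:
            raise ValueError("onset_ratio must be > 1")
        if self.min_duration < 1:
            raise ValueError("min_duration must be >= 1")


@dataclass(frozen=True)
class SpikeCountResult:
    count: int
    spans: tuple[tuple[int, int], ...]  # (onset index, last index at/above onset value)
    skipped_points: int  # onset tests skipped because the previous value was <= 0


def _values(trace: CalciumTrace | np.ndarray) -> np.ndarray:
    if isinstance(trace, CalciumTrace):
        return trace.values
    v = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values")
    return v


def count_spikes(
    trace: CalciumTrace | np.ndarray, params: SpikeParams | None = None
) -> SpikeCountResult:
    """Count calcium spikes by the amplitude-ratio onset rule.

    Scans left to right. An onset occurs at index t when
    ``x[t] >= onset_ratio * x[t-1]`` and ``x[t-1] > 0`` (the ratio is
    undefined for non-positive predecessors, which can occur after baseline
    subtraction; such tests are skipped and tallied in ``skipped_points``).
    The spike spans every subsequent point with value >= the onset value and
    ends at the first point below it; it is counted only if the span
    contains at least ``min_duration`` points. Scanning resumes after the
    span, so spikes never overlap.
    """
    if params is None:
        params = SpikeParams()
    x = _values(trace)
    if x.size < 2:
        raise ValueError("trace must have at least 2 points")
    spans: list[tuple[int, int]] = []
    skipped = 0
    if np.all(x <= 0):
        warnings.warn("all-nonpositive trace: ratio onset rule cannot fire", stacklevel=2)
        return SpikeCountResult(0, (), int(x.size - 1))
    t = 1
    while t < x.size:
        prev = x[t - 1]
        if prev <= 0:
            skipped += 1
            t += 1
            continue
        if x[t] >= params.onset_ratio * prev:
            onset_val = x[t]
            end = t + 1
            while end < x.size and x[end] >= onset_val:
                end += 1
            span_len = end - t
            if span_len >= params.min_duration:
                spans.append((t, end - 1))
            # resume after the spike end (first sub-onset point)
            t = end + 1
        else:
            t += 1
    return SpikeCountResult(len(spans), tuple(spans), skipped)


def average_power(trace: CalciumTrace | np.ndarray) -> float:
    """Mean squared value of the trace, ``(1/T) * sum x_t^2``."""
    x = _values(trace)
    if x.size < 1:
        raise ValueError("empty trace")
    return float(np.mean(x**2))


def rescaled_range(segment: np.ndarray, sd_mode: str = "paper") -> float:
    """Mean of the (R/S)_i series of a segment.

    With X the segment, Y_i = X_i - mean(X), Z the cumulative sum of Y,
    R_i = max(Z_1..Z_i) - min(Z_1..Z_i), and S_i a standard-deviation
    series:

    - ``sd_mode="paper"``: S_i = sqrt((1/i) * sum_{k<=i} (X_k - u_k)^2)
      with u_k the running mean of the first k points (each term centred on
      its own prefix mean);
    - ``sd_mode="classic"``: S_i = population SD of the first i points
      (every term centred on u_i).

    Returns the mean of R_i/S_i over indices with S_i > 0 (constant
    prefixes are skipped rather than propagating infinities).

    Raises
    ------
    ConstantSegmentError
        If the segment is constant (every S_i is 0).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("segment must have at least 2 points")
    if sd_mode not in ("paper", "classic"):
        raise ValueError("sd_mode must be 'paper' or 'classic'")
    if x.min() == x.max():
        raise ConstantSegmentError("constant segment: R/S undefined")
    i = np.arange(1, x.size + 1, dtype=float)
    Z = np.cumsum(x - x.mean())
    R = np.maximum.accumulate(Z) - np.minimum.accumulate(Z)
    u = np.cumsum(x) / i
    if sd_mode == "paper":
        S = np.sqrt(np.cumsum((x - u) ** 2) / i)
    else:
        S = np.sqrt(np.maximum(np.cumsum(x**2) / i - u**2, 0.0))
    valid = S > 0
    return float(np.mean(R[valid] / S[valid]))


@dataclass(frozen=True)
class HurstParams:
    """Window layout and seed for rescaled-range Hurst estimation.

    max_window/min_window : dyadic extremes of the window pyramid
        (defaults 512 and 8; both must be powers of two).
    seed : seed for the random placement of the top-level window.
    sd_mode : which standard-deviation series :func:`rescaled_range` uses.
    """

    max_window: int = 512
    min_window: int = 8
    seed: int | None = None
    sd_mode: str = "paper"

    def __post_init__(self) -> None:
        for w in (self.max_window, self.min_window):
            if w < 2 or (w & (w - 1)) != 0:
                raise ValueError("window sizes must be powers of 2 (>= 2)")
        if not self.min_window < self.max_window:
            raise ValueError("min_window must be < max_window")


@dataclass(frozen=True)
class HurstResult:
    value: float
    excluded: bool  # True when H > 1 (estimator artifact; drop from population stats)
    window_start: int

    def __float__(self) -> float:
        return self.value


def hurst_exponent(
    trace: CalciumTrace | np.ndarray, params: HurstParams | None = None
) -> HurstResult:
    """Estimate the Hurst exponent of a trace by dyadic R/S analysis.

    One ``max_window``-length window is placed uniformly at random (seeded)
    in the trace. For each dyadic size s = max_window, max_window/2, ...,
    min_window the window is tiled from its left edge with contiguous
    sub-windows of size s and their rescaled ranges averaged (constant
    sub-windows are skipped). The estimate is the OLS slope of
    log2(mean R/S) against log2(s). Estimates with H > 1 are returned with
    ``excluded=True`` so population pipelines can drop them.
    """
    if params is None:
        params = HurstParams()
    x = _values(trace)
    if x.size < params.max_window:
        raise ValueError(
            f"trace length {x.size} shorter than max_window {params.max_window}"
        )
    rng = np.random.default_rng(params.seed)
    start = int(rng.integers(0, x.size - params.max_window + 1))
    window = x[start : start + params.max_window]
    if window.min() == window.max():
        raise ConstantSegmentError("constant window: Hurst undefined")
    sizes: list[int] = []
    mean_rs: list[float] = []
    s = params.max_window
    while s >= params.min_window:
        subs = window[: (params.max_window // s) * s].reshape(-1, s)
        vals = []
        for sub in subs:
            try:
                vals.append(rescaled_range(sub, sd_mode=params.sd_mode))
            except ConstantSegmentError:
                continue
        if vals:
            sizes.append(s)
            mean_rs.append(float(np.mean(vals)))
        s //= 2
    if len(sizes) < 2:
        raise ConstantSegmentError("too few non-constant windows for regression")
    slope = float(np.polyfit(np.log2(sizes), np.log2(mean_rs), 1)[0])
    return HurstResult(value=slope, excluded=slope > 1.0, window_start=start)
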