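"""Population-level comparison statistics and meta-analyses.

Two populations of per-cell measure values are compared with a two-sample
Kolmogorov–Smirnov test (significance) and Cohen's d (effect size),

    d = (mean(A) - mean(B)) / s_pooled,
    s_pooled^2 = ((|A|-1) s_A^2 + (|B|-1) s_B^2) / (|A| + |B| - 2),

with sample (n-1) variances. |d| is summarised into star bands at the
guideline edges 0.20 / 0.50 / 0.80 / 1.00 / 2.00 ("small" / "medium" /
"large" plus two extra bands for strongly separated calcium populations);
bands are lower-inclusive (|d| >= edge). KS p-values are Bonferroni-scaled
by the number of comparisons in the analysis (adjusted p = min(1, m*p)).

Two meta-analyses probe robustness:

- `subsample_separation`: how quickly the KS p-value falls as the sample
  size grows, estimated by repeated with-replacement subsampling, with an
  A-vs-A control that must stay null.
- `parameter_sweep`: Cohen's d of the Markovian Entropy comparison over a
  grid of (n, k), flagging where the sign of d flips relative to the
  (2, 1) reference cell — the data-sparseness artifact that appears when
  the transition matrix outgrows the trace length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .comparators import (
    ConstantSegmentError,
    HurstParams,
    SpikeParams,
    average_power,
    count_spikes,
    hurst_exponent,
)
from .markov_entropy import EntropyParams, markovian_entropy
from .synthetic import derive_seed
from .trace_io import TraceSet

__all__ = [
    "STAR_EDGES",
    "ComparisonResult",
    "star_band",
    "cohens_d",
    "ks_2sample",
    "measure_values",
    "compare_populations",
    "subsample_separation",
    "parameter_sweep",
    "SweepResult",
]

#: star-band edges on |d|, lower-inclusive, highest band first
STAR_EDGES: tuple[tuple[float, str], ...] = (
    (2.00, "*****"),
    (1.00, "****"),
    (0.80, "***"),
    (0.50, "**"),
    (0.20, "*"),
)

MEASURES = ("entropy", "spikes", "power", "hurst")


def star_band(d: float) -> str:
    """Map a Cohen's d to its star band ('ns' below |d| = 0.20)."""
    a = abs(float(d))
    for edge, stars in STAR_EDGES:
        if a >= edge:
            return stars
    return "ns"


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Signed Cohen's d, mean(A) - mean(B) over the pooled (n-1) SD.

    Raises ValueError when either sample has fewer than 2 points or the
    pooled SD is zero (d undefined).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 points for sample variances")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var <= 0:
        raise ValueError("pooled standard deviation is zero: d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def ks_2sample(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic two-sided p-value."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def measure_values(
    traceset: TraceSet,
    measure: str,
    entropy_params: EntropyParams | None = None,
    spike_params: SpikeParams | None = None,
    hurst_params: HurstParams | None = None,
) -> pd.DataFrame:
    """Per-cell values of one measure for a TraceSet.

    Returns a DataFrame with columns ``cell_id``, ``value`` and an
    ``excluded`` flag (True for Hurst estimates with H > 1 and for traces
    where the measure is undefined, e.g. a constant window). For the
    entropy measure, dead/constant cells yield value 0 with
    ``degenerate=True`` rather than exclusion.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {MEASURES}")
    rows = []
    for i, trace in enumerate(traceset):
        row: dict = {"cell_id": trace.cell_id, "excluded": False}
        try:
            if measure == "entropy":
                res = markovian_entropy(trace, entropy_params)
                row["value"] = res.value
                row["degenerate"] = res.degenerate
                row["unobserved_rows"] = res.unobserved_rows
            elif measure == "spikes":
                row["value"] = float(count_spikes(trace, spike_params).count)
            elif measure == "power":
                row["value"] = average_power(trace)
            else:
                hp = hurst_params if hurst_params is not None else HurstParams()
                if hp.seed is not None:
                    # independent window placement per cell, reproducible
                    hp = HurstParams(
                        max_window=hp.max_window,
                        min_window=hp.min_window,
                        seed=derive_seed(hp.seed, i),
                        sd_mode=hp.sd_mode,
                    )
                res = hurst_exponent(trace, hp)
                row["value"] = res.value
                row["excluded"] = res.excluded
        except ConstantSegmentError:
            row["value"] = np.nan
            row["excluded"] = True
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one two-population comparison under one measure."""

    measure: str
    pop_a: str
    pop_b: str
    n_a: int
    n_b: int
    ks_statistic: float
    p_value: float
    p_adjusted: float
    cohens_d: float
    star_band: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def compare_populations(
    set_a: TraceSet,
    set_b: TraceSet,
    measure: str,
    entropy_params: EntropyParams | None = None,
    spike_params: SpikeParams | None = None,
    hurst_params: HurstParams | None = None,
    n_comparisons_for_bonferroni: int = 1,
) -> ComparisonResult:
    """Compare two trace populations under one per-cell measure.

    Computes the measure for every cell (Hurst H > 1 and undefined values
    excluded first), then the KS test, Cohen's d (sign convention:
    mean(A) - mean(B), A first), the Bonferroni-adjusted p
    (min(1, m * p)) and the star band.
    """
    if n_comparisons_for_bonferroni < 1:
        raise ValueError("n_comparisons_for_bonferroni must be >= 1")
    vals = []
    for ts in (set_a, set_b):
        df = measure_values(
            ts, measure,
            entropy_params=entropy_params,
            spike_params=spike_params,
            hurst_params=hurst_params,
        )
        kept = df.loc[~df["excluded"], "value"].to_numpy(dtype=float)
        if kept.size < 2:
            raise ValueError(
                f"population {ts.name!r} yields fewer than 2 usable "
                f"{measure} values"
            )
        vals.append(kept)
    a, b = vals
    ks_stat, p = ks_2sample(a, b)
    d = cohens_d(a, b)
    return ComparisonResult(
        measure=measure,
        pop_a=set_a.name,
        pop_b=set_b.name,
        n_a=int(a.size),
        n_b=int(b.size),
        ks_statistic=ks_stat,
        p_value=p,
        p_adjusted=float(min(1.0, n_comparisons_for_bonferroni * p)),
        cohens_d=d,
        star_band=star_band(d),
    )


def subsample_separation(
    set_a_values: Sequence[float],
    set_b_values: Sequence[float],
    sizes: Sequence[int],
    reps: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean and SD of the KS p-value as a function of subsample size.

    For each size s, draws ``reps`` pairs of size-s with-replacement
    samples — one from each population — and records the two-sample KS
    p-value; also runs an A-vs-A control (both samples from A) that
    quantifies the null behaviour. Fully determined by ``seed``.

    Returns a tidy DataFrame with columns ``size``, ``comparison``
    ("a_vs_b" or "control_a_vs_a"), ``mean_p``, ``sd_p``.
    """
    a = np.asarray(set_a_values, dtype=float)
    b = np.asarray(set_b_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("populations must be nonempty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for size in sizes:
        if size < 2:
            raise ValueError("subsample sizes must be >= 2")
        for label, (x, y) in (
            ("a_vs_b", (a, b)),
            ("control_a_vs_a", (a, a)),
        ):
            ps = np.empty(reps)
            for r in range(reps):
                sx = x[rng.integers(0, x.size, size)]
                sy = y[rng.integers(0, y.size, size)]
                ps[r] = ks_2sample(sx, sy)[1]
            records.append(
                {
                    "size": int(size),
                    "comparison": label,
                    "mean_p": float(ps.mean()),
                    "sd_p": float(ps.std(ddof=1)) if reps > 1 else 0.0,
                }
            )
    return pd.DataFrame(records)


@dataclass(frozen=True)
class SweepResult:
    """Cohen's d of the entropy comparison over an (n, k) grid."""

    grid: pd.DataFrame  # columns: n, k, cohens_d
    reference: tuple[int, int]  # the (n, k) cell whose sign anchors the frontier
    sign_change_cells: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def d_at(self, n: int, k: int) -> float:
        sel = self.grid[(self.grid["n"] == n) & (self.grid["k"] == k)]
        if sel.empty:
            raise KeyError(f"(n={n}, k={k}) not in sweep grid")
        return float(sel["cohens_d"].iloc[0])


def parameter_sweep(
    set_a: TraceSet,
    set_b: TraceSet,
    n_values: Sequence[int],
    k_values: Sequence[int],
    truncate_to: int | None = None,
) -> SweepResult:
    """Cohen's d of entropy(A) vs entropy(B) over a grid of (n, k).

    Optionally truncates every trace to its first ``truncate_to`` points
    before analysis, which shrinks the usable data and pulls the
    sparseness artifact to smaller (n, k). The returned
    ``sign_change_cells`` lists the grid cells whose d has the opposite
    sign from the reference cell — (2, 1) when present, else the smallest
    (n, k) in the grid.
    """
    n_values = sorted(set(int(v) for v in n_values))
    k_values = sorted(set(int(v) for v in k_values))
    if not n_values or not k_values:
        raise ValueError("grid must be nonempty")
    if truncate_to is not None:
        min_len = min(min(len(t) for t in set_a), min(len(t) for t in set_b))
        if truncate_to > min_len:
            raise ValueError(f"truncate_to={truncate_to} exceeds shortest trace {min_len}")

    def values_for(ts: TraceSet, n: int, k: int) -> np.ndarray:
        out = np.empty(len(ts))
        for i, trace in enumerate(ts):
            v = trace.values if truncate_to is None else trace.values[:truncate_to]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sparse-regime warnings expected here
                out[i] = markovian_entropy(v, EntropyParams(n=n, k=k)).value
        return out

    records = []
    for n in n_values:
        for k in k_values:
            d = cohens_d(values_for(set_a, n, k), values_for(set_b, n, k))
            records.append({"n": n, "k": k, "cohens_d": d})
    grid = pd.DataFrame(records)
    ref = (2, 1) if (2 in n_values and 1 in k_values) else (n_values[0], k_values[0])
    d_ref = float(
        grid[(grid["n"] == ref[0]) & (grid["k"] == ref[1])]["cohens_d"].iloc[0]
    )
    flipped = tuple(
        (int(r["n"]), int(r["k"]))
        for _, r in grid.iterrows()
        if np.sign(r["cohens_d"]) != 0 and np.sign(r["cohens_d"]) == -np.sign(d_ref)
    )
    return SweepResult(grid=grid, reference=ref, sign_change_cells=flipped)
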