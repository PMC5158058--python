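"""Markovian Entropy of a calcium-activity time series.

The measure models a fluorescence trace as a k-th order, n-state Markov
process and scores how unpredictable its state transitions are:

1.  **Discretize** — split the observed values into n empirical quantiles
    and replace each value by the index of its quantile, giving a symbol
    sequence of the same length over the alphabet {0, ..., n-1}. Quantile
    binning needs no user thresholds, gives each state near-equal occupancy,
    and makes the measure exactly invariant under any strictly increasing
    transform of the signal.
2.  **Tally transitions** — slide over the sequence and count every
    (k-gram -> next symbol) transition into an n^k-by-n count matrix whose
    rows enumerate all k-grams in lexicographic order; row-normalise the
    observed rows into transition probabilities.
3.  **Score** — sum the Shannon entropies ``-sum_i p_i log2 p_i`` of the
    rows and divide by ``n^k * log2(n)``, the maximum attainable sum. The
    result lies in [0, 1]: 0 means every observed transition is
    deterministic, 1 means every k-gram's next state is uniformly random.

Unobserved k-grams contribute zero bits while remaining in the denominator,
so in the sparse regime (``n^k * n`` comparable to the trace length) the
value is depressed for mechanical rather than dynamical reasons; the
``unobserved_rows`` count and a warning surface that regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trace_io import CalciumTrace

__all__ = [
    "EntropyParams",
    "SymbolSequence",
    "TransitionModel",
    "EntropyResult",
    "discretize",
    "build_transition_model",
    "markovian_entropy",
]


@dataclass(frozen=True)
class EntropyParams:
    """Number of states ``n`` (>= 2) and Markov order ``k`` (>= 1).

    ``n = 2, k = 1`` is the recommended setting for traces of a few hundred
    points; larger values demand exponentially more data (the transition
    matrix has ``n^k * n`` entries).
    """

    n: int = 2
    k: int = 1

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class SymbolSequence:
    """A trace discretized over an alphabet of ``n`` quantile states."""

    symbols: np.ndarray
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int64)
        if s.ndim != 1:
            raise ValueError("symbols must be 1-D")
        if s.size and (s.min() < 0 or s.max() >= self.n):
            raise ValueError("symbols out of range [0, n)")
        object.__setattr__(self, "symbols", s)

    def __len__(self) -> int:
        return int(self.symbols.size)


@dataclass(frozen=True)
class TransitionModel:
    """k-gram -> next-state counts and row-normalised probabilities.

    Rows index all ``n^k`` k-grams lexicographically with the OLDEST symbol
    as the most significant digit; columns index the next state. Rows never
    observed in the data are all-zero in both matrices.
    """

    counts: np.ndarray
    probabilities: np.ndarray
    n: int
    k: int

    @property
    def row_observed(self) -> np.ndarray:
        """Boolean mask of rows with at least one observed transition."""
        return self.counts.sum(axis=1) > 0

    @property
    def n_unobserved_rows(self) -> int:
        return int((~self.row_observed).sum())


@dataclass(frozen=True)
class EntropyResult:
    """Normalized Markovian Entropy and its per-row decomposition.

    ``value`` is the fraction of the maximum ``n^k * log2(n)`` bits, in
    [0, 1]; ``row_entropies`` holds the raw per-row bits.
    """

    value: float
    row_entropies: np.ndarray
    unobserved_rows: int
    params: EntropyParams
    degenerate: bool = False


def _trace_values(trace: CalciumTrace | np.ndarray) -> np.ndarray:
    if isinstance(trace, CalciumTrace):
        return trace.values
    v = np.asarray(trace, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D trace of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in trace")
    return v


def discretize(trace: CalciumTrace | np.ndarray, n: int) -> SymbolSequence:
    """Quantile-discretize a trace into ``n`` states.

    Boundaries are the empirical quantiles at levels ``j/n`` for
    ``j = 1..n-1`` (linear interpolation between order statistics, the
    numpy default). A value's symbol is the number of boundaries strictly
    below it, so values tied with a boundary go to the LOWER state. A
    constant trace cannot be discretized meaningfully; it maps to all-zero
    symbols with ``degenerate=True``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    v = _trace_values(trace)
    if v.size == 0:
        raise ValueError("empty trace")
    if v.min() == v.max():
        return SymbolSequence(np.zeros(v.size, dtype=np.int64), n=n, degenerate=True)
    levels = np.arange(1, n) / n
    boundaries = np.quantile(v, levels, method="linear")
    # count of boundaries strictly below each value (boundaries are sorted)
    symbols = np.searchsorted(boundaries, v, side="left")
    return SymbolSequence(symbols.astype(np.int64), n=n, degenerate=False)


def build_transition_model(seq: SymbolSequence, k: int) -> TransitionModel:
    """Tally every k-gram -> next-symbol transition of a symbol sequence.

    For each position t in ``[k, len-1]`` the count at
    ``(row(seq[t-k:t]), seq[t])`` is incremented; total counts equal
    ``len(seq) - k``. Observed rows are then normalised by their row sums.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    s = seq.symbols
    n = seq.n
    if s.size <= k:
        raise ValueError(f"sequence length {s.size} must exceed k={k}")
    n_rows = n**k
    # row code of the k-gram ending just before t, oldest symbol most significant
    powers = n ** np.arange(k - 1, -1, -1, dtype=np.int64)
    grams = np.lib.stride_tricks.sliding_window_view(s[:-1], k) @ powers
    nxt = s[k:]
    counts = np.zeros((n_rows, n), dtype=np.int64)
    np.add.at(counts, (grams, nxt), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probabilities = np.where(row_sums > 0, counts / np.maximum(row_sums, 1), 0.0)
    return TransitionModel(counts=counts, probabilities=probabilities, n=n, k=k)


def _row_entropies_bits(probabilities: np.ndarray) -> np.ndarray:
    p = probabilities
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=1)


def markovian_entropy(
    trace: CalciumTrace | np.ndarray,
    params: EntropyParams | None = None,
    *,
    n: int | None = None,
    k: int | None = None,
) -> EntropyResult:
    """Normalized Markovian Entropy of a trace.

    Accepts either an :class:`EntropyParams` or ``n=``/``k=`` keywords.
    Returns an :class:`EntropyResult`; a degenerate (constant) trace yields
    value 0 with the flag set rather than an error, so population pipelines
    survive dead cells.
    """
    if params is None:
        params = EntropyParams(n=n if n is not None else 2, k=k if k is not None else 1)
    elif n is not None or k is not None:
        raise TypeError("pass either params or n/k keywords, not both")
    v = _trace_values(trace)
    if v.size <= params.k:
        raise ValueError(f"trace length {v.size} must exceed k={params.k}")
    n_rows = params.n**params.k
    if n_rows * params.n > v.size - params.k:
        warnings.warn(
            f"sparse regime: transition matrix has {n_rows * params.n} entries "
            f"but only {v.size - params.k} transitions are available; the "
            "entropy value will be mechanically depressed",
            stacklevel=2,
        )
    seq = discretize(v, params.n)
    if seq.degenerate:
        return EntropyResult(
            value=0.0,
            row_entropies=np.zeros(n_rows),
            unobserved_rows=n_rows - 1,
            params=params,
            degenerate=True,
        )
    model = build_transition_model(seq, params.k)
    row_ent = _row_entropies_bits(model.probabilities)
    value = float(row_ent.sum() / (n_rows * np.log2(params.n)))
    return EntropyResult(
        value=value,
        row_entropies=row_ent,
        unobserved_rows=model.n_unobserved_rows,
        params=params,
        degenerate=False,
    )
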