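"""Synthetic calcium-like traces with known ground truth.

Three generators cover the qualitative trace families seen in calcium
imaging, each fully seeded:

- **Markov-chain traces** (`gen_chain_trace`): a discrete chain over n
  fluorescence levels plus Gaussian noise. The generating chain's exact
  normalized entropy is available (`true_entropy`), so the Markovian
  Entropy estimator can be checked against an analytic target.
- **Spike traces** (`gen_spike_trace`): a flat baseline plus Bernoulli
  events convolved with an exponential decay — the "clean action
  potential" regime where spike counting is the natural measure.
- **Irregular traces** (`gen_irregular_trace`): stationary AR(1) noise
  around a mean level — the complex, irregular activity of progenitor-like
  cells that resists feature-based description.

`add_trend` superimposes slow linear or exponential-decay trends for
testing detrending, and `gen_population` builds seeded TraceSets with a
prefix-stable per-cell seed derivation: extending a population keeps the
existing cells' traces bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .trace_io import CalciumTrace, TraceSet

__all__ = [
    "ChainSpec",
    "SpikeTraceSpec",
    "IrregularTraceSpec",
    "gen_chain_trace",
    "symmetric_two_state",
    "true_entropy",
    "gen_spike_trace",
    "gen_irregular_trace",
    "add_trend",
    "gen_population",
    "derive_seed",
]


def derive_seed(master_seed: int, index: int) -> int:
    """Stable per-cell seed from a master seed and cell index.

    Uses numpy's SeedSequence hashing, truncated below 2^31; cell i's seed
    never depends on how many cells are generated (prefix property).
    """
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ChainSpec:
    """A noisy observation of an n-state Markov chain.

    transition_matrix : n-by-n row-stochastic matrix.
    levels : strictly increasing fluorescence level per state.
    noise_sd : SD of the additive Gaussian noise; must stay below half the
        minimum level gap so quantile binning recovers the states.
    """

    transition_matrix: tuple[tuple[float, ...], ...]
    levels: tuple[float, ...]
    noise_sd: float = 0.05
    length: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition_matrix must be square")
        if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition_matrix rows must be nonnegative and sum to 1")
        lv = np.asarray(self.levels, dtype=float)
        if lv.size != P.shape[0]:
            raise ValueError("levels must match the number of states")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("levels must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.noise_sd >= np.min(np.diff(lv)) / 2:
            raise ValueError("noise_sd must be < half the minimum level gap")
        if self.length < 2:
            raise ValueError("length must be >= 2")
        object.__setattr__(
            self, "transition_matrix", tuple(tuple(row) for row in P.tolist())
        )
        object.__setattr__(self, "levels", tuple(lv.tolist()))

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.transition_matrix, dtype=float)


def symmetric_two_state(stay_probability: float, **kwargs) -> ChainSpec:
    """Convenience: symmetric 2-state chain with the given stay probability."""
    p = float(stay_probability)
    return ChainSpec(
        transition_matrix=((p, 1 - p), (1 - p, p)), levels=(0.0, 1.0), **kwargs
    )


def _stationary_distribution(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def gen_chain_trace(spec: ChainSpec) -> tuple[CalciumTrace, np.ndarray]:
    """Sample a chain trace; returns (trace, true symbol path).

    The initial state is drawn from the chain's stationary distribution;
    emissions are ``levels[state] + N(0, noise_sd)``.
    """
    P = spec.matrix
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.length)
    cum_rows = np.cumsum(P, axis=1)
    cum_pi = np.cumsum(_stationary_distribution(P))
    states = np.empty(spec.length, dtype=np.int64)
    states[0] = np.searchsorted(cum_pi, u[0], side="right")
    for t in range(1, spec.length):
        states[t] = np.searchsorted(cum_rows[states[t - 1]], u[t], side="right")
    values = np.asarray(spec.levels)[states]
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.length)
    trace = CalciumTrace(cell_id=f"chain_{spec.seed}", values=values)
    return trace, states


def true_entropy(transition_matrix: np.ndarray, n: int | None = None) -> float:
    """Exact normalized entropy of a row-stochastic matrix (the k=1 target).

    ``sum_rows H(row) / (n * log2 n)`` with ``0 * log2 0 = 0``. This is the
    population value the Markovian Entropy estimator converges to on long
    traces from the chain (all rows observed, unweighted row sum).
    """
    P = np.asarray(transition_matrix, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition_matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("rows must be nonnegative and sum to 1")
    if n is None:
        n = P.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, -P * np.log2(np.where(P > 0, P, 1.0)), 0.0)
    return float(terms.sum() / (n * np.log2(n)))


@dataclass(frozen=True)
class SpikeTraceSpec:
    """Baseline + Bernoulli spike events + noise.

    Each event contributes a transient with a one-frame rise (half
    amplitude at the event frame, full amplitude one frame later) followed
    by an exponential decay with constant ``decay_tau``. The finite rise
    mirrors real indicator kinetics, where the peak lags the onset by at
    least one sample — which is also what lets a ratio-onset spike counter
    observe the excursion at or above its onset value for more than one
    time point.
    """

    baseline: float = 1.0
    spike_rate: float = 0.01
    amplitude: float = 3.0
    decay_tau: float = 5.0
    noise_sd: float = 0.02
    length: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.spike_rate < 1:
            raise ValueError("spike_rate must be in [0, 1)")
        if self.amplitude < 0 or self.decay_tau <= 0 or self.noise_sd < 0:
            raise ValueError("amplitude >= 0, decay_tau > 0, noise_sd >= 0 required")
        if self.spike_rate > 0 and self.amplitude < 0.5 * self.baseline:
            raise ValueError(
                "amplitude must be >= 0.5 * baseline for the 150% onset rule to fire"
            )
        if self.length < 2:
            raise ValueError("length must be >= 2")


def gen_spike_trace(spec: SpikeTraceSpec) -> tuple[CalciumTrace, np.ndarray]:
    """Sample a spike-dominated trace; returns (trace, true event times)."""
    rng = np.random.default_rng(spec.seed)
    events = np.flatnonzero(rng.random(spec.length) < spec.spike_rate)
    t = np.arange(spec.length, dtype=float)
    values = np.full(spec.length, float(spec.baseline))
    for te in events:
        values[te] += 0.5 * spec.amplitude
        if te + 1 < spec.length:
            tail = t[te + 1 :] - (te + 1)
            values[te + 1 :] += spec.amplitude * np.exp(-tail / spec.decay_tau)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=spec.length)
    trace = CalciumTrace(cell_id=f"spikes_{spec.seed}", values=values)
    return trace, events


@dataclass(frozen=True)
class IrregularTraceSpec:
    """Stationary AR(1) activity around a mean level."""

    ar_coefficient: float = 0.8
    innovation_sd: float = 1.0
    mean_level: float = 0.0
    length: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.ar_coefficient) < 1:
            raise ValueError("|ar_coefficient| must be < 1 (stationarity)")
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be > 0")
        if self.length < 2:
            raise ValueError("length must be >= 2")


def gen_irregular_trace(spec: IrregularTraceSpec) -> CalciumTrace:
    """Sample a stationary AR(1) trace (x0 drawn from the stationary law)."""
    rng = np.random.default_rng(spec.seed)
    a = spec.ar_coefficient
    x = np.empty(spec.length)
    x[0] = rng.normal(0.0, spec.innovation_sd / np.sqrt(1 - a**2))
    eps = rng.normal(0.0, spec.innovation_sd, size=spec.length - 1)
    for t in range(1, spec.length):
        x[t] = a * x[t - 1] + eps[t - 1]
    return CalciumTrace(cell_id=f"irregular_{spec.seed}", values=x + spec.mean_level)


def add_trend(
    trace: CalciumTrace, kind: str = "linear", magnitude: float = 1.0
) -> CalciumTrace:
    """Superimpose a slow trend: ``magnitude * t/T`` or ``magnitude * exp(-3t/T)``."""
    if kind not in ("linear", "exponential_decay"):
        raise ValueError("kind must be 'linear' or 'exponential_decay'")
    if not np.isfinite(magnitude):
        raise ValueError("magnitude must be finite")
    T = len(trace)
    t = np.arange(T, dtype=float)
    trend = magnitude * (t / T) if kind == "linear" else magnitude * np.exp(-3 * t / T)
    return CalciumTrace(
        cell_id=trace.cell_id,
        values=trace.values + trend,
        sampling_rate_hz=trace.sampling_rate_hz,
    )


def gen_population(
    spec: ChainSpec | SpikeTraceSpec | IrregularTraceSpec,
    n_cells: int,
    seed: int,
    name: str | None = None,
) -> TraceSet:
    """Generate a TraceSet of independent traces from one spec.

    Cell i's trace uses ``derive_seed(seed, i)`` in place of the spec's own
    seed, so the set is fully determined by the master seed and the first
    cells are unchanged when ``n_cells`` grows.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    traces: list[CalciumTrace] = []
    for i in range(n_cells):
        cell_spec = replace(spec, seed=derive_seed(seed, i))
        if isinstance(spec, ChainSpec):
            trace, _ = gen_chain_trace(cell_spec)
        elif isinstance(spec, SpikeTraceSpec):
            trace, _ = gen_spike_trace(cell_spec)
        elif isinstance(spec, IrregularTraceSpec):
            trace = gen_irregular_trace(cell_spec)
        else:
            raise TypeError(f"unsupported spec type {type(spec).__name__}")
        traces.append(
            CalciumTrace(cell_id=f"cell_{i + 1:04d}", values=trace.values)
        )
    return TraceSet(name=name if name is not None else "synthetic", traces=traces)
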