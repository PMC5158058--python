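"""Asymmetric-least-squares (AsLS) baseline correction.

Calcium recordings often ride on slow trends — photobleaching decay, focal
drift, slow accumulation — that corrupt trend-sensitive measures. The
Eilers–Boelens baseline estimator finds a smooth curve z minimising

    sum_i w_i (y_i - z_i)^2  +  lambda * sum_i (Delta^2 z_i)^2

where the weights are asymmetric: w_i = p where the signal sits above the
baseline (y_i > z_i) and w_i = 1 - p below it. With small p the baseline is
pushed underneath positive excursions (calcium transients) while the
second-difference penalty keeps it smooth. The weights are re-derived from
the current baseline and the penalised solve repeated until they stop
changing. Detrending subtracts the estimated baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .trace_io import CalciumTrace

__all__ = ["BaselineParams", "estimate_baseline", "detrend"]


@dataclass(frozen=True)
class BaselineParams:
    """Parameters of the AsLS baseline estimator.

    lam : smoothness penalty on second differences (larger = stiffer
        baseline). Default 1e5, in the canonical recommended range
        (1e2–1e9) for series of this length.
    p : asymmetry weight in (0, 1); the weight of points above the baseline.
        Default 0.01 — appropriate when excursions are positive-going, as
        calcium transients are.
    max_iter : cap on reweighting iterations (default 20).
    tol : convergence threshold on the maximum absolute weight change
        (weights take values p or 1-p, so convergence means no point
        switched sides).
    """

    lam: float = 1e5
    p: float = 0.01
    max_iter: int = 20
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be > 0")
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


def _values(trace: CalciumTrace | np.ndarray) -> np.ndarray:
    if isinstance(trace, CalciumTrace):
        return trace.values
    v = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input")
    return v


def estimate_baseline(
    trace: CalciumTrace | np.ndarray, params: BaselineParams | None = None
) -> np.ndarray:
    """Estimate the AsLS baseline of a trace.

    Each iteration solves the weighted penalised system
    ``(W + lam * D'D) z = W y`` exactly (sparse Cholesky-style solve), where
    D is the second-difference operator, then updates the weights to
    ``p`` above / ``1 - p`` below the new baseline. Weights start at 1
    (an ordinary penalised smooth) before the first asymmetric update.

    Returns an array of the same length as the input.
    """
    if params is None:
        params = BaselineParams()
    y = _values(trace)
    m = y.size
    if m < 4:
        raise ValueError(f"trace too short for baseline estimation: {m} < 4")

    D = sp.diags_array(
        [np.ones(m - 2), -2 * np.ones(m - 2), np.ones(m - 2)],
        offsets=[0, 1, 2],
        shape=(m - 2, m),
        format="csc",
    )
    DTD = (params.lam * (D.T @ D)).tocsc()
    w = np.ones(m)
    z = y
    for _ in range(params.max_iter):
        W = sp.diags_array(w, format="csc")
        z = spsolve(W + DTD, w * y)
        w_new = np.where(y > z, params.p, 1.0 - params.p)
        if np.max(np.abs(w_new - w)) <= params.tol:
            break
        w = w_new
    return np.asarray(z, dtype=float)


def detrend(
    trace: CalciumTrace, params: BaselineParams | None = None
) -> CalciumTrace:
    """Subtract the AsLS baseline from a trace.

    The result keeps the cell id and sampling metadata; values are
    ``y - baseline`` and therefore hover around zero away from transients.
    """
    baseline = estimate_baseline(trace, params)
    return CalciumTrace(
        cell_id=trace.cell_id,
        values=trace.values - baseline,
        sampling_rate_hz=trace.sampling_rate_hz,
    )
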