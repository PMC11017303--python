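"""Weighted pool-adjacent-violators (PAVA) for ordered exponential means.

The inner loop of the single-index fit maximizes, at fixed ``Lambda``, a
reduced likelihood equivalent to ``L`` independent exponential trials with
nondecreasing means ``r_1* <= ... <= r_L*``: trial ``l`` has ``m_l^d``
uncensored observations and observed mean ``eta_bar_l``.  The constrained
MLE coincides with the weighted least-squares isotonic fit of the
``eta_bar`` values with weights ``m_l^d``, which PAVA computes exactly in
linear time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = ["IsotonicProblem", "pava_weighted"]


@dataclass(frozen=True)
class IsotonicProblem:
    """Block means ``eta_bar_l >= 0`` and positive weights ``m_l^d``."""

    means: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        m = np.ascontiguousarray(self.means, dtype=float)
        w = np.ascontiguousarray(self.weights, dtype=float)
        if m.ndim != 1 or w.ndim != 1 or m.shape != w.shape:
            raise ValueError("means and weights must be matching 1-d arrays")
        if m.shape[0] < 1:
            raise ValueError("empty isotonic problem")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("means must be finite and nonnegative")
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "weights", w)


@njit(cache=False)
def _pava(y, w):  # pragma: no cover - exercised through pava_weighted
    L = y.shape[0]
    mean = np.empty(L)
    wsum = np.empty(L)
    count = np.empty(L, dtype=np.int64)
    top = -1
    for i in range(L):
        top += 1
        mean[top] = y[i]
        wsum[top] = w[i]
        count[top] = 1
        # pool while the last two blocks violate the order constraint
        while top > 0 and mean[top - 1] > mean[top]:
            tw = wsum[top - 1] + wsum[top]
            mean[top - 1] = (wsum[top - 1] * mean[top - 1] + wsum[top] * mean[top]) / tw
            wsum[top - 1] = tw
            count[top - 1] += count[top]
            top -= 1
    out = np.empty(L)
    j = 0
    for k in range(top + 1):
        for _ in range(count[k]):
            out[j] = mean[k]
            j += 1
    return out


def pava_weighted(problem: IsotonicProblem) -> np.ndarray:
    """Nondecreasing weighted-mean fit ``r_1* <= ... <= r_L*``.

    Returns the max-min of weighted running averages,

        r_l* = max_{k <= l} min_{l <= q} sum_{k<=s<=q} w_s eta_bar_s
                                          / sum_{k<=s<=q} w_s,

    computed by the stack-based linear-time algorithm.  Each output level
    is the weighted average of a contiguous run of input means.
    """
    return _pava(problem.means, problem.weights)
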