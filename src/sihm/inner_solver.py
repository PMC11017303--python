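"""Inner profile step: link and baseline hazard at a fixed index direction.

For a fixed unit vector ``beta`` the profile step alternates two closed-form
updates until a fixed point is reached:

(M1) holding ``Lambda`` fixed, the constrained MLE of the link values at the
     distinct uncensored index values is a weighted isotonic (PAVA) fit of
     the block means ``eta_bar_l = (1/m_l^d) sum_i Lambda(y_i) I(z_i in I_l)``
     with weights ``m_l^d``;
(M2) holding ``r`` fixed, the full likelihood is maximized by the
     Breslow-type estimator

         Lambda*(t) = sum_i delta_i I(y_i <= t)
                      / sum_j I(y_j >= y_i) / r(z_j),

     rescaled to ``Lambda = Lambda* / Lambda*(tau)`` so ``Lambda(tau) = 1``.

Subjects whose index exceeds the largest uncensored value (interval
``I_{L+1}``) are all censored; the algorithm assigns them the last link
level ``r_L`` both in the likelihood and in the Breslow risk sets.

The profile log-likelihood evaluated at the fixed point,

    l_p(beta) = sum_i delta_i [log dLambda(y_i) - log r(z_i)]
                - sum_i Lambda(y_i) / r(z_i),

depends on ``beta`` only through the ordering / grouping of the index
values, which the outer optimizer exploits via caching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from numba import njit

from .data_model import (
    MonotoneStepFunction,
    NoEventsError,
    StepCumHazard,
    SurvivalDataset,
)
from .isotonic import _pava

__all__ = [
    "IndexedSample",
    "InnerResult",
    "index_by_score",
    "eta_bar",
    "m1_update",
    "m2_update",
    "fit_inner",
    "profile_loglik",
    "full_loglik",
    "squarem_accelerator",
]

# Index values are grouped after rounding to this many significant digits;
# exact float comparison is too brittle under reordered dot products.
_SIG_DIGITS = 12

# Link values of exactly zero (possible when every Lambda(y) in the leading
# block is zero) are floored only inside logs and divisions.
_R_FLOOR = 1e-300


def _round_sig(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = z.copy()
    nz = z != 0
    if np.any(nz):
        mag = np.floor(np.log10(np.abs(z[nz])))
        fac = 10.0 ** (_SIG_DIGITS - 1 - mag)
        out[nz] = np.round(z[nz] * fac) / fac
    return out


@dataclass(frozen=True)
class IndexedSample:
    """Sample sorted and grouped by the index ``z_i = x_i' beta``.

    ``knots`` are the ordered distinct (rounded) index values of uncensored
    observations; ``block_of`` maps each observation to its interval index
    ``l`` in ``{1, ..., L+1}``; ``md`` counts uncensored observations per
    knot.
    """

    z: np.ndarray
    order: np.ndarray
    knots: np.ndarray
    block_of: np.ndarray
    md: np.ndarray

    @property
    def n_knots(self) -> int:
        return self.knots.shape[0]


def index_by_score(data: SurvivalDataset, beta: np.ndarray) -> IndexedSample:
    """Sort and group the sample by the index induced by ``beta``."""
    beta = np.asarray(beta, dtype=float)
    data.require_events()
    z = data.covariates @ beta
    zr = _round_sig(z)
    events = data.events == 1
    knots = np.unique(zr[events])
    if knots.shape[0] < 1:
        raise NoEventsError("no uncensored observations")
    block0 = np.searchsorted(knots, zr, side="left")
    md = np.bincount(block0[events], minlength=knots.shape[0]).astype(float)
    order = np.argsort(zr, kind="stable")
    return IndexedSample(z=z, order=order, knots=knots, block_of=block0 + 1, md=md)


def eta_bar(
    indexed: IndexedSample, cumhaz: StepCumHazard, data: SurvivalDataset
) -> np.ndarray:
    """Block means ``eta_bar_l``: all subjects in ``I_l`` contribute to the
    numerator, only uncensored ones to the denominator; interval ``L+1`` is
    excluded."""
    lam = cumhaz(data.times)
    L = indexed.n_knots
    b0 = indexed.block_of - 1
    inside = b0 < L
    sums = np.bincount(b0[inside], weights=lam[inside], minlength=L)
    return sums / indexed.md


def m1_update(
    indexed: IndexedSample, cumhaz: StepCumHazard, data: SurvivalDataset
) -> MonotoneStepFunction:
    """(M1): PAVA fit of the block means, installed on the knots."""
    eta = eta_bar(indexed, cumhaz, data)
    values = _pava(eta, indexed.md)
    return MonotoneStepFunction(knots=indexed.knots, values=values)


def _r_per_subject(indexed: IndexedSample, link: MonotoneStepFunction) -> np.ndarray:
    """Per-subject link values by block, with interval L+1 mapped to r_L."""
    idx = np.minimum(indexed.block_of - 1, indexed.n_knots - 1)
    return link.values[idx]


def m2_update(data: SurvivalDataset, r_per_subject: np.ndarray) -> StepCumHazard:
    """(M2): normalized Breslow-type cumulative hazard.

    Tied event times share one jump: summed event count over the common
    risk-set denominator.  The result satisfies ``Lambda(tau) = 1``.
    """
    r = np.asarray(r_per_subject, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r_per_subject must be strictly positive")
    y = data.times
    events = data.events == 1
    asc = np.argsort(y, kind="stable")
    ya = y[asc]
    te, counts = np.unique(y[events], return_counts=True)
    if te.shape[0] == 0:
        raise NoEventsError("no events: Breslow estimator undefined")
    invr = 1.0 / r
    suff = np.concatenate((np.cumsum(invr[asc][::-1])[::-1], [0.0]))
    s_k = np.searchsorted(ya, te, side="left")
    raw = counts / suff[s_k]
    k_tau = int(np.searchsorted(te, data.tau, side="right"))
    total = float(raw[:k_tau].sum())
    if not total > 0:
        raise NoEventsError("no events at or before tau: Lambda*(tau) = 0")
    return StepCumHazard(jump_times=te, jumps=raw / total, tau=data.tau)


def full_loglik(
    data: SurvivalDataset, r_per_subject: np.ndarray, cumhaz: StepCumHazard
) -> float:
    """Log-likelihood with the baseline hazard replaced by its jump masses.

    ``sum_i delta_i [log dLambda(y_i) - log r_i] - sum_i Lambda(y_i)/r_i``,
    with a ``-inf`` sentinel when an event observation has ``r_i = 0``.
    """
    r = np.asarray(r_per_subject, dtype=float)
    events = data.events == 1
    if np.any(r[events] <= 0):
        return -np.inf
    lam = cumhaz(data.times)
    jumps = cumhaz.jump_at(data.times[events])
    if np.any(jumps <= 0):
        return -np.inf
    ll = float(np.sum(np.log(jumps) - np.log(r[events])))
    ll -= float(np.sum(lam / np.maximum(r, _R_FLOOR)))
    return ll


@dataclass
class InnerResult:
    """Fixed point of the (M1)/(M2) alternation at one ``beta``."""

    link: MonotoneStepFunction
    cumhaz: StepCumHazard
    converged: bool
    iterations: int
    history: Optional[list] = None

    def __iter__(self):
        return iter((self.link, self.cumhaz, self.converged, self.iterations))


def _inner_delta(
    r_new: np.ndarray, r_old: np.ndarray, cum_new: np.ndarray, cum_old: np.ndarray
) -> float:
    dr = float(np.max(np.abs(r_new - r_old) / (1.0 + np.abs(r_new))))
    dj = float(np.max(np.abs(cum_new - cum_old)))
    return dr + dj


def fit_inner(
    data: SurvivalDataset,
    beta: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    accelerator: Optional[Callable] = None,
    return_history: bool = False,
    r0: Optional[np.ndarray] = None,
) -> InnerResult:
    """Alternate (M1) and (M2) from the Cox-null start ``r == 1`` until the
    relative change in the link values plus the change in the cumulative
    hazard at the jump times falls below ``tol``.

    ``accelerator``, if given, is a callable ``accelerator(step, x0, tol,
    max_iter) -> (x, iterations, converged)`` applied to the fixed-point map
    on the per-knot link values; plain iteration is the default.  When
    ``return_history`` is true, the full log-likelihood right after each
    (M1) step is recorded (it is nondecreasing along the iteration).
    ``r0`` overrides the initial per-knot link values.
    """
    indexed = index_by_score(data, beta)
    L = indexed.n_knots
    history: Optional[list] = [] if return_history else None

    def m2_of(values: np.ndarray) -> StepCumHazard:
        link = MonotoneStepFunction(knots=indexed.knots, values=values)
        return m2_update(data, np.maximum(_r_per_subject(indexed, link), _R_FLOOR))

    def one_cycle(values: np.ndarray) -> np.ndarray:
        """(M1) applied to the (M2) hazard of the current link values."""
        return m1_update(indexed, m2_of(values), data).values

    r_old = np.ones(L) if r0 is None else np.asarray(r0, dtype=float)
    cumhaz = m2_of(r_old)

    if accelerator is not None:
        values, iterations, converged = accelerator(one_cycle, r_old, tol, max_iter)
        link = MonotoneStepFunction(knots=indexed.knots, values=values)
        return InnerResult(link, m2_of(values), converged, iterations, history)

    cum_old = np.cumsum(cumhaz.jumps)
    converged = False
    iterations = 0
    link = MonotoneStepFunction(knots=indexed.knots, values=r_old)
    while iterations < max_iter and not converged:
        iterations += 1
        new_link = m1_update(indexed, cumhaz, data)
        if history is not None:
            r_sub = np.maximum(_r_per_subject(indexed, new_link), _R_FLOOR)
            history.append(full_loglik(data, r_sub, cumhaz))
        new_cumhaz = m2_of(new_link.values)
        cum_new = np.cumsum(new_cumhaz.jumps)
        delta = _inner_delta(new_link.values, r_old, cum_new, cum_old)
        link, cumhaz, r_old, cum_old = new_link, new_cumhaz, new_link.values, cum_new
        if delta < tol:
            converged = True
    return InnerResult(link, cumhaz, converged, iterations, history)


def squarem_accelerator(step, x0, tol, max_iter):
    """Minimal SQUAREM-style extrapolation for the link fixed-point map.

    Performs two plain steps, extrapolates with the steplength
    ``alpha = -||r|| / ||v||`` and stabilizes with one more plain step;
    falls back to plain iteration whenever extrapolation leaves the feasible
    (nonnegative, nondecreasing) region.
    """
    x = np.asarray(x0, dtype=float)
    iterations = 0
    while iterations < max_iter:
        x1 = step(x)
        x2 = step(x1)
        iterations += 2
        r = x1 - x
        v = (x2 - x1) - r
        nv = float(np.linalg.norm(v))
        if nv == 0.0:
            x_new = x2
        else:
            alpha = -float(np.linalg.norm(r)) / nv
            cand = x - 2.0 * alpha * r + alpha * alpha * v
            if np.any(cand < 0) or np.any(np.diff(cand) < -1e-12):
                x_new = x2
            else:
                x_new = step(cand)
                iterations += 1
        if np.max(np.abs(x_new - x) / (1.0 + np.abs(x_new))) < tol:
            return x_new, iterations, True
        x = x_new
    return x, iterations, False


# ---------------------------------------------------------------------------
# Fast path used by the outer optimizer: the whole fixed point runs in a
# single compiled loop over a per-dataset workspace.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Workspace:
    """Per-dataset precomputation independent of ``beta``."""

    asc: np.ndarray  # order sorting times ascending
    m_idx: np.ndarray  # per subject: index of last event time <= y_i, -1 if none
    s_k: np.ndarray  # per event time: first ascending position in its risk set
    d_k: np.ndarray  # events per distinct event time
    k_tau: int  # number of distinct event times <= tau
    delta: np.ndarray  # uint8 event indicators


def _make_workspace(data: SurvivalDataset) -> _Workspace:
    data.require_events()
    y = data.times
    events = data.events == 1
    asc = np.argsort(y, kind="stable")
    ya = y[asc]
    te, counts = np.unique(y[events], return_counts=True)
    k_tau = int(np.searchsorted(te, data.tau, side="right"))
    if k_tau == 0:
        raise NoEventsError("no events at or before tau")
    return _Workspace(
        asc=asc.astype(np.int64),
        m_idx=(np.searchsorted(te, y, side="right") - 1).astype(np.int64),
        s_k=np.searchsorted(ya, te, side="left").astype(np.int64),
        d_k=counts.astype(float),
        k_tau=k_tau,
        delta=data.events.astype(np.uint8),
    )


@njit(cache=False)
def _m2_jumps(invr, asc, s_k, d_k, k_tau):  # pragma: no cover
    n = invr.shape[0]
    K = s_k.shape[0]
    suff = np.empty(n + 1)
    suff[n] = 0.0
    for q in range(n - 1, -1, -1):
        suff[q] = suff[q + 1] + invr[asc[q]]
    raw = np.empty(K)
    for k in range(K):
        raw[k] = d_k[k] / suff[s_k[k]]
    total = 0.0
    for k in range(k_tau):
        total += raw[k]
    return raw / total


@njit(cache=False)
def _fixed_point(
    block0, md, delta, asc, m_idx, s_k, d_k, k_tau, tol, max_iter
):  # pragma: no cover
    n = block0.shape[0]
    L = md.shape[0]
    K = s_k.shape[0]
    floor = 1e-300

    invr = np.ones(n)
    jumps = _m2_jumps(invr, asc, s_k, d_k, k_tau)
    cum = np.cumsum(jumps)

    r = np.ones(L)
    iterations = 0
    converged = False
    while iterations < max_iter:
        iterations += 1
        # (M1)
        eta = np.zeros(L)
        for i in range(n):
            b = block0[i]
            if b < L:
                if m_idx[i] >= 0:
                    eta[b] += cum[m_idx[i]]
        for l in range(L):
            eta[l] /= md[l]
        new_r = _pava(eta, md)
        for i in range(n):
            b = block0[i]
            if b >= L:
                b = L - 1
            rv = new_r[b]
            if rv < floor:
                rv = floor
            invr[i] = 1.0 / rv
        # (M2)
        new_jumps = _m2_jumps(invr, asc, s_k, d_k, k_tau)
        new_cum = np.cumsum(new_jumps)
        dr = 0.0
        for l in range(L):
            d = abs(new_r[l] - r[l]) / (1.0 + abs(new_r[l]))
            if d > dr:
                dr = d
        dj = 0.0
        for k in range(K):
            d = abs(new_cum[k] - cum[k])
            if d > dj:
                dj = d
        r = new_r
        jumps = new_jumps
        cum = new_cum
        if dr + dj < tol:
            converged = True
            break

    # profile log-likelihood at the fixed point
    ll = 0.0
    for i in range(n):
        b = block0[i]
        if b >= L:
            b = L - 1
        rv = r[b]
        lam_i = cum[m_idx[i]] if m_idx[i] >= 0 else 0.0
        if delta[i] == 1:
            if rv <= 0.0:
                return r, jumps, iterations, converged, -np.inf
            ll += np.log(jumps[m_idx[i]]) - np.log(rv)
        rdiv = rv if rv > floor else floor
        ll -= lam_i / rdiv
    return r, jumps, iterations, converged, ll


def _profile_fast(ws: _Workspace, data: SurvivalDataset, beta, tol, max_iter):
    indexed = index_by_score(data, beta)
    return indexed, _fixed_point(
        (indexed.block_of - 1).astype(np.int64),
        indexed.md,
        ws.delta,
        ws.asc,
        ws.m_idx,
        ws.s_k,
        ws.d_k,
        ws.k_tau,
        tol,
        max_iter,
    )


def profile_loglik(
    data: SurvivalDataset,
    beta: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> float:
    """Profile log-likelihood ``l_p(beta)`` at the inner fixed point."""
    ws = _make_workspace(data)
    _, (_, _, _, _, ll) = _profile_fast(ws, data, beta, tol, max_iter)
    return float(ll)
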