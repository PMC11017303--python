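"""Outer profile-likelihood maximization over the unit sphere.

The profile log-likelihood is maximized over ``beta`` with ``||beta|| = 1``
by parameterizing the sphere with spherical coordinates

    beta = S(theta) = (cos t1, sin t1 cos t2, ...,
                       sin t1 ... sin t_{p-2} cos t_{p-1},
                       sin t1 ... sin t_{p-2} sin t_{p-1}),

``t1..t_{p-2} in [0, pi]``, ``t_{p-1} in [0, 2 pi]`` (for ``p = 2`` the
single angle lives on ``[0, 2 pi)``).  The surface is piecewise constant —
it depends on ``beta`` only through the induced grouping of index values —
so the search is derivative-free: Nelder-Mead from the negative normalized
Cox MPLE mapped through ``S^{-1}``, followed by randomized perturbation
restarts (independent uniforms on ``[-h, h]`` per angle) that replace the
incumbent only on a strict likelihood improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .cox_reference import cox_mple, negative_normalized
from .data_model import SingleIndexFit, SurvivalDataset
from .inner_solver import _make_workspace, _profile_fast, _round_sig, fit_inner

__all__ = [
    "OptimizerOptions",
    "sphere_from_angles",
    "angles_from_vector",
    "wrap_angles",
    "fit",
]


@dataclass(frozen=True)
class OptimizerOptions:
    """Settings of the outer search.

    ``restarts`` perturbation rounds (default 20) with independent uniform
    perturbations on ``[-perturb_halfwidth, +perturb_halfwidth]`` per angle.
    Simplex termination is driven by the function-value tolerance since the
    surface is piecewise constant; ``maxfev`` defaults to ``500 p`` function
    evaluations per Nelder-Mead run.
    """

    restarts: int = 20
    perturb_halfwidth: float = 0.5
    seed: int = 0
    fatol: float = 1e-8
    xatol: float = 1e-4
    maxfev: int | None = None
    inner_tol: float = 1e-8
    inner_max_iter: int = 1000
    direction: str = "inc"

    def __post_init__(self):
        if self.restarts < 0:
            raise ValueError("restarts must be >= 0")
        if self.perturb_halfwidth <= 0:
            raise ValueError("perturb_halfwidth must be > 0")
        if self.direction not in ("inc", "dec"):
            raise ValueError("direction must be 'inc' or 'dec'")


def sphere_from_angles(theta: np.ndarray) -> np.ndarray:
    """Spherical map ``S``: ``(p-1)`` angles to a unit ``p``-vector."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    q = theta.shape[0]
    if q < 1:
        raise ValueError("need p >= 2, i.e. at least one angle")
    sin_prod = np.concatenate(([1.0], np.cumprod(np.sin(theta))))
    beta = np.empty(q + 1)
    beta[:q] = sin_prod[:q] * np.cos(theta)
    beta[q] = sin_prod[q]
    return beta


def angles_from_vector(beta: np.ndarray) -> np.ndarray:
    """Inverse map ``S^{-1}`` with ``t1..t_{p-2}`` in ``[0, pi]`` and the
    trailing angle in ``[0, 2 pi)``; degenerate trailing angles are 0."""
    beta = np.asarray(beta, dtype=float)
    p = beta.shape[0]
    if p < 2:
        raise ValueError("need p >= 2")
    norm = np.linalg.norm(beta)
    if norm == 0:
        raise ValueError("zero vector has no direction")
    b = beta / norm
    theta = np.zeros(p - 1)
    for j in range(p - 2):
        rest = np.linalg.norm(b[j + 1 :])
        theta[j] = np.arctan2(rest, b[j])
    last = np.arctan2(b[p - 1], b[p - 2])
    theta[p - 2] = np.mod(last, 2 * np.pi)
    if p > 2 and np.linalg.norm(b[p - 2 :]) == 0:
        theta[p - 2] = 0.0
    return theta


def wrap_angles(theta: np.ndarray) -> np.ndarray:
    """Map arbitrary Nelder-Mead proposals back into the angle box:
    the trailing angle modulo ``2 pi``, the others reflected into
    ``[0, pi]``."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float)).copy()
    q = theta.shape[0]
    if q > 1:
        t = np.mod(theta[: q - 1], 2 * np.pi)
        t = np.where(t > np.pi, 2 * np.pi - t, t)
        theta[: q - 1] = t
    theta[q - 1] = np.mod(theta[q - 1], 2 * np.pi)
    return theta


def _negate_for_direction(data: SurvivalDataset, direction: str) -> SurvivalDataset:
    if direction == "inc":
        return data
    return SurvivalDataset(
        times=data.times,
        events=data.events,
        covariates=-data.covariates,
        tau=data.tau,
    )


def fit(data: SurvivalDataset, options: OptimizerOptions | None = None) -> SingleIndexFit:
    """Semiparametric MLE of the shape-restricted single-index hazard model.

    Runs Nelder-Mead on the profile log-likelihood starting from
    ``S^{-1}(-beta_P/||beta_P||)`` (falling back to ``theta = 0`` with a
    warning if the Cox fit fails), then ``restarts`` perturb-and-retry
    rounds keeping a new solution only when its profile log-likelihood is
    strictly larger.  Returns the fit with the inner-solver output at the
    incumbent ``beta``.
    """
    options = options or OptimizerOptions()
    if data.p < 2:
        raise ValueError("the single-index model needs p >= 2 covariates")
    data.require_events()
    work_data = _negate_for_direction(data, options.direction)

    rng = np.random.default_rng(options.seed)
    mple_start = None
    try:
        cfit = cox_mple(work_data)
        if not cfit.converged or np.linalg.norm(cfit.beta_p) == 0:
            raise ValueError("Cox MPLE did not converge")
        mple_start = negative_normalized(cfit)
        theta0 = angles_from_vector(mple_start)
    except (ValueError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"MPLE initializer failed ({exc}); starting at theta = 0")
        theta0 = np.zeros(data.p - 1)

    ws = _make_workspace(work_data)
    X = work_data.covariates
    events = work_data.events == 1
    cache: dict[bytes, float] = {}

    def profile_value(theta: np.ndarray) -> float:
        # l_p(beta) depends on beta only through the block assignment of
        # the index values, so identical groupings are computed once
        beta = sphere_from_angles(wrap_angles(theta))
        zr = _round_sig(X @ beta)
        knots = np.unique(zr[events])
        block0 = np.searchsorted(knots, zr, side="left")
        key = block0.tobytes()
        ll = cache.get(key)
        if ll is None:
            _, (_, _, _, _, ll) = _profile_fast(
                ws, work_data, beta, options.inner_tol, options.inner_max_iter
            )
            cache[key] = float(ll)
        return ll

    maxfev = options.maxfev or 500 * data.p

    def run_nm(start: np.ndarray):
        res = minimize(
            lambda th: -profile_value(th),
            np.atleast_1d(start),
            method="Nelder-Mead",
            options={
                "fatol": options.fatol,
                "xatol": options.xatol,
                "maxfev": maxfev,
            },
        )
        return wrap_angles(res.x), -res.fun

    theta_best, ll_best = run_nm(theta0)
    ll_start = ll_best
    restarts_improved = 0
    for _ in range(options.restarts):
        pert = rng.uniform(
            -options.perturb_halfwidth, options.perturb_halfwidth, data.p - 1
        )
        theta_new, ll_new = run_nm(theta_best + pert)
        if ll_new > ll_best:
            theta_best, ll_best = theta_new, ll_new
            restarts_improved += 1
    if ll_best < ll_start:  # acceptance is improve-only; cannot happen
        raise AssertionError("restart bookkeeping lost the incumbent")

    beta_hat = sphere_from_angles(theta_best)
    inner = fit_inner(
        work_data,
        beta_hat,
        tol=options.inner_tol,
        max_iter=options.inner_max_iter,
    )
    return SingleIndexFit(
        beta=beta_hat,
        theta=theta_best,
        link=inner.link,
        cumhaz=inner.cumhaz,
        loglik=float(ll_best),
        inner_iterations=inner.iterations,
        converged=inner.converged,
        restarts_improved=restarts_improved,
        direction=options.direction,
        mple_start=mple_start,
    )
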