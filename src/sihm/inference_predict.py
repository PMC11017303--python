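"""Post-fit quantities: link on the log scale, survival prediction,
and percentile bootstrap intervals for the index coefficients."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import SingleIndexFit, SurvivalDataset
from . import profile_optimizer
from .profile_optimizer import OptimizerOptions

__all__ = [
    "BootstrapResult",
    "link_phi",
    "predict_survival",
    "bootstrap_ci",
    "export_link_table",
    "export_cumhaz_table",
]


def link_phi(fit: SingleIndexFit, z) -> np.ndarray:
    """Estimated link on the hazard scale, ``phi_hat(z) = -log r_hat(z)``;
    nonincreasing in ``z``.  Where ``r_hat`` is zero, ``+inf``."""
    r = fit.link(z)
    with np.errstate(divide="ignore"):
        return -np.log(r)


def predict_survival(fit: SingleIndexFit, x, t) -> np.ndarray:
    """Predicted survival ``S(t | x) = exp{-Lambda_hat(t) / r_hat(x' beta)}``
    for ``0 <= t <= tau``; no extrapolation beyond the identifiability
    horizon."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > fit.cumhaz.tau):
        raise ValueError("prediction times must lie in [0, tau]")
    z = fit.index(x)
    r = fit.link(z)
    lam = fit.cumhaz(t)
    return np.exp(-np.atleast_1d(lam)[None, :] / np.atleast_1d(r)[:, None]).squeeze()


@dataclass
class BootstrapResult:
    """Componentwise percentile bounds from nonparametric-bootstrap refits.

    Replicate coefficient vectors (all unit norm) are sign-aligned with the
    point estimate before taking percentiles.  Percentile intervals for
    this estimator are not calibrated; their coverage may differ from the
    nominal level (see ``notes``).
    """

    replicates: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B: int
    level: float
    seed: int
    n_failed: int = 0
    notes: str = (
        "percentile bootstrap; coverage of these intervals is not guaranteed "
        "to match the nominal level"
    )


def bootstrap_ci(
    data: SurvivalDataset,
    B: int = 500,
    level: float = 0.95,
    seed: int = 0,
    options: Optional[OptimizerOptions] = None,
    point_estimate: Optional[np.ndarray] = None,
    estimator=None,
) -> BootstrapResult:
    """Percentile bootstrap for the index coefficients.

    Resamples rows with replacement, refits per replicate and takes the
    componentwise ``(1-level)/2`` and ``1-(1-level)/2`` empirical
    percentiles.  Each replicate vector is flipped in sign when its inner
    product with the point estimate is negative, so that the interval is
    anchored to one representative of the +/- beta pair.  ``estimator``
    may override the refitting routine (signature
    ``estimator(dataset, seed) -> unit vector``).
    """
    if B < 2:
        raise ValueError("need B >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    base = options or OptimizerOptions()

    if estimator is None:
        def estimator(ds: SurvivalDataset, s: int) -> np.ndarray:
            return profile_optimizer.fit(ds, replace(base, seed=s)).beta

    if point_estimate is None:
        point_estimate = estimator(data, base.seed)
    point_estimate = np.asarray(point_estimate, dtype=float)

    rng = np.random.default_rng(seed)
    reps = []
    failed = 0
    for b in range(B):
        idx = rng.integers(0, data.n, size=data.n)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        try:
            boot = SurvivalDataset(
                times=data.times[idx],
                events=data.events[idx],
                covariates=data.covariates[idx],
                tau=data.tau,
            )
            bh = np.asarray(estimator(boot, rep_seed), dtype=float)
        except Exception:
            failed += 1
            continue
        if float(bh @ point_estimate) < 0:
            bh = -bh
        reps.append(bh)
    if failed > 0.2 * B:
        raise RuntimeError(f"{failed}/{B} bootstrap replicates failed")
    arr = np.asarray(reps)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(arr, alpha, axis=0)
    upper = np.quantile(arr, 1.0 - alpha, axis=0)
    return BootstrapResult(
        replicates=arr,
        lower=lower,
        upper=upper,
        B=B,
        level=level,
        seed=seed,
        n_failed=failed,
    )


def export_link_table(fit: SingleIndexFit) -> pd.DataFrame:
    """Delimited-export view of the estimated link: ``(z, r_hat, phi_hat)``."""
    return pd.DataFrame(
        {
            "z": fit.link.knots,
            "r_hat": fit.link.values,
            "phi_hat": link_phi(fit, fit.link.knots),
        }
    )


def export_cumhaz_table(fit: SingleIndexFit) -> pd.DataFrame:
    """Delimited-export view of the cumulative hazard: ``(t, Lambda_hat)``."""
    return pd.DataFrame(
        {
            "t": fit.cumhaz.jump_times,
            "Lambda_hat": np.cumsum(fit.cumhaz.jumps),
        }
    )
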