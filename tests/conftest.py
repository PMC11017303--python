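import itertools

import numpy as np
import pytest

from sihm.data_model import SurvivalDataset
from sihm.simulation import ScenarioSpec, draw_dataset

# Calibrated censoring parameters are expensive to recompute (10^6 draws),
# so scenario fixtures pin values produced by calibrate_censoring once with
# its default calibration seed; the calibration itself is tested separately.
CALIBRATED = {
    ("II", 1 / 3, 0.25): (0.234375, 2.081481543944173),
}


def brute_force_isotonic(means, weights):
    """Exhaustive weighted least-squares monotone fit for small L.

    Enumerates every partition of 1..L into contiguous blocks, fits each
    block at its weighted mean, keeps partitions whose block means are
    nondecreasing, and returns the feasible fit with the smallest weighted
    sum of squares.
    """
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    L = means.shape[0]
    best, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=L - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [L]
        fit = np.empty(L)
        ok = True
        prev = -np.inf
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            m = np.average(means[lo:hi], weights=weights[lo:hi])
            if m < prev - 1e-12:
                ok = False
                break
            prev = m
            fit[lo:hi] = m
        if not ok:
            continue
        sse = float(np.sum(weights * (means - fit) ** 2))
        if sse < best_sse - 1e-12:
            best, best_sse = fit, sse
    return best


def pava_maxmin(means, weights):
    """Literal max-min of weighted running averages (cubic time)."""
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    L = means.shape[0]
    out = np.empty(L)
    for l in range(L):
        best = -np.inf
        for k in range(l + 1):
            worst = np.inf
            for q in range(l, L):
                w = weights[k : q + 1]
                worst = min(worst, float(np.average(means[k : q + 1], weights=w)))
            best = max(best, worst)
        out[l] = best
    return out


def make_dataset(times, events, covariates, tau=None):
    times = np.asarray(times, dtype=float)
    return SurvivalDataset(
        times=times,
        events=np.asarray(events),
        covariates=np.asarray(covariates, dtype=float),
        tau=float(tau if tau is not None else times.max()),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def scenario2_dataset(n, seed, a=1 / 3, censoring=0.25):
    lam, tau = CALIBRATED[("II", a, censoring)]
    spec = ScenarioSpec(
        scenario="II", a=a, n=n, target_censoring=censoring,
        seed=seed, lambda_c=lam, tau=tau,
    )
    return draw_dataset(spec)


@pytest.fixture(scope="session")
def small_scenario2():
    """n=60 scenario-II sample used by several optimizer tests."""
    return scenario2_dataset(60, seed=0)


@pytest.fixture(scope="session")
def medium_scenario2():
    return scenario2_dataset(300, seed=3)
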