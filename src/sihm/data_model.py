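"""Core data structures for shape-restricted single-index hazard models.

The model for a failure time ``T`` given a covariate vector ``x`` is

    lambda(t | x) = lambda(t) / r(x' beta),      t in [0, tau],

where the link ``r`` is an unknown *nondecreasing* positive function
(equivalently ``phi = -log r`` is nonincreasing) and ``lambda`` is an
unspecified baseline hazard.  The semiparametric scale ambiguities are
removed by the identifiability constraints ``Lambda(tau) = 1`` (with
``Lambda`` the baseline cumulative hazard) and ``||beta|| = 1``.

This module holds the validated containers shared by the fitting,
simulation and prediction code: the right-censored sample, the step-function
estimates of the link and the cumulative hazard, and the bundled fit result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ValidationError",
    "InvalidTimeError",
    "InvalidStatusError",
    "NoEventsError",
    "DegenerateTimesError",
    "SurvivalDataset",
    "MonotoneStepFunction",
    "StepCumHazard",
    "SingleIndexFit",
    "validate_dataset",
]


class ValidationError(ValueError):
    """Base class for dataset validation failures."""


class InvalidTimeError(ValidationError):
    """A follow-up time is missing, non-finite or not strictly positive."""


class InvalidStatusError(ValidationError):
    """An event indicator is outside {0, 1}."""


class NoEventsError(ValidationError):
    """The sample contains no observed failures."""


class DegenerateTimesError(ValidationError):
    """All follow-up times coincide; risk sets carry no information."""


@dataclass(frozen=True)
class SurvivalDataset:
    """A right-censored survival sample ``{(y_i, delta_i, x_i)}``.

    Parameters
    ----------
    times
        Observed follow-up times ``y_i > 0`` (failure or censoring,
        whichever came first), in an arbitrary time unit.
    events
        Event indicators ``delta_i`` in {0, 1}; 1 means the failure was
        observed at ``y_i``.
    covariates
        ``n x p`` real matrix of covariate values, no missing entries.
    tau
        Analysis horizon; the cumulative hazard is normalized so that
        ``Lambda(tau) = 1``.  Defaults to ``max(times)``.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray
    tau: float

    def __post_init__(self):
        times = np.ascontiguousarray(self.times, dtype=float)
        events = np.ascontiguousarray(self.events)
        covariates = np.ascontiguousarray(self.covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if times.ndim != 1 or events.ndim != 1:
            raise ValidationError("times and events must be one-dimensional")
        n = times.shape[0]
        if n < 2:
            raise ValidationError(f"need at least 2 observations, got {n}")
        if events.shape[0] != n or covariates.shape[0] != n:
            raise ValidationError("times, events and covariates disagree in length")
        if not np.all(np.isfinite(times)) or np.any(times <= 0):
            raise InvalidTimeError("all follow-up times must be finite and > 0")
        ev = np.asarray(events, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise InvalidStatusError("event indicators must be 0 or 1")
        if covariates.shape[1] < 1:
            raise ValidationError("at least one covariate column is required")
        if not np.all(np.isfinite(covariates)):
            raise ValidationError("covariates contain missing or non-finite values")
        if np.all(times == times[0]):
            raise DegenerateTimesError("all follow-up times are identical")
        tau = float(self.tau)
        if not np.isfinite(tau) or tau <= 0:
            raise ValidationError("tau must be finite and > 0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", ev.astype(np.int8))
        object.__setattr__(self, "covariates", covariates)
        object.__setattr__(self, "tau", tau)

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def require_events(self) -> None:
        if self.n_events == 0:
            raise NoEventsError("no observed failures in the sample")


def validate_dataset(raw, tau: Optional[float] = None) -> SurvivalDataset:
    """Build a :class:`SurvivalDataset` from a plain numeric table.

    The table must have at least two rows and columns
    ``(time, status, x1, ..., xp)``.  ``tau`` defaults to the largest
    observed time.  Raises a named :class:`ValidationError` subclass on
    any contract violation, including a sample with zero events.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 3:
        raise ValidationError(
            "expected a table with >= 2 rows and >= 3 columns (time, status, covariates)"
        )
    if not np.all(np.isfinite(arr[:, 0])):
        raise InvalidTimeError("missing or non-finite follow-up time")
    times = arr[:, 0]
    events = arr[:, 1]
    if tau is None:
        tau = float(np.max(times))
    ds = SurvivalDataset(times=times, events=events, covariates=arr[:, 2:], tau=tau)
    ds.require_events()
    return ds


@dataclass(frozen=True)
class MonotoneStepFunction:
    """A nondecreasing step function: the estimated link ``r``.

    ``knots`` are the ordered distinct index values ``z_1* < ... < z_L*``
    taken from uncensored observations; ``values`` are the fitted levels
    ``r_1* <= ... <= r_L*``.  Evaluation follows the interval convention
    ``I_1 = (-inf, z_1*], ..., I_L = (z_{L-1}*, z_L*]`` and the last level
    extends over ``I_{L+1} = (z_L*, inf)``: the value at ``z`` is
    ``values[l]`` for ``z`` in ``I_{l+1 <= L}``, and ``values[L-1]`` beyond
    the last knot.  Evaluation at a knot returns that knot's value.
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        knots = np.ascontiguousarray(self.knots, dtype=float)
        values = np.ascontiguousarray(self.values, dtype=float)
        if knots.ndim != 1 or values.ndim != 1 or knots.shape != values.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.shape[0] < 1:
            raise ValueError("need at least one knot")
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if np.any(np.diff(values) < 0):
            raise ValueError("values must be nondecreasing")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("values must be finite and nonnegative")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    @property
    def n_knots(self) -> int:
        return self.knots.shape[0]

    def __call__(self, z):
        idx = np.searchsorted(self.knots, np.asarray(z, dtype=float), side="left")
        idx = np.minimum(idx, self.n_knots - 1)
        return self.values[idx]


@dataclass(frozen=True)
class StepCumHazard:
    """Right-continuous step estimate of the cumulative hazard ``Lambda``.

    ``Lambda(t)`` is the sum of ``jumps`` at ``jump_times <= t`` and
    ``Lambda(0) = 0``.  After normalization ``Lambda(tau) = 1``.
    """

    jump_times: np.ndarray
    jumps: np.ndarray
    tau: float

    def __post_init__(self):
        t = np.ascontiguousarray(self.jump_times, dtype=float)
        j = np.ascontiguousarray(self.jumps, dtype=float)
        if t.ndim != 1 or j.ndim != 1 or t.shape != j.shape or t.shape[0] < 1:
            raise ValueError("jump_times and jumps must be matching 1-d arrays")
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("jump_times must be strictly increasing and positive")
        if np.any(j < 0) or not np.all(np.isfinite(j)):
            raise ValueError("jumps must be finite and nonnegative")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError("tau must be finite and > 0")
        object.__setattr__(self, "jump_times", t)
        object.__setattr__(self, "jumps", j)
        object.__setattr__(self, "tau", float(self.tau))

    def __call__(self, t):
        cum = np.concatenate(([0.0], np.cumsum(self.jumps)))
        idx = np.searchsorted(self.jump_times, np.asarray(t, dtype=float), side="right")
        return cum[idx]

    def jump_at(self, t):
        """Jump mass at exactly ``t`` (0 if ``t`` is not a jump time)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.jump_times, t, side="left")
        idx_c = np.minimum(idx, self.jump_times.shape[0] - 1)
        out = np.where(self.jump_times[idx_c] == t, self.jumps[idx_c], 0.0)
        return out

    @property
    def is_normalized(self) -> bool:
        return bool(abs(float(self(self.tau)) - 1.0) < 1e-10)


@dataclass
class SingleIndexFit:
    """The fitted model: ``beta_hat``, ``r_hat``, ``Lambda_hat`` and diagnostics.

    ``beta`` has unit norm and equals the spherical map of ``theta``; the
    link values are nondecreasing in the index ``x' beta``.  ``direction``
    records the reporting convention requested at fit time ("inc" fits the
    nondecreasing-``r`` representation directly; "dec" reports ``-beta``
    alongside, since negating the index converts one representation into
    the other).
    """

    beta: np.ndarray
    theta: np.ndarray
    link: MonotoneStepFunction
    cumhaz: StepCumHazard
    loglik: float
    inner_iterations: int = 0
    converged: bool = True
    restarts_improved: int = 0
    direction: str = "inc"
    mple_start: Optional[np.ndarray] = None

    def index(self, x) -> np.ndarray:
        """Index value(s) on the scale the link is defined on.

        With ``direction == "dec"`` the model was fitted on the negated
        covariates, so the link applies to ``-x' beta``.
        """
        x = np.atleast_2d(np.asarray(x, dtype=float))
        sign = -1.0 if self.direction == "dec" else 1.0
        return sign * (x @ self.beta)
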