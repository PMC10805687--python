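"""Evaluation statistics for right-censored survival predictions.

Implements the two nonparametric estimators (Kaplan–Meier product-limit
survival curve, Nelson–Aalen cumulative hazard) together with the two model
scores used throughout the package:

* Harrell's concordance index (C-index) — the fraction of comparable subject
  pairs whose predicted risk ordering agrees with their observed event
  ordering. A pair is comparable only when the earlier observed time belongs
  to a subject whose event was observed and the two times differ; tied risk
  predictions receive half credit. 1.0 is a perfect ranking, 0.5 is chance,
  0.0 a perfectly inverted ranking.

* The Brier score at a time point and its integral (IBS), corrected for
  right-censoring by inverse-probability-of-censoring weights (IPCW). The
  weights come from a Kaplan–Meier estimate of the *censoring* distribution
  (event indicator flipped), evaluated at the left limit G(t-) for subjects
  whose event occurred by the evaluation time.

Conventions (documented because common variants differ):

* Pairs whose observed times are exactly equal are never comparable in the
  C-index. Zero comparable pairs raises rather than silently returning 0.5.
* Higher risk always means an earlier expected event.
* The default IBS window is [min event time, max event time] of the data the
  score is computed on, truncated to where the censoring survival G stays
  positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "StepFunction",
    "MetricResult",
    "kaplan_meier",
    "nelson_aalen",
    "concordance_index",
    "brier_score",
    "integrated_brier_score",
]


class StepFunction:
    """Right-continuous step function over time.

    Parameters
    ----------
    times:
        Strictly increasing grid of jump locations.
    values:
        Function value at and after each jump (one per grid point).
    value_before_first:
        Value on ``(-inf, times[0])``; 1.0 for survival curves, 0.0 for
        cumulative hazards.
    """

    __slots__ = ("times", "values", "value_before_first")

    def __init__(self, times, values, value_before_first: float):
        times = np.atleast_1d(np.asarray(times, dtype=float))
        values = np.atleast_1d(np.asarray(values, dtype=float))
        if times.size != values.size:
            raise ValueError("times and values must have equal length")
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.times = times
        self.values = values
        self.value_before_first = float(value_before_first)

    def __call__(self, t):
        """Evaluate right-continuously: value of the last jump at or before t."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.value_before_first)
            return float(out) if out.ndim == 0 else out
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(
            idx < 0,
            self.value_before_first,
            self.values[np.clip(idx, 0, max(self.times.size - 1, 0))],
        )
        return float(out) if out.ndim == 0 else out

    def left_limit(self, t):
        """Evaluate the left limit: value just before t (jumps at t excluded)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            out = np.full(t.shape, self.value_before_first)
            return float(out) if out.ndim == 0 else out
        idx = np.searchsorted(self.times, t, side="left") - 1
        out = np.where(
            idx < 0,
            self.value_before_first,
            self.values[np.clip(idx, 0, max(self.times.size - 1, 0))],
        )
        return float(out) if out.ndim == 0 else out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"StepFunction({self.times.size} steps)"


@dataclass(frozen=True)
class MetricResult:
    """Scalar metric with the bookkeeping needed to interpret it."""

    value: float
    n_pairs_comparable: int | None = None
    time_window: tuple[float, float] | None = None

    def __float__(self) -> float:
        return self.value


def _check_survival_arrays(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.size == 0:
        raise ValueError("empty survival data")
    if time.shape != event.shape:
        raise ValueError("time and event must have the same shape")
    if np.any(time <= 0) or not np.all(np.isfinite(time)):
        raise ValueError("survival times must be finite and strictly positive")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return time, ev.astype(int)


def _event_table(time, event):
    """Distinct observed times with event counts and risk-set sizes."""
    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    uniq, first = np.unique(t, return_index=True)
    counts = np.diff(np.append(first, t.size))
    d = np.add.reduceat(e, first)
    n_at_risk = t.size - np.concatenate(([0], np.cumsum(counts)[:-1]))
    return uniq, d, n_at_risk


def kaplan_meier(time, event) -> StepFunction:
    """Product-limit estimate of the survival function, S(0) = 1."""
    time, event = _check_survival_arrays(time, event)
    uniq, d, n = _event_table(time, event)
    mask = d > 0
    if not np.any(mask):
        return StepFunction([], [], 1.0)
    surv = np.cumprod(1.0 - d[mask] / n[mask])
    return StepFunction(uniq[mask], surv, 1.0)


def nelson_aalen(time, event) -> StepFunction:
    """Nelson–Aalen cumulative hazard: H(t) = sum over event times of d_i/n_i."""
    time, event = _check_survival_arrays(time, event)
    uniq, d, n = _event_table(time, event)
    mask = d > 0
    if not np.any(mask):
        return StepFunction([], [], 0.0)
    chf = np.cumsum(d[mask] / n[mask])
    return StepFunction(uniq[mask], chf, 0.0)


def concordance_index(time, event, risk) -> MetricResult:
    """Harrell's concordance index of a scalar risk score.

    A pair (i, j) is comparable iff the earlier observed time belongs to a
    subject with an observed event and the two times differ. The pair is
    concordant when that subject's risk is strictly higher; equal risks count
    0.5. Raises when no pair is comparable.
    """
    time, event = _check_survival_arrays(time, event)
    risk = np.asarray(risk, dtype=float)
    if risk.shape != time.shape:
        raise ValueError("risk must match time/event in length")
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores must be finite")

    order = np.argsort(time, kind="mergesort")
    t, e, r = time[order], event[order], risk[order]
    n = t.size
    comparable = 0
    concordant = 0.0
    for i in range(n):
        if e[i] != 1:
            continue
        # strictly later observed times: ties in time are never comparable
        j0 = int(np.searchsorted(t, t[i], side="right"))
        if j0 >= n:
            continue
        later = r[j0:]
        comparable += later.size
        concordant += np.count_nonzero(r[i] > later) + 0.5 * np.count_nonzero(
            r[i] == later
        )
    if comparable == 0:
        raise ValueError(
            "no comparable pairs: need two differing times with the earlier "
            "one an observed event"
        )
    return MetricResult(value=concordant / comparable, n_pairs_comparable=comparable)


def _predicted_survival_at(predictions, t) -> np.ndarray:
    """Evaluate per-subject predicted survival at a single time point."""
    if isinstance(predictions, StepFunction):
        raise TypeError("predictions must be one StepFunction per subject")
    if isinstance(predictions, np.ndarray) and predictions.ndim == 1:
        return predictions.astype(float)
    return np.array([p(t) for p in predictions], dtype=float)


def brier_score(
    t_eval: float,
    predictions,
    time,
    event,
    censor_km: StepFunction | None = None,
) -> MetricResult:
    """IPCW Brier score at time ``t_eval``.

    ``predictions`` is a sequence of per-subject survival StepFunctions (or a
    precomputed vector of survival probabilities at ``t_eval``). ``censor_km``
    is the Kaplan–Meier estimate of the censoring distribution (event
    indicator flipped); it is estimated from ``time``/``event`` when omitted.
    """
    time, event = _check_survival_arrays(time, event)
    s_hat = _predicted_survival_at(predictions, t_eval)
    if s_hat.shape != time.shape:
        raise ValueError("one prediction per subject required")
    if censor_km is None:
        censor_km = kaplan_meier(time, 1 - event)

    g_at_t = censor_km(t_eval)
    past_event = (time <= t_eval) & (event == 1)
    still_alive = time > t_eval
    if np.any(still_alive) and g_at_t <= 0.0:
        raise ValueError(
            f"censoring survival G({t_eval}) = 0; choose a smaller time window"
        )
    contrib = np.zeros_like(time)
    if np.any(past_event):
        g_left = np.asarray(censor_km.left_limit(time[past_event]), dtype=float)
        if np.any(g_left <= 0.0):
            raise ValueError(
                "censoring survival G(T-) = 0 for an observed event; choose a "
                "smaller time window"
            )
        contrib[past_event] = (0.0 - s_hat[past_event]) ** 2 / g_left
    contrib[still_alive] = (1.0 - s_hat[still_alive]) ** 2 / g_at_t
    # subjects censored at or before t_eval contribute 0
    return MetricResult(value=float(np.mean(contrib)), time_window=(t_eval, t_eval))


def integrated_brier_score(
    predictions: Sequence[StepFunction],
    time,
    event,
    window: tuple[float, float] | None = None,
    grid=None,
) -> MetricResult:
    """Trapezoidal integral of the IPCW Brier score, normalised by window length.

    The default grid is the set of distinct observed event times inside the
    window; the default window spans the observed event times, truncated where
    the censoring-survival estimate G reaches zero.
    """
    time, event = _check_survival_arrays(time, event)
    censor_km = kaplan_meier(time, 1 - event)

    if grid is None:
        event_times = np.unique(time[event == 1])
        if event_times.size < 2:
            raise ValueError("need at least two distinct event times for the IBS")
        if window is None:
            window = (float(event_times[0]), float(event_times[-1]))
        lo, hi = float(window[0]), float(window[1])
        if not lo < hi:
            raise ValueError(f"degenerate time window [{lo}, {hi}]")
        grid = event_times[(event_times >= lo) & (event_times <= hi)]
        # truncate where G hits zero: weights would be undefined beyond
        g_vals = np.asarray(censor_km(grid), dtype=float)
        grid = grid[g_vals > 0.0]
    else:
        grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("degenerate integration grid for the IBS")

    scores = np.array(
        [
            brier_score(t, predictions, time, event, censor_km=censor_km).value
            for t in grid
        ]
    )
    span = grid[-1] - grid[0]
    value = float(np.trapezoid(scores, grid) / span)
    if math.isnan(value):
        raise ValueError("IBS is undefined on this window")
    return MetricResult(value=value, time_window=(float(grid[0]), float(grid[-1])))
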