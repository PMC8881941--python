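"""Breath-by-breath energetics: steady-state estimation and sequential comparisons.

Indirect calorimetry samples metabolic power once per breath. Over a 2-minute
walking bout the measured rate approaches its steady state as a first-order
(cardiopulmonary) transient with time constant tau ~ 42 s, so the trial's
rate is estimated by fitting ``y(t) = y_ss + (y0 - y_ss) exp(-t / tau)``.
A 4-minute standing baseline is averaged and subtracted to give the net rate
of walking. Within each block, consecutive trials form (reference A,
comparison B) pairs whose normalized difference ``x = 100 (B - A) / A``
(percent) is the stimulus for the psychometric analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BreathSeries",
    "SteadyStateEstimate",
    "fit_first_order",
    "standing_baseline",
    "net_rate",
    "estimate_net_rates",
    "build_comparisons",
]

logger = logging.getLogger(__name__)

TAU_BOUNDS = (10.0, 120.0)
TAU_INIT = 42.0
MIN_BREATHS = 5


@dataclass(frozen=True)
class BreathSeries:
    """Timestamped instantaneous metabolic power over one interval.

    ``t`` is seconds since the interval start (strictly increasing), ``y`` is
    metabolic power in W/kg.
    """

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("breath series contains non-finite values")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("breath timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class SteadyStateEstimate:
    """Result of the first-order transient fit.

    ``y_ss`` is the steady-state rate (the trial's metabolic rate), ``y0``
    the extrapolated initial rate, ``tau`` the time constant in seconds,
    ``rss`` the residual sum of squares.  ``converged`` is False when the
    solver failed and the tail-mean fallback produced ``y_ss``.
    """

    y_ss: float
    y0: float
    tau: float
    rss: float
    converged: bool = True


def _first_order(t, y_ss, y0, tau):
    return y_ss + (y0 - y_ss) * np.exp(-t / tau)


def fit_first_order(series: BreathSeries) -> SteadyStateEstimate:
    """Least-squares fit of a first-order response to one trial's breaths.

    All three parameters (y_ss, y0, tau) are free; tau is bounded to
    [10, 120] s and initialized at 42 s.  On solver failure the steady state
    falls back to the mean of the final 60 s and the estimate is marked
    non-converged.

    Raises
    ------
    ValueError
        If the series has fewer than 5 breaths.
    """
    if len(series) < MIN_BREATHS:
        raise ValueError(f"need at least {MIN_BREATHS} breaths to fit, got {len(series)}")
    t, y = series.t, series.y
    span = np.ptp(t)
    tail = y[t >= t[-1] - span / 3] if span > 0 else y
    p0 = (float(np.mean(tail)), float(y[0]), TAU_INIT)
    bounds = ([-np.inf, -np.inf, TAU_BOUNDS[0]], [np.inf, np.inf, TAU_BOUNDS[1]])
    try:
        popt, _ = curve_fit(_first_order, t, y, p0=p0, bounds=bounds, maxfev=20000)
        resid = y - _first_order(t, *popt)
        return SteadyStateEstimate(
            y_ss=float(popt[0]), y0=float(popt[1]), tau=float(popt[2]),
            rss=float(resid @ resid), converged=True,
        )
    except (RuntimeError, ValueError):
        mask = t >= t[-1] - 60.0
        y_ss = float(np.mean(y[mask]))
        resid = y[mask] - y_ss
        logger.warning("first-order fit failed; falling back to final-60 s mean")
        return SteadyStateEstimate(
            y_ss=y_ss, y0=float("nan"), tau=float("nan"),
            rss=float(resid @ resid), converged=False,
        )


def standing_baseline(series: BreathSeries) -> float:
    """Baseline metabolic rate: mean power over the standing interval."""
    if len(series) == 0:
        raise ValueError("empty standing series")
    return float(np.mean(series.y))


def net_rate(y_ss: float, baseline: float) -> float:
    """Net metabolic rate: steady-state minus standing baseline (W/kg).

    Non-positive results are flagged with a warning (noise can produce them);
    downstream comparison building drops such references.
    """
    net = y_ss - baseline
    if net <= 0:
        logger.warning("non-positive net rate %.4f (y_ss=%.4f, baseline=%.4f)", net, y_ss, baseline)
    return net


def estimate_net_rates(breaths: pd.DataFrame, standing: pd.DataFrame) -> pd.DataFrame:
    """Per-trial net steady-state rates from long-format breath tables.

    ``breaths`` holds walking-trial breaths (``participant_id, block, trial,
    t_seconds, power_w_per_kg``); ``standing`` holds the baseline interval
    (``participant_id, t_seconds, power_w_per_kg``). Each trial gets a
    first-order fit; each participant's standing mean is subtracted. Returns
    one row per trial: ``participant_id, block, trial, y_ss, baseline,
    net_w_per_kg, tau, converged``.
    """
    baselines = {
        pid: standing_baseline(BreathSeries(g["t_seconds"].to_numpy(), g["power_w_per_kg"].to_numpy()))
        for pid, g in standing.groupby("participant_id")
    }
    rows = []
    for (pid, block, trial), g in breaths.groupby(["participant_id", "block", "trial"], sort=True):
        if pid not in baselines:
            raise ValueError(f"no standing baseline for participant {pid}")
        g = g.sort_values("t_seconds")
        series = BreathSeries(g["t_seconds"].to_numpy(), g["power_w_per_kg"].to_numpy())
        est = fit_first_order(series)
        rows.append(
            {
                "participant_id": pid,
                "block": block,
                "trial": trial,
                "y_ss": est.y_ss,
                "baseline": baselines[pid],
                "net_w_per_kg": net_rate(est.y_ss, baselines[pid]),
                "tau": est.tau,
                "converged": est.converged,
            }
        )
    return pd.DataFrame(rows)


def build_comparisons(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Turn ordered within-block trials into sequential (reference, comparison) pairs.

    Parameters
    ----------
    trials
        One row per trial with columns ``participant_id``, ``block``,
        ``trial`` (presentation order within block), ``net_w_per_kg``, and
        ``response`` (0/1, NA on the first trial of each block).

    Returns
    -------
    (comparisons, n_dropped)
        ``comparisons`` has one row per consecutive within-block pair with
        columns ``participant_id, block, pair_index, A_w_per_kg, B_w_per_kg,
        x_percent, response``; pairs never span block boundaries.
        ``n_dropped`` counts pairs discarded for a non-positive reference
        (x is undefined there).

    Raises
    ------
    ValueError
        If a non-first trial is missing its response.
    """
    required = {"participant_id", "block", "trial", "net_w_per_kg", "response"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trials frame missing columns: {sorted(missing)}")

    rows = []
    n_dropped = 0
    for (pid, block), grp in trials.groupby(["participant_id", "block"], sort=True):
        grp = grp.sort_values("trial")
        nets = grp["net_w_per_kg"].to_numpy(dtype=float)
        resp = grp["response"].to_numpy()
        for i in range(1, len(grp)):
            if pd.isna(resp[i]):
                raise ValueError(
                    f"missing response for participant {pid}, block {block}, "
                    f"trial {grp['trial'].iloc[i]}"
                )
            a, b = nets[i - 1], nets[i]
            if a <= 0:
                n_dropped += 1
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "block": block,
                    "pair_index": i,
                    "A_w_per_kg": a,
                    "B_w_per_kg": b,
                    "x_percent": 100.0 * (b - a) / a,
                    "response": int(resp[i]),
                }
            )
    if n_dropped:
        logger.info("dropped %d comparison pairs with non-positive reference", n_dropped)
    cols = ["participant_id", "block", "pair_index", "A_w_per_kg", "B_w_per_kg", "x_percent", "response"]
    return pd.DataFrame(rows, columns=cols), n_dropped
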