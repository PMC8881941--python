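"""Cohort-level statistics and headline quantities.

Summarizes per-participant JND point estimates (mean/SD/SE), checks their
normality, converts the cohort-average psychometric curve into the
probability of perceiving a given metabolic-rate change, regresses JNDs on
fitness covariates, and sweeps the prior's upper bound to probe sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .inference import McmcSettings, PriorSpec, fit_independent
from .psychometrics import (
    GAMMA_DEFAULT,
    LAPSE_DEFAULT,
    PsychometricModel,
    psychometric_prob,
)

__all__ = [
    "CohortSummary",
    "KsResult",
    "RegressionResult",
    "summarize_cohort",
    "ks_normality",
    "perceive_probability",
    "fitness_regression",
    "prior_sensitivity",
]


@dataclass(frozen=True)
class CohortSummary:
    n: int
    mean_jnd: float
    sd_jnd: float
    se_jnd: float
    min_jnd: float
    max_jnd: float


@dataclass(frozen=True)
class KsResult:
    """One-sample KS test against a normal with sample-estimated parameters.

    Because the reference mean/SD are estimated from the same sample, the
    nominal p-value is approximate (Lilliefors caveat); ``note`` records this.
    """

    statistic: float
    p_value: float
    note: str = "normal parameters estimated from sample; p-value approximate (Lilliefors caveat)"


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS of JND on one covariate with an F-test of the slope."""

    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    band_x: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray


def summarize_cohort(estimates: Sequence[float]) -> CohortSummary:
    """Sample mean, SD (n-1 denominator), SE = SD/sqrt(n), min and max."""
    est = np.asarray(estimates, dtype=float)
    if len(est) < 2:
        raise ValueError(f"need at least 2 estimates, got {len(est)}")
    sd = float(np.std(est, ddof=1))
    return CohortSummary(
        n=len(est),
        mean_jnd=float(np.mean(est)),
        sd_jnd=sd,
        se_jnd=sd / np.sqrt(len(est)),
        min_jnd=float(np.min(est)),
        max_jnd=float(np.max(est)),
    )


def ks_normality(estimates: Sequence[float]) -> KsResult:
    """One-sample Kolmogorov-Smirnov test for normality of the JND estimates."""
    est = np.asarray(estimates, dtype=float)
    if len(est) < 5:
        raise ValueError(f"need at least 5 estimates, got {len(est)}")
    sd = np.std(est, ddof=1)
    if sd == 0:
        raise ValueError("zero sample SD; KS test undefined")
    stat, p = stats.kstest(est, "norm", args=(np.mean(est), sd))
    return KsResult(statistic=float(stat), p_value=float(p))


def perceive_probability(mean_jnd: float, delta: float) -> float:
    """Probability the average observer perceives a ``delta``-percent rate change.

    Evaluates the cohort-average psychometric curve (alpha = 0,
    gamma = lambda = 0.02, beta = k / mean_jnd) at ``delta``.  By
    construction perceive_probability(j, j) = 0.75 for any j > 0 and
    perceive_probability(j, 0) = 0.50.
    """
    if not mean_jnd > 0:
        raise ValueError(f"mean JND must be positive, got {mean_jnd}")
    model = PsychometricModel.from_jnd(mean_jnd)
    return float(psychometric_prob(delta, model))


def fitness_regression(estimates: Sequence[float], covariate: Sequence[float]) -> RegressionResult:
    """OLS regression of JND point estimates on one fitness covariate.

    The F-test of the regression (one predictor, so F = t^2 of the slope)
    tests slope = 0 at the usual 5% level; the returned band is the 95%
    confidence band for the mean response over the covariate range.
    """
    y = np.asarray(estimates, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need matched estimates/covariate arrays of length >= 3")
    if np.var(x) == 0:
        raise ValueError("degenerate covariate (zero variance)")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 100)
    pred = fit.get_prediction(sm.add_constant(grid)).conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        f_statistic=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        band_x=grid,
        band_lower=pred[:, 0],
        band_upper=pred[:, 1],
    )


def prior_sensitivity(
    comparisons: pd.DataFrame,
    upper_bounds: Sequence[float] = (60.0, 70.0, 80.0),
    default_upper: float = 70.0,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> pd.DataFrame:
    """Refit every participant's independent JND under each prior upper bound.

    Returns one row per bound with the cohort mean of the point estimates and
    the shift relative to the bound equal to ``default_upper``. Seeds are
    derived deterministically per (participant, bound) so identical calls
    reproduce identical outputs.
    """
    mcmc = mcmc or McmcSettings()
    pids = sorted(comparisons["participant_id"].unique())
    rows = []
    for bi, ub in enumerate(upper_bounds):
        prior = PriorSpec(lower=0.0, upper=float(ub))
        estimates = []
        for pi, pid in enumerate(pids):
            sub = comparisons[comparisons["participant_id"] == pid]
            fit_seed = int(np.random.SeedSequence(entropy=seed, spawn_key=(bi, pi)).generate_state(1)[0] % (2**31))
            summary = fit_independent(sub, prior, mcmc, seed=fit_seed, gamma=gamma, lapse=lapse)
            estimates.append(summary.point_estimate)
        rows.append({"upper_bound": float(ub), "mean_jnd": float(np.mean(estimates))})
    table = pd.DataFrame(rows)
    ref = table.loc[table["upper_bound"] == float(default_upper), "mean_jnd"]
    baseline = float(ref.iloc[0]) if len(ref) else float("nan")
    table["shift_vs_default"] = table["mean_jnd"] - baseline
    return table
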