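"""Bayesian JND estimation, posterior summaries, and WAIC model comparison.

Each model places a uniform prior on the JND (default 0-70%, with a small
floor to keep the slope finite) and a Bernoulli likelihood on the binary
responses through the logistic psychometric function. Three structures are
compared:

* pooled       — one JND shared by every participant;
* independent  — one JND per participant;
* variable-WF  — two JNDs per participant, split at the median absolute
                 reference rate, allowing the Weber fraction to change with
                 reference magnitude.

All posteriors are one-dimensional, and are sampled with an affine-invariant
ensemble sampler (emcee); walkers play the role of chains and split-R-hat is
computed across them. A brute-force grid integration of the same posterior
serves as an independent oracle for testing. WAIC is reported on the elpd
scale (higher is better), with one binary response as the pointwise unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import emcee
import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .psychometrics import (
    GAMMA_DEFAULT,
    LAPSE_DEFAULT,
    pointwise_log_likelihood,
    scale_constant_k,
)

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "POOLED_MCMC_DEFAULTS",
    "PosteriorSummary",
    "VariableWfFit",
    "WaicResult",
    "GridPosterior",
    "ModeEstimate",
    "fit_independent",
    "fit_pooled",
    "fit_variable_wf",
    "posterior_mode",
    "credible_interval",
    "grid_posterior_oracle",
    "compute_waic",
    "cohort_waic",
    "compare_models",
    "split_rhat",
]


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior on the JND in percent.

    ``floor`` (default 0.1%) is the implementation's lower clamp on the
    sampled value: at JND -> 0 the slope k/JND diverges, and 0.1% is far
    below any plausible human threshold.
    """

    lower: float = 0.0
    upper: float = 70.0
    floor: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper:
            raise ValueError(f"need 0 <= lower < upper, got ({self.lower}, {self.upper})")

    @property
    def support(self) -> tuple[float, float]:
        return (max(self.lower, self.floor), self.upper)


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings: chains (ensemble walkers come in pairs per chain),
    tuning (burn-in) iterations, and kept posterior draws (total, all chains).

    ``thin`` keeps every thin-th ensemble step, trading extra iterations for
    lower autocorrelation in the kept draws (the draw count is unaffected).
    """

    chains: int = 4
    tune: int = 8000
    draws: int = 4000
    thin: int = 4

    def __post_init__(self) -> None:
        if self.chains < 2 or self.tune < 1 or self.draws < 100 or self.thin < 1:
            raise ValueError("need >= 2 chains, >= 1 tuning step, >= 100 draws, thin >= 1")


#: The pooled model uses lighter settings (it sees every response at once).
POOLED_MCMC_DEFAULTS = McmcSettings(chains=4, tune=2000, draws=2000)

RHAT_THRESHOLD = 1.01
FLATNESS_RATIO = 1.5  # KDE max/mean below this flags a non-identified plateau


@dataclass(frozen=True)
class ModeEstimate:
    """Posterior mode with a flatness diagnostic (True = KDE plateau, the
    posterior is essentially the prior and the mode is not identified)."""

    value: float
    flat: bool


@dataclass(frozen=True)
class PosteriorSummary:
    """JND posterior for one model fit.

    ``point_estimate`` is the posterior mode (the MLE under a uniform prior on
    its support); ``ci95`` the equal-tailed 95% credible interval.
    """

    draws: np.ndarray
    point_estimate: float
    ci95: tuple[float, float]
    diagnostics: dict
    prior: PriorSpec

    @property
    def flat(self) -> bool:
        return bool(self.diagnostics.get("flat_posterior", False))


@dataclass(frozen=True)
class VariableWfFit:
    """Two-JND fit: posteriors below/above the median absolute reference rate."""

    low: PosteriorSummary
    high: PosteriorSummary
    split_value: float
    is_high: np.ndarray  # aligned with the input comparison order


@dataclass(frozen=True)
class WaicResult:
    """WAIC on the elpd scale: higher score = better predictive fit."""

    score: float
    se: float
    p_eff: float
    pointwise: np.ndarray


@dataclass(frozen=True)
class GridPosterior:
    """Normalized posterior density on a JND grid (brute-force oracle)."""

    grid: np.ndarray
    density: np.ndarray

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def _extract_xy(comparisons: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = comparisons["x_percent"].to_numpy(dtype=float)
    r = comparisons["response"].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite x_percent in comparisons")
    if not np.isin(r, (0.0, 1.0)).all():
        raise ValueError("responses must be 0/1")
    return x, r


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an (n_chains, n_draws) array (Gelman et al.)."""
    n_chains, n = chains.shape
    half = n // 2
    halves = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    b = n * np.var(chain_means, ddof=1)
    w = np.mean(np.var(halves, axis=1, ddof=1))
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _sample_jnd(
    x: np.ndarray,
    r: np.ndarray,
    prior: PriorSpec,
    mcmc: McmcSettings,
    seed: int,
    gamma: float,
    lapse: float,
) -> tuple[np.ndarray, dict]:
    """Run the ensemble sampler on the 1-D JND posterior; return draws + diagnostics."""
    lo, hi = prior.support
    k = scale_constant_k(gamma, lapse)
    span = 1.0 - lapse - gamma

    def log_prob(theta: np.ndarray) -> np.ndarray:
        j = theta[:, 0]
        out = np.full(j.shape, -np.inf)
        ok = (j > lo) & (j < hi)
        if ok.any():
            beta = k / j[ok]
            with np.errstate(over="ignore"):
                p = gamma + span / (1.0 + np.exp(-np.outer(beta, x)))
            out[ok] = (r * np.log(p) + (1.0 - r) * np.log1p(-p)).sum(axis=1)
        return out

    nwalkers = max(4, 2 * mcmc.chains)
    rng = np.random.RandomState(seed)
    sampler = emcee.EnsembleSampler(nwalkers, 1, log_prob, vectorize=True)
    sampler.random_state = rng.get_state()
    p0 = rng.uniform(lo + 1e-3 * (hi - lo), hi - 1e-3 * (hi - lo), (nwalkers, 1))
    state = sampler.run_mcmc(p0, mcmc.tune)
    sampler.reset()
    steps = max(2, math.ceil(mcmc.draws / nwalkers))
    sampler.run_mcmc(state, steps, thin_by=mcmc.thin)
    chain = sampler.get_chain()[:, :, 0].T  # (nwalkers, steps)
    draws = chain.reshape(-1)[: mcmc.draws]
    diagnostics = {
        "n_chains": nwalkers,
        "n_draws": int(len(draws)),
        "rhat": split_rhat(chain),
        "accept_rate": float(np.mean(sampler.acceptance_fraction)),
        "divergences": 0,  # not applicable to the ensemble sampler; kept for schema parity
        "seed": int(seed),
    }
    return draws, diagnostics


def _summarize(draws: np.ndarray, diagnostics: dict, prior: PriorSpec) -> PosteriorSummary:
    mode = posterior_mode(draws, prior.support)
    diagnostics = dict(diagnostics)
    diagnostics["flat_posterior"] = mode.flat
    if diagnostics.get("rhat", 1.0) > RHAT_THRESHOLD:
        diagnostics["rhat_warning"] = True
    return PosteriorSummary(
        draws=draws,
        point_estimate=mode.value,
        ci95=credible_interval(draws),
        diagnostics=diagnostics,
        prior=prior,
    )


def fit_independent(
    comparisons: pd.DataFrame,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> PosteriorSummary:
    """Posterior over a single JND for one participant's comparisons.

    Raises ValueError on an empty comparison set.
    """
    if len(comparisons) == 0:
        raise ValueError("cannot fit with zero comparisons")
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    x, r = _extract_xy(comparisons)
    draws, diag = _sample_jnd(x, r, prior, mcmc, seed, gamma, lapse)
    return _summarize(draws, diag, prior)


def fit_pooled(
    comparisons: pd.DataFrame,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> PosteriorSummary:
    """Single shared-JND posterior over the concatenated cohort responses.

    Identical model to :func:`fit_independent` applied to all responses at
    once; default sampler settings are lighter (2000 tune / 2000 draws).
    """
    mcmc = mcmc or POOLED_MCMC_DEFAULTS
    return fit_independent(comparisons, prior, mcmc, seed, gamma, lapse)


def fit_variable_wf(
    comparisons: pd.DataFrame,
    prior: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    seed: int = 0,
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> VariableWfFit:
    """Two-JND fit for one participant, split at the median reference rate.

    Comparisons whose absolute reference rate A lies strictly below the
    participant's median A get the "low" JND; the rest get the "high" JND.
    Raises ValueError when all references are identical (split undefined) or
    either half would be empty.
    """
    if len(comparisons) < 2:
        raise ValueError("need at least 2 comparisons to split")
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    a = np.abs(comparisons["A_w_per_kg"].to_numpy(dtype=float))
    if np.ptp(a) == 0:
        raise ValueError("all reference rates identical; median split undefined")
    split = float(np.median(a))
    is_high = a >= split
    if is_high.all():  # odd ties: ensure both halves populated
        is_high = a > split
    low, high = comparisons.loc[~is_high], comparisons.loc[is_high]
    if len(low) == 0 or len(high) == 0:
        raise ValueError("median split produced an empty half")
    return VariableWfFit(
        low=fit_independent(low, prior, mcmc, seed, gamma, lapse),
        high=fit_independent(high, prior, mcmc, seed + 1, gamma, lapse),
        split_value=split,
        is_high=is_high,
    )


def posterior_mode(draws: np.ndarray, support: tuple[float, float]) -> ModeEstimate:
    """Mode of a Gaussian-KDE density over the draws (Silverman bandwidth,
    evaluated on a 1000-point grid over the prior support).

    Under a uniform prior the posterior mode is the maximum-likelihood
    estimate on the support.  A near-flat KDE (max/mean ratio below 1.5)
    flags a non-identified plateau.
    """
    draws = np.asarray(draws, dtype=float)
    if len(draws) < 100:
        raise ValueError(f"need >= 100 draws for a mode estimate, got {len(draws)}")
    if np.ptp(draws) == 0:
        return ModeEstimate(value=float(draws[0]), flat=False)
    kde = gaussian_kde(draws, bw_method="silverman")
    grid = np.linspace(support[0], support[1], 1000)
    dens = kde(grid)
    flat = bool(dens.max() / dens.mean() < FLATNESS_RATIO)
    return ModeEstimate(value=float(grid[np.argmax(dens)]), flat=flat)


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval (default 2.5th-97.5th percentiles)."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    draws = np.asarray(draws, dtype=float)
    if len(draws) < 100:
        raise ValueError(f"need >= 100 draws for an interval, got {len(draws)}")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return (float(lo), float(hi))


def grid_posterior_oracle(
    comparisons: pd.DataFrame,
    prior: PriorSpec | None = None,
    n_grid: int = 2000,
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> GridPosterior:
    """Brute-force posterior by 1-D quadrature on a JND grid.

    Density proportional to exp(log-likelihood) times the uniform prior,
    normalized by the trapezoid rule to integrate to one. With zero
    comparisons this returns the prior itself. Serves as the independent
    oracle for the MCMC fits.
    """
    prior = prior or PriorSpec()
    lo, hi = prior.support
    grid = np.linspace(lo, hi, n_grid)
    if len(comparisons) == 0:
        dens = np.full(n_grid, 1.0 / (hi - lo))
        return GridPosterior(grid=grid, density=dens)
    x, r = _extract_xy(comparisons)
    ll = pointwise_log_likelihood(x, r, grid, gamma, lapse).sum(axis=1)
    logdens = ll - ll.max()
    dens = np.exp(logdens)
    dens /= np.trapezoid(dens, grid)
    return GridPosterior(grid=grid, density=dens)


def compute_waic(ll: np.ndarray) -> WaicResult:
    """WAIC from a (draws x responses) pointwise log-likelihood matrix.

    elpd_waic = sum_i [ lppd_i - p_i ] with lppd_i = log mean_d exp(ll_di)
    (log-sum-exp stabilized) and p_i = var_d(ll_di); the standard error is
    sqrt(n * var_i(pointwise)).  Reported on the elpd scale: higher wins.
    """
    ll = np.asarray(ll, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a (draws, responses) matrix")
    if ll.shape[0] < 100:
        raise ValueError(f"need >= 100 draws, got {ll.shape[0]}")
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite entries in the log-likelihood matrix")
    s, n = ll.shape
    lppd = logsumexp(ll, axis=0) - np.log(s)
    p = np.var(ll, axis=0, ddof=1)
    pointwise = lppd - p
    score = float(pointwise.sum())
    se = float(np.sqrt(n * np.var(pointwise, ddof=1))) if n > 1 else 0.0
    return WaicResult(score=score, se=se, p_eff=float(p.sum()), pointwise=pointwise)


def cohort_waic(
    n_total: int,
    blocks: Iterable[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> WaicResult:
    """WAIC over a cohort whose responses are fit by different posteriors.

    ``blocks`` yields ``(jnd_draws, x, r, indices)`` tuples: one block per
    posterior (e.g. one per participant in the independent model), where
    ``indices`` places that block's responses in the canonical cohort order
    so pointwise vectors stay aligned across competing models. Every
    response index must be covered exactly once.
    """
    pointwise = np.full(n_total, np.nan)
    p_terms = np.full(n_total, np.nan)
    for draws, x, r, idx in blocks:
        ll = pointwise_log_likelihood(x, r, draws, gamma, lapse)
        s = ll.shape[0]
        lppd = logsumexp(ll, axis=0) - np.log(s)
        p = np.var(ll, axis=0, ddof=1)
        if np.any(np.isfinite(pointwise[idx])):
            raise ValueError("overlapping response indices across blocks")
        pointwise[idx] = lppd - p
        p_terms[idx] = p
    if np.any(np.isnan(pointwise)):
        raise ValueError("some responses not covered by any block")
    score = float(pointwise.sum())
    se = float(np.sqrt(n_total * np.var(pointwise, ddof=1))) if n_total > 1 else 0.0
    return WaicResult(score=score, se=se, p_eff=float(p_terms.sum()), pointwise=pointwise)


def compare_models(waics: Mapping[str, WaicResult]) -> pd.DataFrame:
    """Rank models by WAIC with differences to the best model.

    All models must be scored on the identical response set (aligned
    pointwise vectors).  Returns a frame sorted by score (descending) with
    columns ``model, score, se, p_eff, d_score, d_se`` where ``d_score`` is
    the gap to the top model and ``d_se`` the standard error of that gap
    computed from the pointwise differences.
    """
    if not waics:
        raise ValueError("no models to compare")
    lengths = {len(w.pointwise) for w in waics.values()}
    if len(lengths) != 1:
        raise ValueError(f"models scored on different response sets: sizes {sorted(lengths)}")
    n = lengths.pop()
    order = sorted(waics, key=lambda m: waics[m].score, reverse=True)
    top = waics[order[0]]
    rows = []
    for name in order:
        w = waics[name]
        diff = top.pointwise - w.pointwise
        d_se = float(np.sqrt(n * np.var(diff, ddof=1))) if n > 1 else 0.0
        rows.append(
            {
                "model": name,
                "score": w.score,
                "se": w.se,
                "p_eff": w.p_eff,
                "d_score": top.score - w.score,
                "d_se": d_se,
            }
        )
    return pd.DataFrame(rows)
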