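"""Logistic psychometric function for forced-choice discrimination of metabolic rate.

The observation model for a sequential two-alternative task ("is the current
level of exertion higher than the previous one?") is a logistic psychometric
function of the reference-normalized stimulus difference ``x`` (in percent)::

    Psi(x) = gamma + (1 - lambda - gamma) / (1 + exp(-beta * (x - alpha)))

with threshold point ``alpha`` (fixed at 0 for an unbiased discrimination
task), slope ``beta`` (the single free parameter, per percentage point),
false-positive rate ``gamma`` and lapse rate ``lambda`` (both fixed at 0.02).
The Just Noticeable Difference (JND) is the stimulus change detected with 75%
accuracy: half the distance between the x-values where Psi crosses 0.25 and
0.75. With the other parameters fixed this collapses to

    JND = k / beta,
    k   = 1/2 * ln[ ((0.75 - gamma) * (1 - lambda - 0.25))
                  / ((1 - lambda - 0.75) * (0.25 - gamma)) ]

so the JND (equivalently, the Weber fraction expressed in percent) depends on
the slope alone.  All x values in this package are percent changes of net
metabolic rate relative to the reference trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GAMMA_DEFAULT",
    "LAPSE_DEFAULT",
    "PsychometricModel",
    "scale_constant_k",
    "psychometric_prob",
    "jnd_from_beta",
    "beta_from_jnd",
    "jnd_from_quartiles",
    "log_likelihood",
    "pointwise_log_likelihood",
]

GAMMA_DEFAULT = 0.02
LAPSE_DEFAULT = 0.02


def scale_constant_k(gamma: float = GAMMA_DEFAULT, lapse: float = LAPSE_DEFAULT) -> float:
    """Scale constant ``k`` linking the logistic slope to the JND.

    ``k = 1/2 ln[((0.75-gamma)(0.75-lapse)) / ((0.25-lapse)(0.25-gamma))]``
    (the 0.75-lapse and 0.25-lapse factors are ``1-lapse-0.25`` and
    ``1-lapse-0.75`` simplified).  For ``gamma == lapse`` this reduces to
    ``ln((0.75-gamma)/(0.25-gamma))``; with both zero, ``k = ln 3``.

    Raises
    ------
    ValueError
        If any log factor is non-positive (requires ``gamma, lapse < 0.25``).
    """
    if not (0 <= gamma < 0.25 and 0 <= lapse < 0.25):
        raise ValueError(
            f"scale constant requires 0 <= gamma, lapse < 0.25; got gamma={gamma}, lapse={lapse}"
        )
    num = (0.75 - gamma) * (0.75 - lapse)
    den = (0.25 - lapse) * (0.25 - gamma)
    return 0.5 * math.log(num / den)


@dataclass(frozen=True)
class PsychometricModel:
    """Logistic psychometric model with fixed guess/lapse rates.

    Parameters
    ----------
    beta
        Slope of the logistic, per percentage point of stimulus. The only
        parameter estimated from data.
    alpha
        Threshold point on the x-axis (percent). Fixed at 0: zero change is
        judged "higher" with probability one half.
    gamma
        False-positive (guess) rate; the floor of the curve.
    lapse
        Lapse rate; the curve saturates at ``1 - lapse``.
    """

    beta: float
    alpha: float = 0.0
    gamma: float = GAMMA_DEFAULT
    lapse: float = LAPSE_DEFAULT
    k: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not (0 <= self.gamma and 0 <= self.lapse and self.gamma + self.lapse < 0.5):
            raise ValueError(
                f"need 0 <= gamma, lapse and gamma + lapse < 0.5; got {self.gamma}, {self.lapse}"
            )
        object.__setattr__(self, "k", scale_constant_k(self.gamma, self.lapse))

    @property
    def jnd(self) -> float:
        """JND in percent: ``k / beta``."""
        return self.k / self.beta

    @classmethod
    def from_jnd(
        cls,
        jnd: float,
        alpha: float = 0.0,
        gamma: float = GAMMA_DEFAULT,
        lapse: float = LAPSE_DEFAULT,
    ) -> "PsychometricModel":
        """Build a model from its JND (percent) instead of its slope."""
        if not jnd > 0:
            raise ValueError(f"JND must be positive, got {jnd}")
        beta = scale_constant_k(gamma, lapse) / jnd
        return cls(beta=beta, alpha=alpha, gamma=gamma, lapse=lapse)


def psychometric_prob(x, model: PsychometricModel):
    """Probability of responding "comparison is higher" at stimulus ``x`` (percent).

    Vectorized over ``x``; the result lies strictly in ``(gamma, 1 - lapse)``
    and increases monotonically in ``x``.
    """
    x = np.asarray(x, dtype=float)
    span = 1.0 - model.lapse - model.gamma
    with np.errstate(over="ignore"):
        p = model.gamma + span / (1.0 + np.exp(-model.beta * (x - model.alpha)))
    return p if p.ndim else float(p)


def jnd_from_beta(beta: float, k: float) -> float:
    """JND (percent) from the logistic slope: ``k / beta``."""
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return k / beta


def beta_from_jnd(jnd: float, k: float) -> float:
    """Logistic slope from the JND (percent): ``k / jnd``. Inverse of jnd_from_beta."""
    if not jnd > 0:
        raise ValueError(f"JND must be positive, got {jnd}")
    return k / jnd


def jnd_from_quartiles(model: PsychometricModel, tol: float = 1e-12) -> float:
    """JND from the defining construction: half the spread between the 0.25 and 0.75 crossings.

    Numerically inverts Psi at 0.75 and 0.25 by bracketed root finding (Psi is
    monotone, so the bracket is safe) and returns half the difference.  Agrees
    with ``k / beta`` to solver tolerance for any valid parameter set,
    including ``gamma != lapse``.
    """
    for q in (0.25, 0.75):
        if not (model.gamma < q < 1.0 - model.lapse):
            raise ValueError(f"quantile {q} outside the attainable range of Psi")
    half_width = 1000.0 / model.beta  # generous bracket in percent
    lo, hi = model.alpha - half_width, model.alpha + half_width

    def invert(q: float) -> float:
        return brentq(lambda x: psychometric_prob(x, model) - q, lo, hi, xtol=tol)

    return (invert(0.75) - invert(0.25)) / 2.0


def _prob_from_jnd(x: np.ndarray, jnd, gamma: float, lapse: float) -> np.ndarray:
    k = scale_constant_k(gamma, lapse)
    beta = k / np.asarray(jnd, dtype=float)
    span = 1.0 - lapse - gamma
    arg = np.multiply.outer(beta, x) if np.ndim(beta) else beta * x
    with np.errstate(over="ignore"):
        return gamma + span / (1.0 + np.exp(-arg))


def log_likelihood(
    x,
    responses,
    jnd: float,
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> float:
    """Bernoulli log-likelihood of binary responses under a given JND.

    ``sum_i [ r_i ln Psi(x_i) + (1 - r_i) ln(1 - Psi(x_i)) ]`` with
    ``beta = k / jnd``.  Finite for any finite inputs because Psi is bounded
    inside ``(gamma, 1 - lapse)``.
    """
    if not jnd > 0:
        raise ValueError(f"JND must be positive, got {jnd}")
    x = np.asarray(x, dtype=float)
    r = np.asarray(responses, dtype=float)
    p = _prob_from_jnd(x, jnd, gamma, lapse)
    return float(np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p)))


def pointwise_log_likelihood(
    x,
    responses,
    jnd_draws,
    gamma: float = GAMMA_DEFAULT,
    lapse: float = LAPSE_DEFAULT,
) -> np.ndarray:
    """Per-response log-likelihood matrix over posterior draws.

    Returns an array of shape ``(n_draws, n_responses)`` whose ``(d, i)``
    entry is the Bernoulli log-likelihood of response ``i`` under JND draw
    ``d`` — the pointwise input WAIC expects.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(responses, dtype=float)
    draws = np.asarray(jnd_draws, dtype=float)
    if np.any(draws <= 0):
        raise ValueError("all JND draws must be positive")
    p = _prob_from_jnd(x, draws, gamma, lapse)
    return r * np.log(p) + (1.0 - r) * np.log1p(-p)
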