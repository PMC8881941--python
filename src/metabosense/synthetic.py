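"""Synthetic discrimination studies with known ground truth.

Generates complete studies with the structure the analysis assumes: N
participants each completing blocks of 10 two-minute walking trials (9
sequential comparisons per block), where each trial's net metabolic rate is
set by a randomized ankle-exoskeleton torque profile, measured rates follow a
first-order cardiopulmonary transient (tau = 42 s) sampled breath by breath
with noise, and binary "higher exertion?" responses are Bernoulli draws from
the logistic psychometric function at each participant's true JND.

The torque-profile -> net-rate map is a SYNTHETIC surrogate: a smooth, fixed
quadratic response surface in the three normalized profile parameters,
rescaled into the configured rate range (default 1.5-6.6 W/kg). Real
exoskeleton energetics have no such closed form; downstream inference needs
only realistic rate variation, which is all the surrogate provides.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .metabolics import BreathSeries
from .psychometrics import scale_constant_k

__all__ = [
    "TorqueProfile",
    "StudyConfig",
    "ParticipantTruth",
    "Trial",
    "Participant",
    "SyntheticStudy",
    "sample_torque_profile",
    "surrogate_metabolic_rate",
    "simulate_breath_series",
    "simulate_response",
    "generate_study",
]

TAU_DEFAULT = 42.0  # cardiopulmonary time constant, seconds


@dataclass(frozen=True)
class TorqueProfile:
    """Square-pulse ankle assistance profile: onset/duration as stride fractions, magnitude in A.

    Constraints: onset in [0.25, 0.50]; magnitude in [15, 25] A; duration in
    [0.10, 0.60] of stride, with a raised floor of 0.20 when onset < 0.30.
    """

    onset: float
    magnitude: float
    duration: float

    def __post_init__(self) -> None:
        if not 0.25 <= self.onset <= 0.50:
            raise ValueError(f"onset {self.onset} outside [0.25, 0.50]")
        if not 15.0 <= self.magnitude <= 25.0:
            raise ValueError(f"magnitude {self.magnitude} outside [15, 25] A")
        d_min = 0.20 if self.onset < 0.30 else 0.10
        if not d_min <= self.duration <= 0.60:
            raise ValueError(
                f"duration {self.duration} outside [{d_min}, 0.60] for onset {self.onset}"
            )


def sample_torque_profile(rng: np.random.Generator) -> TorqueProfile:
    """Draw a torque profile from the protocol's uniform distributions.

    onset ~ U(0.25, 0.50); magnitude ~ U(15, 25) A; duration ~ U(d_min, 0.60)
    where d_min = 0.20 for onset < 0.30 (device-wear constraint) else 0.10.
    """
    onset = rng.uniform(0.25, 0.50)
    magnitude = rng.uniform(15.0, 25.0)
    d_min = 0.20 if onset < 0.30 else 0.10
    duration = rng.uniform(d_min, 0.60)
    return TorqueProfile(onset=onset, magnitude=magnitude, duration=duration)


@dataclass(frozen=True)
class StudyConfig:
    """Generator settings; defaults mirror the study protocol.

    10 participants x 11 blocks x 10 trials (9 responses/block); true JNDs
    uniform over (6, 70) percent; responses lapse at 0.02; net rates spanning
    1.5-6.6 W/kg; tau = 42 s transients sampled every ~4 s (+/- 1 s jitter)
    with additive Gaussian noise of 8% of the local steady state; 4-minute
    standing baseline.
    """

    n_participants: int = 10
    blocks_per_participant: int = 11
    trials_per_block: int = 10
    jnd_range: tuple[float, float] = (6.0, 70.0)
    lapse: float = 0.02
    rate_range: tuple[float, float] = (1.5, 6.6)
    standing_range: tuple[float, float] = (1.0, 1.5)
    tau_seconds: float = TAU_DEFAULT
    trial_duration_s: float = 120.0
    standing_duration_s: float = 240.0
    breath_interval_s: float = 4.0
    breath_jitter_s: float = 1.0
    noise_frac: float = 0.08

    def __post_init__(self) -> None:
        if self.trials_per_block < 2:
            raise ValueError("need at least 2 trials per block (else no comparisons)")
        if self.n_participants < 1 or self.blocks_per_participant < 1:
            raise ValueError("participant and block counts must be positive")
        if not self.rate_range[0] < self.rate_range[1]:
            raise ValueError(f"invalid rate range {self.rate_range}")
        if not 0 < self.jnd_range[0] <= self.jnd_range[1]:
            raise ValueError(f"invalid JND range {self.jnd_range}")
        if not 0 <= self.lapse < 0.5:
            raise ValueError(f"lapse {self.lapse} outside [0, 0.5)")
        if self.tau_seconds <= 0 or self.trial_duration_s <= 0:
            raise ValueError("tau and trial duration must be positive")


@dataclass(frozen=True)
class ParticipantTruth:
    """Ground truth for one simulated participant."""

    participant_id: str
    jnd_percent: float
    lapse: float
    standing_w_per_kg: float
    tau_seconds: float
    surrogate_shift: float
    surrogate_scale: float

    def __post_init__(self) -> None:
        if not self.jnd_percent > 0:
            raise ValueError("true JND must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse outside [0, 0.5)")
        if not self.tau_seconds > 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class Trial:
    block: int
    trial: int
    profile: TorqueProfile
    true_net_w_per_kg: float
    breaths: BreathSeries
    response: Optional[int]  # None on the first trial of a block


@dataclass(frozen=True)
class Participant:
    truth: ParticipantTruth
    standing_breaths: BreathSeries
    trials: tuple[Trial, ...]


@dataclass(frozen=True)
class SyntheticStudy:
    config: StudyConfig
    seed: int
    participants: tuple[Participant, ...]

    def validate(self) -> None:
        """Assert the structural invariants of a generated study."""
        cfg = self.config
        assert len(self.participants) == cfg.n_participants
        lo, hi = cfg.rate_range
        for p in self.participants:
            assert len(p.trials) == cfg.blocks_per_participant * cfg.trials_per_block
            for blk in range(1, cfg.blocks_per_participant + 1):
                blk_trials = [t for t in p.trials if t.block == blk]
                assert len(blk_trials) == cfg.trials_per_block
                responses = [t.response for t in blk_trials if t.response is not None]
                assert len(responses) == cfg.trials_per_block - 1
                assert blk_trials[0].response is None
            for t in p.trials:
                assert lo <= t.true_net_w_per_kg <= hi
                assert np.all(np.diff(t.breaths.t) > 0)


def surrogate_metabolic_rate(
    profile: TorqueProfile,
    shift: float = 0.0,
    scale: float = 1.0,
    rate_range: tuple[float, float] = (1.5, 6.6),
) -> float:
    """Synthetic profile -> net steady-state rate map (W/kg).

    A fixed quadratic response surface in the normalized profile parameters,
    affinely rescaled into ``rate_range``; ``shift`` and ``scale`` give each
    participant their own smooth deformation of the surface. Deterministic:
    identical (profile, shift, scale) always yield the identical rate.
    """
    lo, hi = rate_range
    if lo >= hi:
        raise ValueError(f"rate range misconfigured: {rate_range}")
    u_on = (profile.onset - 0.25) / 0.25
    u_mag = (profile.magnitude - 15.0) / 10.0
    u_dur = (profile.duration - 0.10) / 0.50
    # positive-weight quadratic surface; bounded in [0, 1] on the unit cube
    f = (2.0 * u_mag + 1.2 * u_dur + 0.6 * u_on + 0.7 * u_mag * u_dur) / 4.5
    g = float(np.clip(shift + scale * f, 0.0, 1.0))
    return lo + (hi - lo) * g


def simulate_breath_series(
    prev_rate: float,
    target_rate: float,
    rng: np.random.Generator,
    tau: float = TAU_DEFAULT,
    noise_sd: float = 0.0,
    duration_s: float = 120.0,
    breath_interval_s: float = 4.0,
    jitter_s: float = 0.0,
) -> BreathSeries:
    """Breath-sampled first-order transient from ``prev_rate`` toward ``target_rate``.

    The noiseless trajectory is ``y(t) = target + (prev - target) exp(-t/tau)``;
    i.i.d. Gaussian noise of ``noise_sd`` is added per breath. Breath times
    step by ``breath_interval_s`` with uniform jitter of ``+/- jitter_s``
    (floored at 0.5 s so timestamps stay strictly increasing), covering
    ``duration_s``.
    """
    if breath_interval_s <= 0:
        raise ValueError(f"breath interval must be positive, got {breath_interval_s}")
    if tau <= 0 or duration_s <= 0:
        raise ValueError("tau and duration must be positive")
    times = []
    t = 0.0
    while True:
        step = breath_interval_s + (rng.uniform(-jitter_s, jitter_s) if jitter_s > 0 else 0.0)
        t += max(0.5, step)
        if t > duration_s:
            break
        times.append(t)
    t_arr = np.asarray(times)
    y = target_rate + (prev_rate - target_rate) * np.exp(-t_arr / tau)
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(len(t_arr))
    return BreathSeries(t=t_arr, y=y)


def simulate_response(
    x_percent: float,
    true_jnd_percent: float,
    lapse: float,
    rng: np.random.Generator,
) -> int:
    """Bernoulli "comparison is higher" response from the psychometric function.

    p = lapse + (1 - 2*lapse) / (1 + exp(-(k/JND) x)) with alpha = 0 and the
    guess rate tied to the lapse rate (symmetric discrimination task).
    """
    if not true_jnd_percent > 0:
        raise ValueError("true JND must be positive")
    beta = scale_constant_k(lapse, lapse) / true_jnd_percent
    p = lapse + (1.0 - 2.0 * lapse) / (1.0 + np.exp(-beta * x_percent))
    return int(rng.random() < p)


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full synthetic study; bit-reproducible from (config, seed)."""
    cfg = config if config is not None else StudyConfig()
    rng = np.random.default_rng(seed)
    participants = []
    for i in range(cfg.n_participants):
        truth = ParticipantTruth(
            participant_id=f"P{i + 1:02d}",
            jnd_percent=float(rng.uniform(*cfg.jnd_range)),
            lapse=cfg.lapse,
            standing_w_per_kg=float(rng.uniform(*cfg.standing_range)),
            tau_seconds=cfg.tau_seconds,
            surrogate_shift=float(rng.uniform(-0.05, 0.05)),
            surrogate_scale=float(rng.uniform(0.90, 1.05)),
        )
        standing = simulate_breath_series(
            truth.standing_w_per_kg,
            truth.standing_w_per_kg,
            rng,
            tau=cfg.tau_seconds,
            noise_sd=cfg.noise_frac * truth.standing_w_per_kg,
            duration_s=cfg.standing_duration_s,
            breath_interval_s=cfg.breath_interval_s,
            jitter_s=cfg.breath_jitter_s,
        )
        trials = []
        for blk in range(1, cfg.blocks_per_participant + 1):
            prev_gross = truth.standing_w_per_kg  # blocks start from rest
            prev_net = None
            for tr in range(1, cfg.trials_per_block + 1):
                profile = sample_torque_profile(rng)
                net = surrogate_metabolic_rate(
                    profile, truth.surrogate_shift, truth.surrogate_scale, cfg.rate_range
                )
                gross = net + truth.standing_w_per_kg
                breaths = simulate_breath_series(
                    prev_gross,
                    gross,
                    rng,
                    tau=cfg.tau_seconds,
                    noise_sd=cfg.noise_frac * gross,
                    duration_s=cfg.trial_duration_s,
                    breath_interval_s=cfg.breath_interval_s,
                    jitter_s=cfg.breath_jitter_s,
                )
                if tr == 1:
                    response = None
                else:
                    x = 100.0 * (net - prev_net) / prev_net
                    response = simulate_response(x, truth.jnd_percent, truth.lapse, rng)
                trials.append(
                    Trial(
                        block=blk, trial=tr, profile=profile,
                        true_net_w_per_kg=net, breaths=breaths, response=response,
                    )
                )
                prev_gross, prev_net = gross, net
        participants.append(
            Participant(truth=truth, standing_breaths=standing, trials=tuple(trials))
        )
    study = SyntheticStudy(config=cfg, seed=seed, participants=tuple(participants))
    study.validate()
    return study
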