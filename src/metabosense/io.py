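"""Study serialization, run configuration, and the end-to-end pipeline.

File formats (all plain text):

``breaths.csv``
    participant_id, block, trial, t_seconds, power_w_per_kg — one row per
    breath of a walking trial; t_seconds counts from the trial start.
``standing.csv``
    participant_id, t_seconds, power_w_per_kg — the 4-minute standing
    baseline interval per participant.
``trials.csv``
    participant_id, block, trial, onset, magnitude_A, duration, response —
    one row per trial with its torque-profile parameters; response is 0/1,
    empty on the first trial of every block.
``truth.json``
    Generator ground truth (true JNDs, standing rates, true net rates,
    surrogate parameters) plus the config echo and seed.
``comparisons.csv``
    participant_id, block, pair_index, A_w_per_kg, B_w_per_kg, x_percent,
    response — one row per sequential within-block pair.
``results.json`` and ``posteriors/<participant>_<model>.csv``
    Point estimates, credible intervals, diagnostics, WAIC table, seeds and
    config echo; raw posterior draws per fit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import analysis, metabolics
from .inference import (
    McmcSettings,
    POOLED_MCMC_DEFAULTS,
    PriorSpec,
    cohort_waic,
    compare_models,
    fit_independent,
    fit_pooled,
    fit_variable_wf,
)
from .psychometrics import GAMMA_DEFAULT, LAPSE_DEFAULT
from .synthetic import StudyConfig, SyntheticStudy, generate_study

__all__ = [
    "RunConfig",
    "StudyData",
    "write_study",
    "read_study",
    "study_to_frames",
    "write_results",
    "run_pipeline",
]

BREATH_COLUMNS = ["participant_id", "block", "trial", "t_seconds", "power_w_per_kg"]
STANDING_COLUMNS = ["participant_id", "t_seconds", "power_w_per_kg"]
TRIAL_COLUMNS = ["participant_id", "block", "trial", "onset", "magnitude_A", "duration", "response"]


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a full pipeline run."""

    study: StudyConfig = field(default_factory=StudyConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    pooled_mcmc: McmcSettings = POOLED_MCMC_DEFAULTS
    gamma: float = GAMMA_DEFAULT
    lapse: float = LAPSE_DEFAULT
    seed: int = 0
    deltas: tuple[float, ...] = (9.6,)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for key, klass in (
            ("study", StudyConfig),
            ("prior", PriorSpec),
            ("mcmc", McmcSettings),
            ("pooled_mcmc", McmcSettings),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                for tkey in ("jnd_range", "rate_range", "standing_range"):
                    if tkey in sub:
                        sub[tkey] = tuple(sub[tkey])
                kwargs[key] = klass(**sub)
        if "deltas" in kwargs:
            kwargs["deltas"] = tuple(kwargs["deltas"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class StudyData:
    """In-memory study: long-format frames plus optional ground truth."""

    breaths: pd.DataFrame
    standing: pd.DataFrame
    trials: pd.DataFrame
    truth: Optional[dict] = None


def study_to_frames(study: SyntheticStudy) -> StudyData:
    """Flatten a generated study into the documented long-format tables."""
    breath_rows, standing_rows, trial_rows = [], [], []
    truth: dict = {"seed": study.seed, "config": dataclasses.asdict(study.config), "participants": {}}
    for p in study.participants:
        pid = p.truth.participant_id
        for t, y in zip(p.standing_breaths.t, p.standing_breaths.y):
            standing_rows.append({"participant_id": pid, "t_seconds": t, "power_w_per_kg": y})
        true_nets = {}
        for tr in p.trials:
            for t, y in zip(tr.breaths.t, tr.breaths.y):
                breath_rows.append(
                    {"participant_id": pid, "block": tr.block, "trial": tr.trial,
                     "t_seconds": t, "power_w_per_kg": y}
                )
            trial_rows.append(
                {"participant_id": pid, "block": tr.block, "trial": tr.trial,
                 "onset": tr.profile.onset, "magnitude_A": tr.profile.magnitude,
                 "duration": tr.profile.duration,
                 "response": tr.response if tr.response is not None else pd.NA}
            )
            true_nets[f"{tr.block}/{tr.trial}"] = tr.true_net_w_per_kg
        truth["participants"][pid] = {
            "jnd_percent": p.truth.jnd_percent,
            "lapse": p.truth.lapse,
            "standing_w_per_kg": p.truth.standing_w_per_kg,
            "tau_seconds": p.truth.tau_seconds,
            "surrogate_shift": p.truth.surrogate_shift,
            "surrogate_scale": p.truth.surrogate_scale,
            "true_net_w_per_kg": true_nets,
        }
    return StudyData(
        breaths=pd.DataFrame(breath_rows, columns=BREATH_COLUMNS),
        standing=pd.DataFrame(standing_rows, columns=STANDING_COLUMNS),
        trials=pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS),
        truth=truth,
    )


def write_study(study: SyntheticStudy | StudyData, outdir: str | Path) -> Path:
    """Write breaths.csv, standing.csv, trials.csv and truth.json to ``outdir``."""
    data = study_to_frames(study) if isinstance(study, SyntheticStudy) else study
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.breaths.to_csv(outdir / "breaths.csv", index=False)
    data.standing.to_csv(outdir / "standing.csv", index=False)
    data.trials.to_csv(outdir / "trials.csv", index=False)
    if data.truth is not None:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(data.truth, fh, indent=1, sort_keys=True)
    return outdir


def _check_numeric(df: pd.DataFrame, columns: list[str], fname: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{fname}: non-numeric value in column '{col}' at line {row}")
        df[col] = coerced
    return df


def _require_columns(df: pd.DataFrame, columns: list[str], fname: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{fname}: missing columns {missing}")


def read_study(indir: str | Path) -> StudyData:
    """Read and validate a study directory written by :func:`write_study`.

    Malformed rows raise ValueError naming the file, column and line number.
    Real data exported to the same schema loads identically (truth.json is
    optional).
    """
    indir = Path(indir)
    breaths = pd.read_csv(indir / "breaths.csv")
    _require_columns(breaths, BREATH_COLUMNS, "breaths.csv")
    breaths = _check_numeric(breaths, ["block", "trial", "t_seconds", "power_w_per_kg"], "breaths.csv")

    standing = pd.read_csv(indir / "standing.csv")
    _require_columns(standing, STANDING_COLUMNS, "standing.csv")
    standing = _check_numeric(standing, ["t_seconds", "power_w_per_kg"], "standing.csv")

    trials = pd.read_csv(indir / "trials.csv")
    _require_columns(trials, TRIAL_COLUMNS, "trials.csv")
    trials = _check_numeric(trials, ["block", "trial", "onset", "magnitude_A", "duration", "response"], "trials.csv")

    dup = trials.duplicated(subset=["participant_id", "block", "trial"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ValueError(f"trials.csv: duplicate (participant, block, trial) key at line {row}")

    # every non-first trial of a block needs a response
    for (pid, block), grp in trials.groupby(["participant_id", "block"]):
        grp = grp.sort_values("trial")
        missing = grp["response"].isna()
        missing.iloc[0] = False
        if missing.any():
            idx = missing.idxmax()
            raise ValueError(
                f"trials.csv: missing value in column 'response' at line {int(idx) + 2} "
                f"(participant {pid}, block {block}, trial {int(grp.loc[idx, 'trial'])})"
            )

    truth = None
    truth_path = indir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return StudyData(breaths=breaths, standing=standing, trials=trials, truth=truth)


def _fit_seed(seed: int, model_index: int, participant_index: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(model_index, participant_index))
    return int(ss.generate_state(1)[0] % (2**31))


def _summary_dict(s) -> dict:
    return {
        "point_estimate": s.point_estimate,
        "ci95": list(s.ci95),
        "diagnostics": s.diagnostics,
        "prior": {"lower": s.prior.lower, "upper": s.prior.upper, "floor": s.prior.floor},
    }


def run_pipeline(config: RunConfig, outdir: str | Path, study: StudyData | None = None) -> dict:
    """Execute simulate (or ingest) -> metabolics -> fit -> compare -> report.

    When ``study`` is None a synthetic study is generated from
    ``config.study`` and ``config.seed``. Returns the results dict that is
    also written to ``results.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if study is None:
        study = study_to_frames(generate_study(config.study, config.seed))
        write_study(study, outdir)

    # metabolics stage
    rates = metabolics.estimate_net_rates(study.breaths, study.standing)
    trials = study.trials.merge(rates, on=["participant_id", "block", "trial"], validate="one_to_one")
    comparisons, n_dropped = metabolics.build_comparisons(trials)
    comparisons.to_csv(outdir / "comparisons.csv", index=False)

    # canonical response order for WAIC alignment
    comparisons = comparisons.sort_values(["participant_id", "block", "pair_index"]).reset_index(drop=True)
    n_total = len(comparisons)
    pids = sorted(comparisons["participant_id"].unique())

    posterior_dir = outdir / "posteriors"
    posterior_dir.mkdir(exist_ok=True)

    def save_draws(name: str, draws: np.ndarray) -> None:
        pd.DataFrame({"jnd_percent": draws}).to_csv(posterior_dir / f"{name}.csv", index=False)

    results: dict = {
        "config": config.to_dict(),
        "seed": config.seed,
        "n_comparisons": n_total,
        "n_dropped_pairs": n_dropped,
        "participants": {},
    }

    ind_blocks, var_blocks = [], []
    for pi, pid in enumerate(pids):
        mask = (comparisons["participant_id"] == pid).to_numpy()
        sub = comparisons.loc[mask]
        idx = np.flatnonzero(mask)
        x = sub["x_percent"].to_numpy(float)
        r = sub["response"].to_numpy(float)

        ind = fit_independent(sub, config.prior, config.mcmc, _fit_seed(config.seed, 0, pi),
                              config.gamma, config.lapse)
        save_draws(f"{pid}_independent", ind.draws)
        ind_blocks.append((ind.draws, x, r, idx))

        var = fit_variable_wf(sub, config.prior, config.mcmc, _fit_seed(config.seed, 2, pi),
                              config.gamma, config.lapse)
        save_draws(f"{pid}_variable_low", var.low.draws)
        save_draws(f"{pid}_variable_high", var.high.draws)
        var_blocks.append((var.low.draws, x[~var.is_high], r[~var.is_high], idx[~var.is_high]))
        var_blocks.append((var.high.draws, x[var.is_high], r[var.is_high], idx[var.is_high]))

        results["participants"][pid] = {
            "independent": _summary_dict(ind),
            "variable_wf": {
                "low": _summary_dict(var.low),
                "high": _summary_dict(var.high),
                "split_w_per_kg": var.split_value,
            },
        }

    pooled = fit_pooled(comparisons, config.prior, config.pooled_mcmc,
                        _fit_seed(config.seed, 1, 0), config.gamma, config.lapse)
    save_draws("pooled", pooled.draws)
    results["pooled"] = _summary_dict(pooled)

    all_x = comparisons["x_percent"].to_numpy(float)
    all_r = comparisons["response"].to_numpy(float)
    waics = {
        "independent": cohort_waic(n_total, ind_blocks, config.gamma, config.lapse),
        "pooled": cohort_waic(n_total, [(pooled.draws, all_x, all_r, np.arange(n_total))],
                              config.gamma, config.lapse),
        "variable_wf": cohort_waic(n_total, var_blocks, config.gamma, config.lapse),
    }
    table = compare_models(waics)
    results["waic"] = table.to_dict(orient="records")

    # cohort report over independent point estimates
    estimates = [results["participants"][pid]["independent"]["point_estimate"] for pid in pids]
    if len(estimates) >= 2:
        summary = analysis.summarize_cohort(estimates)
        results["cohort"] = dataclasses.asdict(summary)
        if len(estimates) >= 5 and summary.sd_jnd > 0:
            ks = analysis.ks_normality(estimates)
            results["cohort"]["ks_normality"] = dataclasses.asdict(ks)
        results["cohort"]["perceive_probability"] = {
            str(d): analysis.perceive_probability(summary.mean_jnd, d) for d in config.deltas
        }

    write_results(results, outdir)
    return results


def write_results(results: dict, outdir: str | Path) -> Path:
    path = Path(outdir) / "results.json"
    with open(path, "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=float)
    return path


def read_results(indir: str | Path) -> dict:
    with open(Path(indir) / "results.json") as fh:
        return json.load(fh)
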