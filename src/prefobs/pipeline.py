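"""End-to-end orchestration of the synthetic study, plus generic statistics
helpers (rank correlation, repeated-measures power).

``run_full_synthetic_study`` chains every stage: design generation ->
dictator simulation -> preference fitting -> informative-trial selection ->
observer sessions -> RL and Bayes-optimal forward simulation -> summary
tables.  Every stage draws from seeds spawned off one master seed, so a
given (config, seed) pair fully determines all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import accuracy, empirical_chance_level
from .synthetic import (
    StudyConfig,
    build_observer_sessions,
    generate_dictator_dataset,
    make_design,
    sample_dictators,
    select_for_dictator,
    simulate_observer_cohort,
)

logger = logging.getLogger("prefobs")

__all__ = [
    "rank_correlation",
    "rm_anova_power",
    "power_rm_anova",
    "StudyResultTables",
    "run_full_synthetic_study",
]


def rank_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def rm_anova_power(
    n: int,
    effect_f: float,
    n_measurements: int,
    alpha: float = 0.05,
    corr_among_measures: float = 0.5,
    nonsphericity: float = 1.0,
) -> float:
    """Analytic power of a one-group repeated-measures ANOVA (within
    factor), under the G*Power convention: noncentrality
    ``lambda = f**2 * n * m / (1 - rho)`` with degrees of freedom
    ``(m - 1) * eps`` and ``(n - 1) * (m - 1) * eps``."""
    m = n_measurements
    eps = nonsphericity
    lam = effect_f**2 * n * m / (1.0 - corr_among_measures)
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    crit = stats.f.ppf(1.0 - alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def power_rm_anova(
    effect_f: float,
    n_measurements: int,
    alpha: float = 0.05,
    power_target: float = 0.9,
    corr_among_measures: float = 0.5,
    nonsphericity: float = 1.0,
    n_max: int = 10**6,
) -> int:
    """Smallest sample size whose analytic repeated-measures power reaches
    the target."""
    if effect_f <= 0 or not 0 < power_target < 1:
        raise ValueError("effect_f must be > 0 and power_target in (0, 1)")
    for n in range(2, n_max + 1):
        if (
            rm_anova_power(
                n, effect_f, n_measurements, alpha, corr_among_measures, nonsphericity
            )
            >= power_target
        ):
            return n
    raise ValueError(f"power {power_target} unreachable within n <= {n_max}")


@dataclass
class StudyResultTables:
    """Output bundle of a full synthetic study."""

    learning_curves: pd.DataFrame  # condition x slot mean accuracy +/- SE (RL cohort)
    recovery_table: pd.DataFrame  # per dictator: true vs fitted preferences
    chance_level: float
    model_comparison: pd.DataFrame  # RL vs BO estimate-vs-truth metrics
    seed: int
    config_hash: str

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.learning_curves.to_csv(out / "learning_curves.csv", index=False)
        self.recovery_table.to_csv(out / "recovery_table.csv", index=False)
        self.model_comparison.to_csv(out / "model_comparison.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "chance_level": self.chance_level,
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                },
                indent=2,
            )
        )


def _config_hash(config: StudyConfig, seed: int) -> str:
    payload = json.dumps({**asdict(config), "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _learning_curves(cohort: pd.DataFrame) -> pd.DataFrame:
    est = cohort[cohort["kind"] == "estimate"].copy()
    est["accuracy"] = [
        accuracy(v, t) for v, t in zip(est["value"], est["true_preference"])
    ]
    grouped = est.groupby(["condition", "index"])["accuracy"]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(
        columns={"index": "slot", "mean": "mean_accuracy", "sem": "se_accuracy", "count": "n"}
    )


def run_full_synthetic_study(
    config: StudyConfig | None = None,
    seed: int = 0,
    *,
    n_fit_starts: int = 8,
    order_budget: int = 50,
    bo_resolution: int | dict = 15,
    rl_params=None,
    out_dir=None,
) -> StudyResultTables:
    """Generate, select, observe, simulate, and summarise one synthetic
    study end to end.  Fully deterministic given (config, seed)."""
    from .choice import ChoicePreferenceSoftmax
    from .ddm import RTPreferenceDDM

    config = config or StudyConfig()
    master = np.random.SeedSequence(seed)
    (s_design, s_dict, s_data, s_select, s_sessions, s_rl) = master.spawn(6)

    logger.info("stage=design seed=%s", s_design.entropy)
    design = make_design(config, np.random.default_rng(s_design))
    dictators = sample_dictators(config, np.random.default_rng(s_dict))
    logger.info("stage=dictators n=%d trials=%d", len(dictators), len(design))

    data_rng = np.random.default_rng(s_data)
    datasets = {
        d.dictator_id: generate_dictator_dataset(d, design, data_rng) for d in dictators
    }

    # per-dictator preference fits (joint choice+RT for selection; RT-only
    # and choice-only for the recovery table)
    recovery_rows = []
    fitted_joint = {}
    for i, d in enumerate(dictators):
        df = datasets[d.dictator_id]
        fit_seed = 10_000 + i
        joint = RTPreferenceDDM(mode="joint", n_starts=n_fit_starts, random_state=fit_seed).fit(df)
        rt_only = RTPreferenceDDM(mode="rt", n_starts=n_fit_starts, random_state=fit_seed).fit(df)
        choice_only = ChoicePreferenceSoftmax(n_starts=n_fit_starts, random_state=fit_seed).fit(df)
        fitted_joint[d.dictator_id] = joint.preference_
        recovery_rows.append(
            {
                "dictator_id": d.dictator_id,
                "true_preference": d.preference,
                "fitted_joint": joint.preference_,
                "fitted_rt_only": rt_only.preference_,
                "fitted_choice_only": choice_only.preference_,
                "loglik_joint": joint.loglik_,
                "loglik_rt_only": rt_only.loglik_,
                "loglik_choice_only": choice_only.loglik_,
            }
        )
        logger.info(
            "stage=fit dictator=%s true=%.3f joint=%.3f rt=%.3f choice=%.3f",
            d.dictator_id,
            d.preference,
            joint.preference_,
            rt_only.preference_,
            choice_only.preference_,
        )
    recovery = pd.DataFrame(recovery_rows)

    select_rng = np.random.default_rng(s_select)
    selections = {
        d.dictator_id: select_for_dictator(
            datasets[d.dictator_id],
            fitted_joint[d.dictator_id],
            order_budget=order_budget,
            seed=int(select_rng.integers(2**31)),
        )
        for d in dictators
    }

    sessions = build_observer_sessions(
        selections, dictators, config, np.random.default_rng(s_sessions)
    )
    logger.info("stage=sessions n=%d", len(sessions))

    rl_cohort = simulate_observer_cohort(
        sessions, agent="rl", params=rl_params, rng=np.random.default_rng(s_rl)
    )
    learning = _learning_curves(rl_cohort)

    bo_cohort = simulate_observer_cohort(sessions, agent="bo", bo_resolution=bo_resolution)

    chance = empirical_chance_level(
        [d.preference for d in dictators], n_samples=10_000, seed=seed
    )

    comparison = _model_comparison(rl_cohort, bo_cohort)
    tables = StudyResultTables(
        learning_curves=learning,
        recovery_table=recovery,
        chance_level=chance,
        model_comparison=comparison,
        seed=seed,
        config_hash=_config_hash(config, seed),
    )
    if out_dir is not None:
        tables.write(out_dir)
    return tables


def _model_comparison(rl_cohort: pd.DataFrame, bo_cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for model, cohort in (("rl", rl_cohort), ("bo", bo_cohort)):
        est = cohort[cohort["kind"] == "estimate"]
        final = est[est["index"] == est["index"].max()]
        per_dict = final.groupby(["condition", "dictator_id"]).agg(
            estimate=("value", "mean"), truth=("true_preference", "first")
        )
        for cond, sub in per_dict.groupby(level="condition"):
            err = sub["estimate"] - sub["truth"]
            try:
                corr = rank_correlation(sub["estimate"], sub["truth"])
            except ValueError:  # too few dictators or constant estimates
                corr = np.nan
            rows.append(
                {
                    "model": model,
                    "condition": cond,
                    "rmse": float(np.sqrt((err**2).mean())),
                    "correlation": corr,
                    "n_dictators": len(sub),
                }
            )
    return pd.DataFrame(rows)
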