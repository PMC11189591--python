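"""CSV interchange: schema-validated readers and writers.

All tables are plain UTF-8 CSV with a mandatory header row and a schema
version recorded in a leading comment line (``# prefobs-schema: <name> v1``).
Column order is irrelevant on read; schema violations are reported with the
offending row numbers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SCHEMAS",
    "write_table",
    "read_table",
    "SchemaError",
    "sessions_to_table",
    "table_to_sessions",
]

_CONDITIONS = {"none", "rt_only", "choice_only", "both"}
_SIDES = {"left", "right"}


class SchemaError(ValueError):
    """A CSV table violated its declared schema."""


def _check_unit_col(df, col):
    vals = df[col].astype(float)
    bad = df.index[(vals < 0) | (vals > 1) | vals.isna()].tolist()
    return [(r, f"{col} must lie in [0, 1]") for r in bad]


def _check_positive(df, col, allow_na=False):
    vals = pd.to_numeric(df[col], errors="coerce")
    mask = vals <= 0
    if not allow_na:
        mask |= vals.isna()
    else:
        mask &= vals.notna()
    return [(r, f"{col} must be positive") for r in df.index[mask].tolist()]


def _check_member(df, col, allowed, allow_na=False):
    vals = df[col]
    mask = ~vals.isin(allowed)
    if allow_na:
        mask &= vals.notna()
    return [(r, f"{col} must be one of {sorted(allowed)}") for r in df.index[mask].tolist()]


SCHEMAS = {
    "dictator_trials": {
        "columns": ["dictator_id", "trial", "left", "right", "choice", "rt"],
        "checks": lambda df: (
            _check_unit_col(df, "left")
            + _check_unit_col(df, "right")
            + _check_member(df, "choice", _SIDES)
            + _check_positive(df, "rt")
        ),
    },
    "selection_manifest": {
        "columns": ["dictator_id", "trial", "category", "role", "order_index"],
        "checks": lambda df: (
            _check_member(df, "category", {"fast", "slow", "uninformative"})
            + _check_member(df, "role", {"observation", "prediction"})
        ),
    },
    "observer_sessions": {
        "columns": [
            "observer_id",
            "dictator_id",
            "condition",
            "kind",
            "slot_or_trial",
            "left",
            "right",
            "choice_shown",
            "rt_shown",
            "estimate",
            "prediction",
            "prediction_rt",
        ],
        "checks": lambda df: (
            _check_member(df, "condition", _CONDITIONS)
            + _check_member(df, "kind", {"observation", "estimation", "prediction"})
            + _check_member(df, "choice_shown", _SIDES, allow_na=True)
            + _check_positive(df, "rt_shown", allow_na=True)
        ),
    },
    "fits": {
        "columns": ["entity_id", "model", "param", "value", "nll"],
        "checks": lambda df: [],
    },
}


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a schema-conformant CSV with a version comment line."""
    spec = SCHEMAS[schema]
    missing = set(spec["columns"]) - set(df.columns)
    if missing:
        raise SchemaError(f"{schema}: missing columns {sorted(missing)}")
    _raise_on_violations(df[spec["columns"]], spec, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# prefobs-schema: {schema} v1\n")
        df[spec["columns"]].to_csv(fh, index=False)


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema."""
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, comment="#")
    missing = set(spec["columns"]) - set(df.columns)
    if missing:
        raise SchemaError(f"{schema}: missing columns {sorted(missing)} in {path}")
    df = df[spec["columns"]]
    _raise_on_violations(df, spec, schema)
    return df


def sessions_to_table(sessions) -> pd.DataFrame:
    """Flatten :class:`~prefobs.core.ObserverSession` objects into the
    ``observer_sessions`` schema (one row per observation, estimation slot,
    and prediction trial)."""
    rows = []
    for s in sessions:
        base = {
            "observer_id": s.observer_id,
            "dictator_id": s.dictator_id,
            "condition": s.condition.value,
        }
        for k, obs in enumerate(s.observations):
            rows.append(
                {
                    **base,
                    "kind": "observation",
                    "slot_or_trial": k,
                    "left": obs.pair.left,
                    "right": obs.pair.right,
                    "choice_shown": obs.choice,
                    "rt_shown": obs.rt,
                    "estimate": np.nan,
                    "prediction": None,
                    "prediction_rt": np.nan,
                }
            )
        reported = s.reported_estimates or [np.nan] * len(s.estimation_slots)
        for slot, est in zip(s.estimation_slots, reported):
            rows.append(
                {
                    **base,
                    "kind": "estimation",
                    "slot_or_trial": slot,
                    "left": np.nan,
                    "right": np.nan,
                    "choice_shown": None,
                    "rt_shown": np.nan,
                    "estimate": est,
                    "prediction": None,
                    "prediction_rt": np.nan,
                }
            )
        preds = s.predicted_choices or [None] * len(s.prediction_pairs)
        pred_rts = s.prediction_rts or [np.nan] * len(s.prediction_pairs)
        for i, pair in enumerate(s.prediction_pairs):
            rows.append(
                {
                    **base,
                    "kind": "prediction",
                    "slot_or_trial": i,
                    "left": pair.left,
                    "right": pair.right,
                    "choice_shown": None,
                    "rt_shown": np.nan,
                    "estimate": np.nan,
                    "prediction": preds[i],
                    "prediction_rt": pred_rts[i],
                }
            )
    return pd.DataFrame(rows, columns=SCHEMAS["observer_sessions"]["columns"])


def table_to_sessions(df: pd.DataFrame):
    """Rebuild :class:`~prefobs.core.ObserverSession` objects from an
    ``observer_sessions`` table."""
    from .core import AllocationPair, Condition, Observation, ObserverSession

    sessions = []
    for (obs_id, d_id), sub in df.groupby(["observer_id", "dictator_id"], sort=False):
        cond = Condition(sub["condition"].iloc[0])
        obs_rows = sub[sub["kind"] == "observation"].sort_values("slot_or_trial")
        observations = [
            Observation(
                pair=AllocationPair(left=r.left, right=r.right, trial_index=int(r.slot_or_trial)),
                condition=cond,
                choice=r.choice_shown if isinstance(r.choice_shown, str) else None,
                rt=r.rt_shown if np.isfinite(r.rt_shown) else None,
            )
            for r in obs_rows.itertuples()
        ]
        est_rows = sub[sub["kind"] == "estimation"].sort_values("slot_or_trial")
        slots = tuple(int(v) for v in est_rows["slot_or_trial"])
        estimates = est_rows["estimate"].tolist()
        reported = None if all(not np.isfinite(e) for e in estimates) else estimates
        pred_rows = sub[sub["kind"] == "prediction"].sort_values("slot_or_trial")
        pairs = [
            AllocationPair(left=r.left, right=r.right, trial_index=int(r.slot_or_trial))
            for r in pred_rows.itertuples()
        ]
        pred_choices = [
            c if isinstance(c, str) else None for c in pred_rows["prediction"]
        ]
        predicted = None if all(c is None for c in pred_choices) else pred_choices
        sessions.append(
            ObserverSession(
                observer_id=str(obs_id),
                dictator_id=str(d_id),
                condition=cond,
                observations=observations,
                estimation_slots=slots,
                prediction_pairs=pairs,
                reported_estimates=reported,
                predicted_choices=predicted,
            )
        )
    return sessions


def _raise_on_violations(df: pd.DataFrame, spec: dict, schema: str) -> None:
    violations = spec["checks"](df)
    if violations:
        detail = "; ".join(f"row {r}: {msg}" for r, msg in violations[:10])
        raise SchemaError(f"{schema}: {len(violations)} invalid row(s) — {detail}")
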