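"""Evaluation battery for fitted value sets.

Predicted-versus-observed summaries, RMSE and mean prediction error,
Bland-Altman agreement statistics, a dominance-based monotonicity audit
over random adjacent state pairs, and the cost-per-QALY arithmetic used
to translate utility differences into funding decisions.

Differences are defined as observed - predicted throughout.  Aggregate
statistics exclude the anchored full-health row by default, since it is
fixed at 1 by construction rather than estimated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lattice import (
    DEFAULT_LATTICE,
    HealthState,
    LatticeSpec,
    dominates,
    neighbors,
    sample_states_without_replacement,
)
from .synthetic import ValuationStudy

log = logging.getLogger(__name__)

__all__ = [
    "PredictionSummary",
    "BlandAltmanStats",
    "summarize",
    "rmse",
    "mean_error",
    "bland_altman",
    "monotonicity_audit",
    "cost_per_qaly",
    "comparison_report",
]

FULL_HEALTH_CODE = "111111"


@dataclass
class PredictionSummary:
    """Per-state observed means joined with model predictions.

    ``frame`` columns: state, observed_mean, n_obs, predicted_mean,
    predicted_sd — the layout of a published posterior-summary table.
    """

    frame: pd.DataFrame

    REQUIRED = ("state", "observed_mean", "n_obs", "predicted_mean", "predicted_sd")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"summary frame lacks columns {missing}")
        self.frame = self.frame.reset_index(drop=True)

    def rows(self, exclude_full_health: bool = True) -> pd.DataFrame:
        f = self.frame
        if exclude_full_health:
            f = f.loc[f["state"] != FULL_HEALTH_CODE]
        return f

    def differences(self, exclude_full_health: bool = True) -> np.ndarray:
        f = self.rows(exclude_full_health)
        return (f["observed_mean"] - f["predicted_mean"]).to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PredictionSummary":
        return cls(pd.read_csv(path, dtype={"state": str}, float_precision="round_trip"))


@dataclass
class BlandAltmanStats:
    """Mean bias and 95% limits of agreement between observed and predicted."""

    mean_bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    loa_length: float


def summarize(
    study: ValuationStudy,
    predictions: pd.DataFrame | Mapping[str, tuple[float, float]],
    *,
    add_full_health: bool = True,
) -> PredictionSummary:
    """Join per-state observed means of non-missing values with predictions.

    ``predictions`` is a frame with columns state/predicted_mean/predicted_sd
    (as produced by :func:`sf6dval.model.predict`) or a mapping
    ``code -> (mean, sd)``.  Design states with zero non-missing
    observations are excluded with a warning.  A conventional full-health
    row (observed 1, predicted 1, SD 0) is prepended unless disabled.
    """
    if isinstance(predictions, Mapping):
        pred = pd.DataFrame(
            {
                "state": list(predictions),
                "predicted_mean": [predictions[k][0] for k in predictions],
                "predicted_sd": [predictions[k][1] for k in predictions],
            }
        )
    else:
        pred = predictions.copy()
    obs = study.observed()
    grouped = obs.groupby("state")["y"].agg(["mean", "count"]).reset_index()
    grouped.columns = ["state", "observed_mean", "n_obs"]
    empty = {s.code for s in study.design_states} - set(grouped["state"])
    if empty:
        log.warning(
            "excluding %d design states with zero non-missing observations", len(empty)
        )
    covered = set(pred["state"])
    lacking = set(grouped["state"]) - covered
    if lacking:
        raise ValueError(f"predictions missing for states {sorted(lacking)[:5]}")
    out = grouped.merge(pred, on="state", how="left")
    if add_full_health and FULL_HEALTH_CODE not in set(out["state"]):
        fh = pd.DataFrame(
            {
                "state": [FULL_HEALTH_CODE],
                "observed_mean": [1.0],
                "n_obs": [0],
                "predicted_mean": [1.0],
                "predicted_sd": [0.0],
            }
        )
        out = pd.concat([fh, out], ignore_index=True)
    return PredictionSummary(out[list(PredictionSummary.REQUIRED)])


def _diffs(summary: PredictionSummary | pd.DataFrame, exclude_full_health: bool) -> np.ndarray:
    if isinstance(summary, pd.DataFrame):
        summary = PredictionSummary(summary)
    return summary.differences(exclude_full_health)


def rmse(summary, exclude_full_health: bool = True) -> float:
    """Root mean squared observed-minus-predicted error over included rows."""
    d = _diffs(summary, exclude_full_health)
    if len(d) == 0:
        raise ValueError("no rows left after exclusion")
    return float(np.sqrt((d**2).mean()))


def mean_error(summary, exclude_full_health: bool = True) -> float:
    """Mean of observed - predicted over included rows (signed bias)."""
    d = _diffs(summary, exclude_full_health)
    if len(d) == 0:
        raise ValueError("no rows left after exclusion")
    return float(d.mean())


def bland_altman(
    summary, exclude_full_health: bool = True, ddof: int = 0
) -> BlandAltmanStats:
    """Bland-Altman agreement statistics for observed vs predicted means.

    ``ddof=0`` (population SD) reproduces the published statistics for the
    reference table; pass ``ddof=1`` for the sample convention.
    """
    d = _diffs(summary, exclude_full_health)
    if len(d) < 2:
        raise ValueError("need at least 2 rows for agreement statistics")
    mb = float(d.mean())
    sd = float(d.std(ddof=ddof))
    return BlandAltmanStats(
        mean_bias=mb,
        sd_diff=sd,
        loa_lower=mb - 1.96 * sd,
        loa_upper=mb + 1.96 * sd,
        loa_length=2 * 1.96 * sd,
    )


def monotonicity_audit(
    predict_fn: Callable[[Sequence[HealthState]], np.ndarray] | Callable[[HealthState], float],
    spec: LatticeSpec = DEFAULT_LATTICE,
    n_states: int = 10_000,
    seed: int | None = None,
    *,
    ties_violate: bool = True,
) -> float:
    """Fraction of random adjacent pairs whose predicted utilities conflict
    with dominance.

    Samples ``n_states`` states without replacement, picks one neighbour of
    each uniformly at random, and counts a pair as non-monotone when the
    dominating (healthier) state's prediction is not strictly above the
    dominated state's (ties count as violations unless ``ties_violate`` is
    False — a value set should strictly separate dominated states).

    ``predict_fn`` may be vectorised (sequence of states -> array) or a
    plain scalar function of one state.
    """
    rng = np.random.default_rng(seed)
    sampled = sample_states_without_replacement(spec, n_states, rng=rng)
    pairs = []
    for s in sampled:
        nbrs = neighbors(s, spec)
        pairs.append((s, nbrs[rng.integers(len(nbrs))]))
    flat: list[HealthState] = [s for pair in pairs for s in pair]
    try:
        vals = np.asarray(predict_fn(flat), dtype=float)
        if vals.shape != (len(flat),):
            raise TypeError
    except (TypeError, AttributeError, ValueError):
        vals = np.array([predict_fn(s) for s in flat], dtype=float)
    bad = 0
    for i, (a, b) in enumerate(pairs):
        ua, ub = vals[2 * i], vals[2 * i + 1]
        better_first = dominates(a, b)  # adjacent pairs are always comparable
        hi, lo = (ua, ub) if better_first else (ub, ua)
        if hi < lo or (ties_violate and hi == lo):
            bad += 1
    return bad / n_states


def cost_per_qaly(cost: float, qaly_gain: float) -> int:
    """Cost divided by QALY gain, rounded to the nearest whole currency unit."""
    if qaly_gain <= 0:
        raise ValueError(f"QALY gain must be positive, got {qaly_gain}")
    return int(round(cost / qaly_gain))


def comparison_report(
    summaries: Mapping[str, PredictionSummary],
    *,
    exclude_full_health: bool = True,
    ddof: int = 0,
) -> dict:
    """Per-model RMSE, mean error and Bland-Altman block, JSON-serialisable."""
    out = {}
    for name, s in summaries.items():
        ba = bland_altman(s, exclude_full_health, ddof=ddof)
        out[name] = {
            "rmse": rmse(s, exclude_full_health),
            "mean_error": mean_error(s, exclude_full_health),
            "bland_altman": asdict(ba),
            "n_states": int(len(s.rows(exclude_full_health))),
        }
    return out


def write_report(report: dict, path_json: str | Path, path_csv: str | Path | None = None) -> None:
    Path(path_json).write_text(json.dumps(report, indent=1))
    if path_csv is not None:
        rows = []
        for name, block in report.items():
            flat = {
                "model": name,
                "rmse": block["rmse"],
                "mean_error": block["mean_error"],
                "n_states": block["n_states"],
                **{f"ba_{k}": v for k, v in block["bland_altman"].items()},
            }
            rows.append(flat)
        pd.DataFrame(rows).to_csv(path_csv, index=False)
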