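"""Synthetic standard-gamble valuation studies.

The surveys this package models are not publicly deposited, so every
stage of the pipeline is exercised against simulated studies generated
here with exactly the statistical structure the inference assumes:

* a latent true utility surface ``u`` over the lattice, anchored at
  ``u(full health) = 1``, built from nonnegative additive per-dimension
  level decrements plus an optional smooth correlated perturbation
  (sampled from the same squared-exponential lattice kernel the model
  uses), so that with zero perturbation the truth is exactly monotone
  with respect to dominance;
* respondents ``j`` with covariate vector ``t_j`` and a multiplicative
  effect ``alpha_j ~ LogNormal(t_j' gamma_alpha, tau^2)``;
* adjusted SG valuations ``y_ij = 1 - alpha_j (1 - u(x_ij)) + eps_ij``
  with ``eps_ij ~ N(0, upsilon^2)``, clamped to [-1, 1] (values worse
  than dead are bounded at -1 in the survey protocol);
* completely-at-random missingness, and a balanced-random allocation of
  design states to respondents.

The default two-country scenario mirrors the published designs: a large
"prior" country with 249 design states valued by 611 respondents (6
states each, 148 missing -> 3,518 observations) and a target country
with 197 states valued by 582 respondents (8 states each, 60 missing ->
4,596 observations).  Country B's truth is country A's with
per-dimension reweighted decrements plus a smooth linear shift, so the
model's additive cross-country correction has the right functional form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lattice import (
    DEFAULT_LATTICE,
    HealthState,
    LatticeSpec,
    levels_array,
    parse_state,
    sample_states_without_replacement,
    state_index,
)

__all__ = [
    "TrueUtility",
    "Respondent",
    "ValuationStudy",
    "default_decrements",
    "make_true_utility",
    "simulate_respondents",
    "simulate_study",
    "make_two_country_scenario",
]


# ---------------------------------------------------------------------------
# true utility surfaces


@dataclass(frozen=True)
class TrueUtility:
    """A full value set: utility for every state of the lattice.

    ``values`` is indexed by the canonical enumeration order of ``spec``.
    ``u(full health) = 1`` exactly; ``meta`` records the generator inputs.
    """

    spec: LatticeSpec
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.spec.n_states,):
            raise ValueError(
                f"values must have length {self.spec.n_states}, got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    def __call__(self, state: HealthState) -> float:
        return float(self.values[state_index(state, self.spec)])

    def at(self, states: Sequence[HealthState]) -> np.ndarray:
        return np.array([self(s) for s in states])

    def to_csv(self, path: str | Path) -> None:
        from .lattice import enumerate_states

        frame = pd.DataFrame(
            {
                "state": [s.code for s in enumerate_states(self.spec)],
                "utility": self.values,
            }
        )
        frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, spec: LatticeSpec = DEFAULT_LATTICE) -> "TrueUtility":
        frame = pd.read_csv(path, dtype={"state": str}, float_precision="round_trip")
        values = np.empty(spec.n_states)
        values[:] = np.nan
        for code, u in zip(frame["state"], frame["utility"]):
            values[state_index(parse_state(code, spec), spec)] = u
        if np.isnan(values).any():
            raise ValueError("utility CSV does not cover the full lattice")
        return cls(spec, values, meta={"source": str(path)})


_SF6D_LIKE_DECREMENTS = (
    (0.0, 0.020, 0.025, 0.060, 0.100, 0.140),  # physical functioning
    (0.0, 0.015, 0.020, 0.060),                # role limitation
    (0.0, 0.030, 0.035, 0.065, 0.100),         # social functioning
    (0.0, 0.020, 0.025, 0.080, 0.130, 0.170),  # bodily pain
    (0.0, 0.025, 0.030, 0.075, 0.120),         # mental health
    (0.0, 0.025, 0.030, 0.055, 0.090),         # vitality
)


def default_decrements(spec: LatticeSpec = DEFAULT_LATTICE) -> list[np.ndarray]:
    """Per-dimension, per-level utility decrements of realistic SF-6D shape.

    Worst-level decrements sum to 0.68, putting the unperturbed pits state
    at 0.32 — the order of magnitude of published SF-6D value sets.  The
    within-dimension profiles include near-flat adjacent levels (published
    value sets often separate middle levels by well under 0.01), so the
    truth is strictly monotone but many adjacent pairs differ only
    slightly — exactly the pairs a noisy value set mis-orders.
    """
    if spec.level_counts == tuple(len(d) for d in _SF6D_LIKE_DECREMENTS):
        return [np.array(d) for d in _SF6D_LIKE_DECREMENTS]
    # other lattice shapes: interpolate each profile onto the level count
    out = []
    for prof, c in zip(_SF6D_LIKE_DECREMENTS, spec.level_counts):
        x = np.linspace(0.0, 1.0, c)
        xp = np.linspace(0.0, 1.0, len(prof))
        out.append(np.interp(x, xp, prof))
    return out


def _kron_gp_sample(
    spec: LatticeSpec, roughness: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One zero-mean unit-variance draw from the squared-exponential lattice
    kernel exp(-sum_d b_d (x_d - x_d')^2).

    The kernel is separable across dimensions, so its Cholesky factor is a
    Kronecker product of six small per-dimension factors; a draw over all
    18,000 states costs a handful of tiny tensor contractions.
    """
    factors = []
    for b, c in zip(roughness, spec.level_counts):
        g = np.arange(1, c + 1, dtype=float)
        k = np.exp(-b * (g[:, None] - g[None, :]) ** 2)
        k[np.diag_indices_from(k)] += 1e-10
        factors.append(np.linalg.cholesky(k))
    z = rng.standard_normal(spec.level_counts)
    for d, L in enumerate(factors):
        z = np.moveaxis(np.tensordot(L, z, axes=(1, d)), 0, d)
    return z.reshape(-1)


def _validate_decrements(
    decrements: Sequence[np.ndarray], spec: LatticeSpec
) -> list[np.ndarray]:
    if len(decrements) != 6:
        raise ValueError("decrements must be one array per dimension")
    decs = []
    for d, (arr, c) in enumerate(zip(decrements, spec.level_counts)):
        a = np.asarray(arr, dtype=float)
        if a.shape != (c,):
            raise ValueError(f"dimension {d + 1} needs {c} decrement values")
        if (a < 0).any() or (np.diff(a) < -1e-12).any():
            raise ValueError(
                f"decrements must be nonnegative and nondecreasing (dimension {d + 1})"
            )
        if a[0] != 0.0:
            raise ValueError(
                f"level-1 decrement must be 0 so that u(full health) = 1 "
                f"(dimension {d + 1} has {a[0]})"
            )
        decs.append(a)
    return decs


def _assemble_truth(
    spec: LatticeSpec,
    decs: list[np.ndarray],
    severity_curvature: float,
    linear_shift: float,
    pert_field: np.ndarray | None,
    floor: float,
) -> np.ndarray:
    """1 - h(total decrement) - shift * severity + perturbation, floor-rescaled.

    ``h(t) = t (1 + kappa t / t_max) / (1 + kappa)`` bends the additive
    decrement total while fixing h(0) = 0 and h(t_max) = t_max, so the
    surface stays monotone and anchored but is no longer additive across
    dimensions (utility loss accelerates with overall severity).
    """
    D = sum(np.meshgrid(*decs, indexing="ij")).reshape(-1)
    tmax = D.max()
    k = severity_curvature
    if k > 0 and tmax > 0:
        D = D * (1.0 + k * D / tmax) / (1.0 + k)
    u = 1.0 - D
    if linear_shift:
        lv = levels_array(_enumerated(spec))
        counts = np.array(spec.level_counts, float)
        severity = ((lv - 1) / np.maximum(counts - 1, 1)).mean(axis=1)
        u = u - linear_shift * severity
    if pert_field is not None:
        u = u + pert_field
    umin = u.min()
    if umin < floor:
        u = 1.0 - (1.0 - u) * (1.0 - floor) / (1.0 - umin)
    return u


def make_true_utility(
    spec: LatticeSpec = DEFAULT_LATTICE,
    decrements: Sequence[np.ndarray] | None = None,
    perturbation_scale: float = 0.03,
    floor: float = 0.02,
    seed: int | None = None,
    *,
    roughness: float | Sequence[float] = 0.1,
    severity_curvature: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TrueUtility:
    """Build an anchored true utility surface over the whole lattice.

    ``u(x) = 1 - sum_d decrement_d(level_d) + perturbation(x)``, where the
    perturbation is a smooth correlated lattice field of standard deviation
    ``perturbation_scale`` re-anchored to vanish at full health.  A positive
    ``severity_curvature`` additionally bends the decrement total (see
    :func:`_assemble_truth`): a monotone non-additive interaction whereby
    utility loss accelerates with overall severity, as published value sets
    exhibit; unlike the perturbation it never breaks monotonicity.  If the
    lattice minimum falls below ``floor``, the whole departure from full
    health is rescaled so the minimum equals ``floor`` (anchoring is
    preserved; with zero perturbation, so is monotonicity).
    """
    decs = _validate_decrements(
        default_decrements(spec) if decrements is None else decrements, spec
    )
    if rng is None:
        rng = np.random.default_rng(seed)
    b = np.full(6, roughness, dtype=float) if np.isscalar(roughness) else np.asarray(roughness, float)
    field_ = None
    if perturbation_scale > 0:
        field_ = _kron_gp_sample(spec, b, rng) * perturbation_scale
        field_ = field_ - field_[state_index(spec.full_health, spec)]
    u = _assemble_truth(spec, decs, severity_curvature, 0.0, field_, floor)
    meta = {
        "seed": seed,
        "perturbation_scale": perturbation_scale,
        "floor": floor,
        "roughness": list(map(float, b)),
        "severity_curvature": severity_curvature,
        "decrements": [list(map(float, a)) for a in decs],
    }
    return TrueUtility(spec, u, meta=meta)


# ---------------------------------------------------------------------------
# respondents and studies


@dataclass(frozen=True)
class Respondent:
    """A survey respondent: covariates ``t_j`` (first entry 1) and the latent
    multiplicative effect ``alpha_j > 0``."""

    id: int
    covariates: tuple[float, ...]
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not self.covariates or self.covariates[0] != 1.0:
            raise ValueError("covariates must start with the constant 1")


def simulate_respondents(
    J: int,
    covariate_spec: str = "intercept",
    gamma_alpha: Sequence[float] | None = None,
    tau2: float = 0.04,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> list[Respondent]:
    """Draw ``J`` respondents with ``alpha_j ~ LogNormal(t_j' gamma_alpha, tau2)``.

    ``covariate_spec`` is ``"intercept"`` (t_j = [1]) or ``"intercept+age_sex"``
    (t_j = [1, centered age in decades, sex indicator]).  ``tau2 = 0`` with
    ``gamma_alpha = 0`` degenerates to ``alpha_j = 1`` for all respondents.
    """
    if tau2 < 0:
        raise ValueError(f"tau2 must be nonnegative, got {tau2}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if covariate_spec == "intercept":
        T = np.ones((J, 1))
    elif covariate_spec == "intercept+age_sex":
        age = rng.normal(0.0, 1.5, size=J)  # centered, in decades
        sex = rng.integers(0, 2, size=J).astype(float)
        T = np.column_stack([np.ones(J), age, sex])
    else:
        raise ValueError(f"unknown covariate_spec {covariate_spec!r}")
    g = np.zeros(T.shape[1]) if gamma_alpha is None else np.asarray(gamma_alpha, float)
    if g.shape != (T.shape[1],):
        raise ValueError(
            f"gamma_alpha length {g.shape} does not match covariate_spec "
            f"({T.shape[1]} columns)"
        )
    log_alpha = T @ g + (np.sqrt(tau2) * rng.standard_normal(J) if tau2 > 0 else 0.0)
    return [
        Respondent(j, tuple(T[j]), float(np.exp(np.atleast_1d(log_alpha)[j])))
        for j in range(J)
    ]


@dataclass
class ValuationStudy:
    """Respondent-level adjusted SG valuation records.

    ``records`` has columns ``respondent_id, state, y, missing`` (``y`` is NaN
    where ``missing`` is set); ``respondents`` the generating (or latent)
    respondent list; ``design_states`` the distinct states valued.
    """

    records: pd.DataFrame
    respondents: list[Respondent]
    design_states: list[HealthState]
    name: str = "study"

    def __post_init__(self) -> None:
        design = {s.code for s in self.design_states}
        bad = set(self.records["state"]) - design
        if bad:
            raise ValueError(f"records reference states outside the design: {sorted(bad)[:5]}")

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_observed(self) -> int:
        return int((~self.records["missing"]).sum())

    def observed(self) -> pd.DataFrame:
        return self.records.loc[~self.records["missing"]].reset_index(drop=True)

    def covariate_matrix(self) -> np.ndarray:
        return np.array([r.covariates for r in self.respondents])

    # -- round-trip I/O -----------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        T = self.covariate_matrix()
        p = T.shape[1]
        cols = {f"t{k}": T[:, k] for k in range(p)}
        resp = pd.DataFrame({"respondent_id": [r.id for r in self.respondents], **cols})
        out = self.records.merge(resp, on="respondent_id", how="left")
        out.to_csv(path, index=False, float_format="%.17g")
        side = Path(path).with_suffix(".meta.json")
        side.write_text(
            json.dumps(
                {
                    "name": self.name,
                    "design_states": [s.code for s in self.design_states],
                    "alpha": [r.alpha for r in self.respondents],
                    "respondent_ids": [r.id for r in self.respondents],
                },
                indent=1,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path, spec: LatticeSpec = DEFAULT_LATTICE) -> "ValuationStudy":
        frame = pd.read_csv(path, dtype={"state": str}, float_precision="round_trip")
        side = Path(path).with_suffix(".meta.json")
        meta = json.loads(side.read_text())
        tcols = sorted(c for c in frame.columns if c.startswith("t") and c[1:].isdigit())
        per_resp = frame.drop_duplicates("respondent_id").set_index("respondent_id")
        alphas = dict(zip(meta["respondent_ids"], meta["alpha"]))
        respondents = [
            Respondent(int(rid), tuple(float(per_resp.loc[rid, c]) for c in tcols), alphas[rid])
            for rid in meta["respondent_ids"]
        ]
        records = frame[["respondent_id", "state", "y", "missing"]].copy()
        design = [parse_state(c, spec) for c in meta["design_states"]]
        return cls(records, respondents, design, name=meta["name"])


def simulate_study(
    true_u: TrueUtility,
    respondents: Sequence[Respondent],
    design_states: Sequence[HealthState],
    states_per_respondent: int,
    upsilon2: float = 0.02,
    missing_rate: float = 0.0,
    seed: int | None = None,
    *,
    name: str = "study",
    rng: np.random.Generator | None = None,
) -> ValuationStudy:
    """Simulate one valuation study from the measurement model.

    Each respondent values ``states_per_respondent`` distinct design states
    under a balanced-random allocation (every design state ends up valued by
    approximately equal numbers of respondents).  Values are
    ``y = 1 - alpha_j (1 - u(x)) + N(0, upsilon2)`` clamped to [-1, 1].
    Exactly ``round(missing_rate * n_records)`` records, chosen completely at
    random, are flagged missing (their ``y`` is NaN).
    """
    if not design_states:
        raise ValueError("design_states must be nonempty")
    if states_per_respondent > len(design_states):
        raise ValueError(
            f"states_per_respondent={states_per_respondent} exceeds the "
            f"{len(design_states)} design states"
        )
    if not 0 <= missing_rate < 1:
        raise ValueError(f"missing_rate must be in [0, 1), got {missing_rate}")
    if upsilon2 < 0:
        raise ValueError(f"upsilon2 must be nonnegative, got {upsilon2}")
    if rng is None:
        rng = np.random.default_rng(seed)

    S = len(design_states)
    u_design = true_u.at(design_states)
    counts = np.zeros(S)
    rows_j, rows_s = [], []
    for r in respondents:
        # least-valued states first, random tie-breaks: near-perfect balance
        order = np.argsort(counts + rng.random(S), kind="stable")
        chosen = order[:states_per_respondent]
        counts[chosen] += 1
        rows_j.extend([r.id] * states_per_respondent)
        rows_s.extend(chosen.tolist())
    rows_j = np.array(rows_j)
    rows_s = np.array(rows_s)

    alpha = np.array([r.alpha for r in respondents])
    id_pos = {r.id: k for k, r in enumerate(respondents)}
    a = alpha[[id_pos[j] for j in rows_j]]
    y = 1.0 - a * (1.0 - u_design[rows_s])
    if upsilon2 > 0:
        y = y + np.sqrt(upsilon2) * rng.standard_normal(len(y))
    y = np.clip(y, -1.0, 1.0)

    n = len(y)
    missing = np.zeros(n, dtype=bool)
    n_missing = int(round(missing_rate * n))
    if n_missing:
        missing[rng.choice(n, size=n_missing, replace=False)] = True
    y = np.where(missing, np.nan, y)

    records = pd.DataFrame(
        {
            "respondent_id": rows_j,
            "state": [design_states[s].code for s in rows_s],
            "y": y,
            "missing": missing,
        }
    )
    return ValuationStudy(records, list(respondents), list(design_states), name=name)


# ---------------------------------------------------------------------------
# two-country scenarios


def make_two_country_scenario(
    seed: int,
    shift: float = 0.05,
    dimension_reweights: Sequence[float] = (1.3, 1.1, 1.2, 1.25, 1.15, 1.2),
    *,
    spec: LatticeSpec = DEFAULT_LATTICE,
    n_states_a: int = 249,
    n_respondents_a: int = 611,
    states_per_respondent_a: int = 6,
    missing_a: int = 148,
    n_states_b: int = 197,
    n_respondents_b: int = 582,
    states_per_respondent_b: int = 8,
    missing_b: int = 60,
    perturbation_scale: float = 0.02,
    severity_curvature: float = 1.0,
    tau2: float = 0.04,
    upsilon2: float = 0.02,
    covariate_spec: str = "intercept",
    shared_design: bool = True,
) -> tuple[TrueUtility, TrueUtility, ValuationStudy, ValuationStudy]:
    """A large prior-country study (A) and a target-country study (B).

    The defaults reproduce the published survey designs (A: 249 states x 611
    respondents x 6 values with 148 missing; B: 197 x 582 x 8 with 60
    missing); pass smaller values for quick experiments.  B's truth is A's
    with per-dimension decrement reweighting plus a smooth linear downward
    shift of magnitude ``shift`` (zero at full health, full at the pits), so
    with ``shift = 0`` and unit reweights the two truths are identical.
    With ``shared_design`` (the default) country B re-values a random subset
    of country A's design states, emulating a target-country survey that
    selects its states from the established design — the setting in which a
    carried-over posterior is informative exactly where the new study
    measures.  All randomness descends deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_resp_a, s_study_a, s_resp_b, s_study_b, s_design = ss.spawn(6)
    rng_truth = np.random.default_rng(s_truth)
    floor = 0.02

    decs_a = default_decrements(spec)
    field = None
    if perturbation_scale > 0:
        field = _kron_gp_sample(spec, np.full(6, 0.1), rng_truth) * perturbation_scale
        field = field - field[state_index(spec.full_health, spec)]
    truth_a = TrueUtility(
        spec,
        _assemble_truth(spec, decs_a, severity_curvature, 0.0, field, floor),
        meta={
            "seed": seed,
            "perturbation_scale": perturbation_scale,
            "severity_curvature": severity_curvature,
            "floor": floor,
        },
    )

    # B: reweighted decrements + linear downward shift, same smooth
    # perturbation and curvature — the systematic part of the cross-country
    # difference is exactly an offset-plus-linear correction.
    w = np.asarray(dimension_reweights, float)
    decs_b = [wd * a for wd, a in zip(w, decs_a)]
    truth_b = TrueUtility(
        spec,
        _assemble_truth(spec, decs_b, severity_curvature, shift, field, floor),
        meta={
            "seed": seed,
            "shift": shift,
            "dimension_reweights": list(map(float, w)),
            "severity_curvature": severity_curvature,
            "derived_from": "A",
        },
    )

    rng_design = np.random.default_rng(s_design)
    design_a = sample_states_without_replacement(
        spec, n_states_a, rng=rng_design, exclude=[spec.full_health]
    )
    if shared_design and n_states_b <= n_states_a:
        pick = rng_design.choice(n_states_a, size=n_states_b, replace=False)
        design_b = [design_a[i] for i in sorted(pick)]
    else:
        design_b = sample_states_without_replacement(
            spec, n_states_b, rng=rng_design, exclude=[spec.full_health]
        )

    resp_a = simulate_respondents(
        n_respondents_a, covariate_spec, tau2=tau2, rng=np.random.default_rng(s_resp_a)
    )
    resp_b = simulate_respondents(
        n_respondents_b, covariate_spec, tau2=tau2, rng=np.random.default_rng(s_resp_b)
    )
    study_a = simulate_study(
        truth_a,
        resp_a,
        design_a,
        states_per_respondent_a,
        upsilon2=upsilon2,
        missing_rate=missing_a / (n_respondents_a * states_per_respondent_a),
        rng=np.random.default_rng(s_study_a),
        name="country_a",
    )
    study_b = simulate_study(
        truth_b,
        resp_b,
        design_b,
        states_per_respondent_b,
        upsilon2=upsilon2,
        missing_rate=missing_b / (n_respondents_b * states_per_respondent_b),
        rng=np.random.default_rng(s_study_b),
        name="country_b",
    )
    return truth_a, truth_b, study_a, study_b


def _enumerated(spec: LatticeSpec):
    from .lattice import enumerate_states

    return enumerate_states(spec)
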