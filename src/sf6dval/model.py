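"""Nonparametric Bayesian valuation model with cross-country transfer.

The measurement model for respondent ``j``'s adjusted standard-gamble
valuation of health state ``x_ij`` is

    y_ij = 1 - alpha_j (1 - u(x_ij)) + eps_ij,      eps_ij ~ N(0, upsilon^2),
    alpha_j ~ LogNormal(t_j' gamma_alpha, tau^2),

so each respondent stretches or compresses their distance from full
health by a multiplicative factor.  The utility function ``u`` over the
lattice carries a multivariate-normal prior:

* standalone mode:   E u(x) = 1 + gamma0 + beta' z(x),
                     cov    = sigma^2 c(x, x'),
* transfer mode:     E u(x) = E u_base(x) + gamma0 + beta' z(x),
                     cov    = cov_base(x, x') + sigma^2 c(x, x'),

with ``z(x) = levels(x) - 1`` (so full health contributes nothing to the
linear term), the squared-exponential lattice kernel
``c(x, x') = exp(-sum_d b_d (x_d - x_d')^2)``, and in transfer mode the
``base`` being another country's fitted posterior (mean vector plus
covariance matrix), carried over via :func:`posterior_as_prior`.  The
prior is conditioned exactly on ``u(full health) = 1`` — an anchor, not
a penalty — which together with centering the prior median of the
respondent effects at 1 resolves the multiplicative scale confounding.

Inference is Metropolis-within-Gibbs: ``u`` by its exact multivariate
normal full conditional (the likelihood is linear-Gaussian in ``u``
given the alphas), each ``alpha_j`` by vectorised random-walk Metropolis
on the log scale, the regression and variance hyperparameters by
conjugate updates, and ``(gamma0, beta)`` and ``log sigma^2`` (and
optionally the log roughnesses) from their *collapsed* conditionals with
``u`` integrated out of the likelihood — given the alphas the records
collapse to state-level weighted means that are Gaussian around the
prior mean with covariance ``V_c + diag(1/precision)``, so the
collapsed updates cost one small Cholesky each.  Updating the
covariance parameters against the latent ``u`` instead would trap the
chain: the field's own posterior noise masquerades as prior variance and
``sigma^2`` never learns how close the new country is to the base.
``u`` is redrawn from its full conditional immediately afterwards, which
keeps the block update exact.  Proposal scales are tuned during burn-in
toward 20-40% acceptance and frozen afterwards.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from .lattice import (
    DEFAULT_LATTICE,
    HealthState,
    LatticeSpec,
    levels_array,
    parse_state,
)
from .synthetic import ValuationStudy

log = logging.getLogger(__name__)

__all__ = [
    "correlation",
    "correlation_matrix",
    "UtilityPosterior",
    "PriorSpec",
    "ModelParams",
    "MCMCConfig",
    "Hyperpriors",
    "ModelFit",
    "build_prior",
    "log_likelihood",
    "fit",
    "predict",
    "posterior_as_prior",
    "load_prior_from_table",
]


# ---------------------------------------------------------------------------
# kernel


def correlation_matrix(
    levels_a: np.ndarray, levels_b: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """exp(-sum_d b_d (a_d - b_d)^2) for all pairs of level rows."""
    b = np.asarray(b, float)
    if (b < 0).any():
        raise ValueError(f"roughness parameters must be nonnegative, got {b}")
    d2 = (levels_a[:, None, :] - levels_b[None, :, :]) ** 2
    return np.exp(-(d2 * b).sum(axis=2))


def correlation(x: HealthState, x2: HealthState, b: Sequence[float]) -> float:
    """Kernel correlation between two states; 1 iff identical (all b_d > 0)."""
    return float(
        correlation_matrix(levels_array([x]), levels_array([x2]), np.asarray(b, float))[
            0, 0
        ]
    )


# ---------------------------------------------------------------------------
# posterior container


@dataclass
class UtilityPosterior:
    """Posterior (or prior) moments of u at an ordered set of states.

    This is the object one country hands to the next: the mean vector
    ``E u(x)`` and the full covariance ``cov(u(x), u(x'))``.
    """

    states: list[HealthState]
    mean: np.ndarray
    cov: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        n = len(self.states)
        if self.mean.shape != (n,) or self.cov.shape != (n, n):
            raise ValueError("mean/cov dimensions do not match the state list")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        lam_min = np.linalg.eigvalsh(self.cov).min() if n else 0.0
        if lam_min < -1e-8:
            raise ValueError(f"covariance is not PSD (min eigenvalue {lam_min:.3g})")

    def index(self) -> dict[str, int]:
        return {s.code: i for i, s in enumerate(self.states)}

    def resolve(
        self, states: Sequence[HealthState], roughness: np.ndarray
    ) -> "UtilityPosterior":
        """Moments at ``states``: exact where stored, kernel-extended elsewhere.

        New states get a universal-kriging extension of this posterior
        under the squared-exponential kernel: a linear trend in the
        (centered) levels, anchored at full health, is fitted to the
        stored means and extended exactly, and the trend residuals are
        kriged with weights ``L = K10 K00^{-1}``; so a state far from
        every stored state reverts to the fitted linear value set rather
        than to full health.  The extended covariance is ``L V0 L' +
        s^2 (K11 - K10 K00^{-1} K01)`` with residual scale ``s^2`` set to
        the mean stored posterior variance.
        """
        idx = self.index()
        missing = [s for s in states if s.code not in idx]
        if not missing:
            sel = [idx[s.code] for s in states]
            return UtilityPosterior(
                list(states), self.mean[sel], self.cov[np.ix_(sel, sel)], dict(self.meta)
            )
        L0 = levels_array(self.states)
        L1 = levels_array(missing)
        K00 = correlation_matrix(L0, L0, roughness)
        K00[np.diag_indices_from(K00)] += 1e-8
        K10 = correlation_matrix(L1, L0, roughness)
        K11 = correlation_matrix(L1, L1, roughness)
        W = np.linalg.solve(K00, K10.T).T
        Z0 = (L0 - 1).astype(float)
        Z1 = (L1 - 1).astype(float)
        trend, *_ = np.linalg.lstsq(Z0, self.mean - 1.0, rcond=None)
        resid0 = self.mean - 1.0 - Z0 @ trend
        m1 = 1.0 + Z1 @ trend + W @ resid0
        s2 = float(np.mean(np.diag(self.cov))) if len(self.states) else 0.0
        schur = K11 - W @ K10.T
        V11 = W @ self.cov @ W.T + s2 * schur
        V10 = W @ self.cov
        # assemble in requested order
        order = list(self.states) + missing
        mean = np.concatenate([self.mean, m1])
        n0 = len(self.states)
        cov = np.zeros((len(order), len(order)))
        cov[:n0, :n0] = self.cov
        cov[n0:, :n0] = V10
        cov[:n0, n0:] = V10.T
        cov[n0:, n0:] = 0.5 * (V11 + V11.T)
        cov = _psd_repair(cov)
        full = UtilityPosterior(order, mean, cov, dict(self.meta))
        return full.resolve(states, roughness)

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"state": [s.code for s in self.states], "mean": self.mean}
        ).to_csv(d / "mean.csv", index=False, float_format="%.17g")
        pd.DataFrame(self.cov, columns=[s.code for s in self.states]).to_csv(
            d / "cov.csv", index=False, float_format="%.17g"
        )
        (d / "meta.json").write_text(json.dumps(self.meta, indent=1, default=str))

    @classmethod
    def load(cls, directory: str | Path, spec: LatticeSpec = DEFAULT_LATTICE) -> "UtilityPosterior":
        d = Path(directory)
        m = pd.read_csv(d / "mean.csv", dtype={"state": str}, float_precision="round_trip")
        cov = pd.read_csv(d / "cov.csv", float_precision="round_trip").to_numpy()
        meta = json.loads((d / "meta.json").read_text())
        states = [parse_state(c, spec) for c in m["state"]]
        return cls(states, m["mean"].to_numpy(), cov, meta)


def _psd_repair(cov: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues at zero and re-symmetrise."""
    cov = 0.5 * (cov + cov.T)
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        clipped = float(-w[w < 0].sum())
        log.warning("PSD repair clipped eigenvalue mass %.3g", clipped)
    w = np.clip(w, tol, None)
    return (v * w) @ v.T


# ---------------------------------------------------------------------------
# specs


@dataclass
class PriorSpec:
    """Prior over u: standalone GP, or a base posterior plus a GP correction."""

    mode: Literal["standalone", "transfer"] = "standalone"
    base: UtilityPosterior | None = None
    gamma0: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(6))
    sigma2: float = math.exp(-3.0)
    roughness: np.ndarray = field(default_factory=lambda: np.full(6, 0.1))

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.roughness = np.asarray(self.roughness, float)
        if self.beta.shape != (6,) or self.roughness.shape != (6,):
            raise ValueError("beta and roughness must be 6-vectors")
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")
        if (self.roughness < 0).any():
            raise ValueError("roughness parameters must be nonnegative")
        if (self.mode == "transfer") != (self.base is not None):
            raise ValueError("base posterior must be supplied iff mode='transfer'")


@dataclass
class ModelParams:
    """One point in the hyperparameter space (used for likelihood evaluation)."""

    gamma_alpha: np.ndarray
    tau2: float
    upsilon2: float
    gamma0: float = 0.0
    beta: np.ndarray = field(default_factory=lambda: np.zeros(6))
    sigma2: float = math.exp(-3.0)

    def __post_init__(self) -> None:
        self.gamma_alpha = np.atleast_1d(np.asarray(self.gamma_alpha, float))
        self.beta = np.asarray(self.beta, float)
        if self.tau2 <= 0 or self.upsilon2 <= 0:
            raise ValueError("tau2 and upsilon2 must be positive")


@dataclass
class Hyperpriors:
    """Weakly informative hyperpriors on the [-1, 1] utility scale."""

    gamma0_sd: float = 1.0
    beta_sd: float = 1.0
    log_sigma2_mean: float = -6.0
    log_sigma2_sd: float = 2.0
    var_shape: float = 2.0  # inverse-gamma for tau2 and upsilon2
    var_rate: float = 0.05
    gamma_alpha_sd: float = 1.0
    gamma_alpha_intercept_sd: float = 0.05  # shrinks prior median of alpha to 1
    log_roughness_mean: float = math.log(0.1)
    log_roughness_sd: float = 0.5


@dataclass
class MCMCConfig:
    iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 5
    seed: int | None = None
    sample_alpha: bool = True
    sample_theta: bool = True  # gamma0 and beta
    sample_sigma2: bool = True
    sample_roughness: bool = False
    fixed_upsilon2: float | None = None
    fixed_tau2: float | None = None
    alpha_proposal: float = 0.15
    sigma2_proposal: float = 0.5
    roughness_proposal: float = 0.2
    adapt: bool = True
    adapt_interval: int = 50
    hyper: Hyperpriors = field(default_factory=Hyperpriors)

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


# ---------------------------------------------------------------------------
# prior assembly


class _PriorWorkspace:
    """Precomputed matrices over F = design states + full health (last row).

    Exposes, for a given sigma^2 (and roughness), the anchored prior
    N(a + W theta, V_c) over the design states, where theta = (gamma0,
    beta) and conditioning on u(full health) = 1 has been carried out
    exactly.
    """

    def __init__(
        self,
        design: list[HealthState],
        prior: PriorSpec,
        lattice: LatticeSpec,
    ) -> None:
        self.design = design
        self.prior = prior
        self.lattice = lattice
        self.F = design + [lattice.full_health]
        self.LF = levels_array(self.F)
        self.Z = (self.LF[:-1] - 1).astype(float)  # design rows, centered levels
        self.n = len(design)
        if prior.mode == "transfer":
            base = prior.base.resolve(self.F, prior.roughness)
            self.b0 = base.mean
            self.B = base.cov
        else:
            self.b0 = np.ones(len(self.F))
            self.B = np.zeros((len(self.F), len(self.F)))
        self._update_kernel(prior.roughness)
        self._cache_sigma2 = None

    def _update_kernel(self, roughness: np.ndarray) -> None:
        self.roughness = np.asarray(roughness, float)
        self.C = correlation_matrix(self.LF, self.LF, self.roughness)
        self._cache_sigma2 = None

    def anchored(self, sigma2: float):
        """(a, W, V_c, cho, V_c^{-1}) for the current kernel and given sigma2."""
        if self._cache_sigma2 == sigma2:
            return self._anchor
        V = self.B + sigma2 * self.C
        vff = V[-1, -1]
        k = V[:-1, -1] / vff
        a = self.b0[:-1] + k * (1.0 - self.b0[-1])
        W = np.column_stack([1.0 - k, self.Z])
        Vc = V[:-1, :-1] - np.outer(k, V[:-1, -1])
        Vc = 0.5 * (Vc + Vc.T)
        Vc[np.diag_indices_from(Vc)] += 1e-10
        try:
            cho = cho_factor(Vc, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic path
            raise np.linalg.LinAlgError(
                f"anchored prior covariance not positive definite (sigma2={sigma2})"
            ) from exc
        Vinv = cho_solve(cho, np.eye(self.n))
        logdet = 2.0 * np.log(np.diag(cho[0])).sum()
        self._anchor = (a, W, Vc, cho, Vinv, logdet)
        self._cache_sigma2 = sigma2
        return self._anchor

    def mvn_logpdf(self, u: np.ndarray, theta: np.ndarray, sigma2: float) -> float:
        a, W, _, cho, _, logdet = self.anchored(sigma2)
        r = u - a - W @ theta
        x = cho_solve(cho, r)
        return -0.5 * (self.n * math.log(2 * math.pi) + logdet + r @ x)


def build_prior(
    states: Sequence[HealthState],
    spec: PriorSpec,
    lattice: LatticeSpec = DEFAULT_LATTICE,
) -> tuple[np.ndarray, np.ndarray]:
    """Anchored prior mean and covariance of u at ``states``.

    Assembles mean = base + gamma0 + beta' z and covariance = base_cov +
    sigma^2 C (base terms zero/one in standalone mode), then conditions
    exactly on u(full health) = 1.  Full-health entries in ``states`` come
    back with mean 1 and zero variance.
    """
    fh = lattice.full_health
    inner = [s for s in states if s != fh]
    ws = _PriorWorkspace(inner, spec, lattice)
    a, W, Vc, *_ = ws.anchored(spec.sigma2)
    theta = np.concatenate([[spec.gamma0], spec.beta])
    mean_inner = a + W @ theta
    # scatter back into the requested order
    n = len(states)
    mean = np.ones(n)
    cov = np.zeros((n, n))
    pos = {s.code: i for i, s in enumerate(inner)}
    sel = [i for i, s in enumerate(states) if s != fh]
    inner_idx = [pos[states[i].code] for i in sel]
    mean[sel] = mean_inner[inner_idx]
    cov[np.ix_(sel, sel)] = Vc[np.ix_(inner_idx, inner_idx)]
    return mean, cov


# ---------------------------------------------------------------------------
# likelihood


def log_likelihood(
    study: ValuationStudy,
    u_at_design: np.ndarray | dict,
    params: ModelParams,
    alphas: np.ndarray | None = None,
) -> float:
    """Joint log density of the observed values and the respondent effects.

    Sum over non-missing records of the Gaussian log density of ``y_ij`` at
    mean ``1 - alpha_j (1 - u(x_ij))``, variance ``upsilon^2``, plus the
    log-normal log density of each ``alpha_j``.  ``u_at_design`` is either a
    vector aligned with ``study.design_states`` or a mapping ``code -> u``.
    """
    if isinstance(u_at_design, dict):
        u = np.array([u_at_design[s.code] for s in study.design_states])
    else:
        u = np.asarray(u_at_design, float)
        if u.shape != (len(study.design_states),):
            raise ValueError(
                "u_at_design must supply one value per design state "
                f"({len(study.design_states)}), got shape {u.shape}"
            )
    obs = study.observed()
    code_pos = {s.code: i for i, s in enumerate(study.design_states)}
    sidx = obs["state"].map(code_pos)
    if sidx.isna().any():
        raise ValueError("observed record on a state with no supplied u value")
    if alphas is None:
        alphas = np.array([r.alpha for r in study.respondents])
    id_pos = {r.id: k for k, r in enumerate(study.respondents)}
    a = alphas[[id_pos[j] for j in obs["respondent_id"]]]
    mu = 1.0 - a * (1.0 - u[sidx.to_numpy(dtype=int)])
    r = obs["y"].to_numpy() - mu
    n = len(r)
    ll = -0.5 * (n * math.log(2 * math.pi * params.upsilon2) + (r**2).sum() / params.upsilon2)
    T = study.covariate_matrix()
    la = np.log(alphas)
    rz = la - T @ params.gamma_alpha
    J = len(alphas)
    ll += -0.5 * (J * math.log(2 * math.pi * params.tau2) + (rz**2).sum() / params.tau2)
    ll += -la.sum()  # log-normal Jacobian
    return float(ll)


# ---------------------------------------------------------------------------
# fit


@dataclass
class ModelFit:
    """Retained MCMC draws plus everything needed to predict from them."""

    states: list[HealthState]
    u: np.ndarray  # (draws, n_states)
    alpha: np.ndarray  # (draws, J)
    gamma_alpha: np.ndarray  # (draws, p)
    tau2: np.ndarray
    upsilon2: np.ndarray
    gamma0: np.ndarray
    beta: np.ndarray  # (draws, 6)
    sigma2: np.ndarray
    roughness: np.ndarray  # (draws, 6); constant rows unless sampled
    prior: PriorSpec
    config: MCMCConfig
    acceptance: dict
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    meta: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.u.shape[0]

    def posterior_mean_u(self) -> np.ndarray:
        return self.u.mean(axis=0)

    def posterior_sd_u(self) -> np.ndarray:
        return self.u.std(axis=0, ddof=1)

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cols = {}
        for i, s in enumerate(self.states):
            cols[f"u_{s.code}"] = self.u[:, i]
        for j in range(self.alpha.shape[1]):
            cols[f"alpha_{j}"] = self.alpha[:, j]
        for k in range(self.gamma_alpha.shape[1]):
            cols[f"gamma_alpha_{k}"] = self.gamma_alpha[:, k]
        cols["tau2"] = self.tau2
        cols["upsilon2"] = self.upsilon2
        cols["gamma0"] = self.gamma0
        for k in range(6):
            cols[f"beta_{k}"] = self.beta[:, k]
        cols["sigma2"] = self.sigma2
        for k in range(6):
            cols[f"b_{k}"] = self.roughness[:, k]
        pd.DataFrame(cols).to_csv(d / "draws.csv", index=False, float_format="%.17g")
        meta = {
            "states": [s.code for s in self.states],
            "acceptance": self.acceptance,
            "meta": self.meta,
            "level_counts": list(self.lattice.level_counts),
            "config": {
                k: v
                for k, v in vars(self.config).items()
                if not isinstance(v, Hyperpriors)
            },
            "hyper": vars(self.config.hyper),
            "prior": {
                "mode": self.prior.mode,
                "gamma0": self.prior.gamma0,
                "beta": self.prior.beta.tolist(),
                "sigma2": self.prior.sigma2,
                "roughness": self.prior.roughness.tolist(),
            },
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1, default=str))
        if self.prior.base is not None:
            self.prior.base.save(d / "base_posterior")

    @classmethod
    def load(cls, directory: str | Path) -> "ModelFit":
        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        lattice = LatticeSpec(tuple(meta["level_counts"]))
        frame = pd.read_csv(d / "draws.csv", float_precision="round_trip")
        states = [parse_state(c, lattice) for c in meta["states"]]
        u = frame[[f"u_{c}" for c in meta["states"]]].to_numpy()
        acols = sorted(
            (c for c in frame.columns if c.startswith("alpha_")),
            key=lambda c: int(c.split("_")[1]),
        )
        gcols = sorted(
            (c for c in frame.columns if c.startswith("gamma_alpha_")),
            key=lambda c: int(c.split("_")[-1]),
        )
        base = None
        if (d / "base_posterior").exists():
            base = UtilityPosterior.load(d / "base_posterior", lattice)
        pmeta = meta["prior"]
        prior = PriorSpec(
            mode=pmeta["mode"],
            base=base,
            gamma0=pmeta["gamma0"],
            beta=np.array(pmeta["beta"]),
            sigma2=pmeta["sigma2"],
            roughness=np.array(pmeta["roughness"]),
        )
        cfg_kwargs = meta["config"]
        cfg = MCMCConfig(**cfg_kwargs, hyper=Hyperpriors(**meta["hyper"]))
        return cls(
            states=states,
            u=u,
            alpha=frame[acols].to_numpy(),
            gamma_alpha=frame[gcols].to_numpy(),
            tau2=frame["tau2"].to_numpy(),
            upsilon2=frame["upsilon2"].to_numpy(),
            gamma0=frame["gamma0"].to_numpy(),
            beta=frame[[f"beta_{k}" for k in range(6)]].to_numpy(),
            sigma2=frame["sigma2"].to_numpy(),
            roughness=frame[[f"b_{k}" for k in range(6)]].to_numpy(),
            prior=prior,
            config=cfg,
            acceptance=meta["acceptance"],
            lattice=lattice,
            meta=meta["meta"],
        )


def fit(
    study: ValuationStudy,
    prior: PriorSpec,
    config: MCMCConfig | None = None,
    lattice: LatticeSpec = DEFAULT_LATTICE,
) -> ModelFit:
    """Run the Metropolis-within-Gibbs sampler on one valuation study.

    Missing records are dropped before fitting.  Full health, if it appears
    among the design states, is held fixed at u = 1 (it is the anchor, not a
    parameter).  Reproducible under ``config.seed``.
    """
    if config is None:
        config = MCMCConfig()
    hp = config.hyper
    rng = np.random.default_rng(config.seed)

    fh = lattice.full_health
    design = [s for s in study.design_states if s != fh]
    if len(design) < 2:
        raise ValueError("need at least 2 non-anchor design states to fit")
    ws = _PriorWorkspace(design, prior, lattice)
    n = ws.n

    obs = study.observed()
    code_pos = {s.code: i for i, s in enumerate(design)}
    sidx = np.array([code_pos.get(c, n) for c in obs["state"]])  # n == full health slot
    y = obs["y"].to_numpy()
    N = len(y)
    id_pos = {r.id: k for k, r in enumerate(study.respondents)}
    jidx = np.array([id_pos[j] for j in obs["respondent_id"]])
    T = study.covariate_matrix()
    J, p = T.shape
    TtT = T.T @ T
    gprior_prec = np.diag(
        [1.0 / hp.gamma_alpha_intercept_sd**2] + [1.0 / hp.gamma_alpha_sd**2] * (p - 1)
    )
    theta_prec = np.diag([1.0 / hp.gamma0_sd**2] + [1.0 / hp.beta_sd**2] * 6)

    # state
    sigma2 = prior.sigma2
    theta = np.concatenate([[prior.gamma0], prior.beta])
    a, W, Vc, cho, Vinv, _ = ws.anchored(sigma2)
    u = np.clip(a + W @ theta, -0.95, 1.0)
    alpha = np.ones(J)
    log_alpha = np.zeros(J)
    gamma_a = np.zeros(p)
    tau2 = config.fixed_tau2 if config.fixed_tau2 is not None else 0.04
    ups2 = config.fixed_upsilon2 if config.fixed_upsilon2 is not None else 0.02
    if not np.isfinite(u).all():
        raise RuntimeError("non-finite prior mean at initialization")

    ufull = np.append(u, 1.0)
    scale_alpha = config.alpha_proposal
    scale_sigma2 = config.sigma2_proposal
    scale_rough = config.roughness_proposal
    acc = {"alpha": 0, "sigma2": 0, "roughness": 0}
    tries = {"alpha": 0, "sigma2": 0, "roughness": 0}
    win = {"alpha": [0, 0], "sigma2": [0, 0], "roughness": [0, 0]}

    D = config.n_draws
    out_u = np.empty((D, n))
    out_alpha = np.empty((D, J))
    out_ga = np.empty((D, p))
    out_tau2 = np.empty(D)
    out_ups2 = np.empty(D)
    out_gamma0 = np.empty(D)
    out_beta = np.empty((D, 6))
    out_sigma2 = np.empty(D)
    out_rough = np.empty((D, 6))
    d_out = 0

    def collapsed_loglik(
        sigma2_val: float, theta_val: np.ndarray, obs: np.ndarray,
        u_hat: np.ndarray, prec: np.ndarray
    ) -> float:
        """log p(state-level means | sigma2, theta, alpha, upsilon2), u integrated out."""
        a_, W_, Vc_, *_ = ws.anchored(sigma2_val)
        M = Vc_[np.ix_(obs, obs)].copy()
        M[np.diag_indices_from(M)] += 1.0 / prec
        r = u_hat - (a_ + W_ @ theta_val)[obs]
        Lm = cholesky(M, lower=True)
        x = solve_triangular(Lm, r, lower=True)
        return -0.5 * (
            len(r) * math.log(2 * math.pi)
            + 2.0 * np.log(np.diag(Lm)).sum()
            + x @ x
        )

    for it in range(config.iterations):
        in_burn = it < config.burn_in

        # --- alpha: vectorised log-scale random walk ----------------------
        if config.sample_alpha:
            dvec = 1.0 - ufull[sidx]
            C1 = np.bincount(jidx, weights=dvec * (y - 1.0), minlength=J)
            C2 = np.bincount(jidx, weights=dvec**2, minlength=J)
            mu_j = T @ gamma_a

            def alpha_logpost(la: np.ndarray) -> np.ndarray:
                av = np.exp(la)
                return (
                    -(av**2 * C2 + 2.0 * av * C1) / (2.0 * ups2)
                    - (la - mu_j) ** 2 / (2.0 * tau2)
                )

            prop = log_alpha + scale_alpha * rng.standard_normal(J)
            delta = alpha_logpost(prop) - alpha_logpost(log_alpha)
            accept = np.log(rng.random(J)) < delta
            log_alpha = np.where(accept, prop, log_alpha)
            alpha = np.exp(log_alpha)
            acc["alpha"] += int(accept.sum())
            tries["alpha"] += J
            win["alpha"][0] += int(accept.sum())
            win["alpha"][1] += J

            # gamma_alpha: conjugate normal regression on log alpha
            prec = gprior_prec + TtT / tau2
            rhs_g = T.T @ log_alpha / tau2
            Lg = cholesky(prec, lower=True)
            mu_g = cho_solve((Lg, True), rhs_g)
            gamma_a = mu_g + solve_triangular(
                Lg, rng.standard_normal(p), lower=True, trans="T"
            )

            # tau2: conjugate inverse-gamma
            if config.fixed_tau2 is None:
                rz = log_alpha - T @ gamma_a
                tau2 = 1.0 / rng.gamma(
                    hp.var_shape + 0.5 * J, 1.0 / (hp.var_rate + 0.5 * (rz**2).sum())
                )

        # --- upsilon2: conjugate inverse-gamma ----------------------------
        resid = y - 1.0 + alpha[jidx] * (1.0 - ufull[sidx])
        if config.fixed_upsilon2 is None:
            ups2 = 1.0 / rng.gamma(
                hp.var_shape + 0.5 * N, 1.0 / (hp.var_rate + 0.5 * (resid**2).sum())
            )

        # --- collapse records to state-level weighted means ----------------
        a_rec = alpha[jidx]
        w_rec = a_rec**2 / ups2
        b_rec = a_rec * (y - 1.0 + a_rec) / ups2
        Adiag = np.bincount(sidx, weights=w_rec, minlength=n + 1)[:n]
        bvec = np.bincount(sidx, weights=b_rec, minlength=n + 1)[:n]
        obs_mask = Adiag > 0
        obs_idx = np.flatnonzero(obs_mask)
        u_hat = bvec[obs_idx] / Adiag[obs_idx]
        prec_s = Adiag[obs_idx]

        # --- theta = (gamma0, beta): collapsed conjugate update -----------
        if config.sample_theta:
            a_, W_, Vc_, *_ = ws.anchored(sigma2)
            M = Vc_[np.ix_(obs_idx, obs_idx)].copy()
            M[np.diag_indices_from(M)] += 1.0 / prec_s
            Lm = cholesky(M, lower=True)
            Wo = W_[obs_idx]
            MiW = cho_solve((Lm, True), Wo)
            prec_t = theta_prec + Wo.T @ MiW
            rhs_t = MiW.T @ (u_hat - a_[obs_idx])
            Lt = cholesky(prec_t, lower=True)
            mu_t = cho_solve((Lt, True), rhs_t)
            theta = mu_t + solve_triangular(
                Lt, rng.standard_normal(7), lower=True, trans="T"
            )

        # --- sigma2: collapsed random walk on the log scale ----------------
        if config.sample_sigma2:
            ls2 = math.log(sigma2)
            prop = ls2 + scale_sigma2 * rng.standard_normal()
            cur_lp = (
                collapsed_loglik(sigma2, theta, obs_idx, u_hat, prec_s)
                - 0.5 * ((ls2 - hp.log_sigma2_mean) / hp.log_sigma2_sd) ** 2
            )
            try:
                prop_lp = (
                    collapsed_loglik(math.exp(prop), theta, obs_idx, u_hat, prec_s)
                    - 0.5 * ((prop - hp.log_sigma2_mean) / hp.log_sigma2_sd) ** 2
                )
            except np.linalg.LinAlgError:
                prop_lp = -np.inf
            tries["sigma2"] += 1
            win["sigma2"][1] += 1
            if math.log(rng.random()) < prop_lp - cur_lp:
                sigma2 = math.exp(prop)
                acc["sigma2"] += 1
                win["sigma2"][0] += 1

        # --- roughness (optional): collapsed joint log-scale random walk --
        if config.sample_roughness:
            lb = np.log(ws.roughness)
            prop_lb = lb + scale_rough * rng.standard_normal(6)
            cur_lp = collapsed_loglik(sigma2, theta, obs_idx, u_hat, prec_s) - 0.5 * (
                ((lb - hp.log_roughness_mean) / hp.log_roughness_sd) ** 2
            ).sum()
            saved = ws.roughness.copy()
            ws._update_kernel(np.exp(prop_lb))
            try:
                prop_lp = collapsed_loglik(
                    sigma2, theta, obs_idx, u_hat, prec_s
                ) - 0.5 * (
                    ((prop_lb - hp.log_roughness_mean) / hp.log_roughness_sd) ** 2
                ).sum()
            except np.linalg.LinAlgError:
                prop_lp = -np.inf
            tries["roughness"] += 1
            win["roughness"][1] += 1
            if math.log(rng.random()) < prop_lp - cur_lp:
                acc["roughness"] += 1
                win["roughness"][0] += 1
            else:
                ws._update_kernel(saved)

        # --- u: exact multivariate-normal full conditional -----------------
        a, W, Vc, cho, Vinv, _ = ws.anchored(sigma2)
        m_c = a + W @ theta
        P = Vinv + np.diag(Adiag)
        rhs = Vinv @ m_c + bvec
        Lp = cholesky(P, lower=True)
        mu = cho_solve((Lp, True), rhs)
        z = rng.standard_normal(n)
        u = mu + solve_triangular(Lp, z, lower=True, trans="T")
        ufull[:n] = u

        # --- adaptation during burn-in ------------------------------------
        if config.adapt and in_burn and (it + 1) % config.adapt_interval == 0:
            for key, scale_name in (
                ("alpha", "scale_alpha"),
                ("sigma2", "scale_sigma2"),
                ("roughness", "scale_rough"),
            ):
                got, tot = win[key]
                if tot:
                    rate = got / tot
                    factor = math.exp(np.clip(rate - 0.3, -0.5, 0.5))
                    if scale_name == "scale_alpha":
                        scale_alpha = float(np.clip(scale_alpha * factor, 1e-3, 5.0))
                    elif scale_name == "scale_sigma2":
                        scale_sigma2 = float(np.clip(scale_sigma2 * factor, 1e-3, 5.0))
                    else:
                        scale_rough = float(np.clip(scale_rough * factor, 1e-3, 5.0))
                win[key] = [0, 0]

        # --- storage -------------------------------------------------------
        if not in_burn and (it - config.burn_in) % config.thinning == 0 and d_out < D:
            out_u[d_out] = u
            out_alpha[d_out] = alpha
            out_ga[d_out] = gamma_a
            out_tau2[d_out] = tau2
            out_ups2[d_out] = ups2
            out_gamma0[d_out] = theta[0]
            out_beta[d_out] = theta[1:]
            out_sigma2[d_out] = sigma2
            out_rough[d_out] = ws.roughness
            d_out += 1

    rates = {
        k: (acc[k] / tries[k] if tries[k] else None) for k in acc
    }
    return ModelFit(
        states=design,
        u=out_u[:d_out],
        alpha=out_alpha[:d_out],
        gamma_alpha=out_ga[:d_out],
        tau2=out_tau2[:d_out],
        upsilon2=out_ups2[:d_out],
        gamma0=out_gamma0[:d_out],
        beta=out_beta[:d_out],
        sigma2=out_sigma2[:d_out],
        roughness=out_rough[:d_out],
        prior=prior,
        config=config,
        acceptance=rates,
        lattice=lattice,
        meta={"study": study.name, "n_observed": int(N), "n_respondents": int(J)},
    )


# ---------------------------------------------------------------------------
# prediction and transfer


def _extension_moments(
    fit_: ModelFit,
    targets: list[HealthState],
    want_cov: bool,
    max_draws: int | None = None,
):
    """Per-draw conditional-normal extension of u to off-design states.

    For each retained draw, u at the targets given that draw's design-state
    values (and the anchor u(full health) = 1) is normal under that draw's
    prior covariance; moments across draws follow by the laws of total
    mean/variance: mean of conditional means, plus covariance of conditional
    means and mean of conditional covariances.
    """
    prior = fit_.prior
    lattice = fit_.lattice
    F = fit_.states + [lattice.full_health]
    allstates = F + targets
    LA = levels_array(allstates)
    nF, nT = len(F), len(targets)
    Z = (LA - 1).astype(float)
    if prior.mode == "transfer":
        base = prior.base.resolve(allstates, prior.roughness)
        b0, B = base.mean, base.cov
    else:
        b0 = np.ones(len(allstates))
        B = np.zeros((len(allstates), len(allstates)))

    draws = fit_.n_draws
    step = 1
    if max_draws is not None and draws > max_draws:
        step = draws // max_draws
    use = np.arange(0, draws, step)
    nd = len(use)

    mean_acc = np.zeros((nd, nT))
    cov_acc = np.zeros((nT, nT)) if want_cov else np.zeros(nT)

    rough_varies = fit_.config.sample_roughness
    C_all = correlation_matrix(LA, LA, fit_.roughness[0])
    for k, t in enumerate(use):
        if rough_varies:
            C_all = correlation_matrix(LA, LA, fit_.roughness[t])
        s2 = fit_.sigma2[t]
        V = B + s2 * C_all
        m = b0 + fit_.gamma0[t] + Z @ fit_.beta[t]
        VFF = V[:nF, :nF].copy()
        VFF[np.diag_indices_from(VFF)] += 1e-10
        VTF = V[nF:, :nF]
        known = np.append(fit_.u[t], 1.0)
        choF = cho_factor(VFF, lower=True)
        w = cho_solve(choF, known - m[:nF])
        mean_acc[k] = m[nF:] + VTF @ w
        X = solve_triangular(choF[0], VTF.T, lower=True)
        if want_cov:
            cov_acc += V[nF:, nF:] - X.T @ X
        else:
            cov_acc += np.diag(V[nF:, nF:]) - (X**2).sum(axis=0)

    mmean = mean_acc.mean(axis=0)
    if want_cov:
        dev = mean_acc - mmean
        cov = dev.T @ dev / max(nd - 1, 1) + cov_acc / nd
        return mmean, cov
    var_between = mean_acc.var(axis=0, ddof=1) if nd > 1 else np.zeros(nT)
    return mmean, var_between + cov_acc / nd


def predict(
    fit_: ModelFit,
    states: Sequence[HealthState],
    prior: PriorSpec | None = None,
    *,
    max_draws: int | None = None,
) -> pd.DataFrame:
    """Posterior mean and SD of u at arbitrary lattice states.

    Design states use the stored draws directly; full health is the anchor
    (mean 1, SD 0); any other state is filled in by per-draw conditional-
    normal extension under that draw's covariance and hyperparameters.
    """
    lattice = fit_.lattice
    for s in states:
        lattice.validate(s)
    fh = lattice.full_health
    pos = {s.code: i for i, s in enumerate(fit_.states)}
    mean = np.empty(len(states))
    sd = np.empty(len(states))
    targets, tpos = [], []
    for i, s in enumerate(states):
        if s == fh:
            mean[i], sd[i] = 1.0, 0.0
        elif s.code in pos:
            col = fit_.u[:, pos[s.code]]
            mean[i], sd[i] = col.mean(), col.std(ddof=1)
        else:
            targets.append(s)
            tpos.append(i)
    if targets:
        m, v = _extension_moments(fit_, targets, want_cov=False, max_draws=max_draws)
        mean[tpos] = m
        sd[tpos] = np.sqrt(np.clip(v, 0.0, None))
    return pd.DataFrame(
        {"state": [s.code for s in states], "predicted_mean": mean, "predicted_sd": sd}
    )


def posterior_as_prior(
    fit_: ModelFit,
    states: Sequence[HealthState],
    *,
    label: str | None = None,
    max_draws: int | None = None,
) -> UtilityPosterior:
    """Package a fit's posterior at ``states`` for use as the next country's prior.

    Mean and covariance are taken across (conditionally extended) draws;
    the result is PSD-repaired if draw noise leaves tiny negative
    eigenvalues.
    """
    if fit_.n_draws < 2:
        raise ValueError("need at least 2 retained draws to form a posterior")
    lattice = fit_.lattice
    fh = lattice.full_health
    pos = {s.code: i for i, s in enumerate(fit_.states)}
    design_mask = [s.code in pos or s == fh for s in states]
    if all(design_mask):
        cols = []
        for s in states:
            cols.append(np.ones(fit_.n_draws) if s == fh else fit_.u[:, pos[s.code]])
        M = np.column_stack(cols)
        mean = M.mean(axis=0)
        cov = np.cov(M, rowvar=False)
        cov = np.atleast_2d(cov)
    else:
        inner = [s for s in states if s != fh]
        m_in, c_in = _joint_moments(fit_, inner, max_draws=max_draws)
        mean = np.empty(len(states))
        cov = np.zeros((len(states), len(states)))
        sel = [i for i, s in enumerate(states) if s != fh]
        mean[[i for i, s in enumerate(states) if s == fh]] = 1.0
        mean[sel] = m_in
        cov[np.ix_(sel, sel)] = c_in
    cov = _psd_repair(cov)
    meta = {"country": label or fit_.meta.get("study", ""), "n_draws": fit_.n_draws}
    return UtilityPosterior(list(states), mean, cov, meta)


def _joint_moments(fit_: ModelFit, states: list[HealthState], max_draws=None):
    """Joint mean/cov across draws for a mix of design and off-design states."""
    pos = {s.code: i for i, s in enumerate(fit_.states)}
    targets = [s for s in states if s.code not in pos]
    if not targets:
        M = np.column_stack([fit_.u[:, pos[s.code]] for s in states])
        return M.mean(axis=0), np.atleast_2d(np.cov(M, rowvar=False))
    # build per-draw vectors: stored values for design states, conditional
    # means for the rest, then add the average conditional covariance.
    m_t, cov_t = _extension_moments(fit_, targets, want_cov=True, max_draws=max_draws)
    # assemble covariance between design columns and extended columns from the
    # per-draw conditional means: rerun the extension capturing per-draw means
    # is already folded into cov_t for target-target; design-target cross terms
    # need the draws, so recompute via a joint pass.
    nT = len(targets)
    draws = fit_.n_draws
    step = 1
    if max_draws is not None and draws > max_draws:
        step = draws // max_draws
    use = np.arange(0, draws, step)
    prior = fit_.prior
    lattice = fit_.lattice
    F = fit_.states + [lattice.full_health]
    allstates = F + targets
    LA = levels_array(allstates)
    nF = len(F)
    Z = (LA - 1).astype(float)
    if prior.mode == "transfer":
        base = prior.base.resolve(allstates, prior.roughness)
        b0, B = base.mean, base.cov
    else:
        b0 = np.ones(len(allstates))
        B = np.zeros((len(allstates), len(allstates)))
    C_all = correlation_matrix(LA, LA, fit_.roughness[0])
    vecs = np.empty((len(use), len(states)))
    cond_cov_sum = np.zeros((nT, nT))
    tmap = {s.code: k for k, s in enumerate(targets)}
    for k, t in enumerate(use):
        if fit_.config.sample_roughness:
            C_all = correlation_matrix(LA, LA, fit_.roughness[t])
        V = B + fit_.sigma2[t] * C_all
        m = b0 + fit_.gamma0[t] + Z @ fit_.beta[t]
        VFF = V[:nF, :nF].copy()
        VFF[np.diag_indices_from(VFF)] += 1e-10
        VTF = V[nF:, :nF]
        known = np.append(fit_.u[t], 1.0)
        choF = cho_factor(VFF, lower=True)
        w = cho_solve(choF, known - m[:nF])
        cm = m[nF:] + VTF @ w
        X = solve_triangular(choF[0], VTF.T, lower=True)
        cond_cov_sum += V[nF:, nF:] - X.T @ X
        for i, s in enumerate(states):
            vecs[k, i] = fit_.u[t, pos[s.code]] if s.code in pos else cm[tmap[s.code]]
    mean = vecs.mean(axis=0)
    cov = np.atleast_2d(np.cov(vecs, rowvar=False))
    tsel = [i for i, s in enumerate(states) if s.code not in pos]
    cov[np.ix_(tsel, tsel)] += cond_cov_sum / len(use)
    return mean, cov


def load_prior_from_table(
    records: pd.DataFrame | None = None,
    which: Literal["UK", "HK", "HKUK"] = "UK",
    *,
    roughness: float | Sequence[float] = 0.1,
    lattice: LatticeSpec = DEFAULT_LATTICE,
) -> UtilityPosterior:
    """Rebuild a country posterior from published per-state means and SDs.

    The published table reports marginal posterior means and SDs but no
    cross-state covariances, so the covariance is approximated as
    ``D R D`` with ``D = diag(SD)`` and ``R`` the squared-exponential
    kernel correlation at the supplied roughness — an explicit modelling
    choice, since the original joint posterior is not recoverable.
    """
    if records is None:
        from .fixtures import load_table1

        records = load_table1()
    colmap = {"UK": ("uk_mean", "uk_sd"), "HK": ("hk_mean", "hk_sd"), "HKUK": ("hkuk_mean", "hkuk_sd")}
    try:
        mcol, scol = colmap[which]
    except KeyError:
        raise ValueError(f"which must be one of {sorted(colmap)}, got {which!r}")
    if mcol not in records.columns or scol not in records.columns:
        raise ValueError(f"table lacks columns {mcol}/{scol}")
    if records[scol].isna().any():
        raise ValueError(f"missing SDs in column {scol}")
    states = [parse_state(c, lattice) for c in records["state"]]
    mean = records[mcol].to_numpy(dtype=float)
    sd = records[scol].to_numpy(dtype=float)
    if (sd < 0).any():
        raise ValueError("negative SD in table")
    b = np.full(6, roughness, float) if np.isscalar(roughness) else np.asarray(roughness, float)
    R = correlation_matrix(levels_array(states), levels_array(states), b)
    cov = R * np.outer(sd, sd)
    return UtilityPosterior(states, mean, cov, {"source": f"table1:{which}", "roughness": b.tolist()})
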