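"""Bayesian estimation of the emotion-sharing tree in five variants.

* ``M1`` — one pooled parameter set (j, rb, s, e) for both emotions.
* ``M2`` — emotion-specific authenticity judgment only (j_anger,
  j_happiness, rb, s, e).
* ``M3`` — emotion-specific judgment, sharing and elicitation; one response
  bias shared with the neutral condition (seven group parameters).
* ``M4`` — M3's parameters per participant through independent logit-normal
  random effects.
* ``M5`` — M4 with the seven random effects jointly multivariate normal,
  their correlation matrix under an LKJ(2) prior.

Pooled variants (M1–M3) place Beta(2, 2) priors on the probabilities; the
hierarchical variants place Normal(0, 2) priors on the logit-scale group
means, half-normal(1) priors on the random-effect scales, and (M5) an
LKJ(2) prior on the effect correlations.

Sampling is adaptive random-walk Metropolis-within-Gibbs on the logit
scale.  For the hierarchical variants the per-participant effect updates
are conditionally independent given the hyperparameters, so one sweep
proposes and accepts them for all participants simultaneously; proposal
scales adapt during warmup toward a 44% acceptance rate.  The per-trial
pointwise log-likelihood is stored for WAIC.

The LKJ prior is sampled through the canonical partial correlations of the
C-vine construction, under which the partial correlations are independent
shifted-Beta variables; this makes the implied prior over correlation
matrices exactly LKJ without an explicit matrix Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit
from scipy.stats import gaussian_kde

from .tree import (
    EFFECT_NAMES,
    EMOTION_CATEGORIES,
    NEUTRAL_CATEGORIES,
    ResponseCounts,
    emotion_cell_probs,
)

__all__ = [
    "EFFECT_NAMES",
    "ModelSpec",
    "SamplerConfig",
    "MPTModel",
    "CountsData",
    "PosteriorDraws",
    "FitSummary",
    "build_model",
    "fit",
    "rhat",
    "summarize",
    "extract_subject_effects",
    "parameter_correlations",
]

_VARIANTS = ("M1", "M2", "M3", "M4", "M5")
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one model variant.

    ``beta_prior`` are the Beta shape parameters for M1–M3 probabilities
    ((1, 1) is the flat sensitivity alternative).  ``alpha_scale``,
    ``tau_scale`` and ``lkj_eta`` configure the hierarchical hyperpriors.
    ``shared_rb`` keeps one response bias across emotions (with
    ``shared_rb=False``, M3 carries rb_anger and rb_happiness and neutral
    trials use their average).  ``mvn_on_alpha`` switches M5 to the variant
    that correlates the group means instead of the subject effects.
    """

    variant: str
    beta_prior: tuple[float, float] = (2.0, 2.0)
    alpha_scale: float = 2.0
    tau_scale: float = 1.0
    lkj_eta: float = 2.0
    shared_rb: bool = True
    mvn_on_alpha: bool = False

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected {_VARIANTS}")
        if min(self.beta_prior) <= 0:
            raise ValueError("Beta prior shapes must be positive")
        if self.lkj_eta <= 0:
            raise ValueError("LKJ shape must be positive")
        if self.variant in ("M4", "M5") and not self.shared_rb:
            raise ValueError(
                "hierarchical variants model the seven shared-rb effects; "
                "per-emotion rb is available for M3 only"
            )


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run lengths and diagnostics thresholds (defaults: 5000 warmup
    and 5000 retained draws in each of four chains)."""

    warmup: int = 5000
    draws: int = 5000
    chains: int = 4
    seed: int = 0
    rhat_threshold: float = 1.01
    store_pointwise: bool = True

    def __post_init__(self) -> None:
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws must be >= 1 and warmup >= 0")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")


@dataclass(frozen=True)
class MPTModel:
    """Opaque model object produced by :func:`build_model`."""

    spec: ModelSpec
    param_names: tuple[str, ...]

    @property
    def hierarchical(self) -> bool:
        return self.spec.variant in ("M4", "M5")


def build_model(spec: ModelSpec) -> MPTModel:
    """Resolve a variant specification into its free-parameter layout."""
    v = spec.variant
    if v == "M1":
        names: tuple[str, ...] = ("j", "rb", "s", "e")
    elif v == "M2":
        names = ("j_anger", "j_happiness", "rb", "s", "e")
    elif v == "M3":
        if spec.shared_rb:
            names = EFFECT_NAMES
        else:
            names = (
                "j_anger", "e_anger", "s_anger",
                "j_happiness", "e_happiness", "s_happiness",
                "rb_anger", "rb_happiness",
            )
    else:  # M4 / M5: group means of the seven effects
        names = EFFECT_NAMES
    return MPTModel(spec=spec, param_names=tuple(names))


# ---------------------------------------------------------------------------
# Data layout

#: Canonical cell order: 4 anger, 4 happiness, 2 neutral.
CELL_LABELS = tuple(
    [("anger", c) for c in EMOTION_CATEGORIES]
    + [("happiness", c) for c in EMOTION_CATEGORIES]
    + [("neutral", c) for c in NEUTRAL_CATEGORIES]
)


@dataclass
class CountsData:
    """Dense per-participant count arrays in canonical cell order."""

    participants: list[str]
    emotion: np.ndarray  # (n, 2, 4): [anger, happiness] x categories
    neutral: np.ndarray  # (n, 2): ["1", "0"]

    @classmethod
    def from_counts(cls, counts: Iterable[ResponseCounts]) -> "CountsData":
        counts = list(counts)
        participants = sorted({c.participant_id for c in counts})
        idx = {p: i for i, p in enumerate(participants)}
        n = len(participants)
        emotion = np.zeros((n, 2, 4), dtype=np.int64)
        neutral = np.zeros((n, 2), dtype=np.int64)
        for c in counts:
            i = idx[c.participant_id]
            if c.condition == "neutral":
                neutral[i] += c.as_array()
            else:
                cond = 0 if c.condition == "anger" else 1
                emotion[i, cond] += c.as_array()
        return cls(participants, emotion, neutral)

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return int(self.emotion.sum() + self.neutral.sum())

    def cell_matrix(self) -> np.ndarray:
        """(n, 10) counts in canonical cell order."""
        return np.concatenate(
            [self.emotion.reshape(len(self.participants), 8), self.neutral], axis=1
        )

    def trial_expansion(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-trial (participant index, cell index) in canonical order."""
        cm = self.cell_matrix()
        part_idx = np.repeat(
            np.arange(cm.shape[0]), cm.sum(axis=1)
        )
        cell_idx = np.concatenate(
            [np.repeat(np.arange(10), row) for row in cm]
        ) if cm.size else np.empty(0, dtype=int)
        return part_idx.astype(np.int64), cell_idx.astype(np.int64)


def _as_counts_data(counts) -> CountsData:
    if isinstance(counts, CountsData):
        return counts
    return CountsData.from_counts(counts)


# ---------------------------------------------------------------------------
# Cell probabilities from group parameters (pooled variants)


def _pooled_cells(model: MPTModel, p: np.ndarray) -> np.ndarray:
    """Map probability-scale parameters (..., d) to cells (..., 10)."""
    v = model.spec.variant
    p = np.asarray(p)
    if v == "M1":
        j, rb, s, e = (p[..., i] for i in range(4))
        ca = emotion_cell_probs(j, rb, s, e)
        ch = ca
        rbn = rb
    elif v == "M2":
        ja, jh, rb, s, e = (p[..., i] for i in range(5))
        ca = emotion_cell_probs(ja, rb, s, e)
        ch = emotion_cell_probs(jh, rb, s, e)
        rbn = rb
    elif v == "M3" and model.spec.shared_rb:
        ja, ea, sa, jh, eh, sh, rb = (p[..., i] for i in range(7))
        ca = emotion_cell_probs(ja, rb, sa, ea)
        ch = emotion_cell_probs(jh, rb, sh, eh)
        rbn = rb
    elif v == "M3":
        ja, ea, sa, jh, eh, sh, rba, rbh = (p[..., i] for i in range(8))
        ca = emotion_cell_probs(ja, rba, sa, ea)
        ch = emotion_cell_probs(jh, rbh, sh, eh)
        rbn = 0.5 * (rba + rbh)
    else:
        raise ValueError(f"{v} is not a pooled variant")
    return np.concatenate(
        [ca, ch, np.stack([rbn, 1.0 - rbn], axis=-1)], axis=-1
    )


def _subject_cells(probs: np.ndarray) -> np.ndarray:
    """(..., 7) subject probabilities in EFFECT_NAMES order → (..., 10) cells."""
    ja, ea, sa, jh, eh, sh, rb = (probs[..., i] for i in range(7))
    ca = emotion_cell_probs(ja, rb, sa, ea)
    ch = emotion_cell_probs(jh, rb, sh, eh)
    return np.concatenate(
        [ca, ch, np.stack([rb, 1.0 - rb], axis=-1)], axis=-1
    )


_LOG_FLOOR = 1e-300


def _safe_log(x: np.ndarray) -> np.ndarray:
    return np.log(np.clip(x, _LOG_FLOOR, None))


# ---------------------------------------------------------------------------
# LKJ prior via canonical partial correlations (C-vine)


def _vine_shapes(k: int, eta: float) -> np.ndarray:
    """Beta shape for each packed lower-triangular entry, by column."""
    cols = np.concatenate([np.full(k - 1 - j, j) for j in range(k - 1)])
    return eta + (k - 2 - cols) / 2.0


def _pack_index(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of packed lower-triangular entries, column-major."""
    rows, cols = [], []
    for j in range(k - 1):
        for i in range(j + 1, k):
            rows.append(i)
            cols.append(j)
    return np.array(rows), np.array(cols)


def cholesky_from_partials(z: np.ndarray, k: int) -> np.ndarray:
    """Cholesky factor of the correlation matrix implied by canonical
    partial correlations ``z`` (packed column-major, each in (−1, 1))."""
    rows, cols = _pack_index(k)
    zmat = np.zeros((k, k))
    zmat[rows, cols] = z
    chol = np.zeros((k, k))
    chol[0, 0] = 1.0
    for i in range(1, k):
        res = 1.0
        for j in range(i):
            chol[i, j] = zmat[i, j] * np.sqrt(res)
            res -= chol[i, j] ** 2
        chol[i, i] = np.sqrt(max(res, 1e-14))
    return chol


def corr_from_partials(z: np.ndarray, k: int) -> np.ndarray:
    chol = cholesky_from_partials(z, k)
    return chol @ chol.T


def _lkj_logprior_y(y: np.ndarray, shapes: np.ndarray) -> float:
    """Log prior of unconstrained ``y`` with z = tanh(y): the shifted-Beta
    density of each partial correlation combines with the tanh Jacobian to
    ``b · log(1 − z²)`` up to a constant, and
    log(1 − tanh²y) = 2·(log 2 − log(eʸ + e⁻ʸ))."""
    log1mz2 = 2.0 * (np.log(2.0) - np.logaddexp(y, -y))
    return float(np.sum(shapes * log1mz2))


# ---------------------------------------------------------------------------
# Posterior container


@dataclass
class PosteriorDraws:
    """Chains × draws of all model parameters plus the per-trial pointwise
    log-likelihood matrix used for WAIC."""

    variant: str
    spec: ModelSpec
    param_names: tuple[str, ...]
    group: dict[str, np.ndarray]          # name -> (chains, draws), prob scale
    participants: list[str]
    data: CountsData | None
    pointwise: np.ndarray | None = None   # (chains*draws, n_trials)
    alpha: np.ndarray | None = None       # (chains, draws, 7)
    tau: np.ndarray | None = None         # (chains, draws, 7)
    u: np.ndarray | None = None           # (chains, draws, n, 7)
    omega: np.ndarray | None = None       # (chains, draws, 7, 7)

    @property
    def n_chains(self) -> int:
        return next(iter(self.group.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.group.values())).shape[1]

    @property
    def hierarchical(self) -> bool:
        return self.u is not None

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """All scalar parameters as name → (chains, draws) arrays."""
        out = dict(self.group)
        if self.alpha is not None:
            for k, name in enumerate(EFFECT_NAMES):
                out[f"alpha[{name}]"] = self.alpha[..., k]
        if self.tau is not None:
            for k, name in enumerate(EFFECT_NAMES):
                out[f"tau[{name}]"] = self.tau[..., k]
        if self.omega is not None:
            for i in range(7):
                for j in range(i):
                    out[f"omega[{EFFECT_NAMES[i]},{EFFECT_NAMES[j]}]"] = (
                        self.omega[..., i, j]
                    )
        return out

    def to_inference_data(self) -> az.InferenceData:
        posterior = {k: v for k, v in self.scalar_draws().items()}
        if self.u is not None:
            posterior["u"] = self.u
        return az.from_dict(posterior=posterior)

    def stacked(self, name: str) -> np.ndarray:
        """Flatten a group parameter across chains."""
        return self.group[name].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """Columnar (chain, draw, parameter, value) view of scalar draws."""
        rows = []
        for name, arr in self.scalar_draws().items():
            c, d = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "chain": np.repeat(np.arange(c), d),
                        "draw": np.tile(np.arange(d), c),
                        "parameter": name,
                        "value": arr.reshape(-1),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


FitSummary = pd.DataFrame  # rows: parameter; columns: MAP, 2.5%, 97.5%


# ---------------------------------------------------------------------------
# Adaptive Metropolis-within-Gibbs, pooled variants


def _fit_pooled(
    model: MPTModel, data: CountsData, cfg: SamplerConfig
) -> PosteriorDraws:
    d = len(model.param_names)
    a_shape, b_shape = model.spec.beta_prior
    total = data.cell_matrix().sum(axis=0).astype(float)

    def logpost(x: np.ndarray) -> float:
        p = expit(x)
        # Beta(a, b) prior plus the logit Jacobian p(1-p)
        lp = float(np.sum(a_shape * np.log(p) + b_shape * np.log1p(-p)))
        cells = _pooled_cells(model, p)
        return lp + float(total @ _safe_log(cells))

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    draws = np.empty((cfg.chains, cfg.draws, d))
    cov_checkpoints = {cfg.warmup // 2, (3 * cfg.warmup) // 4}
    for c, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 0.5, size=d)
        lp = logpost(x)
        scales = np.full(d, 0.5)
        acc = np.zeros(d)
        # joint proposals with the empirical covariance learned in warmup
        # break the strong (s, e) posterior correlation
        history: list[np.ndarray] = []
        cov_chol: np.ndarray | None = None
        s_joint = 2.38 / np.sqrt(d)
        acc_joint = 0.0
        for it in range(cfg.warmup + cfg.draws):
            for k in range(d):
                prop = x.copy()
                prop[k] += scales[k] * rng.standard_normal()
                lp_prop = logpost(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    acc[k] += 1
            if cov_chol is not None:
                prop = x + s_joint * (cov_chol @ rng.standard_normal(d))
                lp_prop = logpost(prop)
                if np.log(rng.random()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    acc_joint += 1
            if it < cfg.warmup:
                history.append(x.copy())
                if (it + 1) % 50 == 0:
                    scales *= np.exp(np.clip(acc / 50.0 - _TARGET_ACCEPT, -0.5, 0.5))
                    acc[:] = 0
                    if cov_chol is not None:
                        s_joint *= np.exp(np.clip(acc_joint / 50.0 - 0.25, -0.5, 0.5))
                        acc_joint = 0.0
                if (it + 1) in cov_checkpoints and len(history) > 10 * d:
                    cov = np.cov(np.array(history[len(history) // 2:]).T)
                    cov_chol = np.linalg.cholesky(cov + 1e-9 * np.eye(d))
            if it >= cfg.warmup:
                draws[c, it - cfg.warmup] = x

    probs = expit(draws)
    group = {name: probs[..., k] for k, name in enumerate(model.param_names)}
    post = PosteriorDraws(
        variant=model.spec.variant,
        spec=model.spec,
        param_names=model.param_names,
        group=group,
        participants=list(data.participants),
        data=data,
    )
    if cfg.store_pointwise and data.n_trials > 0:
        flat = probs.reshape(-1, d)
        logcells = _safe_log(_pooled_cells(model, flat))  # (S, 10)
        _, cell_idx = data.trial_expansion()
        post.pointwise = logcells[:, cell_idx].astype(np.float32)
    return post


# ---------------------------------------------------------------------------
# Adaptive Metropolis-within-Gibbs, hierarchical variants


class _HierState:
    """Mutable single-chain state with cached likelihood and u-prior."""

    def __init__(self, model, data, rng):
        self.model = model
        self.spec = model.spec
        self.data = data
        self.rng = rng
        self.n = data.n_participants
        self.counts = data.cell_matrix().astype(float)  # (n, 10)
        self.alpha = rng.normal(0.0, 0.3, size=7)
        self.ltau = rng.normal(-1.0, 0.2, size=7)
        self.u = rng.normal(0.0, 0.1, size=(self.n, 7))
        self.correlated_u = self.spec.variant == "M5" and not self.spec.mvn_on_alpha
        self.corr_alpha = self.spec.variant == "M5" and self.spec.mvn_on_alpha
        if self.spec.variant == "M5":
            self.y = rng.normal(0.0, 0.1, size=21)
            self.lkj_shapes = _vine_shapes(7, self.spec.lkj_eta)
        else:
            self.y = None
        self._refresh_corr()
        self.ll = self._loglik(self.alpha, self.u)

    # likelihood -----------------------------------------------------------
    def _loglik(self, alpha, u):
        probs = expit(alpha + u)
        cells = _safe_log(_subject_cells(probs))
        return np.einsum("nc,nc->n", self.counts, cells)

    # correlation machinery ------------------------------------------------
    def _refresh_corr(self):
        if self.spec.variant == "M5":
            self.chol_omega = cholesky_from_partials(np.tanh(self.y), 7)
            self.omega = self.chol_omega @ self.chol_omega.T
        else:
            self.omega = np.eye(7)
            self.chol_omega = np.eye(7)

    def _u_prior_terms(self, u=None, tau=None):
        """Per-subject log prior of the random effects (up to a constant)."""
        u = self.u if u is None else u
        tau = np.exp(self.ltau) if tau is None else tau
        if self.correlated_u:
            scaled_chol = tau[:, None] * self.chol_omega  # diag(tau) @ L
            sol = solve_triangular(scaled_chol, u.T, lower=True)
            quad = np.sum(sol**2, axis=0)
            logdet = np.sum(np.log(np.diag(scaled_chol)))
            return -0.5 * quad - logdet
        # independent effects (M4, and M5 with mvn_on_alpha)
        return np.sum(
            -0.5 * (u / tau[None, :]) ** 2 - np.log(tau)[None, :], axis=1
        )

    def hyper_logprior(self, alpha=None, ltau=None, y=None):
        alpha = self.alpha if alpha is None else alpha
        ltau = self.ltau if ltau is None else ltau
        tau = np.exp(ltau)
        if self.corr_alpha:
            scaled = self.chol_omega * self.spec.alpha_scale
            sol = solve_triangular(scaled, alpha, lower=True)
            lp = float(-0.5 * np.sum(sol**2) - np.sum(np.log(np.diag(scaled))))
        else:
            lp = float(np.sum(-0.5 * (alpha / self.spec.alpha_scale) ** 2))
        # half-normal(tau_scale) on tau, plus the log Jacobian of log tau
        lp += float(np.sum(-0.5 * (tau / self.spec.tau_scale) ** 2 + ltau))
        if self.y is not None:
            y = self.y if y is None else y
            lp += _lkj_logprior_y(y, self.lkj_shapes)
        return lp


def _fit_hierarchical(
    model: MPTModel, data: CountsData, cfg: SamplerConfig
) -> PosteriorDraws:
    if data.n_participants < 2:
        raise ValueError("hierarchical variants require at least 2 participants")
    n = data.n_participants
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.chains)
    is_m5 = model.spec.variant == "M5"

    alpha_draws = np.empty((cfg.chains, cfg.draws, 7))
    tau_draws = np.empty((cfg.chains, cfg.draws, 7))
    u_draws = np.empty((cfg.chains, cfg.draws, n, 7), dtype=np.float32)
    omega_draws = np.empty((cfg.chains, cfg.draws, 7, 7)) if is_m5 else None

    for c, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        st = _HierState(model, data, rng)
        s_u = np.full((n, 7), 0.3)
        s_ujoint = np.full(n, 0.3)
        acc_ujoint = np.zeros(n)
        s_alpha = np.full(7, 0.1)
        s_shift = np.full(7, 0.1)
        s_ltau = np.full(7, 0.3)
        s_rescale = np.full(7, 0.2)
        s_y = np.full(21, 0.3) if is_m5 else None
        acc_u = np.zeros((n, 7))
        acc_alpha = np.zeros(7)
        acc_shift = np.zeros(7)
        acc_ltau = np.zeros(7)
        acc_rescale = np.zeros(7)
        acc_y = np.zeros(21) if is_m5 else None
        prior_u = st._u_prior_terms()

        for it in range(cfg.warmup + cfg.draws):
            # --- independence refresh from the conditional prior: with the
            # proposal equal to the prior conditional of u[.,k] given the
            # other columns, acceptance reduces to the likelihood ratio and
            # weakly informed components are redrawn almost freely ---------
            tau_now = np.exp(st.ltau)
            scaled = tau_now[:, None] * st.chol_omega
            prec = np.linalg.inv(scaled @ scaled.T)
            for k in range(7):
                cond_sd = 1.0 / np.sqrt(prec[k, k])
                cond_mean = st.u[:, k] - (st.u @ prec[:, k]) / prec[k, k]
                prop_u = st.u.copy()
                prop_u[:, k] = cond_mean + cond_sd * rng.standard_normal(n)
                ll_prop = st._loglik(st.alpha, prop_u)
                accept = np.log(rng.random(n)) < ll_prop - st.ll
                st.u[accept, k] = prop_u[accept, k]
                st.ll = np.where(accept, ll_prop, st.ll)
            prior_u = st._u_prior_terms()

            # --- subject effects, one component at a time, all subjects ----
            for k in range(7):
                prop_u = st.u.copy()
                prop_u[:, k] = st.u[:, k] + s_u[:, k] * rng.standard_normal(n)
                ll_prop = st._loglik(st.alpha, prop_u)
                prior_prop = st._u_prior_terms(u=prop_u)
                delta = (ll_prop - st.ll) + (prior_prop - prior_u)
                accept = np.log(rng.random(n)) < delta
                st.u[accept, k] = prop_u[accept, k]
                st.ll = np.where(accept, ll_prop, st.ll)
                prior_u = np.where(accept, prior_prop, prior_u)
                acc_u[:, k] += accept

            # --- joint per-subject proposal along the current effect
            # covariance, so u decorrelates along the posterior's own axes -
            tau_now = np.exp(st.ltau)
            prop_u = st.u + s_ujoint[:, None] * (
                rng.standard_normal((n, 7)) @ (tau_now[:, None] * st.chol_omega).T
                if is_m5
                else rng.standard_normal((n, 7)) * tau_now[None, :]
            )
            ll_prop = st._loglik(st.alpha, prop_u)
            prior_prop = st._u_prior_terms(u=prop_u)
            accept = np.log(rng.random(n)) < (ll_prop - st.ll) + (
                prior_prop - prior_u
            )
            st.u[accept] = prop_u[accept]
            st.ll = np.where(accept, ll_prop, st.ll)
            prior_u = np.where(accept, prior_prop, prior_u)
            acc_ujoint += accept

            # --- group means ----------------------------------------------
            for k in range(7):
                prop_a = st.alpha.copy()
                prop_a[k] += s_alpha[k] * rng.standard_normal()
                ll_prop = st._loglik(prop_a, st.u)
                delta = float(np.sum(ll_prop - st.ll))
                delta += st.hyper_logprior(alpha=prop_a) - st.hyper_logprior()
                if np.log(rng.random()) < delta:
                    st.alpha = prop_a
                    st.ll = ll_prop
                    acc_alpha[k] += 1

            # --- joint location shift: alpha_k + δ, u[.,k] − δ keeps the
            # likelihood invariant and decorrelates the group mean from the
            # subject effects ----------------------------------------------
            for k in range(7):
                delta = s_shift[k] * rng.standard_normal()
                prop_a = st.alpha.copy()
                prop_a[k] += delta
                prop_u = st.u.copy()
                prop_u[:, k] -= delta
                prior_prop = st._u_prior_terms(u=prop_u)
                d_move = float(np.sum(prior_prop - prior_u))
                d_move += st.hyper_logprior(alpha=prop_a) - st.hyper_logprior()
                if np.log(rng.random()) < d_move:
                    st.alpha = prop_a
                    st.u = prop_u
                    prior_u = prior_prop
                    acc_shift[k] += 1

            # --- effect scales --------------------------------------------
            for k in range(7):
                prop_lt = st.ltau.copy()
                prop_lt[k] += s_ltau[k] * rng.standard_normal()
                prior_prop = st._u_prior_terms(tau=np.exp(prop_lt))
                delta = float(np.sum(prior_prop - prior_u))
                delta += st.hyper_logprior(ltau=prop_lt) - st.hyper_logprior()
                if np.log(rng.random()) < delta:
                    st.ltau = prop_lt
                    prior_u = prior_prop
                    acc_ltau[k] += 1

            # --- interweaving rescale: tau_k and u[.,k] move together with
            # the standardized effects v = u/tau held fixed, which restores
            # mixing for weakly identified components (funnel geometry);
            # the map u -> u·e^δ contributes a log-Jacobian of n·δ ---------
            for k in range(7):
                delta = s_rescale[k] * rng.standard_normal()
                prop_lt = st.ltau.copy()
                prop_lt[k] += delta
                prop_u = st.u.copy()
                prop_u[:, k] = st.u[:, k] * np.exp(delta)
                ll_prop = st._loglik(st.alpha, prop_u)
                prior_prop = st._u_prior_terms(u=prop_u, tau=np.exp(prop_lt))
                d_move = float(np.sum(ll_prop - st.ll))
                d_move += float(np.sum(prior_prop - prior_u))
                d_move += st.hyper_logprior(ltau=prop_lt) - st.hyper_logprior()
                d_move += n * delta
                if np.log(rng.random()) < d_move:
                    st.ltau = prop_lt
                    st.u = prop_u
                    st.ll = ll_prop
                    prior_u = prior_prop
                    acc_rescale[k] += 1

            # --- correlation partials (M5); several passes per sweep since
            # these updates are cheap relative to likelihood evaluations ---
            if is_m5:
                for m in list(range(21)) * 3:
                    prop_y = st.y.copy()
                    prop_y[m] += s_y[m] * rng.standard_normal()
                    prop_chol = cholesky_from_partials(np.tanh(prop_y), 7)
                    old_chol = st.chol_omega
                    old_hyper = st.hyper_logprior()
                    st.chol_omega = prop_chol
                    new_hyper = st.hyper_logprior(y=prop_y)
                    delta = new_hyper - old_hyper
                    if st.correlated_u:
                        prior_prop = st._u_prior_terms()
                        delta += float(np.sum(prior_prop - prior_u))
                    else:
                        prior_prop = prior_u
                    if np.log(rng.random()) < delta:
                        st.y = prop_y
                        prior_u = prior_prop
                        st.omega = prop_chol @ prop_chol.T
                        acc_y[m] += 1
                    else:
                        st.chol_omega = old_chol

            # --- warmup adaptation ----------------------------------------
            if it < cfg.warmup and (it + 1) % 50 == 0:
                s_u *= np.exp(np.clip(acc_u / 50.0 - _TARGET_ACCEPT, -0.5, 0.5))
                s_ujoint *= np.exp(
                    np.clip(acc_ujoint / 50.0 - 0.25, -0.5, 0.5)
                )
                acc_ujoint[:] = 0
                s_alpha *= np.exp(
                    np.clip(acc_alpha / 50.0 - _TARGET_ACCEPT, -0.5, 0.5)
                )
                s_shift *= np.exp(
                    np.clip(acc_shift / 50.0 - _TARGET_ACCEPT, -0.5, 0.5)
                )
                s_ltau *= np.exp(
                    np.clip(acc_ltau / 50.0 - _TARGET_ACCEPT, -0.5, 0.5)
                )
                s_rescale *= np.exp(
                    np.clip(acc_rescale / 50.0 - _TARGET_ACCEPT, -0.5, 0.5)
                )
                acc_u[:] = 0
                acc_alpha[:] = 0
                acc_shift[:] = 0
                acc_ltau[:] = 0
                acc_rescale[:] = 0
                if is_m5:
                    s_y *= np.exp(
                        np.clip(acc_y / 150.0 - _TARGET_ACCEPT, -0.5, 0.5)
                    )
                    acc_y[:] = 0

            if it >= cfg.warmup:
                i = it - cfg.warmup
                alpha_draws[c, i] = st.alpha
                tau_draws[c, i] = np.exp(st.ltau)
                u_draws[c, i] = st.u
                if is_m5:
                    omega_draws[c, i] = st.omega

    group = {
        name: expit(alpha_draws[..., k]) for k, name in enumerate(EFFECT_NAMES)
    }
    post = PosteriorDraws(
        variant=model.spec.variant,
        spec=model.spec,
        param_names=model.param_names,
        group=group,
        participants=list(data.participants),
        data=data,
        alpha=alpha_draws,
        tau=tau_draws,
        u=u_draws,
        omega=omega_draws,
    )
    if cfg.store_pointwise and data.n_trials > 0:
        post.pointwise = _hier_pointwise(post, data)
    return post


def _hier_pointwise(post: PosteriorDraws, data: CountsData) -> np.ndarray:
    part_idx, cell_idx = data.trial_expansion()
    flat_idx = part_idx * 10 + cell_idx
    alpha = post.alpha.reshape(-1, 7)
    u = post.u.reshape(-1, data.n_participants, 7).astype(np.float64)
    s_total = alpha.shape[0]
    out = np.empty((s_total, len(flat_idx)), dtype=np.float32)
    chunk = max(1, int(2e7 // (data.n_participants * 10)))
    for start in range(0, s_total, chunk):
        stop = min(start + chunk, s_total)
        probs = expit(alpha[start:stop, None, :] + u[start:stop])
        logcells = _safe_log(_subject_cells(probs))  # (b, n, 10)
        out[start:stop] = logcells.reshape(stop - start, -1)[:, flat_idx]
    return out


def fit(
    model: MPTModel,
    counts: Iterable[ResponseCounts] | CountsData,
    sampler: SamplerConfig = SamplerConfig(),
) -> PosteriorDraws:
    """Draw from the posterior of ``model`` given response counts.

    Emits a convergence warning (never a hard failure) naming the worst
    parameters when any R-hat exceeds the configured threshold.
    """
    data = _as_counts_data(counts)
    if model.hierarchical:
        post = _fit_hierarchical(model, data, sampler)
    else:
        post = _fit_pooled(model, data, sampler)
    diag = rhat(post)
    worst = diag.dropna().sort_values(ascending=False)
    if len(worst) and worst.iloc[0] > sampler.rhat_threshold:
        offenders = ", ".join(
            f"{k}={v:.3f}" for k, v in worst.head(5).items()
        )
        warnings.warn(
            f"R-hat above {sampler.rhat_threshold} for some parameters: "
            f"{offenders}",
            RuntimeWarning,
            stacklevel=2,
        )
    return post


# ---------------------------------------------------------------------------
# Diagnostics and summaries


def rhat(draws: PosteriorDraws | dict[str, np.ndarray]) -> pd.Series:
    """Rank-normalized split R-hat per scalar parameter.

    Accepts a fitted posterior or a plain name → (chains, draws) mapping.
    Constant draws yield NaN (flagged, not raised); a single chain raises.
    """
    arrays = draws.scalar_draws() if isinstance(draws, PosteriorDraws) else dict(draws)
    out = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError(
                f"parameter {name!r}: R-hat requires >= 2 chains of draws"
            )
        if np.allclose(arr, arr.reshape(-1)[0]):
            out[name] = float("nan")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[name] = float(az.rhat(arr, method="rank"))
    return pd.Series(out, name="rhat")


def _kde_mode(samples: np.ndarray, lo: float, hi: float, n_grid: int = 512) -> float:
    kde = gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(lo, hi, n_grid)
    return float(grid[np.argmax(kde(grid))])


def summarize(
    draws: PosteriorDraws, params: Sequence[str] | None = None
) -> FitSummary:
    """MAP (kernel-density mode on the probability scale) and central 95%
    interval for each group-level probability parameter."""
    if draws.n_chains * draws.n_draws < 100:
        raise ValueError("at least 100 draws are required for mode estimation")
    names = list(params) if params is not None else list(draws.group)
    rows = []
    for name in names:
        x = draws.stacked(name)
        lo_q, hi_q = np.quantile(x, [0.025, 0.975])
        m = _kde_mode(x, 0.0, 1.0)
        if not lo_q <= m <= hi_q:
            warnings.warn(
                f"MAP of {name!r} falls outside its 95% interval "
                "(possible in skewed posteriors)",
                RuntimeWarning,
                stacklevel=2,
            )
        rows.append({"parameter": name, "MAP": m, "2.5%": lo_q, "97.5%": hi_q})
    return pd.DataFrame(rows).set_index("parameter")


def extract_subject_effects(
    draws: PosteriorDraws, scale: str = "effects"
) -> pd.DataFrame:
    """Posterior-mean per-participant random effects (``scale='effects'``)
    or the implied subject-level probabilities (``scale='probability'``)."""
    if not draws.hierarchical:
        raise ValueError("subject effects exist only for hierarchical fits")
    if scale == "effects":
        mean = draws.u.astype(np.float64).mean(axis=(0, 1))
    elif scale == "probability":
        mean = expit(
            draws.alpha[:, :, None, :] + draws.u.astype(np.float64)
        ).mean(axis=(0, 1))
    else:
        raise ValueError("scale must be 'effects' or 'probability'")
    return pd.DataFrame(mean, index=draws.participants, columns=list(EFFECT_NAMES))


def parameter_correlations(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior median and central 95% interval of the 21 pairwise
    random-effect correlations (final-model output)."""
    if draws.omega is None:
        raise ValueError("parameter correlations require an M5 fit")
    rows = []
    om = draws.omega.reshape(-1, 7, 7)
    for i in range(7):
        for j in range(i + 1, 7):
            vals = om[:, j, i]
            lo, med, hi = np.quantile(vals, [0.025, 0.5, 0.975])
            rows.append(
                {
                    "parameter_a": EFFECT_NAMES[i],
                    "parameter_b": EFFECT_NAMES[j],
                    "median": med,
                    "2.5%": lo,
                    "97.5%": hi,
                }
            )
    return pd.DataFrame(rows)
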