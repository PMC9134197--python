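"""Synthetic emotion-sharing studies for end-to-end pipeline testing.

Generates complete studies that mirror the design the package targets:
~88 participants, each rating 64 anger, 64 happiness and 20 neutral dynamic
facial-expression clips (148 trials), with per-participant tree parameters
drawn from a correlated hierarchical logit-normal population, raw
(judgment, valence) ratings consistent with the encoding rule, and Likert
questionnaire items (ECS, IRI subscales, SPS, SIAS) with controllable
reliability and trait–parameter loadings.

Every downstream stage — encoding, model fitting, model comparison, trait
correlations — is testable by recovery against the stored ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .preprocess import EncodingRule
from .tree import (
    EFFECT_NAMES,
    ConditionParameters,
    MPTParameters,
    TrialOutcome,
    sample_categories,
)

__all__ = [
    "EFFECT_NAMES",
    "DEFAULT_GROUP_PROBS",
    "PopulationConfig",
    "ScaleSpec",
    "QuestionnaireDesign",
    "SyntheticStudy",
    "generate_population",
    "generate_dataset",
    "generate_raw_ratings",
    "generate_questionnaires",
    "generate_study",
    "expected_probability",
    "write_trials",
    "write_questionnaires",
    "write_truth",
]

#: Group-level probabilities used for the default population location —
#: the point estimates of the study this design emulates (a convenience
#: so that default simulations resemble realistic data, not a claim).
DEFAULT_GROUP_PROBS = {
    "j_anger": 0.070,
    "e_anger": 0.840,
    "s_anger": 0.006,
    "j_happiness": 0.382,
    "e_happiness": 0.865,
    "s_happiness": 0.965,
    "rb": 0.164,
}

DEFAULT_TRIALS = {"anger": 64, "happiness": 64, "neutral": 20}


def _default_alpha() -> np.ndarray:
    return logit(np.array([DEFAULT_GROUP_PROBS[k] for k in EFFECT_NAMES]))


@dataclass
class PopulationConfig:
    """Hierarchical logit-normal population of tree parameters.

    ``alpha`` are logit-scale group means in :data:`EFFECT_NAMES` order,
    ``tau`` the random-effect scales, and ``omega`` the 7×7 correlation
    matrix of the effects; subject parameters are
    ``inverse-logit(alpha + u_n)`` with ``u_n ~ N(0, diag(tau)·omega·diag(tau))``.
    """

    alpha: np.ndarray = field(default_factory=_default_alpha)
    tau: np.ndarray = field(default_factory=lambda: np.full(7, 0.5))
    omega: np.ndarray = field(default_factory=lambda: np.eye(7))
    n_participants: int = 88
    trials: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_TRIALS))
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        k = len(EFFECT_NAMES)
        if self.alpha.shape != (k,) or self.tau.shape != (k,):
            raise ValueError(f"alpha and tau must have shape ({k},)")
        if np.any(self.tau < 0):
            raise ValueError("tau must be non-negative")
        if self.omega.shape != (k, k):
            raise ValueError(f"omega must be {k}x{k}")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if not np.allclose(np.diag(self.omega), 1.0):
            raise ValueError("omega must have unit diagonal")
        if np.linalg.eigvalsh(self.omega).min() <= 1e-10:
            raise ValueError("omega must be positive definite")
        for cond, n in self.trials.items():
            if n < 0:
                raise ValueError(f"negative trial count for {cond!r}")

    def covariance(self) -> np.ndarray:
        return np.diag(self.tau) @ self.omega @ np.diag(self.tau)


def _participant_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"p{i:0{width}d}" for i in range(1, n + 1)]


def draw_random_effects(
    config: PopulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw u_n ~ N(0, diag(tau)·omega·diag(tau)) for every participant."""
    cov = config.covariance()
    # Cholesky of the correlation, scaled — stable even when some tau are 0
    chol = np.linalg.cholesky(config.omega + 1e-12 * np.eye(len(EFFECT_NAMES)))
    z = rng.standard_normal((config.n_participants, len(EFFECT_NAMES)))
    u = (z @ chol.T) * config.tau
    del cov
    return pd.DataFrame(
        u, index=_participant_ids(config.n_participants), columns=list(EFFECT_NAMES)
    )


def generate_population(
    config: PopulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant tree parameters from the hierarchical population.

    Returns ``(params, effects)``: probabilities inverse-logit(alpha + u_n)
    and the raw logit-scale random effects u_n, both indexed by participant
    and with columns :data:`EFFECT_NAMES`.  Deterministic given the config
    seed (or the supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    effects = draw_random_effects(config, rng)
    params = pd.DataFrame(
        expit(config.alpha + effects.to_numpy()),
        index=effects.index,
        columns=effects.columns,
    )
    return params, effects


def subject_condition_parameters(row: pd.Series) -> ConditionParameters:
    """View one participant's parameter row as per-condition tree parameters."""
    return ConditionParameters(
        anger=MPTParameters(
            j=row["j_anger"], rb=row["rb"], s=row["s_anger"], e=row["e_anger"]
        ),
        happiness=MPTParameters(
            j=row["j_happiness"], rb=row["rb"], s=row["s_happiness"],
            e=row["e_happiness"],
        ),
        shared_rb=True,
    )


def generate_dataset(
    subject_params: pd.DataFrame,
    trials: dict[str, int] | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TrialOutcome]:
    """Forward-simulate every participant's trials through the latent tree.

    Trial outcomes are emitted participant by participant in condition order
    (anger, happiness, neutral); reproducible per seed.
    """
    trials = dict(DEFAULT_TRIALS) if trials is None else trials
    for cond, n in trials.items():
        if n < 0:
            raise ValueError(f"negative trial count for {cond!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out: list[TrialOutcome] = []
    for pid, row in subject_params.iterrows():
        cp = subject_condition_parameters(row)
        for condition in ("anger", "happiness", "neutral"):
            n = trials.get(condition, 0)
            if n == 0:
                continue
            cats = sample_categories(cp.for_condition(condition), condition, n, rng)
            out.extend(TrialOutcome(str(pid), condition, str(c)) for c in cats)
    return out


def generate_raw_ratings(
    trials: list[TrialOutcome],
    seed: int | np.random.Generator = 0,
    rule: EncodingRule = EncodingRule(),
) -> pd.DataFrame:
    """Emit raw (judgment, valence) rows consistent with each trial's category.

    The inverse of outcome encoding: the detection digit fixes the
    genuine/posed judgment and the experience digit restricts the valence to
    the qualifying (or non-qualifying) region of −3..+3 under ``rule``;
    within the region the valence is sampled uniformly.  Neutral-trial
    valences are unconstrained.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = []
    stim_counter: dict[tuple[str, str], int] = {}
    for t in trials:
        k = (t.participant_id, t.condition)
        stim_counter[k] = stim_counter.get(k, 0) + 1
        stimulus_id = f"{t.condition}_{stim_counter[k]:03d}"
        if t.condition == "neutral":
            judgment = "genuine" if t.category == "1" else "posed"
            valence = int(rng.integers(-3, 4))
        else:
            judgment = "genuine" if t.category[0] == "1" else "posed"
            region = rule.qualifying_valences(t.condition, t.category[1] == "1")
            valence = int(rng.choice(region))
        rows.append(
            {
                "participant_id": t.participant_id,
                "stimulus_id": stimulus_id,
                "condition": t.condition,
                "judgment": judgment,
                "valence": valence,
                "category": t.category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "stimulus_id", "condition",
            "judgment", "valence", "category",
        ],
    )


# ---------------------------------------------------------------------------
# Questionnaires


@dataclass(frozen=True)
class ScaleSpec:
    """One questionnaire (sub)scale: item count, response range, population
    mean and SD of the participant mean score, and target inter-item
    correlation (which fixes the internal consistency via Spearman–Brown)."""

    n_items: int
    response_range: tuple[int, int]
    mean: float
    sd: float
    inter_item_r: float

    def spearman_brown_alpha(self) -> float:
        k, r = self.n_items, self.inter_item_r
        return k * r / (1 + (k - 1) * r)


def _default_scales() -> dict[str, ScaleSpec]:
    # Item counts are fixed by the instruments (ECS 15; IRI subscales 7 each;
    # SPS and SIAS 20).  Means/SDs emulate a typical Japanese crowdsourcing
    # sample; inter-item correlations are backed out of the reliabilities
    # reported for such samples via r = alpha / (k - alpha*(k-1)).
    def r_from_alpha(alpha: float, k: int) -> float:
        return alpha / (k - alpha * (k - 1))

    return {
        "ECS": ScaleSpec(15, (1, 5), 2.63, 0.52, r_from_alpha(0.85, 15)),
        "EC": ScaleSpec(7, (1, 5), 3.46, 0.65, r_from_alpha(0.77, 7)),
        "PT": ScaleSpec(7, (1, 5), 3.06, 0.62, r_from_alpha(0.66, 7)),
        "PD": ScaleSpec(7, (1, 5), 3.20, 0.75, r_from_alpha(0.77, 7)),
        "FS": ScaleSpec(7, (1, 5), 3.19, 0.79, r_from_alpha(0.78, 7)),
        "SPS": ScaleSpec(20, (0, 4), 1.03, 0.60, r_from_alpha(0.90, 20)),
        "SIAS": ScaleSpec(20, (0, 4), 1.98, 0.81, r_from_alpha(0.93, 20)),
    }


@dataclass
class QuestionnaireDesign:
    """Scales to simulate plus the trait–parameter loading matrix.

    ``loadings`` has one row per scale (same keys as ``scales``) and one
    column per random effect; a loading of λ makes the scale's latent trait
    correlate λ with that standardized effect.  All-zero loadings (default)
    make traits independent of the tree parameters.
    """

    scales: dict[str, ScaleSpec] = field(default_factory=_default_scales)
    loadings: pd.DataFrame | None = None
    discretize: bool = True

    def __post_init__(self) -> None:
        if self.loadings is None:
            self.loadings = pd.DataFrame(
                0.0, index=list(self.scales), columns=list(EFFECT_NAMES)
            )
        else:
            self.loadings = self.loadings.reindex(
                index=list(self.scales), columns=list(EFFECT_NAMES)
            )
            if self.loadings.isna().any().any():
                raise ValueError(
                    "loadings must cover every (scale, effect) pair with "
                    "finite values"
                )


def _censored_location(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Latent normal location whose doubly-censored mean equals the target.

    Clamping at the response-range ends would otherwise bias scales whose
    mean sits near a bound (floor effects); solved by bisection on the
    censored-normal mean formula.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    if sd == 0:
        return target_mean

    def censored_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return (
            lo * norm.cdf(a)
            + hi * norm.sf(b)
            + mu * (norm.cdf(b) - norm.cdf(a))
            + sd * (norm.pdf(a) - norm.pdf(b))
        )

    if not censored_mean(lo - 6 * sd) < target_mean < censored_mean(hi + 6 * sd):
        raise ValueError(f"target mean {target_mean} unreachable in [{lo}, {hi}]")
    return float(
        brentq(lambda mu: censored_mean(mu) - target_mean, lo - 6 * sd, hi + 6 * sd)
    )


def generate_questionnaires(
    design: QuestionnaireDesign,
    random_effects: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    tau: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate Likert item responses tied to the participants' effects.

    Each scale's latent trait is λᵀ·(standardized random effects) plus an
    independent completion to unit variance; item responses are
    ``mean + a·trait + noise`` with ``a`` and the noise SD chosen so the
    inter-item correlation and mean-score SD match the scale spec, then
    rounded to the nearest response category and clamped to the range.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    u = random_effects.to_numpy()
    if tau is None:
        sd_u = u.std(axis=0, ddof=1)
    else:
        sd_u = np.asarray(tau, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_std = np.where(sd_u > 0, u / np.where(sd_u > 0, sd_u, 1.0), 0.0)
    n = len(random_effects)
    rows = []
    for name, spec in design.scales.items():
        lam = design.loadings.loc[name].to_numpy()
        lam_norm2 = float(lam @ lam)
        if lam_norm2 > 1.0:
            raise ValueError(
                f"loadings for scale {name!r} have squared norm {lam_norm2:.3f} > 1"
            )
        trait = u_std @ lam + np.sqrt(1.0 - lam_norm2) * rng.standard_normal(n)
        k, r = spec.n_items, spec.inter_item_r
        item_var = spec.sd**2 / (r + (1 - r) / k)
        a = np.sqrt(r * item_var)
        noise_sd = np.sqrt((1 - r) * item_var)
        location = spec.mean
        if design.discretize:
            lo, hi = spec.response_range
            location = _censored_location(spec.mean, np.sqrt(item_var), lo, hi)
        items = (
            location
            + a * trait[:, None]
            + noise_sd * rng.standard_normal((n, k))
        )
        if design.discretize:
            lo, hi = spec.response_range
            items = np.clip(np.rint(items), lo, hi)
        for p_idx, pid in enumerate(random_effects.index):
            for item_idx in range(k):
                rows.append(
                    {
                        "participant_id": str(pid),
                        "scale": name,
                        "item": item_idx + 1,
                        "response": items[p_idx, item_idx],
                    }
                )
    return pd.DataFrame(rows, columns=["participant_id", "scale", "item", "response"])


# ---------------------------------------------------------------------------
# Whole studies


@dataclass
class SyntheticStudy:
    """A complete simulated study with its ground truth."""

    population: PopulationConfig
    subject_params: pd.DataFrame
    random_effects: pd.DataFrame
    trials: list[TrialOutcome]
    raw_ratings: pd.DataFrame
    questionnaires: pd.DataFrame


def generate_study(
    config: PopulationConfig | None = None,
    design: QuestionnaireDesign | None = None,
    rule: EncodingRule = EncodingRule(),
) -> SyntheticStudy:
    """Generate population, trials, raw ratings and questionnaires in one go."""
    config = config or PopulationConfig()
    design = design or QuestionnaireDesign()
    ss = np.random.SeedSequence(config.seed)
    rng_pop, rng_trials, rng_raw, rng_q = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    params, effects = generate_population(config, rng_pop)
    trials = generate_dataset(params, config.trials, rng_trials)
    raw = generate_raw_ratings(trials, rng_raw, rule)
    questionnaires = generate_questionnaires(design, effects, rng_q, tau=config.tau)
    return SyntheticStudy(config, params, effects, trials, raw, questionnaires)


def expected_probability(
    alpha: float, tau: float, n_nodes: int = 80
) -> float:
    """Population mean of inverse-logit(alpha + u), u ~ N(0, tau²), by
    Gauss–Hermite quadrature (reference value for marginal-recovery tests)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    return float(weights @ expit(alpha + tau * nodes) / weights.sum())


def write_trials(study: SyntheticStudy, path: str | Path) -> None:
    study.raw_ratings.to_csv(path, index=False)


def write_questionnaires(study: SyntheticStudy, path: str | Path) -> None:
    study.questionnaires.to_csv(path, index=False)


def write_truth(study: SyntheticStudy, path: str | Path) -> None:
    truth = study.subject_params.copy()
    truth.index.name = "participant_id"
    truth.to_csv(path)
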