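"""Multinomial processing tree of emotion sharing from facial expressions.

The tree decomposes a perceiver's reaction to a dynamic facial expression
into four latent branch probabilities:

* ``j``  — perceiving a genuine feeling state from an *emotional* expression,
* ``rb`` — perceiving a feeling state from a *neutral* expression
  (response bias),
* ``s``  — sharing the feeling state, conditional on having detected it,
* ``e``  — direct elicitation of a same-valence feeling state, irrespective
  of detection.

Emotion trials produce one of four observable categories ``"00"``, ``"01"``,
``"10"``, ``"11"``; the first digit records whether the perceiver judged the
expression genuine (detection), the second whether they reported a
same-valence experience.  Neutral trials produce ``"1"`` (feeling state
perceived) or ``"0"``.

This module holds the analytic category probabilities, a forward
branch-sampling simulator (the Monte-Carlo oracle of the analytic formulas),
and the categorical log-likelihood that every model variant shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CONDITIONS",
    "EMOTION_CONDITIONS",
    "EMOTION_CATEGORIES",
    "NEUTRAL_CATEGORIES",
    "EFFECT_NAMES",
    "MPTParameters",
    "ConditionParameters",
    "CategoryProbabilities",
    "TrialOutcome",
    "ResponseCounts",
    "category_probabilities",
    "collapsed_identities",
    "simulate_response",
    "sample_categories",
    "log_likelihood",
]

EMOTION_CONDITIONS = ("anger", "happiness")
CONDITIONS = EMOTION_CONDITIONS + ("neutral",)
EMOTION_CATEGORIES = ("00", "01", "10", "11")
NEUTRAL_CATEGORIES = ("1", "0")

#: Canonical order of the seven per-emotion branch parameters (shared rb),
#: used consistently for group means, random effects and reports.
EFFECT_NAMES = (
    "j_anger",
    "e_anger",
    "s_anger",
    "j_happiness",
    "e_happiness",
    "s_happiness",
    "rb",
)


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"parameter {name}={value!r} outside [0, 1]")


def _check_condition(condition: str) -> None:
    if condition not in CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )


@dataclass(frozen=True)
class MPTParameters:
    """The four branch probabilities of the tree.

    Endpoint values 0 and 1 are accepted here for analytic tests; priors and
    samplers operate strictly inside the open interval via the logit link.
    """

    j: float
    rb: float
    s: float
    e: float

    def __post_init__(self) -> None:
        for name in ("j", "rb", "s", "e"):
            _check_unit(name, getattr(self, name))

    def as_array(self) -> np.ndarray:
        return np.array([self.j, self.rb, self.s, self.e], dtype=float)


@dataclass(frozen=True)
class ConditionParameters:
    """Per-emotion branch probabilities for one (synthetic) participant.

    When ``shared_rb`` is set the response bias is common to both emotions
    and the neutral condition.
    """

    anger: MPTParameters
    happiness: MPTParameters
    shared_rb: bool = True

    def __post_init__(self) -> None:
        if self.shared_rb and self.anger.rb != self.happiness.rb:
            raise ValueError("shared_rb=True requires anger.rb == happiness.rb")

    @property
    def rb(self) -> float:
        """Response bias governing neutral trials."""
        if self.shared_rb:
            return self.anger.rb
        return 0.5 * (self.anger.rb + self.happiness.rb)

    def for_condition(self, condition: str) -> MPTParameters:
        _check_condition(condition)
        if condition == "anger":
            return self.anger
        if condition == "happiness":
            return self.happiness
        # neutral trials depend on rb only; carry it in a full parameter set
        return MPTParameters(j=0.0, rb=self.rb, s=0.0, e=0.0)


@dataclass(frozen=True)
class CategoryProbabilities:
    """Multinomial cell probabilities for one condition."""

    condition: str
    probs: Mapping[str, float]

    @property
    def categories(self) -> tuple[str, ...]:
        return (
            NEUTRAL_CATEGORIES if self.condition == "neutral" else EMOTION_CATEGORIES
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.probs[c] for c in self.categories], dtype=float)

    def __getitem__(self, category: str) -> float:
        return self.probs[category]


@dataclass(frozen=True)
class TrialOutcome:
    participant_id: str
    condition: str
    category: str

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        valid = (
            NEUTRAL_CATEGORIES if self.condition == "neutral" else EMOTION_CATEGORIES
        )
        if self.category not in valid:
            raise ValueError(
                f"category {self.category!r} invalid for condition "
                f"{self.condition!r}; expected one of {valid}"
            )


@dataclass(frozen=True)
class ResponseCounts:
    """Per-participant, per-condition sufficient statistic of the
    categorical likelihood."""

    participant_id: str
    condition: str
    counts: Mapping[str, int]
    n_trials: int = field(default=-1)

    def __post_init__(self) -> None:
        _check_condition(self.condition)
        valid = (
            NEUTRAL_CATEGORIES if self.condition == "neutral" else EMOTION_CATEGORIES
        )
        for cat, n in self.counts.items():
            if cat not in valid:
                raise ValueError(
                    f"category {cat!r} invalid for condition {self.condition!r}"
                )
            if n < 0:
                raise ValueError(f"negative count for category {cat!r}")
        total = int(sum(self.counts.values()))
        if self.n_trials == -1:
            object.__setattr__(self, "n_trials", total)
        elif total != self.n_trials:
            raise ValueError(
                f"counts sum to {total}, expected n_trials={self.n_trials}"
            )

    def as_array(self) -> np.ndarray:
        valid = (
            NEUTRAL_CATEGORIES if self.condition == "neutral" else EMOTION_CATEGORIES
        )
        return np.array([self.counts.get(c, 0) for c in valid], dtype=np.int64)


def emotion_cell_probs(
    j: np.ndarray, rb: np.ndarray, s: np.ndarray, e: np.ndarray
) -> np.ndarray:
    """Vectorized four-cell probabilities (..., 4) in the order 00,01,10,11.

    Written exactly as the printed branch expansions, including the six-term
    form of θ11; the algebraically collapsed form is kept separate in
    :func:`collapsed_identities` as an internal cross-check.
    """
    j, rb, s, e = np.broadcast_arrays(j, rb, s, e)
    t00 = (1 - j) * (1 - rb) * (1 - e)
    t01 = (1 - j) * (1 - rb) * e
    t10 = (1 - j) * rb * (1 - s) * (1 - e) + j * (1 - s) * (1 - e)
    t11 = (
        j * s * e
        + j * s * (1 - e)
        + j * (1 - s) * e
        + (1 - j) * rb * s * e
        + (1 - j) * rb * (1 - s) * e
        + (1 - j) * rb * s * (1 - e)
    )
    return np.stack([t00, t01, t10, t11], axis=-1)


def category_probabilities(
    params: MPTParameters, condition: str
) -> CategoryProbabilities:
    """Analytic cell probabilities of the tree for one condition.

    Emotion conditions return the four-cell distribution; the neutral
    condition depends on the response bias only: θ1 = rb, θ0 = 1 − rb.
    """
    _check_condition(condition)
    if condition == "neutral":
        return CategoryProbabilities(
            condition, {"1": params.rb, "0": 1.0 - params.rb}
        )
    cells = emotion_cell_probs(params.j, params.rb, params.s, params.e)
    return CategoryProbabilities(
        condition, dict(zip(EMOTION_CATEGORIES, cells.tolist()))
    )


def collapsed_identities(params: MPTParameters) -> tuple[float, float]:
    """Algebraic collapse of the tree: the total detection probability
    ``D = j + (1−j)·rb`` and the conditional sharing-or-elicitation
    probability ``P(11)/D = 1 − (1−s)(1−e)``.

    Equals θ10+θ11 and θ11/D of :func:`category_probabilities`.  When D is 0
    the conditional is undefined and returned as NaN.
    """
    d = params.j + (1 - params.j) * params.rb
    if d == 0.0:
        return 0.0, float("nan")
    return d, 1.0 - (1 - params.s) * (1 - params.e)


def sample_categories(
    params: MPTParameters,
    condition: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` outcome categories by traversing the latent branches.

    Detection is attempted via ``j`` (emotion trials), falling back to the
    response bias ``rb``; detected trials then branch on sharing ``s`` and
    elicitation ``e``, undetected trials on elicitation alone.  Returns an
    array of category label strings.
    """
    _check_condition(condition)
    if condition == "neutral":
        perceived = rng.random(n) < params.rb
        return np.where(perceived, "1", "0")
    via_j = rng.random(n) < params.j
    via_rb = rng.random(n) < params.rb
    detected = via_j | via_rb
    shared = rng.random(n) < params.s
    elicited = rng.random(n) < params.e
    same_state = np.where(detected, shared | elicited, elicited)
    first = np.where(detected, "1", "0")
    second = np.where(same_state, "1", "0")
    return np.char.add(first, second)


def simulate_response(
    params: MPTParameters,
    condition: str,
    rng_seed: int | np.random.Generator,
    participant_id: str = "sim",
) -> TrialOutcome:
    """Sample a single trial outcome from the latent tree (forward model)."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    category = sample_categories(params, condition, 1, rng)[0]
    return TrialOutcome(participant_id, condition, str(category))


def log_likelihood(counts: ResponseCounts, theta: CategoryProbabilities) -> float:
    """Trial-level categorical log-likelihood Σ_c n_c·log θ_c.

    No multinomial coefficient is included: the pointwise unit for model
    comparison is the individual trial.  A positive count on a zero-
    probability cell yields −inf (flagged value, not an exception).
    """
    if counts.condition != theta.condition:
        raise ValueError(
            f"counts condition {counts.condition!r} does not match "
            f"theta condition {theta.condition!r}"
        )
    n = counts.as_array().astype(float)
    p = theta.as_array()
    if np.any(p < 0):
        raise ValueError("negative cell probability")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > 0, n * np.log(p), 0.0)
    return float(np.sum(terms))
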