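"""Encoding of raw behavioral rows into tree outcome categories.

A raw trial carries a binary authenticity judgment (genuine / posed) and a
valence rating on the integer scale −3..+3.  The outcome category's first
digit records the judgment; the second digit records whether the reported
valence qualifies as a same-valence experience for the trial's emotion:
above +1 for happiness, below −1 for anger (``strict`` rule), with an
``inclusive`` variant admitting the boundary ratings ±1.  Neutral trials are
encoded from the judgment alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .tree import CONDITIONS, ResponseCounts, TrialOutcome

__all__ = [
    "EncodingRule",
    "encode_outcome",
    "encode_trials",
    "counts_from_trials",
    "counts_to_frame",
    "load_trials",
    "load_questionnaires",
]

JUDGMENTS = ("genuine", "posed")

TRIAL_COLUMNS = ["participant_id", "stimulus_id", "condition", "judgment", "valence"]
QUESTIONNAIRE_COLUMNS = ["participant_id", "scale", "item", "response"]


@dataclass(frozen=True)
class EncodingRule:
    """Valence threshold rule mapping ratings to the same-state digit.

    ``strict`` (default): happiness qualifies iff valence > +1, anger iff
    valence < −1.  ``inclusive``: ≥ +1 / ≤ −1.  Valence 0 never qualifies
    under either mode.
    """

    mode: Literal["strict", "inclusive"] = "strict"

    def __post_init__(self) -> None:
        if self.mode not in ("strict", "inclusive"):
            raise ValueError(f"unknown encoding mode {self.mode!r}")

    def same_state(self, valence: int, condition: str) -> bool:
        if condition == "happiness":
            return valence > 1 if self.mode == "strict" else valence >= 1
        if condition == "anger":
            return valence < -1 if self.mode == "strict" else valence <= -1
        raise ValueError("same_state is defined for emotion conditions only")

    def qualifying_valences(self, condition: str, same_state: bool) -> tuple[int, ...]:
        """Integer ratings mapped to (or away from) the same-state digit."""
        full = tuple(range(-3, 4))
        qualifying = tuple(v for v in full if self.same_state(v, condition))
        return qualifying if same_state else tuple(
            v for v in full if v not in qualifying
        )


def encode_outcome(
    judgment: str,
    valence: int,
    condition: str,
    rule: EncodingRule = EncodingRule(),
) -> str:
    """Map one (judgment, valence) pair to its outcome category."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if judgment not in JUDGMENTS:
        raise ValueError(f"unknown judgment {judgment!r}")
    if condition == "neutral":
        return "1" if judgment == "genuine" else "0"
    valence = int(valence)
    if not -3 <= valence <= 3:
        raise ValueError(f"valence {valence} outside −3..+3")
    first = "1" if judgment == "genuine" else "0"
    second = "1" if rule.same_state(valence, condition) else "0"
    return first + second


def encode_trials(
    raw: pd.DataFrame, rule: EncodingRule = EncodingRule()
) -> list[TrialOutcome]:
    """Encode a raw trial table (see :func:`load_trials`) into outcomes."""
    outcomes = []
    for row in raw.itertuples(index=False):
        try:
            category = encode_outcome(row.judgment, row.valence, row.condition, rule)
        except ValueError as err:
            raise ValueError(
                f"row (participant={row.participant_id!r}, "
                f"stimulus={row.stimulus_id!r}): {err}"
            ) from err
        outcomes.append(TrialOutcome(str(row.participant_id), row.condition, category))
    return outcomes


def counts_from_trials(trials: Iterable[TrialOutcome]) -> list[ResponseCounts]:
    """Aggregate trial outcomes to per-(participant, condition) counts."""
    acc: dict[tuple[str, str], dict[str, int]] = {}
    for t in trials:
        key = (t.participant_id, t.condition)
        cell = acc.setdefault(key, {})
        cell[t.category] = cell.get(t.category, 0) + 1
    return [
        ResponseCounts(pid, cond, counts)
        for (pid, cond), counts in sorted(acc.items())
    ]


def counts_to_frame(counts: Iterable[ResponseCounts]) -> pd.DataFrame:
    """Tabular view: participant_id, condition, n00, n01, n10, n11, n_yes, n_no."""
    rows = []
    for c in counts:
        row = {"participant_id": c.participant_id, "condition": c.condition,
               "n00": 0, "n01": 0, "n10": 0, "n11": 0, "n_yes": 0, "n_no": 0}
        if c.condition == "neutral":
            row["n_yes"] = c.counts.get("1", 0)
            row["n_no"] = c.counts.get("0", 0)
        else:
            for cat in ("00", "01", "10", "11"):
                row[f"n{cat}"] = c.counts.get(cat, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def load_trials(path: str | Path) -> pd.DataFrame:
    """Load and validate a raw trial CSV.

    Requires columns participant_id, stimulus_id, condition, judgment,
    valence; rejects unknown condition labels, unparseable or out-of-range
    valences, and duplicate (participant, stimulus) rows, naming the
    offending lines.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "stimulus_id": str})
    _require_columns(df, TRIAL_COLUMNS, path)

    bad_cond = df.loc[~df["condition"].isin(CONDITIONS)]
    if len(bad_cond):
        raise ValueError(
            f"{path}: unknown condition label(s) "
            f"{sorted(bad_cond['condition'].unique())} "
            f"at rows {bad_cond.index.tolist()[:10]}"
        )
    valence = pd.to_numeric(df["valence"], errors="coerce")
    bad_val = df.loc[valence.isna() | (valence < -3) | (valence > 3)]
    if len(bad_val):
        raise ValueError(
            f"{path}: unparseable or out-of-range valence at rows "
            f"{bad_val.index.tolist()[:10]}"
        )
    df["valence"] = valence.astype(int)
    dup = df.duplicated(subset=["participant_id", "stimulus_id"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (participant, stimulus) rows at "
            f"{df.index[dup].tolist()[:10]}"
        )
    bad_judgment = df.loc[~df["judgment"].isin(JUDGMENTS)]
    if len(bad_judgment):
        raise ValueError(
            f"{path}: unknown judgment label(s) at rows "
            f"{bad_judgment.index.tolist()[:10]}"
        )
    return df


def load_questionnaires(path: str | Path) -> pd.DataFrame:
    """Load and validate a long-format questionnaire item CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "scale": str})
    _require_columns(df, QUESTIONNAIRE_COLUMNS, path)
    response = pd.to_numeric(df["response"], errors="coerce")
    if response.isna().any():
        raise ValueError(
            f"{path}: unparseable response at rows "
            f"{df.index[response.isna()].tolist()[:10]}"
        )
    df["response"] = response
    dup = df.duplicated(subset=["participant_id", "scale", "item"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (participant, scale, item) rows at "
            f"{df.index[dup].tolist()[:10]}"
        )
    return df
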