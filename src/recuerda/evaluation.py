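"""Quantitative evaluation: word error rate and voted appropriateness.

Two instruments are implemented.

**Word error rate.**  For a reference transcript of N tokens aligned to a
hypothesis under unit edit costs,

    WER = (S + I + D) / N,

with S substitutions, I insertions and D deletions.  Both transcripts run
through the same normalization pipeline as the dialogue engine, so WER is
case- and punctuation-insensitive.  The S/I/D split comes from a
Wagner–Fischer backtrace whose tie-breaking prefers substitution over
deletion over insertion; the total S+I+D is the (path-independent) edit
distance.  WER can exceed 1 when the hypothesis is much longer than the
reference.

**Voted appropriateness.**  Bystander evaluators read a fixed dialogue and
choose, among four candidate continuations (the system's actual response
at hidden position 0 plus three distractors), the one the system should
have given.  Rvoted is the per-candidate vote count, Rmax the per-dialogue
maximum.  Agreement percentages count, for each candidate position, the
share of dialogues where that position reaches Rmax — ties count for every
tied position, so the percentages can sum above 100.  Pearson correlation
between position-0 Rvoted and Rmax summarizes how often the system's own
response is among the most voted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ConstantInputError,
    EmptyInputError,
    EmptyReferenceError,
    InvalidVoteError,
    LengthMismatchError,
    RangeError,
)
from .normalize import normalize

__all__ = [
    "WERResult",
    "word_error_rate",
    "sid_alignment",
    "aggregate_wer",
    "wer_table",
    "EvaluationDialogue",
    "VoteTable",
    "RvotedResult",
    "rvoted",
    "agreement_percentages",
    "CorrelationResult",
    "pearson",
    "StarRatingSummary",
    "star_rating_summary",
    "read_votes_csv",
    "write_votes_csv_scaffold",
    "round_half_up",
]

N_CANDIDATES = 4


def round_half_up(x: float, ndigits: int) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# word error rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WERResult:
    """Alignment counts for one reference/hypothesis pair."""

    N: int
    S: int
    I: int
    D: int

    @property
    def wer(self) -> float:
        return (self.S + self.I + self.D) / self.N

    @property
    def distance(self) -> int:
        return self.S + self.I + self.D


def sid_alignment(ref: Sequence[str], hyp: Sequence[str]) -> tuple[int, int, int]:
    """Unit-cost Levenshtein alignment of two token sequences.

    Returns ``(S, I, D)``.  The backtrace resolves cost ties by preferring
    substitution, then deletion, then insertion; the sum S+I+D is the edit
    distance regardless of tie-breaking.
    """
    m, n = len(ref), len(hyp)
    # cost matrix, row-major python lists (fast enough at transcript scale)
    prev = list(range(n + 1))
    rows = [prev]
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        ri = ref[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (ri != hyp[j - 1])
            dele = prev[j] + 1
            ins = cur[j - 1] + 1
            cur[j] = sub if sub <= dele and sub <= ins else (dele if dele <= ins else ins)
        rows.append(cur)
        prev = cur
    s = i_cnt = d_cnt = 0
    i, j = m, n
    while i > 0 or j > 0:
        cost = rows[i][j]
        if i > 0 and j > 0 and rows[i - 1][j - 1] + (ref[i - 1] != hyp[j - 1]) == cost:
            s += ref[i - 1] != hyp[j - 1]
            i -= 1
            j -= 1
        elif i > 0 and rows[i - 1][j] + 1 == cost:
            d_cnt += 1
            i -= 1
        else:
            i_cnt += 1
            j -= 1
    return s, i_cnt, d_cnt


def word_error_rate(reference: str, hypothesis: str) -> WERResult:
    """WER of ``hypothesis`` against ``reference``.

    Both strings are normalized (punctuation stripped, case folded,
    stutter repeats collapsed) before alignment.  Raises
    :class:`EmptyReferenceError` when the reference normalizes to zero
    tokens.
    """
    ref = normalize(reference).tokens
    hyp = normalize(hypothesis).tokens
    if not ref:
        raise EmptyReferenceError("reference transcript normalizes to zero tokens")
    s, i, d = sid_alignment(ref, hyp)
    return WERResult(N=len(ref), S=s, I=i, D=d)


def aggregate_wer(results: Iterable["WERResult | float"]) -> float:
    """Arithmetic mean WER over per-file results or raw wer values."""
    values = [r.wer if isinstance(r, WERResult) else float(r) for r in results]
    if not values:
        raise EmptyInputError("no WER values to aggregate")
    return float(np.mean(values))


def wer_table(
    rows: Mapping[str, Sequence[float]], labels: Sequence[str] | None = None
) -> str:
    """Aligned-text WER table: one row per file, an Average row per system."""
    systems = list(rows)
    n = len(next(iter(rows.values())))
    for name, col in rows.items():
        if len(col) != n:
            raise LengthMismatchError(f"column {name!r} has {len(col)} values, expected {n}")
    labels = list(labels) if labels is not None else [f"pair{i + 1}" for i in range(n)]
    width = max(7, *(len(s) for s in systems)) + 2
    lwidth = max(7, *(len(s) for s in labels)) + 2
    lines = ["".ljust(lwidth) + "".join(s.rjust(width) for s in systems)]
    for i, label in enumerate(labels):
        lines.append(
            label.ljust(lwidth)
            + "".join(f"{rows[s][i]:.2f}".rjust(width) for s in systems)
        )
    lines.append(
        "Average".ljust(lwidth)
        + "".join(
            f"{round_half_up(aggregate_wer(rows[s]), 3):.3f}".rjust(width)
            for s in systems
        )
    )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# voted appropriateness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvaluationDialogue:
    """One static-context evaluation item.

    ``candidates`` holds exactly four response strings; position 0 is the
    response the system actually gave (its position is hidden from the
    evaluators), positions 1-3 are distractors.
    """

    dialogue_id: str
    context_id: str
    turns: tuple[tuple[str, str], ...]  # (speaker, text)
    candidates: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.candidates) != N_CANDIDATES:
            raise ValueError(
                f"dialogue {self.dialogue_id}: expected {N_CANDIDATES} candidates, "
                f"got {len(self.candidates)}"
            )
        if len(self.turns) < 4:
            raise ValueError(f"dialogue {self.dialogue_id}: needs at least 4 turns")

    def to_dict(self) -> dict:
        return {
            "dialogue_id": self.dialogue_id,
            "context_id": self.context_id,
            "turns": [{"speaker": s, "text": t} for s, t in self.turns],
            "candidates": list(self.candidates),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "EvaluationDialogue":
        return cls(
            dialogue_id=doc["dialogue_id"],
            context_id=doc["context_id"],
            turns=tuple((t["speaker"], t["text"]) for t in doc["turns"]),
            candidates=tuple(doc["candidates"]),
        )


@dataclass(frozen=True)
class VoteTable:
    """Votes for one dialogue: evaluator id → chosen candidate index."""

    dialogue_id: str
    votes: Mapping[str, int]

    def __post_init__(self) -> None:
        for evaluator, idx in self.votes.items():
            if not 0 <= idx < N_CANDIDATES:
                raise InvalidVoteError(
                    f"dialogue {self.dialogue_id}: evaluator {evaluator!r} voted "
                    f"for candidate {idx}, outside 0..{N_CANDIDATES - 1}"
                )


@dataclass(frozen=True)
class RvotedResult:
    dialogue_id: str
    counts: tuple[int, int, int, int]

    @property
    def rmax(self) -> int:
        return max(self.counts)

    @property
    def n_votes(self) -> int:
        return sum(self.counts)


def rvoted(dialogue: EvaluationDialogue, votes: VoteTable) -> RvotedResult:
    """Per-candidate vote counts for one dialogue, with Rmax.

    Each evaluator contributes exactly one vote, so the counts sum to the
    number of evaluators who voted on the dialogue.
    """
    counts = [0] * N_CANDIDATES
    for idx in votes.votes.values():
        counts[idx] += 1
    return RvotedResult(dialogue_id=dialogue.dialogue_id, counts=tuple(counts))


def agreement_percentages(
    dialogues: Sequence[EvaluationDialogue], votes: Sequence[VoteTable]
) -> tuple[float, float, float, float]:
    """Share of dialogues (percent) where each position reaches Rmax.

    Ties count for every tied position, so the four percentages may sum
    above 100.  Requires one vote table per dialogue.
    """
    if len(dialogues) != len(votes):
        raise LengthMismatchError(
            f"{len(dialogues)} dialogues but {len(votes)} vote tables"
        )
    if not dialogues:
        raise EmptyInputError("no dialogues to score")
    at_max = [0] * N_CANDIDATES
    for dlg, table in zip(dialogues, votes):
        res = rvoted(dlg, table)
        for pos, count in enumerate(res.counts):
            if count == res.rmax:
                at_max[pos] += 1
    return tuple(100.0 * c / len(dialogues) for c in at_max)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p_value: float


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-test p-value.

    Requires equal lengths of at least 3 and non-constant vectors.
    """
    if len(x) != len(y):
        raise LengthMismatchError(f"len(x)={len(x)} != len(y)={len(y)}")
    if len(x) < 3:
        raise EmptyInputError("need at least 3 pairs for a correlation")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ConstantInputError("correlation is undefined for a constant vector")
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(r=float(res.statistic), n=len(x), p_value=float(res.pvalue))


@dataclass(frozen=True)
class StarRatingSummary:
    mean: float  # rounded half-up to 2 decimals
    counts: dict[int, int]
    percentages: dict[int, float]
    n: int


def star_rating_summary(ratings: Sequence[int]) -> StarRatingSummary:
    """Mean and distribution of 1-5 star ratings."""
    if not ratings:
        raise EmptyInputError("no ratings")
    for r in ratings:
        if not (isinstance(r, (int, np.integer)) and 1 <= r <= 5):
            raise RangeError(f"rating {r!r} outside 1..5")
    counts = {star: sum(1 for r in ratings if r == star) for star in range(1, 6)}
    n = len(ratings)
    return StarRatingSummary(
        mean=round_half_up(sum(ratings) / n, 2),
        counts=counts,
        percentages={star: round_half_up(100.0 * c / n, 1) for star, c in counts.items()},
        n=n,
    )


# ---------------------------------------------------------------------------
# votes CSV interface
# ---------------------------------------------------------------------------

_VOTE_COLUMNS = ["dialogue_id", "evaluator_id", "chosen_candidate"]


def read_votes_csv(path: str | Path) -> dict[str, VoteTable]:
    """Parse a votes CSV (dialogue_id, evaluator_id, chosen_candidate).

    Rows with an empty choice (scaffold rows) are skipped.  A duplicate
    (dialogue, evaluator) pair or an out-of-range candidate raises
    :class:`InvalidVoteError`.
    """
    per_dialogue: dict[str, dict[str, int]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in _VOTE_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise InvalidVoteError(f"votes CSV missing columns: {missing}")
        for row in reader:
            choice = (row["chosen_candidate"] or "").strip()
            if not choice:
                continue
            did, evaluator = row["dialogue_id"], row["evaluator_id"]
            try:
                idx = int(choice)
            except ValueError as exc:
                raise InvalidVoteError(
                    f"dialogue {did}: non-integer candidate {choice!r}"
                ) from exc
            table = per_dialogue.setdefault(did, {})
            if evaluator in table:
                raise InvalidVoteError(
                    f"dialogue {did}: evaluator {evaluator!r} voted twice"
                )
            table[evaluator] = idx
    return {did: VoteTable(dialogue_id=did, votes=votes) for did, votes in per_dialogue.items()}


def write_votes_csv_scaffold(
    path: str | Path,
    dialogues: Sequence[EvaluationDialogue],
    evaluator_ids: Sequence[str] = (),
) -> None:
    """Write an empty votes CSV for human (or synthetic) voting."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_VOTE_COLUMNS)
        for dlg in dialogues:
            for evaluator in evaluator_ids:
                writer.writerow([dlg.dialogue_id, evaluator, ""])
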