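"""Dialogue manager: turn-taking, context tracking and session logging.

A session opens in the ``beginning_conversation`` context with a rendered
greeting.  Each user turn runs the pipeline normalize → match → render:
a match in another context switches the active context; when nothing
matches (or every template skips for lack of profile data) the per-context
fallback prompt is emitted.  After two consecutive fallbacks the system
takes the initiative and proposes a new context whose customized templates
the profile can actually fill.  Matching a farewell trigger renders the
goodbye and closes the session.

Transcripts are JSONL, one turn per line; they reference the patient only
by id and never embed the profile.  Timestamps come from an injectable
clock; the default is a deterministic per-session turn counter so that
identical (profile, seed, scripted input) reproduce byte-identical logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from random import Random
from typing import Callable, Iterable

from . import kb as kbmod
from .errors import SessionClosedError
from .kb import KnowledgeBase, MatchResult, select_and_render
from .normalize import normalize
from .profiles import PatientProfile

__all__ = [
    "Turn",
    "SessionState",
    "SessionSummary",
    "DialogueEngine",
    "export_transcript",
    "import_transcript",
    "turn_counter_clock",
]

OPENING_CONTEXT = "beginning_conversation"
LEAVE_CONTEXT = "leave_conversation"


def turn_counter_clock() -> Callable[[], int]:
    """Deterministic clock: 0, 1, 2, ... per emitted turn."""
    counter = iter(range(10**9))
    return lambda: next(counter)


@dataclass(frozen=True)
class Turn:
    speaker: str  # "user" | "system"
    raw_text: str
    context_id: str
    t: float
    normalized_text: str | None = None  # user turns only

    def to_dict(self) -> dict:
        doc = {
            "speaker": self.speaker,
            "raw_text": self.raw_text,
            "context_id": self.context_id,
            "t": self.t,
        }
        if self.normalized_text is not None:
            doc["normalized_text"] = self.normalized_text
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "Turn":
        return cls(
            speaker=doc["speaker"],
            raw_text=doc["raw_text"],
            context_id=doc["context_id"],
            t=doc["t"],
            normalized_text=doc.get("normalized_text"),
        )


@dataclass
class SessionState:
    session_id: str
    patient_id: str
    profile: PatientProfile
    rng: Random
    clock: Callable[[], float]
    active_context: str = OPENING_CONTEXT
    turn_index: int = 0
    recent_responses: dict[str, list[str]] = field(default_factory=dict)
    predicate_store: dict[str, str] = field(default_factory=dict)
    transcript: list[Turn] = field(default_factory=list)
    contexts_visited: list[str] = field(default_factory=list)
    response_counts: dict[str, int] = field(default_factory=dict)
    stall_count: int = 0
    closed: bool = False
    summarized: bool = False


@dataclass(frozen=True)
class SessionSummary:
    session_id: str
    patient_id: str
    turn_count: int
    contexts_visited: tuple[str, ...]
    responses_per_context: dict[str, int]


class DialogueEngine:
    """Runs therapy sessions over a knowledge base.

    Parameters
    ----------
    kb:
        Loaded knowledge base (defaults to the shipped Spanish one).
    memory_k:
        Per-context non-repetition window: a template is not reused while
        it sits among the last ``memory_k`` responses of its context.
    n_stall:
        Consecutive fallbacks after which the system proposes a new,
        profile-populated context.
    clock_factory:
        Zero-argument callable returning a per-session clock; defaults to
        the deterministic turn counter.
    """

    def __init__(
        self,
        kb: KnowledgeBase | None = None,
        memory_k: int = 3,
        n_stall: int = 2,
        clock_factory: Callable[[], Callable[[], float]] = turn_counter_clock,
    ):
        self.kb = kb if kb is not None else kbmod.default_kb()
        self.memory_k = memory_k
        self.n_stall = n_stall
        self.clock_factory = clock_factory

    # -- session lifecycle -------------------------------------------------

    def start_session(self, profile: PatientProfile, seed: int) -> tuple[SessionState, str]:
        """Open a session and return it with the rendered greeting."""
        session = SessionState(
            session_id=f"s{seed}",
            patient_id=profile.patient_id,
            profile=profile,
            rng=Random(seed),
            clock=self.clock_factory(),
        )
        opening_cat = self.kb.opening_category(OPENING_CONTEXT)
        text = None
        if opening_cat is not None:
            text = self._render(session, opening_cat)
        if text is None:
            text = self._fallback_text(session)
        self._emit_system(session, text)
        session.contexts_visited.append(OPENING_CONTEXT)
        return session, text

    def step(self, session: SessionState, user_text: str) -> str:
        """Process one user utterance and return the system response."""
        if session.closed:
            raise SessionClosedError("session is closed")
        utt = normalize(user_text)
        session.transcript.append(
            Turn(
                speaker="user",
                raw_text=user_text,
                context_id=session.active_context,
                t=session.clock(),
                normalized_text=utt.text,
            )
        )

        response: str | None = None
        hit: MatchResult | None = kbmod.match(self.kb, utt, session.active_context)
        if (
            hit is not None
            and hit.context_id == OPENING_CONTEXT
            and session.active_context != OPENING_CONTEXT
        ):
            # the greeting context is never revisited mid-session
            hit = None
        if hit is not None:
            response = self._render(session, hit.category)
            if response is not None and hit.context_id != session.active_context:
                self._switch_context(session, hit.context_id)

        if response is None:
            session.stall_count += 1
            if session.stall_count >= self.n_stall:
                response = self._propose_context(session)
            if response is None:
                response = self._fallback_text(session)
        else:
            session.stall_count = 0

        self._emit_system(session, response)
        session.turn_index += 1
        if session.active_context == LEAVE_CONTEXT:
            session.closed = True
        return response

    def end_session(self, session: SessionState) -> SessionSummary:
        """Close the session and summarize it."""
        if session.summarized:
            raise SessionClosedError("session already ended")
        session.closed = True
        session.summarized = True
        return SessionSummary(
            session_id=session.session_id,
            patient_id=session.patient_id,
            turn_count=session.turn_index,
            contexts_visited=tuple(session.contexts_visited),
            responses_per_context=dict(session.response_counts),
        )

    # -- internals ---------------------------------------------------------

    def _render(self, session: SessionState, category) -> str | None:
        cid = category.context_id
        recent = session.recent_responses.get(cid, [])
        out = select_and_render(
            self.kb,
            category,
            session.profile,
            recent=recent,
            rng=session.rng,
            predicates=session.predicate_store,
        )
        if out is None:
            return None
        text, template_id = out
        mem = session.recent_responses.setdefault(cid, [])
        mem.append(template_id)
        del mem[:-self.memory_k]
        return text

    def _fallback_text(self, session: SessionState) -> str:
        cat = self.kb.fallback_category(session.active_context)
        if cat is not None:
            text = self._render(session, cat)
            if text is not None:
                return text
        return "¿Me cuentas un poco más?"

    def _populated_contexts(self, session: SessionState) -> list[str]:
        """Contexts whose introduction the profile can personalize."""
        out = []
        for cid, ctx in self.kb.contexts.items():
            if cid in (OPENING_CONTEXT, LEAVE_CONTEXT, session.active_context):
                continue
            intro = self.kb.intro_category(cid)
            if intro is None:
                continue
            for t in intro.templates:
                if t.is_srai:
                    continue
                slots = t.required_slots
                if slots and all(session.profile.get_slot(s) is not None for s in slots):
                    out.append(cid)
                    break
        return out

    def _propose_context(self, session: SessionState) -> str | None:
        candidates = self._populated_contexts(session)
        if not candidates:
            return None
        target = candidates[session.rng.randrange(len(candidates))]
        intro = self.kb.intro_category(target)
        if intro is None:
            return None
        text = self._render_in_context(session, target, intro)
        if text is None:
            return None
        self._switch_context(session, target)
        session.stall_count = 0
        return text

    def _render_in_context(self, session, cid, category) -> str | None:
        return self._render(session, category)

    def _switch_context(self, session: SessionState, cid: str) -> None:
        session.active_context = cid
        if cid not in session.contexts_visited:
            session.contexts_visited.append(cid)

    def _emit_system(self, session: SessionState, text: str) -> None:
        session.transcript.append(
            Turn(
                speaker="system",
                raw_text=text,
                context_id=session.active_context,
                t=session.clock(),
            )
        )
        session.response_counts[session.active_context] = (
            session.response_counts.get(session.active_context, 0) + 1
        )


# ---------------------------------------------------------------------------
# transcript I/O
# ---------------------------------------------------------------------------

def export_transcript(session: SessionState) -> str:
    """Serialize the transcript as JSONL, one turn per line."""
    return "".join(
        json.dumps(turn.to_dict(), ensure_ascii=False) + "\n"
        for turn in session.transcript
    )


def import_transcript(text: str) -> list[Turn]:
    """Parse a JSONL transcript back into turns (lossless round-trip)."""
    return [Turn.from_dict(json.loads(line)) for line in text.splitlines() if line.strip()]
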