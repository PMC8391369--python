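"""Patient profiles: the personalization record behind every dialogue.

A profile answers a fixed questionnaire organised in three topic blocks —
personal information (11 questions), family relationships (4) and life
history / lifestyle (17), 32 questions in total.  Each question defines a
*slot* (``patient_name``, ``comida_favorita``, ...) whose value can be
substituted into customized dialogue templates.  Registered family members
additionally expose the derived slots ``fam<i>_name`` and
``parentesco_fam<i>`` (name and kinship term of the i-th relative).

Profiles are stored one JSON document per patient in a directory store.
When a patient withdraws, :meth:`ProfileStore.delete_profile` removes the
profile document *and* every session log referencing the patient, and
reports what was removed.
"""

from __future__ import annotations

import json
import re
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import NotFoundError, SchemaError, UnknownSlotError

__all__ = [
    "Question",
    "TopicBlock",
    "ProfileSchema",
    "FamilyMember",
    "PatientProfile",
    "DeletionReport",
    "ProfileStore",
    "load_schema",
    "default_schema",
]

#: Required block identifiers and their question counts.
EXPECTED_BLOCKS: dict[str, int] = {
    "personal_information": 11,
    "family_relationships": 4,
    "life_history_lifestyle": 17,
}

_VALUE_KINDS = {"free_text", "date", "enum"}

_FAM_NAME_RE = re.compile(r"^fam([1-9]\d*)_name$")
_FAM_REL_RE = re.compile(r"^parentesco_fam([1-9]\d*)$")


@dataclass(frozen=True)
class Question:
    slot_name: str
    prompt_text: str
    value_kind: str = "free_text"
    required: bool = False


@dataclass(frozen=True)
class TopicBlock:
    topic_id: str
    questions: tuple[Question, ...]


@dataclass(frozen=True)
class ProfileSchema:
    """The validated questionnaire: 3 blocks, 11 + 4 + 17 = 32 questions."""

    blocks: tuple[TopicBlock, ...]

    @property
    def slot_names(self) -> tuple[str, ...]:
        return tuple(q.slot_name for b in self.blocks for q in b.questions)

    def __contains__(self, slot_name: str) -> bool:
        return slot_name in set(self.slot_names)

    def __len__(self) -> int:
        return sum(len(b.questions) for b in self.blocks)


def load_schema(source: str | Path | Mapping) -> ProfileSchema:
    """Parse and validate a questionnaire schema document.

    ``source`` is a path to a JSON document or an already-parsed mapping
    with a ``topics`` list of blocks.  Raises :class:`SchemaError` when the
    block structure deviates from the 11/4/17 layout or a slot name is
    duplicated.
    """
    if isinstance(source, (str, Path)):
        doc = json.loads(Path(source).read_text(encoding="utf-8"))
    else:
        doc = source
    try:
        raw_blocks = doc["topics"]
    except (KeyError, TypeError) as exc:
        raise SchemaError("schema document has no 'topics' list") from exc

    if len(raw_blocks) != len(EXPECTED_BLOCKS):
        raise SchemaError(
            f"expected {len(EXPECTED_BLOCKS)} topic blocks, found {len(raw_blocks)}"
        )

    blocks: list[TopicBlock] = []
    for raw, (topic_id, count) in zip(raw_blocks, EXPECTED_BLOCKS.items()):
        if raw.get("topic_id") != topic_id:
            raise SchemaError(
                f"topic block {raw.get('topic_id')!r} out of order; expected {topic_id!r}"
            )
        questions = []
        for q in raw.get("questions", []):
            kind = q.get("value_kind", "free_text")
            if kind not in _VALUE_KINDS:
                raise SchemaError(f"unknown value_kind {kind!r} for slot {q.get('slot_name')!r}")
            questions.append(
                Question(
                    slot_name=q["slot_name"],
                    prompt_text=q["prompt_text"],
                    value_kind=kind,
                    required=bool(q.get("required", False)),
                )
            )
        if len(questions) != count:
            raise SchemaError(
                f"block {topic_id!r} must contain {count} questions, found {len(questions)}"
            )
        blocks.append(TopicBlock(topic_id=topic_id, questions=tuple(questions)))

    schema = ProfileSchema(blocks=tuple(blocks))
    names = schema.slot_names
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise SchemaError(f"duplicate slot names: {sorted(dupes)}")
    for name in names:
        if _FAM_NAME_RE.match(name) or _FAM_REL_RE.match(name):
            raise SchemaError(f"slot {name!r} collides with derived family slots")
    return schema


_DEFAULT_SCHEMA: ProfileSchema | None = None


def default_schema() -> ProfileSchema:
    """The questionnaire shipped with the package (cached)."""
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        with resources.files("recuerda.data").joinpath("schema.json").open(
            "r", encoding="utf-8"
        ) as fh:
            _DEFAULT_SCHEMA = load_schema(json.load(fh))
    return _DEFAULT_SCHEMA


@dataclass(frozen=True)
class FamilyMember:
    """One registered relative; positions are contiguous starting at 1."""

    index: int
    name: str
    relationship: str


@dataclass
class PatientProfile:
    """One patient's answers plus registered family members.

    ``answers`` holds only answered slots; a missing answer is represented
    by absence, never by an empty string.
    """

    patient_id: str
    answers: dict[str, str]
    family: tuple[FamilyMember, ...] = ()
    created_at: str = ""

    def get_slot(self, slot_name: str) -> str | None:
        """Stored value, derived family slot, or ``None`` — never raises."""
        if slot_name in self.answers:
            return self.answers[slot_name]
        m = _FAM_NAME_RE.match(slot_name)
        if m:
            i = int(m.group(1))
            return self.family[i - 1].name if i <= len(self.family) else None
        m = _FAM_REL_RE.match(slot_name)
        if m:
            i = int(m.group(1))
            return self.family[i - 1].relationship if i <= len(self.family) else None
        return None

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "answers": dict(self.answers),
            "family": [
                {"index": f.index, "name": f.name, "relationship": f.relationship}
                for f in self.family
            ],
            "created_at": self.created_at,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PatientProfile":
        return cls(
            patient_id=doc["patient_id"],
            answers=dict(doc["answers"]),
            family=tuple(
                FamilyMember(index=f["index"], name=f["name"], relationship=f["relationship"])
                for f in doc.get("family", [])
            ),
            created_at=doc.get("created_at", ""),
        )


def _validate_family(family: Iterable[FamilyMember]) -> tuple[FamilyMember, ...]:
    fam = tuple(family)
    for pos, member in enumerate(fam, start=1):
        if member.index != pos:
            raise SchemaError(
                f"family member indices must be contiguous from 1; "
                f"position {pos} has index {member.index}"
            )
        if not member.name.strip() or not member.relationship.strip():
            raise SchemaError("family member name and relationship must be non-empty")
    return fam


def build_profile(
    schema: ProfileSchema,
    answers: Mapping[str, str],
    family: Iterable[FamilyMember] = (),
    patient_id: str | None = None,
    created_at: str | None = None,
) -> PatientProfile:
    """Validate answers against ``schema`` and assemble a profile.

    Unknown answer keys raise :class:`UnknownSlotError`.  Values are
    trimmed; answers that trim to the empty string are treated as
    unanswered and stored as absent.
    """
    known = set(schema.slot_names)
    clean: dict[str, str] = {}
    for key, value in answers.items():
        if key not in known:
            raise UnknownSlotError(f"{key!r} is not a slot of the questionnaire schema")
        trimmed = str(value).strip()
        if trimmed:
            clean[key] = trimmed
    return PatientProfile(
        patient_id=patient_id or f"pwad-{uuid.uuid4().hex[:12]}",
        answers=clean,
        family=_validate_family(family),
        created_at=created_at
        or datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )


@dataclass(frozen=True)
class DeletionReport:
    patient_id: str
    removed_profile: str
    removed_session_logs: tuple[str, ...]


class ProfileStore:
    """Directory-backed store: one JSON document per profile.

    Layout::

        <root>/profiles/<patient_id>.json
        <root>/sessions/<patient_id>/<session_id>.jsonl
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        (self.root / "profiles").mkdir(parents=True, exist_ok=True)
        (self.root / "sessions").mkdir(parents=True, exist_ok=True)

    # -- paths ------------------------------------------------------------

    def _profile_path(self, patient_id: str) -> Path:
        return self.root / "profiles" / f"{patient_id}.json"

    def session_dir(self, patient_id: str) -> Path:
        return self.root / "sessions" / patient_id

    # -- CRUD -------------------------------------------------------------

    def create_profile(
        self,
        schema: ProfileSchema,
        answers: Mapping[str, str],
        family: Iterable[FamilyMember] = (),
        patient_id: str | None = None,
        created_at: str | None = None,
    ) -> PatientProfile:
        profile = build_profile(schema, answers, family, patient_id, created_at)
        self.save(profile)
        return profile

    def save(self, profile: PatientProfile) -> None:
        path = self._profile_path(profile.patient_id)
        path.write_text(
            json.dumps(profile.to_dict(), ensure_ascii=False, indent=2) + "\n",
            encoding="utf-8",
        )

    def load(self, patient_id: str) -> PatientProfile:
        path = self._profile_path(patient_id)
        if not path.exists():
            raise NotFoundError(f"no profile stored under id {patient_id!r}")
        return PatientProfile.from_dict(json.loads(path.read_text(encoding="utf-8")))

    def list_ids(self) -> list[str]:
        return sorted(p.stem for p in (self.root / "profiles").glob("*.json"))

    def save_session_log(self, patient_id: str, session_id: str, jsonl_text: str) -> Path:
        d = self.session_dir(patient_id)
        d.mkdir(parents=True, exist_ok=True)
        path = d / f"{session_id}.jsonl"
        path.write_text(jsonl_text, encoding="utf-8")
        return path

    def delete_profile(self, patient_id: str) -> DeletionReport:
        """Remove every trace of ``patient_id`` from the store.

        Deletes the profile document and all session logs; the report
        lists each removed file.  Raises :class:`NotFoundError` when the
        id is unknown.
        """
        path = self._profile_path(patient_id)
        if not path.exists():
            raise NotFoundError(f"no profile stored under id {patient_id!r}")
        removed_logs: list[str] = []
        sess = self.session_dir(patient_id)
        if sess.exists():
            for log in sorted(sess.glob("*")):
                removed_logs.append(str(log))
                log.unlink()
            sess.rmdir()
        path.unlink()
        return DeletionReport(
            patient_id=patient_id,
            removed_profile=str(path),
            removed_session_logs=tuple(removed_logs),
        )
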