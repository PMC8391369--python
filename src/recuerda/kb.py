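"""AIML-subset knowledge base: pattern matching and template rendering.

The conversation is organised in 20 dialogue contexts (greetings, family,
hobbies, food dishes, ...), each authored as one XML file in a small AIML
dialect (see ``data/DIALECT.md``).  A *category* pairs a token pattern —
possibly containing the wildcards ``_`` and ``*`` — with one or more
response templates.  Templates are *generic* (plain text) or *customized*
(they substitute patient-profile slots via ``<get name="..."/>``).

Matching follows classic graphmaster semantics: the active context is
searched first, then the context-switch triggers of the other contexts,
then the global categories; within a tier priority is ``_`` > exact token
> ``*``, resolved left to right.  Both wildcards consume one or more
tokens; captured spans are returned as bindings.

Rendering selects a template seeded-uniformly among those not in the
session's recent-response memory, skipping customized templates whose
slots are absent from the profile; a category whose templates all skip
yields ``None`` and the dialogue layer falls back.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from random import Random
from typing import Iterable, Mapping, Sequence

from .errors import KBSlotError, KBSyntaxError
from .normalize import NormalizedUtterance, normalize
from .profiles import PatientProfile, ProfileSchema, default_schema

__all__ = [
    "TABLE_OF_CONTEXTS",
    "GLOBAL_TOPIC",
    "Literal",
    "SlotRef",
    "Conditional",
    "SraiRef",
    "ResponseTemplate",
    "DialogueCategory",
    "DialogueContext",
    "MatchResult",
    "KnowledgeBase",
    "load_kb",
    "default_kb",
    "match",
    "render_template",
    "select_and_render",
    "lint_kb",
    "LintFinding",
]

#: The 20 dialogue contexts the shipped knowledge base covers, with the
#: conversational topic each one addresses.
TABLE_OF_CONTEXTS: dict[str, str] = {
    "beginning_conversation": "Beginning conversation",
    "leave_conversation": "Leave conversation",
    "agent_profile": "Agent profile",
    "pwad_profile": "PwAD profile",
    "family": "Family",
    "habits": "Habits",
    "skills": "Skills",
    "hobbies": "Hobbies",
    "household_chores": "Household chores",
    "visited_places": "Visited places",
    "movies": "Movies",
    "tv_shows": "TV shows",
    "actors": "Actors",
    "music": "Music",
    "singers": "Singers",
    "sports": "Sports",
    "sport_teams": "Sport teams",
    "food_dishes": "Food dishes",
    "beverages": "Beverages",
    "festivities": "Festivities",
}

#: Reserved topic name for categories reachable from any context.
GLOBAL_TOPIC = "global"

WILDCARDS = ("_", "*")

_ROLES = {"normal", "trigger", "fallback", "opening"}
_MAX_SRAI_DEPTH = 10


# ---------------------------------------------------------------------------
# template parts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Literal:
    text: str


@dataclass(frozen=True)
class SlotRef:
    name: str


@dataclass(frozen=True)
class Conditional:
    """Render inner parts only when ``slot`` has a value.

    The dialect restricts the inner parts to literals and references to
    the guarding slot itself, so a satisfied condition can never leave a
    dangling placeholder.
    """

    slot: str
    parts: tuple["Literal | SlotRef", ...]


@dataclass(frozen=True)
class SraiRef:
    """Redirect: re-match ``text`` as if the user had said it."""

    text: str


Part = "Literal | SlotRef | Conditional | SraiRef"


@dataclass(frozen=True)
class ResponseTemplate:
    """One renderable response: literal and slot-reference segments."""

    template_id: str
    parts: tuple
    follow_up: bool = field(default=False)

    @property
    def is_srai(self) -> bool:
        return len(self.parts) == 1 and isinstance(self.parts[0], SraiRef)

    @property
    def required_slots(self) -> tuple[str, ...]:
        """Slots that must be present for the template to render."""
        out = []
        for p in self.parts:
            if isinstance(p, SlotRef):
                out.append(p.name)
        return tuple(dict.fromkeys(out))

    @property
    def referenced_slots(self) -> tuple[str, ...]:
        out = []
        for p in self.parts:
            if isinstance(p, SlotRef):
                out.append(p.name)
            elif isinstance(p, Conditional):
                out.append(p.slot)
        return tuple(dict.fromkeys(out))

    @property
    def static_text(self) -> str:
        """Template text with slot references elided (for linting)."""
        chunks = []
        for p in self.parts:
            if isinstance(p, Literal):
                chunks.append(p.text)
            elif isinstance(p, Conditional):
                chunks.extend(q.text for q in p.parts if isinstance(q, Literal))
        return "".join(chunks)


@dataclass(frozen=True)
class DialogueCategory:
    context_id: str
    pattern: tuple[str, ...]
    templates: tuple[ResponseTemplate, ...]
    role: str = "normal"

    @property
    def kind(self) -> str:
        """``customized`` when any template references a profile slot."""
        for t in self.templates:
            if t.referenced_slots:
                return "customized"
        return "generic"


@dataclass(frozen=True)
class DialogueContext:
    context_id: str
    description: str
    categories: tuple[DialogueCategory, ...]


@dataclass(frozen=True)
class MatchResult:
    context_id: str
    category: DialogueCategory
    bindings: tuple[tuple[str, ...], ...]


# ---------------------------------------------------------------------------
# graphmaster trie
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("children", "category")

    def __init__(self) -> None:
        self.children: dict[str, _Node] = {}
        self.category: DialogueCategory | None = None


class Graphmaster:
    """Token trie with classic AIML branch priority ``_`` > word > ``*``."""

    def __init__(self) -> None:
        self.root = _Node()
        self.duplicates: list[tuple[str, ...]] = []

    def insert(self, category: DialogueCategory) -> None:
        node = self.root
        for tok in category.pattern:
            node = node.children.setdefault(tok, _Node())
        if node.category is not None:
            self.duplicates.append(category.pattern)
            return  # first-loaded category wins
        node.category = category

    def search(
        self, tokens: Sequence[str]
    ) -> tuple[DialogueCategory, tuple[tuple[str, ...], ...]] | None:
        return self._search(self.root, tuple(tokens), ())

    def _search(self, node, tokens, bound):
        if not tokens:
            if node.category is not None:
                return node.category, bound
            return None
        child = node.children.get("_")
        if child is not None:
            for i in range(1, len(tokens) + 1):
                hit = self._search(child, tokens[i:], bound + (tokens[:i],))
                if hit is not None:
                    return hit
        child = node.children.get(tokens[0])
        if child is not None:
            hit = self._search(child, tokens[1:], bound)
            if hit is not None:
                return hit
        child = node.children.get("*")
        if child is not None:
            for i in range(1, len(tokens) + 1):
                hit = self._search(child, tokens[i:], bound + (tokens[:i],))
                if hit is not None:
                    return hit
        return None


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_ALLOWED_TEMPLATE_TAGS = {"random", "li", "get", "srai", "condition"}


def _parse_pattern(text: str | None, source: str) -> tuple[str, ...]:
    if text is None or not text.split():
        raise KBSyntaxError(f"{source}: empty pattern")
    tokens: list[str] = []
    for word in text.split():
        if word in WILDCARDS:
            tokens.append(word)
            continue
        norm = normalize(word).tokens
        if len(norm) != 1:
            raise KBSyntaxError(
                f"{source}: pattern word {word!r} does not normalize to one token"
            )
        tokens.append(norm[0])
    return tuple(tokens)


def _parse_inline(elem: ET.Element, source: str) -> list:
    """Parse the mixed content of a template or <li> into parts."""
    parts: list = []

    def add_text(text: str | None) -> None:
        if text:
            parts.append(Literal(text))

    add_text(elem.text)
    for child in elem:
        tag = child.tag
        if tag == "get":
            name = child.attrib.get("name")
            if not name:
                raise KBSyntaxError(f"{source}: <get> without name attribute")
            parts.append(SlotRef(name))
        elif tag == "condition":
            slot = child.attrib.get("name")
            if not slot:
                raise KBSyntaxError(f"{source}: <condition> without name attribute")
            inner: list = []
            if child.text:
                inner.append(Literal(child.text))
            for sub in child:
                if sub.tag != "get":
                    raise KBSyntaxError(
                        f"{source}: only <get> allowed inside <condition>, found <{sub.tag}>"
                    )
                if sub.attrib.get("name") != slot:
                    raise KBSyntaxError(
                        f"{source}: <get name={sub.attrib.get('name')!r}> inside "
                        f"<condition name={slot!r}> must reference the guarding slot"
                    )
                inner.append(SlotRef(slot))
                if sub.tail:
                    inner.append(Literal(sub.tail))
            parts.append(Conditional(slot=slot, parts=tuple(inner)))
        elif tag == "srai":
            if (child.text or "").strip() == "":
                raise KBSyntaxError(f"{source}: empty <srai>")
            parts.append(SraiRef(child.text.strip()))
        elif tag in _ALLOWED_TEMPLATE_TAGS:
            raise KBSyntaxError(f"{source}: <{tag}> not allowed here")
        else:
            raise KBSyntaxError(f"{source}: unknown tag <{tag}>")
        add_text(child.tail)
    # srai must stand alone
    if any(isinstance(p, SraiRef) for p in parts):
        meaningful = [
            p for p in parts
            if not (isinstance(p, Literal) and not p.text.strip())
        ]
        if len(meaningful) != 1:
            raise KBSyntaxError(f"{source}: <srai> must be the whole template")
        return [meaningful[0]]
    return parts


def _strip_literal_edges(parts: list) -> tuple:
    out = list(parts)
    if out and isinstance(out[0], Literal):
        out[0] = Literal(out[0].text.lstrip())
    if out and isinstance(out[-1], Literal):
        out[-1] = Literal(out[-1].text.rstrip())
    return tuple(p for p in out if not (isinstance(p, Literal) and p.text == ""))


def _mk_template(parts: list, template_id: str) -> ResponseTemplate:
    clean = _strip_literal_edges(parts)
    follow_up = False
    if clean and isinstance(clean[-1], Literal):
        follow_up = clean[-1].text.rstrip().endswith("?")
    return ResponseTemplate(template_id=template_id, parts=clean, follow_up=follow_up)


def _parse_template(elem: ET.Element, source: str, base_id: str) -> tuple[ResponseTemplate, ...]:
    randoms = [c for c in elem if c.tag == "random"]
    if randoms:
        if len(randoms) != 1 or (elem.text or "").strip() or len(list(elem)) != 1:
            raise KBSyntaxError(f"{source}: <random> must be the whole template")
        templates = []
        for i, li in enumerate(randoms[0]):
            if li.tag != "li":
                raise KBSyntaxError(f"{source}: <random> may contain only <li>")
            templates.append(_mk_template(_parse_inline(li, source), f"{base_id}.{i}"))
        if not templates:
            raise KBSyntaxError(f"{source}: empty <random>")
        return tuple(templates)
    return (_mk_template(_parse_inline(elem, source), f"{base_id}.0"),)


def _valid_slot(name: str, schema: ProfileSchema) -> bool:
    if name in schema:
        return True
    import re

    return bool(re.match(r"^fam[1-9]\d*_name$", name) or re.match(r"^parentesco_fam[1-9]\d*$", name))


@dataclass
class ValidationReport:
    warnings: list[str] = field(default_factory=list)
    missing_contexts: list[str] = field(default_factory=list)
    extra_contexts: list[str] = field(default_factory=list)


class KnowledgeBase:
    """In-memory knowledge base indexed by dialogue context."""

    def __init__(
        self,
        contexts: dict[str, DialogueContext],
        global_categories: tuple[DialogueCategory, ...],
        schema: ProfileSchema,
        validation: ValidationReport,
    ):
        self.contexts = contexts
        self.global_categories = global_categories
        self.schema = schema
        self.validation = validation
        # per-context tries over matchable categories (not fallback/opening)
        self._context_tries: dict[str, Graphmaster] = {}
        for cid, ctx in contexts.items():
            gm = Graphmaster()
            for cat in ctx.categories:
                if cat.role in ("normal", "trigger"):
                    gm.insert(cat)
            self._context_tries[cid] = gm
            validation.warnings.extend(
                f"{cid}: duplicate pattern {' '.join(p)}" for p in gm.duplicates
            )
        # trigger trie across all contexts (context-switch tier)
        self._trigger_trie = Graphmaster()
        self._trigger_context: dict[int, str] = {}
        for cid, ctx in contexts.items():
            for cat in ctx.categories:
                if cat.role == "trigger":
                    self._trigger_trie.insert(cat)
        # global tier
        self._global_trie = Graphmaster()
        for cat in global_categories:
            if cat.role in ("normal", "trigger"):
                self._global_trie.insert(cat)

    # convenience -----------------------------------------------------------

    def context_ids(self) -> list[str]:
        return list(self.contexts)

    def fallback_category(self, context_id: str) -> DialogueCategory | None:
        ctx = self.contexts.get(context_id)
        if ctx is not None:
            for cat in ctx.categories:
                if cat.role == "fallback":
                    return cat
        for cat in self.global_categories:
            if cat.role == "fallback":
                return cat
        return None

    def opening_category(self, context_id: str) -> DialogueCategory | None:
        ctx = self.contexts.get(context_id)
        if ctx is None:
            return None
        for cat in ctx.categories:
            if cat.role == "opening":
                return cat
        return None

    def intro_category(self, context_id: str) -> DialogueCategory | None:
        """Category used when the system itself proposes this context."""
        ctx = self.contexts.get(context_id)
        if ctx is None:
            return None
        for cat in ctx.categories:
            if cat.role == "trigger" and not all(t.is_srai for t in cat.templates):
                return cat
        return self.fallback_category(context_id)


def _parse_file(path: Path, schema: ProfileSchema):
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise KBSyntaxError(f"{path.name}: malformed XML ({exc})") from exc
    root = tree.getroot()
    if root.tag != "aiml":
        raise KBSyntaxError(f"{path.name}: root element must be <aiml>, found <{root.tag}>")
    out: list[tuple[str, str, DialogueCategory]] = []  # (topic, description, category)
    for topic in root:
        if topic.tag != "topic":
            raise KBSyntaxError(f"{path.name}: expected <topic>, found <{topic.tag}>")
        topic_name = topic.attrib.get("name")
        if not topic_name:
            raise KBSyntaxError(f"{path.name}: <topic> without name attribute")
        description = topic.attrib.get("description", "")
        for k, cat_el in enumerate(topic):
            if cat_el.tag != "category":
                raise KBSyntaxError(f"{path.name}: expected <category>, found <{cat_el.tag}>")
            role = cat_el.attrib.get("role", "normal")
            if role not in _ROLES:
                raise KBSyntaxError(f"{path.name}: unknown category role {role!r}")
            pattern_el = cat_el.find("pattern")
            template_el = cat_el.find("template")
            if pattern_el is None or template_el is None:
                raise KBSyntaxError(
                    f"{path.name}: <category> needs <pattern> and <template>"
                )
            for child in cat_el:
                if child.tag not in ("pattern", "template"):
                    raise KBSyntaxError(f"{path.name}: unknown tag <{child.tag}> in category")
            source = f"{path.name}:{topic_name}[{k}]"
            pattern = _parse_pattern(pattern_el.text, source)
            templates = _parse_template(template_el, source, f"{topic_name}/{k}")
            for t in templates:
                for slot in t.referenced_slots:
                    if not _valid_slot(slot, schema):
                        raise KBSlotError(
                            f"{source}: template references unknown slot {slot!r}"
                        )
            out.append(
                (topic_name, description,
                 DialogueCategory(context_id=topic_name, pattern=pattern,
                                  templates=templates, role=role))
            )
    return out


def load_kb(
    paths: Iterable[str | Path],
    schema: ProfileSchema | None = None,
    expected_contexts: Mapping[str, str] | None = TABLE_OF_CONTEXTS,
) -> KnowledgeBase:
    """Load and validate knowledge-base files.

    Raises :class:`KBSyntaxError` for malformed XML or tags outside the
    dialect and :class:`KBSlotError` for slot references absent from the
    profile schema.  A validation report (missing/extra contexts versus
    the shipped 20, duplicate patterns) is attached to the returned KB.
    """
    schema = schema or default_schema()
    by_context: dict[str, list[DialogueCategory]] = {}
    descriptions: dict[str, str] = {}
    global_cats: list[DialogueCategory] = []
    for path in paths:
        for topic_name, description, cat in _parse_file(Path(path), schema):
            if topic_name == GLOBAL_TOPIC:
                global_cats.append(cat)
                continue
            by_context.setdefault(topic_name, []).append(cat)
            if description:
                descriptions[topic_name] = description

    report = ValidationReport()
    if expected_contexts is not None:
        report.missing_contexts = [c for c in expected_contexts if c not in by_context]
        report.extra_contexts = [c for c in by_context if c not in expected_contexts]
        report.warnings.extend(f"missing context: {c}" for c in report.missing_contexts)
        report.warnings.extend(f"context not in the shipped table: {c}" for c in report.extra_contexts)

    contexts = {
        cid: DialogueContext(
            context_id=cid,
            description=descriptions.get(cid, ""),
            categories=tuple(cats),
        )
        for cid, cats in by_context.items()
    }
    for cid, ctx in contexts.items():
        if not ctx.categories:
            raise KBSyntaxError(f"context {cid} has no categories")
    return KnowledgeBase(contexts, tuple(global_cats), schema, report)


def default_kb(schema: ProfileSchema | None = None) -> KnowledgeBase:
    """Load the Spanish knowledge base shipped with the package."""
    data = resources.files("recuerda.data").joinpath("kb")
    with resources.as_file(data) as kb_dir:
        paths = sorted(Path(kb_dir).glob("*.aiml"))
        return load_kb(paths, schema=schema)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match(
    kb: KnowledgeBase,
    utterance: NormalizedUtterance | Sequence[str],
    active_context: str,
) -> MatchResult | None:
    """Find the highest-priority category matching ``utterance``.

    Search order: categories of the active context, then the
    context-switch triggers of every context, then the global categories.
    Within a tier, classic graphmaster priority applies.  Returns ``None``
    on no match.
    """
    tokens = utterance.tokens if isinstance(utterance, NormalizedUtterance) else tuple(utterance)
    if not tokens:
        return None
    tiers = []
    if active_context in kb._context_tries:
        tiers.append(kb._context_tries[active_context])
    tiers.append(kb._trigger_trie)
    tiers.append(kb._global_trie)
    for trie in tiers:
        hit = trie.search(tokens)
        if hit is not None:
            cat, bindings = hit
            return MatchResult(context_id=cat.context_id, category=cat, bindings=bindings)
    return None


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_template(
    template: ResponseTemplate,
    profile: PatientProfile,
    predicates: Mapping[str, str] | None = None,
) -> str | None:
    """Substitute slot values into one template.

    Returns the rendered text, or ``None`` (skip) when a required slot has
    no value.  Slot lookup order: profile (including derived family
    slots), then the session predicate store.
    """
    predicates = predicates or {}

    def lookup(name: str) -> str | None:
        value = profile.get_slot(name)
        if value is None:
            value = predicates.get(name)
        return value

    chunks: list[str] = []
    for part in template.parts:
        if isinstance(part, Literal):
            chunks.append(part.text)
        elif isinstance(part, SlotRef):
            value = lookup(part.name)
            if value is None:
                return None
            chunks.append(value)
        elif isinstance(part, Conditional):
            value = lookup(part.slot)
            if value is None:
                continue
            for inner in part.parts:
                chunks.append(inner.text if isinstance(inner, Literal) else value)
        elif isinstance(part, SraiRef):
            raise ValueError("srai templates must be resolved by select_and_render")
    return "".join(chunks)


def select_and_render(
    kb: KnowledgeBase,
    category: DialogueCategory,
    profile: PatientProfile,
    recent: Sequence[str] = (),
    rng: Random | int | None = None,
    predicates: Mapping[str, str] | None = None,
    _depth: int = 0,
) -> tuple[str, str] | None:
    """Pick one template of ``category`` and render it.

    Templates whose ids appear in ``recent`` (the per-context
    non-repetition memory) are avoided when a fresh alternative renders;
    selection among eligible templates is uniform under the seeded
    ``rng``.  Returns ``(text, template_id)`` or ``None`` when every
    template skips.
    """
    if _depth > _MAX_SRAI_DEPTH:
        return None
    if rng is None or isinstance(rng, int):
        rng = Random(rng)

    rendered: list[tuple[str, str]] = []  # (template_id, text)
    for t in category.templates:
        if t.is_srai:
            redirect = match(kb, normalize(t.parts[0].text), category.context_id)
            if redirect is None:
                continue
            sub = select_and_render(
                kb, redirect.category, profile, recent, rng, predicates, _depth + 1
            )
            if sub is not None:
                rendered.append((t.template_id, sub[0]))
            continue
        text = render_template(t, profile, predicates)
        if text is not None:
            rendered.append((t.template_id, text))
    if not rendered:
        return None
    fresh = [r for r in rendered if r[0] not in recent]
    pool = fresh or rendered
    template_id, text = pool[rng.randrange(len(pool))]
    return text, template_id


# ---------------------------------------------------------------------------
# linting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LintFinding:
    kind: str  # "no_question" | "single_template" | "long_sentence"
    context_id: str
    detail: str


def lint_kb(kb: KnowledgeBase, max_words: int = 20) -> list[LintFinding]:
    """Check the authored KB against the dementia-communication strategy.

    Findings: (a) templates outside ``leave_conversation`` that do not end
    with a question (every turn should invite the patient to continue);
    (b) contexts offering a single response template (repetition risk);
    (c) sentences longer than ``max_words`` words (responses should stay
    simple and short).
    """
    findings: list[LintFinding] = []
    for cid, ctx in kb.contexts.items():
        n_templates = 0
        for cat in ctx.categories:
            for t in cat.templates:
                if t.is_srai:
                    continue
                n_templates += 1
                if cid != "leave_conversation" and not t.follow_up:
                    findings.append(
                        LintFinding("no_question", cid,
                                    f"template {t.template_id} does not end with a question")
                    )
                for sentence in _sentences(t.static_text):
                    if len(sentence.split()) > max_words:
                        findings.append(
                            LintFinding("long_sentence", cid,
                                        f"template {t.template_id}: {sentence[:40]!r}...")
                        )
        if n_templates == 1:
            findings.append(
                LintFinding("single_template", cid, "context offers a single response")
            )
    return findings


def _sentences(text: str) -> list[str]:
    import re

    parts = re.split(r"[.!?¡¿]+", text)
    return [p.strip() for p in parts if p.strip()]
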