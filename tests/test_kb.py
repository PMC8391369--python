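"""Knowledge base: loading, graphmaster matching, rendering, linting."""

from random import Random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import recuerda as rc
from recuerda.errors import KBSlotError, KBSyntaxError
from recuerda.kb import (
    TABLE_OF_CONTEXTS,
    DialogueCategory,
    Graphmaster,
    Literal,
    ResponseTemplate,
    lint_kb,
    load_kb,
    match,
    render_template,
    select_and_render,
)
from recuerda.normalize import normalize

# ---------------------------------------------------------------------------
# loading & validation
# ---------------------------------------------------------------------------


def test_shipped_kb_covers_all_contexts(kb):
    assert set(kb.contexts) == set(TABLE_OF_CONTEXTS)
    assert len(kb.contexts) == 20
    assert kb.validation.missing_contexts == []
    for ctx in kb.contexts.values():
        assert len(ctx.categories) >= 1


def test_every_context_offers_generic_and_customized_mix(kb):
    kinds = {
        cid: {c.kind for c in ctx.categories}
        for cid, ctx in kb.contexts.items()
    }
    # most contexts personalize; a few (greetings, agent) may be fully generic
    assert sum("customized" in k for k in kinds.values()) >= 15


def _write_kb(tmp_path, body, name="mini.aiml"):
    path = tmp_path / name
    path.write_text(body, encoding="utf-8")
    return path


def test_unknown_tag_rejected(tmp_path):
    path = _write_kb(
        tmp_path,
        """<aiml><topic name="family"><category><pattern>HOLA</pattern>
        <template><think>x</think>¿Sí?</template></category></topic></aiml>""",
    )
    with pytest.raises(KBSyntaxError):
        load_kb([path])


def test_malformed_xml_rejected(tmp_path):
    path = _write_kb(tmp_path, "<aiml><topic name='x'>")
    with pytest.raises(KBSyntaxError):
        load_kb([path])


def test_unknown_slot_rejected(tmp_path):
    path = _write_kb(
        tmp_path,
        """<aiml><topic name="family"><category><pattern>HOLA</pattern>
        <template>¿Te gusta <get name="xyz"/>?</template></category></topic></aiml>""",
    )
    with pytest.raises(KBSlotError):
        load_kb([path])


def test_missing_context_reported_as_warning(tmp_path):
    path = _write_kb(
        tmp_path,
        """<aiml><topic name="family"><category><pattern>HOLA</pattern>
        <template>¿Cómo estás?</template></category></topic></aiml>""",
    )
    kb = load_kb([path])
    assert "beginning_conversation" in kb.validation.missing_contexts
    assert len(kb.validation.missing_contexts) == 19


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def test_exact_match_in_active_context(kb):
    hit = match(kb, normalize("hola"), "beginning_conversation")
    assert hit is not None
    assert hit.context_id == "beginning_conversation"
    assert hit.category.pattern == ("hola",)


def test_no_match_is_none(kb, tmp_path):
    mini = _write_kb(
        tmp_path,
        """<aiml><topic name="family"><category><pattern>HOLA</pattern>
        <template>¿Qué tal?</template></category></topic></aiml>""",
    )
    mini_kb = load_kb([mini])
    assert match(mini_kb, normalize("zanahoria"), "family") is None


def test_specific_pattern_beats_catch_all(tmp_path):
    mini = _write_kb(
        tmp_path,
        """<aiml><topic name="family">
        <category><pattern>*</pattern><template>¿Sí?</template></category>
        <category><pattern>ME GUSTA *</pattern><template>¿Por qué te gusta?</template></category>
        </topic></aiml>""",
    )
    kb = load_kb([mini])
    hit = match(kb, normalize("me gusta el fútbol"), "family")
    assert hit.category.pattern == ("me", "gusta", "*")
    assert hit.bindings == (("el", "fútbol"),)


def test_trigger_in_other_context_switches(kb):
    hit = match(kb, normalize("quiero platicar de mi familia"), "beginning_conversation")
    assert hit.context_id == "family"
    assert hit.category.role == "trigger"


def test_global_categories_are_last_resort(kb):
    hit = match(kb, normalize("me gusta el pan"), "family")
    assert hit.context_id == "global"


# -- graphmaster priority against a brute-force enumerator ------------------


def _brute_force_best(patterns, tokens):
    """Enumerate all matches of all patterns; pick by documented priority.

    Trace codes per consumed input token: 0 enter ``_``, 1 exact, 2 enter
    ``*``, 3 continue the current wildcard; the winner has the
    lexicographically smallest trace (ties: first-loaded pattern).
    """

    def traces(pattern, pi, ti, trace):
        if pi == len(pattern):
            if ti == len(tokens):
                yield tuple(trace)
            return
        el = pattern[pi]
        if el in ("_", "*"):
            enter = 0 if el == "_" else 2
            for k in range(1, len(tokens) - ti + 1):
                yield from traces(pattern, pi + 1, ti + k, trace + [enter] + [3] * (k - 1))
        elif ti < len(tokens) and tokens[ti] == el:
            yield from traces(pattern, pi + 1, ti + 1, trace + [1])

    best = None
    for idx, pattern in enumerate(patterns):
        for trace in traces(pattern, 0, 0, []):
            key = (trace, idx)
            if best is None or key < best:
                best = key
    return None if best is None else best[1]


def _dummy_category(pattern, idx):
    return DialogueCategory(
        context_id="t",
        pattern=pattern,
        templates=(ResponseTemplate(f"t/{idx}", (Literal("¿ok?"),), True),),
    )


_pattern_token = st.sampled_from(["a", "b", "c", "*", "_"])
_patterns = st.lists(
    st.lists(_pattern_token, min_size=1, max_size=4).map(tuple),
    min_size=1,
    max_size=6,
)
_inputs = st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=5).map(tuple)


@given(_patterns, _inputs)
def test_graphmaster_agrees_with_brute_force_priority(patterns, tokens):
    gm = Graphmaster()
    cats = [_dummy_category(p, i) for i, p in enumerate(patterns)]
    for cat in cats:
        gm.insert(cat)
    hit = gm.search(tokens)
    # de-duplicate patterns the trie collapses (first-loaded wins)
    seen, effective = set(), []
    for p in patterns:
        if p not in seen:
            seen.add(p)
            effective.append(p)
    expected = _brute_force_best(effective, tokens)
    if expected is None:
        assert hit is None
    else:
        assert hit is not None
        assert hit[0].pattern == effective[expected]


def test_wildcard_bindings_cover_consumed_spans():
    gm = Graphmaster()
    gm.insert(_dummy_category(("_", "b", "*"), 0))
    cat, bindings = gm.search(("x", "y", "b", "z", "w"))
    assert bindings == (("x", "y"), ("z", "w"))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

FIG3_SENTENCES = {
    "¿Es verdad que Patricia es tu hija?",
    "¿Te gustaría platicar de tu hija Patricia?",
}


def test_family_templates_render_worked_example(kb, patricia_profile):
    hit = match(kb, normalize("familia"), "beginning_conversation")
    seen = set()
    for seed in range(30):
        out = select_and_render(kb, hit.category, patricia_profile, rng=Random(seed))
        seen.add(out[0])
    assert FIG3_SENTENCES <= seen


def test_customized_template_skips_without_family(kb, schema):
    lonely = rc.build_profile(schema, {}, [], patient_id="solo")
    hit = match(kb, normalize("familia"), "beginning_conversation")
    outs = {
        select_and_render(kb, hit.category, lonely, rng=Random(s))[0]
        for s in range(20)
    }
    # only the generic alternative can render; Patricia-style slots are absent
    assert all("tu" not in o or "familia" in o for o in outs)
    for out in outs:
        assert "<get" not in out and "{" not in out


def test_render_skip_when_all_templates_customized(kb, schema):
    lonely = rc.build_profile(schema, {}, [], patient_id="solo")
    hit = match(kb, normalize("sí"), "family")
    assert hit.context_id == "family"
    assert select_and_render(kb, hit.category, lonely, rng=Random(0)) is None


def test_greeting_contains_patient_name(kb, patricia_profile):
    cat = kb.opening_category("beginning_conversation")
    out, _ = select_and_render(kb, cat, patricia_profile, rng=Random(0))
    assert "María" in out
    assert out.endswith("?")


def test_render_is_deterministic_under_seed(kb, profile):
    hit = match(kb, normalize("familia"), "beginning_conversation")
    a = select_and_render(kb, hit.category, profile, rng=Random(42))
    b = select_and_render(kb, hit.category, profile, rng=Random(42))
    assert a == b


def test_non_repetition_window(kb, profile):
    """With more templates than the memory holds, no repeats in a window."""
    hit = match(kb, normalize("familia"), "beginning_conversation")
    recent: list[str] = []
    rng = Random(0)
    produced = []
    for _ in range(12):
        out, tid = select_and_render(kb, hit.category, profile, recent=recent[-2:], rng=rng)
        recent.append(tid)
        produced.append(tid)
    for a, b in zip(produced, produced[1:]):
        assert a != b


def test_render_template_substitutes_verbatim(kb, patricia_profile):
    tmpl = ResponseTemplate(
        "x", (Literal("¿Quieres hablar de "), rc.kb.SlotRef("fam1_name"), Literal("?")), True
    )
    assert render_template(tmpl, patricia_profile) == "¿Quieres hablar de Patricia?"


def test_srai_redirect(tmp_path):
    mini = _write_kb(
        tmp_path,
        """<aiml><topic name="family">
        <category><pattern>BASE</pattern><template>¿Todo bien?</template></category>
        <category><pattern>ALIAS</pattern><template><srai>BASE</srai></template></category>
        </topic></aiml>""",
    )
    kb = load_kb([mini])
    hit = match(kb, normalize("alias"), "family")
    out, _ = select_and_render(kb, hit.category, rc.generate_profile(0), rng=Random(0))
    assert out == "¿Todo bien?"


# ---------------------------------------------------------------------------
# linting
# ---------------------------------------------------------------------------


def test_shipped_kb_is_lint_clean(kb):
    assert lint_kb(kb) == []


def test_lint_flags_statement_outside_leave(tmp_path):
    mini = _write_kb(
        tmp_path,
        """<aiml><topic name="hobbies">
        <category><pattern>HOLA</pattern><template>Qué bien.</template></category>
        <category><pattern>NO</pattern><template>¿Seguro?</template></category>
        </topic></aiml>""",
    )
    findings = lint_kb(load_kb([mini]))
    assert any(f.kind == "no_question" for f in findings)


def test_lint_flags_single_template_context(tmp_path):
    mini = _write_kb(
        tmp_path,
        """<aiml><topic name="hobbies">
        <category><pattern>HOLA</pattern><template>¿Qué tal?</template></category>
        </topic></aiml>""",
    )
    findings = lint_kb(load_kb([mini]))
    assert any(f.kind == "single_template" for f in findings)


def test_lint_flags_long_sentences(kb):
    findings = lint_kb(kb, max_words=3)
    assert any(f.kind == "long_sentence" for f in findings)
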