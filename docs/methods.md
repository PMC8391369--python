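# Methods

This note documents the models and procedures implemented in `recuerda`,
the parameters that matter, the numerical choices, and what the synthetic
fixtures do and do not show about real use.

## Text normalization

User utterances (as an ASR service would transcribe them) are cleaned in
a fixed order: Unicode NFC normalization, full case folding (`Á`→`á`,
`Ñ`→`ñ`), replacement of non-alphanumeric characters by separators,
whitespace tokenization, and collapsing of runs of identical consecutive
tokens — a disfluency artifact of spontaneous elderly speech ("este
este", "um um").  Design choices:

- The kept character class is Unicode letters and digits; Spanish
  diacritics are therefore preserved verbatim everywhere (patterns,
  slots, stored answers).  An apostrophe is kept only intra-word.
- Only *single-token* repeats collapse; multi-token repeats ("no sé no
  sé") are meaningful and kept.
- Normalization is idempotent (property-tested), and knowledge-base
  patterns are normalized with the same pipeline, so patterns and inputs
  share one alphabet.

## Knowledge base and matching

The conversation is partitioned into 20 dialogue contexts (greetings,
farewell, agent profile, patient profile, family, habits, skills,
hobbies, household chores, visited places, movies, TV shows, actors,
music, singers, sports, sport teams, food dishes, beverages,
festivities).  Each context is one XML file in a strict AIML subset
(`data/DIALECT.md`): `category`/`pattern`/`template`, topic scoping,
`<random>` alternatives, `<get>` slot references, `<condition>` on slot
presence, and `<srai>` redirection capped at depth 10.  The subset is
deliberately small — tags outside it are load-time errors, and every
slot reference is validated against the questionnaire schema.

Matching is classic graphmaster search over a token trie with branch
priority `_` > exact token > `*`, resolved left to right; both wildcards
consume ≥ 1 token.  Search runs in three tiers: the active context's
categories, then the *trigger* categories of all contexts (a hit switches
the conversation), then the reserved `global` topic.  A property test
checks the trie search against an independent brute-force enumerator that
lists every (pattern, segmentation) match and picks the winner by an
explicit trace ordering.

Rendering picks uniformly (seeded) among a category's templates that are
not in the per-context recent-response memory (default `memory_k = 3`
responses — the non-repetition mechanism is unspecified in the source
system, so a small sliding window was chosen) and whose referenced slots
all have values.  A customized template with a missing slot *skips*;
if every template of a category skips, the dialogue layer falls back.
`<condition>` content is restricted to literals plus `<get>` of the
guarding slot, so a rendered response can never contain placeholder
residue.

A lint enforces the dementia-communication strategy the knowledge base is
authored under: every response outside the farewell context ends with a
question (keeping the patient engaged), every context offers more than
one response (avoiding repetitiveness), and sentences stay short
(default ceiling 20 words).  The shipped KB passes with zero findings.

## Dialogue management

A session opens in the greeting context with a rendered (personalized
when possible) welcome.  Each turn: normalize → match → render.  Policy
choices where the original behaviour was unspecified:

- Context switching is *pattern-triggered* (the user mentions a topic) or
  *system-initiated*: after `n_stall = 2` consecutive fallbacks the
  engine proposes a new context drawn (seeded) from contexts whose
  introductory templates the profile can fill.
- The greeting context is never re-entered after the session has moved
  on.
- Fallback prompts are authored per-context in the KB (role
  `fallback`), keeping all patient-facing Spanish out of the code.
- Matching a farewell trigger renders the goodbye (the one context whose
  responses are statements, not questions) and closes the session.

Timestamps come from an injectable clock whose default is a per-session
turn counter (t = 0, 1, 2, …), making transcripts byte-reproducible for
identical (profile, seed, scripted input); a wall clock can be injected
where real timing matters.  Transcripts are JSONL, reference the patient
only by id, and round-trip losslessly.

## Profiles

The questionnaire has exactly 3 topic blocks of 11, 4 and 17 questions
(32 total) with unique slot names; the loader rejects anything else.
Only a few slot names are fixed by the system's design
(`patient_name`, `fam1_name`, `parentesco_fam1`); the remaining 31 slots
were reconstructed so that each lifestyle question feeds exactly one
dialogue context (e.g. `comida_favorita` → food dishes).  Storage is one
JSON document per profile in a directory store — desk-scale and
inspectable; a database server adds nothing at this size.  Missing
answers are stored as *absent*, never as empty strings, and deletion
removes the profile document plus all session logs, returning a report
(tests verify a full-store scan finds no trace of the id).

## Word error rate

For reference/hypothesis token sequences (both normalized by the same
pipeline — making the metric case- and punctuation-insensitive, the
usual ASR-evaluation convention),

    WER = (S + I + D) / N

with counts from a unit-cost Wagner–Fischer alignment.  The backtrace
resolves cost ties preferring substitution, then deletion, then
insertion; this only canonicalizes the S/I/D split — the total S+I+D is
the path-independent edit distance, verified in tests against a
brute-force recursive oracle (exhaustively for all pairs of length ≤ 6
over a 3-symbol alphabet, deduplicated by symbol-relabeling class) and
cross-checked against the `edlib` alignment library.  WER may exceed 1;
an empty-after-normalization reference is an error.  Table averages are
printed rounded half-up to 3 decimals (star-rating means to 2), matching
reporting convention.

## Voted appropriateness

In the static-context (bystander) scheme, evaluators read a fixed
dialogue of ≥ 4 turns and vote for the most appropriate of 4 candidate
continuations; the system's true response sits at hidden position 0.
`Rvoted` is the per-candidate count, `Rmax` the dialogue maximum; with
11 evaluators the attainable range is 0–11 and counts conserve to the
number of voters.  Agreement percentages are *tie-inclusive*: a position
counts whenever its `Rvoted` equals `Rmax`, so the four percentages can
sum above 100 (with no votes at all, every position trivially ties at 0
and all four count — documented edge of the literal rule).  The Pearson
correlation between position-0 `Rvoted` and `Rmax` uses the exact
t-transform for its two-sided p-value (appropriate at n ≈ 40; a
permutation test would add nothing here); constant vectors are rejected
rather than silently returning NaN.

## Synthetic fixtures

The generators reproduce the evaluation design: 20 contexts × 2
dialogues = 40 items, ≥ 4 turns, 4 candidates, 11 evaluators.  Profiles
draw from pools of plausible Mexican-Spanish values (names, dishes,
rancheras, festivities) with 1–3 relatives.  The simulated user is
rule-based — a topic mention, affirmations, echoes of its own profile
values — chosen over a learned model for determinism and offline
operation.  Distractor candidates are fluent responses rendered from
*other* contexts (never string-equal to the true response): contextually
wrong but well-formed, which is what makes the bystander task
discriminative.  Synthetic votes draw from fixed preference weights
(0.55/0.30/0.10/0.05) emulating evaluators who usually favour the
system's response.

Transcript pairs corrupt normalized reference tokens independently:
deletion with probability `del`, substitution by a different vocabulary
word with `sub`, insertion with `ins`; replacements avoid equalling
their neighbours so the normalizer's repeat collapse cannot mask an
error.  A recovery test confirms measured S/N lies within 3 binomial
standard errors of the configured substitution rate (400 pairs,
≈ 4,800 reference tokens).

**What passing fixtures show — and don't.**  They show the engine, the
metrics and the evaluation design are internally correct and
reproducible.  They do not show that real PwAD speech matches the
simulated user (no disfluency beyond stutters, no topic drift, no ASR
confusions beyond the independence corruption model), nor that human
evaluators behave like the weighted synthetic voters; vote-level human
results are therefore replaced in testing by arithmetic and bound
properties of the metrics themselves.

## Problem sizes and limitations

Default test and script sizes (40 dialogues, 400 transcript pairs,
exhaustive alignment pairs at length ≤ 6 over 3 symbols) were chosen as
the smallest sizes at which the checked properties are meaningful.
Known limitations: no AIML `<that>`-style response-conditioned matching
(context scoping covers the shipped KB; noted as a possible extension);
matching is exact-token (no fuzzy matching of misrecognized words);
cloud ASR/TTS adapters are contracts only; the engine is
language-agnostic but the shipped KB and fixtures are Spanish.
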