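# recuerda

A Spanish, text-mode conversational system for delivering **reminiscence
therapy** to people with early-stage Alzheimer's disease (PwAD), together
with the quantitative machinery used to evaluate such a system.

Reminiscence therapy evokes autobiographical memories through guided
conversation about a person's own life — family, habits, favourite food,
music, festivities.  Because early-stage Alzheimer's spares long-term
memory while impairing short-term memory, a dialogue agent that knows the
patient's life history can sustain these conversations and relieve
overburdened caregivers.  `recuerda` implements the whole pipeline as a
library:

- **profiles** — a 32-question personalization questionnaire (11 personal,
  4 family, 17 life-history/lifestyle questions) whose answers become
  *slots* (`patient_name`, `comida_favorita`, …); registered relatives
  expose derived slots `fam<i>_name` / `parentesco_fam<i>`.  Profiles live
  in a JSON directory store with a verifiable right-to-withdraw deletion
  contract.
- **kb** — a 20-context knowledge base authored in a validated AIML
  subset (see `src/recuerda/data/DIALECT.md`): token patterns with `_`/`*`
  wildcards matched in classic graphmaster priority (`_` > exact > `*`,
  left-to-right), and response templates that are either *generic* or
  *customized* via profile-slot substitution.
- **dialogue** — the dialogue manager: normalize → match → render on each
  turn, context switching on topic mentions, seeded non-repetitive
  template selection, per-context fallbacks, system-initiated topic
  proposals after stalls, and byte-reproducible JSONL transcripts.
- **normalize** — ASR-style text cleanup: punctuation stripping with
  Spanish diacritics preserved, Unicode case folding, and collapsing of
  stutter repeats ("este este" → "este").
- **speech** — pluggable ASR/TTS adapter contracts; the text-mode defaults
  are the identity transcriber and a recording-only synthesizer at a 0.8
  relative speech rate (slow, clear speech for dementia communication).
- **evaluation** — word error rate `WER = (S + I + D) / N` from a
  unit-cost Levenshtein alignment of token sequences (S substitutions, I
  insertions, D deletions, N reference tokens); the *voted
  appropriateness* metric `Rvoted` (bystander evaluators vote for the
  best of 4 candidate responses per dialogue), per-dialogue `Rmax`,
  tie-inclusive agreement percentages, Pearson correlation, and star-
  rating aggregation.
- **fixtures** — seeded synthetic inputs: fully answered profiles,
  rule-based simulated users, the 40-dialogue evaluation set (2 dialogues
  × 20 contexts, 4 candidates each), synthetic evaluator votes, and
  reference/hypothesis transcript pairs corrupted at configurable
  substitution/insertion/deletion rates.

## Worked example

```bash
python examples/01_conversation.py
```

```
patient: Guadalupe, first relative: Leticia (hermana)

  SYSTEM: ¡Muy buenos días, Guadalupe! ¿Cómo amaneciste hoy?
  USER:   hola
  SYSTEM: ¡Hola, Guadalupe! Me da mucho gusto saludarte. ¿Cómo estás?
  USER:   quiero platicar de mi familia
  SYSTEM: ¿Te gustaría platicar de tu hermana Leticia?
  USER:   sí
  SYSTEM: ¡Qué bonito! ¿Qué recuerdos felices tienes con Leticia?
  ...
  USER:   adiós
  SYSTEM: Me dio mucho gusto platicar contigo, Guadalupe. ¡Hasta pronto!

exchanges: 7, contexts visited: ['beginning_conversation', 'family',
'food_dishes', 'leave_conversation']
```

The greeting and the family follow-ups are *customized* templates filled
from the synthetic profile; mentioning food switches the active context;
the farewell trigger closes the session.  Every response outside the
farewell context ends with a question — a lint-enforced property of the
shipped knowledge base (`recuerda validate-kb`).

The other examples demonstrate WER benchmarking on corrupted transcripts
(`02_wer_benchmark.py`), the full bystander-voting evaluation with 11
synthetic evaluators (`03_voted_appropriateness.py`) and the profile
store's deletion contract (`04_profile_store.py`).

## Command line

A thin CLI wraps the library:

```bash
recuerda validate-kb                      # lint the shipped KB
recuerda --seed 5 --profile-store ./store chat <patient-id>
recuerda eval-wer --ref ref.txt --hyp hyp.txt
recuerda --seed 2 gen-fixtures --out ./fx # profile + 40 dialogues + votes scaffold
recuerda eval-votes fx/evaluation_set.json fx/votes.csv
```

Exit codes: 0 success, 2 usage/missing input, 3 data error.  Everything
is deterministic under `--seed`.

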