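# Knowledge-base dialect

The knowledge base is authored in a small, strictly validated subset of
AIML.  One UTF-8 XML file per dialogue context is recommended.

## Structure

```xml
<aiml version="subset-1.0">
  <topic name="context_id" description="...">
    <category role="trigger|fallback|opening">   <!-- role optional -->
      <pattern>TOKENS WITH * AND _</pattern>
      <template>...</template>
    </category>
  </topic>
</aiml>
```

- `topic/@name` is the dialogue context id; the reserved name `global`
  holds categories reachable from every context.
- `category/@role` (default `normal`):
  - `normal` — matchable only while its context is active;
  - `trigger` — additionally matchable from any other context; a match
    switches the conversation to this context;
  - `fallback` — never pattern-matched; rendered when the active context
    produces no response (its pattern is ignored, use `*`);
  - `opening` — rendered once to open a session (greeting contexts only);
    never pattern-matched against user input.

## Patterns

Whitespace-separated tokens.  Word tokens are normalized with the same
pipeline as user utterances (case folding, diacritics preserved), so
patterns may be authored in conventional AIML uppercase.  Two wildcards,
each consuming **one or more** tokens:

- `_` — higher priority than an exact token;
- `*` — lower priority than an exact token.

Matching follows classic graphmaster order (`_` > exact > `*`, resolved
left to right).  A pattern must match the entire utterance.

## Templates

Mixed content of literal text and the following tags:

- `<get name="slot"/>` — substitute a profile slot (questionnaire slot,
  derived family slot `fam<i>_name` / `parentesco_fam<i>`, or a session
  predicate).  If the slot has no value the whole template is skipped.
- `<condition name="slot">... <get name="slot"/> ...</condition>` —
  render the inner content only when the slot has a value; inner content
  is restricted to literals and `<get>` of the guarding slot.
- `<random><li>...</li>...</random>` — a list of alternative templates;
  must be the entire template.  Selection at runtime is seeded-uniform
  among alternatives not in the recent-response memory.
- `<srai>TEXT</srai>` — redirect: match TEXT as if the user had said it
  (within the same context); must be the entire template; recursion depth
  is capped at 10.

Slot names are validated against the profile schema at load time; any
tag outside this subset is a syntax error.
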