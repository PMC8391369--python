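"""Text normalization for transcribed user utterances.

Spontaneous speech transcribed by an ASR service arrives with punctuation,
inconsistent casing and stuttered repeats caused by false starts ("este
este", "um um", "ee ee").  Before an utterance is compared against the
knowledge-base patterns it is cleaned in a fixed order:

1. Unicode NFC normalization (composed accents, deterministic equality),
2. full case folding (``Á`` → ``á``, ``Ñ`` → ``ñ``),
3. punctuation and other non-alphanumeric characters become separators
   (Spanish letters with diacritics count as alphanumeric; an apostrophe
   flanked by letters or digits is kept as part of the word),
4. whitespace tokenization,
5. runs of identical consecutive tokens collapse to a single token.

Only single-token repeats are collapsed; multi-token repeats such as
"no sé no sé" are left intact.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

__all__ = ["NormalizedUtterance", "normalize", "tokenize"]

_APOSTROPHES = {"'", "’"}


def tokenize(text: str) -> list[str]:
    """Split ``text`` on whitespace, dropping empty tokens."""
    return text.split()


def _is_word_char(ch: str) -> bool:
    return ch.isalnum()


def _strip_nonword(text: str) -> str:
    """Replace non-alphanumeric characters by spaces.

    An apostrophe is preserved only when flanked by word characters on
    both sides (intra-word, e.g. "d'una"); typographic apostrophes are
    folded to U+0027 first.
    """
    chars = list(text)
    out: list[str] = []
    for i, ch in enumerate(chars):
        if ch in _APOSTROPHES:
            prev_ok = i > 0 and _is_word_char(chars[i - 1])
            next_ok = i + 1 < len(chars) and _is_word_char(chars[i + 1])
            out.append("'" if prev_ok and next_ok else " ")
        elif _is_word_char(ch):
            out.append(ch)
        else:
            out.append(" ")
    return "".join(out)


def _collapse_repeats(tokens: list[str]) -> list[str]:
    out: list[str] = []
    for tok in tokens:
        if not out or out[-1] != tok:
            out.append(tok)
    return out


@dataclass(frozen=True)
class NormalizedUtterance:
    """A cleaned utterance: original text plus its normalized tokens."""

    raw: str
    tokens: tuple[str, ...]
    text: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "text", " ".join(self.tokens))

    def __bool__(self) -> bool:
        return bool(self.tokens)


def normalize(text: str) -> NormalizedUtterance:
    """Clean and tokenize one utterance.

    Empty input (or input with no alphanumeric content) yields an empty
    token list; it never raises.

    >>> normalize("este este um um ee ee").tokens
    ('este', 'um', 'ee')
    >>> normalize("¿Cómo estás?").tokens
    ('cómo', 'estás')
    """
    cleaned = unicodedata.normalize("NFC", text).casefold()
    cleaned = unicodedata.normalize("NFC", cleaned)
    cleaned = _strip_nonword(cleaned)
    tokens = _collapse_repeats(tokenize(cleaned))
    return NormalizedUtterance(raw=text, tokens=tuple(tokens))
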