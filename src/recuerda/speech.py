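"""Pluggable ASR/TTS adapter contracts.

The engine itself is text-mode: the default ASR adapter is the identity on
strings and the default TTS adapter records what it would have spoken
without producing audio.  Cloud speech services can be attached out of
tree by implementing the same two protocols; the engine never imports a
cloud client.

The TTS contract carries a relative speech rate whose default is 0.8 —
slightly slower than normal speech, the recommended pace when talking
with people with dementia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

__all__ = [
    "DEFAULT_TTS_RATE",
    "ASRAdapter",
    "TTSAdapter",
    "TextModeASR",
    "NullTTS",
    "SynthesisRecord",
    "text_mode_asr",
    "null_tts",
]

DEFAULT_TTS_RATE = 0.8


@runtime_checkable
class ASRAdapter(Protocol):
    language: str

    def transcribe(self, audio) -> str: ...


@runtime_checkable
class TTSAdapter(Protocol):
    rate: float

    def synthesize(self, text: str): ...


@dataclass(frozen=True)
class SynthesisRecord:
    """What a TTS backend was asked to speak, and how fast."""

    text: str
    rate: float


class TextModeASR:
    """Identity adapter: the 'audio' is already text."""

    def __init__(self, language: str = "es"):
        self.language = language

    def transcribe(self, audio: str) -> str:
        return audio


class NullTTS:
    """Records synthesis requests without producing audio."""

    def __init__(self, rate: float = DEFAULT_TTS_RATE):
        if rate <= 0:
            raise ValueError(f"speech rate must be positive, got {rate}")
        self.rate = rate
        self.records: list[SynthesisRecord] = []

    def synthesize(self, text: str) -> SynthesisRecord:
        record = SynthesisRecord(text=text, rate=self.rate)
        self.records.append(record)
        return record


def text_mode_asr(text: str) -> str:
    """Identity transcription for text-mode operation."""
    return text


def null_tts(text: str, rate: float = DEFAULT_TTS_RATE) -> SynthesisRecord:
    """Record a synthesis request at ``rate`` (default 0.8) without audio."""
    if rate <= 0:
        raise ValueError(f"speech rate must be positive, got {rate}")
    return SynthesisRecord(text=text, rate=rate)
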