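"""Reading, writing and validating SALT-style conversation transcripts.

The dialect implemented here follows the common Systematic Analysis of
Language Transcripts (SALT) conventions for examiner-child conversation
samples:

* one c-unit (communication unit) per line, prefixed by a speaker code
  (``C`` for the child, ``E`` for the examiner) and a space;
* mazes — disfluent material such as false starts, repetitions and filled
  pauses — enclosed in parentheses, e.g. ``(My mom) My dad picked me up.``;
* bound morphemes marked with a slash suffix on the root, e.g. ``dog/s``,
  ``walk/ed``, ``go/ing``, ``he/'s``;
* a partially unintelligible word transcribed as ``X`` and a fully
  unintelligible segment as ``XX``;
* an abandoned (incomplete) c-unit terminated with ``>``;
* optional metadata header lines starting with ``+``, e.g.
  ``+ duration_min: 6.27``.

Tokenization splits on whitespace, strips terminal punctuation and
case-folds.  The closed filler lexicon (``ah, uh, um, mm, hmm, like, well,
you know, I mean``) is matched during tokenization; the two multiword
fillers are matched greedily left-to-right and kept as single units.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "FILLER_LEXICON",
    "MULTIWORD_FILLERS",
    "Token",
    "Maze",
    "MazeKind",
    "Speaker",
    "CUnit",
    "Transcript",
    "Diagnostic",
    "ParseError",
    "parse_transcript",
    "write_transcript",
    "validate_transcript",
]

#: Closed set of filler words; multiword entries are matched as units.
FILLER_LEXICON = frozenset(
    {"ah", "uh", "um", "mm", "hmm", "like", "well", "you know", "i mean"}
)
MULTIWORD_FILLERS = (("you", "know"), ("i", "mean"))

_TERMINAL_PUNCT = ".?!,;:"


class ParseError(ValueError):
    """Raised when a transcript document violates the dialect."""


class Speaker(str, Enum):
    child = "C"
    examiner = "E"


class MazeKind(str, Enum):
    content = "content"
    filler_only = "filler_only"


@dataclass(frozen=True, slots=True)
class Token:
    """A single transcribed word.

    ``surface`` keeps the slash morpheme markers (lower-cased);
    ``root`` is the surface up to the first marker; ``n_morphemes`` is
    1 plus the number of slash-marked bound morphemes.
    """

    surface: str
    root: str
    n_morphemes: int = 1
    is_filler: bool = False
    is_unintelligible: bool = False

    @property
    def plain(self) -> str:
        """Surface with morpheme markers removed (``dog/s`` -> ``dogs``)."""
        return self.surface.replace("/", "")


@dataclass(frozen=True, slots=True)
class Maze:
    tokens: tuple[Token, ...]

    @property
    def kind(self) -> MazeKind:
        if any(not t.is_filler and not t.is_unintelligible for t in self.tokens):
            return MazeKind.content
        return MazeKind.filler_only


@dataclass(frozen=True, slots=True)
class CUnit:
    """One communication unit: a main clause with its modifiers, or a
    freestanding fragment.  ``tokens`` are the fluent (out-of-maze) words;
    ``maze_positions`` gives, for each maze, the index in ``tokens`` before
    which it occurred."""

    speaker: Speaker
    tokens: tuple[Token, ...]
    mazes: tuple[Maze, ...] = ()
    maze_positions: tuple[int, ...] = ()
    is_complete: bool = True

    @property
    def is_fluent(self) -> bool:
        return not self.mazes

    @property
    def is_intelligible(self) -> bool:
        if any(t.is_unintelligible for t in self.tokens):
            return False
        return not any(t.is_unintelligible for m in self.mazes for t in m.tokens)

    def _mazes_by_position(self) -> dict[int, list[Maze]]:
        grouped: dict[int, list[Maze]] = {}
        for p, m in zip(self.maze_positions, self.mazes):
            grouped.setdefault(p, []).append(m)
        return grouped

    def all_tokens(self) -> Iterable[Token]:
        """Tokens in order, maze-internal ones included."""
        grouped = self._mazes_by_position()
        for i in range(len(self.tokens) + 1):
            for m in grouped.get(i, ()):
                yield from m.tokens
            if i < len(self.tokens):
                yield self.tokens[i]


@dataclass(slots=True)
class Transcript:
    participant_id: str
    cunits: tuple[CUnit, ...]
    duration_min: float

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be positive")
        self.cunits = tuple(self.cunits)

    def child_cunits(self) -> list[CUnit]:
        return [c for c in self.cunits if c.speaker is Speaker.child]

    def to_dict(self) -> dict:
        """JSON-serialisable structure, for debugging and audit exports."""
        return {
            "participant_id": self.participant_id,
            "duration_min": self.duration_min,
            "cunits": [
                {
                    "speaker": c.speaker.value,
                    "tokens": [t.surface for t in c.tokens],
                    "mazes": [
                        {"position": p, "tokens": [t.surface for t in m.tokens],
                         "kind": m.kind.value}
                        for p, m in zip(c.maze_positions, c.mazes)
                    ],
                    "is_complete": c.is_complete,
                    "is_intelligible": c.is_intelligible,
                }
                for c in self.cunits
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True, slots=True)
class Diagnostic:
    code: str
    message: str


def _make_token(word: str) -> Token | None:
    """Build a Token from one whitespace-delimited word, or None if the
    word is empty after stripping punctuation."""
    raw = word.strip()
    while raw and raw[-1] in _TERMINAL_PUNCT:
        raw = raw[:-1]
    if not raw:
        return None
    if raw in ("X", "XX"):
        return Token(surface=raw.lower(), root=raw.lower(), n_morphemes=1,
                     is_unintelligible=True)
    surface = raw.casefold()
    parts = surface.split("/")
    root = parts[0]
    n_morphemes = 1 + sum(1 for p in parts[1:] if p)
    return Token(
        surface=surface,
        root=root,
        n_morphemes=n_morphemes,
        is_filler=surface in FILLER_LEXICON,
    )


def _tokenize(words: list[str]) -> tuple[Token, ...]:
    """Tokenize a word list, merging multiword fillers greedily."""
    toks: list[Token] = []
    i = 0
    cleaned = [w for w in words if _make_token(w) is not None]
    while i < len(cleaned):
        merged = False
        if i + 1 < len(cleaned):
            a = _make_token(cleaned[i])
            b = _make_token(cleaned[i + 1])
            if a and b and not a.is_unintelligible and not b.is_unintelligible:
                pair = (a.surface, b.surface)
                if pair in MULTIWORD_FILLERS:
                    unit = " ".join(pair)
                    toks.append(Token(surface=unit, root=unit, n_morphemes=1,
                                      is_filler=True))
                    i += 2
                    merged = True
        if not merged:
            tok = _make_token(cleaned[i])
            if tok is not None:
                toks.append(tok)
            i += 1
    return tuple(toks)


_MAZE_RE = re.compile(r"\(([^()]*)\)")


def _parse_cunit(line: str, lineno: int) -> CUnit:
    code, _, body = line.partition(" ")
    try:
        speaker = Speaker(code)
    except ValueError:
        raise ParseError(f"line {lineno}: unknown speaker code {code!r}") from None
    body = body.strip()
    is_complete = True
    if body.endswith(">"):
        is_complete = False
        body = body[:-1].rstrip()
    if body.count("(") != body.count(")"):
        raise ParseError(f"line {lineno}: unclosed maze parenthesis")

    mazes: list[Maze] = []
    positions: list[int] = []
    out_words: list[str] = []
    cursor = 0
    n_out_tokens_before: list[int] = []
    for m in _MAZE_RE.finditer(body):
        pre = body[cursor:m.start()].split()
        out_words.extend(pre)
        maze_tokens = _tokenize(m.group(1).split())
        if maze_tokens:
            mazes.append(Maze(tokens=maze_tokens))
            n_out_tokens_before.append(len(_tokenize(out_words)))
        cursor = m.end()
    out_words.extend(body[cursor:].split())
    if "(" in " ".join(out_words) or ")" in " ".join(out_words):
        raise ParseError(f"line {lineno}: nested or stray maze parenthesis")
    tokens = _tokenize(out_words)
    positions = n_out_tokens_before
    return CUnit(
        speaker=speaker,
        tokens=tokens,
        mazes=tuple(mazes),
        maze_positions=tuple(positions),
        is_complete=is_complete,
    )


def parse_transcript(text: str, duration_min: float | None = None,
                     participant_id: str = "") -> Transcript:
    """Parse a SALT-dialect document into a :class:`Transcript`.

    ``duration_min`` may be given as an argument or as a ``+ duration_min:``
    header line in the document; the argument wins if both are present.
    """
    if not text.strip():
        raise ParseError("empty transcript document")
    header: dict[str, str] = {}
    cunits: list[CUnit] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("+"):
            key, _, value = line[1:].partition(":")
            header[key.strip()] = value.strip()
            continue
        cunits.append(_parse_cunit(line, lineno))
    if duration_min is None:
        if "duration_min" in header:
            duration_min = float(header["duration_min"])
        else:
            raise ParseError("no duration_min supplied (argument or header)")
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    pid = participant_id or header.get("participant_id", "")
    return Transcript(participant_id=pid, cunits=tuple(cunits),
                      duration_min=float(duration_min))


def _emit_token(tok: Token) -> str:
    if tok.is_unintelligible:
        return tok.surface.upper()
    return tok.surface


def _emit_cunit(c: CUnit) -> str:
    parts: list[str] = []
    grouped = c._mazes_by_position()
    for i in range(len(c.tokens) + 1):
        for m in grouped.get(i, ()):
            parts.append("(" + " ".join(_emit_token(t) for t in m.tokens) + ")")
        if i < len(c.tokens):
            parts.append(_emit_token(c.tokens[i]))
    body = " ".join(parts)
    terminator = "." if c.is_complete else ">"
    return f"{c.speaker.value} {body}{terminator}"


def write_transcript(t: Transcript) -> str:
    """Serialise a Transcript back to the dialect.

    Round-trip guarantee: ``parse_transcript(write_transcript(t))`` equals
    ``t`` on the structured representation.
    """
    lines = []
    if t.participant_id:
        lines.append(f"+ participant_id: {t.participant_id}")
    lines.append(f"+ duration_min: {t.duration_min!r}")
    lines.extend(_emit_cunit(c) for c in t.cunits)
    return "\n".join(lines) + "\n"


def validate_transcript(t: Transcript) -> list[Diagnostic]:
    """Machine-readable warnings about conditions that make downstream
    measures undefined.  Diagnostics, never exceptions."""
    out: list[Diagnostic] = []
    child = t.child_cunits()
    if not child:
        out.append(Diagnostic("no_child_speech",
                              "transcript contains no child c-units"))
        return out
    n_um = n_uh = 0
    for c in child:
        for tok in c.all_tokens():
            if tok.surface == "um":
                n_um += 1
            elif tok.surface == "uh":
                n_uh += 1
    if n_um + n_uh == 0:
        out.append(Diagnostic(
            "um_proportion_undefined",
            "no um or uh tokens: um proportion has a zero denominator"))
    eligible = [c for c in child
                if c.is_complete and c.is_fluent and c.is_intelligible]
    if not eligible:
        out.append(Diagnostic(
            "no_eligible_cunits",
            "no complete, fluent, intelligible child c-units: "
            "MLUM and NDWR are undefined"))
    n_content = sum(1 for c in child for m in c.mazes
                    if m.kind is MazeKind.content)
    n_fillers = sum(1 for c in child for m in c.mazes
                    if m.kind is MazeKind.filler_only
                    for tok in m.tokens if tok.is_filler)
    if n_content + n_fillers == 0:
        out.append(Diagnostic(
            "content_maze_proportion_undefined",
            "no mazes or fillers: content maze proportion has a zero "
            "denominator"))
    return out
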