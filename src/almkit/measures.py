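"""The automated language measures (ALMs) computed per transcript.

Six measures live here; the seventh (repetition proportion) has its own
module because of its approximate-matching machinery.  All proportions are
returned as ``float`` in [0, 1]; a measure whose denominator is zero is
returned as ``None`` ("undefined") and never silently imputed — exclusion
decisions belong to the pipeline, not to the measure.

Measure definitions
-------------------
MLUM
    Mean length of utterance in morphemes, over all complete, fluent and
    intelligible child c-units.  Morphemes are counted from the slash
    markers in the transcription (``dog/s`` = 2).
NDWR
    Number of different word roots over the same eligible c-units; roots
    are the transcribed surface up to the first slash marker, case-folded,
    with no lemmatization (``ran`` and ``run/ing`` are distinct roots).
um proportion
    #um / (#um + #uh), counted anywhere in child speech, mazes included
    (filled pauses are transcribed inside mazes).
content maze proportion
    #content mazes / (#content mazes + #fillers in filler-only mazes).
    A content maze is one containing at least one non-filler word.
unintelligible proportion
    Fraction of child c-units that are partially or fully unintelligible.
CPM
    Attempted child c-units per minute of task audio, incomplete and
    unintelligible units included.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Optional

import math

from .salt import CUnit, MazeKind, Transcript

__all__ = [
    "ALMProfile",
    "ALM_NAMES",
    "eligible_cunits",
    "compute_mlum",
    "compute_ndwr",
    "compute_um_proportion",
    "compute_content_maze_proportion",
    "compute_unintelligible_proportion",
    "compute_cpm",
    "compute_profile",
]

ALM_NAMES = (
    "mlum",
    "ndwr",
    "um_prop",
    "content_maze_prop",
    "unintell_prop",
    "cpm",
    "repetition_prop",
)


@dataclass(frozen=True, slots=True)
class ALMProfile:
    """The seven per-participant measures.  ``None`` encodes an undefined
    value (zero denominator)."""

    mlum: Optional[float]
    ndwr: Optional[int]
    um_prop: Optional[float]
    content_maze_prop: Optional[float]
    unintell_prop: float
    cpm: float
    repetition_prop: float

    def as_dict(self) -> dict[str, Optional[float]]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __post_init__(self) -> None:
        for name in ("um_prop", "content_maze_prop", "unintell_prop",
                     "repetition_prop"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")


def eligible_cunits(t: Transcript) -> list[CUnit]:
    """Child c-units that are complete, fluent and intelligible — the
    eligibility rule shared by MLUM and NDWR."""
    return [c for c in t.child_cunits()
            if c.is_complete and c.is_fluent and c.is_intelligible]


def compute_mlum(t: Transcript) -> Optional[float]:
    elig = eligible_cunits(t)
    if not elig:
        return None
    total = sum(tok.n_morphemes for c in elig for tok in c.tokens)
    return total / len(elig)


def compute_ndwr(t: Transcript) -> Optional[int]:
    elig = eligible_cunits(t)
    if not elig:
        return None
    roots = {tok.root for c in elig for tok in c.tokens}
    return len(roots)


def compute_um_proportion(t: Transcript) -> Optional[float]:
    n_um = n_uh = 0
    for c in t.child_cunits():
        for tok in c.all_tokens():
            if tok.surface == "um":
                n_um += 1
            elif tok.surface == "uh":
                n_uh += 1
    if n_um + n_uh == 0:
        return None
    return n_um / (n_um + n_uh)


def compute_content_maze_proportion(t: Transcript) -> Optional[float]:
    n_content = 0
    n_fillers = 0
    for c in t.child_cunits():
        for m in c.mazes:
            if m.kind is MazeKind.content:
                n_content += 1
            else:
                n_fillers += sum(1 for tok in m.tokens if tok.is_filler)
    if n_content + n_fillers == 0:
        return None
    return n_content / (n_content + n_fillers)


def compute_unintelligible_proportion(t: Transcript) -> float:
    child = t.child_cunits()
    if not child:
        raise ValueError("transcript has no child c-units")
    n_unintell = sum(1 for c in child if not c.is_intelligible)
    return n_unintell / len(child)


def compute_cpm(t: Transcript) -> float:
    # numerator: every attempted child c-unit, incomplete/unintelligible too
    if not (t.duration_min > 0) or math.isnan(t.duration_min):
        raise ValueError("duration_min must be a positive number")
    return len(t.child_cunits()) / t.duration_min


def compute_profile(t: Transcript) -> ALMProfile:
    """All seven measures for one transcript.

    Raises ``ValueError`` if the transcript has no child speech; individual
    undefined measures are encoded as ``None``.
    """
    from .repetition import DEFAULT_TABLE, compute_repetition_proportion

    if not t.child_cunits():
        raise ValueError("transcript has no child c-units")
    return ALMProfile(
        mlum=compute_mlum(t),
        ndwr=compute_ndwr(t),
        um_prop=compute_um_proportion(t),
        content_maze_prop=compute_content_maze_proportion(t),
        unintell_prop=compute_unintelligible_proportion(t),
        cpm=compute_cpm(t),
        repetition_prop=compute_repetition_proportion(t, DEFAULT_TABLE),
    )
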