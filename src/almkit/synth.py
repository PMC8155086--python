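"""Synthetic examiner-child conversation cohorts.

Generates SALT-dialect transcripts plus covariates with controllable
group-level language atypicality, so the whole measurement and validation
pipeline can be exercised end-to-end without clinical data.  The generator
emulates the structure of a semi-structured conversational task: the
examiner asks scripted open-ended questions about friends and
relationships; the child replies in short bursts of c-units realized from
a per-group token model:

* utterance length (in words) drawn from a shifted negative binomial, with
  slash-marked bound morphemes sprinkled at a fixed rate so the morpheme
  count per word is controllable;
* vocabulary drawn Zipf-like from a finite per-group pool, so lexical
  diversity saturates with sample length the way real vocabularies do;
* mazes inserted per c-unit, either content mazes (false starts from the
  child's own vocabulary) or filler mazes whose filled pauses realize the
  group's um-versus-uh preference;
* per-c-unit unintelligibility and abandonment;
* echoes: with some probability a child turn opens by copying a contiguous
  2-5 word window of the examiner's previous question, with an optional
  pronoun flip — planted echolalia that the repetition matcher can find by
  construction.

Default group parameters follow the direction and rough magnitude of
published ASD-versus-control contrasts on these measures (lower MLUM,
lexical diversity, um preference and speech rate in the case group;
higher content-maze, unintelligibility and echo rates); they are study
conditions, not tuning knobs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .salt import (CUnit, Maze, Speaker, Token, Transcript, _make_token,
                   write_transcript)
from .measures import ALM_NAMES, compute_profile

__all__ = [
    "GroupParams",
    "CohortSpec",
    "SyntheticParticipant",
    "default_cohort_spec",
    "null_cohort_spec",
    "generate_cohort",
    "write_cohort",
    "parameter_recovery_check",
    "EXAMINER_QUESTIONS",
]

EXAMINER_QUESTIONS = (
    "What do you like to do with your friend/s?",
    "Tell me about your best friend.",
    "Why would someone want to have friend/s?",
    "What make/s someone a good friend?",
    "How did you meet your friend?",
    "What kind/s of thing/s do you talk about?",
    "Why do people get married?",
    "What happen/ed the last time you play/ed together?",
)

_OTHER_FILLERS = ("like", "well", "mm", "hmm", "ah", "you know", "i mean")
_SUFFIXES = ("s", "ed", "ing")
_PRONOUN_FLIP = {"you": "i", "i": "you", "me": "you", "we": "you",
                 "he": "she", "she": "he", "him": "her", "her": "him"}


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one diagnostic group."""

    mean_morphemes: float = 6.6   # target mean utterance length in morphemes
    vocab_size: int = 400         # finite lexicon pool
    maze_rate: float = 0.40       # P(c-unit carries a maze)
    p_content_maze: float = 0.36  # P(maze is a content maze | maze)
    um_pref: float = 0.70         # P(um | filled pause is um-or-uh)
    p_um_uh_filler: float = 0.80  # P(filler maze is um/uh vs other filler)
    unintell_prob: float = 0.009  # P(c-unit partially unintelligible)
    incomplete_prob: float = 0.03
    echo_prob: float = 0.03       # P(child turn opens with an echo)
    echo_len: tuple[int, int] = (2, 5)
    cpm: float = 13.5             # mean c-units per minute
    cpm_sd: float = 2.5
    mean_cunits: float = 78.0     # mean child c-units per transcript
    p_suffix: float = 0.30        # P(word carries a bound morpheme marker)
    age_range: tuple[float, float] = (7.0, 17.0)
    iq_mean: float = 112.0
    iq_sd: float = 13.5
    p_male: float = 0.60

    def __post_init__(self) -> None:
        for name in ("maze_rate", "p_content_maze", "um_pref",
                     "p_um_uh_filler", "unintell_prob", "incomplete_prob",
                     "echo_prob", "p_suffix", "p_male"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.cpm <= 0 or self.mean_cunits < 1 or self.vocab_size < 10:
            raise ValueError("invalid rate or size parameter")


#: case-group defaults: the direction of published ASD contrasts
ASD_PARAMS = GroupParams(
    mean_morphemes=5.8, vocab_size=250, maze_rate=0.45, p_content_maze=0.59,
    um_pref=0.455, unintell_prob=0.026, echo_prob=0.06, cpm=11.2,
    cpm_sd=2.5, mean_cunits=73.0, iq_mean=99.0, iq_sd=19.7, p_male=0.83,
)
CONTROL_PARAMS = GroupParams(
    mean_morphemes=6.6, vocab_size=400, maze_rate=0.40, p_content_maze=0.36,
    um_pref=0.70, unintell_prob=0.009, echo_prob=0.03, cpm=13.5,
    cpm_sd=2.8, mean_cunits=80.0, iq_mean=112.0, iq_sd=13.5, p_male=0.59,
)


@dataclass(frozen=True)
class CohortSpec:
    groups: dict[str, GroupParams]
    sizes: dict[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.groups) != set(self.sizes):
            raise ValueError("groups and sizes must share keys")
        if any(n < 1 for n in self.sizes.values()):
            raise ValueError("group sizes must be >= 1")


@dataclass
class SyntheticParticipant:
    participant_id: str
    group: str
    age: float
    iq: float
    sex: str
    transcript: Transcript
    true_params: GroupParams


def default_cohort_spec(n_per_group: int = 50, seed: int = 0,
                        mean_cunits: float | None = None) -> CohortSpec:
    """Two-group cohort with planted case-control contrasts in all seven
    generative parameters."""
    asd, ctrl = ASD_PARAMS, CONTROL_PARAMS
    if mean_cunits is not None:
        asd = replace(asd, mean_cunits=mean_cunits)
        ctrl = replace(ctrl, mean_cunits=mean_cunits)
    return CohortSpec(groups={"asd": asd, "control": ctrl},
                      sizes={"asd": n_per_group, "control": n_per_group},
                      seed=seed)


def null_cohort_spec(n_per_group: int = 30, seed: int = 0,
                     mean_cunits: float = 20.0) -> CohortSpec:
    """Two groups with *identical* generative parameters — the null
    configuration used for type-I-error checks."""
    p = replace(CONTROL_PARAMS, mean_cunits=mean_cunits)
    return CohortSpec(groups={"a": p, "b": p},
                      sizes={"a": n_per_group, "b": n_per_group}, seed=seed)


def _beta_jitter(mean: float, concentration: float,
                 rng: np.random.Generator) -> float:
    """Participant-level draw of a probability with the given group mean.
    Degenerate means (0 or 1) are returned unchanged so edge-case specs
    stay exact."""
    if mean <= 0.0 or mean >= 1.0:
        return mean
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return float(rng.beta(a, b))


def _individualize(params: GroupParams,
                   rng: np.random.Generator) -> GroupParams:
    """One participant's parameters: group means plus individual
    differences.  Children within a diagnostic group are not clones; the
    jitter keeps group distributions overlapping the way clinical samples
    do."""
    # jitter magnitudes chosen so group-level ALM standard deviations land
    # near published clinical descriptives (e.g. um proportion SD ~ 0.35,
    # MLUM SD ~ 1.5-1.9, heavily skewed unintelligibility)
    return replace(
        params,
        mean_morphemes=params.mean_morphemes
        * float(rng.lognormal(0.0, 0.25)),
        vocab_size=max(30, int(params.vocab_size
                               * rng.lognormal(0.0, 0.5))),
        maze_rate=_beta_jitter(params.maze_rate, 20.0, rng),
        p_content_maze=_beta_jitter(params.p_content_maze, 6.0, rng),
        um_pref=_beta_jitter(params.um_pref, 2.5, rng),
        unintell_prob=_beta_jitter(params.unintell_prob, 20.0, rng),
        echo_prob=_beta_jitter(params.echo_prob, 10.0, rng),
    )


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / (np.arange(1, n + 1) + 2.7)
    return w / w.sum()


def _tokenize_question(q: str) -> list[str]:
    toks = []
    for w in q.split():
        t = _make_token(w)
        if t is not None:
            toks.append(t.surface)
    return toks


class _ChildModel:
    """Per-participant sampling state."""

    def __init__(self, params: GroupParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        self.vocab = [f"w{i:04d}" for i in range(params.vocab_size)]
        self.weights = _zipf_weights(params.vocab_size)
        # mean words per utterance implied by the morpheme target
        self.mean_words = max(params.mean_morphemes / (1 + params.p_suffix),
                              1.2)

    def draw_words(self, n: int) -> list[str]:
        idx = self.rng.choice(len(self.vocab), size=n, p=self.weights)
        words = []
        for i in idx:
            w = self.vocab[i]
            if self.rng.random() < self.p.p_suffix:
                w = w + "/" + _SUFFIXES[self.rng.integers(len(_SUFFIXES))]
            words.append(w)
        return words

    def utterance_length(self) -> int:
        mu = self.mean_words - 1.0
        r = 8.0
        lam = self.rng.gamma(r, mu / r)
        return 1 + int(self.rng.poisson(lam))


def _echo_words(examiner_words: list[str], params: GroupParams,
                rng: np.random.Generator) -> list[str]:
    lo, hi = params.echo_len
    if len(examiner_words) < 2:
        return []
    length = int(rng.integers(lo, hi + 1))
    length = min(length, len(examiner_words))
    start = int(rng.integers(0, len(examiner_words) - length + 1))
    window = examiner_words[start:start + length]
    if rng.random() < 0.5:
        window = [_PRONOUN_FLIP.get(w, w) for w in window]
    return window


def _child_cunit(model: _ChildModel, rng: np.random.Generator,
                 echo: list[str]) -> CUnit:
    p = model.p
    words = echo + model.draw_words(model.utterance_length())
    tokens = [_make_token(w) for w in words]
    tokens = tuple(t for t in tokens if t is not None)

    mazes: tuple[Maze, ...] = ()
    positions: tuple[int, ...] = ()
    if rng.random() < p.maze_rate:
        if rng.random() < p.p_content_maze:
            maze_toks = tuple(_make_token(w)
                              for w in model.draw_words(int(rng.integers(1, 4))))
        else:
            if rng.random() < p.p_um_uh_filler:
                word = "um" if rng.random() < p.um_pref else "uh"
            else:
                word = _OTHER_FILLERS[rng.integers(len(_OTHER_FILLERS))]
            tok = _make_token(word)
            if tok is None and " " in word:  # multiword filler
                tok = Token(surface=word, root=word, n_morphemes=1,
                            is_filler=True)
            maze_toks = (tok,)
        # multiword fillers come back from _make_token as a single word;
        # rebuild them as filler units
        rebuilt = []
        for t in maze_toks:
            if t.surface in ("you know", "i mean"):
                rebuilt.append(Token(surface=t.surface, root=t.surface,
                                     n_morphemes=1, is_filler=True))
            else:
                rebuilt.append(t)
        mazes = (Maze(tokens=tuple(rebuilt)),)
        positions = (0,)

    if rng.random() < p.unintell_prob and tokens:
        i = int(rng.integers(0, len(tokens)))
        tokens = tokens[:i] + (Token(surface="x", root="x", n_morphemes=1,
                                     is_unintelligible=True),) + tokens[i + 1:]

    return CUnit(
        speaker=Speaker.child,
        tokens=tokens,
        mazes=mazes,
        maze_positions=positions,
        is_complete=rng.random() >= p.incomplete_prob,
    )


def _generate_transcript(pid: str, params: GroupParams,
                         rng: np.random.Generator) -> Transcript:
    model = _ChildModel(params, rng)
    target = max(3, int(rng.poisson(params.mean_cunits)))
    cunits: list[CUnit] = []
    n_child = 0
    while n_child < target:
        q = EXAMINER_QUESTIONS[rng.integers(len(EXAMINER_QUESTIONS))]
        ex_tokens = tuple(t for t in (_make_token(w) for w in q.split())
                          if t is not None)
        cunits.append(CUnit(speaker=Speaker.examiner, tokens=ex_tokens))
        examiner_plain = [t.plain for t in ex_tokens]

        burst = 1 + int(rng.poisson(2.0))
        echo: list[str] = []
        if rng.random() < params.echo_prob:
            echo = _echo_words(examiner_plain, params, rng)
        for j in range(burst):
            if n_child >= target:
                break
            cunits.append(_child_cunit(model, rng, echo if j == 0 else []))
            n_child += 1

    rate = max(params.cpm + params.cpm_sd * rng.standard_normal(), 2.0)
    duration = n_child / rate
    return Transcript(participant_id=pid, cunits=tuple(cunits),
                      duration_min=duration)


def generate_cohort(spec: CohortSpec) -> list[SyntheticParticipant]:
    """Deterministic given ``spec.seed``: same spec, same cohort."""
    rng = np.random.default_rng(spec.seed)
    out: list[SyntheticParticipant] = []
    i = 0
    for group in sorted(spec.groups):
        params = spec.groups[group]
        for _ in range(spec.sizes[group]):
            pid = f"P{i:04d}"
            age = float(rng.uniform(*params.age_range))
            iq = float(np.clip(rng.normal(params.iq_mean, params.iq_sd),
                               70, 160))
            sex = "M" if rng.random() < params.p_male else "F"
            transcript = _generate_transcript(pid, _individualize(params, rng),
                                              rng)
            out.append(SyntheticParticipant(
                participant_id=pid, group=group, age=age, iq=iq, sex=sex,
                transcript=transcript, true_params=params))
            i += 1
    return out


def write_cohort(participants: list[SyntheticParticipant],
                 outdir: str) -> str:
    """Emit SALT-dialect files, a cohort CSV and the true parameters;
    returns the cohort table path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    seen_groups = {}
    for p in participants:
        path = os.path.join(outdir, f"{p.participant_id}.slt")
        with open(path, "w") as fh:
            fh.write(write_transcript(p.transcript))
        rows.append({
            "participant_id": p.participant_id, "group": p.group,
            "age": p.age, "iq": p.iq, "sex": p.sex,
            "duration_min": p.transcript.duration_min,
        })
        seen_groups[p.group] = p.true_params
    table_path = os.path.join(outdir, "cohort.csv")
    pd.DataFrame(rows).to_csv(table_path, index=False)
    with open(os.path.join(outdir, "true_params.json"), "w") as fh:
        json.dump({g: asdict(ps) for g, ps in seen_groups.items()}, fh,
                  indent=2, default=list)
    return table_path


_PLANTED_TARGET = {
    "mlum": "mean_morphemes",
    "um_prop": "um_pref",
    "content_maze_prop": "p_content_maze",
    "unintell_prop": "unintell_prob",
    "cpm": "cpm",
}


def parameter_recovery_check(spec: CohortSpec, n_reps: int = 5
                             ) -> pd.DataFrame:
    """Compare group-level ALM means against their generating parameters
    over replicate cohorts.  Returns one row per (replicate, group,
    measure) with the planted value where one maps directly onto the
    measure."""
    rows = []
    for rep in range(n_reps):
        cohort = generate_cohort(replace(spec, seed=spec.seed + rep))
        # parameter columns get a prefix so they cannot collide with
        # measure names (both sides have a "cpm")
        profiles = pd.DataFrame([
            {"group": p.group,
             **{"param_" + k: v for k, v in p.true_params.__dict__.items()},
             **compute_profile(p.transcript).as_dict()}
            for p in cohort])
        for group, sub in profiles.groupby("group"):
            for alm in ALM_NAMES:
                planted = (sub.iloc[0]["param_" + _PLANTED_TARGET[alm]]
                           if alm in _PLANTED_TARGET else np.nan)
                rows.append({
                    "replicate": rep, "group": group, "alm": alm,
                    "recovered_mean": sub[alm].mean(),
                    "planted": planted,
                    "bias": sub[alm].mean() - planted,
                })
    return pd.DataFrame(rows)
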