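"""Repetition proportion: the child's echo of the examiner's previous turn.

A child turn is compared against the examiner's immediately previous turn
only.  Words are matched in contiguous runs of two or more, with limited
pronoun substitution (``you/I/me/we/us`` interchangeable, ``him/her``
interchangeable, ``he/she`` interchangeable) and with a closed set of
function words (``the, a, an, is, are, am, 'm, 's, 're``) deleted from both
turns before matching.  Deleted words count neither as matched words nor
as child words: in the canonical exchange

    Examiner:  And the moon was coming up.
    Child:     The moon was coming up then.

the child repeats four words (moon, was, coming, up) out of five surviving
child words, giving a repetition proportion of 4/5.

Maze-internal and unintelligible child words are excluded from both the
numerator and the denominator.  Slash-marked clitic suffixes that appear in
the deletable set ('m, 's, 're) are split into standalone units before
matching, so ``he/'s tall`` can echo ``he is tall``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .salt import CUnit, Speaker, Token, Transcript

__all__ = [
    "SubstitutionTable",
    "DEFAULT_TABLE",
    "MatchSpan",
    "match_spans",
    "compute_repetition_proportion",
    "brute_force_repetition_oracle",
    "turn_words",
]

_CLITIC_SUFFIXES = {"'m", "'s", "'re"}


@dataclass(frozen=True)
class SubstitutionTable:
    """Which words may be substituted for each other, and which may be
    deleted, during approximate matching."""

    substitutable_groups: tuple[frozenset[str], ...] = (
        frozenset({"you", "i", "me", "we", "us"}),
        frozenset({"him", "her"}),
        frozenset({"he", "she"}),
    )
    deletable: frozenset[str] = frozenset(
        {"the", "a", "an", "is", "are", "am", "'m", "'s", "'re"}
    )

    def canon(self, word: str) -> str:
        """Canonical representative of a word's substitution class."""
        w = word.casefold()
        for group in self.substitutable_groups:
            if w in group:
                return min(group)
        return w

    def is_deletable(self, word: str) -> bool:
        return word.casefold() in self.deletable


DEFAULT_TABLE = SubstitutionTable()


@dataclass(frozen=True, slots=True)
class MatchSpan:
    """A contiguous echoed run.  Indices are into the deletion-filtered
    child and examiner turn word lists; ``matched_child_words`` is the run
    length (>= 2)."""

    child_start: int
    child_stop: int
    examiner_start: int
    examiner_stop: int

    @property
    def matched_child_words(self) -> int:
        return self.child_stop - self.child_start


def _expand_clitics(tok: Token) -> list[str]:
    """Split deletable clitic suffixes into standalone units; join other
    bound-morpheme markers into the word (dog/s -> dogs)."""
    parts = tok.surface.split("/")
    kept = parts[0]
    out: list[str] = []
    for suffix in parts[1:]:
        if suffix in _CLITIC_SUFFIXES:
            out.append(suffix)
        else:
            kept += suffix
    return [kept] + out


def turn_words(cunits: list[CUnit]) -> list[str]:
    """Flatten a turn (consecutive same-speaker c-units) into its matchable
    words: out-of-maze, intelligible, clitics split."""
    words: list[str] = []
    for c in cunits:
        for tok in c.tokens:
            if tok.is_unintelligible:
                continue
            words.extend(_expand_clitics(tok))
    return words


def _filter_deletable(words: list[str], table: SubstitutionTable) -> list[str]:
    return [w for w in words if not table.is_deletable(w)]


def match_spans(examiner_tokens: list[str], child_tokens: list[str],
                table: SubstitutionTable = DEFAULT_TABLE) -> list[MatchSpan]:
    """Non-overlapping echoed runs maximizing total matched child words.

    Both inputs are plain word lists (mazes and unintelligible tokens
    already removed).  Deletable words are dropped from both sides first;
    matching then requires contiguous equality under the substitution
    classes, runs of length >= 2.  Among selections with maximal total
    coverage, the leftmost-longest one is returned.
    """
    ex = [table.canon(w) for w in _filter_deletable(examiner_tokens, table)]
    ch = [table.canon(w) for w in _filter_deletable(child_tokens, table)]
    n, m = len(ch), len(ex)
    if n < 2 or m < 2:
        return []

    # run_len[c][e]: length of the longest common run starting at ch[c], ex[e]
    run_len = [[0] * (m + 1) for _ in range(n + 1)]
    for c in range(n - 1, -1, -1):
        for e in range(m - 1, -1, -1):
            if ch[c] == ex[e]:
                run_len[c][e] = run_len[c + 1][e + 1] + 1

    # longest candidate run starting at child index c
    max_run = [max(run_len[c][:m], default=0) for c in range(n)]

    # best[i]: max matched child words achievable in ch[i:]
    best = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        best[i] = best[i + 1]
        for length in range(2, max_run[i] + 1):
            best[i] = max(best[i], length + best[i + length])

    # reconstruct: leftmost start, then longest run, then leftmost examiner
    spans: list[MatchSpan] = []
    i = 0
    while i < n:
        chosen = None
        if best[i] > best[i + 1]:
            for length in range(max_run[i], 1, -1):
                if length + best[i + length] == best[i]:
                    e0 = next(e for e in range(m) if run_len[i][e] >= length)
                    chosen = MatchSpan(i, i + length, e0, e0 + length)
                    break
        if chosen is None:
            i += 1
        else:
            spans.append(chosen)
            i = chosen.child_stop
    return spans


def compute_repetition_proportion(
        t: Transcript, table: SubstitutionTable = DEFAULT_TABLE) -> float:
    """Matched child words over total (surviving) child words, across the
    whole transcript.  Child turns with no immediately preceding examiner
    turn contribute zero matches."""
    # group consecutive same-speaker c-units into turns
    turns: list[tuple[Speaker, list[CUnit]]] = []
    for c in t.cunits:
        if turns and turns[-1][0] is c.speaker:
            turns[-1][1].append(c)
        else:
            turns.append((c.speaker, [c]))

    any_child_word = any(
        not tok.is_unintelligible
        for c in t.child_cunits() for tok in c.tokens)
    if not any_child_word:
        raise ValueError("transcript has no matchable child words")

    matched = 0
    total = 0
    prev_examiner_words: list[str] | None = None
    for speaker, cunits in turns:
        words = turn_words(cunits)
        if speaker is Speaker.examiner:
            prev_examiner_words = words
            continue
        surviving = _filter_deletable(words, table)
        total += len(surviving)
        if prev_examiner_words:
            spans = match_spans(prev_examiner_words, words, table)
            matched += sum(s.matched_child_words for s in spans)
        prev_examiner_words = None
    if total == 0:
        # child spoke, but every word was deletable: nothing echoable
        return 0.0
    return matched / total


def brute_force_repetition_oracle(
        examiner_tokens: list[str], child_tokens: list[str],
        table: SubstitutionTable = DEFAULT_TABLE) -> int:
    """Exhaustive-enumeration oracle for the matched-child-word count of a
    single exchange.  Independent of :func:`match_spans`: it enumerates
    every set of non-overlapping contiguous child runs and every contiguous
    examiner run, comparing word by word.  Guarded to short turns."""
    if len(examiner_tokens) > 10 or len(child_tokens) > 10:
        raise ValueError("oracle restricted to turns of <= 10 tokens")
    ex = [table.canon(w) for w in examiner_tokens
          if not table.is_deletable(w)]
    ch = [table.canon(w) for w in child_tokens
          if not table.is_deletable(w)]

    def run_matches(c0: int, length: int) -> bool:
        segment = ch[c0:c0 + length]
        for e0 in range(len(ex) - length + 1):
            if ex[e0:e0 + length] == segment:
                return True
        return False

    def search(i: int) -> int:
        if i >= len(ch):
            return 0
        best = search(i + 1)  # skip ch[i]
        for length in range(2, len(ch) - i + 1):
            if run_matches(i, length):
                best = max(best, length + search(i + length))
        return best

    return search(0)
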