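# almkit

Automated language measures (ALMs) for examiner–child conversation
transcripts, with ordinal clinical recoding, a statistical validation
battery, and a synthetic-cohort generator for end-to-end pipeline testing.

## The problem

Natural-language samples from semi-structured clinical conversations
(e.g. the conversation task of an autism diagnostic assessment) carry
rich information about a child's expressive language: utterance length,
lexical diversity, disfluency patterns, filled-pause choices,
intelligibility, speech rate, and echolalia. Scoring these by hand is
slow and inconsistent. `almkit` computes seven scalar **automated
language measures** directly from SALT-style transcripts:

| measure | definition | direction of impairment |
|---|---|---|
| `mlum` | mean length of utterance in morphemes over complete, fluent, intelligible child c-units | low |
| `ndwr` | number of different word roots over the same eligible c-units | low |
| `um_prop` | filled-pause choice: #um / (#um + #uh) | low |
| `content_maze_prop` | #content mazes / (#content mazes + #filler tokens in filler-only mazes) | high |
| `unintell_prop` | proportion of child c-units containing unintelligible material | high |
| `cpm` | attempted child c-units per minute | low |
| `repetition_prop` | proportion of child words echoed (in matched sets of ≥ 2 words) from the examiner's immediately previous turn, under limited pronoun substitution and function-word deletion | high |

Raw measures are then recoded to a 1–4 ordinal impairment scale at the
cohort's 50/75/90th centiles (reversed for the low-impairment-direction
measures) and fed to a validation battery: Kruskal–Wallis group
comparisons with rank η² and Games–Howell post-hocs, pairwise-complete
Spearman correlations, and logistic classification models (per-measure
and combined, covariate-adjusted) with Nagelkerke R², Wald tests, and
ROC/AUC — all fitted on one shared listwise-complete subsample so the
models stay comparable.

Because clinical corpora cannot ship with the code, the package includes
a calibrated synthetic cohort generator that plants group contrasts in
all seven generative parameters, so every stage of the pipeline can be
exercised, tested and calibrated offline.

## Worked example

The transcript dialect: `E `/`C ` speaker prefixes, one c-unit per line,
mazes in parentheses, bound morphemes slash-marked (`dog/s`, `he/'s`),
`X` for an unintelligible word, trailing `>` for an abandoned c-unit.

```python
from almkit import parse_transcript
from almkit.measures import compute_profile

text = """\
+ participant_id: P01
+ duration_min: 2.5
C (Um) I like play/ing game/s with my friend/s.
C We go to the park.
C (My mom) My dad drive/s us there.
C He/'s really nice.
C (Uh) my friend like/s the swing/s.
C I see him every day X.
C (You know) we play/ed ball yesterday>
C It was fun.
C The dog/s run/ing around.
C (Um) (uh) I love it.
"""
profile = compute_profile(parse_transcript(text))
print(profile.as_dict())
```

prints (hand-checkable against the transcription rules):

```python
{'mlum': 4.5, 'ndwr': 14, 'um_prop': 0.5,
 'content_maze_prop': 0.16666666666666666, 'unintell_prop': 0.1,
 'cpm': 4.0, 'repetition_prop': 0.0}
```

Echo detection on a single exchange:

```python
from almkit import parse_transcript
from almkit.repetition import compute_repetition_proportion

t = parse_transcript(
    "E And the moon was coming up.\nC The moon was coming up then.\n",
    duration_min=1.0)
print(compute_repetition_proportion(t))   # 0.8
```

The child's "the moon was coming up then" has five scoreable words after
removing the deletable function word "the"; four of them ("moon was
coming up") form a contiguous matched set echoed from the examiner's
turn, hence 4/5 = 0.8.

## Command-line pipeline

```bash
almkit simulate --n-per-group 50 --seed 1 --out scratch/cohort
almkit compute  --input scratch/cohort --out scratch/alms
almkit recode   --alm-table scratch/alms/alms.csv --out scratch/ordinal
almkit validate --scores-table scratch/ordinal/alms_ordinal.csv \
                --cohort scratch/cohort/cohort.csv --out scratch/report
```

Each step writes a `run_meta.json` (version + options hash). `compute`
records per-file diagnostics in `exclusions.json` instead of aborting;
`recode` saves its fitted centile bins (`bins.json`) so they can be
reapplied to new data with `--bins`; `validate` emits `report.json`,
`models.csv` and an ROC figure.

## Library map

- `almkit.salt` — transcript parsing, writing, validation diagnostics
- `almkit.measures` — the seven ALMs and `compute_profile`
- `almkit.repetition` — echo matching (substitution/deletion rules, DP
  matcher + brute-force oracle)
- `almkit.recoding` — centile bin fitting and ordinal scoring
- `almkit.stats` — Kruskal–Wallis/η², Games–Howell, Spearman, logistic
  models, ROC, `run_validation`
- `almkit.synth` — synthetic cohort generation and parameter recovery
- `almkit.cli` — the `almkit` command-line group
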