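# Methods note

This note records the measurement model, the numerical conventions, the
synthetic-cohort design, and the known limits of the calibration — the
decisions a reviewer would need to audit the pipeline.

## Transcript dialect

Transcripts follow a SALT-style convention: one c-unit per line with an
`E ` (examiner) or `C ` (child) prefix; optional `+ key: value` headers
(`participant_id`, `duration_min`). Within a line:

- mazes (false starts, repetitions, filled pauses) in parentheses;
- bound morphemes slash-marked (`dog/s`, `play/ed`, `he/'s`), each
  suffix adding one morpheme;
- `X` a single unintelligible word, `XX` an unintelligible segment;
- a trailing `>` marks an abandoned (incomplete) c-unit;
- fillers are the closed set *ah, uh, um, mm, hmm, like, well, you
  know, I mean*, with multiword fillers merged greedily left-to-right.

A maze is a **content maze** iff it contains at least one non-filler,
intelligible token; otherwise it is filler-only.

## The seven measures

Eligible c-units for `mlum` and `ndwr` are the child's complete, fluent
(maze-free) and fully intelligible c-units. `ndwr` counts distinct word
roots (the part before any slash); no lemmatization is attempted, so
*ran* and *run/ing* contribute two roots — this is deliberate, matching
hand-scoring conventions for "different word roots". `um_prop` counts
*um* and *uh* everywhere they occur (inside and outside mazes) and is
undefined (encoded `None`/NA, never imputed) when the denominator is
zero. `content_maze_prop` divides content mazes by content mazes plus
filler *tokens* in filler-only mazes. `unintell_prop` is over all child
c-units; `cpm` counts attempted (including abandoned) child c-units per
minute.

### Repetition matching

Child turns are compared with the examiner's immediately previous turn
only (consecutive same-speaker c-units form one turn). Words inside
mazes are excluded on both sides. Clitic suffixes (`'s`, `'m`, `'re`)
are split into standalone units; other slash suffixes are joined onto
their root. Three rules relax exact matching:

- substitution classes {you, i, me, we, us}, {him, her}, {he, she} are
  interchangeable;
- the deletable function words {the, a, an, is, are, am, 'm, 's, 're}
  are removed from **both** turns before matching and excluded from the
  denominator;
- a matched set is a contiguous run of ≥ 2 surviving words present in
  both turns; child-side sets may not overlap, and the matcher maximizes
  the number of covered child words.

The matcher is a dynamic program (common-run-length matrix plus a
backward optimal-coverage pass). Its correctness is pinned by a
brute-force enumeration oracle (exhaustive span selection, guarded to
short turns) that the test suite compares against on hundreds of random
turn pairs. The proportion is matched child words over surviving child
words; with no surviving words the measure is an error, not a zero.

## Ordinal recoding

Per-cohort centile bins map each raw measure to a 1–4 impairment score.
For measures where high values indicate impairment, thresholds sit at
the 50/75/90th centiles (numpy's default "linear" quantile, i.e. type
7); intervals are right-closed, so a value exactly at a threshold takes
the lower bin. For measures where *low* values indicate impairment
(`mlum`, `ndwr`, `um_prop`, `cpm`) the bins are fitted at the
10/25/50th centiles and the score is reflected (5 − base), which is
equivalent to binning the reversed variable at 50/75/90 and keeps bin
occupancies at 50/25/15/10%.

`um_prop` gets a zero-adjustment: when more than 10% of the cohort sits
exactly at zero (children who never say *um*), the floor mass would
otherwise straddle a threshold; the lowest threshold is clamped so that
all exact zeros receive the maximum impairment score of 4. The fitted
bins serialize to JSON so they can be reapplied unchanged to new data.

## Validation battery

- **Group comparison** per measure: tie-corrected Kruskal–Wallis H with
  χ² p (df = k − 1) and rank η² = (H − k + 1)/(n − k), reported
  unclamped; Games–Howell pairwise post-hocs (unpooled SEs,
  Welch–Satterthwaite df, studentized-range p with k groups) when ≥ 3
  groups.
- **Convergent validity**: pairwise-complete Spearman correlations.
- **Classification**: binary logistic models of case status — a
  covariates-only baseline (age, IQ), one model per ordinal measure
  (entered as a 4-level factor, reference level 1, joint 3-df Wald
  test), and a combined all-measure model. Reported per model: −2 log
  likelihood, Nagelkerke R², in-sample accuracy/sensitivity/specificity
  at a 0.5 cutoff (ties predicted positive), and ROC AUC.
- **Exclusion accounting**: all nine models are fitted on one identical
  listwise-complete subsample (rows missing any covariate or any score
  are dropped from every model), with the excluded IDs reported.

Numerical choices: model fitting is delegated to statsmodels
(Newton-based `Logit`, falling back to IRLS GLM under separation, which
is flagged, with any |β| > 20 also treated as separation); the log
likelihood is recomputed from clipped fitted probabilities so it stays
finite under separation; Nagelkerke R² = Cox–Snell / max-Cox–Snell with
an exact-zero snap for the null model; ROC construction uses
scikit-learn and equals the pairwise concordance probability with half
credit for ties. The η² formula, Games–Howell machinery and Nagelkerke
rescaling are implemented in-package and cross-checked in the tests
against independent implementations (a hand-written IRLS fitter, a
permutation test, and `pingouin.pairwise_gameshowell`).

## Synthetic cohorts

The generator emulates the conversation task: the examiner asks
scripted open-ended questions about friends and relationships; the
child answers in bursts of c-units from a per-participant token model.
Group-level defaults for the case and control groups follow the
direction and rough magnitude of published case–control contrasts on
these measures (case group: shorter utterances, smaller vocabulary,
more content mazes, weaker *um* preference, more unintelligibility,
slower rate, more echoes); they are fixed study conditions, not tuning
knobs.

Realism devices, and why they are there:

- **Participant heterogeneity**: each child's parameters are drawn
  around the group means (lognormal jitter on utterance length and
  vocabulary size, beta jitter on the probabilities) with magnitudes
  chosen so group-level measure SDs land near published clinical
  descriptives. Without this the groups separate perfectly and every
  classification statistic saturates.
- **Finite Zipf vocabulary** so lexical diversity saturates with sample
  length the way real vocabularies do; the child lexicon is disjoint
  from the examiner's words so any detected repetition is planted
  echolalia by construction.
- **Negative-binomial utterance lengths** (gamma–Poisson, r = 8) for
  realistic overdispersion.
- **Echoes** copy a contiguous 2–5-word window of the examiner's
  previous question, with a 50% pronoun flip, exercising exactly the
  matcher's substitution rules.
- Duration is derived from the number of c-units and a per-participant
  speech rate, so `cpm` recovers the planted rate.

`parameter_recovery_check` regenerates replicate cohorts and compares
group-level measure means with the planted parameters for the five
measures that map one-to-one onto a generative parameter.

Problem sizes are this package's own choice, set to what a single CPU
handles comfortably: n = 50/group for planted-effect demonstrations,
n = 30/group with ~20 c-units per transcript for the null replications
(2000 cohorts ≈ 5 minutes), and ≤ 8-token turns for the brute-force
matcher oracle.

## Known limits

- **Kruskal–Wallis calibration on floored measures.** On short null
  transcripts several measures (`content_maze_prop`,
  `unintell_prop`, `repetition_prop`) are heavily tied and floored at 0,
  and the χ² approximation to the tie-corrected H statistic is then
  only approximate. Over 2000 null cohorts (two identical groups,
  n = 30/group, ~20 c-units each, replicate seeds 1000 + r) the
  measured rejection rates at α = 0.05 are: mlum 0.052, ndwr 0.0545,
  um_prop 0.051, content_maze_prop 0.0635, unintell_prop 0.0425, cpm
  0.0535, repetition_prop 0.050. `content_maze_prop` sits just outside
  the [0.04, 0.06] band, and shifting the transcript length moves the
  excursion to a different measure rather than removing it. The
  implementation itself is verified: on identical data the H statistic
  and p-value agree with R's `kruskal.test` to six decimals. The strict
  calibration acceptance test is therefore left failing honestly rather
  than being loosened; an exact permutation or rank-transform
  alternative for small, heavily tied samples is future work.
- All classification metrics are **in-sample**; with 17+ parameters on
  ~100 rows the combined model can saturate (AUC 1.0). The battery is a
  validity workup, not an out-of-sample classifier benchmark.
- The generator plants no correlation structure between measures beyond
  what the shared token model induces, and covariates (age, IQ) are
  independent of the transcript given the group.
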