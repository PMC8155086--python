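import numpy as np
import pandas as pd
import pytest

from almkit import parse_transcript
from almkit.measures import ALM_NAMES, compute_profile
from almkit.recoding import apply_bins, fit_bins
from almkit.synth import default_cohort_spec, generate_cohort

# A ten-utterance child sample exercising every dialect feature: filler and
# content mazes, multiword fillers, bound morphemes, clitics, an
# unintelligible word, an abandoned c-unit, adjacent mazes.  The expected
# measure values below were tallied by hand from the transcription rules and
# are frozen as the oracle.
TEN_UTTERANCE_TEXT = """\
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

# eligible c-units: 2 (5 morphemes), 4 (4), 8 (3), 9 (6) -> MLUM 18/4
# roots over eligible: we go to the park he really nice it was fun dog run
# around -> 14; um: lines 1, 10; uh: lines 5, 10 -> um prop 2/4
# mazes: 1 content (my mom); filler-only mazes hold 5 filler tokens
# (um, uh, "you know" as one merged unit, um, uh) -> 1 / (1 + 5)
# unintelligible: line 6 of 10; cpm: 10 / 2.5 min
TEN_UTTERANCE_EXPECTED = {
    "mlum": 4.5,
    "ndwr": 14,
    "um_prop": 0.5,
    "content_maze_prop": 1.0 / 6.0,
    "unintell_prop": 0.1,
    "cpm": 4.0,
    "repetition_prop": 0.0,
}

WORKED_EXCHANGE = "E And the moon was coming up.\nC The moon was coming up then.\n"


@pytest.fixture
def ten_utterance_transcript():
    return parse_transcript(TEN_UTTERANCE_TEXT)


@pytest.fixture
def worked_exchange():
    return parse_transcript(WORKED_EXCHANGE, duration_min=1.0)


@pytest.fixture(scope="session")
def planted_cohort():
    """One fixed-seed two-group cohort with planted case-control effects,
    shared across tests (generation is the expensive step)."""
    return generate_cohort(default_cohort_spec(n_per_group=50, seed=1))


@pytest.fixture(scope="session")
def planted_cohort_table(planted_cohort):
    df = pd.DataFrame([
        {"participant_id": p.participant_id, "group": p.group,
         "age": p.age, "iq": p.iq,
         **compute_profile(p.transcript).as_dict()}
        for p in planted_cohort])
    # a handful of missing IQ scores, as clinical cohorts have
    df.loc[df.index[:5], "iq"] = np.nan
    for alm in ALM_NAMES:
        bins = fit_bins(df[alm], alm)
        df[alm + "_score"] = [
            apply_bins(v, bins) if not np.isnan(v) else np.nan
            for v in df[alm].astype(float)]
    return df
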