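import json
import os
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from almkit.measures import compute_profile
from almkit.salt import write_transcript
from almkit.synth import (
    ASD_PARAMS, CONTROL_PARAMS, CohortSpec, GroupParams,
    default_cohort_spec, generate_cohort, null_cohort_spec,
    parameter_recovery_check, write_cohort,
)


def _small_spec(params: GroupParams, n: int = 8, seed: int = 0) -> CohortSpec:
    return CohortSpec(groups={"g": params}, sizes={"g": n}, seed=seed)


class TestDeterminism:
    def test_same_seed_reproduces_cohort_byte_for_byte(self):
        spec = default_cohort_spec(n_per_group=4, seed=9, mean_cunits=20)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        for pa, pb in zip(a, b):
            assert write_transcript(pa.transcript) == \
                write_transcript(pb.transcript)
            assert (pa.age, pa.iq, pa.sex, pa.group) == \
                (pb.age, pb.iq, pb.sex, pb.group)

    def test_different_seeds_differ(self):
        a = generate_cohort(default_cohort_spec(2, seed=1, mean_cunits=20))
        b = generate_cohort(default_cohort_spec(2, seed=2, mean_cunits=20))
        assert any(write_transcript(x.transcript)
                   != write_transcript(y.transcript) for x, y in zip(a, b))

    def test_ids_unique_and_groups_sized(self):
        cohort = generate_cohort(default_cohort_spec(5, seed=3,
                                                     mean_cunits=15))
        ids = [p.participant_id for p in cohort]
        assert len(set(ids)) == len(ids) == 10
        assert sum(p.group == "asd" for p in cohort) == 5


class TestPlantedEdgeCases:
    def test_zero_echo_probability_gives_zero_repetition(self):
        params = replace(CONTROL_PARAMS, echo_prob=0.0, mean_cunits=30.0)
        for p in generate_cohort(_small_spec(params, seed=4)):
            prof = compute_profile(p.transcript)
            assert prof.repetition_prop == 0.0

    def test_nonzero_echo_probability_is_detected(self):
        params = replace(CONTROL_PARAMS, echo_prob=0.5, mean_cunits=40.0)
        props = [compute_profile(p.transcript).repetition_prop
                 for p in generate_cohort(_small_spec(params, seed=5))]
        assert np.mean(props) > 0.0

    def test_um_pref_one_yields_um_proportion_one(self):
        params = replace(CONTROL_PARAMS, um_pref=1.0, mean_cunits=40.0)
        props = [compute_profile(p.transcript).um_prop
                 for p in generate_cohort(_small_spec(params, seed=6))]
        defined = [v for v in props if v is not None]
        assert defined and all(v == 1.0 for v in defined)

    def test_no_mazes_means_undefined_content_maze_proportion(self):
        params = replace(CONTROL_PARAMS, maze_rate=0.0, mean_cunits=20.0)
        for p in generate_cohort(_small_spec(params, seed=7)):
            prof = compute_profile(p.transcript)
            assert prof.content_maze_prop is None
            assert prof.um_prop is None

    def test_zero_unintelligibility(self):
        params = replace(CONTROL_PARAMS, unintell_prob=0.0, mean_cunits=20.0)
        for p in generate_cohort(_small_spec(params, seed=8)):
            assert compute_profile(p.transcript).unintell_prop == 0.0


class TestRecovery:
    def test_planted_parameters_recovered(self):
        df = parameter_recovery_check(
            default_cohort_spec(n_per_group=50, seed=13), n_reps=3)
        means = df.groupby(["group", "alm"])[
            ["recovered_mean", "planted"]].mean()
        for group in ("asd", "control"):
            for alm, tol in (("um_prop", 0.05), ("content_maze_prop", 0.07),
                             ("cpm", 1.0)):
                row = means.loc[(group, alm)]
                assert abs(row["recovered_mean"] - row["planted"]) < tol, \
                    (group, alm)

    def test_group_contrasts_point_the_planted_direction(self):
        df = parameter_recovery_check(default_cohort_spec(50, seed=17),
                                      n_reps=2)
        m = df.groupby(["group", "alm"])["recovered_mean"].mean()
        # case group: shorter utterances, fewer distinct roots, lower um
        # preference, slower; more content mazes and unintelligibility
        for alm in ("mlum", "ndwr", "um_prop", "cpm"):
            assert m[("asd", alm)] < m[("control", alm)], alm
        for alm in ("content_maze_prop", "unintell_prop", "repetition_prop"):
            assert m[("asd", alm)] > m[("control", alm)], alm

    def test_null_spec_groups_are_exchangeable(self):
        spec = null_cohort_spec(n_per_group=5, seed=0)
        assert spec.groups["a"] == spec.groups["b"]
        assert spec.groups["a"].mean_cunits == 20.0


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"maze_rate": 1.5}, {"um_pref": -0.1}, {"cpm": 0.0},
        {"vocab_size": 3}, {"mean_cunits": 0.0},
    ])
    def test_invalid_group_params(self, kwargs):
        with pytest.raises(ValueError):
            GroupParams(**kwargs)

    def test_mismatched_group_keys(self):
        with pytest.raises(ValueError):
            CohortSpec(groups={"a": ASD_PARAMS}, sizes={"b": 3})

    def test_nonpositive_size(self):
        with pytest.raises(ValueError):
            CohortSpec(groups={"a": ASD_PARAMS}, sizes={"a": 0})


class TestWriteCohort:
    def test_files_table_and_params_emitted(self, tmp_path):
        cohort = generate_cohort(default_cohort_spec(2, seed=21,
                                                     mean_cunits=10))
        table = write_cohort(cohort, str(tmp_path))
        df = pd.read_csv(table)
        assert len(df) == 4
        assert {"participant_id", "group", "age", "iq", "sex",
                "duration_min"} <= set(df.columns)
        for pid in df["participant_id"]:
            assert os.path.exists(tmp_path / f"{pid}.slt")
        with open(tmp_path / "true_params.json") as fh:
            params = json.load(fh)
        assert set(params) == {"asd", "control"}
        assert params["asd"]["um_pref"] == pytest.approx(0.455)
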