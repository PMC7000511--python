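"""Session generation, recency validation, cohort sampling, synthesis."""

import math

import numpy as np
import pandas as pd
import pytest

from piddm import (
    CONDITIONS,
    InfeasibleDesignError,
    SessionDesign,
    TrialSpec,
    generate_session,
    sample_cohort,
    validate_sequence,
)
from piddm.task import (
    BURN_IN_TRIALS,
    CONSONANT_POOL,
    GROUP_ESTIMATES,
    CohortSpec,
    GroupSpec,
    default_cohort_spec,
    group_spec_from_estimates,
    read_behavior_csv,
    synthesize_dataset,
    write_behavior_csv,
)


class TestSessionDesign:
    def test_default_totals(self):
        d = SessionDesign()
        assert d.n_trials == 480
        assert d.condition_counts() == {
            "positive": 240,
            "nonrecent_negative": 120,
            "recent_negative": 120,
        }

    def test_counts_sum_exactly_with_awkward_proportions(self):
        d = SessionDesign(
            n_blocks=1,
            trials_per_block=160,
            proportions={"positive": 1 / 3, "nonrecent_negative": 1 / 3, "recent_negative": 1 / 3},
        )
        counts = d.condition_counts()
        assert sum(counts.values()) == 160

    def test_bad_proportions_raise(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SessionDesign(proportions={"positive": 0.5, "nonrecent_negative": 0.5, "recent_negative": 0.5})

    def test_duplicate_pool_raises(self):
        with pytest.raises(ValueError, match="duplicates"):
            SessionDesign(stimulus_pool=("b", "b", "c", *CONSONANT_POOL[3:]))


class TestGenerateSession:
    def test_default_session_counts_and_zero_violations(self, session_trials):
        report = validate_sequence(session_trials)
        assert report.n_trials == 480
        assert report.condition_counts == {
            "positive": 240,
            "nonrecent_negative": 120,
            "recent_negative": 120,
        }
        assert report.n_violations == 0 and report.ok

    def test_burn_in_has_no_recent_negatives(self, session_trials):
        for t in session_trials[:BURN_IN_TRIALS]:
            assert t.condition != "recent_negative"

    def test_many_seeds_all_valid(self):
        for seed in range(5):
            trials = generate_session(SessionDesign(n_blocks=1, trials_per_block=80), seed)
            assert validate_sequence(trials).ok

    def test_deterministic_per_seed(self):
        a = generate_session(SessionDesign(), seed=7)
        b = generate_session(SessionDesign(), seed=7)
        c = generate_session(SessionDesign(), seed=8)
        assert a == b
        assert a != c

    def test_target_set_size(self, session_trials):
        assert all(len(t.target_set) == 4 for t in session_trials)
        assert all(len(set(t.target_set)) == 4 for t in session_trials)

    def test_block_assignment(self, session_trials):
        assert session_trials[0].block == 1
        assert session_trials[160].block == 2
        assert session_trials[-1].block == 3

    def test_small_pool_infeasible(self):
        with pytest.raises(InfeasibleDesignError, match="pool"):
            generate_session(SessionDesign(stimulus_pool=tuple("bcdfghjk")), seed=0)

    def test_all_recent_infeasible(self):
        design = SessionDesign(
            n_blocks=1,
            trials_per_block=10,
            proportions={"positive": 0.0, "nonrecent_negative": 0.0, "recent_negative": 1.0},
        )
        with pytest.raises(InfeasibleDesignError):
            generate_session(design, seed=0)


class TestValidateSequence:
    def _trial(self, i, target, probe, condition):
        return TrialSpec(index=i, block=1, target_set=tuple(target), probe=probe, condition=condition)

    def test_detects_planted_violations(self):
        trials = [
            self._trial(0, "bcdf", "g", "nonrecent_negative"),
            self._trial(1, "klmn", "z", "recent_negative"),  # z not in previous set
            self._trial(2, "pqrs", "q", "positive"),
            self._trial(3, "tvwx", "t", "nonrecent_negative"),  # probe in current set
        ]
        report = validate_sequence(trials)
        labels = [msg for _i, msg in report.violations]
        assert any("not in preceding" in m for m in labels)
        assert any("in current target set" in m for m in labels)
        assert report.n_violations == 2

    def test_recent_without_lookback_flagged(self):
        trials = [self._trial(0, "bcdf", "g", "recent_negative")]
        report = validate_sequence(trials)
        assert any("no preceding" in m for _i, m in report.violations)

    def test_nonrecent_two_back_flagged(self):
        trials = [
            self._trial(0, "bcdf", "g", "nonrecent_negative"),
            self._trial(1, "klmn", "z", "nonrecent_negative"),
            self._trial(2, "pqrs", "b", "nonrecent_negative"),  # b in set two back
        ]
        report = validate_sequence(trials)
        assert any("2 back" in m for _i, m in report.violations)

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="empty"):
            validate_sequence([])


class TestCohortSampling:
    def test_sd_from_se_scaling(self):
        spec = group_spec_from_estimates("young")
        est = GROUP_ESTIMATES["young"]
        root_n = math.sqrt(est["n"])
        assert spec.sds["a"] == pytest.approx(est["a_se"] * root_n)
        assert spec.sds["v"]["positive"] == pytest.approx(est["v_se"]["positive"] * root_n)

    def test_default_cohort_sizes(self):
        cohort = sample_cohort(default_cohort_spec(seed=3))
        groups = pd.Series([p.group for p in cohort.values()]).value_counts()
        assert groups["young"] == 25 and groups["older"] == 38

    def test_zero_sd_returns_exact_means(self):
        g = group_spec_from_estimates("young", sd_from_se=False)
        cohort = sample_cohort(CohortSpec(groups=[g], seed=0))
        p = next(iter(cohort.values()))
        assert p.params.v["positive"] == GROUP_ESTIMATES["young"]["v"]["positive"]
        assert p.params.a["positive"] == GROUP_ESTIMATES["young"]["a"]

    def test_deterministic(self):
        a = sample_cohort(default_cohort_spec(seed=11))
        b = sample_cohort(default_cohort_spec(seed=11))
        for pid in a:
            assert a[pid].params.to_dict() == b[pid].params.to_dict()

    def test_large_cohort_mean_near_target(self):
        g = group_spec_from_estimates("young", n_participants=400)
        cohort = sample_cohort(CohortSpec(groups=[g], seed=5))
        vs = np.array([p.params.v["positive"] for p in cohort.values()])
        sd = g.sds["v"]["positive"]
        # sample mean within 4 standard errors of the target
        assert abs(vs.mean() - 0.366) < 4 * sd / math.sqrt(400)

    def test_mean_below_bound_raises(self):
        g = GroupSpec("bad", 2, means={"v": 0.001, "a": 0.15, "ter": 0.3})
        with pytest.raises(ValueError, match="below bound"):
            sample_cohort(CohortSpec(groups=[g]))

    def test_negative_sd_raises(self):
        with pytest.raises(ValueError, match="SD"):
            GroupSpec("bad", 2, means={"v": 0.3, "a": 0.15, "ter": 0.3}, sds={"a": -0.1})


class TestSynthesizeDataset:
    def test_schema_and_size(self, young_params):
        from piddm.task import Participant

        cohort = {"p1": Participant("p1", "young", young_params)}
        design = SessionDesign(n_blocks=1, trials_per_block=48)
        df = synthesize_dataset(cohort, design, seed=4)
        assert len(df) == 48
        assert list(df["participant_id"].unique()) == ["p1"]
        assert set(df["condition"]) <= set(CONDITIONS)
        assert (df["rt_s"] > 0).all()
        assert set(df["accuracy"]) <= {0, 1}

    def test_participant_data_independent_of_cohort(self, young_params, older_params):
        from piddm.task import Participant

        design = SessionDesign(n_blocks=1, trials_per_block=48)
        solo = synthesize_dataset({"p1": Participant("p1", "young", young_params)}, design, seed=4)
        both = synthesize_dataset(
            {
                "p1": Participant("p1", "young", young_params),
                "p2": Participant("p2", "older", older_params),
            },
            design,
            seed=4,
        )
        pd.testing.assert_frame_equal(solo, both[both["participant_id"] == "p1"].reset_index(drop=True))

    def test_csv_round_trip(self, tmp_path, young_dataset):
        path = tmp_path / "behavior.csv"
        write_behavior_csv(young_dataset, path)
        back = read_behavior_csv(path)
        assert len(back) == len(young_dataset)
        assert np.allclose(back["rt_s"], young_dataset["rt_s"])

    def test_csv_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"rt_s": [0.5]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_behavior_csv(path)
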