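"""Trajectory assembly, outcome classification, milestone tables."""

import pytest
from hypothesis import given, settings, strategies as st

from ddtcf.errors import ValidationError
from ddtcf.monitoring import (
    CultureTimepoint,
    Medium,
    Milestones,
    Outcome,
    Stage,
    build_trajectory,
    classify_outcome,
    milestone_table,
    read_longitudinal_csv,
    relative_change,
    write_outcome_csv,
)


def _tp(stage, tcf=None, passage=None, medium=Medium.ABM):
    if stage is Stage.P0:
        medium = Medium.NONE
    return CultureTimepoint(
        stage=stage,
        passage_index=stage.value if passage is None else passage,
        medium=medium,
        tcf=tcf,
    )


def _full_trajectory(final_tcf, transduced=True, sample_id="S1"):
    stages = [_tp(Stage.P0, 0.5), _tp(Stage.P1, 0.5)]
    if transduced:
        stages.append(_tp(Stage.TRANSDUCED, 0.6))
    stages.append(_tp(Stage.FINAL, final_tcf, passage=10))
    return build_trajectory(sample_id, Medium.ABM, stages)


class TestBuildTrajectory:
    def test_p0_only_has_no_milestones(self):
        traj = build_trajectory("S1", Medium.ABM, [_tp(Stage.P0, 0.4)])
        assert not traj.milestones.viable_at_p1
        assert not traj.milestones.transduced
        assert traj.milestones.line_established is None

    def test_full_chain_milestones(self):
        traj = _full_trajectory(1.0)
        assert traj.milestones.viable_at_p1 and traj.milestones.transduced
        assert traj.milestones.line_established is None  # unset until classified

    def test_duplicate_stage_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            build_trajectory("S1", Medium.ABM, [_tp(Stage.P1, 0.5), _tp(Stage.P1, 0.6)])

    def test_timepoints_sorted_by_stage(self):
        traj = build_trajectory(
            "S1", Medium.ABM, [_tp(Stage.FINAL, 0.9, passage=9), _tp(Stage.P0, 0.5)]
        )
        assert [tp.stage for tp in traj.timepoints] == [Stage.P0, Stage.FINAL]

    def test_p0_medium_must_be_none(self):
        with pytest.raises(ValidationError):
            CultureTimepoint(Stage.P0, 0, Medium.ABM, 0.5)


class TestRelativeChange:
    @pytest.mark.parametrize(
        "p0, p1, expected", [(0.5, 0.5, 0.0), (0.4, 0.6, 0.5), (0.5, 0.25, -0.5)]
    )
    def test_arithmetic(self, p0, p1, expected):
        assert relative_change(p0, p1) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            relative_change(0.0, 0.5)

    @given(
        st.floats(min_value=0.01, max_value=1.0),
        st.floats(min_value=-0.9, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_identity(self, f, x):
        assert relative_change(f, f * (1 + x)) == pytest.approx(x, abs=1e-9)


class TestClassifyOutcome:
    def test_terminal_states(self):
        assert classify_outcome(_full_trajectory(1.0)).outcome is Outcome.ESTABLISHED
        assert classify_outcome(_full_trajectory(0.0)).outcome is Outcome.FAILED
        assert classify_outcome(_full_trajectory(0.5)).outcome is Outcome.INDETERMINATE

    def test_missing_final_tcf_rejected(self):
        traj = build_trajectory("S1", Medium.ABM, [_tp(Stage.P0, 0.5), _tp(Stage.P1, 0.5)])
        with pytest.raises(ValidationError):
            classify_outcome(traj)

    def test_untransduced_culture_is_never_established(self):
        traj = _full_trajectory(1.0, transduced=False)
        call = classify_outcome(traj)
        assert call.outcome is not Outcome.ESTABLISHED

    def test_sets_line_established_milestone(self):
        traj = _full_trajectory(1.0)
        classify_outcome(traj)
        assert traj.milestones.line_established is True
        traj = _full_trajectory(0.0)
        classify_outcome(traj)
        assert traj.milestones.line_established is False

    def test_depends_only_on_final_and_milestones(self):
        with_intermediate = _full_trajectory(1.0)
        without = build_trajectory(
            "S1",
            Medium.ABM,
            [_tp(Stage.P1, 0.01), _tp(Stage.TRANSDUCED, 0.02), _tp(Stage.FINAL, 1.0, passage=9)],
        )
        assert (
            classify_outcome(with_intermediate).outcome
            is classify_outcome(without).outcome
            is Outcome.ESTABLISHED
        )

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            classify_outcome(_full_trajectory(1.0), success_threshold=0.2, failure_threshold=0.5)


class TestMilestoneTable:
    def test_aggregate_counts(self):
        # 17 viable cultures, 10 transduced, 3 of those established
        trajs = []
        for i in range(17):
            transduced = i < 10
            final_tcf = 1.0 if i < 3 else 0.0
            t = _full_trajectory(final_tcf, transduced=transduced, sample_id=f"S{i}")
            classify_outcome(t)
            trajs.append(t)
        table = milestone_table(trajs)
        assert int(table["viable_at_p1"].sum()) == 17
        assert int(table["transduced"].sum()) == 10
        assert int(table["line_established"].sum()) == 3

    def test_empty_input(self):
        assert milestone_table([]).empty

    def test_one_sample_two_media_gives_two_rows(self):
        t1 = build_trajectory("S1", Medium.ABM, [_tp(Stage.P0, 0.5)])
        t2 = build_trajectory("S1", Medium.NSM, [_tp(Stage.P0, 0.5)])
        table = milestone_table([t1, t2])
        assert len(table) == 2 and set(table["medium"]) == {"ABM", "NSM"}

    def test_milestone_chain_is_monotone(self):
        with pytest.raises(ValidationError):
            Milestones(viable_at_p1=False, transduced=True)
        with pytest.raises(ValidationError):
            Milestones(viable_at_p1=True, transduced=False, line_established=True)


class TestLongitudinalCsv:
    def test_read_and_classify(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "sample_id,medium,stage,passage_index,tcf\n"
            "S1,ABM,P0,0,0.5\n"
            "S1,ABM,P1,1,0.6\n"
            "S1,ABM,TRANSDUCED,2,0.8\n"
            "S1,ABM,FINAL,12,1.0\n"
            "S1,NSM,P0,0,0.5\n"
            "S1,NSM,P1,1,NA\n"
        )
        trajs = read_longitudinal_csv(path)
        assert len(trajs) == 2
        abm = next(t for t in trajs if t.medium is Medium.ABM)
        call = classify_outcome(abm)
        assert call.outcome is Outcome.ESTABLISHED
        out = tmp_path / "outcome.csv"
        write_outcome_csv([(abm, call)], out)
        assert "S1,ABM,ESTABLISHED,1.0" in out.read_text()
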