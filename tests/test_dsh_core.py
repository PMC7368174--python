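import itertools

import pytest

from dshrisk.dsh_core import (
    PatientState,
    assign_scores,
    build_tree,
    classify_state,
    score_trajectory,
    state_score,
)
from dshrisk.ehr_data import ConfigurationError, WindowError

from conftest import ev, make_timeline

BTW = (50.0, 56.0)


def right_turn_scores(node, rights=0, root_score=1.0, acc=None):
    if acc is None:
        acc = []
    acc.append((node.score, root_score * 2 ** rights))
    if node.left is not None:
        right_turn_scores(node.left, rights, root_score, acc)
    if node.right is not None:
        right_turn_scores(node.right, rights + 1, root_score, acc)
    return acc


class TestTreeConstruction:
    def test_four_level_tree_has_max_score_eight(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        scores = {n.score for n in tree.root.walk()}
        assert tree.max_score() == 8
        assert scores == {1, 2, 4, 8}

    def test_two_level_tree_scores(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=2)
        assert {n.score for n in tree.root.walk()} == {1, 2}

    @pytest.mark.parametrize("n_levels", range(2, 7))
    def test_max_score_law(self, config, n_levels):
        # oracle: fold the doubling rule n_levels - 1 times from a root of 1
        expected = 1
        for _ in range(n_levels - 1):
            expected *= 2
        tree = build_tree(config.conditions["t2d"], n_levels=n_levels)
        assert tree.max_score() == expected

    @pytest.mark.parametrize("n_levels", range(2, 7))
    def test_score_conservation_exhaustive(self, config, n_levels):
        """Every node's score equals root x 2^(right turns on its path)."""
        tree = build_tree(config.conditions["t2d"], n_levels=n_levels)
        for got, want in right_turn_scores(tree.root):
            assert got == want

    def test_root_score_zero_zeroes_everything(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        assign_scores(tree, 0)
        assert all(n.score == 0 for n in tree.root.walk())

    def test_left_branch_keeps_parent_score(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        node = tree.root.right.left  # right then left
        assert (tree.root.score, tree.root.right.score, node.score) == (1, 2, 2)

    def test_depth_out_of_range_rejected(self, config):
        with pytest.raises(ConfigurationError):
            build_tree(config.conditions["t2d"], n_levels=7)


def make_state(present=1, treated=0, line="none", dose="none", controlled=None,
               band=None, name="t2d"):
    return PatientState(name, 52.0, present, treated, line, dose, controlled, band)


class TestStateScore:
    def test_disease_free_scores_zero(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        assert state_score(tree, make_state(present=0)) == 0

    def test_maximally_intensified_scores_eight(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        st = make_state(treated=1, line="last", controlled=0)
        assert state_score(tree, st) == 8

    def test_all_left_path_keeps_root_score(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        st = make_state(treated=0, controlled=1)
        assert state_score(tree, st) == 1

    def test_unknown_control_maps_left(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        assert state_score(tree, make_state(treated=1, line="first")) == 2

    def test_monotone_intensification(self, config):
        """Flipping any field to its more severe value never lowers the score."""
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        lines = ["first", "second", "last"]
        for treated, line, controlled in itertools.product(
                [0, 1], lines, [0, 1, None]):
            if not treated:
                line_eff = "none"
            else:
                line_eff = line
            base = state_score(tree, make_state(treated=treated, line=line_eff,
                                                controlled=controlled))
            if not treated:
                worse = state_score(tree, make_state(treated=1, line="first",
                                                     controlled=controlled))
                assert worse >= base
            elif line_eff != "last":
                nxt = lines[lines.index(line_eff) + 1]
                worse = state_score(tree, make_state(treated=1, line=nxt,
                                                     controlled=controlled))
                assert worse >= base
            if controlled != 0:
                worse = state_score(tree, make_state(treated=treated, line=line_eff,
                                                     controlled=0))
                assert worse >= base

    def test_mismatched_condition_rejected(self, config):
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        with pytest.raises(ValueError):
            state_score(tree, make_state(name="obesity", band=1))


class TestClassifyState:
    def test_worked_example_second_line_controlled(self, config):
        """Metformin + sulfonylurea with HbA1c 6.0%: diabetic, second-line, controlled."""
        tl = make_timeline(events=[
            ev(50.5, "medication", "metformin"),
            ev(51.0, "medication", "sulfonylurea"),
            ev(51.5, "lab", "hba1c", 6.0, "%"),
        ])
        st = classify_state(tl, config.conditions["t2d"], 52.0, BTW,
                            config.measurement_units)
        assert (st.present, st.treated, st.therapy_line, st.controlled) == (1, 1, "second", 1)
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        assert state_score(tree, st) == 4

    def test_null_state_when_never_indicated(self, config):
        tl = make_timeline(events=[ev(51.0, "lab", "hba1c", 5.5, "%")])
        st = classify_state(tl, config.conditions["t2d"], 52.0, BTW,
                            config.measurement_units)
        assert (st.present, st.treated, st.therapy_line) == (0, 0, "none")

    def test_lab_only_presence_untreated_uncontrolled(self, config):
        tl = make_timeline(events=[ev(51.0, "lab", "hba1c", 7.2, "%")])
        st = classify_state(tl, config.conditions["t2d"], 52.0, BTW,
                            config.measurement_units)
        assert (st.present, st.treated, st.controlled) == (1, 0, 0)

    def test_presence_is_sticky_after_control(self, config):
        tl = make_timeline(events=[
            ev(51.0, "lab", "hba1c", 7.2, "%"),
            ev(53.0, "lab", "hba1c", 6.0, "%"),
        ])
        st = classify_state(tl, config.conditions["t2d"], 54.0, BTW,
                            config.measurement_units)
        assert (st.present, st.controlled) == (1, 1)

    def test_hypertension_three_classes_is_last_line(self, config):
        tl = make_timeline(events=[
            ev(50.5, "medication", "ace_inhibitor"),
            ev(51.0, "medication", "diuretic"),
            ev(51.5, "medication", "beta_blocker"),
        ])
        st = classify_state(tl, config.conditions["hypertension"], 52.0, BTW,
                            config.measurement_units)
        assert st.therapy_line == "last"

    def test_obesity_bands_and_trend(self, config):
        tl = make_timeline(events=[
            ev(51.0, "vital", "bmi", 36.0),
            ev(52.0, "vital", "bmi", 41.0),
        ])
        st = classify_state(tl, config.conditions["obesity"], 53.0, BTW,
                            config.measurement_units)
        assert (st.present, st.band, st.controlled) == (1, 2, 0)
        tree = build_tree(config.conditions["obesity"], n_levels=4)
        assert state_score(tree, st) == 8  # >=35, >=40, rising

    def test_age_outside_window_raises(self, config):
        tl = make_timeline()
        with pytest.raises(WindowError):
            classify_state(tl, config.conditions["t2d"], 58.0, BTW)


class TestScoreTrajectory:
    def test_one_sample_per_encounter(self, config):
        tl = make_timeline(events=[ev(50.5 + i, "lab", "hba1c", 7.0, "%")
                                   for i in range(5)])
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        traj = score_trajectory(tl, tree, config.conditions["t2d"], BTW,
                                config.measurement_units)
        assert len(traj.samples) == 5
        assert traj.ages == sorted(traj.ages)

    def test_disease_free_patient_all_zero(self, config):
        tl = make_timeline(events=[ev(51.0, "lab", "hba1c", 5.2, "%"),
                                   ev(52.0, "lab", "hba1c", 5.4, "%")])
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        traj = score_trajectory(tl, tree, config.conditions["t2d"], BTW,
                                config.measurement_units)
        assert traj.scores == [0.0, 0.0]

    def test_escalating_therapy_non_decreasing_scores(self, config):
        tl = make_timeline(events=[
            ev(51.0, "medication", "metformin"),
            ev(52.0, "medication", "sulfonylurea"),
            ev(53.0, "medication", "insulin"),
        ])
        tree = build_tree(config.conditions["t2d"], n_levels=4)
        traj = score_trajectory(tl, tree, config.conditions["t2d"], BTW,
                                config.measurement_units)
        scores = traj.scores
        assert scores == sorted(scores)
        assert scores[0] > 0  # therapy implies presence
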