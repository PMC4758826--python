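"""Event structure, stage partitioning, HRF convolution and design assembly."""

import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist

from lfconn.task_design import (
    EventTrain,
    TRIAL_RATE_S,
    assemble_design,
    build_study_design,
    canonical_hrf_convolve,
    first_level_design,
    novelty_contrast,
    read_design,
    read_events,
    stage_regressors,
    task_contrast,
    write_design,
    write_events,
)


class TestBuildStudyDesign:
    def test_instruction_has_four_rule_slides_of_4s(self):
        trains, _ = build_study_design("instruction", 4, seed=0)
        assert len(trains["rule"]) == 4
        assert np.allclose(trains["rule"].durations, 4.0)

    def test_trial_slot_count_and_fixation_fraction(self):
        # one 180-s block: slots of 1.7 s, exactly 1/3 fixation
        trains, _ = build_study_design("instruction", 1, seed=5)
        n_slots = int(np.floor(180.0 / TRIAL_RATE_S))
        n_fix = round(n_slots / 3)
        assert len(trains["fixation"]) == n_fix
        assert len(trains["trial"]) == n_slots - n_fix

    def test_zero_length_block_gives_empty_trial_train(self):
        trains, _ = build_study_design("instruction", 1, seed=0, block_length=0.0)
        assert len(trains["trial"]) == 0

    def test_feedback_follows_half_of_trials_on_average(self):
        trains, _ = build_study_design("feedback", 4, seed=1)
        n_fb = len(trains["feedback_pos"]) + len(trains["feedback_neg"])
        n_trials = len(trains["trial"])
        assert 0.4 < n_fb / n_trials < 0.6

    def test_negative_feedback_concentrates_early(self):
        # errors decay geometrically across stages, so most negative
        # feedback falls in the first stage of each block
        trains, part = build_study_design("feedback", 4, seed=2)
        neg = trains["feedback_neg"]
        # assign feedback (onset = trial onset + 1.7) back to its trial stage
        _, stages = part.stage_of(neg.onsets - TRIAL_RATE_S)
        assert (stages == 0).mean() > 0.5

    def test_block_lengths(self):
        _, p1 = build_study_design("instruction", 2, seed=0)
        _, p2 = build_study_design("feedback", 2, seed=0)
        assert p1.n_stages == 6 and p2.n_stages == 5
        # instruction blocks are offset by the 4-s rule slide
        assert np.allclose(np.diff(p1.block_starts), 184.0)
        assert np.allclose(np.diff(p2.block_starts), 150.0)

    @pytest.mark.parametrize("bad", ["unknown", "", "Instruction"])
    def test_unknown_study_rejected(self, bad):
        with pytest.raises(ValueError):
            build_study_design(bad, 1, seed=0)

    def test_nonpositive_blocks_rejected(self):
        with pytest.raises(ValueError):
            build_study_design("instruction", 0, seed=0)

    def test_same_seed_reproducible(self):
        a, _ = build_study_design("feedback", 2, seed=9)
        b, _ = build_study_design("feedback", 2, seed=9)
        for k in a:
            assert np.array_equal(a[k].onsets, b[k].onsets)


class TestStageRegressors:
    @pytest.mark.parametrize("study,n_stages", [("instruction", 6), ("feedback", 5)])
    def test_stage_count(self, study, n_stages):
        trains, part = build_study_design(study, 2, seed=3)
        stages = stage_regressors(trains["trial"], part)
        assert len(stages) == n_stages

    def test_stages_partition_trials_exactly(self, instruction_design):
        trains, part = instruction_design
        stages = stage_regressors(trains["trial"], part)
        pooled = np.sort(np.concatenate([s.onsets for s in stages]))
        assert np.array_equal(pooled, trains["trial"].onsets)
        counts = sum(len(s) for s in stages)
        assert counts == len(trains["trial"])

    def test_empty_train_gives_empty_stages(self, instruction_design):
        _, part = instruction_design
        empty = EventTrain("trial", [], [], [])
        stages = stage_regressors(empty, part)
        assert len(stages) == part.n_stages
        assert all(len(s) == 0 for s in stages)


class TestCanonicalHRFConvolve:
    def test_empty_train_gives_zero_vector(self):
        empty = EventTrain("x", [], [], [])
        r = canonical_hrf_convolve(empty, TR=2.0, n_scans=50)
        assert np.allclose(r, 0.0)

    def test_unit_impulse_samples_the_hrf(self):
        # impulse at t=0 -> regressor equals the canonical double-gamma
        # sampled at scan times, to fine-grid numerical accuracy
        train = EventTrain("x", [0.0], [0.0], [1.0])
        r = canonical_hrf_convolve(train, TR=2.0, n_scans=16)
        t = np.arange(16) * 2.0
        h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
        tf = np.arange(0, 32, 1e-3)
        hf = gamma_dist.pdf(tf, 6) - gamma_dist.pdf(tf, 16) / 6.0
        expected = h / hf.max()
        assert np.allclose(r, expected, atol=1e-6)

    def test_linearity_over_disjoint_trains(self):
        a = EventTrain("a", [0.0, 10.0], [1.7, 1.7], [1.0, 1.0])
        b = EventTrain("b", [5.0, 20.0], [1.7, 1.7], [1.0, 2.0])
        union = EventTrain(
            "u", [0.0, 5.0, 10.0, 20.0], [1.7] * 4, [1.0, 1.0, 1.0, 2.0]
        )
        ra = canonical_hrf_convolve(a, 2.0, 40)
        rb = canonical_hrf_convolve(b, 2.0, 40)
        ru = canonical_hrf_convolve(union, 2.0, 40)
        assert np.allclose(ru, ra + rb, atol=1e-12)

    def test_event_beyond_session_rejected(self):
        train = EventTrain("x", [120.0], [1.0], [1.0])
        with pytest.raises(ValueError):
            canonical_hrf_convolve(train, 2.0, 50)


class TestContrasts:
    def test_novelty_weights(self):
        assert np.array_equal(
            novelty_contrast("instruction").weights, [3, 2, 1, -1, -2, -3]
        )
        assert np.array_equal(novelty_contrast("feedback").weights, [2, 1, 0, -1, -2])

    def test_novelty_zero_sum_task_all_ones(self):
        for study in ("instruction", "feedback"):
            assert novelty_contrast(study).weights.sum() == 0
            assert np.all(task_contrast(study).weights == 1)
        assert task_contrast("instruction").weights.size == 6
        assert task_contrast("feedback").weights.size == 5

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError):
            novelty_contrast("other")


class TestAssembleDesign:
    @pytest.mark.parametrize("study", ["instruction", "feedback"])
    def test_full_first_level_design_has_14_columns(self, study):
        trains, part = build_study_design(study, 2, seed=4)
        n_scans = 184 if study == "instruction" else 150
        motion = np.zeros((n_scans, 6)) + np.arange(6)
        design = first_level_design(trains, part, motion, 2.0, n_scans)
        assert len(design.columns) == 14
        assert design.columns.count("constant") == 1

    def test_constant_only_matrix(self):
        d = assemble_design({}, None, 2.0, 30)
        assert d.columns == ["constant"]
        assert np.allclose(d.values, 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assemble_design({"x": np.zeros(10)}, None, 2.0, 20)

    def test_duplicate_names_rejected(self):
        from lfconn.task_design import DesignMatrix  # noqa: F401

        with pytest.raises(ValueError):
            assemble_design(
                {"motion_1": np.zeros(10)}, np.zeros((10, 6)), 2.0, 10
            )


class TestEventTrainInvariants:
    def test_nonascending_onsets_rejected(self):
        with pytest.raises(ValueError):
            EventTrain("x", [1.0, 1.0], [0, 0], [1, 1])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            EventTrain("x", [1.0], [0, 0], [1])


def test_events_and_design_tsv_roundtrip(tmp_path, instruction_design):
    trains, part = instruction_design
    p = tmp_path / "events.tsv"
    write_events(trains, p)
    back = read_events(p)
    assert set(back) == set(trains)
    assert np.allclose(back["trial"].onsets, trains["trial"].onsets)

    design = first_level_design(trains, part, np.zeros((184, 6)), 2.0, 184)
    q = tmp_path / "design.tsv"
    write_design(design, q)
    back_d = read_design(q, TR=2.0)
    assert back_d.columns == design.columns
    assert np.allclose(back_d.values, design.values)


def test_design_from_yaml_config(tmp_path):
    from lfconn.task_design import design_from_config

    cfg = tmp_path / "session.yaml"
    cfg.write_text("study: feedback\nn_blocks: 2\nseed: 5\nTR: 2.0\n")
    trains, partition, full = design_from_config(cfg)
    assert partition.n_stages == 5
    assert full["TR"] == 2.0
    ref, _ = build_study_design("feedback", 2, seed=5)
    assert np.array_equal(trains["trial"].onsets, ref["trial"].onsets)

    bad = tmp_path / "bad.yaml"
    bad.write_text("n_blocks: 2\n")
    with pytest.raises(ValueError):
        design_from_config(bad)
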