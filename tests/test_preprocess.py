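import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import graspmvpa as g
from graspmvpa.design import TrialEvent
from graspmvpa.preprocess import (PreprocessError, baseline_volume_indices,
                                  zscore_fold)
from graspmvpa.synth import MotionTrace, RoiTimeSeries


def make_trace(pid, run, n_vol, max_trans, max_rot):
    trans = np.zeros((n_vol, 3))
    rot = np.zeros((n_vol, 3))
    trans[n_vol // 2, 0] = max_trans
    rot[n_vol // 2, 1] = max_rot
    return MotionTrace(pid, run, trans, rot)


class TestExcludeRuns:
    @pytest.mark.parametrize("trans, rot, kept", [
        (1.9, 1.5, True),    # both under threshold
        (2.1, 0.5, False),   # translation alone excludes (either suffices)
        (0.5, 2.1, False),   # rotation alone excludes
        (2.0, 2.0, True),    # exactly at threshold is retained (strictly greater)
    ])
    def test_threshold_rule(self, trans, rot, kept):
        traces = {0: [make_trace(0, r, 20, 0.1, 0.1) for r in range(3)]
                  + [make_trace(0, 3, 20, trans, rot)]}
        retained = g.exclude_runs(traces)
        assert (3 in retained[0]) is kept

    def test_too_few_retained_runs_is_an_error(self):
        traces = {0: [make_trace(0, 0, 20, 0.1, 0.1),
                      make_trace(0, 1, 20, 5.0, 0.0),
                      make_trace(0, 2, 20, 5.0, 0.0)]}
        with pytest.raises(PreprocessError, match="at least 2"):
            g.exclude_runs(traces)


@pytest.fixture()
def flat_run(default_design):
    """A constant-100 run with the default trial layout."""
    table = g.build_trial_table(default_design, seed=0)
    events = table.for_run(0)
    n_vox = 5
    mat = np.full((n_vox, default_design.volumes_per_run), 100.0)
    return RoiTimeSeries(0, 0, "V1", mat, np.arange(n_vox)), events


class TestPercentSignalChange:
    def test_two_percent_step_reads_as_two(self, default_design, flat_run):
        ts, events = flat_run
        for ev in events:
            v = g.phase_volume_index(ev, "instruction", default_design)
            ts.matrix[:, v + 3: v + 6] = 102.0  # the lagged 3-volume window
        res = g.percent_signal_change(ts, events, "instruction", default_design)
        assert res.value == pytest.approx(2.0)

    def test_window_starts_three_volumes_after_onset(self, default_design, flat_run):
        ts, events = flat_run
        for ev in events:  # values at the onset volume itself must not matter
            v = g.phase_volume_index(ev, "instruction", default_design)
            ts.matrix[:, v] = 500.0
        res = g.percent_signal_change(ts, events, "instruction", default_design)
        assert res.value == pytest.approx(0.0)

    def test_null_generator_yields_zero(self, small_design):
        truth = g.make_ground_truth("null", seed=0, noise_sd=0.0,
                                    drift_amplitude=0.0,
                                    universal_response_amplitude=0.0,
                                    roi_names=("V1",), n_voxels_per_roi={"V1": 4})
        table = g.build_trial_table(small_design, 0)
        ts = g.simulate_roi_run(small_design, table.for_run(0), truth, "V1", 0)
        res = g.percent_signal_change(ts, table.for_run(0), "action", small_design)
        assert res.value == pytest.approx(0.0)

    def test_non_positive_baseline_is_an_error(self, default_design, flat_run):
        ts, events = flat_run
        ts.matrix[:] = 0.0
        with pytest.raises(PreprocessError, match="baseline"):
            g.percent_signal_change(ts, events, "action", default_design)

    def test_baseline_volumes_are_lead_in_plus_last_iti(self, default_design):
        table = g.build_trial_table(default_design, seed=0)
        events = table.for_run(0)
        base = baseline_volume_indices(default_design, events)
        assert list(base[:6]) == [0, 1, 2, 3, 4, 5]
        # first trial: onset 12 s, ITI ends at 36 s -> volume 17
        assert 17 in base
        assert len(base) == 6 + 16


@pytest.fixture()
def contrast_inputs(small_design):
    """Two flat runs where voxel 0 responds during stimulus windows."""
    table = g.build_trial_table(small_design, seed=1)
    rng = np.random.default_rng(0)
    ts_by_run, ev_by_run = {}, {}
    for run in range(2):
        events = table.for_run(run)
        mat = 100.0 + rng.normal(0, 0.5, (6, small_design.volumes_per_run))
        for ev in events:
            v = g.phase_volume_index(ev, "instruction", small_design)
            mat[0, v + 3: v + 6] += 5.0
        ts_by_run[run] = RoiTimeSeries(0, run, "V1", mat, np.arange(6))
        ev_by_run[run] = events
    return ts_by_run, ev_by_run


class TestSelectionContrast:
    def test_responding_voxel_scores_high_noise_voxels_near_zero(
            self, small_design, contrast_inputs):
        ts_by_run, ev_by_run = contrast_inputs
        scores, vids = g.selection_contrast(ts_by_run, ev_by_run, small_design)
        assert scores[0] > 10.0
        assert np.all(np.abs(scores[1:]) < 4.0)

    def test_scores_are_orientation_blind(self, small_design, contrast_inputs):
        ts_by_run, ev_by_run = contrast_inputs
        flipped = {run: [TrialEvent(e.participant_id, e.run_index,
                                    e.trial_index_in_run, e.condition,
                                    -e.orientation, e.trial_onset_seconds,
                                    e.phase_onsets_seconds)
                         for e in events]
                   for run, events in ev_by_run.items()}
        s1, _ = g.selection_contrast(ts_by_run, ev_by_run, small_design)
        s2, _ = g.selection_contrast(ts_by_run, flipped, small_design)
        assert np.array_equal(s1, s2)

    def test_zero_variance_voxel_scores_zero(self, small_design, contrast_inputs):
        ts_by_run, ev_by_run = contrast_inputs
        for ts in ts_by_run.values():
            ts.matrix[3, :] = 42.0
        scores, _ = g.selection_contrast(ts_by_run, ev_by_run, small_design)
        assert scores[3] == 0.0

    def test_single_run_rejected(self, small_design, contrast_inputs):
        ts_by_run, ev_by_run = contrast_inputs
        with pytest.raises(PreprocessError, match="2 retained runs"):
            g.selection_contrast({0: ts_by_run[0]}, ev_by_run, small_design)


class TestSelectVoxels:
    def test_cap_binds_on_large_rois(self):
        rng = np.random.default_rng(1)
        sel = g.select_voxels(rng.normal(size=400), np.arange(400))
        assert len(sel.voxel_ids) == 250

    def test_small_roi_keeps_all_voxels(self):
        rng = np.random.default_rng(1)
        sel = g.select_voxels(rng.normal(size=180), np.arange(180))
        assert len(sel.voxel_ids) == 180

    def test_boundary_tie_broken_by_ascending_voxel_id(self):
        scores = np.array([5.0, 3.0, 3.0, 3.0, 1.0])
        sel_a = g.select_voxels(scores, np.arange(5), k=2)
        sel_b = g.select_voxels(scores, np.arange(5), k=2)
        assert list(sel_a.voxel_ids) == [0, 1]
        assert list(sel_a.voxel_ids) == list(sel_b.voxel_ids)

    def test_empty_roi_is_an_error(self):
        with pytest.raises(PreprocessError, match="empty"):
            g.select_voxels(np.array([]), np.array([]))


class TestExtractPatterns:
    @pytest.fixture()
    def marked_run(self, default_design):
        table = g.build_trial_table(default_design, seed=0)
        events = table.for_run(0)
        mat = np.zeros((4, default_design.volumes_per_run))
        mat[:] = np.arange(default_design.volumes_per_run)[None, :]  # col = index
        ts = RoiTimeSeries(0, 0, "V1", mat, np.arange(4))
        sel = g.select_voxels(np.ones(4), np.arange(4), k=4)
        return ts, sel, events

    def test_instruction_samples_single_volume_4s_after_onset(
            self, default_design, marked_run):
        ts, sel, events = marked_run
        samples = g.extract_patterns(ts, sel, events, "instruction", default_design)
        for ev, s in zip(events, samples):
            v = g.phase_volume_index(ev, "instruction", default_design)
            assert np.all(s.features == v + 2)

    def test_action_averages_volumes_8_and_10s_after_onset(
            self, default_design, marked_run):
        ts, sel, events = marked_run
        samples = g.extract_patterns(ts, sel, events, "action", default_design)
        for ev, s in zip(events, samples):
            v = g.phase_volume_index(ev, "action", default_design)
            assert np.all(s.features == (v + 4 + v + 5) / 2.0)

    def test_one_sample_per_trial_with_labels(self, default_design, marked_run):
        ts, sel, events = marked_run
        samples = g.extract_patterns(ts, sel, events, "judgment", default_design)
        assert len(samples) == len(events)
        assert [(s.condition, s.orientation) for s in samples] == \
            [(e.condition, e.orientation) for e in events]

    def test_output_ignores_non_window_volumes(self, default_design, marked_run):
        ts, sel, events = marked_run
        before = g.extract_patterns(ts, sel, events, "action", default_design)
        rng = np.random.default_rng(0)
        window = set()
        for ev in events:
            v = g.phase_volume_index(ev, "action", default_design)
            window.update((v + 4, v + 5))
        outside = [c for c in range(default_design.volumes_per_run) if c not in window]
        ts.matrix[:, outside] = rng.normal(size=(4, len(outside))) * 1e3
        after = g.extract_patterns(ts, sel, events, "action", default_design)
        for a, b in zip(before, after):
            assert np.array_equal(a.features, b.features)

    def test_window_beyond_run_names_the_trial(self, default_design, marked_run):
        ts, sel, _ = marked_run
        late = TrialEvent(0, 0, 99, "DG", 45, 374.0,
                          {p: 374.0 + default_design.phase_onset_in_trial(p)
                           for p in ("instruction", "wait1", "action", "wait2",
                                     "judgment", "iti")})
        with pytest.raises(PreprocessError, match="trial 99"):
            g.extract_patterns(ts, sel, [late], "judgment", default_design)


class TestZscoreFold:
    def test_train_columns_standardized_test_uses_train_stats(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3.0, 2.0, (20, 4))
        test = rng.normal(3.0, 2.0, (5, 4))
        ztr, zte = zscore_fold(train, test)
        assert np.allclose(ztr.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(ztr.std(axis=0), 1.0, atol=1e-12)
        assert np.allclose(zte, (test - train.mean(axis=0)) / train.std(axis=0))

    def test_constant_feature_maps_to_zero_without_error(self):
        train = np.array([[1.0, 2.0], [1.0, 3.0]])
        test = np.array([[7.0, 4.0]])
        ztr, zte = zscore_fold(train, test)
        assert np.all(ztr[:, 0] == 0.0) and zte[0, 0] == 0.0

    @given(arrays(np.float64, (6, 3), elements=st.floats(-50, 50)))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_idempotent_on_already_standardized_train(self, train):
        ztr, _ = zscore_fold(train, train[:1])
        z2, _ = zscore_fold(ztr, ztr[:1])
        assert np.allclose(ztr, z2, atol=1e-9)


class TestSelectionOrthogonality:
    def test_selection_does_not_bias_null_decoding(self, small_design):
        """Top-k selection on orientation-pooled contrast must leave
        decoding of information-free data at chance (checked over 20
        simulated participants)."""
        truth = g.make_ground_truth("null", seed=0, roi_names=("V1",),
                                    n_voxels_per_roi={"V1": 40})
        accs = []
        for seed in range(20):
            table = g.build_trial_table(small_design, seed, 0)
            ev = {r: table.for_run(r) for r in range(small_design.n_runs)}
            ts = {r: g.simulate_roi_run(small_design, ev[r], truth, "V1", 300 + seed * 7 + r)
                  for r in ev}
            scores, vids = g.selection_contrast(ts, ev, small_design)
            sel = g.select_voxels(scores, vids, k=20)
            samples = [s for r in ev
                       for s in g.extract_patterns(ts[r], sel, ev[r], "action",
                                                   small_design)
                       if s.condition == "DG"]
            accs.append(g.loro_accuracy(samples).accuracy)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.5) < 3 * se + 1e-9
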