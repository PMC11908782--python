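"""Trial segmentation, correlation flagging, best frequency, RFS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import colliscope as cs
from colliscope.responses import (
    InsufficientRepeatsError,
    SegmentationError,
    TrialTensor,
    flag_responsive,
    response_auc,
    trial_correlation,
)


def _tensor_from_array(data, levels=None, freqs=None, frame_rate=29.9, pre_s=0.0):
    """Wrap a (cells, combos, repeats, samples) array into a TrialTensor."""
    n_cells, n_combos, _, n_samples = data.shape
    if levels is None:
        levels = np.full(n_combos, 80.0)
    if freqs is None:
        freqs = 1000.0 * (1 + np.arange(n_combos))
    combo_table = pd.DataFrame(
        {"combo_id": np.arange(n_combos), "level_db": levels, "freq_hz": freqs}
    )
    return TrialTensor(
        data=np.asarray(data, dtype=float),
        combo_table=combo_table,
        frame_rate_hz=frame_rate,
        window_s=n_samples / frame_rate,
        pre_s=pre_s,
        stim_duration_s=0.5,
        cell_ids=[f"cell{i:04d}" for i in range(n_cells)],
    )


class TestSegmentTrials:
    def test_protocol_tensor_shape(self, tone_grid):
        # 35 combos x 5 repeats, 1.1 s window at 29.9 Hz -> 33 samples
        sched = cs.make_schedule(tone_grid, n_repeats=5, seed=0)
        n_frames = int(round((sched.total_duration_s + 2.0) * 29.9))
        dff = cs.DffTraces(np.zeros((n_frames, 3)), 29.9, ["a", "b", "c"])
        tensor = cs.segment_trials(dff, sched, pre_s=0.0, post_s=0.6)
        assert tensor.data.shape == (3, 35, 5, 33)

    def test_bare_stimulus_window(self, tone_grid):
        sched = cs.make_schedule(tone_grid, n_repeats=1, seed=0)
        n_frames = int(round((sched.total_duration_s + 1.0) * 29.9))
        dff = cs.DffTraces(np.zeros((n_frames, 1)), 29.9, ["a"])
        tensor = cs.segment_trials(dff, sched, pre_s=0.0, post_s=0.0)
        assert tensor.n_samples == round(0.5 * 29.9)

    def test_single_run_rejected_by_correlation(self, tone_grid):
        sched = cs.make_schedule(tone_grid, n_repeats=1, seed=0)
        n_frames = int(round((sched.total_duration_s + 1.0) * 29.9))
        dff = cs.DffTraces(np.zeros((n_frames, 1)), 29.9, ["a"])
        tensor = cs.segment_trials(dff, sched)
        assert tensor.n_repeats == 1
        with pytest.raises(InsufficientRepeatsError):
            trial_correlation(tensor)

    def test_window_beyond_recording_reported(self, tone_grid):
        sched = cs.make_schedule(tone_grid, n_repeats=1, seed=0)
        dff = cs.DffTraces(np.zeros((100, 1)), 29.9, ["a"])
        with pytest.raises(SegmentationError):
            cs.segment_trials(dff, sched)

    def test_repeats_concatenated_across_runs(self, tone_grid):
        s1 = cs.make_schedule(tone_grid, n_repeats=1, seed=1)
        s2 = cs.make_schedule(tone_grid, n_repeats=1, seed=2)
        n_frames = int(round((s1.total_duration_s + 1.0) * 29.9))
        d1 = cs.DffTraces(np.zeros((n_frames, 2)), 29.9, ["a", "b"])
        d2 = cs.DffTraces(np.ones((n_frames, 2)), 29.9, ["a", "b"])
        tensor = cs.segment_trials(d1, s1, extra_runs=[(d2, s2)])
        assert tensor.n_repeats == 2


class TestTrialCorrelation:
    def test_identical_repeats_correlate_perfectly(self, rng):
        wave = rng.normal(size=12)
        data = np.tile(wave, (1, 1, 4, 1))
        r = trial_correlation(_tensor_from_array(data))
        assert r["mean_r"].iloc[0] == pytest.approx(1.0)

    def test_negated_repeat_gives_minus_one(self, rng):
        wave = rng.normal(size=12)
        data = np.stack([wave, -wave])[None, None]
        r = trial_correlation(_tensor_from_array(data))
        assert r["mean_r"].iloc[0] == pytest.approx(-1.0)

    def test_white_noise_uncorrelated(self, rng):
        data = rng.normal(size=(100, 1, 5, 30))
        r = trial_correlation(_tensor_from_array(data))["mean_r"]
        assert np.abs(r).max() < 0.3
        assert abs(r.mean()) < 0.03

    def test_matches_brute_force_pairwise_pearson(self, rng):
        data = rng.normal(size=(4, 3, 5, 20))
        tensor = _tensor_from_array(data)
        got = trial_correlation(tensor).set_index(["cell_id", "combo_id"])["mean_r"]
        for ci in range(4):
            for combo in range(3):
                rs = [
                    stats.pearsonr(data[ci, combo, i], data[ci, combo, j]).statistic
                    for i, j in itertools.combinations(range(5), 2)
                ]
                assert got[(f"cell{ci:04d}", combo)] == pytest.approx(
                    np.mean(rs), abs=1e-10
                )

    def test_constant_trial_pairs_score_zero(self):
        data = np.zeros((1, 1, 3, 10))
        data[0, 0, 0] = np.sin(np.arange(10))
        r = trial_correlation(_tensor_from_array(data))["mean_r"].iloc[0]
        assert r == 0.0


class TestFlagging:
    def test_strictly_above_threshold(self, rng):
        wave = np.sin(np.linspace(0, 3, 15))
        data = wave + 0.5 * rng.normal(size=(1, 1, 3, 15))
        tensor = _tensor_from_array(data)
        r = trial_correlation(tensor)["mean_r"].iloc[0]
        at = flag_responsive(tensor, threshold=r)  # r == threshold: not flagged
        assert not at.table["responsive"].iloc[0]
        below = flag_responsive(tensor, threshold=r - 1e-6)
        assert below.table["responsive"].iloc[0]

    def test_monotone_in_threshold(self, small_experiment):
        dff = cs.process_experiment(small_experiment)
        tensor = cs.segment_trials(dff, small_experiment.schedule)
        loose = flag_responsive(tensor, threshold=0.4).table["responsive"]
        strict = flag_responsive(tensor, threshold=0.6).table["responsive"]
        assert (strict <= loose).all()

    def test_unresponsive_cell_has_no_any_flag(self, rng):
        data = rng.normal(size=(1, 2, 4, 20)) * 0.001
        table = flag_responsive(_tensor_from_array(data), threshold=0.6)
        assert not table.any_responsive().iloc[0]

    def test_auc_excludes_suppression_by_default(self):
        data = np.zeros((1, 1, 2, 10))
        data[:, :, :, :5] = 1.0
        data[:, :, :, 5:] = -2.0
        tensor = _tensor_from_array(data)
        rectified = response_auc(tensor)["auc"].iloc[0]
        signed = response_auc(tensor, signed=True)["auc"].iloc[0]
        assert rectified > 0
        assert signed < 0

    def test_auc_matches_trapezoid_oracle(self, rng):
        data = np.abs(rng.normal(size=(2, 2, 3, 12)))
        tensor = _tensor_from_array(data)
        got = response_auc(tensor).set_index(["cell_id", "combo_id"])["auc"]
        for ci in range(2):
            for combo in range(2):
                avg = data[ci, combo].mean(axis=0)
                expected = np.trapezoid(np.clip(avg, 0, None), dx=1 / 29.9)
                assert got[(f"cell{ci:04d}", combo)] == pytest.approx(expected, abs=1e-12)


def _response_table(rows):
    df = pd.DataFrame(rows, columns=["cell_id", "combo_id", "level_db", "freq_hz", "mean_r", "responsive", "auc"])
    return cs.ResponseTable(table=df, threshold=0.6, window_s=1.1)


class TestBestFrequencyAndRfs:
    def test_argmax_over_flagged_combos(self):
        table = _response_table(
            [
                ("c", 0, 80.0, 5000.0, 0.9, True, 1.0),
                ("c", 1, 80.0, 10000.0, 0.9, True, 3.0),
                ("c", 2, 80.0, 20000.0, 0.9, True, 2.0),
            ]
        )
        assert cs.best_frequency(table)["c"] == 10000.0

    def test_single_flagged_combo(self):
        table = _response_table([("c", 0, 80.0, 7071.0, 0.7, True, 0.5)])
        assert cs.best_frequency(table)["c"] == 7071.0

    def test_tie_breaks_toward_lower_frequency(self):
        table = _response_table(
            [
                ("c", 0, 80.0, 10000.0, 0.9, True, 2.0),
                ("c", 1, 80.0, 20000.0, 0.9, True, 2.0),
            ]
        )
        assert cs.best_frequency(table)["c"] == 10000.0

    def test_unflagged_cell_is_nan(self):
        table = _response_table([("c", 0, 80.0, 5000.0, 0.1, False, 0.2)])
        assert np.isnan(cs.best_frequency(table)["c"])

    def test_rfs_counts_flagged_combos(self):
        rows = []
        flagged = {(40.0, 5000.0), (40.0, 10000.0), (80.0, 5000.0)}
        for level in (40.0, 80.0):
            for i, freq in enumerate((5000.0, 10000.0, 20000.0)):
                rows.append(
                    ("c", i, level, freq, 0.9, (level, freq) in flagged, 1.0)
                )
        record = cs.receptive_field_sum(_response_table(rows))
        assert record.rfs_total["c"] == 3
        assert record.rfs_by_level.loc["c", 40.0] == 2
        assert record.rfs_by_level.loc["c", 80.0] == 1

    def test_no_flags_gives_zero_rfs(self):
        table = _response_table([("c", 0, 80.0, 5000.0, 0.0, False, 0.0)])
        record = cs.receptive_field_sum(table)
        assert record.rfs_total["c"] == 0

    def test_single_combo_rfs_one(self):
        table = _response_table([("c", 0, 80.0, 5000.0, 0.9, True, 1.0)])
        assert cs.receptive_field_sum(table).rfs_total["c"] == 1
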