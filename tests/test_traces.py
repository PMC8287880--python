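"""Tests for the single-cell trace statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sigvsim import (
    CellTrace,
    LineageCell,
    LineageForest,
    activation_time,
    coefficient_of_variation,
    compare_activation_by_prestress,
    cumulative_activation_curve,
    filter_overshooting,
    fold_change,
    fraction_activated_snapshot,
    instantaneous_growth_rate,
    survival_fraction,
    summarize_activation,
)
from sigvsim.traces import ActivationSummary


def make_trace(fluor, stress_time=100.0, dt=10.0, **kwargs):
    fluor = np.asarray(fluor, dtype=float)
    return CellTrace(cell_id=kwargs.pop("cell_id", 0),
                     times=np.arange(len(fluor)) * dt,
                     fluorescence=fluor, stress_time=stress_time, **kwargs)


def step_trace(n_frames=40, stress_frame=10, on_frame=14, high=100.0, dt=10.0):
    f = np.zeros(n_frames)
    f[on_frame:] = high
    return make_trace(f, stress_time=stress_frame * dt, dt=dt)


class TestActivationTime:
    def test_exact_step_crossing(self):
        # stress at frame 10, signal jumps at frame 14: 40 min after stress
        s = activation_time(step_trace(), final_window=100)
        assert not s.censored
        assert s.activation_time == pytest.approx(40.0)
        assert s.final_level == pytest.approx(100.0)

    def test_flat_zero_trace_is_censored(self):
        s = activation_time(make_trace(np.zeros(40)))
        assert s.censored and s.activation_time is None

    def test_non_responder_is_censored(self):
        # final level below the pre-stress mean: censored even though the
        # half-max is technically crossed
        f = np.concatenate([np.full(10, 100.0), np.full(30, 40.0)])
        s = activation_time(make_trace(f), final_window=100)
        assert s.censored

    def test_trace_ending_before_stress_rejected(self):
        with pytest.raises(ValueError):
            activation_time(make_trace(np.zeros(5), stress_time=1000.0))

    @given(gain=st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_pure_gain(self, gain):
        base = step_trace()
        scaled = make_trace(base.fluorescence * gain, stress_time=100.0)
        assert activation_time(scaled).activation_time == \
            activation_time(base).activation_time

    @given(shift=st.integers(0, 20))
    @settings(max_examples=30, deadline=None)
    def test_equivariant_under_time_shift(self, shift):
        base = step_trace()
        shifted = CellTrace(cell_id=0, times=base.times + shift * 10.0,
                            fluorescence=base.fluorescence,
                            stress_time=base.stress_time + shift * 10.0)
        assert activation_time(shifted).activation_time == \
            activation_time(base).activation_time


class TestCumulativeCurve:
    def test_simple_fractions(self):
        s = [ActivationSummary(i, t, 1, 0.5, False)
             for i, t in enumerate([10.0, 20.0, 30.0])]
        curve = cumulative_activation_curve(s, [15, 25, 35])
        assert curve == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_all_censored_is_zero(self):
        s = [ActivationSummary(i, None, 0, 0, True) for i in range(4)]
        assert np.all(cumulative_activation_curve(s, [10, 100]) == 0)

    def test_censored_stay_in_denominator_and_ties_count(self):
        s = [ActivationSummary(0, 10.0, 1, .5, False),
             ActivationSummary(1, 10.0, 1, .5, False),
             ActivationSummary(2, 30.0, 1, .5, False),
             ActivationSummary(3, None, 0, 0, True)]
        assert cumulative_activation_curve(s, [10])[0] == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cumulative_activation_curve([], [10])

    @given(times=st.lists(st.floats(0, 500), min_size=1, max_size=30),
           n_cens=st.integers(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_bounded(self, times, n_cens):
        s = [ActivationSummary(i, t, 1, .5, False) for i, t in enumerate(times)]
        s += [ActivationSummary(100 + i, None, 0, 0, True) for i in range(n_cens)]
        curve = cumulative_activation_curve(s, np.linspace(0, 600, 50))
        assert np.all(np.diff(curve) >= 0)
        assert curve[-1] <= 1
        if n_cens:
            assert curve[-1] < 1  # censored cells keep the curve below 1


class TestSnapshotFraction:
    def test_hand_computed_threshold(self):
        # pre {9,10,11}: sd=1, threshold=16; two of four post values exceed
        assert fraction_activated_snapshot([9, 10, 11], [10, 17, 10, 17]) == 0.5

    def test_none_above_threshold(self):
        assert fraction_activated_snapshot([9, 10, 11], [1, 2, 3]) == 0.0

    def test_zero_variance_strict_inequality(self):
        assert fraction_activated_snapshot([5, 5, 5], [5, 5]) == 0.0

    def test_same_distribution_rarely_crosses_six_sigma(self, rng):
        pre = rng.normal(100, 10, size=1000)
        post = rng.normal(100, 10, size=1000)
        assert fraction_activated_snapshot(pre, post) < 0.01

    def test_k_zero_counts_above_mean(self, rng):
        pre = rng.normal(50, 5, 100)
        post = rng.normal(50, 5, 1000)
        frac = fraction_activated_snapshot(pre, post, k_sd=0.0)
        assert frac == pytest.approx(np.mean(post > pre.mean()))
        assert fraction_activated_snapshot(pre, post, k_sd=1e9) == 0.0


class TestFoldChangeAndCV:
    def test_tenfold(self):
        f = np.concatenate([np.full(10, 10.0), np.full(30, 100.0)])
        tr = make_trace(f, stress_time=100.0)
        assert fold_change(tr, pre_window=100, post_window=100) == pytest.approx(10.0)

    def test_unchanged_trace_is_one(self):
        tr = make_trace(np.full(40, 7.0))
        assert fold_change(tr, 100, 100) == pytest.approx(1.0)

    def test_zero_pre_mean_flagged_undefined(self):
        f = np.concatenate([np.zeros(10), np.full(30, 50.0)])
        assert fold_change(make_trace(f), 100, 100) is None

    def test_cv_examples(self):
        assert coefficient_of_variation([10, 10, 10]) == 0.0
        assert coefficient_of_variation([5, 15]) == pytest.approx(0.7071, abs=1e-4)

    def test_cv_of_normal_draws(self, rng):
        x = rng.normal(100, 20, size=10_000)
        assert coefficient_of_variation(x) == pytest.approx(0.2, abs=0.01)


class TestGrowthRate:
    def test_exponential_closed_form(self):
        # length doubles as e^{0.05 t}: rate 0.05/min at dt=10
        t = np.arange(10) * 10.0
        tr = make_trace(np.zeros(10), stress_time=50.0)
        tr.length = np.exp(0.05 * t)
        rates = instantaneous_growth_rate(tr)
        assert np.allclose(rates.growth_rate, 0.05)
        assert len(rates) == 9

    def test_constant_length_zero_rate(self):
        tr = make_trace(np.zeros(10))
        tr.length = np.full(10, 3.0)
        assert np.allclose(instantaneous_growth_rate(tr).growth_rate, 0.0)

    def test_division_frames_excluded(self):
        tr = make_trace(np.zeros(10))
        tr.length = np.exp(0.05 * np.arange(10) * 10.0)
        tr.division_frames = np.array([5])
        rates = instantaneous_growth_rate(tr)
        assert 4 not in rates.frame.values  # pair (4, 5) spans the division
        assert len(rates) == 8

    def test_nonpositive_length_rejected(self):
        tr = make_trace(np.zeros(5))
        tr.length = np.array([1.0, 0.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            instantaneous_growth_rate(tr)


class TestOvershootFilter:
    def _widths(self, n_traces=10, spike=None):
        traces = []
        rng = np.random.default_rng(5)
        for i in range(n_traces):
            tr = make_trace(np.zeros(30), stress_time=100.0, cell_id=i)
            tr.width = 1.0 + rng.normal(0, 0.01, 30)
            if spike is not None and i == spike:
                tr.width[20:] += 1.0  # ~100 sd above the pre-stress mean
            traces.append(tr)
        return traces

    def test_all_equal_widths_nothing_removed(self):
        traces = self._widths()
        kept, removed = filter_overshooting(traces)
        assert len(kept) == 10 and not removed

    def test_single_spiking_trace_removed(self):
        traces = self._widths(spike=3)
        kept, removed = filter_overshooting(traces)
        assert [tr.cell_id for tr in removed] == [3]

    def test_missing_width_rejected(self):
        with pytest.raises(ValueError):
            filter_overshooting([make_trace(np.zeros(10))])


class TestPrestressComparison:
    def _traces(self, pre_levels):
        traces = []
        for i, level in enumerate(pre_levels):
            f = np.full(40, float(level))
            f[14:] = 200.0
            traces.append(make_trace(f, stress_time=100.0, cell_id=i))
        return traces

    # six low cells at 10, three high at 40: pooled mean + 1 sd ~ 24,
    # splitting the groups as intended
    LEVELS = [10] * 6 + [40] * 3

    def test_identical_samples_do_not_reject(self):
        traces = self._traces(self.LEVELS)
        s = [ActivationSummary(i, 50.0, 200, 100, False) for i in range(9)]
        res = compare_activation_by_prestress(traces, s)
        assert res.ks_statistic == 0.0 and not res.reject_null

    def test_disjoint_supports_reject(self):
        traces = self._traces(self.LEVELS)
        s = [ActivationSummary(i, t, 200, 100, False)
             for i, t in enumerate([100., 110., 120., 130., 140., 150.,
                                    10., 11., 12.])]
        res = compare_activation_by_prestress(traces, s)
        assert res.ks_statistic == 1.0 and res.reject_null

    def test_empty_group_flagged(self):
        traces = self._traces([10, 10, 10, 10])
        s = [ActivationSummary(i, 10.0, 200, 100, False) for i in range(4)]
        res = compare_activation_by_prestress(traces, s)
        assert not res.computable


class TestSurvivalFraction:
    def _forest(self):
        # 2 channels x 3 cells; survivors: channel 0 cell 1, channel 1 cell 4
        cells = []
        for ch in range(2):
            for k in range(3):
                cid = ch * 3 + k
                survives = cid in (1, 4)
                cells.append(LineageCell(
                    cell_id=cid, channel_id=ch, parent_id=None,
                    birth_time=0.0,
                    end_time=500.0 if survives else 320.0,
                    end_cause="movie_end" if survives else "death",
                    position=(k + 0.5) * 3.0, rank_at=k))
        return LineageForest(cells=cells, stress_time=300.0, channel_length=18.0)

    def test_hand_counted_top3(self):
        frac, _ = survival_fraction(self._forest(), "top3_longest",
                                    assay_start=300, assay_end=500)
        assert frac == pytest.approx(2 / 6)

    def test_all_dead_gives_zero(self):
        forest = self._forest()
        for c in forest.cells:
            c.end_time, c.end_cause = 320.0, "death"
        assert survival_fraction(forest, "top3_longest", 300, 500)[0] == 0.0

    def test_longest_lineage_counted_once(self):
        # a surviving top cell that divided twice still contributes 1
        cells = [
            LineageCell(0, 0, None, 0.0, 310.0, "division", 1.5, 0),
            LineageCell(1, 0, 0, 310.0, 400.0, "division", 1.5, np.nan),
            LineageCell(2, 0, 1, 400.0, 600.0, "movie_end", 1.5, np.nan),
            LineageCell(3, 0, 1, 400.0, 600.0, "movie_end", 4.5, np.nan),
            LineageCell(4, 0, None, 0.0, 320.0, "death", 4.5, 1),
            LineageCell(5, 0, None, 0.0, 320.0, "death", 7.5, 2),
        ]
        forest = LineageForest(cells, stress_time=300.0, channel_length=18.0)
        frac, _ = survival_fraction(forest, "top3_longest", 300, 600)
        assert frac == pytest.approx(1 / 3)

    def test_channel_end_exclusion_removes_washed_out(self):
        forest = self._forest()
        # add pre-stress exits defining the channel end around 18 um
        nid = 10
        for ch in range(2):
            for j in range(3):
                forest.cells.append(LineageCell(
                    nid, ch, None, 0.0, 100.0 + j, "left_channel",
                    position=18.0 + 0.1 * (j - 1), rank_at=np.nan))
                nid += 1
        # a dead cell right at the channel end: excluded, not counted dead
        forest.cells.append(LineageCell(nid, 0, None, 0.0, 320.0, "death",
                                        position=18.0, rank_at=np.nan))
        frac, _ = survival_fraction(forest, "channel_end_exclusion", 300, 500)
        assert frac == pytest.approx(2 / 6)

    def test_short_channels_skipped(self):
        cells = [LineageCell(0, 0, None, 0.0, 500.0, "movie_end", 1.5, 0)]
        with pytest.raises(ValueError):
            survival_fraction(LineageForest(cells, 300.0), "top3_longest", 300, 500)
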