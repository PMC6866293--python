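import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vasoreact import (
    BlockMatrix,
    BoldSeries,
    StimulusParadigm,
    TrapezoidParams,
    ZStatMap,
    average_block,
    extract_metrics,
    fit_trapezoid,
    reject_artifact_blocks,
    roi_mean_timeseries,
    segment_blocks,
    simulate_block_response,
    to_percent_change,
    top_fraction_mask,
    trapezoid_value,
)
from vasoreact.core import Volume4D
from vasoreact.reactivity import _profiled_sse


def zmap_from_values(values: np.ndarray) -> ZStatMap:
    return ZStatMap(values=values, mask=np.ones(values.shape, dtype=bool))


class TestTopFractionMask:
    def test_top_20pct_of_1000_distinct(self, rng):
        values = rng.permutation(1000.0 + np.arange(1000.0)).reshape(10, 10, 10)
        roi = top_fraction_mask(zmap_from_values(values), 0.2)
        assert roi.n_voxels == 200
        assert values[roi.voxels].min() > values[~roi.voxels].max()

    def test_fraction_one_returns_whole_mask(self, rng):
        values = rng.normal(size=(5, 5, 4))
        roi = top_fraction_mask(zmap_from_values(values), 1.0)
        assert roi.voxels.all()

    def test_matches_sort_oracle_small(self, rng):
        values = rng.normal(size=(10, 1, 1))
        roi = top_fraction_mask(zmap_from_values(values), 0.2)
        k = math.ceil(0.2 * 10)
        expected = set(np.argsort(-values.ravel(), kind="stable")[:k])
        assert set(np.flatnonzero(roi.voxels.ravel())) == expected

    @settings(derandomize=True, max_examples=50)
    @given(n=st.integers(1, 50), frac_pct=st.integers(1, 100))
    def test_mask_size_is_ceil(self, n, frac_pct):
        fraction = frac_pct / 100.0
        values = np.arange(float(n)).reshape(n, 1, 1)
        roi = top_fraction_mask(zmap_from_values(values), fraction)
        assert roi.n_voxels == math.ceil(fraction * n)

    def test_all_equal_ties_deterministic_with_warning(self):
        values = np.zeros((4, 4, 2))
        with pytest.warns(RuntimeWarning, match="tie-break"):
            roi = top_fraction_mask(zmap_from_values(values), 0.25)
        assert roi.n_voxels == 8
        # lowest linear indices win the tie-break
        assert set(np.flatnonzero(roi.voxels.ravel())) == set(range(8))

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, fraction):
        with pytest.raises(ValueError):
            top_fraction_mask(zmap_from_values(np.ones((2, 2, 2))), fraction)


class TestRoiMean:
    def _run(self, data):
        return Volume4D(data=data, mask=np.ones(data.shape[:3], bool), tr=3.0)

    def test_single_voxel_roi(self, rng):
        data = rng.normal(size=(3, 3, 2, 10))
        roi = top_fraction_mask(
            zmap_from_values(np.arange(18.0).reshape(3, 3, 2)), 1 / 18
        )
        series = roi_mean_timeseries(self._run(data), roi)
        assert np.allclose(series.values, data[2, 2, 1])

    def test_opposite_series_cancel(self):
        data = np.zeros((2, 1, 1, 10))
        s = np.sin(np.arange(10.0)) + 2.0
        data[0, 0, 0], data[1, 0, 0] = s, -s
        roi = top_fraction_mask(zmap_from_values(np.zeros((2, 1, 1)) + 1.0), 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            series = roi_mean_timeseries(self._run(data), roi)
        assert np.allclose(series.values, 0.0)

    def test_matches_mean_oracle(self, rng):
        data = rng.normal(100, 5, size=(4, 4, 2, 12))
        values = rng.normal(size=(4, 4, 2))
        roi = top_fraction_mask(zmap_from_values(values), 5 / 32)
        series = roi_mean_timeseries(self._run(data), roi)
        assert np.allclose(series.values, data[roi.voxels].mean(axis=0))


class TestBlocking:
    def test_default_design_segments_7x16(self, paradigm, rng):
        s = BoldSeries(values=rng.normal(100, 1, 112), tr=3.0)
        raw = segment_blocks(s, paradigm)
        assert raw.shape == (7, 16)
        assert np.array_equal(raw.ravel(), s.values)

    def test_single_block_identity(self, rng):
        p = StimulusParadigm(n_blocks=1)
        s = BoldSeries(values=rng.normal(100, 1, 16), tr=3.0)
        assert np.array_equal(segment_blocks(s, p)[0], s.values)

    def test_trailing_samples_dropped_with_warning(self, paradigm, rng):
        s = BoldSeries(values=rng.normal(100, 1, 115), tr=3.0)
        with pytest.warns(RuntimeWarning, match="3 trailing"):
            raw = segment_blocks(s, paradigm)
        assert raw.shape == (7, 16)

    def test_short_series_rejected(self, paradigm, rng):
        s = BoldSeries(values=rng.normal(100, 1, 100), tr=3.0)
        with pytest.raises(ValueError):
            segment_blocks(s, paradigm)

    def test_percent_change_constant_matrix(self):
        blocks = to_percent_change(np.full((7, 16), 100.0), 3.0)
        assert np.allclose(blocks.blocks, 0.0)
        assert blocks.normalization_mean == 100.0

    def test_percent_change_formula_value(self):
        raw = np.full((2, 4), 100.0)
        raw[0, 0] = 102.0
        m = raw.mean()
        blocks = to_percent_change(raw, 3.0)
        assert blocks.blocks[0, 0] == pytest.approx(100 * (102 - m) / m)

    def test_percent_change_matches_oracle(self, rng):
        raw = rng.uniform(90, 110, size=(7, 16))
        blocks = to_percent_change(raw, 3.0)
        m = raw.mean()
        assert np.allclose(blocks.blocks, 100.0 * (raw - m) / m)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="non-physiological"):
            to_percent_change(np.full((2, 4), -1.0), 3.0)


class TestArtifactRejection:
    def _blocks(self, peaks):
        mat = np.zeros((len(peaks), 16))
        for i, p in enumerate(peaks):
            mat[i, 5] = p
        return BlockMatrix(blocks=mat, tr=3.0,
                           retained=np.ones(len(peaks), bool),
                           normalization_mean=100.0)

    def test_rule_application(self):
        out = reject_artifact_blocks(self._blocks([1.0, 2.9, 3.5]))
        assert out.retained.tolist() == [True, True, False]

    def test_boundary_exactly_3_retained(self):
        out = reject_artifact_blocks(self._blocks([3.0]))
        assert out.retained.tolist() == [True]

    def test_negative_spikes_also_discarded(self):
        out = reject_artifact_blocks(self._blocks([-3.5, 1.0]))
        assert out.retained.tolist() == [False, True]

    def test_two_planted_spikes_among_seven(self, rng):
        peaks = rng.uniform(0.5, 2.5, 7)
        peaks[[2, 5]] = [4.1, 3.7]
        out = reject_artifact_blocks(self._blocks(peaks))
        assert out.n_retained == 5
        assert out.discarded_indices == [2, 5]

    def test_all_discarded_is_an_error(self):
        with pytest.raises(ValueError, match="unfittable"):
            reject_artifact_blocks(self._blocks([5.0, 4.0]))

    def test_mean_statistic_option(self):
        mat = np.vstack([np.full(16, 3.5), np.full(16, 1.0)])
        blocks = BlockMatrix(blocks=mat, tr=3.0,
                             retained=np.ones(2, bool), normalization_mean=100.0)
        out = reject_artifact_blocks(blocks, statistic="mean_abs")
        assert out.retained.tolist() == [False, True]

    def test_normalization_mean_untouched(self):
        out = reject_artifact_blocks(self._blocks([1.0, 4.0]))
        assert out.normalization_mean == 100.0


class TestAverageBlock:
    def test_single_retained_block(self, rng):
        mat = rng.normal(size=(3, 16))
        blocks = BlockMatrix(blocks=mat, tr=3.0,
                             retained=np.array([False, True, False]),
                             normalization_mean=100.0)
        assert np.allclose(average_block(blocks).values, mat[1])

    def test_opposite_blocks_cancel(self, rng):
        v = rng.normal(size=16)
        blocks = BlockMatrix(blocks=np.stack([v, -v]), tr=3.0,
                             retained=np.ones(2, bool), normalization_mean=100.0)
        assert np.allclose(average_block(blocks).values, 0.0)

    def test_matches_mean_oracle_over_retained(self, rng):
        mat = rng.normal(size=(7, 16))
        retained = np.array([True, True, False, True, True, False, True])
        blocks = BlockMatrix(blocks=mat, tr=3.0, retained=retained,
                             normalization_mean=100.0)
        assert np.allclose(average_block(blocks).values, mat[retained].mean(axis=0))

    def test_no_retained_blocks_rejected(self, rng):
        blocks = BlockMatrix(blocks=rng.normal(size=(2, 16)), tr=3.0,
                             retained=np.zeros(2, bool), normalization_mean=100.0)
        with pytest.raises(ValueError):
            average_block(blocks)


class TestFitTrapezoid:
    def test_noiseless_recovery(self, paradigm, planted):
        s = simulate_block_response(planted, paradigm)
        fit = fit_trapezoid(s, paradigm)
        assert fit.params.t_peak == pytest.approx(6.0, abs=0.25)
        assert fit.params.t_return == pytest.approx(28.0, abs=0.25)
        assert fit.amplitude == pytest.approx(1.0, abs=0.01)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_constant_input(self, paradigm):
        s = BoldSeries(values=np.full(16, 0.7), tr=3.0)
        fit = fit_trapezoid(s, paradigm)
        assert fit.params.baseline == pytest.approx(0.7)
        assert fit.amplitude == 0.0
        assert fit.sse == pytest.approx(0.0)
        assert fit.params.t_peak == pytest.approx(0.25)  # documented tie-break

    def test_sse_never_worse_than_flat_model(self, paradigm, rng):
        for _ in range(10):
            y = rng.normal(0, 1, 16)
            fit = fit_trapezoid(BoldSeries(values=y, tr=3.0), paradigm)
            tss = np.sum((y - y.mean()) ** 2)
            assert fit.sse <= tss + 1e-9

    def test_beats_fine_grid_oracle(self, paradigm, rng):
        t = paradigm.tr * np.arange(paradigm.samples_per_block)
        tp_g = np.arange(0.05, 20.0 + 1e-9, 0.05)
        tr_g = np.arange(20.0, 48.0 + 1e-9, 0.05)
        TP, TR = np.meshgrid(tp_g, tr_g, indexing="ij")
        for _ in range(5):
            params = TrapezoidParams(
                baseline=rng.uniform(-0.3, 0.3), amplitude=rng.uniform(0.3, 1.5),
                t_peak=rng.uniform(2, 18), t_return=rng.uniform(21, 47))
            y = trapezoid_value(t, params) + rng.normal(0, 0.2, t.size)
            fit = fit_trapezoid(BoldSeries(values=y, tr=3.0), paradigm)
            oracle = _profiled_sse(y, t, TP.ravel(), 20.0, TR.ravel())[2].min()
            assert fit.sse <= oracle * (1 + 1e-9) + 1e-15

    def test_underdetermined_rejected(self, paradigm):
        with pytest.raises(ValueError):
            fit_trapezoid(BoldSeries(values=np.zeros(5) + [0, 1, 2, 1, 0], tr=3.0),
                          paradigm)

    def test_monotone_noise_degradation(self, paradigm, planted):
        medians = []
        for noise in (0.0, 0.1, 0.3, 0.5):
            errs = []
            for seed in range(40):
                s = simulate_block_response(planted, paradigm, noise, seed=seed)
                fit = fit_trapezoid(s, paradigm, refine=False)
                errs.append(abs(fit.amplitude - planted.amplitude))
            medians.append(np.median(errs))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:]))


class TestMetrics:
    def test_definitions(self, paradigm, planted):
        s = simulate_block_response(planted, paradigm)
        fit = fit_trapezoid(s, paradigm)
        ttp, ttb, amp = extract_metrics(fit, paradigm)
        assert ttp == pytest.approx(6.0, abs=0.25)
        assert ttb == pytest.approx(8.0, abs=0.25)
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_return_at_stimulus_end_gives_zero_ttb(self, paradigm):
        p = TrapezoidParams(baseline=0.0, amplitude=1.0, t_peak=6.0, t_return=20.0)
        s = simulate_block_response(p, paradigm)
        fit = fit_trapezoid(s, paradigm)
        ttp, ttb, amp = extract_metrics(fit, paradigm)
        assert ttb == pytest.approx(0.0, abs=0.25)


class TestCouplingAndDeterminism:
    def test_rejected_spike_changes_fit_only_via_normalization(self, paradigm, planted):
        # raw signal blocks around 1000 with a planted response
        t = paradigm.tr * np.arange(paradigm.samples_per_block)
        resp = 1000.0 * (1 + trapezoid_value(t, planted) / 100.0)
        clean = np.tile(resp, (6, 1))
        spike = resp.copy()
        spike[4] *= 1.08  # ~8% excursion, will be discarded
        with_spike = np.vstack([clean, spike])

        b_clean = reject_artifact_blocks(to_percent_change(clean, 3.0))
        b_spike = reject_artifact_blocks(to_percent_change(with_spike, 3.0))
        assert b_spike.discarded_indices == [6]
        # retained percent-change traces differ only through the grand mean
        m_c, m_s = b_clean.normalization_mean, b_spike.normalization_mean
        assert m_c != m_s
        back_c = m_c * (1 + b_clean.blocks[0] / 100.0)
        back_s = m_s * (1 + b_spike.blocks[0] / 100.0)
        assert np.allclose(back_c, back_s)

        f_c = fit_trapezoid(average_block(b_clean), paradigm)
        f_s = fit_trapezoid(average_block(b_spike), paradigm)
        # same raw response, different denominator: breakpoints agree to grid
        assert f_c.params.t_peak == pytest.approx(f_s.params.t_peak, abs=0.25)
        assert f_c.params.t_return == pytest.approx(f_s.params.t_return, abs=0.25)

    def test_fit_is_deterministic(self, paradigm, planted):
        s = simulate_block_response(planted, paradigm, 0.3, seed=8)
        f1 = fit_trapezoid(s, paradigm)
        f2 = fit_trapezoid(s, paradigm)
        assert f1 == f2
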