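"""Trace features, normalization, classification, averaging, correlation."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import box

from mechanoca.exceptions import DataError, PreconditionError
from mechanoca.traces import (
    CellLayout,
    classify_cells,
    correlate_features,
    features,
    group_average,
    normalize,
)

from conftest import make_trace


class TestNormalize:
    def test_constant_trace(self):
        tr = normalize(make_trace(np.full(30, 7.0)))
        assert tr.i_basal == 7.0
        assert np.allclose(tr.intensity, 1.0)

    def test_amplitude_is_peak_over_baseline(self):
        raw = np.concatenate([np.ones(10), [3.0], np.ones(19)])
        tr = normalize(make_trace(raw))
        assert features(tr).amplitude == pytest.approx(3.0)

    def test_baseline_equals_direct_mean(self):
        rng = np.random.default_rng(11)
        raw = rng.uniform(50, 150, 40)
        tr = normalize(make_trace(raw, stim_frame=12), n_baseline=10)
        direct = sum(raw[2:12]) / 10  # brute-force average
        assert tr.i_basal == pytest.approx(direct, rel=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        tr = normalize(make_trace(rng.uniform(80, 120, 30)))
        again = normalize(tr)
        assert np.allclose(again.intensity, tr.intensity, atol=1e-12)
        assert again.i_basal == pytest.approx(1.0)

    def test_scale_invariance_of_amplitude(self):
        rng = np.random.default_rng(9)
        raw = rng.uniform(90, 200, 40)
        a1 = features(normalize(make_trace(raw))).amplitude
        a2 = features(normalize(make_trace(raw * 17.3))).amplitude
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DataError, match="baseline"):
            normalize(make_trace(np.zeros(20)))

    def test_too_few_baseline_frames_rejected(self):
        with pytest.raises(PreconditionError):
            normalize(make_trace(np.ones(20), stim_frame=5), n_baseline=10)


class TestFeatures:
    def test_triangular_decay_geometry(self):
        """Rise to 3 at t=10 s, linear fall to 1 at t=110 s: the mid-level 2
        is crossed exactly halfway down, 50 s after the peak."""
        t = np.arange(0, 112.0)
        vals = np.interp(t, [0, 10, 110, 111], [1, 3, 1, 1])
        vals[:1] = 1.0
        tr = make_trace(vals, stim_frame=1, frame_interval=1.0, normalized=True)
        f = features(tr)
        assert f.amplitude == pytest.approx(3.0)
        assert f.decay50 == pytest.approx(50.0)

    def test_monotone_rise_has_undefined_decay(self):
        vals = np.concatenate([np.ones(10), np.linspace(1, 4, 20)])
        f = features(make_trace(vals, normalized=True))
        assert not f.decay50_defined

    def test_exponential_decay_matches_dense_oracle(self):
        """Sampled exponential decay: the interpolated crossing must agree
        with a dense-grid brute-force crossing finder to within one frame."""
        dt = 1.23
        amp, tau = 2.0, 30.0
        t = dt * np.arange(131)
        peak_t = t[12]
        vals = np.where(t < peak_t, 1.0, 1.0 + amp * np.exp(-(t - peak_t) / tau))
        vals[:10] = 1.0
        vals[10:12] = [1.5, 2.5]
        tr = make_trace(vals, normalized=True)
        f = features(tr)
        level = (f.amplitude + 1) / 2
        dense_t = np.linspace(peak_t, t[-1], 200001)
        dense_v = 1.0 + amp * np.exp(-(dense_t - peak_t) / tau)
        t_cross = dense_t[np.argmax(dense_v <= level)]
        assert f.decay50 == pytest.approx(t_cross - peak_t, abs=dt)

    def test_amplitude_is_the_post_stimulus_maximum(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([np.ones(10), rng.uniform(0.8, 3.0, 40)])
        tr = make_trace(vals, normalized=True)
        assert features(tr).amplitude == np.max(vals[10:])

    def test_baseline_maxima_are_ignored(self):
        # a spontaneous pre-stimulus spike (frame 0 at 2.0, baseline mean
        # still 1) must not count as the response maximum
        baseline = np.full(10, 8.0 / 9.0)
        baseline[0] = 2.0
        vals = np.concatenate([baseline, np.full(20, 1.4)])
        tr = make_trace(vals, normalized=True)
        assert features(tr).amplitude == pytest.approx(1.4)

    def test_half_max_mode_uses_half_of_maximum(self):
        t = np.arange(0, 112.0)
        vals = np.interp(t, [0, 10, 110, 111], [1, 3, 1, 1])
        tr = make_trace(vals, stim_frame=1, frame_interval=1.0, normalized=True)
        f = features(tr, decay_mode="half_max")
        # level 1.5 on the fall from 3 to 1 over 100 s -> 75 s after peak
        assert f.decay50 == pytest.approx(75.0)

    def test_decay50_stable_under_appended_frames(self):
        t = np.arange(0, 112.0)
        vals = np.interp(t, [0, 10, 110, 111], [1, 3, 1, 1])
        base = make_trace(vals, stim_frame=1, frame_interval=1.0,
                          normalized=True)
        extended = make_trace(np.concatenate([vals, np.ones(50)]),
                              stim_frame=1, frame_interval=1.0, normalized=True)
        assert features(extended).decay50 == features(base).decay50

    def test_unnormalized_trace_rejected(self):
        with pytest.raises(PreconditionError):
            features(make_trace(np.full(20, 7.0)))
        with pytest.raises(PreconditionError, match="baseline"):
            features(make_trace(np.full(20, 7.0), normalized=True))


def brute_force_labels(rects, stim, eps=0.5):
    """Closed-form interval-arithmetic oracle for axis-aligned rectangles."""
    def overlap_area(a, b):
        w = min(a[2], b[2]) - max(a[0], b[0])
        h = min(a[3], b[3]) - max(a[1], b[1])
        return max(w, 0.0) * max(h, 0.0)

    def distance(a, b):
        dx = max(max(a[0], b[0]) - min(a[2], b[2]), 0.0)
        dy = max(max(a[1], b[1]) - min(a[3], b[3]), 0.0)
        return np.hypot(dx, dy)

    labels = {}
    targets = [cid for cid, r in rects.items() if overlap_area(r, stim) > 0]
    for cid, r in rects.items():
        if cid in targets:
            labels[cid] = "target"
        elif any(distance(r, rects[t]) <= eps for t in targets):
            labels[cid] = "neighbor"
        else:
            labels[cid] = "other"
    return labels


class TestClassifyCells:
    def test_single_cell_covering_the_region_is_target(self):
        layout = CellLayout(cells={"a": box(0, 0, 100, 100)},
                            stim_regions=[box(10, 49, 90, 51)])
        assert classify_cells(layout) == {"a": "target"}

    def test_chain_target_neighbor_other(self):
        layout = CellLayout(
            cells={"a": box(0, 0, 10, 10), "b": box(10.1, 0, 20, 10),
                   "c": box(25, 0, 35, 10)},
            stim_regions=[box(2, 2, 8, 4)])
        assert classify_cells(layout) == \
            {"a": "target", "b": "neighbor", "c": "other"}

    def test_empty_stimulation_region_labels_all_other(self):
        layout = CellLayout(cells={"a": box(0, 0, 10, 10)}, stim_regions=[])
        assert classify_cells(layout) == {"a": "other"}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_layouts_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rects = {}
        for i in range(12):
            x, y = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 25, 2)
            rects[f"c{i}"] = (x, y, x + w, y + h)
        sx, sy = rng.uniform(0, 80, 2)
        stim = (sx, sy, sx + 1.4, sy + 40)
        layout = CellLayout(
            cells={cid: box(*r) for cid, r in rects.items()},
            stim_regions=[box(*stim)])
        assert classify_cells(layout) == brute_force_labels(rects, stim)

    def test_labels_partition_the_cells(self):
        rng = np.random.default_rng(3)
        cells = {f"c{i}": box(x, y, x + 10, y + 10)
                 for i, (x, y) in enumerate(rng.uniform(0, 60, (20, 2)))}
        layout = CellLayout(cells=cells, stim_regions=[box(20, 20, 40, 22)])
        labels = classify_cells(layout)
        assert set(labels) == set(cells)
        assert set(labels.values()) <= {"target", "neighbor", "other"}


class TestGroupAverage:
    def _trace_with_amplitude(self, amp, cid, group="target"):
        vals = np.concatenate([np.ones(10), [amp], np.ones(19)])
        return make_trace(vals, cell_id=cid, group=group, normalized=True)

    def test_two_bins_split_by_amplitude_rank(self):
        traces = [self._trace_with_amplitude(a, f"c{a}")
                  for a in (2.0, 3.0, 4.0, 5.0)]
        out = group_average(traces, quantiles=2)
        assert set(out) == {("target", 0), ("target", 1)}
        assert out[("target", 0)].intensity[10] == pytest.approx(2.5)
        assert out[("target", 1)].intensity[10] == pytest.approx(4.5)

    def test_identical_traces_average_to_themselves(self):
        traces = [self._trace_with_amplitude(3.0, f"c{i}") for i in range(8)]
        out = group_average(traces, quantiles=4)
        for tr in out.values():
            assert np.allclose(tr.intensity, traces[0].intensity)

    def test_framewise_mean_matches_direct_recomputation(self):
        rng = np.random.default_rng(8)
        traces = []
        for i in range(40):
            vals = np.concatenate([np.ones(10),
                                   1 + rng.uniform(0.5, 2.0, 30)])
            traces.append(make_trace(vals, cell_id=f"c{i:02d}",
                                     group="neighbor", normalized=True))
        out = group_average(traces, quantiles=1)
        member = [tr.intensity for tr in traces]
        assert np.allclose(out[("neighbor", 0)].intensity,
                           np.sum(member, axis=0) / len(member))

    def test_too_few_traces_reduces_bin_count(self, caplog):
        traces = [self._trace_with_amplitude(a, f"c{a}") for a in (2.0, 3.0)]
        with caplog.at_level("WARNING"):
            out = group_average(traces, quantiles=4)
        assert len(out) == 2
        assert "reducing" in caplog.text

    def test_non_responders_are_excluded(self):
        traces = [self._trace_with_amplitude(1.05, "dud"),
                  self._trace_with_amplitude(3.0, "hit")]
        out = group_average(traces, quantiles=1)
        assert out[("target", 0)].intensity[10] == pytest.approx(3.0)


class TestCorrelateFeatures:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlate_features(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, _ = correlate_features(x, -x)
        assert r == pytest.approx(-1.0)

    def test_independent_samples_have_negligible_correlation(self):
        rng = np.random.default_rng(123)
        r, p = correlate_features(rng.normal(size=1000), rng.normal(size=1000))
        assert abs(r) < 0.1
        assert p > 1e-4

    def test_zero_variance_flagged_as_undefined(self):
        r, p = correlate_features(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)
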