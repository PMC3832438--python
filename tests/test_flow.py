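import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thrombolyzer.errors import AnalysisError, TraceParseError
from thrombolyzer.flow import (
    FlowTrace,
    analyze_trace,
    compare_groups,
    compute_baseline,
    detect_complete_occlusion,
    detect_effective_recanalization,
    detect_reocclusion,
    minute_means,
    read_flow_trace,
    standardize_trace,
    summarize_doses,
    thrombolysis_score,
    write_flow_trace,
)
from thrombolyzer.synthetic import (
    DEFAULT_PK,
    DoseRegimen,
    FlowSimParams,
    simulate_flow_trace,
)

from conftest import make_trace


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def brute_force_occlusion(time_s, flow, threshold, duration_s):
    """O(n^2) scan over every contiguous sub-threshold run."""
    n = len(flow)
    best = None
    for s in range(n):
        if flow[s] >= threshold:
            continue
        if s > 0 and flow[s - 1] < threshold:
            continue  # not a run start
        e = s
        while e + 1 < n and flow[e + 1] < threshold:
            e += 1
        if time_s[e] - time_s[s] >= duration_s and best is None:
            best = time_s[s]
    return best


def riemann_score(trace, monitor_min, baseline, n_grid=2_000_000):
    """Fine-grid Riemann-sum mean flow over the monitoring window."""
    ds = trace.markers["drug_start"]
    end = ds + monitor_min * 60.0
    grid = np.linspace(ds, end, n_grid)
    vals = np.interp(grid, trace.time_s, trace.flow)
    return 100.0 * np.mean(vals) / baseline


# ---------------------------------------------------------------------------
# FlowTrace validation / IO
# ---------------------------------------------------------------------------

class TestFlowTraceValidation:
    def test_empty_rejected(self):
        with pytest.raises(TraceParseError, match="empty"):
            FlowTrace("x", np.array([]), np.array([]))

    def test_nonmonotone_names_row(self):
        with pytest.raises(TraceParseError, match="row 2"):
            FlowTrace("x", np.array([0.0, 1.0, 0.5]), np.zeros(3))

    def test_marker_outside_span_rejected(self):
        with pytest.raises(TraceParseError, match="outside"):
            FlowTrace("x", np.arange(10.0), np.zeros(10),
                      markers={"drug_start": 100.0})

    def test_drug_before_occlusion_rejected(self):
        with pytest.raises(TraceParseError, match="precedes"):
            FlowTrace("x", np.arange(10.0), np.zeros(10),
                      markers={"occlusion_confirmed": 8.0, "drug_start": 2.0})


class TestReadFlowTrace:
    def test_roundtrip_9000_rows(self, tmp_path):
        t = np.arange(9000.0)
        trace = make_trace(np.random.default_rng(0).random(9000),
                           markers={"drug_start": 100.0})
        write_flow_trace(trace, tmp_path / "a.csv")
        back = read_flow_trace(tmp_path / "a.csv")
        assert back.time_s.size == 9000
        np.testing.assert_allclose(back.time_s, t)
        np.testing.assert_allclose(back.flow, trace.flow)
        assert back.markers == {"drug_start": 100.0}

    def test_backwards_time_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("time_s,flow\n0,1\n1,1\n0.5,1\n")
        with pytest.raises(TraceParseError, match="row 2"):
            read_flow_trace(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "cols.csv"
        p.write_text("time_s,blood\n0,1\n")
        with pytest.raises(TraceParseError, match="flow"):
            read_flow_trace(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(TraceParseError, match="empty"):
            read_flow_trace(p)

    def test_header_only(self, tmp_path):
        p = tmp_path / "hdr.csv"
        p.write_text("time_s,flow\n")
        with pytest.raises(TraceParseError, match="no data rows"):
            read_flow_trace(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(TraceParseError, match="no such file"):
            read_flow_trace(tmp_path / "nope.csv")

    def test_negative_flow_clipped_with_count(self, tmp_path):
        # oracle: clip count equals the number of negative entries written
        rng = np.random.default_rng(1)
        flow = rng.normal(0.0, 1.0, 500)
        n_neg = int(np.sum(flow < 0))
        pd.DataFrame({"time_s": np.arange(500.0), "flow": flow}).to_csv(
            tmp_path / "neg.csv", index=False)
        trace = read_flow_trace(tmp_path / "neg.csv")
        assert trace.n_clipped == n_neg
        assert np.all(trace.flow >= 0)


# ---------------------------------------------------------------------------
# compute_baseline
# ---------------------------------------------------------------------------

class TestComputeBaseline:
    def test_constant(self):
        tr = make_trace(np.ones(400), markers={"fecl3_on": 300.0})
        assert compute_baseline(tr) == pytest.approx(1.0)

    def test_linear_ramp_symmetry(self):
        # ramp 0 -> 1 spanning exactly the 300 s window
        flow = np.linspace(0.0, 1.0, 301)
        tr = make_trace(flow, markers={"fecl3_on": 300.0})
        assert compute_baseline(tr) == pytest.approx(0.5)

    def test_window_outside_trace(self):
        tr = make_trace(np.ones(100), markers={"fecl3_on": 99.0})
        with pytest.raises(AnalysisError, match="outside"):
            compute_baseline(tr)

    def test_synthetic_fixture_matches_direct_mean(self, trace_dose5):
        # oracle: plain mean of the raw samples in the window
        end = trace_dose5.markers["fecl3_on"]
        mask = (trace_dose5.time_s >= end - 300.0) & (trace_dose5.time_s <= end)
        oracle = float(np.mean(trace_dose5.flow[mask]))
        assert compute_baseline(trace_dose5) == pytest.approx(oracle, rel=1e-12)
        assert compute_baseline(trace_dose5) == pytest.approx(0.8, abs=0.01)


# ---------------------------------------------------------------------------
# detect_complete_occlusion
# ---------------------------------------------------------------------------

class TestDetectCompleteOcclusion:
    def _trace(self, flow):
        return make_trace(flow, markers={"fecl3_on": 300.0})

    def test_zero_to_end(self):
        flow = np.ones(2000)
        flow[900:] = 0.0
        assert detect_complete_occlusion(self._trace(flow)) == pytest.approx(900.0)

    def test_short_run_absent(self):
        flow = np.ones(2000)
        flow[900:1200] = 0.0  # 300 s < 600 s
        assert detect_complete_occlusion(self._trace(flow)) is None

    def test_second_run_qualifies(self):
        # 400 s run then 700 s run; brute-force oracle picks the second
        flow = np.ones(3000)
        flow[600:1000] = 0.0
        flow[1500:2201] = 0.0
        tr = self._trace(flow)
        got = detect_complete_occlusion(tr)
        oracle = brute_force_occlusion(tr.time_s, flow, 0.05 * 1.0, 600.0)
        assert got == pytest.approx(1500.0)
        assert got == oracle

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        n = 600
        flow = rng.choice([0.0, 1.0], size=n, p=[0.5, 0.5])
        flow[:50] = 1.0  # keep a clean baseline window
        tr = make_trace(flow, markers={"fecl3_on": 49.0})
        base = compute_baseline(tr, window_s=49.0)
        dur = float(rng.integers(5, 100))
        got = detect_complete_occlusion(tr, duration_s=dur, baseline=base)
        oracle = brute_force_occlusion(tr.time_s, flow, 0.05 * base, dur)
        assert got == oracle

    def test_many_random_fixtures_bulk(self):
        # equivalence against the brute-force oracle on 1000 random fixtures
        rng = np.random.default_rng(77)
        for _ in range(1000):
            n = 200
            flow = rng.choice([0.0, 1.0], size=n)
            tr = make_trace(flow)
            dur = float(rng.integers(3, 60))
            got = detect_complete_occlusion(tr, duration_s=dur, baseline=1.0)
            oracle = brute_force_occlusion(tr.time_s, flow, 0.05, dur)
            assert got == oracle


# ---------------------------------------------------------------------------
# standardize_trace
# ---------------------------------------------------------------------------

class TestStandardizeTrace:
    def test_min_maps_to_zero(self):
        tr = make_trace(np.array([0.05, 0.3, 1.0]))
        out = standardize_trace(tr)
        assert np.min(out.flow) == pytest.approx(0.0)
        assert out.standardization_offset == pytest.approx(0.05)

    def test_zero_min_identity(self):
        flow = np.array([0.0, 0.3, 1.0])
        out = standardize_trace(make_trace(flow))
        np.testing.assert_array_equal(out.flow, flow)

    def test_divide_mode_requires_positive_min(self):
        with pytest.raises(AnalysisError):
            standardize_trace(make_trace(np.array([0.0, 1.0])), mode="divide")

    def test_unknown_mode(self):
        with pytest.raises(AnalysisError):
            standardize_trace(make_trace(np.ones(3)), mode="log")

    def test_score_after_standardization_matches_symbolic_oracle(self, trace_dose5):
        # oracle: apply the score formula symbolically to the shifted series
        std = standardize_trace(trace_dose5)
        m = float(np.min(trace_dose5.flow))
        base_std = compute_baseline(trace_dose5) - m
        got = thrombolysis_score(std, baseline=base_std)
        oracle = riemann_score(
            make_trace(trace_dose5.flow - m, markers=trace_dose5.markers),
            120.0, base_std, n_grid=4_000_000)
        assert got == pytest.approx(oracle, rel=1e-3)


# ---------------------------------------------------------------------------
# minute_means
# ---------------------------------------------------------------------------

class TestMinuteMeans:
    def test_constant_trace(self):
        tr = make_trace(np.full(600, 0.7), markers={"drug_start": 0.0})
        mm = minute_means(tr)
        assert np.allclose(mm.to_numpy(), 0.7)

    def test_bin_equals_slice_mean(self, trace_dose5):
        # oracle: direct slice mean of samples 60k .. 60k+59 (1 Hz trace)
        mm = minute_means(trace_dose5)
        ds = trace_dose5.markers["drug_start"]
        rng = np.random.default_rng(0)
        for k in rng.choice(mm.index.to_numpy(), size=10, replace=False):
            lo, hi = ds + 60 * k, ds + 60 * (k + 1)
            mask = (trace_dose5.time_s >= lo) & (trace_dose5.time_s < hi)
            assert mm.loc[k] == pytest.approx(
                float(np.mean(trace_dose5.flow[mask])), rel=1e-12)

    def test_negative_bins_before_drug_start(self, trace_dose5):
        mm = minute_means(trace_dose5)
        assert mm.index.min() < 0
        assert 0 in mm.index

    def test_150_minute_monitoring_gives_150_post_bins(self):
        # 150-minute x-axis of the temporal analysis
        n = 150 * 60 + 60  # a minute of pre-drug padding, then 150 min
        tr = make_trace(np.ones(n), markers={"drug_start": 60.0})
        mm = minute_means(tr)
        assert (mm.index >= 0).sum() == 150

    def test_partial_trailing_bin_dropped(self):
        tr = make_trace(np.ones(60 * 3 + 30), markers={"drug_start": 0.0})
        mm = minute_means(tr)
        assert list(mm.index) == [0, 1, 2]

    def test_too_short_trace(self):
        with pytest.raises(AnalysisError):
            minute_means(make_trace(np.ones(30)))


# ---------------------------------------------------------------------------
# thrombolysis_score
# ---------------------------------------------------------------------------

class TestThrombolysisScore:
    def _tr(self, level, baseline=1.0, monitor_min=120.0):
        n = 300 + int(monitor_min * 60) + 1
        flow = np.full(n, float(level))
        flow[:300] = baseline  # monitored level holds from drug_start onward
        return make_trace(flow, markers={"fecl3_on": 300.0, "drug_start": 300.0})

    def test_baseline_equal_gives_100(self):
        assert thrombolysis_score(self._tr(1.0), baseline=1.0) == pytest.approx(100.0)

    def test_zero_flow_gives_0(self):
        assert thrombolysis_score(self._tr(0.0), baseline=1.0) == pytest.approx(0.0, abs=1e-9)

    def test_half_baseline_gives_50(self):
        assert thrombolysis_score(self._tr(0.5), baseline=1.0) == pytest.approx(50.0, rel=1e-6)

    def test_missing_marker(self):
        tr = make_trace(np.ones(8000))
        with pytest.raises(AnalysisError, match="drug_start"):
            thrombolysis_score(tr)

    def test_short_trace(self):
        tr = make_trace(np.ones(1000), markers={"drug_start": 500.0})
        with pytest.raises(AnalysisError, match="monitoring window"):
            thrombolysis_score(tr)

    def test_trapezoid_matches_riemann_oracle(self, trace_dose5):
        base = compute_baseline(trace_dose5)
        got = thrombolysis_score(trace_dose5, baseline=base)
        oracle = riemann_score(trace_dose5, 120.0, base)
        assert got == pytest.approx(oracle, rel=1e-3)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 9999))
    def test_trapezoid_matches_riemann_on_seeded_fixtures(self, seed):
        tr = simulate_flow_trace(
            None, DoseRegimen.ten_pct_bolus_infusion(5.0), FlowSimParams(),
            DEFAULT_PK, seed=seed)
        base = compute_baseline(tr)
        assert thrombolysis_score(tr, baseline=base) == pytest.approx(
            riemann_score(tr, 120.0, base), rel=1e-3)

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 999))
    def test_scale_invariance(self, c, seed):
        tr = simulate_flow_trace(
            None, DoseRegimen.ten_pct_bolus_infusion(3.75), FlowSimParams(),
            DEFAULT_PK, seed=seed)
        scaled = FlowTrace(tr.animal_id, tr.time_s, tr.flow * c,
                           markers=dict(tr.markers))
        r1 = analyze_trace(tr)
        r2 = analyze_trace(scaled)
        assert r2.score_pct == pytest.approx(r1.score_pct, rel=1e-9)
        assert r2.effective_recanalization_time_min == \
            r1.effective_recanalization_time_min
        assert r2.reocclusion_times_min == r1.reocclusion_times_min


# ---------------------------------------------------------------------------
# detect_effective_recanalization
# ---------------------------------------------------------------------------

def step_trace(jump_minute, level, total_min=120, collapse_minute=None):
    """1 Hz trace: 300 s baseline=1, occluded 0, jumps to `level` at minute
    `jump_minute` post drug; optionally collapses back to 0."""
    n = 300 + total_min * 60 + 1
    flow = np.zeros(n)
    flow[:301] = 1.0
    start = 300 + jump_minute * 60
    end = n if collapse_minute is None else 300 + collapse_minute * 60
    flow[start:end] = level
    return make_trace(flow, markers={"fecl3_on": 300.0, "drug_start": 300.0})


class TestEffectiveRecanalization:
    def test_jump_at_14_sustained(self):
        tr = step_trace(14, 0.6)
        assert detect_effective_recanalization(tr, baseline=1.0) == 14.0

    def test_20_minute_excursion_fails_sustain(self):
        tr = step_trace(14, 0.6, collapse_minute=34)
        assert detect_effective_recanalization(tr, baseline=1.0) is None

    @pytest.mark.parametrize("run,expected", [
        (28, None), (29, None), (30, None), (31, 10.0), (32, 10.0)])
    def test_exact_sustain_boundary(self, run, expected):
        # exhaustive check over run lengths 28..32: > 30 min means 31 bins
        tr = step_trace(10, 0.6, collapse_minute=10 + run)
        assert detect_effective_recanalization(tr, baseline=1.0) == expected

    def test_threshold_is_inclusive(self):
        tr = step_trace(5, 0.5)  # exactly 50% of baseline
        assert detect_effective_recanalization(tr, baseline=1.0) == 5.0

    def test_detection_implies_31_bins_above(self, trace_dose5):
        base = compute_baseline(trace_dose5)
        std = standardize_trace(trace_dose5)
        base_std = compute_baseline(std)
        mm = minute_means(std)
        m = detect_effective_recanalization(std, baseline=base_std, minute=mm)
        assert m is not None
        window = mm.loc[int(m):int(m) + 30]
        assert len(window) == 31
        assert np.all(window.to_numpy() >= 0.5 * base_std)


class TestDetectReocclusion:
    def test_no_drop_empty(self):
        tr = step_trace(5, 0.8)
        assert detect_reocclusion(tr, after_min=5, baseline=1.0) == []

    def test_single_minute_dip_fails_sustain(self):
        tr = step_trace(5, 0.8)
        # one-minute dip at minute 50
        tr.flow[300 + 50 * 60:300 + 51 * 60] = 0.0
        assert detect_reocclusion(tr, after_min=5, baseline=1.0) == []

    def test_two_minute_drop_detected(self):
        tr = step_trace(5, 0.8)
        tr.flow[300 + 50 * 60:300 + 52 * 60] = 0.0
        assert detect_reocclusion(tr, after_min=5, baseline=1.0) == [50.0]

    def test_total_bolus_fixture_single_event(self, trace_total_bolus):
        rep = analyze_trace(trace_total_bolus)
        assert len(rep.reocclusion_times_min) == 1
        assert rep.reocclusion_times_min[0] > rep.effective_recanalization_time_min


# ---------------------------------------------------------------------------
# summaries and comparisons
# ---------------------------------------------------------------------------

def _report(score, recan=None):
    from thrombolyzer.flow import RecanalizationReport
    return RecanalizationReport(
        animal_id="x", baseline_flow=1.0, min_flow=0.0, score_pct=score,
        complete_occlusion_time_s=None,
        effective_recanalization_time_min=recan,
        reocclusion_times_min=[], minute_means=pd.Series(dtype=float))


class TestSummarizeDoses:
    def test_identical_scores(self):
        s = summarize_doses({1.0: [_report(40), _report(40), _report(40)]})
        assert s[0].mean_score_pct == pytest.approx(40.0)
        assert s[0].sd_score_pct == pytest.approx(0.0)

    def test_hand_computable(self):
        s = summarize_doses({1.0: [_report(2), _report(3), _report(4)]})
        assert s[0].mean_score_pct == pytest.approx(3.0)
        assert s[0].sd_score_pct == pytest.approx(1.0)

    def test_singleton_sd_absent_with_warning(self):
        with pytest.warns(UserWarning, match="n=1"):
            s = summarize_doses({1.0: [_report(5)]})
        assert s[0].sd_score_pct is None

    def test_recanalization_counts(self):
        s = summarize_doses({1.0: [_report(50, recan=10.0), _report(5)]})
        assert s[0].n_effective_recanalization == 1
        assert s[0].times_to_recanalization_min == [10.0]

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            summarize_doses({1.0: []})

    def test_seed_fixed_group_matches_two_pass_oracle(self, sim_params):
        reg = DoseRegimen.ten_pct_bolus_infusion(5.0)
        reports = [
            analyze_trace(simulate_flow_trace(None, reg, sim_params,
                                              DEFAULT_PK, seed=100 + i))
            for i in range(5)
        ]
        s = summarize_doses({5.0: reports})[0]
        scores = [r.score_pct for r in reports]
        mean = sum(scores) / len(scores)
        var = sum((x - mean) ** 2 for x in scores) / (len(scores) - 1)
        assert s.mean_score_pct == pytest.approx(mean, rel=1e-12)
        assert s.sd_score_pct == pytest.approx(var ** 0.5, rel=1e-12)


def exact_mannwhitney_p(a, b):
    """Exhaustive enumeration of the two-sided Mann-Whitney p for tiny samples."""
    from itertools import combinations
    pooled = list(a) + list(b)
    n = len(a)

    def u_stat(idx):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for x in grp_a for y in grp_b if x > y) \
            + 0.5 * sum(1 for x in grp_a for y in grp_b if x == y)

    observed = u_stat(tuple(range(n)))
    us = [u_stat(idx) for idx in combinations(range(len(pooled)), n)]
    m = len(pooled) - n
    dev = abs(observed - n * m / 2)
    extreme = sum(1 for u in us if abs(u - n * m / 2) >= dev - 1e-12)
    return extreme / len(us)


class TestCompareGroups:
    def test_degenerate_identical_p1(self):
        res = compare_groups({"a": [5, 5, 5], "b": [5, 5, 5], "c": [5, 5]})
        assert res.method == "degenerate"
        assert res.p_value == 1.0

    def test_two_groups_mann_whitney_exact_oracle(self):
        a, b = [1, 2, 3, 4, 5], [101, 102, 103, 104, 105]
        res = compare_groups({"lo": a, "hi": b})
        assert res.method == "mann_whitney"
        # U = 0 for this full separation; exact two-sided p = 2/C(10,5)
        oracle = exact_mannwhitney_p(a, b)
        assert oracle == pytest.approx(2 / 252)
        assert res.p_value == pytest.approx(oracle, rel=1e-9)
        assert res.p_value < 0.01
        assert res.pairwise[0]["significant"]

    def test_three_group_anova_tukey(self):
        rng = np.random.default_rng(1)
        res = compare_groups({
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0, 1, 8),
            "c": rng.normal(10, 1, 8),
        }, control="a")
        assert res.method == "anova_tukey"
        assert res.p_value < 1e-6
        pc = {(p["group_a"], p["group_b"]): p for p in res.pairwise}
        assert ("a", "c") in pc and pc[("a", "c")]["significant"]
        assert not pc[("a", "b")]["significant"]
        # control filter keeps only pairs involving the control group
        assert all("a" in (p["group_a"], p["group_b"]) for p in res.pairwise)

    def test_saline_vs_high_dose_tukey(self, sim_params):
        # scaled-down dose-response contrast: saline vs 5 mg/kg, n=5 each
        groups = {}
        for label, dose in [("saline", 0.0), ("d2.5", 2.5), ("d5", 5.0)]:
            reg = DoseRegimen.ten_pct_bolus_infusion(dose) if dose > 0 \
                else DoseRegimen(total_dose=0.0)
            groups[label] = [
                analyze_trace(simulate_flow_trace(None, reg, sim_params,
                                                  DEFAULT_PK, seed=i + 1)).score_pct
                for i in range(5)
            ]
        res = compare_groups(groups, control="saline")
        pc = {(p["group_a"], p["group_b"]): p for p in res.pairwise}
        assert pc[("saline", "d5")]["p_value"] < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(AnalysisError):
            compare_groups({"a": [1, 2]})

    def test_small_group_rejected(self):
        with pytest.raises(AnalysisError):
            compare_groups({"a": [1, 2], "b": [3]})

    def test_constant_but_different_groups(self):
        res = compare_groups({"a": [1.0, 1.0], "b": [2.0, 2.0], "c": [3.0, 3.0]})
        assert res.p_value == 0.0
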