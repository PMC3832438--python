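"""Flow-trace analysis: occlusion/recanalization events, thrombolysis score, group summaries.

A :class:`FlowTrace` is a time-stamped carotid blood-flow recording with named
experiment-phase markers. The analysis turns it into a
:class:`RecanalizationReport`: per-animal thrombolysis score, complete-occlusion
time, time to effective recanalization, and reocclusion events; groups of
reports are summarized and compared with standard one-way ANOVA / Tukey HSD
(or Mann-Whitney for two groups).

Conventions
-----------
* Raw traces are in seconds from recording start; event times are reported in
  minutes relative to the ``drug_start`` marker.
* Sustained-threshold event detection (recanalization, reocclusion) operates
  on per-minute mean flow, not raw samples.
* The thrombolysis score is ``100 x mean(flow over monitoring window) /
  baseline`` with the mean computed by trapezoidal integration over time.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, TraceParseError

logger = logging.getLogger(__name__)

MARKER_NAMES = (
    "recording_start",
    "fecl3_on",
    "fecl3_off",
    "occlusion_confirmed",
    "drug_start",
)

__all__ = [
    "FlowTrace",
    "RecanalizationReport",
    "DoseGroupSummary",
    "GroupComparison",
    "read_flow_trace",
    "write_flow_trace",
    "compute_baseline",
    "detect_complete_occlusion",
    "standardize_trace",
    "minute_means",
    "thrombolysis_score",
    "detect_effective_recanalization",
    "detect_reocclusion",
    "analyze_trace",
    "summarize_doses",
    "compare_groups",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FlowTrace:
    """One animal's carotid flow recording.

    Attributes
    ----------
    animal_id : str
        Label of the animal/run.
    time_s : ndarray
        Sample times in seconds from recording start, strictly increasing.
    flow : ndarray
        Blood flow in ml/min, non-negative after clipping.
    markers : dict
        Named event times in seconds (``recording_start``, ``fecl3_on``,
        ``fecl3_off``, ``occlusion_confirmed``, ``drug_start``).
    n_clipped : int
        Number of negative flow samples clipped to zero on ingest.
    standardization_offset : float or None
        Offset removed by :func:`standardize_trace`, if applied.
    """

    animal_id: str
    time_s: np.ndarray
    flow: np.ndarray
    markers: dict = field(default_factory=dict)
    n_clipped: int = 0
    standardization_offset: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.time_s.size == 0:
            raise TraceParseError("empty trace")
        if self.time_s.shape != self.flow.shape:
            raise TraceParseError("time and flow arrays differ in length")
        diffs = np.diff(self.time_s)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise TraceParseError(f"time not strictly increasing at row {row}")
        t0, t1 = self.time_s[0], self.time_s[-1]
        for name, value in self.markers.items():
            if not (t0 <= value <= t1):
                raise TraceParseError(
                    f"marker {name!r}={value} outside recorded span [{t0}, {t1}]"
                )
        occ = self.markers.get("occlusion_confirmed")
        ds = self.markers.get("drug_start")
        if occ is not None and ds is not None and ds < occ:
            raise TraceParseError("drug_start precedes occlusion_confirmed")

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    @property
    def sample_dt_s(self) -> float:
        """Median sampling interval (seconds)."""
        return float(np.median(np.diff(self.time_s)))

    def marker(self, name: str) -> float:
        if name not in self.markers:
            raise AnalysisError(f"required marker {name!r} missing from trace "
                                f"{self.animal_id!r}")
        return float(self.markers[name])


@dataclass
class RecanalizationReport:
    """Per-animal outcome of the flow-trace analysis."""

    animal_id: str
    baseline_flow: float
    min_flow: float
    score_pct: float
    complete_occlusion_time_s: float | None
    effective_recanalization_time_min: float | None
    reocclusion_times_min: list
    minute_means: pd.Series

    def to_dict(self) -> dict:
        d = {
            "animal_id": self.animal_id,
            "baseline_flow": self.baseline_flow,
            "min_flow": self.min_flow,
            "score_pct": self.score_pct,
            "complete_occlusion_time_s": self.complete_occlusion_time_s,
            "effective_recanalization_time_min": self.effective_recanalization_time_min,
            "reocclusion_times_min": list(self.reocclusion_times_min),
            "minute_means": {int(k): float(v) for k, v in self.minute_means.items()},
        }
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class DoseGroupSummary:
    """Mean +/- SD thrombolysis score and recanalization counts for one dose group."""

    label: str
    dose: float
    n: int
    mean_score_pct: float
    sd_score_pct: float | None
    n_effective_recanalization: int
    times_to_recanalization_min: list

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupComparison:
    """Result of the routine group-comparison contract."""

    method: str              # "anova_tukey" | "mann_whitney" | "degenerate"
    statistic: float
    p_value: float
    pairwise: list           # dicts: group_a, group_b, p_value, significant
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_flow_trace(
    path: str | Path,
    markers: Mapping[str, float] | None = None,
    marker_path: str | Path | None = None,
    animal_id: str | None = None,
) -> FlowTrace:
    """Read a two-column ``time_s,flow`` CSV into a validated :class:`FlowTrace`.

    Markers come from an explicit mapping, a sidecar JSON file, or (by default)
    ``<path>.markers.json`` next to the trace if it exists. Negative flow values
    are clipped to zero and the count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise TraceParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"empty file: {path}") from exc
    for col in ("time_s", "flow"):
        if col not in df.columns:
            raise TraceParseError(f"missing column {col!r} in {path}")
    if len(df) == 0:
        raise TraceParseError(f"no data rows in {path}")

    if markers is None:
        side = Path(marker_path) if marker_path else path.with_suffix(path.suffix + ".markers.json")
        if marker_path is not None and not side.exists():
            raise TraceParseError(f"marker file not found: {side}")
        markers = json.loads(side.read_text()) if side.exists() else {}

    flow = df["flow"].to_numpy(dtype=float)
    n_neg = int(np.sum(flow < 0))
    if n_neg:
        logger.warning("%s: clipped %d negative flow values to 0", path, n_neg)
        flow = np.clip(flow, 0.0, None)

    return FlowTrace(
        animal_id=animal_id or path.stem,
        time_s=df["time_s"].to_numpy(dtype=float),
        flow=flow,
        markers=dict(markers),
        n_clipped=n_neg,
    )


def write_flow_trace(trace: FlowTrace, path: str | Path,
                     marker_path: str | Path | None = None) -> None:
    """Write a trace as ``time_s,flow`` CSV plus a markers sidecar JSON."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s, "flow": trace.flow}).to_csv(path, index=False)
    side = Path(marker_path) if marker_path else path.with_suffix(path.suffix + ".markers.json")
    side.write_text(json.dumps({k: float(v) for k, v in trace.markers.items()}, indent=2))


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def compute_baseline(trace: FlowTrace, window_s: float = 300.0,
                     end_marker: str = "fecl3_on") -> float:
    """Mean flow over the pre-injury baseline window.

    The window is the ``window_s`` seconds ending at ``end_marker`` (default
    the FeCl3 application time); if the marker is absent the window starts at
    the beginning of the recording.
    """
    if end_marker in trace.markers:
        end = trace.marker(end_marker)
        start = end - window_s
    else:
        start = float(trace.time_s[0])
        end = start + window_s
    eps = 1e-9
    if start < trace.time_s[0] - eps or end > trace.time_s[-1] + eps:
        raise AnalysisError(
            f"baseline window [{start}, {end}] extends outside trace span"
        )
    mask = (trace.time_s >= start - eps) & (trace.time_s <= end + eps)
    if not np.any(mask):
        raise AnalysisError("baseline window contains no samples")
    return float(np.mean(trace.flow[mask]))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/end (inclusive) indices of maximal runs of True in a boolean array."""
    out: list[tuple[int, int]] = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        out.append((int(s), int(e) - 1))
    return out


def detect_complete_occlusion(
    trace: FlowTrace,
    zero_frac: float = 0.05,
    duration_s: float = 600.0,
    baseline: float | None = None,
) -> float | None:
    """Start time (s) of the first sustained zero-flow run, or None.

    Complete occlusion is the first contiguous run of samples with flow below
    ``zero_frac x baseline`` lasting at least ``duration_s``. Absence is a
    valid outcome, not an error.
    """
    if baseline is None:
        baseline = compute_baseline(trace)
    below = trace.flow < zero_frac * baseline
    for s, e in _runs(below):
        if trace.time_s[e] - trace.time_s[s] >= duration_s:
            return float(trace.time_s[s])
    return None


def standardize_trace(trace: FlowTrace, mode: str = "subtract") -> FlowTrace:
    """Standardize a trace by its per-animal minimum flow.

    ``mode="subtract"`` (default) subtracts the minimum so the occluded plateau
    maps to exactly zero; ``mode="divide"`` divides by the minimum (requires a
    strictly positive minimum and is numerically fragile when the vessel truly
    occludes — exposed for completeness only).
    """
    m = float(np.min(trace.flow))
    if mode == "subtract":
        new_flow = trace.flow - m
        offset = m
    elif mode == "divide":
        if m <= 0:
            raise AnalysisError("divide standardization requires min flow > 0")
        new_flow = trace.flow / m
        offset = m
    else:
        raise AnalysisError(f"unknown standardization mode {mode!r}")
    return FlowTrace(
        animal_id=trace.animal_id,
        time_s=trace.time_s.copy(),
        flow=new_flow,
        markers=dict(trace.markers),
        n_clipped=trace.n_clipped,
        standardization_offset=offset,
    )


def minute_means(trace: FlowTrace, origin_marker: str = "drug_start") -> pd.Series:
    """Per-minute mean flow, binned relative to ``drug_start``.

    Bin ``k`` covers ``[60k, 60(k+1))`` seconds from the origin marker; bins
    before the origin carry negative indices. Partial bins at either edge are
    dropped. Returns a Series indexed by integer bin number.
    """
    if trace.duration_s < 60.0:
        raise AnalysisError("trace spans less than one minute")
    origin = trace.markers.get(origin_marker, float(trace.time_s[0]))
    rel = trace.time_s - origin
    k = np.floor(rel / 60.0).astype(int)
    dt = trace.sample_dt_s
    df = pd.DataFrame({"k": k, "flow": trace.flow})
    means = df.groupby("k")["flow"].mean()
    # keep only bins fully inside the recorded span
    complete = (means.index * 60.0 >= rel[0] - 1e-9) & \
               ((means.index + 1) * 60.0 <= rel[-1] + dt + 1e-9)
    means = means[complete]
    means.index.name = "minute"
    means.name = "flow"
    return means


def thrombolysis_score(
    trace: FlowTrace,
    monitor_min: float = 120.0,
    baseline: float | None = None,
) -> float:
    """Thrombolysis score: 100 x mean monitored flow / baseline flow.

    The mean is the trapezoidal time-integral of flow over
    ``[drug_start, drug_start + monitor_min]`` divided by the window duration;
    endpoint flows are linearly interpolated so the window is exact.
    """
    ds = trace.marker("drug_start")
    end = ds + monitor_min * 60.0
    if end > trace.time_s[-1] + 1e-9:
        raise AnalysisError(
            f"trace ends at {trace.time_s[-1]:.0f}s but monitoring window "
            f"requires {end:.0f}s"
        )
    if baseline is None:
        baseline = compute_baseline(trace)
    if baseline <= 0:
        raise AnalysisError("baseline flow must be positive to compute a score")
    inside = (trace.time_s > ds) & (trace.time_s < end)
    t = np.concatenate(([ds], trace.time_s[inside], [end]))
    f = np.concatenate((
        [np.interp(ds, trace.time_s, trace.flow)],
        trace.flow[inside],
        [np.interp(end, trace.time_s, trace.flow)],
    ))
    mean_flow = np.trapezoid(f, t) / (end - ds)
    return float(100.0 * mean_flow / baseline)


def detect_effective_recanalization(
    trace: FlowTrace,
    frac: float = 0.5,
    sustain_min: int = 30,
    baseline: float | None = None,
    minute: pd.Series | None = None,
) -> float | None:
    """First minute (from drug_start) of sustained flow restoration, or None.

    Effective recanalization requires minute-mean flow of at least
    ``frac x baseline`` for *longer than* ``sustain_min`` minutes, i.e. a run
    of ``sustain_min + 1`` consecutive qualifying minute bins. The reported
    time is the first bin of the run (threshold-crossing time).
    """
    if baseline is None:
        baseline = compute_baseline(trace)
    mm = minute if minute is not None else minute_means(trace)
    post = mm[mm.index >= 0]
    if post.empty:
        return None
    above = (post.to_numpy() >= frac * baseline)
    need = sustain_min + 1
    for s, e in _runs(above):
        if e - s + 1 >= need:
            return float(post.index[s])
    return None


def detect_reocclusion(
    trace: FlowTrace,
    after_min: float,
    frac: float = 0.10,
    sustain_min: int = 2,
    baseline: float | None = None,
    minute: pd.Series | None = None,
) -> list[float]:
    """Start minutes of sustained flow collapse after recanalization.

    A reocclusion is a run of at least ``sustain_min`` consecutive minute bins
    with mean flow below ``frac x baseline``, starting strictly after
    ``after_min`` (the effective-recanalization minute).
    """
    if baseline is None:
        baseline = compute_baseline(trace)
    mm = minute if minute is not None else minute_means(trace)
    post = mm[mm.index > after_min]
    if post.empty:
        return []
    below = post.to_numpy() < frac * baseline
    events = []
    for s, e in _runs(below):
        if e - s + 1 >= sustain_min:
            events.append(float(post.index[s]))
    return events


def analyze_trace(
    trace: FlowTrace,
    monitor_min: float = 120.0,
    frac: float = 0.5,
    sustain_min: int = 30,
    reocclusion_frac: float = 0.10,
    reocclusion_sustain_min: int = 2,
    zero_frac: float = 0.05,
    occlusion_duration_s: float = 600.0,
    standardize: bool = True,
) -> RecanalizationReport:
    """Full per-animal pipeline: baseline, events, score, minute series."""
    baseline = compute_baseline(trace)
    work = standardize_trace(trace) if standardize else trace
    # baseline recomputed on the standardized trace so score/thresholds are
    # consistent with the shifted flow values
    base_std = compute_baseline(work)
    mm = minute_means(work)
    occ = detect_complete_occlusion(work, zero_frac=zero_frac,
                                    duration_s=occlusion_duration_s,
                                    baseline=base_std)
    score = thrombolysis_score(work, monitor_min=monitor_min, baseline=base_std)
    recan = detect_effective_recanalization(work, frac=frac,
                                            sustain_min=sustain_min,
                                            baseline=base_std, minute=mm)
    reocc: list[float] = []
    if recan is not None:
        reocc = detect_reocclusion(work, after_min=recan,
                                   frac=reocclusion_frac,
                                   sustain_min=reocclusion_sustain_min,
                                   baseline=base_std, minute=mm)
    return RecanalizationReport(
        animal_id=trace.animal_id,
        baseline_flow=baseline,
        min_flow=float(np.min(trace.flow)),
        score_pct=score,
        complete_occlusion_time_s=occ,
        effective_recanalization_time_min=recan,
        reocclusion_times_min=reocc,
        minute_means=mm,
    )


# ---------------------------------------------------------------------------
# Group summaries and comparisons
# ---------------------------------------------------------------------------

def summarize_doses(
    reports_by_dose: Mapping[float, Sequence[RecanalizationReport]],
    labels: Mapping[float, str] | None = None,
) -> list[DoseGroupSummary]:
    """Per-group mean/SD of the thrombolysis score plus recanalization counts.

    SD uses the sample (n-1) denominator and is absent (None, with a warning)
    for singleton groups.
    """
    out = []
    for dose in sorted(reports_by_dose):
        reports = list(reports_by_dose[dose])
        if not reports:
            raise AnalysisError(f"empty group for dose {dose}")
        scores = np.array([r.score_pct for r in reports], dtype=float)
        n = len(scores)
        if n >= 2:
            sd = float(np.std(scores, ddof=1))
        else:
            warnings.warn(f"group dose={dose} has n=1; SD not defined")
            sd = None
        times = [r.effective_recanalization_time_min for r in reports
                 if r.effective_recanalization_time_min is not None]
        out.append(DoseGroupSummary(
            label=labels[dose] if labels else str(dose),
            dose=float(dose),
            n=n,
            mean_score_pct=float(np.mean(scores)),
            sd_score_pct=sd,
            n_effective_recanalization=len(times),
            times_to_recanalization_min=times,
        ))
    return out


def compare_groups(
    scores_by_group: Mapping[str, Sequence[float]],
    control: str | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Routine group comparison: one-way ANOVA + Tukey HSD, or Mann-Whitney.

    With exactly two groups the nonparametric Mann-Whitney U path is used.
    With more, one-way ANOVA across groups plus pairwise Tukey HSD. Fully
    degenerate input (every observation identical) reports p = 1 by convention.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in scores_by_group.items()}
    if len(groups) < 2:
        raise AnalysisError("need at least two groups to compare")
    for k, v in groups.items():
        if v.size < 2:
            raise AnalysisError(f"group {k!r} has n < 2")
    labels = list(groups)
    allvals = np.concatenate(list(groups.values()))
    if np.ptp(allvals) == 0:
        pairwise = [
            {"group_a": a, "group_b": b, "p_value": 1.0, "significant": False}
            for i, a in enumerate(labels) for b in labels[i + 1:]
        ]
        return GroupComparison("degenerate", 0.0, 1.0, pairwise, alpha)

    if len(groups) == 2:
        a, b = (groups[k] for k in labels)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        pairwise = [{
            "group_a": labels[0], "group_b": labels[1],
            "p_value": float(res.pvalue),
            "significant": bool(res.pvalue < alpha),
        }]
        return GroupComparison("mann_whitney", float(res.statistic),
                               float(res.pvalue), pairwise, alpha)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = stats.f_oneway(*groups.values())
    if not np.isfinite(p):
        # zero within-group variance with distinct means: maximally significant
        p = 0.0
        f_stat = np.inf
    tukey = stats.tukey_hsd(*groups.values())
    pairwise = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            pv = float(tukey.pvalue[i, j])
            if control is not None and control not in (a, b):
                continue
            pairwise.append({
                "group_a": a, "group_b": b,
                "p_value": pv, "significant": bool(pv < alpha),
            })
    return GroupComparison("anova_tukey", float(f_stat), float(p),
                           pairwise, alpha)
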