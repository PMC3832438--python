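"""Impedance platelet-aggregometry statistics: inhibition and disaggregation.

Inhibition compares the maximal above-baseline impedance of a treated run
(``a``) to an untreated control (``a0``): ``100 x (1 - a/a0)``. The
disaggregation statistic expresses how far impedance has returned from its
maximum toward the pre-agonist baseline at a fixed readout time after the
test agent is added — 100% means full restoration to basal levels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, InvalidInputError, TraceParseError

#: Readout times (s after test-agent addition) at which disaggregation is
#: quoted for each agonist.
DEFAULT_READOUT_S = {"ADP": 14.0, "collagen": 300.0}

__all__ = [
    "AggTrace",
    "AggResult",
    "read_agg_trace",
    "write_agg_trace",
    "max_aggregation",
    "percent_inhibition",
    "percent_disaggregation",
    "DEFAULT_READOUT_S",
]


@dataclass
class AggTrace:
    """Impedance-vs-time aggregometry recording."""

    time_s: np.ndarray
    impedance_ohm: np.ndarray
    agonist: str = ""
    treatment_dose_ug: float = 0.0
    addition_time_s: float | None = None   # test-agent addition (disaggregation)
    agonist_time_s: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.impedance_ohm = np.asarray(self.impedance_ohm, dtype=float)
        if self.time_s.size == 0:
            raise TraceParseError("empty aggregometry trace")
        if self.time_s.shape != self.impedance_ohm.shape:
            raise TraceParseError("time and impedance arrays differ in length")
        if np.any(np.diff(self.time_s) <= 0):
            raise TraceParseError("time not strictly increasing")
        if not np.all(np.isfinite(self.impedance_ohm)):
            raise TraceParseError("impedance contains non-finite values")
        if self.addition_time_s is not None and not (
            self.time_s[0] <= self.addition_time_s <= self.time_s[-1]
        ):
            raise TraceParseError("addition_time_s outside recorded span")


@dataclass
class AggResult:
    """Summary statistics of one aggregometry comparison."""

    max_aggregation_ohm: float
    control_max_ohm: float | None = None
    inhibition_pct: float | None = None
    disaggregation_pct: float | None = None
    readout_time_s: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def read_agg_trace(path: str | Path, meta_path: str | Path | None = None) -> AggTrace:
    """Read a ``time_s,impedance_ohm`` CSV plus optional sidecar metadata JSON."""
    path = Path(path)
    if not path.exists():
        raise TraceParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"empty file: {path}") from exc
    for col in ("time_s", "impedance_ohm"):
        if col not in df.columns:
            raise TraceParseError(f"missing column {col!r} in {path}")
    meta = {}
    side = Path(meta_path) if meta_path else path.with_suffix(path.suffix + ".meta.json")
    if side.exists():
        meta = json.loads(side.read_text())
    return AggTrace(
        time_s=df["time_s"].to_numpy(dtype=float),
        impedance_ohm=df["impedance_ohm"].to_numpy(dtype=float),
        agonist=meta.get("agonist", ""),
        treatment_dose_ug=float(meta.get("treatment_dose_ug", 0.0)),
        addition_time_s=meta.get("addition_time_s"),
        agonist_time_s=meta.get("agonist_time_s"),
    )


def write_agg_trace(trace: AggTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s,
                  "impedance_ohm": trace.impedance_ohm}).to_csv(path, index=False)
    meta = {
        "agonist": trace.agonist,
        "treatment_dose_ug": trace.treatment_dose_ug,
        "addition_time_s": trace.addition_time_s,
        "agonist_time_s": trace.agonist_time_s,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2))


def _baseline(trace: AggTrace, baseline_window_s: float) -> float:
    t0 = trace.time_s[0]
    cutoff = trace.agonist_time_s if trace.agonist_time_s is not None \
        else t0 + baseline_window_s
    mask = trace.time_s < cutoff
    if not np.any(mask):
        raise AnalysisError("no samples before agonist addition for baseline")
    return float(np.mean(trace.impedance_ohm[mask]))


def max_aggregation(trace: AggTrace, baseline_window_s: float = 30.0) -> float:
    """Maximal impedance above the pre-agonist baseline (ohms).

    The baseline is the mean impedance before agonist addition (the marked
    agonist time if present, else the first ``baseline_window_s`` seconds).
    A trace that never leaves baseline yields ~0.
    """
    base = _baseline(trace, baseline_window_s)
    return float(np.max(trace.impedance_ohm) - base)


def percent_inhibition(a: float, a0: float) -> float:
    """Percent inhibition of aggregation: ``100 x (1 - a/a0)``.

    ``a`` is the treated maximal aggregation, ``a0`` the control. Values with
    ``a > a0`` (enhancement) return a negative percentage with a warning
    rather than being clamped.
    """
    if not np.isfinite(a0) or a0 <= 0:
        raise InvalidInputError("control maximal aggregation a0 must be > 0")
    if not np.isfinite(a) or a < 0:
        raise InvalidInputError("treated maximal aggregation a must be >= 0")
    if a > a0:
        warnings.warn("treated aggregation exceeds control; "
                      "reporting negative inhibition (enhancement)")
    return 100.0 * (1.0 - a / a0)


def percent_disaggregation(
    trace: AggTrace,
    readout_s: float,
    baseline_window_s: float = 30.0,
) -> float:
    """Percent restoration toward baseline at ``readout_s`` after addition.

    ``100 x (a_max - a(t_add + readout)) / (a_max - a_baseline)`` where
    ``a_max`` is the peak impedance before the test agent was added and the
    readout value is linearly interpolated. 100% = impedance back to basal
    levels; 0% = unchanged from maximum.
    """
    if trace.addition_time_s is None:
        raise AnalysisError("disaggregation requires addition_time_s")
    if readout_s < 0:
        raise InvalidInputError("readout_s must be >= 0")
    t_read = trace.addition_time_s + readout_s
    if t_read > trace.time_s[-1] + 1e-9:
        raise AnalysisError(
            f"readout at {t_read:.1f}s beyond end of trace "
            f"({trace.time_s[-1]:.1f}s)"
        )
    base = _baseline(trace, baseline_window_s)
    pre = trace.time_s <= trace.addition_time_s
    if not np.any(pre):
        raise AnalysisError("no samples before test-agent addition")
    a_max = float(np.max(trace.impedance_ohm[pre]))
    if a_max <= base:
        raise AnalysisError(
            "maximal aggregation not reached before addition; "
            "disaggregation undefined"
        )
    a_read = float(np.interp(t_read, trace.time_s, trace.impedance_ohm))
    return 100.0 * (a_max - a_read) / (a_max - base)
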