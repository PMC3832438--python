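"""End-to-end study orchestration: simulate -> analyze -> summarize -> report.

A :class:`StudyConfig` describes a multi-group experiment (label, dose,
regimen, group size per group plus simulator/PK calibration and analysis
thresholds). :func:`run_study` produces a deterministic :class:`StudyReport`
with per-animal recanalization reports, per-group summaries, a group
comparison table, and complete provenance (config hash and per-animal seeds).
Per-animal seeds are ``seed_base + crc32(label/index)`` so adding a group
never perturbs the data of existing groups.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .errors import AnalysisError, ThrombolyzerError
from .flow import (
    DoseGroupSummary,
    FlowTrace,
    GroupComparison,
    RecanalizationReport,
    analyze_trace,
    compare_groups,
    summarize_doses,
    write_flow_trace,
)
from .synthetic import (
    DEFAULT_PK,
    DoseRegimen,
    FlowSimParams,
    PKParams,
    REGIMEN_PRESETS,
    hash_seed,
    simulate_flow_trace,
)

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSpec",
    "AnalysisThresholds",
    "StudyConfig",
    "AnimalResult",
    "StudyReport",
    "run_study",
    "group_minute_stats",
    "plot_study",
]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group."""

    label: str
    dose: float
    regimen: DoseRegimen
    n_animals: int = 5

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise AnalysisError("n_animals must be >= 1")


@dataclass(frozen=True)
class AnalysisThresholds:
    frac: float = 0.5
    sustain_min: int = 30
    monitor_min: float = 120.0
    reocclusion_frac: float = 0.10
    reocclusion_sustain_min: int = 2

    def __post_init__(self) -> None:
        if self.frac <= 0 or self.monitor_min <= 0 or self.sustain_min <= 0:
            raise AnalysisError("analysis thresholds must be positive")


@dataclass
class StudyConfig:
    """Declarative description of a simulate-and-analyze study."""

    groups: list                      # of GroupSpec
    sim_params: FlowSimParams = field(default_factory=FlowSimParams)
    pk: PKParams = DEFAULT_PK
    analysis: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    seed_base: int = 0

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise AnalysisError("group labels must be unique")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "groups": [
                {
                    "label": g.label,
                    "dose": g.dose,
                    "regimen": asdict(g.regimen),
                    "n_animals": g.n_animals,
                }
                for g in self.groups
            ],
            "sim_params": asdict(self.sim_params),
            "pk": asdict(self.pk),
            "analysis": asdict(self.analysis),
            "seed_base": self.seed_base,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        groups = []
        for g in d["groups"]:
            reg = g.get("regimen")
            if isinstance(reg, str):
                regimen = REGIMEN_PRESETS[reg](g["dose"])
            elif isinstance(reg, dict):
                regimen = DoseRegimen(**reg)
            elif reg is None:
                regimen = (DoseRegimen.ten_pct_bolus_infusion(g["dose"])
                           if g["dose"] > 0 else DoseRegimen(total_dose=0.0))
            else:
                regimen = reg
            groups.append(GroupSpec(label=g["label"], dose=float(g["dose"]),
                                    regimen=regimen,
                                    n_animals=int(g.get("n_animals", 5))))
        sim = FlowSimParams(**d.get("sim_params", {}))
        pk_d = d.get("pk")
        if pk_d is None:
            pk = DEFAULT_PK
        elif "half_life_min" in pk_d and "elimination_rate" not in pk_d:
            pk = PKParams.from_half_life(pk_d["half_life_min"])
        else:
            pk = PKParams(**pk_d)
        analysis = AnalysisThresholds(**d.get("analysis", {}))
        return cls(groups=groups, sim_params=sim, pk=pk, analysis=analysis,
                   seed_base=int(d.get("seed_base", 0)))

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text())
        return cls.from_dict(data)


@dataclass
class AnimalResult:
    group: str
    dose: float
    index: int
    seed: int
    trace: FlowTrace
    report: RecanalizationReport


@dataclass
class StudyReport:
    config: StudyConfig
    animals: list                         # of AnimalResult
    summaries: list                       # of DoseGroupSummary
    comparison: GroupComparison | None
    provenance: dict

    def scores_by_group(self) -> dict:
        out: dict[str, list[float]] = {}
        for a in self.animals:
            out.setdefault(a.group, []).append(a.report.score_pct)
        return out

    def reports_by_group(self) -> dict:
        out: dict[str, list[RecanalizationReport]] = {}
        for a in self.animals:
            out.setdefault(a.group, []).append(a.report)
        return out

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "groups": [s.to_dict() for s in self.summaries],
            "comparison": None if self.comparison is None else {
                "method": self.comparison.method,
                "statistic": self.comparison.statistic,
                "p_value": self.comparison.p_value,
                "pairwise": self.comparison.pairwise,
            },
            "animals": [
                {
                    "group": a.group,
                    "dose": a.dose,
                    "index": a.index,
                    "seed": a.seed,
                    **a.report.to_dict(),
                }
                for a in self.animals
            ],
        }


def run_study(config: StudyConfig, outdir: str | Path | None = None) -> StudyReport:
    """Execute a full simulated study, deterministically in ``seed_base``.

    If ``outdir`` is given, every intermediate trace CSV, per-animal report
    JSON, a group-summary TSV, and a ``study.json`` report with provenance are
    written there.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        (outdir / "traces").mkdir(parents=True, exist_ok=True)
        (outdir / "reports").mkdir(parents=True, exist_ok=True)

    thr = config.analysis
    animals: list[AnimalResult] = []
    for group in config.groups:
        t0 = time.perf_counter()
        for idx in range(group.n_animals):
            seed = config.seed_base + hash_seed(group.label, idx)
            animal_id = f"{group.label}_{idx}"
            try:
                trace = simulate_flow_trace(
                    None, group.regimen, config.sim_params, config.pk,
                    animal_id=animal_id, seed=seed,
                )
                report = analyze_trace(
                    trace,
                    monitor_min=thr.monitor_min,
                    frac=thr.frac,
                    sustain_min=thr.sustain_min,
                    reocclusion_frac=thr.reocclusion_frac,
                    reocclusion_sustain_min=thr.reocclusion_sustain_min,
                )
            except ThrombolyzerError as exc:
                raise AnalysisError(
                    f"group {group.label!r}, animal {idx}: {exc}"
                ) from exc
            logger.info(
                "%s: score=%.1f%% recan=%s reocc=%s",
                animal_id, report.score_pct,
                report.effective_recanalization_time_min,
                report.reocclusion_times_min,
            )
            animals.append(AnimalResult(group.label, group.dose, idx, seed,
                                        trace, report))
            if outdir is not None:
                write_flow_trace(trace, outdir / "traces" / f"{animal_id}.csv")
                report.to_json(outdir / "reports" / f"{animal_id}.json")
        logger.info("group %s done in %.2fs", group.label,
                    time.perf_counter() - t0)

    by_dose: dict[float, list[RecanalizationReport]] = {}
    labels: dict[float, str] = {}
    for g in config.groups:
        by_dose[g.dose] = [a.report for a in animals if a.group == g.label]
        labels[g.dose] = g.label
    summaries = summarize_doses(by_dose, labels=labels)

    comparison = None
    scores = {g.label: [a.report.score_pct for a in animals if a.group == g.label]
              for g in config.groups}
    if len(scores) >= 2 and all(len(v) >= 2 for v in scores.values()):
        comparison = compare_groups(scores, control=config.groups[0].label)

    provenance = {
        "config_hash": config.config_hash(),
        "seed_base": config.seed_base,
        "seeds": {f"{a.group}_{a.index}": a.seed for a in animals},
        "package_version": __version__,
        "config": config.to_dict(),
    }
    report = StudyReport(config=config, animals=animals, summaries=summaries,
                         comparison=comparison, provenance=provenance)

    if outdir is not None:
        (outdir / "study.json").write_text(json.dumps(report.to_dict(), indent=2))
        _write_group_tsv(report, outdir / "groups.tsv")
    return report


def _write_group_tsv(report: StudyReport, path: Path) -> None:
    lines = ["label\tdose\tn\tmean_score_pct\tsd_score_pct\t"
             "n_effective_recanalization\ttimes_to_recanalization_min"]
    for s in report.summaries:
        sd = "" if s.sd_score_pct is None else f"{s.sd_score_pct:.4f}"
        times = ",".join(f"{t:g}" for t in s.times_to_recanalization_min)
        lines.append(f"{s.label}\t{s.dose:g}\t{s.n}\t{s.mean_score_pct:.4f}\t"
                     f"{sd}\t{s.n_effective_recanalization}\t{times}")
    path.write_text("\n".join(lines) + "\n")


def group_minute_stats(report: StudyReport, group: str):
    """Mean and SD across a group's animals of the post-drug minute means.

    Returns ``(mean, sd)`` pandas Series indexed by minute bin; ``sd`` is None
    for singleton groups. This is exactly what the minute-bar figure renders.
    """
    import pandas as pd

    members = [a for a in report.animals if a.group == group]
    if not members:
        raise AnalysisError(f"no animals in group {group!r}")
    df = pd.concat([a.report.minute_means for a in members], axis=1)
    post = df[df.index >= 0]
    mean = post.mean(axis=1)
    sd = post.std(axis=1, ddof=1) if len(members) > 1 else None
    return mean, sd


def plot_study(report: StudyReport, outdir: str | Path) -> list:
    """Render per-group figures: a minute-mean bar graph (mean +/- SD) and a
    per-animal spaghetti time-flow plot. Returns the list of files written."""
    if not report.animals:
        raise AnalysisError("empty report: nothing to plot")
    try:
        import matplotlib
        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover - matplotlib is a hard dep
        raise ThrombolyzerError(
            "plotting requires matplotlib, which is not available"
        ) from exc

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for group in {a.group for a in report.animals}:
        members = [a for a in report.animals if a.group == group]

        # minute-mean bar graph (mean +/- SD across animals)
        mean, sd = group_minute_stats(report, group)
        fig, ax = plt.subplots(figsize=(8, 3))
        ax.bar(mean.index, mean.to_numpy(), width=1.0,
               yerr=None if sd is None else sd.to_numpy(),
               color="steelblue", ecolor="gray", linewidth=0)
        ax.set_xlabel("minutes from drug start")
        ax.set_ylabel("flow (ml/min)")
        ax.set_title(f"{group}: per-minute mean flow")
        p1 = outdir / f"{group}_minute_bars.png"
        fig.savefig(p1, dpi=110)
        plt.close(fig)

        # spaghetti time-flow curves
        fig, ax = plt.subplots(figsize=(8, 3))
        for a in members:
            ax.plot(a.trace.time_s / 60.0, a.trace.flow, lw=0.6,
                    label=a.trace.animal_id)
        ax.set_xlabel("minutes")
        ax.set_ylabel("flow (ml/min)")
        ax.set_title(f"{group}: time-flow curves")
        p2 = outdir / f"{group}_timeflow.png"
        fig.savefig(p2, dpi=110)
        plt.close(fig)
        written.extend([p1, p2])
    return written
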