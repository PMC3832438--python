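"""Synthetic-data generators: PK-driven thrombosis/lysis flow traces,
aggregometry kinetics, Langmuir titrations, and mono-exponential decay.

The flow simulator couples a one-compartment bolus+infusion pharmacokinetic
model (volume of distribution normalized to 1, so concentration is in
dose-normalized units) to a single latent thrombus-burden state B in [0, 1]:

    dB/dt = -k_lysis * E(C) * B + k_regrowth * [C < conc_crit] * B * (1 - B)

with a Hill lysis drive E(C) = emax * C^h / (C^h + ec50_conc^h) and flow =
baseline * (1 - B) * (1 + noise). Regrowth is gated by the plasma
concentration dropping below ``conc_crit``, which produces abrupt
reocclusion after a short-half-life bolus but not during a sustained
infusion. All randomness is driven by explicit integer seeds.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .aggregometry import AggTrace
from .binding import DecayCurve, TitrationCurve
from .errors import InvalidInputError, SimulationError
from .flow import FlowTrace, write_flow_trace

LN2 = math.log(2.0)

#: Serum sampling grid (minutes) used by the half-life experiment.
DEFAULT_DECAY_GRID_MIN = (0.0, 5.0, 10.0, 20.0, 40.0, 80.0)

__all__ = [
    "PKParams",
    "DoseRegimen",
    "FlowSimParams",
    "ThrombusState",
    "AggSimParams",
    "pk_concentration",
    "simulate_flow_trace",
    "simulate_aggregometry",
    "simulate_titration",
    "simulate_decay",
    "materialize_fixtures",
    "DEFAULT_DECAY_GRID_MIN",
]


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PKParams:
    """One-compartment elimination parameters.

    ``half_life_min`` is redundant with ``elimination_rate`` and must satisfy
    ``half_life_min = ln 2 / elimination_rate``.
    """

    elimination_rate: float      # per minute
    half_life_min: float         # minutes

    def __post_init__(self) -> None:
        if not (np.isfinite(self.elimination_rate) and self.elimination_rate > 0):
            raise InvalidInputError("elimination_rate must be finite and > 0")
        expected = LN2 / self.elimination_rate
        if abs(self.half_life_min - expected) > 1e-9 * expected:
            raise InvalidInputError(
                f"half_life_min={self.half_life_min} inconsistent with "
                f"elimination_rate={self.elimination_rate} (expected {expected})"
            )

    @classmethod
    def from_half_life(cls, half_life_min: float) -> "PKParams":
        if not (np.isfinite(half_life_min) and half_life_min > 0):
            raise InvalidInputError("half_life_min must be finite and > 0")
        return cls(elimination_rate=LN2 / half_life_min, half_life_min=half_life_min)

    @classmethod
    def from_rate(cls, elimination_rate: float) -> "PKParams":
        if not (np.isfinite(elimination_rate) and elimination_rate > 0):
            raise InvalidInputError("elimination_rate must be finite and > 0")
        return cls(elimination_rate=elimination_rate,
                   half_life_min=LN2 / elimination_rate)


#: Default kinetics: reported serum half-life of 4.1 minutes.
DEFAULT_PK = PKParams.from_half_life(4.1)


@dataclass(frozen=True)
class DoseRegimen:
    """Bolus/infusion schedule. Times are minutes from drug start.

    ``bolus_fraction`` of ``total_dose`` is split equally across
    ``bolus_times_min``; the remainder is infused at constant rate over
    ``infusion_duration_min`` (0 = no infusion) starting at
    ``infusion_start_min``.
    """

    total_dose: float                       # mg/kg
    bolus_fraction: float = 1.0             # in [0, 1]
    bolus_times_min: tuple = (0.0,)
    infusion_duration_min: float = 0.0
    infusion_start_min: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.total_dose) or self.total_dose < 0:
            raise InvalidInputError("total_dose must be finite and >= 0")
        if not 0.0 <= self.bolus_fraction <= 1.0:
            raise InvalidInputError("bolus_fraction must lie in [0, 1]")
        times = tuple(float(t) for t in self.bolus_times_min)
        if any(t < 0 for t in times) or list(times) != sorted(times):
            raise InvalidInputError("bolus_times_min must be sorted and non-negative")
        object.__setattr__(self, "bolus_times_min", times)
        if self.infusion_duration_min < 0:
            raise InvalidInputError("infusion_duration_min must be >= 0")
        if self.infusion_amount > 0 and self.infusion_duration_min == 0:
            raise InvalidInputError(
                "non-bolus dose fraction requires infusion_duration_min > 0"
            )

    @property
    def n_boluses(self) -> int:
        return len(self.bolus_times_min)

    @property
    def bolus_amount_each(self) -> float:
        if self.n_boluses == 0:
            return 0.0
        return self.total_dose * self.bolus_fraction / self.n_boluses

    @property
    def infusion_amount(self) -> float:
        return self.total_dose * (1.0 - self.bolus_fraction)

    def with_total_dose(self, dose: float) -> "DoseRegimen":
        return replace(self, total_dose=float(dose))

    # -- presets matching the administration-method experiment -------------
    @classmethod
    def total_bolus(cls, dose: float) -> "DoseRegimen":
        """Whole dose as a single bolus at drug start."""
        return cls(total_dose=dose, bolus_fraction=1.0, bolus_times_min=(0.0,))

    @classmethod
    def double_bolus(cls, dose: float, gap_min: float = 60.0) -> "DoseRegimen":
        """Two half-dose boluses separated by ``gap_min`` minutes."""
        return cls(total_dose=dose, bolus_fraction=1.0,
                   bolus_times_min=(0.0, gap_min))

    @classmethod
    def half_bolus_infusion(cls, dose: float,
                            infusion_min: float = 60.0) -> "DoseRegimen":
        """Half-dose bolus plus the remaining half infused over ``infusion_min``."""
        return cls(total_dose=dose, bolus_fraction=0.5,
                   bolus_times_min=(0.0,), infusion_duration_min=infusion_min)

    @classmethod
    def ten_pct_bolus_infusion(cls, dose: float,
                               infusion_min: float = 60.0) -> "DoseRegimen":
        """10% bolus plus 90% infused over ``infusion_min`` (reference regimen)."""
        return cls(total_dose=dose, bolus_fraction=0.1,
                   bolus_times_min=(0.0,), infusion_duration_min=infusion_min)


REGIMEN_PRESETS = {
    "total_bolus": DoseRegimen.total_bolus,
    "double_bolus": DoseRegimen.double_bolus,
    "half_bolus_infusion": DoseRegimen.half_bolus_infusion,
    "ten_pct_bolus_infusion": DoseRegimen.ten_pct_bolus_infusion,
}


def _reference_dose_to_conc(pk: PKParams = DEFAULT_PK,
                            bolus_fraction: float = 0.1,
                            infusion_min: float = 60.0) -> float:
    """Steady-infusion plasma concentration per unit total dose under the
    reference 10%-bolus + 60-min-infusion regimen. Used to express the lysis
    EC50 (given in mg/kg) on the concentration scale."""
    return (1.0 - bolus_fraction) / (infusion_min * pk.elimination_rate)


@dataclass(frozen=True)
class FlowSimParams:
    """Calibration of the flow simulator.

    ``ec50`` is in mg/kg on the total-dose scale and is converted to
    concentration units via ``dose_to_conc`` (steady-state concentration per
    unit dose under the reference regimen). ``conc_crit`` is on the
    dose-normalized concentration scale.
    """

    baseline_flow: float = 0.8          # ml/min
    noise_cv: float = 0.05
    occlusion_start_min: float = 6.0
    occlusion_rate: float = 0.25        # burden gained per minute during decline
    emax: float = 1.0
    ec50: float = 4.0                   # mg/kg
    hill: float = 4.0
    k_lysis: float = 0.45               # per minute
    k_regrowth: float = 0.30            # per minute
    conc_crit: float = 0.30             # dose-normalized concentration
    dose_to_conc: float = field(default_factory=_reference_dose_to_conc)
    sample_dt_s: float = 1.0
    baseline_min: float = 5.0
    occlusion_wait_min: float = 10.0    # delay from complete occlusion to drug
    monitor_min: float = 122.0          # recording kept after drug start
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_flow", "noise_cv", "occlusion_start_min",
                     "occlusion_rate", "ec50", "k_lysis", "k_regrowth",
                     "conc_crit", "dose_to_conc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0")
        if not 0.0 <= self.emax <= 1.0:
            raise InvalidInputError("emax must lie in [0, 1]")
        if self.hill <= 0:
            raise InvalidInputError("hill must be > 0")
        if self.sample_dt_s <= 0:
            raise InvalidInputError("sample_dt_s must be > 0")
        if self.occlusion_rate <= 0:
            raise InvalidInputError("occlusion_rate must be > 0")


@dataclass
class ThrombusState:
    """Latent occlusive burden; 1 means fully occlusive."""

    burden: float = 0.0

    def clip(self) -> None:
        self.burden = min(1.0, max(0.0, self.burden))


# ---------------------------------------------------------------------------
# Pharmacokinetics
# ---------------------------------------------------------------------------

def pk_concentration(regimen: DoseRegimen, t, pk: PKParams = DEFAULT_PK):
    """Plasma concentration at time ``t`` minutes after drug start.

    Standard one-compartment superposition with volume normalized to 1: each
    bolus ``D`` at ``t0`` contributes ``D * exp(-k(t - t0))`` for ``t >= t0``;
    a zero-order infusion of amount ``A`` over duration ``T`` contributes
    ``A/(T k) * (1 - exp(-k t'))`` while running and decays exponentially
    afterwards. Accepts scalar or array ``t``; scalar in -> scalar out.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise InvalidInputError("t must be finite")
    if np.any(t_arr < 0):
        raise InvalidInputError("t must be >= 0")
    k = pk.elimination_rate
    conc = np.zeros_like(t_arr)
    amount = regimen.bolus_amount_each
    if amount > 0:
        for t0 in regimen.bolus_times_min:
            dt = t_arr - t0
            conc = conc + np.where(dt >= 0, amount * np.exp(-k * np.maximum(dt, 0.0)), 0.0)
    a_inf = regimen.infusion_amount
    if a_inf > 0:
        T = regimen.infusion_duration_min
        rate = a_inf / T
        tp = t_arr - regimen.infusion_start_min
        during = (rate / k) * (1.0 - np.exp(-k * np.clip(tp, 0.0, T)))
        tail = np.where(tp > T, np.exp(-k * np.maximum(tp - T, 0.0)), 1.0)
        conc = conc + np.where(tp >= 0, during * tail, 0.0)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(conc)
    return conc


# ---------------------------------------------------------------------------
# Flow-trace simulator
# ---------------------------------------------------------------------------

def lysis_drive(conc, params: FlowSimParams):
    """Hill lysis drive E(C) in [0, emax]."""
    c = np.asarray(conc, dtype=float)
    ec50_c = params.ec50 * params.dose_to_conc
    with np.errstate(divide="ignore", invalid="ignore"):
        ch = np.power(c, params.hill)
        e = params.emax * ch / (ch + ec50_c ** params.hill)
    return np.where(c > 0, e, 0.0)


def simulate_flow_trace(
    dose: float | None,
    regimen: DoseRegimen,
    params: FlowSimParams = FlowSimParams(),
    pk: PKParams = DEFAULT_PK,
    animal_id: str = "sim",
    seed: int | None = None,
) -> FlowTrace:
    """Simulate a full carotid-flow recording for one animal.

    Phases: stable baseline (``baseline_min``), FeCl3-driven linear decline of
    flow starting at ``occlusion_start_min`` until the burden reaches 1,
    a 10-minute confirmed-occlusion wait, then drug administration with the
    burden evolving by explicit Euler steps of the lysis/regrowth ODE.
    ``dose`` overrides ``regimen.total_dose`` when given. Identical seeds give
    bitwise-identical traces.
    """
    if dose is not None:
        regimen = regimen.with_total_dose(dose)
    if seed is None:
        seed = params.seed
    if not np.isfinite(regimen.total_dose):
        raise InvalidInputError("dose must be finite")

    dt_s = params.sample_dt_s
    dt_min = dt_s / 60.0
    t_occ_min = params.occlusion_start_min + 1.0 / params.occlusion_rate
    drug_start_min = t_occ_min + params.occlusion_wait_min
    total_min = drug_start_min + params.monitor_min
    n = int(round(total_min * 60.0 / dt_s)) + 1
    time_s = np.arange(n) * dt_s
    t_min = time_s / 60.0

    # pre-drug burden: linear ramp 0 -> 1 from occlusion_start
    burden = np.empty(n)
    drug_idx = int(np.searchsorted(t_min, drug_start_min))
    pre = np.clip((t_min[:drug_idx] - params.occlusion_start_min)
                  * params.occlusion_rate, 0.0, 1.0)
    burden[:drug_idx] = pre

    # post-drug: Euler integration driven by the PK concentration
    rel_min = t_min[drug_idx:] - drug_start_min
    conc = np.asarray(pk_concentration(regimen, rel_min, pk))
    drive = lysis_drive(conc, params)
    regrow_on = conc < params.conc_crit
    b = 1.0 if drug_idx > 0 else 0.0
    unstable = False
    post = np.empty(n - drug_idx)
    for i in range(post.size):
        post[i] = b
        db = (-params.k_lysis * drive[i] * b
              + (params.k_regrowth * b * (1.0 - b) if regrow_on[i] else 0.0))
        b = b + db * dt_min
        if b < -1e-6 or b > 1.0 + 1e-6:
            unstable = True
        b = min(1.0, max(0.0, b))
    burden[drug_idx:] = post
    if unstable:
        warnings.warn(
            "Euler step left burden outside [0,1] by more than 1e-6; "
            "sample_dt_s is too large for the configured rates",
            RuntimeWarning,
        )
    if not np.all(np.isfinite(burden)):
        raise SimulationError("non-finite burden encountered")

    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, params.noise_cv, size=n)
    flow = np.clip(params.baseline_flow * (1.0 - burden) * (1.0 + eps), 0.0, None)

    markers = {
        "recording_start": 0.0,
        "fecl3_on": params.baseline_min * 60.0,
        "fecl3_off": (params.baseline_min + 5.0) * 60.0,
        "occlusion_confirmed": t_occ_min * 60.0,
        "drug_start": drug_start_min * 60.0,
    }
    return FlowTrace(animal_id=animal_id, time_s=time_s, flow=flow,
                     markers=markers)


# ---------------------------------------------------------------------------
# Aggregometry simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggSimParams:
    """Impedance-aggregometry kinetics per agonist."""

    baseline_ohm: float = 0.5
    a_max_ohm: float = 16.0             # plateau amplitude above baseline
    k_agg: float = 0.02                 # per second rise rate
    agonist_time_s: float = 30.0
    addition_time_s: float = 300.0      # test-agent addition (disaggregation)
    duration_s: float = 900.0
    ic50_ug: float = 0.1                # inhibition midpoint
    hill_inh: float = 1.5
    disagg_rate_max: float = 0.05       # per second, saturating in dose
    disagg_d50_ug: float = 50.0
    disagg_rate: float | None = None    # explicit rate override (may be inf)
    noise_sd: float = 0.0
    sample_dt_s: float = 1.0


#: Plateau amplitudes for the two agonists used in the aggregation assay.
AGONIST_DEFAULTS = {
    "ADP": {"a_max_ohm": 16.0, "ic50_ug": 0.1, "addition_time_s": 300.0},
    "collagen": {"a_max_ohm": 22.0, "ic50_ug": 2.9, "addition_time_s": 400.0,
                 "k_agg": 0.01},
}


def agg_params_for(agonist: str, **overrides) -> AggSimParams:
    """AggSimParams preconfigured for an agonist label ('ADP' or 'collagen')."""
    base = dict(AGONIST_DEFAULTS.get(agonist, {}))
    base.update(overrides)
    return AggSimParams(**base)


def simulate_aggregometry(
    mode: str,
    agonist: str,
    dose_ug: float,
    params: AggSimParams | None = None,
    seed: int = 0,
) -> AggTrace:
    """Simulate an impedance aggregometry trace.

    ``mode="aggregation"``: agonist added at ``agonist_time_s`` with the test
    agent pre-incubated; impedance rises to a plateau scaled down by the Hill
    inhibition of ``dose_ug``. ``mode="disaggregation"``: an untreated
    aggregation runs to its maximum, then the test agent added at
    ``addition_time_s`` relaxes impedance back toward baseline at a
    dose-dependent rate (``disagg_rate`` may be set to ``inf`` for complete
    instantaneous restoration).
    """
    if dose_ug < 0:
        raise InvalidInputError("dose_ug must be >= 0")
    if params is None:
        params = agg_params_for(agonist)
    t = np.arange(0.0, params.duration_s + params.sample_dt_s / 2,
                  params.sample_dt_s)
    rng = np.random.default_rng(seed)
    base = params.baseline_ohm
    rise = np.where(
        t >= params.agonist_time_s,
        1.0 - np.exp(-params.k_agg * np.maximum(t - params.agonist_time_s, 0.0)),
        0.0,
    )

    if mode == "aggregation":
        d = dose_ug ** params.hill_inh
        inhibition = d / (d + params.ic50_ug ** params.hill_inh) if dose_ug > 0 else 0.0
        imp = base + params.a_max_ohm * rise * (1.0 - inhibition)
        addition = None
    elif mode == "disaggregation":
        imp = base + params.a_max_ohm * rise
        t_add = params.addition_time_s
        if params.disagg_rate is not None:
            k_dis = params.disagg_rate
        else:
            k_dis = params.disagg_rate_max * dose_ug / (dose_ug + params.disagg_d50_ug) \
                if dose_ug > 0 else 0.0
        after = t > t_add
        level_at_add = base + params.a_max_ohm * (
            1.0 - math.exp(-params.k_agg * max(t_add - params.agonist_time_s, 0.0))
        )
        if np.isinf(k_dis):
            decay = np.zeros(int(np.sum(after)))
        else:
            decay = np.exp(-k_dis * (t[after] - t_add))
        imp = np.where(after, 0.0, imp)
        imp[after] = base + (level_at_add - base) * decay
        addition = t_add
    else:
        raise InvalidInputError(f"unknown mode {mode!r}")

    if params.noise_sd > 0:
        imp = imp + rng.normal(0.0, params.noise_sd, size=t.size)
    return AggTrace(
        time_s=t,
        impedance_ohm=imp,
        agonist=agonist,
        treatment_dose_ug=float(dose_ug),
        addition_time_s=addition,
        agonist_time_s=params.agonist_time_s,
    )


# ---------------------------------------------------------------------------
# Titration and decay simulators
# ---------------------------------------------------------------------------

def simulate_titration(
    kd: float,
    a_max: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """One-site Langmuir titration: A([L]) = a_max [L]/(Kd + [L]) + noise."""
    if not (np.isfinite(kd) and kd > 0):
        raise InvalidInputError("kd must be finite and > 0")
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0 or np.any(conc <= 0):
        raise InvalidInputError("concentrations must be positive and non-empty")
    conc = np.sort(conc)
    rng = np.random.default_rng(seed)
    absorbance = a_max * conc / (kd + conc)
    if noise_sd > 0:
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=conc.size)
    return TitrationCurve(ligand_conc=conc, absorbance=absorbance)


def simulate_decay(
    half_life_min: float,
    times: Sequence[float] | None = None,
    f0: float = 100.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> DecayCurve:
    """Mono-exponential decay F(t) = F0 exp(-ln2 t / t_half) (1 + eps).

    The default sampling grid is the serum-collection schedule
    0, 5, 10, 20, 40, 80 minutes.
    """
    if not (np.isfinite(half_life_min) and half_life_min > 0):
        raise InvalidInputError("half_life_min must be finite and > 0")
    if times is None:
        times = DEFAULT_DECAY_GRID_MIN
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise InvalidInputError("times must be non-empty")
    rng = np.random.default_rng(seed)
    f = f0 * np.exp(-LN2 * t / half_life_min)
    if noise_cv > 0:
        f = f * (1.0 + rng.normal(0.0, noise_cv, size=t.size))
    return DecayCurve(time_min=t, fluorescence=f)


# ---------------------------------------------------------------------------
# Fixture materialization
# ---------------------------------------------------------------------------

DEFAULT_STUDY_DOSES = (0.0, 1.0, 1.75, 2.5, 3.75, 5.0, 10.0)


def materialize_fixtures(
    outdir: str | Path,
    seed: int = 0,
    doses: Sequence[float] = DEFAULT_STUDY_DOSES,
    n_per_group: int = 5,
    params: FlowSimParams = FlowSimParams(),
    pk: PKParams = DEFAULT_PK,
) -> dict:
    """Write a full synthetic dose-response study to ``outdir``.

    One ``time_s,flow`` CSV plus markers sidecar per animal, and a
    ``manifest.json`` recording the seed, parameters, and regimen of every
    animal. Returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "pk": asdict(pk),
        "sim_params": asdict(params),
        "animals": [],
    }
    for dose in doses:
        regimen = DoseRegimen.ten_pct_bolus_infusion(dose) if dose > 0 \
            else DoseRegimen(total_dose=0.0)
        for i in range(n_per_group):
            animal_seed = seed + hash_seed(f"dose={dose}", i)
            animal_id = f"dose{dose:g}_animal{i}"
            trace = simulate_flow_trace(None, regimen, params, pk,
                                        animal_id=animal_id, seed=animal_seed)
            csv_path = outdir / f"{animal_id}.csv"
            write_flow_trace(trace, csv_path)
            manifest["animals"].append({
                "animal_id": animal_id,
                "dose": dose,
                "seed": animal_seed,
                "regimen": asdict(regimen),
                "trace": csv_path.name,
                "markers": csv_path.name + ".markers.json",
            })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def hash_seed(group: str, index: int) -> int:
    """Stable per-animal seed offset from (group label, index)."""
    import zlib

    return zlib.crc32(f"{group}/{index}".encode()) & 0x7FFFFFFF
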