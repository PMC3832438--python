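"""Binding and pharmacokinetic curve fitting.

Two estimators:

* ``fit_kd_linearization`` — estimates an equilibrium dissociation constant
  from an ELISA titration by the double-linearization y = 1/(1 - i) against
  x = [L]/i, where i is relative saturation (absorbance normalized to its
  saturation value). For exact one-site Langmuir binding the relationship is
  the identity y = x/Kd, so the slope of an ordinary least-squares line is
  1/Kd and the intercept should vanish; the intercept is fitted freely and
  reported so model misfit is visible.

* ``fit_half_life`` — log-linear least squares on a fluorescence decay,
  k_el = -slope of ln(F) vs t, half-life = ln2 / k_el.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InvalidInputError, TraceParseError

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "DecayCurve",
    "PKFit",
    "read_titration",
    "read_decay",
    "relative_saturation",
    "fit_kd_linearization",
    "fit_half_life",
]


@dataclass
class TitrationCurve:
    """Ligand concentrations with measured absorbances.

    ``i`` (relative saturation, in (0,1)) and ``a_max`` are filled by
    :func:`relative_saturation`; points whose saturation falls outside (0,1)
    are excluded from fitting and counted in ``n_excluded``.
    """

    ligand_conc: np.ndarray     # molar, ascending
    absorbance: np.ndarray      # AU
    a_max: float | None = None
    i: np.ndarray | None = None          # retained points only
    conc_used: np.ndarray | None = None  # concentrations of retained points
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.ligand_conc.size == 0:
            raise TraceParseError("empty titration curve")
        if self.ligand_conc.shape != self.absorbance.shape:
            raise TraceParseError("concentration and absorbance lengths differ")
        if np.any(self.ligand_conc <= 0):
            raise InvalidInputError("ligand concentrations must be > 0")
        if np.any(np.diff(self.ligand_conc) < 0):
            raise InvalidInputError("ligand concentrations must be ascending")


@dataclass
class BindingFit:
    """Result of the Kd linearization fit."""

    kd: float           # molar = 1/slope
    slope: float        # per molar
    intercept: float
    r_squared: float
    n_points_used: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class DecayCurve:
    """Fluorescence decay samples (time in minutes)."""

    time_min: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_min.shape != self.fluorescence.shape:
            raise TraceParseError("time and fluorescence lengths differ")
        if self.time_min.size == 0:
            raise TraceParseError("empty decay curve")


@dataclass
class PKFit:
    """Log-linear elimination fit."""

    k_el: float             # per minute
    half_life_min: float    # = ln2 / k_el
    r_squared: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_titration(path: str | Path) -> TitrationCurve:
    """Read a ``conc_M,absorbance`` CSV."""
    df = _read_csv(path, ("conc_M", "absorbance"))
    order = np.argsort(df["conc_M"].to_numpy())
    return TitrationCurve(
        ligand_conc=df["conc_M"].to_numpy(dtype=float)[order],
        absorbance=df["absorbance"].to_numpy(dtype=float)[order],
    )


def read_decay(path: str | Path) -> DecayCurve:
    """Read a ``time_min,fluorescence`` CSV."""
    df = _read_csv(path, ("time_min", "fluorescence"))
    return DecayCurve(
        time_min=df["time_min"].to_numpy(dtype=float),
        fluorescence=df["fluorescence"].to_numpy(dtype=float),
    )


def _read_csv(path: str | Path, columns: tuple) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TraceParseError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"empty file: {path}") from exc
    for col in columns:
        if col not in df.columns:
            raise TraceParseError(f"missing column {col!r} in {path}")
    return df


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def relative_saturation(
    curve: TitrationCurve,
    a_max: float | None = None,
    a_max_mode: str = "plateau",
) -> TitrationCurve:
    """Fill ``curve.i`` with relative saturation values.

    ``a_max`` is either supplied explicitly (``a_max_mode="value"`` or a
    non-None ``a_max``) or estimated as the mean absorbance at the two highest
    concentrations (``"plateau"``, default). Points with i outside (0, 1) are
    excluded — i = 1 is singular in the 1/(1 - i) transform — and their count
    is logged.
    """
    if np.any(curve.absorbance <= 0) and a_max is None:
        logger.warning("non-positive absorbances present; they will be excluded")
    if a_max is None:
        if a_max_mode == "plateau":
            a_max = float(np.mean(curve.absorbance[-2:])) if curve.absorbance.size >= 2 \
                else float(curve.absorbance[-1])
        else:
            raise InvalidInputError(
                f"a_max_mode {a_max_mode!r} requires an explicit a_max"
            )
    if not np.isfinite(a_max) or a_max <= 0:
        raise FitError("estimated a_max is not positive")
    i = curve.absorbance / a_max
    keep = (i > 0.0) & (i < 1.0)
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("excluded %d titration points with i outside (0,1)", n_excluded)
    if not np.any(keep):
        raise FitError("a_max estimate forces every saturation value out of (0,1)")
    curve.a_max = a_max
    curve.i = i[keep]
    curve.conc_used = curve.ligand_conc[keep]
    curve.n_excluded = n_excluded
    return curve


#: Default saturation working range for the linearization fit. Both
#: transformed coordinates amplify measurement noise without bound as i
#: approaches 0 (x = [L]/i) or 1 (y = 1/(1-i)), so only the informative
#: mid-range of the curve enters the regression by default. Pass
#: ``fit_range=(0, 1)`` to use every point with 0 < i < 1.
DEFAULT_FIT_RANGE = (0.15, 0.85)


def fit_kd_linearization(
    curve: TitrationCurve,
    a_max: float | None = None,
    a_max_mode: str = "plateau",
    fit_range: tuple = DEFAULT_FIT_RANGE,
) -> BindingFit:
    """Estimate Kd as the reciprocal slope of 1/(1 - i) vs [L]/i.

    Runs :func:`relative_saturation` first if the curve has no saturation
    values. Points with saturation outside ``fit_range`` are left out of the
    regression (see :data:`DEFAULT_FIT_RANGE`). Requires at least 3 usable
    points; a non-positive slope is a fit failure (no binding signal).
    """
    if curve.i is None:
        curve = relative_saturation(curve, a_max=a_max, a_max_mode=a_max_mode)
    lo, hi = fit_range
    sel = (curve.i > lo) & (curve.i < hi)
    if not np.any(sel):
        # degenerate curve entirely outside the working range: fall back to
        # every admissible point rather than refusing outright
        sel = np.ones_like(curve.i, dtype=bool)
    i = curve.i[sel]
    conc = curve.conc_used[sel]
    if i.size < 3:
        raise FitError(f"need >= 3 usable points, got {i.size}")
    x = conc / i
    y = 1.0 / (1.0 - i)
    res = stats.linregress(x, y)
    if not np.isfinite(res.slope) or res.slope <= 0:
        raise FitError(f"non-positive slope {res.slope}; cannot form Kd")
    return BindingFit(
        kd=float(1.0 / res.slope),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        n_points_used=int(i.size),
    )


def fit_half_life(decay: DecayCurve) -> PKFit:
    """Log-linear half-life fit: least squares of ln(F) on t.

    k_el is the negated slope; half-life = ln2 / k_el. Non-positive
    fluorescence is invalid; a non-negative slope means no decay.
    """
    t = decay.time_min
    f = decay.fluorescence
    if t.size < 2:
        raise FitError(f"need >= 2 points, got {t.size}")
    if np.any(f <= 0):
        raise InvalidInputError("fluorescence must be positive for log fitting")
    res = stats.linregress(t, np.log(f))
    if res.slope >= 0:
        raise FitError("non-negative slope: signal does not decay")
    k_el = -float(res.slope)
    return PKFit(
        k_el=k_el,
        half_life_min=LN2 / k_el,
        r_squared=float(res.rvalue ** 2),
    )
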