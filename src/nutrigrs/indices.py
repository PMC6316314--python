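"""Derived metabolic indices from fasting and postprandial measurements.

Postprandial curves are timed glucose (mg/dL) or insulin measurements
taken over 0-120 min after a standardized test meal. Areas under the
curve use the trapezoidal rule, either on the raw values (``total``) or
after subtracting the fasting (t=0) value from every point
(``incremental``; negative increments are retained).

Fasting-state indices follow the homeostasis-model conventions:
HOMA-IR = FPG * FSI / 405 and HOMA-beta = 360 * FSI / (FPG - 63), with
glucose in mg/dL and insulin in the study's printed insulin unit, which
is treated as one opaque consistent unit throughout. Early-phase
secretion is the insulinogenic index (0-30 min insulin change over
glucose change) and the oral disposition index multiplies it by the
reciprocal fasting insulin.

Undefined values (a formula pole, a flat glucose excursion, division by
a zero area) are carried as NaN with a logged warning rather than
raised, so cohort-level batch computation always yields one row per
subject-visit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

GLUCOSE = "glucose"
INSULIN = "insulin"

#: Columns of a batch index panel, in output order.
INDEX_COLUMNS = [
    "auc_glu_0_30",
    "auc_glu_30_120",
    "auc_glu_0_120",
    "auc_ins_0_30",
    "auc_ins_30_120",
    "auc_ins_0_120",
    "homa_ir",
    "homa_beta",
    "igi",
    "inc_auc_ins_glu",
    "oral_di",
    "reciprocal_fsi",
]


@dataclass(frozen=True)
class SamplingCurve:
    """Timed measurements of one analyte for one meal test.

    ``times`` are minutes from meal start, strictly increasing and
    starting at 0 (the fasting sample); ``values`` are nonnegative and
    the same length.
    """

    analyte: str
    times: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape or t.size < 2:
            raise ValueError("curve needs matching 1-d times/values of length >= 2")
        if t[0] != 0.0:
            raise ValueError(f"curve must start at t=0 (got t[0]={t[0]})")
        if np.any(np.diff(t) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("curve values must be finite and nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def value_at(self, t: float) -> float:
        idx = np.flatnonzero(self.times == t)
        if idx.size == 0:
            raise GridError(f"time {t} min is not on the sampling grid {self.times}")
        return float(self.values[idx[0]])


class GridError(ValueError):
    """A requested window endpoint is not a sampled timepoint."""


def trapezoid_auc(
    curve: SamplingCurve, t_start: float, t_end: float, mode: str = "total"
) -> float:
    """Trapezoidal area under a sampling curve over [t_start, t_end].

    Both endpoints must be actual grid points (no extrapolation or
    silent interpolation of window edges). ``incremental`` subtracts the
    t=0 value from every point first, keeping negative increments, so
    window additivity holds exactly in both modes.
    """
    if mode not in ("total", "incremental"):
        raise ValueError(f"mode must be 'total' or 'incremental', got {mode!r}")
    if not t_start < t_end:
        raise ValueError(f"need t_start < t_end, got [{t_start}, {t_end}]")
    t, v = curve.times, curve.values
    for endpoint in (t_start, t_end):
        if not np.any(t == endpoint):
            raise GridError(
                f"window endpoint {endpoint} min is not on the sampling grid "
                f"{t.tolist()}"
            )
    if mode == "incremental":
        v = v - v[0]
    mask = (t >= t_start) & (t <= t_end)
    return float(np.trapezoid(v[mask], t[mask]))


def homa_ir(fpg: float, fsi: float) -> float:
    """Insulin-resistance index: FPG [mg/dL] x FSI / 405."""
    if fpg < 0 or fsi < 0:
        raise ValueError(f"HOMA-IR needs nonnegative inputs (fpg={fpg}, fsi={fsi})")
    return fpg * fsi / 405.0


def homa_beta(fpg: float, fsi: float) -> float:
    """Beta-cell-function index: 360 x FSI / (FPG - 63).

    The formula has a pole at FPG = 63 mg/dL; at or below it the index
    is undefined and returned as NaN with a warning.
    """
    if fpg < 0 or fsi < 0:
        raise ValueError(f"HOMA-beta needs nonnegative inputs (fpg={fpg}, fsi={fsi})")
    if fpg <= 63.0:
        log.warning("HOMA-beta undefined at fpg=%.4g <= 63 mg/dL", fpg)
        return float("nan")
    return 360.0 * fsi / (fpg - 63.0)


def insulinogenic_index(
    glucose_curve: SamplingCurve, insulin_curve: SamplingCurve
) -> float:
    """Early insulin secretion: (I30 - I0) / (G30 - G0), sign preserved.

    Undefined (NaN, with a warning) when the 0-30 min glucose change is
    zero.
    """
    dg = glucose_curve.value_at(30.0) - glucose_curve.value_at(0.0)
    di = insulin_curve.value_at(30.0) - insulin_curve.value_at(0.0)
    if dg == 0.0:
        log.warning("insulinogenic index undefined: zero 0-30 min glucose change")
        return float("nan")
    return di / dg


def inc_auc_ratio(
    glucose_curve: SamplingCurve, insulin_curve: SamplingCurve
) -> float:
    """Incremental insulin AUC over incremental glucose AUC, 0-120 min."""
    inc_glu = trapezoid_auc(glucose_curve, 0.0, 120.0, mode="incremental")
    inc_ins = trapezoid_auc(insulin_curve, 0.0, 120.0, mode="incremental")
    if inc_glu == 0.0:
        log.warning("incremental AUC ratio undefined: zero glucose incremental area")
        return float("nan")
    return inc_ins / inc_glu


def oral_disposition_index(igi: float, fsi: float) -> float:
    """Beta-cell function adjusted for sensitivity: IGI x 1/FSI.

    Propagates an undefined IGI; undefined when FSI = 0.
    """
    if np.isnan(igi):
        return float("nan")
    if fsi == 0.0:
        log.warning("oral disposition index undefined: fasting insulin is zero")
        return float("nan")
    return igi / fsi


def bmi(weight_kg: float, height_m: float) -> float:
    """Body mass index: weight [kg] / height^2 [m^2]."""
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return weight_kg / height_m**2


def paee(met_minutes: float, weight_kg: float) -> float:
    """Physical-activity energy expenditure [kcal/day].

    MET-scored daily activity [MET.min/day] x 3.5 [mL O2/kg/min]
    x 0.005 [kcal/mL O2] x body weight [kg].
    """
    if met_minutes < 0 or weight_kg < 0:
        raise ValueError("PAEE inputs must be nonnegative")
    return met_minutes * 3.5 * 0.005 * weight_kg


def compute_index_panel(
    glucose_curve: SamplingCurve,
    insulin_curve: SamplingCurve,
    fpg: float | None = None,
    fsi: float | None = None,
    auc_mode: str = "incremental",
) -> dict[str, float]:
    """All derived indices for one subject-visit.

    When ``fpg``/``fsi`` are omitted they default to the t=0 curve
    values. AUC columns use ``auc_mode``; the incremental insulin/glucose
    ratio is always computed on incremental areas by definition.
    """
    if fpg is None:
        fpg = glucose_curve.value_at(0.0)
    if fsi is None:
        fsi = insulin_curve.value_at(0.0)
    igi = insulinogenic_index(glucose_curve, insulin_curve)
    panel = {
        "auc_glu_0_30": trapezoid_auc(glucose_curve, 0, 30, auc_mode),
        "auc_glu_30_120": trapezoid_auc(glucose_curve, 30, 120, auc_mode),
        "auc_glu_0_120": trapezoid_auc(glucose_curve, 0, 120, auc_mode),
        "auc_ins_0_30": trapezoid_auc(insulin_curve, 0, 30, auc_mode),
        "auc_ins_30_120": trapezoid_auc(insulin_curve, 30, 120, auc_mode),
        "auc_ins_0_120": trapezoid_auc(insulin_curve, 0, 120, auc_mode),
        "homa_ir": homa_ir(fpg, fsi),
        "homa_beta": homa_beta(fpg, fsi),
        "igi": igi,
        "inc_auc_ins_glu": inc_auc_ratio(glucose_curve, insulin_curve),
        "oral_di": oral_disposition_index(igi, fsi),
        "reciprocal_fsi": 1.0 / fsi if fsi > 0 else float("nan"),
    }
    return panel


def curves_from_long(curves: pd.DataFrame) -> dict[tuple[str, str, str], SamplingCurve]:
    """Build SamplingCurve objects from a long-format curve table.

    Expects columns subject_id, visit, analyte, time_min, value; returns
    a map keyed by (subject_id, visit, analyte).
    """
    required = {"subject_id", "visit", "analyte", "time_min", "value"}
    if not required.issubset(curves.columns):
        raise ValueError(f"curve table needs columns {sorted(required)}")
    out: dict[tuple[str, str, str], SamplingCurve] = {}
    for (sid, visit, analyte), sub in curves.groupby(
        ["subject_id", "visit", "analyte"], sort=True
    ):
        sub = sub.sort_values("time_min")
        out[(str(sid), str(visit), str(analyte))] = SamplingCurve(
            analyte=str(analyte),
            times=sub["time_min"].to_numpy(dtype=float),
            values=sub["value"].to_numpy(dtype=float),
        )
    return out


def compute_indices(
    curves: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    auc_mode: str = "incremental",
) -> pd.DataFrame:
    """Batch index computation: one output row per subject-visit.

    ``clinical`` may supply fasting FPG/FSI columns; otherwise the t=0
    curve values stand in. Rows whose indices are undefined carry NaN
    in the affected columns only.
    """
    curve_map = curves_from_long(curves)
    fasting: dict[tuple[str, str], tuple[float, float]] = {}
    if clinical is not None:
        for r in clinical.itertuples():
            fasting[(str(r.subject_id), str(r.visit))] = (
                float(r.fpg),
                float(r.fsi),
            )
    keys = sorted({(sid, visit) for (sid, visit, _a) in curve_map})
    rows = []
    for sid, visit in keys:
        glu = curve_map.get((sid, visit, GLUCOSE))
        ins = curve_map.get((sid, visit, INSULIN))
        if glu is None or ins is None:
            log.warning("subject %s visit %s: missing %s curve; skipped",
                        sid, visit, GLUCOSE if glu is None else INSULIN)
            continue
        fpg, fsi = fasting.get((sid, visit), (None, None))
        if fpg is not None and abs(fpg - glu.value_at(0.0)) > 5.0:
            log.warning(
                "subject %s visit %s: fasting glucose %.4g differs from curve "
                "t=0 value %.4g", sid, visit, fpg, glu.value_at(0.0),
            )
        row = {"subject_id": sid, "visit": visit}
        row.update(compute_index_panel(glu, ins, fpg, fsi, auc_mode=auc_mode))
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "visit"] + INDEX_COLUMNS)
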