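"""Scripted analyses over a generated virtual-subject database.

Three studies mirror the standard uses of an in silico pulse-wave cohort:

1. *Pulse pressure amplification with age* — decompose the
   brachial-to-aortic PP ratio into an early systolic amplification
   component (using aortic P1) and a late systolic augmentation component
   (using aortic P2), and follow the three with age.
2. *Peripheral assessment of aortic stiffness* — correlate the digital-PPG
   indexes (RI, SI, AGI_mod) with the reference foot-to-foot aortic PWV,
   and attribute index variation to cardiovascular properties through
   one-at-a-time relative sensitivity indexes.
3. *Cardiac output monitoring* — implement two pulse-contour CO estimators
   on the radial pressure wave (RMS-based and PP-based), calibrate them on
   the age-matched baseline subject, and measure mean absolute percentage
   errors under isolated CO (HR or SV) and MAP changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import find_fiducials
from .errors import DegenerateSignalError, ParameterError
from .inflow import Waveform

__all__ = [
    "SensitivityResult",
    "COAssessment",
    "ppamp_decomposition",
    "sensitivity_index",
    "correlate_index_with_pwv",
    "calibrate_co",
    "co_estimate",
    "co_assess",
]


@dataclass
class SensitivityResult:
    index_name: str
    parameter_name: str
    age: float
    I: float  # % change of the index per +1 SD of the parameter


@dataclass
class COAssessment:
    algorithm: str
    calibration: dict  # age -> k
    estimates: pd.DataFrame  # rows: subject, columns: CO_ref, CO_est, group
    mape_overall: float = math.nan
    mape_by_group: dict = field(default_factory=dict)


def ppamp_decomposition(aortic: Waveform, brachial: Waveform) -> dict:
    """Split PP amplification into early- and late-systolic components.

    PP_amp = PP_b/PP_a; PP_amp_P1 = PP_b/(P1_a - DBP_a) quantifies the
    amplification of the early systolic portion; PP_amp_P2 =
    PP_b/(P2_a - DBP_a) that of the late systolic (augmented) portion.
    Missing P1/P2 on the aortic wave yield NaN components.
    """
    # work in the wave's raw units, consistent with the fiducial amplitudes
    pa = float(np.max(aortic.y) - np.min(aortic.y))
    pb = float(np.max(brachial.y) - np.min(brachial.y))
    if pa <= 0:
        raise DegenerateSignalError("aortic pulse pressure is zero")
    out = {"PP_amp": pb / pa, "PP_amp_P1": math.nan, "PP_amp_P2": math.nan}
    fid = find_fiducials(aortic, "pressure")
    dbp = float(np.min(aortic.y))
    for name, key in (("p1", "PP_amp_P1"), ("p2", "PP_amp_P2")):
        if fid.has(name):
            rise = fid.amp(name) - dbp
            if rise > 0:
                out[key] = pb / rise
    return out


def _single_offset_row(db: pd.DataFrame, age: float, parameter: str,
                       offset: int) -> pd.Series:
    mask = (db["age"] == age)
    for p in ("HR", "SV", "LVET", "diameter", "PWV", "MAP"):
        want = offset if p == parameter else 0
        mask &= (db[f"off_{p}"] == want)
    rows = db[mask]
    if len(rows) != 1:
        raise ParameterError(
            f"database lacks the single-parameter subject (age={age}, "
            f"{parameter}={offset:+d}); found {len(rows)} rows")
    return rows.iloc[0]


def sensitivity_index(db: pd.DataFrame, parameter: str, index_name: str,
                      age: float) -> SensitivityResult:
    """Relative sensitivity: % change of an index when one input parameter
    moves +1 SD from the age baseline, all others held at baseline."""
    base = _single_offset_row(db, age, parameter, 0)
    plus = _single_offset_row(db, age, parameter, +1)
    b = base[index_name]
    if b == 0 or not np.isfinite(b):
        raise ParameterError(f"baseline {index_name} at age {age} is "
                             f"{b}; sensitivity undefined")
    i_val = 100.0 * (plus[index_name] - b) / b
    return SensitivityResult(index_name=index_name, parameter_name=parameter,
                             age=age, I=float(i_val))


def correlate_index_with_pwv(db: pd.DataFrame, index_name: str,
                             subset: str | float = "all",
                             pwv_column: str = "PWV_aortic",
                             plausible_only: bool = True) -> float:
    """Coefficient of determination (R^2, squared Pearson r) between a PW
    index and the reference foot-to-foot aortic PWV.

    ``subset`` is "all" or a single age.  Only physiologically plausible
    subjects enter by default.  Undefined (NaN) index values are dropped;
    fewer than 3 remaining subjects or zero variance raise an error.
    """
    rows = db
    if plausible_only and "plausible" in db.columns:
        rows = rows[rows["plausible"]]
    if subset != "all":
        rows = rows[rows["age"] == subset]
    x = rows[pwv_column].to_numpy(dtype=float)
    y = rows[index_name].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ParameterError(f"need >= 3 subjects with defined {index_name}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ParameterError("zero variance; R^2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# Cardiac output estimation (case study 3)
# ---------------------------------------------------------------------------

CO_ALGORITHMS = ("RMS", "PP")


def _co_feature(radial_p: Waveform, algorithm: str,
                mean_subtracted: bool = True) -> float:
    """The raw waveform feature each algorithm assumes proportional to CO."""
    y = radial_p.y
    if algorithm == "RMS":
        yy = y - np.mean(y) if mean_subtracted else y
        return float(np.sqrt(np.mean(yy**2)))
    if algorithm == "PP":
        sbp, dbp = float(np.max(y)), float(np.min(y))
        T = radial_p.duration
        return (sbp - dbp) / (T * (sbp + dbp))
    raise ParameterError(f"unknown CO algorithm {algorithm!r}")


def calibrate_co(radial_p: Waveform, co_reference: float, algorithm: str,
                 mean_subtracted: bool = True) -> float:
    """Calibration constant k such that k * feature = reference CO [l/min]."""
    feat = _co_feature(radial_p, algorithm, mean_subtracted)
    if feat <= 0:
        raise DegenerateSignalError("degenerate radial wave; cannot calibrate")
    return co_reference / feat


def co_estimate(radial_p: Waveform, algorithm: str, k: float | None,
                mean_subtracted: bool = True) -> float:
    """Estimate CO [l/min] from one radial pressure cycle.

    RMS algorithm: CO = k * RMS(P - mean(P)) (pulsatile RMS; a raw-RMS
    variant via ``mean_subtracted=False``).  PP algorithm: CO =
    k * PP / (T * (SBP + DBP)), the pulse pressure over an approximation of
    arterial compliance times cycle duration.  ``k`` must come from
    :func:`calibrate_co` on the age-matched baseline subject.
    """
    if k is None:
        raise ParameterError("uncalibrated CO estimator: calibrate first")
    return k * _co_feature(radial_p, algorithm, mean_subtracted)


def co_assess(records: list[dict], algorithm: str,
              mean_subtracted: bool = True) -> COAssessment:
    """Assess a CO algorithm over single-parameter CO/MAP variations.

    ``records`` holds one dict per simulated subject with keys:
    ``age``, ``group`` ("baseline", "CO" for HR/SV offsets, "MAP"),
    ``radial`` (radial pressure Waveform), ``co_ref`` (prescribed HR*SV
    [l/min]).  The estimator is calibrated on each age's baseline record
    and evaluated on that age's varied records; MAPE is reported overall
    and per subgroup.  Empty subgroups are omitted.
    """
    cal = {}
    for rec in records:
        if rec["group"] == "baseline":
            cal[rec["age"]] = calibrate_co(rec["radial"], rec["co_ref"],
                                           algorithm, mean_subtracted)
    rows = []
    for rec in records:
        if rec["group"] == "baseline":
            continue
        age = rec["age"]
        if age not in cal:
            raise ParameterError(f"no baseline calibration for age {age}")
        est = co_estimate(rec["radial"], algorithm, cal[age], mean_subtracted)
        rows.append({"age": age, "group": rec["group"],
                     "CO_ref": rec["co_ref"], "CO_est": est,
                     "ape": 100.0 * abs(est - rec["co_ref"]) / rec["co_ref"]})
    df = pd.DataFrame(rows)
    out = COAssessment(algorithm=algorithm, calibration=cal, estimates=df)
    if len(df):
        out.mape_overall = float(df["ape"].mean())
        out.mape_by_group = {g: float(sub["ape"].mean())
                             for g, sub in df.groupby("group")}
    return out
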