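"""Pulse wave analysis: fiducial points and clinical indexes.

Operates on single clean cycles (simulated signals); no beat segmentation
or artifact handling.  Fiducial detection follows the standard
derivative-based approach: points are located on the wave and on its
smoothed first and second derivatives (Savitzky-Golay local-polynomial
differentiation, window scaled to the sampling rate).

Pressure-wave fiducials: foot, point of maximal dP/dt, early systolic
shoulder P1, late systolic shoulder/peak P2, systolic peak, dicrotic notch,
diastolic peak.  P1 marks the arrival of the reflected wave and P2 its
peak; their difference is the augmentation pressure.  On A-type (elderly)
waves P2 is the systolic peak and P1 a rising-edge shoulder; on C-type
(young) waves P1 is the early systolic peak and P2 a falling-edge shoulder.

PPG fiducials add the a-e waves of the second derivative, used by the
modified aging index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from . import units
from .errors import DegenerateSignalError, DomainError, ParameterError
from .inflow import Waveform, measure_inflow_features

__all__ = [
    "FiducialSet",
    "find_fiducials",
    "pressure_stats",
    "pp_amplification",
    "augmentation_indexes",
    "ppg_stiffness_indexes",
    "foot_to_foot_ptt",
    "pwv",
    "flow_indexes",
    "index_report",
]

#: Savitzky-Golay differentiation window [samples] at 500 Hz (scaled to fs)
SG_WINDOW_500 = 9
SG_POLY = 3

DEFAULT_HEIGHT = 1.75  # m; the network has no subject height


@dataclass
class FiducialSet:
    """Times [s] and amplitudes of detected fiducial points.

    ``points`` maps names to (time, amplitude); absent points are missing
    keys, never fabricated.  For PPG waves the a-e second-derivative wave
    amplitudes are the values of d2PPG/dt2 at those times.
    """

    kind: str
    points: dict = field(default_factory=dict)

    def has(self, name: str) -> bool:
        return name in self.points

    def time(self, name: str) -> float:
        return self.points[name][0]

    def amp(self, name: str) -> float:
        return self.points[name][1]


def _derivatives(y: np.ndarray, fs: float, scale: float = 1.0):
    win = max(5, int(round(scale * SG_WINDOW_500 * fs / 500.0)) | 1)
    win = min(win, y.size - (y.size + 1) % 2)
    d1 = savgol_filter(y, win, SG_POLY, deriv=1, delta=1.0 / fs, mode="wrap")
    d2 = savgol_filter(y, win, SG_POLY, deriv=2, delta=1.0 / fs, mode="wrap")
    return d1, d2


def _local_maxima(y, lo, hi):
    idx = [i for i in range(max(lo, 1), min(hi, y.size - 1))
           if y[i - 1] < y[i] >= y[i + 1]]
    return idx


def _local_minima(y, lo, hi):
    idx = [i for i in range(max(lo, 1), min(hi, y.size - 1))
           if y[i - 1] > y[i] <= y[i + 1]]
    return idx


def _foot_and_upstroke(t, y, d1, d2=None):
    """Foot by intersecting tangents: the crossing of the horizontal line at
    the diastolic minimum with the tangent at the steepest point of the
    *initial* upstroke.

    The tangent point is the maximum of dy/dt within a short window after
    the upstroke onset (the maximum of the second derivative in the
    low-amplitude region).  Anchoring the window at the onset keeps the
    construction valid for stiff-subject central waves, whose slope keeps
    increasing through systole as reflections superpose; a global
    max-slope tangent would land mid-rise and bias the foot late.  The
    window wraps circularly, so a foot just before the cycle boundary is
    handled.  Returns (t_foot, tangent index, diastolic minimum); t_foot
    may be negative when the onset wraps."""
    n = y.size
    ymin = float(np.min(y))
    rng = float(np.max(y)) - ymin
    if d2 is None:
        im = int(np.argmax(d1))
    else:
        # onset corner: the curvature maximum in the low-amplitude region
        # that is preceded by a stretch of diastolic (low) pressure -- this
        # rejects the dip between double systolic peaks, which sits low but
        # directly follows a peak
        fs = 1.0 / (t[1] - t[0])
        wprev = max(3, int(round(0.06 * fs)))
        prev_max = np.maximum.reduce([np.roll(y, k) for k in range(1, wprev + 1)])
        low = np.nonzero((y < ymin + 0.3 * rng)
                         & (prev_max < ymin + 0.35 * rng))[0]
        if low.size == 0:
            low = np.nonzero(y < ymin + 0.3 * rng)[0]
        corner = int(low[int(np.argmax(d2[low]))])
        win = max(3, int(round(0.04 * fs)))
        idxs = (corner + np.arange(win)) % n
        im = int(idxs[int(np.argmax(d1[idxs]))])
        if d1[im] <= 0:  # onset window missed the rise; fall back
            im = int(np.argmax(d1))
    slope = d1[im]
    if slope <= 0:
        raise DegenerateSignalError("no rising edge found")
    t_foot = t[im] - (y[im] - ymin) / slope
    return t_foot, im, ymin


def find_fiducials(wave: Waveform, kind: str = "pressure",
                   prominence_frac: float = 2e-3) -> FiducialSet:
    """Locate fiducial points on one pressure or PPG cycle.

    Absent features (e.g. no diastolic peak in an elderly-type wave) are
    reported as missing.  ``prominence_frac`` is the minimal amplitude
    excursion (fraction of the pulse amplitude) for a shoulder candidate on
    the derivative traces.
    """
    if kind not in ("pressure", "ppg"):
        raise ParameterError(f"unknown wave kind {kind!r}")
    t, y = wave.t, wave.y
    if y.size < 50:
        raise DomainError("need at least 50 samples per cycle")
    rng = float(np.max(y) - np.min(y))
    if rng <= 0 or not np.isfinite(rng):
        raise DegenerateSignalError("flat signal has no fiducial points")
    fs = wave.fs
    d1, d2 = _derivatives(y, fs)
    n = y.size
    fid = FiducialSet(kind=kind)
    pts = fid.points

    t_foot, im, _ = _foot_and_upstroke(t, y, d1, d2)
    pts["foot"] = (t_foot, float(np.min(y)))
    name_slope = "max_dpdt" if kind == "pressure" else "max_slope"
    pts[name_slope] = (t[im], float(d1[im]))

    # systolic peak: global maximum
    isys = int(np.argmax(y))
    pts["systolic_peak"] = (t[isys], float(y[isys]))

    # substantial systolic maxima (early and late systolic peaks); found
    # before the notch so the dip between double systolic peaks is not
    # mistaken for the dicrotic incisura
    sys_hi = min(n - 2, isys + int(0.25 * n))
    sys_maxima = [i for i in _local_maxima(y, im, sys_hi)
                  if y[i] > np.min(y) + 0.25 * rng]

    # dicrotic notch: first local minimum of the wave after the last
    # systolic peak (within 45% of the cycle), else the largest local
    # maximum of d2 there (incisura curvature)
    lo = (max(sys_maxima) if len(sys_maxima) >= 2 else isys) + 2
    hi = min(n - 1, isys + int(0.45 * n))
    notch_idx = None
    mins = _local_minima(y, lo, hi)
    if mins:
        notch_idx = mins[0]
    else:
        cands = _local_maxima(d2, lo, hi)
        if cands:
            notch_idx = max(cands, key=lambda i: d2[i])
    if notch_idx is not None:
        pts["dicrotic_notch"] = (t[notch_idx], float(y[notch_idx]))
        # diastolic peak: local maximum after the notch
        dmax = _local_maxima(y, notch_idx + 1, n - 1)
        if dmax:
            pts["diastolic_peak"] = (t[dmax[0]], float(y[dmax[0]]))

    # P1/P2 systolic shoulders (pressure waves)
    if kind == "pressure":
        _find_p1_p2(fid, t, y, d1, d2, im, isys, notch_idx, sys_maxima,
                    t_foot, fs)
    else:
        # a-e waves ride on subtle curvature changes; a wider differentiation
        # window suppresses spurious micro-extrema of d2
        _, d2s = _derivatives(y, fs, scale=3.0)
        _find_abcde(fid, t, d2s, im, isys, notch_idx, n)
    return fid


#: systolic-peak delay after the foot separating C-type (early forward-wave
#: peak) from A-type (late reflection-augmented peak) central pressure waves
A_TYPE_PEAK_DELAY = 0.16  # s


def _find_p1_p2(fid, t, y, d1, d2, im, isys, notch_idx, sys_maxima, t_foot, fs):
    """Early (P1) and late (P2) systolic shoulders.

    The wave is classified by the delay of the systolic peak after the
    foot.  A-type (late peak): P2 is the systolic peak, P1 the preceding
    local maximum or rising-edge shoulder (local minimum of dP/dt on the
    rise).  C-type (early peak): P1 is the first systolic maximum, P2 the
    following local maximum or falling-edge shoulder (local maximum of
    dP/dt on the decay).  A shoulder that does not exist leaves the point
    missing rather than fabricated.
    """
    pts = fid.points
    n = y.size
    T = (t[-1] - t[0]) + (t[1] - t[0])
    end_sys = notch_idx if notch_idx is not None else min(n - 1, isys + int(0.3 * n))
    peak_delay = (t[isys] - t_foot) % T
    if peak_delay > A_TYPE_PEAK_DELAY:
        # A-type: reflection peak dominates
        pts["p2"] = (t[isys], float(y[isys]))
        earlier = [i for i in sys_maxima if i < isys]
        if earlier:
            pts["p1"] = (t[earlier[0]], float(y[earlier[0]]))
            return
        lo = im + max(2, int(0.01 * fs))
        rise_sh = [i for i in _local_minima(d1, lo, isys - 1) if d1[i] > 0]
        if rise_sh:
            pts["p1"] = (t[rise_sh[0]], float(y[rise_sh[0]]))
        else:
            del pts["p2"]  # no early shoulder found: report both missing
        return
    # C-type: forward-wave peak dominates
    i1 = sys_maxima[0] if sys_maxima else isys
    pts["p1"] = (t[i1], float(y[i1]))
    later = [i for i in sys_maxima if i > i1 and i <= end_sys]
    if later:
        pts["p2"] = (t[later[0]], float(y[later[0]]))
        return
    fall_sh = [i for i in _local_maxima(d1, i1 + 2, end_sys) if d1[i] < 0]
    if fall_sh:
        pts["p2"] = (t[fall_sh[0]], float(y[fall_sh[0]]))
    else:
        cands = _local_minima(np.abs(d2), i1 + 2, end_sys)
        if cands:
            pts["p2"] = (t[cands[0]], float(y[cands[0]]))
        else:
            del pts["p1"]


def _find_abcde(fid, t, d2, im, isys, notch_idx, n):
    """a-e waves of the PPG second derivative, in temporal order.

    a: dominant early systolic d2 maximum (on the upstroke); b: the
    dominant minimum following it; c/d/e: the dominant max/min/max of the
    remaining systolic window, in that order.  Magnitude-based selection
    within ordered windows keeps tiny residual wiggles of the smoothed
    derivative from masquerading as waves."""
    pts = fid.points
    stop = notch_idx + int(0.1 * n) if notch_idx is not None else int(0.7 * n)
    stop = min(stop, n - 1)
    lim = max(isys, 3)
    ia = int(np.argmax(d2[1:lim])) + 1
    if d2[ia] <= 0:
        return
    pts["a"] = (t[ia], float(d2[ia]))
    if ia + 1 >= stop:
        return
    ib = int(np.argmin(d2[ia + 1:stop])) + ia + 1
    if ib + 1 >= stop:
        return
    pts["b"] = (t[ib], float(d2[ib]))
    ic = int(np.argmax(d2[ib + 1:stop])) + ib + 1
    if ic + 1 >= stop:
        return
    pts["c"] = (t[ic], float(d2[ic]))
    idd = int(np.argmin(d2[ic + 1:stop])) + ic + 1
    if idd + 1 >= stop:
        return
    pts["d"] = (t[idd], float(d2[idd]))
    ie = int(np.argmax(d2[idd + 1:stop + 1])) + idd + 1
    pts["e"] = (t[ie], float(d2[ie]))


# ---------------------------------------------------------------------------
# Index computations
# ---------------------------------------------------------------------------

def pressure_stats(wave: Waveform, in_mmhg: bool = False) -> dict:
    """SBP (max), DBP (min), MAP (time average), PP over one cycle.

    Input in Pa unless ``in_mmhg``; output always in mmHg.
    """
    f = 1.0 if in_mmhg else 1.0 / units.MMHG_PA
    sbp = float(np.max(wave.y)) * f
    dbp = float(np.min(wave.y)) * f
    mapv = float(np.mean(wave.y)) * f
    return {"SBP": sbp, "DBP": dbp, "MAP": mapv, "PP": sbp - dbp}


def pp_amplification(aortic: Waveform, brachial: Waveform,
                     in_mmhg: bool = False) -> float:
    """Ratio of brachial to aortic pulse pressure."""
    pa = pressure_stats(aortic, in_mmhg)["PP"]
    pb = pressure_stats(brachial, in_mmhg)["PP"]
    if pa == 0:
        raise DegenerateSignalError("aortic pulse pressure is zero")
    return pb / pa


def augmentation_indexes(fid: FiducialSet, stats: dict) -> dict:
    """AP = P(P2) - P(P1) [same units as the fiducial amplitudes], AIx =
    100*AP/PP [%], Tr = t(P1) - t(foot) [ms]; missing P1/P2 yield NaNs."""
    if not (fid.has("p1") and fid.has("p2")):
        return {"AP": math.nan, "AIx": math.nan, "Tr": math.nan}
    ap = fid.amp("p2") - fid.amp("p1")
    pp = stats["PP"]
    aix = 100.0 * ap / pp if pp else math.nan
    tr = (fid.time("p1") - fid.time("foot")) * 1e3
    return {"AP": ap, "AIx": aix, "Tr": tr}


def ppg_stiffness_indexes(fid: FiducialSet,
                          subject_height: float = DEFAULT_HEIGHT) -> dict:
    """PPG-derived stiffness surrogates from one digital PPG cycle.

    RI: diastolic-peak amplitude over systolic-peak amplitude (relative to
    the wave foot).  SI: height / time from systolic to diastolic peak
    [m/s].  AGI_mod: (b - c - d - e)/a from the second-derivative wave
    amplitudes.  Missing constituents yield NaNs.
    """
    out = {"RI": math.nan, "SI": math.nan, "AGI_mod": math.nan}
    base = fid.amp("foot") if fid.has("foot") else 0.0
    if fid.has("diastolic_peak") and fid.has("systolic_peak"):
        num = fid.amp("diastolic_peak") - base
        den = fid.amp("systolic_peak") - base
        if den:
            out["RI"] = num / den
        dt = fid.time("diastolic_peak") - fid.time("systolic_peak")
        if dt > 0:
            out["SI"] = subject_height / dt
    if all(fid.has(k) for k in "abcde"):
        a = fid.amp("a")
        if a:
            out["AGI_mod"] = (fid.amp("b") - fid.amp("c") - fid.amp("d")
                              - fid.amp("e")) / a
    return out


def wave_foot(wave: Waveform) -> float:
    """Foot time [s] by the intersecting-tangents construction."""
    d1, d2 = _derivatives(wave.y, wave.fs)
    t_foot, _, _ = _foot_and_upstroke(wave.t, wave.y, d1, d2)
    return t_foot


def foot_to_foot_ptt(wave_a: Waveform, wave_b: Waveform) -> float:
    """Pulse transit time [ms] between the feet of two waves of one cycle.

    Feet are located by intersecting tangents; the difference is wrapped
    into [-T/2, T/2) so a foot that falls just before the cycle boundary at
    the distal site still yields the physical delay.
    """
    ta = wave_foot(wave_a)
    tb = wave_foot(wave_b)
    T = wave_a.duration
    d = (tb - ta + 0.5 * T) % T - 0.5 * T
    return d * 1e3


def pwv(ptt_ms: float, path_length_m: float) -> float:
    """Pulse wave velocity [m/s] from transit time [ms] and path length [m]."""
    if ptt_ms <= 0:
        raise DomainError("transit time must be positive")
    return path_length_m / (ptt_ms * 1e-3)


def flow_indexes(q: Waveform, p: Waveform,
                 u: Waveform | None = None) -> dict:
    """Cardiac indexes from the aortic-root flow and pressure of one cycle.

    Flow features {HR, SV, LVET, PFT, RFV} come from the flow wave; CO
    [l/min] = HR*SV; dPdt_max [mmHg/s] from the differentiated pressure;
    cumulative flow volumes [ml] and flow velocity [m/s] evaluated at the
    times of P1 and P2 where those shoulders exist.
    """
    feats = measure_inflow_features(q)
    feats["CO"] = feats["HR"] * feats["SV"] * 1e-3
    d1, _ = _derivatives(p.y, p.fs)
    feats["dPdt_max"] = float(np.max(d1)) / units.MMHG_PA
    fid = find_fiducials(p, "pressure")
    cumvol = np.concatenate([[0.0], np.cumsum(
        0.5 * (q.y[1:] + q.y[:-1]) * q.dt)])
    for name in ("p1", "p2"):
        if fid.has(name):
            tp = fid.time(name)
            feats[f"vol_to_{name}"] = float(np.interp(tp, q.t, cumvol)) * 1e6
            if u is not None:
                feats[f"U_at_{name}"] = float(np.interp(tp, u.t, u.y))
        else:
            feats[f"vol_to_{name}"] = math.nan
            if u is not None:
                feats[f"U_at_{name}"] = math.nan
    return feats


#: PWV measurement paths: (name, proximal site, distal site)
PWV_PATHS = (
    ("aortic", "aortic_root", "iliac_bifurcation"),
    ("carotid_femoral", "carotid", "femoral"),
    ("brachial_radial", "brachial", "radial"),
    ("femoral_ankle", "femoral", "ankle"),
)


def index_report(pws, network, subject_height: float = DEFAULT_HEIGHT) -> dict:
    """Full per-subject index row from one converged pulse-wave set.

    Combines aortic/brachial pressure statistics, PP amplification, carotid
    augmentation indexes, foot-to-foot PTTs/PWVs over the standard paths,
    digital-PPG stiffness indexes, and flow-derived cardiac indexes.
    Missing sites or fiducials appear as NaNs, never as fabricated values.
    """
    row: dict = {}
    waves = pws.waves
    if "aortic_root" in waves:
        sa = pressure_stats(waves["aortic_root"]["P"])
        row.update({f"aortic_{k}": v for k, v in sa.items()})
        row.update(flow_indexes(waves["aortic_root"]["Q"],
                                waves["aortic_root"]["P"],
                                waves["aortic_root"].get("U")))
    if "brachial" in waves:
        sb = pressure_stats(waves["brachial"]["P"])
        row.update({f"brachial_{k}": v for k, v in sb.items()})
    if "aortic_root" in waves and "brachial" in waves:
        row["PP_amp"] = pp_amplification(waves["aortic_root"]["P"],
                                         waves["brachial"]["P"])
    if "carotid" in waves:
        wc = waves["carotid"]["P"]
        fid_c = find_fiducials(wc, "pressure")
        # PP in the wave's own units (Pa) so AP/PP is consistent
        stats_pa = {"PP": float(np.max(wc.y) - np.min(wc.y))}
        aug = augmentation_indexes(fid_c, stats_pa)
        row["carotid_AP"] = (aug["AP"] / units.MMHG_PA
                             if not math.isnan(aug["AP"]) else math.nan)
        row["carotid_AIx"] = aug["AIx"]
        row["carotid_Tr"] = aug["Tr"]
    for name, sa_, sb_ in PWV_PATHS:
        if sa_ in waves and sb_ in waves:
            ptt = foot_to_foot_ptt(waves[sa_]["P"], waves[sb_]["P"])
            row[f"PTT_{name}"] = ptt
            length = network.path_length(sa_, sb_)
            row[f"PWV_{name}"] = (pwv(ptt, length) if ptt > 0 else math.nan)
    if "finger" in waves and "PPG" in waves["finger"]:
        fid_ppg = find_fiducials(waves["finger"]["PPG"], "ppg")
        row.update(ppg_stiffness_indexes(fid_ppg, subject_height))
    return row
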