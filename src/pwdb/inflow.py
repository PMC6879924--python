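"""Aortic-root inflow waveform: construction and feature measurement.

The heart enters the model only through a prescribed periodic volumetric
flow wave Q(t) at the aortic root.  Its defining cardiac features are heart
rate HR (cycle duration T = 60/HR), stroke volume SV (net integral of Q over
one cycle), left ventricular ejection time LVET (end of systolic forward
flow), peak flow time PFT, and reverse flow volume RFV (the brief
end-systolic backflow as the aortic valve closes).

The waveform morphology is a smooth analytic archetype of the adult
ascending-aortic flow wave: a positive systolic lobe (sinusoidal rise to the
peak at PFT, cosinusoidal decay to zero at LVET), a short sin^2 reverse lobe
carrying RFV, and zero flow in diastole.  The remaining shape features are
held fixed across subjects; only the five cardiac parameters move.

LVET covaries with HR and SV through the empirical regression

    LVET[ms] = 244 - 0.926 * HR[beats/min] + 1.08 * SV[ml]

which the population model applies in deviation form about the age mean
(see :mod:`pwdb.aging`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateSignalError, DomainError, ParameterError

__all__ = [
    "Waveform",
    "InflowParams",
    "lvet_from_hr_sv",
    "generate_inflow",
    "measure_inflow_features",
]

#: duration of the end-systolic reverse-flow lobe [s]
REVERSE_LOBE_DURATION = 0.06


@dataclass
class Waveform:
    """Uniformly sampled single-cycle signal at a named site.

    ``kind`` is one of {"P", "U", "A", "Q", "PPG"}.  The grid is half-open:
    t spans [t0, t0 + T) and the signal is periodic with period T.
    """

    t: np.ndarray
    y: np.ndarray
    site: str = ""
    kind: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size != self.y.size or self.t.size < 2:
            raise DomainError("waveform needs matching t/y with length >= 2")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise DomainError("waveform time grid must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.y)):
            raise DomainError("waveform values must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def fs(self) -> float:
        return 1.0 / self.dt

    @property
    def duration(self) -> float:
        """Cycle period T (half-open grid: last sample + dt - first)."""
        return float(self.t[-1] - self.t[0]) + self.dt

    def cyclic_integral(self) -> float:
        """Trapezoidal integral over one full period, including the wrap."""
        core = np.trapezoid(self.y, self.t)
        wrap = 0.5 * (self.y[-1] + self.y[0]) * self.dt
        return float(core + wrap)

    def save_txt(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t, self.y]),
                   header=f"site={self.site} kind={self.kind}", fmt="%.10g")

    @classmethod
    def load_txt(cls, path, site: str = "", kind: str = "") -> "Waveform":
        arr = np.loadtxt(Path(path))
        return cls(t=arr[:, 0], y=arr[:, 1], site=site, kind=kind)


def lvet_from_hr_sv(HR: float, SV: float) -> float:
    """Regression LVET[ms] = 244 - 0.926*HR + 1.08*SV (HR beats/min, SV ml)."""
    lvet = 244.0 - 0.926 * HR + 1.08 * SV
    if HR > 0 and lvet <= 0:
        warnings.warn("regression LVET is nonpositive; inputs far outside "
                      "physiological range", stacklevel=2)
    return lvet


@dataclass
class InflowParams:
    """Cardiac parameters defining one aortic inflow cycle.

    Units follow clinical convention: HR beats/min, SV and RFV ml, LVET and
    PFT ms.  ``fs`` is the sampling rate of the generated waveform.
    """

    HR: float = 75.0
    SV: float = 60.0
    LVET: float | None = None  # ms; None -> from the HR/SV regression
    PFT: float = 79.0
    RFV: float = 0.73
    fs: float = 500.0

    def __post_init__(self):
        if self.LVET is None:
            self.LVET = lvet_from_hr_sv(self.HR, self.SV)
        if self.HR <= 0 or self.SV <= 0 or self.fs <= 0:
            raise ParameterError("HR, SV and fs must be > 0")
        if self.RFV < 0:
            raise ParameterError("RFV must be >= 0")
        if not 0.0 < self.PFT < self.LVET:
            raise ParameterError(
                f"need 0 < PFT ({self.PFT} ms) < LVET ({self.LVET} ms)")
        if self.LVET >= 1000.0 * self.T:
            raise ParameterError("LVET must be shorter than the cardiac cycle")

    @property
    def T(self) -> float:
        """Cycle duration [s]."""
        return 60.0 / self.HR

    def as_dict(self) -> dict:
        return {"HR": self.HR, "SV": self.SV, "LVET": self.LVET,
                "PFT": self.PFT, "RFV": self.RFV}


def _archetype_lobes(t: np.ndarray, tp: float, ts: float, tr: float):
    """Unscaled forward (max 1 at tp, zero outside [0, ts]) and reverse
    (sin^2 dip on [ts, ts+tr]) lobes of the flow archetype."""
    fwd = np.zeros_like(t)
    rise = t <= tp
    fwd[rise] = np.sin(0.5 * np.pi * t[rise] / tp)
    fall = (t > tp) & (t <= ts)
    fwd[fall] = np.cos(0.5 * np.pi * (t[fall] - tp) / (ts - tp))
    rev = np.zeros_like(t)
    lobe = (t > ts) & (t < ts + tr)
    rev[lobe] = -np.sin(np.pi * (t[lobe] - ts) / tr) ** 2
    return fwd, rev


def generate_inflow(params: InflowParams, template=None) -> Waveform:
    """Construct one periodic aortic inflow cycle Q(t) [m^3/s].

    The analytic archetype is warped so that the time of maximum equals PFT,
    the systolic downward zero crossing equals LVET, the reverse-phase volume
    equals RFV, and the net integral over the cycle equals SV (forward volume
    = SV + RFV).  ``template`` may supply an alternative single-cycle shape
    (a :class:`Waveform` with a positive lobe) to be warped instead of the
    built-in archetype; the built-in is used when it is None.
    """
    T = params.T
    tp = params.PFT * 1e-3
    ts = params.LVET * 1e-3
    tr = min(REVERSE_LOBE_DURATION, 0.9 * (T - ts))
    if params.RFV > 0 and tr <= 0:
        raise ParameterError("no room for the reverse-flow lobe after LVET")
    n = int(round(T * params.fs))
    if n < 8:
        raise ParameterError("sampling rate too low for the cycle duration")
    t = np.arange(n) / params.fs

    if template is None:
        fwd, rev = _archetype_lobes(t, tp, ts, tr)
    else:
        fwd = _warp_template(template, t, tp, ts)
        _, rev = _archetype_lobes(t, tp, ts, tr)

    def ptrapz(y):
        return np.trapezoid(y, t) + 0.5 * (y[-1] + y[0]) / params.fs

    sv = params.SV * 1e-6
    rfv = params.RFV * 1e-6
    vol_rev = abs(ptrapz(rev))
    a_rev = rfv / vol_rev if (rfv > 0 and vol_rev > 0) else 0.0
    vol_fwd = ptrapz(fwd)
    a_fwd = (sv + rfv) / vol_fwd
    q = a_fwd * fwd + a_rev * rev
    return Waveform(t=t, y=q, site="aortic_root", kind="Q")


def _warp_template(template: Waveform, t: np.ndarray, tp: float, ts: float):
    """Piecewise-linearly time-warp a template systolic lobe so its peak
    lands at tp and its end-of-systole at ts; zero in diastole."""
    ty, yy = template.t - template.t[0], np.clip(template.y, 0.0, None)
    peak = ty[int(np.argmax(yy))]
    pos = np.nonzero(yy > 1e-12 * yy.max())[0]
    t_end = ty[pos[-1]]
    if peak <= 0 or t_end <= peak:
        raise ParameterError("template must have an interior peak before its end")
    # map [0, peak] -> [0, tp], [peak, t_end] -> [tp, ts]
    src = np.where(t <= tp, t * peak / tp,
                   peak + (t - tp) * (t_end - peak) / max(ts - tp, 1e-9))
    out = np.interp(src, ty, yy, left=0.0, right=0.0)
    out[t > ts] = 0.0
    return out


def measure_inflow_features(q: Waveform) -> dict:
    """Measure {HR, SV, LVET, PFT, RFV} back from a single flow cycle.

    SV is the net cyclic integral [ml]; PFT the time of maximum [ms]; LVET
    the downward zero crossing ending systolic forward flow [ms] (linearly
    interpolated between samples); RFV the magnitude of the negative-phase
    integral [ml].
    """
    y = q.y
    if np.allclose(y, 0.0):
        raise DegenerateSignalError("flow wave is identically zero")
    T = q.duration
    hr = 60.0 / T
    sv = q.cyclic_integral() * 1e6
    ipk = int(np.argmax(y))
    pft = (q.t[ipk] - q.t[0]) * 1e3
    # end of the systolic lobe: first downward zero crossing after the peak
    lvet = None
    for j in range(ipk, y.size - 1):
        if y[j] > 0.0 >= y[j + 1]:
            frac = y[j] / (y[j] - y[j + 1])
            lvet = (q.t[j] + frac * q.dt - q.t[0]) * 1e3
            break
    if lvet is None:
        lvet = T * 1e3  # forward flow throughout the cycle
    neg = np.minimum(y, 0.0)
    rfv = abs(np.trapezoid(neg, q.t) + 0.5 * (neg[-1] + neg[0]) * q.dt) * 1e6
    return {"HR": hr, "SV": sv, "LVET": lvet, "PFT": pft, "RFV": rfv}
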