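"""Blood-flow curves and diastolic parameter extraction.

From a segmented flow three curves are derived per cardiac phase: the maximal
velocity (noise-robust: mean of the pixels above 95% of the in-mask maximum),
the mean velocity, and the flow rate (mean velocity x segmented area, ml/s).
The aortic flow-rate curve locates the end of ejection; the transmitral
curves then yield the classic diastolic indices:

* E, A — early and atrial peak velocities (cm/s) on the maximal-velocity
  curve; the two highest local peaks in diastole at least one sixth of the
  cycle apart, the *earlier* one being E regardless of magnitude;
* Ef, Af — peak filling/atrial rates (ml/s), same detection on the flow-rate
  curve;
* FV — filling volume (ml), area under the flow-rate curve between the start
  and end of filling;
* DT — deceleration time (ms), from the Ef peak to the extrapolated end of
  the Ef wave;
* IVRT — isovolumetric relaxation time (ms), from end of ejection to start of
  filling.

All wave on/offsets are found the same way: a least-squares line through the
limb samples lying between 40% and 70% of the wave's peak (augmented by the
exact piecewise-linear crossings of the 40% and 70% levels), extrapolated to
the time axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .core import CurveError, PCSeries, TimeCurve, ValidationError, logger
from .flowseg import MaskSeries

LIMB_LO_FRAC = 0.40
LIMB_HI_FRAC = 0.70
PEAK_RULE_FRAC = 0.95


@dataclass
class FlowCurves:
    """Maximal-velocity, mean-velocity and flow-rate curves of one flow.

    Velocities are rectified so the flow of interest is positive
    (``flow_sign`` applied); ``q = v_mean x segmented area`` holds at every
    phase.
    """

    v_max: TimeCurve
    v_mean: TimeCurve
    q: TimeCurve
    flow_sign: int = 1


class Peak(NamedTuple):
    index: int
    time: float
    value: float


class PeakPair(NamedTuple):
    first: Peak
    second: Peak | None  # None when only a single admissible peak exists


@dataclass
class DiastolicTimings:
    """Landmark times (ms) delimiting the diastolic period."""

    t_eject_end: float
    t_fill_start: float
    t_fill_end: float
    cycle_length: float

    def __post_init__(self) -> None:
        if not (self.t_fill_start < self.t_fill_end <= self.cycle_length + 1e-9):
            raise ValidationError(
                f"inconsistent timings: fill [{self.t_fill_start}, "
                f"{self.t_fill_end}] within cycle {self.cycle_length}")

    def to_row(self) -> dict:
        return {"t_eject_end_ms": self.t_eject_end,
                "t_fill_start_ms": self.t_fill_start,
                "t_fill_end_ms": self.t_fill_end,
                "cycle_length_ms": self.cycle_length}


@dataclass
class FlowParameters:
    """Velocity- and flow-rate-based diastolic indices of the transmitral flow."""

    E: float
    A: float | None
    EA_ratio: float | None
    Ef: float
    Af: float | None
    EfAf_ratio: float | None
    FV: float
    Ef_over_FV: float
    DT: float
    IVRT: float
    t_E: float = np.nan
    t_A: float = np.nan
    t_Ef: float = np.nan
    t_Af: float = np.nan

    def to_row(self) -> dict:
        none2nan = lambda x: float("nan") if x is None else float(x)
        return {
            "E_MR_cm_per_s": float(self.E),
            "A_MR_cm_per_s": none2nan(self.A),
            "EA_ratio": none2nan(self.EA_ratio),
            "Ef_MR_ml_per_s": float(self.Ef),
            "Af_MR_ml_per_s": none2nan(self.Af),
            "EfAf_ratio": none2nan(self.EfAf_ratio),
            "FV_MR_ml": float(self.FV),
            "Ef_over_FV_per_s": float(self.Ef_over_FV),
            "DT_MR_ms": float(self.DT),
            "IVRT_MR_ms": float(self.IVRT),
            "t_E_ms": float(self.t_E),
            "t_A_ms": none2nan(self.t_A),
            "t_Ef_ms": float(self.t_Ef),
            "t_Af_ms": none2nan(self.t_Af),
        }


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def flow_curves(series: PCSeries, seg: MaskSeries) -> FlowCurves:
    """Per-phase maximal velocity, mean velocity and flow rate of a flow.

    Velocities are taken with the tracked flow's sign rectified to positive.
    The maximal velocity uses the 95% rule; phases with an empty mask yield 0.
    """
    if seg.masks.shape != series.velocity.shape:
        raise ValidationError("mask series does not match the image series")
    P = series.n_phases
    v_max = np.zeros(P)
    v_mean = np.zeros(P)
    q = np.zeros(P)
    for p in range(P):
        m = seg.masks[p]
        if not m.any():
            continue
        w = seg.flow_sign * series.velocity[p][m]
        mx = w.max()
        v_max[p] = w[w >= PEAK_RULE_FRAC * mx].mean()
        v_mean[p] = w.mean()
        q[p] = v_mean[p] * m.sum() * series.pixel_area_cm2
    t = series.times
    return FlowCurves(v_max=TimeCurve(t, v_max, "cm/s"),
                      v_mean=TimeCurve(t, v_mean, "cm/s"),
                      q=TimeCurve(t, q, "ml/s"), flow_sign=seg.flow_sign)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def _level_crossing(t0, v0, t1, v1, level):
    # exact crossing of a piecewise-linear segment with a horizontal level
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def limb_zero_crossing(curve: TimeCurve, peak_index: int, side: str) -> float:
    """Extrapolated time-axis intersection of a wave limb.

    The limb is walked from the peak (forward for ``'descending'``, backward
    for ``'ascending'``) while values strictly decrease.  A least-squares line
    is fit through the limb samples with values in [40%, 70%] of the peak plus
    the exact piecewise-linear crossings of the two levels, and its root is
    returned (ms).

    Raises :class:`CurveError` when the limb never descends below 70% of the
    peak ("limb truncated") or the fit degenerates.
    """
    if side not in ("ascending", "descending"):
        raise ValidationError("side must be 'ascending' or 'descending'")
    t, v = curve.times, curve.values
    n = len(t)
    peak = v[peak_index]
    if peak <= 0:
        raise CurveError("peak value must be positive")
    step = 1 if side == "descending" else -1
    idx = [peak_index]
    j = peak_index
    while 0 <= j + step < n and v[j + step] < v[j]:
        j += step
        idx.append(j)
    limb_t = t[idx] if step == 1 else t[idx][::-1]
    limb_v = v[idx] if step == 1 else v[idx][::-1]
    # limb_t increasing; wave peak at one end
    lo, hi = LIMB_LO_FRAC * peak, LIMB_HI_FRAC * peak
    if limb_v.min() > hi:
        raise CurveError(f"limb truncated: {side} limb of peak at "
                         f"t={t[peak_index]:.1f} ms never descends below 70% of peak")
    pts_t, pts_v = [], []
    in_band = (limb_v >= lo) & (limb_v <= hi)
    pts_t += list(limb_t[in_band])
    pts_v += list(limb_v[in_band])
    for level in (hi, lo):
        for a in range(len(limb_t) - 1):
            va, vb = limb_v[a], limb_v[a + 1]
            if (va - level) * (vb - level) < 0:
                pts_t.append(_level_crossing(limb_t[a], va, limb_t[a + 1], vb, level))
                pts_v.append(level)
                break
    if len(pts_t) < 2:
        raise CurveError("not enough points between 40% and 70% of peak to fit the limb")
    slope, intercept = np.polyfit(pts_t, pts_v, 1)
    if slope == 0:
        raise CurveError("degenerate (flat) limb fit")
    return float(-intercept / slope)


def end_of_ejection(aortic_q: TimeCurve) -> float:
    """End of the ejection phase (ms): extrapolated end of the systolic peak's
    descending limb on the (rectified) aortic flow-rate curve."""
    t, v = aortic_q.times, aortic_q.values
    first_half = t <= t[0] + (t[-1] - t[0]) / 2.0
    if not np.any(v[first_half] > 0):
        raise CurveError("no systolic peak on the aortic flow-rate curve")
    peak_index = int(np.argmax(np.where(first_half, v, -np.inf)))
    return limb_zero_crossing(aortic_q, peak_index, "descending")


def local_maxima(curve: TimeCurve) -> list[Peak]:
    """Interior local maxima; a plateau counts once, at its first sample."""
    t, v = curve.times, curve.values
    out = []
    n = len(v)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if v[i] > v[i - 1] and j + 1 < n and v[i] > v[j + 1]:
            out.append(Peak(i, float(t[i]), float(v[i])))
        i = j + 1
    return out


def detect_two_peaks(curve: TimeCurve, window: tuple[float, float],
                     min_sep: float) -> PeakPair:
    """The two highest admissible local peaks inside a time window.

    Among all local maxima with times in ``window``, the pair separated by at
    least ``min_sep`` ms with the greatest summed amplitude is chosen (ties:
    earliest pair) and ordered by time — the earlier peak is the E-type one
    regardless of magnitude.  With fewer than two admissible peaks a
    single-peak result is returned (``second is None``).
    """
    t0, t1 = window
    peaks = [p for p in local_maxima(curve) if t0 <= p.time <= t1]
    if not peaks:
        raise CurveError(f"no local maxima in window [{t0:.0f}, {t1:.0f}] ms")
    best = None
    for a in range(len(peaks)):
        for b in range(a + 1, len(peaks)):
            if peaks[b].time - peaks[a].time >= min_sep:
                key = (-(peaks[a].value + peaks[b].value),
                       peaks[a].time, peaks[b].time)
                if best is None or key < best[0]:
                    best = (key, PeakPair(peaks[a], peaks[b]))
    if best is None:
        top = max(peaks, key=lambda p: (p.value, -p.time))
        warnings.warn("fewer than two admissible local peaks; returning a "
                      "single-peak result", stacklevel=2)
        return PeakPair(top, None)
    return best[1]


# ---------------------------------------------------------------------------
# parameter assembly
# ---------------------------------------------------------------------------

def compute_flow_parameters(mitral: FlowCurves, aortic_q: TimeCurve,
                            cycle_length: float,
                            ) -> tuple[FlowParameters, DiastolicTimings]:
    """All blood-flow diastolic parameters from the transmitral curves.

    The aortic flow-rate curve supplies the end of ejection, which opens the
    diastolic search window ``[t_eject_end, cycle_length]``.  Velocity peaks
    (E, A) come from the maximal-velocity curve, rate peaks (Ef, Af) from the
    flow-rate curve; filling bounds, DT and IVRT from the 40-70% limb
    extrapolations of the Ef/Af waves.  FV integrates the flow-rate curve over
    the filling period with negative samples clipped to zero.
    """
    t_eject_end = end_of_ejection(aortic_q)
    window = (t_eject_end, cycle_length)
    min_sep = cycle_length / 6.0

    vpeaks = detect_two_peaks(mitral.v_max, window, min_sep)
    qpeaks = detect_two_peaks(mitral.q, window, min_sep)

    ef = qpeaks.first
    t_fill_start = limb_zero_crossing(mitral.q, ef.index, "ascending")
    ef_end = limb_zero_crossing(mitral.q, ef.index, "descending")
    if qpeaks.second is not None:
        t_fill_end = limb_zero_crossing(mitral.q, qpeaks.second.index, "descending")
    else:
        t_fill_end = ef_end
    t_fill_end = min(t_fill_end, cycle_length)

    DT = ef_end - ef.time
    IVRT = t_fill_start - t_eject_end
    if IVRT <= 0:
        warnings.warn("filling starts before the estimated end of ejection; "
                      "IVRT reported as 0", stacklevel=2)
        IVRT = 0.0
    FV = mitral.q.integral(t_fill_start, t_fill_end, clip_negative=True)

    E, A = vpeaks.first, vpeaks.second
    params = FlowParameters(
        E=E.value, A=None if A is None else A.value,
        EA_ratio=None if A is None else E.value / A.value,
        Ef=ef.value,
        Af=None if qpeaks.second is None else qpeaks.second.value,
        EfAf_ratio=None if qpeaks.second is None else ef.value / qpeaks.second.value,
        FV=FV, Ef_over_FV=ef.value / FV if FV > 0 else float("nan"),
        DT=DT, IVRT=IVRT,
        t_E=E.time, t_A=None if A is None else A.time,
        t_Ef=ef.time,
        t_Af=None if qpeaks.second is None else qpeaks.second.time)
    timings = DiastolicTimings(t_eject_end=t_eject_end,
                               t_fill_start=t_fill_start,
                               t_fill_end=t_fill_end,
                               cycle_length=cycle_length)
    logger.info("flow parameters: E=%.1f cm/s at %.0f ms, Ef=%.1f ml/s, "
                "DT=%.0f ms, IVRT=%.0f ms, FV=%.1f ml",
                params.E, params.t_E, params.Ef, params.DT, params.IVRT,
                params.FV)
    return params, timings
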