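"""Myocardial isolation on tissue-velocity series and longitudinal velocities.

The mitral annulus moves up and down within one cycle, so the sign-based
connectivity used for blood flow does not apply to tissue series.  Instead,
every pixel of a rough ROI around the left ventricle contributes its
full-cycle velocity time-profile, and k-means (k = 7 by default) groups the
profiles.  Pixels that stay within the myocardium share the characteristic
S'/E'/A' profile and fall into one cluster; the biggest spatially connected
cluster is taken as the myocardial mask.  From that mask, global and
per-segment maximal-velocity curves are computed, and E' — the first of the
two highest diastolic peaks of the rectified global curve — yields the E/E'
ratio when combined with the transmitral E.

Numerical choices: profiles are clustered raw (no normalisation) with squared
Euclidean distance, seeded k-means++ with 10 restarts; the myocardial
"maximal" velocity reuses the 95% averaging rule of the flow curves, applied
to whichever sign has the larger absolute in-mask extreme (sign retained);
segments are angular quadrants about the cavity centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .core import (CurveError, PCSeries, Roi, TimeCurve, ValidationError,
                   logger)
from .curves import PEAK_RULE_FRAC, Peak, PeakPair, detect_two_peaks

DEFAULT_K = 7
DEFAULT_RESTARTS = 10
SEGMENT_NAMES = ("lateral", "anterior", "septal", "inferior")


@dataclass
class ClusterResult:
    """k-means labelling of ROI pixel profiles and the derived myocardial mask.

    ``label_map`` holds a cluster id (0..k-1) for every ROI pixel and -1
    elsewhere; ``myocardial_mask`` is the biggest spatially connected cluster.
    """

    label_map: np.ndarray
    myocardial_mask: np.ndarray
    k: int
    seed: int
    inertia: float


@dataclass
class MyoParameters:
    """Longitudinal diastolic tissue velocity indices."""

    E_prime: float | None
    t_E_prime: float | None
    E_over_Eprime: float | None = None

    def to_row(self) -> dict:
        none2nan = lambda x: float("nan") if x is None else float(x)
        return {"E_prime_MR_cm_per_s": none2nan(self.E_prime),
                "t_E_prime_ms": none2nan(self.t_E_prime),
                "E_over_Eprime": none2nan(self.E_over_Eprime)}


def pixel_velocity_profiles(series: PCSeries, roi: Roi, *,
                            min_pixels: int = DEFAULT_K,
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Velocity time-profiles of the fixed pixels inside the ROI.

    Returns ``(profiles, index_map)``: profiles is (N pixels, P phases), row i
    being the full-cycle series of the pixel at ``index_map[i] = (row, col)``.
    """
    if series.series_kind != "myocardial":
        raise ValidationError("pixel_velocity_profiles requires a myocardial series")
    mask = roi.to_mask(series.shape)
    n = int(mask.sum())
    if n < min_pixels:
        raise ValidationError(
            f"ROI has {n} pixels, fewer than the {min_pixels} clusters")
    index_map = np.argwhere(mask)
    profiles = series.velocity[:, mask].T
    return profiles, index_map


def cluster_profiles(profiles: np.ndarray, k: int = DEFAULT_K, *,
                     seed: int = 0, restarts: int = DEFAULT_RESTARTS,
                     ) -> tuple[np.ndarray, float]:
    """k-means labels of raw profile vectors (best of ``restarts`` runs).

    Deterministic for a given seed.  Degenerate input (all profiles
    identical) collapses to a single effective cluster with a warning.
    """
    from sklearn.cluster import KMeans

    profiles = np.asarray(profiles, dtype=np.float64)
    n = profiles.shape[0]
    if n < k:
        raise ValidationError(f"{n} profiles but k={k} clusters requested")
    if np.unique(profiles, axis=0).shape[0] == 1:
        warnings.warn("all profiles identical: single effective cluster",
                      stacklevel=2)
        return np.zeros(n, dtype=int), 0.0
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(profiles)
    return labels.astype(int), float(km.inertia_)


def _largest_component(mask: np.ndarray) -> tuple[int, tuple, np.ndarray] | None:
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return None
    sizes = np.bincount(labels.ravel())
    best = None
    for lab in range(1, labels.max() + 1):
        com = ndimage.center_of_mass(labels == lab)
        key = (-sizes[lab], com)
        if best is None or key < best[0]:
            best = (key, (int(sizes[lab]), com, labels == lab))
    return best[1]


def myocardial_cluster(label_map: np.ndarray) -> np.ndarray:
    """Biggest 8-connected spatial component over all cluster labels.

    Size ties are broken by the lexicographically smallest (row, col)
    centroid, mirroring the flow-segmentation rule.
    """
    best = None
    for lab in np.unique(label_map):
        if lab < 0:
            continue
        comp = _largest_component(label_map == lab)
        if comp is None:
            continue
        size, com, mask = comp
        key = (-size, com)
        if best is None or key < best[0]:
            best = (key, mask)
    if best is None:
        return np.zeros(label_map.shape, dtype=bool)
    return best[1]


def cluster_myocardium(series: PCSeries, roi: Roi, *, k: int = DEFAULT_K,
                       seed: int = 0, restarts: int = DEFAULT_RESTARTS,
                       ) -> ClusterResult:
    """Full myocardial isolation: profiles -> k-means -> biggest connected cluster."""
    profiles, index_map = pixel_velocity_profiles(series, roi, min_pixels=k)
    labels, inertia = cluster_profiles(profiles, k, seed=seed, restarts=restarts)
    label_map = np.full(series.shape, -1, dtype=int)
    label_map[index_map[:, 0], index_map[:, 1]] = labels
    myo = myocardial_cluster(label_map)
    logger.info("myocardial cluster: %d px of %d in ROI (k=%d, inertia=%.3g)",
                int(myo.sum()), len(labels), k, inertia)
    return ClusterResult(label_map=label_map, myocardial_mask=myo, k=k,
                         seed=seed, inertia=inertia)


def _signed_peak_velocity(px: np.ndarray) -> float:
    """95%-rule maximal velocity of the dominant sign, sign retained."""
    mx, mn = px.max(), px.min()
    if -mn > mx:
        return float(px[px <= PEAK_RULE_FRAC * mn].mean())
    return float(px[px >= PEAK_RULE_FRAC * mx].mean())


def myo_velocity_curves(series: PCSeries, myocardial_mask: np.ndarray,
                        cavity_centre: tuple[float, float] | None = None, *,
                        reference_angle_deg: float = 0.0,
                        segment_names: tuple = SEGMENT_NAMES,
                        ) -> tuple[TimeCurve, TimeCurve, dict]:
    """Global and per-segment longitudinal velocity curves of the myocardium.

    Returns ``(global_max, global_mean, segments)`` where segments maps each
    name to its maximal-velocity TimeCurve (or None when the quadrant is
    empty).  Segments are 90-degree sectors about the cavity centre (the mask
    centroid when not given), with sector boundaries at ``reference_angle_deg``
    + {0, 90, 180, 270} measured from the +column axis.
    """
    myocardial_mask = np.asarray(myocardial_mask, dtype=bool)
    if not myocardial_mask.any():
        raise ValidationError("myocardial mask is empty")
    if cavity_centre is None:
        cavity_centre = ndimage.center_of_mass(myocardial_mask)
    P = series.n_phases
    t = series.times

    px_idx = np.argwhere(myocardial_mask)
    dr = px_idx[:, 0] - cavity_centre[0]
    dc = px_idx[:, 1] - cavity_centre[1]
    theta = (np.degrees(np.arctan2(dr, dc)) - reference_angle_deg) % 360.0
    seg_of_px = (theta // 90.0).astype(int)

    g_max = np.zeros(P)
    g_mean = np.zeros(P)
    seg_vals = {name: np.zeros(P) for name in segment_names}
    vel = series.velocity[:, myocardial_mask.nonzero()[0], myocardial_mask.nonzero()[1]]
    for p in range(P):
        px = vel[p]
        g_max[p] = _signed_peak_velocity(px)
        g_mean[p] = px.mean()
        for s, name in enumerate(segment_names):
            sel = px[seg_of_px == s]
            if sel.size:
                seg_vals[name][p] = _signed_peak_velocity(sel)
    segments = {}
    for s, name in enumerate(segment_names):
        if np.any(seg_of_px == s):
            segments[name] = TimeCurve(t, seg_vals[name], "cm/s")
        else:
            warnings.warn(f"segment {name!r} has no pixels; curve omitted",
                          stacklevel=2)
            segments[name] = None
    return (TimeCurve(t, g_max, "cm/s"), TimeCurve(t, g_mean, "cm/s"), segments)


def default_filling_window(mean_curve: TimeCurve) -> tuple[float, float]:
    """Filling window from the tissue curve itself (no flow timings).

    The systolic direction is that of the extreme in the first half-cycle;
    diastole moves the annulus the opposite way.  The window opens at the last
    zero crossing of the mean curve before its largest diastolic-direction
    excursion and closes at cycle end.
    """
    t, v = mean_curve.times, mean_curve.values
    half = t <= t[0] + (t[-1] - t[0]) / 2.0
    s_idx = int(np.argmax(np.where(half, np.abs(v), -np.inf)))
    s_sign = 1.0 if v[s_idx] > 0 else -1.0
    d = -s_sign * v  # diastolic-direction (positive during filling)
    peak = int(np.argmax(d))
    if d[peak] <= 0:
        raise CurveError("no diastolic-direction excursion on the tissue curve")
    start = t[0]
    for i in range(peak, 0, -1):
        if d[i - 1] <= 0 < d[i]:
            start = t[i - 1] if d[i - 1] == 0 else float(
                t[i - 1] + (0 - d[i - 1]) * (t[i] - t[i - 1]) / (d[i] - d[i - 1]))
            break
    return float(start), float(t[-1] + (t[1] - t[0]))


def detect_e_prime(myo_curve: TimeCurve, filling_window: tuple[float, float],
                   min_sep: float) -> tuple[float | None, float | None]:
    """E': magnitude and time of the earlier of the two highest diastolic peaks.

    The curve is rectified toward the diastolic direction (sign of its mean
    within the filling window) and the same constrained two-peak detection as
    for the flow curves is applied; with a single admissible peak, that peak
    is E'.  Returns ``(None, None)`` with a warning when no local maximum
    exists in the window.
    """
    t0, t1 = filling_window
    in_win = (myo_curve.times >= t0) & (myo_curve.times <= t1)
    if not in_win.any():
        raise ValidationError("filling window contains no samples")
    mean_v = myo_curve.values[in_win].mean()
    sign = -1.0 if mean_v < 0 else 1.0
    rect = TimeCurve(myo_curve.times, sign * myo_curve.values, myo_curve.unit)
    try:
        pair = detect_two_peaks(rect, filling_window, min_sep)
    except CurveError:
        warnings.warn("no local maxima in the filling window; E' undefined",
                      stacklevel=2)
        return None, None
    return pair.first.value, pair.first.time


def compute_myo_parameters(myo_max_curve: TimeCurve, *,
                           filling_window: tuple[float, float] | None = None,
                           mean_curve: TimeCurve | None = None,
                           cycle_length: float | None = None,
                           E: float | None = None) -> MyoParameters:
    """Assemble E' (and E/E' when the transmitral E is supplied)."""
    if cycle_length is None:
        dt = myo_max_curve.times[1] - myo_max_curve.times[0]
        cycle_length = float(myo_max_curve.times[-1] + dt)
    if filling_window is None:
        src = mean_curve if mean_curve is not None else myo_max_curve
        filling_window = default_filling_window(src)
    e_prime, t_e_prime = detect_e_prime(myo_max_curve, filling_window,
                                        cycle_length / 6.0)
    ratio = None
    if e_prime is not None and E is not None and e_prime > 0:
        ratio = E / e_prime
    return MyoParameters(E_prime=e_prime, t_E_prime=t_e_prime,
                         E_over_Eprime=ratio)
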