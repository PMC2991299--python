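"""Semi-automated segmentation of a through-plane flow pattern.

On velocity-encoded images a jet is a connected region of same-signed
velocity, so the flow of interest can be tracked without any shape prior.
The algorithm takes one rough user ROI on a single phase and proceeds in
three steps:

1. the mean-velocity curve inside the rough ROI picks the *reference phase*
   (highest absolute mean) and the sign of the flow of interest;
2. at the reference phase the biggest connected component of that sign inside
   the (dilated) ROI initialises the mask;
3. the component's centre of mass is propagated phase by phase toward both
   ends of the cycle, each step selecting the biggest same-signed component
   containing (or nearly containing) the propagated point.

The centre-of-mass constraint keeps the tracker on the flow of interest when
another jet (e.g. the aortic one near the mitral valve) enters the search
region.

Fixed numerical choices (documented in docs/methods.md): 8-connectivity;
search region = rough ROI dilated by a disk of radius 3 px; components under
4 px are ignored during tracking; the propagated point is rounded to the
nearest pixel and a component is accepted when its closest pixel lies within
2 px of the point; equal-size ties go to the component with the
lexicographically smallest (row, col) centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .core import PCSeries, Roi, SegmentationError, ValidationError, logger

SEARCH_DILATION_PX = 3
MIN_COMPONENT_PX = 4
POINT_TOLERANCE_PX = 2.0
MIN_ROI_PX = 16


@dataclass
class MaskSeries:
    """Per-phase binary masks of one tracked flow pattern.

    ``centroids[p]`` is the (row, col) centre of mass of ``masks[p]`` or None
    when the mask is empty; ``areas`` are pixel counts; ``flow_sign`` is +1 or
    -1 (the velocity sign of the tracked flow); ``seed_phase`` is the
    reference phase the tracking started from.
    """

    masks: np.ndarray
    centroids: list
    seed_phase: int
    flow_sign: int
    areas: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValidationError("masks must be a (P, H, W) stack")
        if self.areas is None:
            self.areas = self.masks.sum(axis=(1, 2))
        self.areas = np.asarray(self.areas, dtype=np.int64)
        if self.flow_sign not in (1, -1):
            raise ValidationError("flow_sign must be +1 or -1")

    @property
    def n_phases(self) -> int:
        return self.masks.shape[0]

    def areas_cm2(self, pixel_area_cm2: float) -> np.ndarray:
        return self.areas * pixel_area_cm2


def load_mask_series(path) -> MaskSeries:
    """Read a MaskSeries written by :func:`pcmr.core.write_results`."""
    with np.load(path) as d:
        cents = [None if np.isnan(c[0]) else (float(c[0]), float(c[1]))
                 for c in d["centroids"]]
        return MaskSeries(masks=d["masks"], centroids=cents,
                          seed_phase=int(d["seed_phase"]),
                          flow_sign=int(d["flow_sign"]), areas=d["areas"])


def default_init_phase(series: PCSeries, flow_kind: str) -> int:
    """Suggested phase for drawing the rough ROI: mid-cycle for transmitral
    flow (the valve is open in diastole), start of cycle for aortic flow."""
    if flow_kind == "mitral":
        return series.n_phases // 2
    if flow_kind == "aortic":
        return 0
    raise ValidationError(f"flow_kind must be 'mitral' or 'aortic', got {flow_kind!r}")


def reference_phase(series: PCSeries, roi: Roi) -> tuple[int, int]:
    """Phase of highest |mean ROI velocity| and the sign of that mean.

    Ties go to the earliest phase.  An all-zero mean curve means there is no
    flow to segment and raises :class:`SegmentationError`.
    """
    m = roi.to_mask(series.shape)
    if not m.any():
        raise SegmentationError("ROI rasterises to an empty mask")
    means = series.velocity[:, m].mean(axis=1)
    idx = int(np.argmax(np.abs(means)))
    if np.abs(means[idx]) == 0.0:
        raise SegmentationError("no flow detected in ROI")
    return idx, (1 if means[idx] > 0 else -1)


def _component_table(velocity_image: np.ndarray, sign: int,
                     search_region: np.ndarray, min_area: int):
    """Label same-signed components inside the search region.

    Returns (labels image, list of (label, size, centroid)) with components
    below ``min_area`` dropped.
    """
    cand = search_region & (sign * velocity_image > 0)
    labels = cc_label(cand, connectivity=2)
    out = []
    if labels.max():
        sizes = np.bincount(labels.ravel())
        coms = ndimage.center_of_mass(cand, labels, np.arange(1, labels.max() + 1))
        for lab in range(1, labels.max() + 1):
            if sizes[lab] >= min_area:
                out.append((lab, int(sizes[lab]), coms[lab - 1]))
    return labels, out


def _pick_largest(labels: np.ndarray, table: list) -> np.ndarray:
    """Largest component; ties by lexicographically smallest centroid."""
    best = min(table, key=lambda t: (-t[1], t[2]))
    return labels == best[0]


def largest_signed_component(velocity_image: np.ndarray, sign: int,
                             search_region: np.ndarray,
                             required_point: tuple[int, int] | None = None,
                             min_area: int = 1) -> np.ndarray:
    """Biggest 8-connected component of sign-matching pixels.

    Considers pixels of ``search_region`` where ``sign(velocity) == sign``
    (strictly; zero velocity belongs to neither sign).  With a
    ``required_point``, only the component containing that pixel qualifies.
    An all-False mask is a valid result when no component qualifies.
    """
    if not np.any(search_region):
        raise ValidationError("search_region is empty")
    if sign not in (1, -1):
        raise ValidationError("sign must be +1 or -1")
    labels, table = _component_table(velocity_image, sign, search_region, min_area)
    empty = np.zeros(velocity_image.shape, dtype=bool)
    if not table:
        return empty
    if required_point is not None:
        lab = labels[required_point[0], required_point[1]]
        if lab and any(t[0] == lab for t in table):
            return labels == lab
        return empty
    return _pick_largest(labels, table)


def _round_point(com: tuple[float, float], shape: tuple[int, int]) -> tuple[int, int]:
    r = int(np.floor(com[0] + 0.5))
    c = int(np.floor(com[1] + 0.5))
    return (min(max(r, 0), shape[0] - 1), min(max(c, 0), shape[1] - 1))


def _track_step(velocity_image: np.ndarray, sign: int, search: np.ndarray,
                point: tuple[int, int]) -> np.ndarray | None:
    """Mask for one phase given the propagated point; None when nothing fits."""
    labels, table = _component_table(velocity_image, sign, search,
                                     MIN_COMPONENT_PX)
    if not table:
        return None
    lab = labels[point[0], point[1]]
    if lab and any(t[0] == lab for t in table):
        return labels == lab
    # point fell on a wrong-sign pixel: accept the largest component whose
    # nearest pixel is within tolerance (handles valve-closed phases)
    near = []
    for t in table:
        comp_px = np.argwhere(labels == t[0])
        d = np.sqrt(((comp_px - np.array(point)) ** 2).sum(axis=1)).min()
        if d <= POINT_TOLERANCE_PX:
            near.append(t)
    if not near:
        return None
    return _pick_largest(labels, near)


def segment_flow(series: PCSeries, roi: Roi, flow_kind: str) -> MaskSeries:
    """Track the mitral or aortic flow pattern over the whole cycle.

    See the module docstring for the three-step algorithm.  Phases where the
    flow vanishes get an empty mask and the previous centroid is carried
    forward so tracking can resume when the flow reappears.
    """
    if series.series_kind != "flow":
        raise ValidationError("segment_flow requires a flow series")
    if flow_kind not in ("mitral", "aortic"):
        raise ValidationError(f"flow_kind must be 'mitral' or 'aortic', got {flow_kind!r}")
    roi_mask = roi.to_mask(series.shape)
    if roi_mask.sum() < MIN_ROI_PX:
        raise ValidationError(
            f"rough ROI must enclose >= {MIN_ROI_PX} pixels, got {int(roi_mask.sum())}")
    search = ndimage.binary_dilation(roi_mask, structure=disk(SEARCH_DILATION_PX))

    ref, sign = reference_phase(series, roi)
    init = largest_signed_component(series.velocity[ref], sign, search,
                                    required_point=None, min_area=MIN_COMPONENT_PX)
    if not init.any():
        raise SegmentationError("initialization failed: no signed component in ROI")

    P = series.n_phases
    masks = np.zeros((P,) + series.shape, dtype=bool)
    masks[ref] = init
    centroids: list = [None] * P
    centroids[ref] = ndimage.center_of_mass(init)

    for direction in (1, -1):
        point = _round_point(centroids[ref], series.shape)
        p = ref + direction
        while 0 <= p < P:
            m = _track_step(series.velocity[p], sign, search, point)
            if m is not None:
                masks[p] = m
                centroids[p] = ndimage.center_of_mass(m)
                point = _round_point(centroids[p], series.shape)
            p += direction

    ms = MaskSeries(masks=masks, centroids=centroids, seed_phase=ref,
                    flow_sign=sign)
    logger.info("segmented %s flow: reference phase %d, sign %+d, "
                "mask areas %d-%d px", flow_kind, ref, sign,
                int(ms.areas.min()), int(ms.areas.max()))
    return ms
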