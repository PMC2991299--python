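"""Core data model and I/O for phase-contrast cardiac MR (PC-CMR) velocity series.

A PC-CMR acquisition yields, for every cardiac phase of a retrospectively
ECG-gated cycle, a modulus (magnitude) image and a velocity-encoded phase
image.  After decoding, the phase image holds the through-plane velocity in
cm/s, signed by direction, with full phase scale mapping to the encoding
velocity ``venc``.  This module defines the in-memory containers shared by all
analysis stages (:class:`PCSeries`, :class:`Roi`, :class:`TimeCurve`), the
raw-phase to velocity decoding, and reading/writing of series and results.

Conventions
-----------
* pixel coordinates are 0-based ``(row, col)``; pixel centres sit at integer
  positions and region membership is pixel-centre-in-shape;
* the time of cardiac phase ``i`` is ``i * frame_interval`` ms, with phase 0
  at the ECG R-wave;
* aliased pixels (|v| at the venc bound) are kept, counted and logged — no
  phase unwrapping is attempted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("pcmr")

SERIES_KINDS = ("flow", "myocardial")


class PcmrError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PcmrError):
    """Input data violate a structural invariant."""


class SegmentationError(PcmrError):
    """Segmentation could not be initialised or tracked."""


class CurveError(PcmrError):
    """A curve landmark could not be extracted."""


# ---------------------------------------------------------------------------
# velocity decoding
# ---------------------------------------------------------------------------

def decode_velocity(raw_phase_stack: np.ndarray, venc: float,
                    raw_fullscale: int) -> np.ndarray:
    """Map raw phase values linearly onto velocities in cm/s.

    A raw value of ``+raw_fullscale`` corresponds to ``+venc`` cm/s, 0 to
    0 cm/s; the mapping is linear and sign-preserving.

    Raises
    ------
    ValidationError
        If any raw value falls outside ``[-raw_fullscale, +raw_fullscale]``;
        the message identifies the first offending phase.
    """
    if raw_fullscale <= 0:
        raise ValidationError(f"raw_fullscale must be > 0, got {raw_fullscale}")
    raw = np.asarray(raw_phase_stack)
    out_of_range = (raw < -raw_fullscale) | (raw > raw_fullscale)
    if np.any(out_of_range):
        if raw.ndim >= 3:
            bad = np.where(out_of_range.reshape(raw.shape[0], -1).any(axis=1))[0]
            raise ValidationError(
                f"raw phase values outside [-{raw_fullscale}, {raw_fullscale}] "
                f"in phase(s) {bad.tolist()}")
        raise ValidationError(
            f"raw phase values outside [-{raw_fullscale}, {raw_fullscale}]")
    return raw.astype(np.float64) / float(raw_fullscale) * float(venc)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PCSeries:
    """Paired modulus/velocity image stacks over one cardiac cycle.

    Parameters
    ----------
    modulus, velocity : ndarray, shape (P, H, W)
        Magnitude images (arbitrary units) and decoded velocities (cm/s,
        signed).  ``P`` cardiac phases of ``H x W`` pixels, ``P >= 8``.
    frame_interval : float
        Milliseconds per cardiac phase.
    venc : float
        Encoding velocity in cm/s; ``|velocity| <= venc`` everywhere.
    pixel_spacing : (float, float)
        (row, col) pixel size in mm.
    series_kind : {'flow', 'myocardial'}
    """

    modulus: np.ndarray
    velocity: np.ndarray
    frame_interval: float
    venc: float
    pixel_spacing: tuple[float, float]
    series_kind: str

    def __post_init__(self) -> None:
        self.modulus = np.asarray(self.modulus, dtype=np.float64)
        self.velocity = np.asarray(self.velocity, dtype=np.float64)
        self.pixel_spacing = (float(self.pixel_spacing[0]),
                              float(self.pixel_spacing[1]))
        if self.modulus.ndim != 3 or self.velocity.ndim != 3:
            raise ValidationError("modulus and velocity must be (P, H, W) stacks")
        if self.modulus.shape != self.velocity.shape:
            raise ValidationError(
                f"modulus shape {self.modulus.shape} != velocity shape "
                f"{self.velocity.shape}")
        if self.n_phases < 8:
            raise ValidationError(f"need at least 8 cardiac phases, got {self.n_phases}")
        if self.frame_interval <= 0:
            raise ValidationError("frame_interval must be > 0")
        if min(self.pixel_spacing) <= 0:
            raise ValidationError("pixel_spacing must be > 0")
        if self.series_kind not in SERIES_KINDS:
            raise ValidationError(
                f"series_kind must be one of {SERIES_KINDS}, got {self.series_kind!r}")
        vmax = np.abs(self.velocity).max()
        if vmax > self.venc + 1e-9:
            raise ValidationError(
                f"|velocity| exceeds venc={self.venc}: max {vmax:.3f} cm/s")
        n_alias = int(np.sum(np.isclose(np.abs(self.velocity), self.venc)))
        if n_alias:
            logger.warning("%d pixel(s) at the venc bound — possible aliasing "
                           "(kept, not unwrapped)", n_alias)

    @property
    def n_phases(self) -> int:
        return self.modulus.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.modulus.shape[1], self.modulus.shape[2]

    @property
    def cycle_length(self) -> float:
        """Cardiac cycle length in ms (= P * frame_interval)."""
        return self.n_phases * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Time of each phase in ms (phase i at i * frame_interval)."""
        return np.arange(self.n_phases) * self.frame_interval

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1] / 100.0


@dataclass
class Roi:
    """Rough region of interest drawn on a single cardiac phase.

    ``shape`` is ``'polygon'`` (coordinates: (N, 2) array of (row, col)
    vertices) or ``'ellipse'`` (coordinates: dict with ``center`` (row, col),
    ``radii`` (r_row, r_col) in pixels and optional ``rotation_deg``).
    Membership is pixel-centre-in-shape.
    """

    phase_index: int
    shape: str = "polygon"
    coordinates: Any = None

    def __post_init__(self) -> None:
        if self.shape not in ("polygon", "ellipse"):
            raise ValidationError(f"unknown ROI shape {self.shape!r}")
        if self.shape == "polygon":
            self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
            if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2 \
                    or self.coordinates.shape[0] < 3:
                raise ValidationError("polygon ROI needs >= 3 (row, col) vertices")

    def validate_bounds(self, image_shape: tuple[int, int]) -> None:
        h, w = image_shape
        if self.shape == "polygon":
            r, c = self.coordinates[:, 0], self.coordinates[:, 1]
            if r.min() < 0 or c.min() < 0 or r.max() > h - 1 or c.max() > w - 1:
                raise ValidationError("ROI vertices outside image bounds")
        else:
            cr, cc = self.coordinates["center"]
            rr, rc = self.coordinates["radii"]
            if cr - rr < 0 or cc - rc < 0 or cr + rr > h - 1 or cc + rc > w - 1:
                raise ValidationError("ROI ellipse outside image bounds")

    def to_mask(self, image_shape: tuple[int, int]) -> np.ndarray:
        """Rasterise to a boolean (H, W) mask (pixel-centre inclusion)."""
        self.validate_bounds(image_shape)
        if self.shape == "polygon":
            from skimage.draw import polygon2mask
            return polygon2mask(image_shape, self.coordinates)
        cr, cc = self.coordinates["center"]
        rr, rc = self.coordinates["radii"]
        theta = np.deg2rad(self.coordinates.get("rotation_deg", 0.0))
        r, c = np.mgrid[0:image_shape[0], 0:image_shape[1]].astype(np.float64)
        dr, dc = r - cr, c - cc
        u = np.cos(theta) * dc + np.sin(theta) * dr
        v = -np.sin(theta) * dc + np.cos(theta) * dr
        return (u / rc) ** 2 + (v / rr) ** 2 <= 1.0

    def to_dict(self) -> dict:
        coords = self.coordinates
        if self.shape == "polygon":
            coords = np.asarray(coords).tolist()
        return {"phase_index": int(self.phase_index), "shape": self.shape,
                "coordinates": coords}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Roi":
        return cls(phase_index=int(d["phase_index"]), shape=d["shape"],
                   coordinates=d["coordinates"])


def load_roi(path: str | Path) -> Roi:
    with open(path) as fh:
        return Roi.from_dict(json.load(fh))


def save_roi(roi: Roi, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(roi.to_dict(), fh, indent=2, sort_keys=True)


@dataclass
class TimeCurve:
    """Sampled curve over the cardiac cycle, piecewise linear between samples.

    times are in ms and strictly increasing (one sample per cardiac phase);
    values carry the unit named by ``unit`` ('cm/s' or 'ml/s').
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError("times and values must be 1-D and equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def interp(self, t: float | np.ndarray) -> float | np.ndarray:
        return np.interp(t, self.times, self.values)

    def scaled(self, c: float) -> "TimeCurve":
        return TimeCurve(self.times.copy(), self.values * c, self.unit)

    def integral(self, t0: float, t1: float, clip_negative: bool = False) -> float:
        """Exact integral of the piecewise-linear curve over [t0, t1].

        Result is in ``unit`` x seconds (times are ms, divided by 1000), so a
        flow-rate curve in ml/s integrates to ml.  With ``clip_negative``,
        negative *samples* are set to 0 before integrating.
        """
        if t1 < t0:
            raise ValidationError("integral bounds must satisfy t0 <= t1")
        lo = max(t0, self.times[0])
        hi = min(t1, self.times[-1])
        if hi <= lo:
            return 0.0
        vals = np.maximum(self.values, 0.0) if clip_negative else self.values
        inner = (self.times > lo) & (self.times < hi)
        ts = np.concatenate(([lo], self.times[inner], [hi]))
        vs = np.interp(ts, self.times, vals)
        return float(np.trapezoid(vs, ts) / 1000.0)


# ---------------------------------------------------------------------------
# series containers (NIfTI + JSON sidecar) and DICOM reading
# ---------------------------------------------------------------------------

_SIDECAR = "series.json"
_MOD_FILE = "modulus.nii"
_VEL_FILE = "velocity.nii"


def write_pc_series(series: PCSeries, out_dir: str | Path,
                    overwrite: bool = False) -> Path:
    """Write a series as two NIfTI stacks plus a JSON metadata sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = [out / _MOD_FILE, out / _VEL_FILE, out / _SIDECAR]
    if not overwrite:
        existing = [str(p) for p in targets if p.exists()]
        if existing:
            raise PcmrError(f"refusing to overwrite existing file(s): {existing}")
    # NIfTI is (i, j, k) = (row, col, phase); stacks are (P, H, W) in memory.
    for arr, path in ((series.modulus, targets[0]), (series.velocity, targets[1])):
        img = nib.Nifti1Image(np.transpose(arr, (1, 2, 0)), affine=np.eye(4))
        nib.save(img, str(path))
    meta = {
        "venc_cm_s": series.venc,
        "frame_interval_ms": series.frame_interval,
        "pixel_spacing_mm": list(series.pixel_spacing),
        "series_kind": series.series_kind,
        "n_phases": series.n_phases,
        "cycle_length_ms": series.cycle_length,
    }
    with open(targets[2], "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return out


def _load_container(path: Path) -> PCSeries:
    import nibabel as nib

    sidecar = path / _SIDECAR
    if not sidecar.exists():
        raise ValidationError(f"no {_SIDECAR} sidecar in {path}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    for key in ("venc_cm_s", "frame_interval_ms", "pixel_spacing_mm", "series_kind"):
        if key not in meta:
            raise ValidationError(f"sidecar missing required key {key!r}"
                                  + (" (venc is never guessed)" if key == "venc_cm_s" else ""))
    modulus = np.transpose(np.asanyarray(nib.load(str(path / _MOD_FILE)).dataobj), (2, 0, 1))
    velocity = np.transpose(np.asanyarray(nib.load(str(path / _VEL_FILE)).dataobj), (2, 0, 1))
    series = PCSeries(
        modulus=modulus, velocity=velocity,
        frame_interval=float(meta["frame_interval_ms"]),
        venc=float(meta["venc_cm_s"]),
        pixel_spacing=tuple(meta["pixel_spacing_mm"]),
        series_kind=meta["series_kind"],
    )
    if "cycle_length_ms" in meta and not np.isclose(
            float(meta["cycle_length_ms"]), series.cycle_length):
        raise ValidationError(
            f"sidecar cycle_length_ms={meta['cycle_length_ms']} inconsistent with "
            f"P x frame_interval = {series.cycle_length}")
    logger.info("loaded %s series: P=%d, venc=%.1f cm/s, dt=%.1f ms, "
                "spacing=%s mm", series.series_kind, series.n_phases,
                series.venc, series.frame_interval, series.pixel_spacing)
    return series


def _is_phase_dicom(ds) -> bool:
    image_type = [t.upper() for t in getattr(ds, "ImageType", [])]
    return any(t in ("P", "PHASE", "V", "VELOCITY") for t in image_type)


def _is_magnitude_dicom(ds) -> bool:
    image_type = [t.upper() for t in getattr(ds, "ImageType", [])]
    return any(t in ("M", "MAG", "MAGNITUDE") for t in image_type)


def _load_dicom(path: Path, venc: float | None, series_kind: str,
                raw_fullscale: int | None) -> PCSeries:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    mags, phases = [], []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if _is_phase_dicom(ds):
            phases.append(ds)
        elif _is_magnitude_dicom(ds):
            mags.append(ds)
    if not phases:
        raise ValidationError("phase series not found")
    if not mags:
        raise ValidationError("magnitude series not found")
    if len(mags) != len(phases):
        raise ValidationError(
            f"magnitude/phase count mismatch: {len(mags)} vs {len(phases)}")
    if venc is None:
        raise ValidationError(
            "venc not provided: DICOM venc tags are vendor-dependent; pass it "
            "explicitly (it is never guessed)")
    key = lambda ds: float(getattr(ds, "TriggerTime", 0.0))
    mags.sort(key=key)
    phases.sort(key=key)
    trig = np.array([key(ds) for ds in phases])
    intervals = np.diff(trig)
    if len(intervals) and not np.allclose(intervals, intervals[0], atol=1e-6):
        raise ValidationError(
            f"non-uniform frame intervals: {np.unique(np.round(intervals, 6)).tolist()}")
    frame_interval = float(intervals[0]) if len(intervals) else 1.0
    spacing = tuple(float(s) for s in phases[0].PixelSpacing)

    def pixels(ds):
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept

    modulus = np.stack([pixels(ds) for ds in mags])
    raw_phase = np.stack([pixels(ds) for ds in phases])
    if raw_fullscale is None:
        bits = int(getattr(phases[0], "BitsStored", 12))
        raw_fullscale = 2 ** (bits - 1)
    velocity = decode_velocity(raw_phase, venc, raw_fullscale)
    return PCSeries(modulus=modulus, velocity=velocity,
                    frame_interval=frame_interval, venc=venc,
                    pixel_spacing=spacing, series_kind=series_kind)


def load_pc_series(path: str | Path, format: str = "auto", *,
                   venc: float | None = None, series_kind: str = "flow",
                   raw_fullscale: int | None = None) -> PCSeries:
    """Load a PC series from a NIfTI container directory or a DICOM directory.

    For DICOM input the encoding velocity must be supplied via ``venc`` —
    vendor tags are unreliable and the value is never guessed.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"series path does not exist: {path}")
    if format == "auto":
        format = "container" if (path / _SIDECAR).exists() else "dicom"
    if format == "container":
        return _load_container(path)
    if format == "dicom":
        return _load_dicom(path, venc, series_kind, raw_fullscale)
    raise ValidationError(f"unknown series format {format!r}")


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------

def _params_to_row(params: Any) -> dict[str, Any]:
    if dataclasses.is_dataclass(params) and hasattr(params, "to_row"):
        return params.to_row()
    if dataclasses.is_dataclass(params):
        return dataclasses.asdict(params)
    return dict(params)


def write_results(out_dir: str | Path, *, params: Any | None = None,
                  curves: Mapping[str, TimeCurve] | None = None,
                  masks: Any | None = None, seed: int | None = None,
                  overwrite: bool = False,
                  extra_meta: Mapping[str, Any] | None = None) -> list[Path]:
    """Write parameters (JSON + one-row CSV), curves (CSV) and masks (npz).

    Existing files are refused unless ``overwrite`` is set; on failure,
    partially written files from this call are removed.  Output is
    byte-reproducible for identical inputs (no timestamps).
    """
    import pandas as pd
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    planned: list[Path] = []
    if params is not None:
        planned += [out / "params.json", out / "params.csv"]
    if curves:
        planned += [out / "curves.csv"]
    elif curves is not None:
        logger.info("empty curve list: curves file omitted")
    if masks is not None:
        planned += [out / "masks.npz", out / "masks.json"]
    if not overwrite:
        existing = [str(p) for p in planned if p.exists()]
        if existing:
            raise PcmrError(f"refusing to overwrite existing file(s): {existing} "
                            "(pass overwrite=True)")
    written: list[Path] = []
    try:
        if params is not None:
            row = _params_to_row(params)
            with open(out / "params.json", "w") as fh:
                json.dump(row, fh, indent=2, sort_keys=True, default=float)
            written.append(out / "params.json")
            pd.DataFrame([row]).to_csv(out / "params.csv", index=False)
            written.append(out / "params.csv")
        if curves:
            names = list(curves)
            base = curves[names[0]].times
            for n in names[1:]:
                if not np.array_equal(curves[n].times, base):
                    raise ValidationError("curves must share the same time axis")
            df = pd.DataFrame({"time_ms": base})
            for n in names:
                df[n] = curves[n].values
            df.to_csv(out / "curves.csv", index=False)
            written.append(out / "curves.csv")
        if masks is not None:
            np.savez(out / "masks.npz",
                     masks=np.asarray(masks.masks, dtype=bool),
                     centroids=np.array(
                         [c if c is not None else (np.nan, np.nan)
                          for c in masks.centroids], dtype=np.float64),
                     areas=np.asarray(masks.areas, dtype=np.int64),
                     seed_phase=masks.seed_phase, flow_sign=masks.flow_sign)
            written.append(out / "masks.npz")
            sidecar = {"n_phases": int(np.asarray(masks.masks).shape[0]),
                       "software": "pcmr", "version": __version__,
                       "seed": seed}
            if extra_meta:
                sidecar.update(extra_meta)
            with open(out / "masks.json", "w") as fh:
                json.dump(sidecar, fh, indent=2, sort_keys=True, default=float)
            written.append(out / "masks.json")
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return written
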