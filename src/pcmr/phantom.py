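"""Synthetic PC-CMR phantoms with exactly known ground truth.

Two phantoms mimic the acquisitions the pipeline analyses:

* the **flow phantom** — a transmitral jet with a biphasic (E/A) triangular
  waveform and parabolic spatial profile, an opposite-signed aortic jet active
  during systole, and tissue annuli around both orifices carrying a
  longitudinal S'/E'/A' waveform, as the myocardium surrounding a jet does on
  real basal velocity images (the sign contrast between jet and surrounding
  tissue is precisely what the connectivity-based segmentation exploits);
* the **myocardial phantom** — a myocardial ring moving with the S'/E'/A'
  waveform, a cavity filled with per-pixel erratic "blood" profiles, and a
  near-static background, which is what the k-means profile clustering has to
  disentangle.

Seeded Gaussian noise is added everywhere and velocities beyond the encoding
velocity wrap (alias) as they would physically.  Waveforms are triangular by
default so every landmark the pipeline extrapolates (40-70% limb fits) is
analytically exact and recovery error measures the implementation, not model
mismatch; a raised-cosine option exercises robustness to curved limbs.

Default timing/geometry follows a typical acquisition: 15 ms frames for flow
(venc 180 cm/s), 20 ms for tissue (venc 15 cm/s), 1.9 x 1.9 mm pixels, and a
900 ms cycle.  Default truth values sit at healthy-control magnitudes
(E = 80 cm/s, A = 60 cm/s, DT = 185 ms, IVRT = 78 ms, E' = 11.3 cm/s).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import PCSeries, Roi, ValidationError


def _wave(t: np.ndarray, t0: float, tp: float, t1: float, peak: float,
          shape: str = "triangular") -> np.ndarray:
    """One unimodal wave: 0 at t0, peak at tp, back to 0 at t1, 0 outside."""
    t = np.asarray(t, dtype=np.float64)
    out = np.zeros_like(t)
    up = (t >= t0) & (t <= tp)
    down = (t > tp) & (t <= t1)
    if shape == "triangular":
        if tp > t0:
            out[up] = peak * (t[up] - t0) / (tp - t0)
        down_dur = t1 - tp
        if down_dur > 0:
            out[down] = peak * (t1 - t[down]) / down_dur
    elif shape == "raised_cosine":
        if tp > t0:
            out[up] = peak * 0.5 * (1 - np.cos(np.pi * (t[up] - t0) / (tp - t0)))
        if t1 > tp:
            out[down] = peak * 0.5 * (1 + np.cos(np.pi * (t[down] - tp) / (t1 - tp)))
    else:
        raise ValidationError(f"unknown waveform shape {shape!r}")
    return out


@dataclass
class PhantomConfig:
    """Geometry, timing and ground-truth waveform parameters of the phantoms.

    All spatial sizes are mm, velocities cm/s, times ms.  The flow and
    myocardial factory defaults (:meth:`flow_default`, :meth:`myo_default`)
    encode the acquisition settings described in the module docstring.
    """

    grid: tuple[int, int] = (96, 96)
    n_phases: int = 60
    frame_interval_ms: float = 15.0
    pixel_spacing_mm: float = 1.9
    venc_cm_s: float = 180.0
    waveform_shape: str = "triangular"
    noise_sd: float = 2.0
    background_offset: float = 0.0

    # transmitral jet
    mitral_centre: tuple[int, int] = (48, 32)
    mitral_radius_mm: float = 15.0
    E_true: float = 80.0
    A_true: float = 60.0
    t_E: float = 540.0
    t_A: float = 780.0
    DT_true: float = 185.0
    IVRT_true: float = 78.0
    A_rise_ms: float = 55.0
    A_fall_ms: float = 90.0

    # aortic jet (opposite sign, systolic)
    aortic_centre: tuple[int, int] = (48, 72)
    aortic_radius_mm: float = 9.0
    aortic_peak: float = 100.0
    aortic_onset: float = 60.0
    aortic_t_peak: float = 200.0
    eject_end: float = 420.0

    # longitudinal tissue waveform (annuli of the flow phantom and the ring
    # of the myocardial phantom); S' is systolic, E'/A' diastolic, signs as
    # seen against a positive transmitral jet
    S_prime: float = 8.0
    E_prime_true: float = 10.0
    A_prime: float = 5.0
    t_S: tuple[float, float, float] = (60.0, 210.0, 420.0)
    t_Ep: tuple[float, float, float] = (480.0, 560.0, 660.0)
    t_Ap: tuple[float, float, float] = (780.0, 860.0, 900.0)

    # tissue annuli of the flow phantom (outer radii; inner = orifice radius);
    # diastasis_drift is a small residual annular velocity between the E' and
    # A' excursions — real tissue never sits at exactly zero, and leaving it
    # there would make pixel sign a pure coin flip under noise
    mitral_ring_outer_mm: float = 26.0
    aortic_ring_outer_mm: float = 15.0
    diastasis_drift: float = -1.5
    drift_ramp_ms: float = 30.0

    # myocardial phantom geometry
    ring_centre: tuple[int, int] = (48, 48)
    ring_inner_mm: float = 22.0
    ring_outer_mm: float = 32.0
    cavity_amp_range: tuple[float, float] = (6.0, 12.0)
    cavity_offset_range: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        if self.n_phases < 8 or self.frame_interval_ms <= 0:
            raise ValidationError("need >= 8 phases and a positive frame interval")
        if self.ring_inner_mm >= self.ring_outer_mm:
            raise ValidationError("ring radii inverted")
        if self.t_A - self.t_E < self.cycle_length / 6.0:
            raise ValidationError("E/A peak separation below one sixth of the cycle")
        if self.t_fill_start >= self.t_E:
            raise ValidationError("IVRT leaves no room for the E-wave upstroke")
        if self.t_E + self.DT_true > self.t_A - self.A_rise_ms:
            raise ValidationError("waves overlap: E wave ends after the A wave starts")
        if self.t_fill_end > self.cycle_length:
            raise ValidationError("A wave extends past the cycle end")

    # -- derived timing -----------------------------------------------------
    @property
    def cycle_length(self) -> float:
        return self.n_phases * self.frame_interval_ms

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.frame_interval_ms

    @property
    def t_fill_start(self) -> float:
        return self.eject_end + self.IVRT_true

    @property
    def t_fill_end(self) -> float:
        return self.t_A + self.A_fall_ms

    @classmethod
    def flow_default(cls, **overrides) -> "PhantomConfig":
        return cls(**overrides)

    @classmethod
    def myo_default(cls, **overrides) -> "PhantomConfig":
        defaults = dict(n_phases=45, frame_interval_ms=20.0, venc_cm_s=15.0,
                        noise_sd=0.5, E_prime_true=11.3)
        defaults.update(overrides)
        return cls(**defaults)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            d = json.load(fh)
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)


@dataclass
class PhantomTruth:
    """Generator ground truth: per-phase true masks and true parameter values."""

    params: dict
    seed: int
    mitral_masks: np.ndarray | None = None
    aortic_masks: np.ndarray | None = None
    ring_mask: np.ndarray | None = None

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "truth.json", "w") as fh:
            json.dump({"params": self.params, "seed": self.seed}, fh,
                      indent=2, sort_keys=True, default=float)
        arrays = {}
        for name in ("mitral_masks", "aortic_masks", "ring_mask"):
            val = getattr(self, name)
            if val is not None:
                arrays[name] = val
        if arrays:
            np.savez(out / "truth_masks.npz", **arrays)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def transmitral_waveform(t, cfg: PhantomConfig) -> np.ndarray:
    """Centre velocity (cm/s) of the transmitral jet at time(s) t.

    Sum of the E wave (rising from the start of filling to ``E_true`` at
    ``t_E``, back to 0 after ``DT_true``) and the A wave (peak ``A_true`` at
    ``t_A``); zero elsewhere.  Overlapping supports are rejected at config
    construction.
    """
    e = _wave(np.atleast_1d(t), cfg.t_fill_start, cfg.t_E,
              cfg.t_E + cfg.DT_true, cfg.E_true, cfg.waveform_shape)
    a = _wave(np.atleast_1d(t), cfg.t_A - cfg.A_rise_ms, cfg.t_A,
              cfg.t_fill_end, cfg.A_true, cfg.waveform_shape)
    out = e + a
    return out if np.ndim(t) else float(out[0])


def aortic_waveform(t, cfg: PhantomConfig) -> np.ndarray:
    """Centre velocity of the aortic jet: systolic, opposite sign to inflow."""
    out = -_wave(np.atleast_1d(t), cfg.aortic_onset, cfg.aortic_t_peak,
                 cfg.eject_end, cfg.aortic_peak, cfg.waveform_shape)
    return out if np.ndim(t) else float(out[0])


def tissue_waveform(t, cfg: PhantomConfig, include_drift: bool = False,
                    ) -> np.ndarray:
    """Longitudinal tissue velocity: systolic S' (same sign as inflow jet),
    diastolic E' and A' excursions of opposite sign (annular recoil).

    With ``include_drift`` (used for the flow phantom's scenery annuli) a
    small residual diastolic velocity ramps in after the end of ejection, so
    the annulus never sits at exactly zero between the E' and A' waves.
    """
    t1 = np.atleast_1d(t)
    out = (_wave(t1, *cfg.t_S, cfg.S_prime, cfg.waveform_shape)
           - _wave(t1, *cfg.t_Ep, cfg.E_prime_true, cfg.waveform_shape)
           - _wave(t1, *cfg.t_Ap, cfg.A_prime, cfg.waveform_shape))
    if include_drift and cfg.diastasis_drift:
        ramp = np.clip((t1 - cfg.eject_end) / cfg.drift_ramp_ms, 0.0, 1.0)
        out = out + cfg.diastasis_drift * ramp
    return out if np.ndim(t) else float(out[0])


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------

def _distance_mm(shape, centre, spacing) -> np.ndarray:
    r, c = np.mgrid[0:shape[0], 0:shape[1]].astype(np.float64)
    return np.hypot(r - centre[0], c - centre[1]) * spacing


def _wrap(v: np.ndarray, venc: float) -> np.ndarray:
    """Phase wrapping: velocities beyond +/-venc alias back into range."""
    return np.mod(v + venc, 2 * venc) - venc


def _true_flow_params(cfg: PhantomConfig, profile_sum_cm2: float) -> dict:
    """Analytic truth for every parameter the flow pipeline estimates.

    ``profile_sum_cm2`` is the pixelised integral of the spatial profile
    (sum over jet pixels of the parabola, times pixel area), so the true
    flow rate is ``waveform(t) * profile_sum_cm2`` and FV is its closed-form
    time integral (exact for triangles).
    """
    # both wave shapes integrate to half-height x support
    t_e_end = cfg.t_E + cfg.DT_true
    area_e = 0.5 * cfg.E_true * (t_e_end - cfg.t_fill_start) / 1000.0
    area_a = 0.5 * cfg.A_true * (cfg.t_fill_end - (cfg.t_A - cfg.A_rise_ms)) / 1000.0
    ef = cfg.E_true * profile_sum_cm2
    af = cfg.A_true * profile_sum_cm2
    fv = (area_e + area_a) * profile_sum_cm2
    return {
        "E": cfg.E_true, "A": cfg.A_true, "EA_ratio": cfg.E_true / cfg.A_true,
        "Ef": ef, "Af": af, "EfAf_ratio": ef / af, "FV": fv,
        "Ef_over_FV": ef / fv, "DT": cfg.DT_true, "IVRT": cfg.IVRT_true,
        "t_E": cfg.t_E, "t_A": cfg.t_A, "eject_end": cfg.eject_end,
        "t_fill_start": cfg.t_fill_start, "t_fill_end": cfg.t_fill_end,
    }


def make_flow_phantom(cfg: PhantomConfig | None = None, seed: int = 0,
                      ) -> tuple[PCSeries, PhantomTruth]:
    """Flow-series phantom: transmitral + aortic jets inside tissue annuli."""
    if cfg is None:
        cfg = PhantomConfig.flow_default()
    peak_centre = max(cfg.E_true, cfg.A_true, cfg.aortic_peak,
                      cfg.S_prime, cfg.E_prime_true, cfg.A_prime)
    if peak_centre >= cfg.venc_cm_s:
        raise ValidationError(
            f"true velocity {peak_centre} cm/s >= venc {cfg.venc_cm_s}: would alias")

    H, W = cfg.grid
    d_m = _distance_mm(cfg.grid, cfg.mitral_centre, cfg.pixel_spacing_mm)
    d_a = _distance_mm(cfg.grid, cfg.aortic_centre, cfg.pixel_spacing_mm)
    if d_m[cfg.aortic_centre] <= cfg.mitral_ring_outer_mm + cfg.aortic_radius_mm:
        raise ValidationError("mitral and aortic structures overlap")

    prof_m = np.where(d_m < cfg.mitral_radius_mm,
                      1.0 - (d_m / cfg.mitral_radius_mm) ** 2, 0.0)
    prof_a = np.where(d_a < cfg.aortic_radius_mm,
                      1.0 - (d_a / cfg.aortic_radius_mm) ** 2, 0.0)
    ring_m = (d_m >= cfg.mitral_radius_mm) & (d_m <= cfg.mitral_ring_outer_mm)
    ring_a = (d_a >= cfg.aortic_radius_mm) & (d_a <= cfg.aortic_ring_outer_mm)

    t = cfg.times
    w_m = transmitral_waveform(t, cfg)
    w_a = aortic_waveform(t, cfg)
    w_t = tissue_waveform(t, cfg, include_drift=True)

    clean = (w_m[:, None, None] * prof_m[None]
             + w_a[:, None, None] * prof_a[None]
             + w_t[:, None, None] * (ring_m | ring_a)[None]
             + cfg.background_offset)
    rng = np.random.default_rng(seed)
    velocity = _wrap(clean + rng.normal(0.0, cfg.noise_sd, clean.shape)
                     if cfg.noise_sd > 0 else clean.copy(), cfg.venc_cm_s)

    modulus = np.full((cfg.n_phases, H, W), 80.0)
    modulus[:, prof_m > 0] = 240.0
    modulus[:, prof_a > 0] = 240.0
    modulus[:, ring_m | ring_a] = 160.0

    series = PCSeries(modulus=modulus, velocity=velocity,
                      frame_interval=cfg.frame_interval_ms,
                      venc=cfg.venc_cm_s,
                      pixel_spacing=(cfg.pixel_spacing_mm, cfg.pixel_spacing_mm),
                      series_kind="flow")

    jet_m = prof_m > 0
    jet_a = prof_a > 0
    mitral_masks = (w_m[:, None, None] > 0) & jet_m[None]
    aortic_masks = (w_a[:, None, None] < 0) & jet_a[None]
    profile_sum_cm2 = float(prof_m.sum()) * series.pixel_area_cm2
    truth = PhantomTruth(params=_true_flow_params(cfg, profile_sum_cm2),
                         seed=seed, mitral_masks=mitral_masks,
                         aortic_masks=aortic_masks)
    return series, truth


def make_myo_phantom(cfg: PhantomConfig | None = None, seed: int = 0,
                     ) -> tuple[PCSeries, PhantomTruth]:
    """Tissue-series phantom: moving myocardial ring, erratic cavity blood,
    near-static background."""
    if cfg is None:
        cfg = PhantomConfig.myo_default()
    worst = max(cfg.S_prime, cfg.E_prime_true, cfg.A_prime,
                cfg.cavity_amp_range[1] + max(abs(cfg.cavity_offset_range[0]),
                                              abs(cfg.cavity_offset_range[1])))
    if worst >= cfg.venc_cm_s:
        raise ValidationError(
            f"true velocity {worst} cm/s >= venc {cfg.venc_cm_s}: would alias")

    H, W = cfg.grid
    d = _distance_mm(cfg.grid, cfg.ring_centre, cfg.pixel_spacing_mm)
    ring = (d >= cfg.ring_inner_mm) & (d <= cfg.ring_outer_mm)
    cavity = d < cfg.ring_inner_mm

    t = cfg.times
    w_t = tissue_waveform(t, cfg)
    clean = w_t[:, None, None] * ring[None].astype(np.float64)

    rng = np.random.default_rng(seed)
    n_cav = int(cavity.sum())
    amp = rng.uniform(*cfg.cavity_amp_range, n_cav)
    phase = rng.uniform(0, 2 * np.pi, n_cav)
    offs = rng.uniform(*cfg.cavity_offset_range, n_cav)
    cav_profiles = (amp[None, :] * np.sin(2 * np.pi * t[:, None] / cfg.cycle_length
                                          + phase[None, :]) + offs[None, :])
    clean[:, cavity] = cav_profiles

    velocity = _wrap(clean + rng.normal(0.0, cfg.noise_sd, clean.shape)
                     if cfg.noise_sd > 0 else clean.copy(), cfg.venc_cm_s)

    modulus = np.full((cfg.n_phases, H, W), 50.0)
    modulus[:, cavity] = 300.0
    modulus[:, ring] = 200.0

    series = PCSeries(modulus=modulus, velocity=velocity,
                      frame_interval=cfg.frame_interval_ms,
                      venc=cfg.venc_cm_s,
                      pixel_spacing=(cfg.pixel_spacing_mm, cfg.pixel_spacing_mm),
                      series_kind="myocardial")
    truth = PhantomTruth(
        params={"E_prime": cfg.E_prime_true, "t_E_prime": cfg.t_Ep[1],
                "S_prime": cfg.S_prime, "A_prime": cfg.A_prime,
                "t_fill_start": cfg.t_fill_start},
        seed=seed, ring_mask=ring)
    return series, truth


# ---------------------------------------------------------------------------
# operator emulation and ROI helpers
# ---------------------------------------------------------------------------

def circular_roi(centre: tuple[float, float], radius_px: float,
                 phase_index: int, n_vertices: int = 24) -> Roi:
    """A polygonal ROI approximating a circle (the usual rough hand drawing)."""
    ang = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    verts = np.stack([centre[0] + radius_px * np.sin(ang),
                      centre[1] + radius_px * np.cos(ang)], axis=1)
    return Roi(phase_index=phase_index, shape="polygon", coordinates=verts)


def annular_roi(centre: tuple[float, float], radius_px: float,
                phase_index: int) -> Roi:
    """Elliptical (circular) ROI; used for the rough LV region."""
    return Roi(phase_index=phase_index, shape="ellipse",
               coordinates={"center": list(centre),
                            "radii": [radius_px, radius_px]})


def perturb_roi(roi: Roi, max_shift_px: float, seed: int,
                image_shape: tuple[int, int] | None = None) -> Roi:
    """Jitter ROI vertices uniformly within +/-max_shift_px (seeded).

    Emulates a second operator's slightly different rough drawing.  The
    perturbed ROI must stay inside the image when ``image_shape`` is given;
    it may legitimately drift off the flow, in which case downstream
    segmentation fails with its own error.
    """
    rng = np.random.default_rng(seed)
    if roi.shape == "polygon":
        jitter = rng.uniform(-max_shift_px, max_shift_px, roi.coordinates.shape)
        out = Roi(phase_index=roi.phase_index, shape="polygon",
                  coordinates=roi.coordinates + jitter)
    else:
        coords = dict(roi.coordinates)
        shift = rng.uniform(-max_shift_px, max_shift_px, 2)
        coords["center"] = [coords["center"][0] + shift[0],
                            coords["center"][1] + shift[1]]
        out = Roi(phase_index=roi.phase_index, shape="ellipse", coordinates=coords)
    if image_shape is not None:
        out.validate_bounds(image_shape)
    return out
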