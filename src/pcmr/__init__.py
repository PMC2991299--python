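"""pcmr — semi-automated diastolic function analysis of PC-CMR velocity series.

Segmentation of transmitral/aortic flow patterns on velocity-encoded cardiac
MR images, extraction of velocity- and flow-rate-based diastolic parameters
(E, A, E/A, Ef, Af, Ef/Af, FV, Ef/FV, DT, IVRT), k-means isolation of the
myocardium for E' and E/E', cohort statistics, and synthetic phantoms with
known ground truth.
"""

from __future__ import annotations

__version__ = "0.1.0"

from .core import (CurveError, PCSeries, PcmrError, Roi, SegmentationError,
                   TimeCurve, ValidationError, decode_velocity, load_pc_series,
                   load_roi, save_roi, write_pc_series, write_results)
from .flowseg import (MaskSeries, default_init_phase, largest_signed_component,
                      load_mask_series, reference_phase, segment_flow)
from .curves import (DiastolicTimings, FlowCurves, FlowParameters,
                     compute_flow_parameters, detect_two_peaks,
                     end_of_ejection, flow_curves, limb_zero_crossing)
from .myocardium import (ClusterResult, MyoParameters, cluster_myocardium,
                         cluster_profiles, compute_myo_parameters,
                         detect_e_prime, myo_velocity_curves,
                         myocardial_cluster, pixel_velocity_profiles)
from .cohort import (RocResult, cohort_analysis, mann_whitney,
                     overlap_percentage, pearson, roc, variability_pct)
from .phantom import (PhantomConfig, PhantomTruth, annular_roi, circular_roi,
                      make_flow_phantom, make_myo_phantom, perturb_roi,
                      transmitral_waveform)


def analyze_flow(series: PCSeries, mitral_roi: Roi, aortic_roi: Roi):
    """Full blood-flow pipeline: segment both flows, build curves, extract
    all diastolic parameters.

    Returns ``(params, timings, mitral_seg, aortic_seg, mitral_curves)``.
    """
    mitral_seg = segment_flow(series, mitral_roi, "mitral")
    aortic_seg = segment_flow(series, aortic_roi, "aortic")
    mitral_curves = flow_curves(series, mitral_seg)
    aortic_curves = flow_curves(series, aortic_seg)
    params, timings = compute_flow_parameters(mitral_curves, aortic_curves.q,
                                              series.cycle_length)
    return params, timings, mitral_seg, aortic_seg, mitral_curves


def analyze_myocardium(series: PCSeries, roi: Roi, *, seed: int = 0,
                       filling_window: tuple[float, float] | None = None,
                       E: float | None = None):
    """Full tissue pipeline: cluster profiles, isolate the myocardium,
    compute velocity curves and E' (and E/E' when E is given).

    Returns ``(myo_params, cluster_result, global_max_curve, segments)``.
    """
    result = cluster_myocardium(series, roi, seed=seed)
    g_max, g_mean, segments = myo_velocity_curves(series, result.myocardial_mask)
    params = compute_myo_parameters(g_max, filling_window=filling_window,
                                    mean_curve=g_mean,
                                    cycle_length=series.cycle_length, E=E)
    return params, result, g_max, segments
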