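import numpy as np
import pytest

from pcmr import (PCSeries, PhantomConfig, annular_roi, circular_roi,
                  make_flow_phantom, make_myo_phantom)

# canonical rough ROIs for the default phantom geometry
MITRAL_ROI = dict(centre=(48, 32), radius_px=9.5)
AORTIC_ROI = dict(centre=(48, 72), radius_px=6.0)
MYO_ROI = dict(centre=(48, 48), radius_px=19.0)


def mitral_roi(phase_index=30, radius_px=MITRAL_ROI["radius_px"]):
    return circular_roi(MITRAL_ROI["centre"], radius_px, phase_index)


def aortic_roi(phase_index=0, radius_px=AORTIC_ROI["radius_px"]):
    return circular_roi(AORTIC_ROI["centre"], radius_px, phase_index)


def myo_roi(radius_px=MYO_ROI["radius_px"]):
    return annular_roi(MYO_ROI["centre"], radius_px, phase_index=0)


@pytest.fixture(scope="session")
def flow_phantom():
    """Default flow phantom (sigma = 2 cm/s), seed 0."""
    return make_flow_phantom(seed=0)


@pytest.fixture(scope="session")
def clean_flow_phantom():
    """Noise-free flow phantom."""
    return make_flow_phantom(PhantomConfig.flow_default(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def myo_phantom():
    """Default myocardial phantom (sigma = 0.5 cm/s), seed 0."""
    return make_myo_phantom(seed=0)


@pytest.fixture(scope="session")
def clean_myo_phantom():
    return make_myo_phantom(PhantomConfig.myo_default(noise_sd=0.0), seed=0)


def tiny_series(velocity, frame_interval=15.0, venc=180.0, kind="flow",
                spacing=(1.9, 1.9)):
    """Minimal PCSeries around a given velocity stack."""
    velocity = np.asarray(velocity, dtype=float)
    return PCSeries(modulus=np.ones_like(velocity), velocity=velocity,
                    frame_interval=frame_interval, venc=venc,
                    pixel_spacing=spacing, series_kind=kind)
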