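import numpy as np
import pytest

from wormcal.config import PipelineConfig
from wormcal.pipeline import run_video_pipeline
from wormcal.synth import WormVideoParams, gen_worm_video


def small_params(**overrides) -> WormVideoParams:
    """Reduced worm geometry used throughout the unit tests.

    Same model as the full-size defaults, just a shorter recording and a
    smaller image so per-test renders stay fast.
    """
    base = dict(
        duration=4.0,
        image_size=(96, 220),
        worm_length=150.0,
        worm_halfwidth=9.0,
        midline_wave_amplitude=9.0,
        muscle_band_width=4.0,
        noise_sd=10.0,
        seed=0,
    )
    base.update(overrides)
    return WormVideoParams(**base)


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def noiseless_video():
    """One noiseless event-free small video with its ground truth."""
    params = small_params(noise_sd=0.0, transient_rate=0.0)
    video, gt = gen_worm_video(params)
    return params, video, gt


@pytest.fixture(scope="session")
def event_video():
    """A noiseless small video guaranteed to contain scripted events."""
    for seed in range(50):
        params = small_params(noise_sd=0.0, transient_rate=0.5, seed=seed)
        video, gt = gen_worm_video(params)
        if len(gt.event_times) >= 1 and all(
            0.5 < t < params.duration - 1.5 for t in gt.event_times
        ):
            return params, video, gt
    raise RuntimeError("no suitable seed found")  # pragma: no cover


@pytest.fixture(scope="session")
def pipeline_on_event_video(event_video, default_config):
    params, video, gt = event_video
    return params, gt, run_video_pipeline(video, default_config)
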