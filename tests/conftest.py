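import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mousefield.synthetic import (
    GaitParams,
    SyntheticTrialSpec,
    generate_trial,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def locomotion_spec(
    n_bouts: int = 6,
    bout_frames: int = 320,
    gap_frames: int = 80,
    gait_params: GaitParams | list[GaitParams] | None = None,
    noise_sd_px: float = 0.5,
    seed: int = 1,
) -> SyntheticTrialSpec:
    """Trial spec alternating locomotion bouts with idle gaps."""
    segs = []
    f = 0
    for _ in range(n_bouts):
        segs.append(("locomotion", f, f + bout_frames))
        f += bout_frames
        if gap_frames > 0:
            segs.append(("idle", f, f + gap_frames))
            f += gap_frames
    return SyntheticTrialSpec(
        duration_s=f / 80.0,
        state_sequence=segs,
        gait_params=gait_params or GaitParams(),
        noise_sd_px=noise_sd_px,
        seed=seed,
    )


@pytest.fixture(scope="session")
def trot_trial():
    """Six trot bouts at 0.2 m/s with a 0.5 rad diagonal-pair lag."""
    spec = locomotion_spec(
        gait_params=GaitParams(speed=0.2, gait="trot", diag_offset_rad=0.5, stride_freq_hz=4.0)
    )
    return generate_trial(spec)


@pytest.fixture(scope="session")
def walk_trial():
    spec = locomotion_spec(
        gait_params=GaitParams(speed=0.08, gait="walk", stride_freq_hz=2.0),
        seed=2,
    )
    return generate_trial(spec)


@pytest.fixture(scope="session")
def mixed_trial():
    """Two minutes across all eight behavioral states."""
    spec = SyntheticTrialSpec(duration_s=120.0, seed=7, mean_dwell_s=2.5)
    return generate_trial(spec)
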