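import numpy as np
import pytest

from cervikin import SEGMENTS, SegmentSeries, build_ssc
from cervikin.synthetic import (
    PhantomSpec,
    generate_profile,
    render_frames,
    young_profile,
)
from cervikin.tracking import templates_from_phantom, track_sequence


def series_from(rec):
    return {s: SegmentSeries(s, rec.segment_angles[s], fps=rec.fps) for s in SEGMENTS}


@pytest.fixture(scope="session")
def young_rec():
    """Noiseless recording with the consistent young-adult pattern."""
    return generate_profile(young_profile(noise_sd=0.0))


@pytest.fixture(scope="session")
def young_curve(young_rec):
    return build_ssc(series_from(young_rec))


@pytest.fixture(scope="session")
def phantom():
    return PhantomSpec(image_size=(256, 256))


@pytest.fixture(scope="session")
def phantom_run(phantom):
    """Rendered phantom stack (default blur/noise) with its tracked poses."""
    rec = generate_profile(young_profile(noise_sd=0.0, n_frames=16))
    stack, _ = render_frames(rec, phantom)
    templates = templates_from_phantom(phantom)
    poses = track_sequence(stack, templates)
    return {"rec": rec, "stack": stack, "templates": templates, "poses": poses,
            "phantom": phantom}
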