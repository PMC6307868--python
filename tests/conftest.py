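import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import neurorg as ng

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """512 px frame, full 97-frame session, PO channel only."""
    return ng.ImagingConfig(frame_shape=(512, 512), n_frames=97, channels=("PO",))


@pytest.fixture(scope="session")
def small_geometry(small_config):
    return ng.make_geometry(
        small_config, n_neurites=3, seed=1, soma_radius=6.0, min_length=25, max_length=30
    )


@pytest.fixture(scope="session")
def small_tracks(small_config, small_geometry):
    return ng.sample_tracks(
        small_geometry, ng.PRESETS["control-PO"], 6, small_config, seed=2
    )


@pytest.fixture(scope="session")
def small_stack(small_config, small_geometry, small_tracks):
    stack, truth = ng.render_timelapse(
        small_geometry, small_tracks, None, small_config, seed=3
    )
    return stack, truth


@pytest.fixture(scope="session")
def small_masks(small_stack):
    from neurorg import pipeline

    stack, _ = small_stack
    return pipeline.segment_stack(stack)


def centerline_pixels(geometry, index, margin_um=2.0):
    """Rounded pixel coordinates along a neurite centerline."""
    arc = geometry.path_arclength_um(index)
    n = int(arc[-1] / geometry.pixel_size)
    pts, _ = geometry.point_at_arc(index, np.linspace(margin_um, arc[-1] - margin_um, n))
    return np.round(pts).astype(int)
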