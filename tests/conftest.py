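import numpy as np
import pytest

from perivax.geometry import build_geometry
from perivax.scenarios import straight_track_geometry


@pytest.fixture(scope="session")
def default_geometry():
    return build_geometry(seed=7)


@pytest.fixture(scope="session")
def spread_geometry():
    """Larger field with many tracks; cells stay well separated when rendered."""
    return build_geometry(field_size=(1600, 1600), n_tracks=10,
                          track_length=(350, 550), seed=2)


@pytest.fixture(scope="session")
def straight_geometry():
    return straight_track_geometry()


@pytest.fixture(scope="session")
def long_straight_geometry():
    """Single long straight corridor at 1 µm/px; T zone near the left edge."""
    return straight_track_geometry(pixel_size=1.0, t_zone_center=(120.0, 500.0),
                                   track_half_width=25.0, track_length=650.0)
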