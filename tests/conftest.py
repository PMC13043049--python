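import numpy as np
import pandas as pd
import pytest

from ethodyad.io import BODYPARTS, CageGeometry, KeypointTrack


@pytest.fixture
def geometry() -> CageGeometry:
    """Left compartment, divider at x=200, 10 px/cm, 20 Hz."""
    return CageGeometry(
        compartment_box=(0.0, 0.0, 200.0, 254.0),
        divider_x=200.0,
        px_per_cm=10.0,
        frame_rate_hz=20.0,
    )


def make_track(
    centers: np.ndarray,
    headings_deg: np.ndarray,
    geometry: CageGeometry,
    body_len_px: float = 80.0,
    animal_id: str = "a1",
) -> KeypointTrack:
    """Keypoint track with given centers and absolute heading angles.

    Headings are degrees from the +x axis; keypoints are laid exactly along
    the body axis with zero jitter, confidence 1.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    ang = np.radians(np.atleast_1d(np.asarray(headings_deg, dtype=float)))
    n = len(centers)
    u = np.column_stack([np.cos(ang), np.sin(ang)])
    p = np.column_stack([-np.sin(ang), np.cos(ang)])
    offs = {
        "nose": 0.5 * body_len_px * u,
        "ear_left": 0.3 * body_len_px * u + 0.1 * body_len_px * p,
        "ear_right": 0.3 * body_len_px * u - 0.1 * body_len_px * p,
        "spine1": 0.2 * body_len_px * u,
        "spine2": 0.0 * u,
        "spine3": -0.2 * body_len_px * u,
        "tail_base": -0.5 * body_len_px * u,
    }
    data = {
        "frame": np.arange(n),
        "clock_s": np.arange(n) / geometry.frame_rate_hz,
    }
    for bp in BODYPARTS:
        xy = centers + offs[bp]
        data[f"{bp}_x"] = xy[:, 0]
        data[f"{bp}_y"] = xy[:, 1]
        data[f"{bp}_conf"] = np.ones(n)
    return KeypointTrack(animal_id, pd.DataFrame(data))


@pytest.fixture
def track_factory(geometry):
    def _make(centers, headings_deg, **kw):
        return make_track(centers, headings_deg, geometry, **kw)

    return _make
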