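"""Behavioral decomposition of keypoint tracks.

Three per-animal variables are derived from the 7-keypoint pose in the
divided cage:

* **direction to divider** — unitless orientation score in [−1, +1]: the
  tail-base→nose axis is compared with the unit normal pointing from the
  animal's compartment toward the divider; the unsigned angle φ ∈ [0°, 180°]
  is rescaled linearly, value = 1 − φ/90°, so +1 = facing the divider,
  0 = parallel, −1 = facing away.  Clockwise and counterclockwise rotations
  are treated equally (mirror symmetry).
* **distance to divider** — horizontal distance (cm) between the animal
  center and the divider line, independent of the vertical coordinate.
* **locomotion speed** — frame-to-frame displacement hypotenuse of the
  animal center, converted to cm/s; assigned to the later frame.

The "center of the animal" is the centroid of the three spine keypoints
(robust to nose/tail occlusion); a full 7-keypoint centroid is available via
``center="all"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BODYPARTS, SPINE_PARTS, AlignmentError, CageGeometry, KeypointTrack

logger = logging.getLogger(__name__)

VARIABLES = ("direction", "distance_cm", "speed_cms")


@dataclass
class VariableSeries:
    """One decomposed per-frame variable for one animal."""

    animal_id: str
    variable: str
    values: np.ndarray
    missing: np.ndarray
    clock_s: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.clock_s = np.asarray(self.clock_s, dtype=float)
        if not (len(self.values) == len(self.missing) == len(self.clock_s)):
            raise ValueError("values, missing and clock_s must share length")

    def __len__(self) -> int:
        return len(self.values)

    def valid(self) -> np.ndarray:
        return self.values[~self.missing]


def interpolate_low_confidence(
    track: KeypointTrack,
    threshold: float = 0.6,
    max_gap_s: float = 1.0,
) -> KeypointTrack:
    """Repair frames with low-confidence keypoints by linear interpolation.

    Frames where any body part's confidence falls below ``threshold`` (or a
    coordinate is NaN) are interpolated from neighboring good frames up to a
    maximum gap of ``max_gap_s``; longer gaps are marked missing.
    """
    df = track.data.copy()
    t = df["clock_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    max_gap = max(1, int(round(max_gap_s / dt)))

    conf = df[[f"{bp}_conf" for bp in BODYPARTS]].to_numpy(dtype=float)
    coords = df[[f"{bp}_{c}" for bp in BODYPARTS for c in ("x", "y")]].to_numpy(float)
    bad = (np.nan_to_num(conf, nan=0.0) < threshold).any(axis=1) | np.isnan(
        coords
    ).any(axis=1)
    missing = df["missing"].to_numpy(dtype=bool) | bad
    if not bad.any():
        return track

    # run lengths of bad stretches decide interpolate vs mark-missing
    still_missing = np.zeros(len(df), dtype=bool)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    starts, ends = idx[::2], idx[1::2]
    for s, e in zip(starts, ends):
        if (e - s) > max_gap or s == 0 or e == len(df):
            still_missing[s:e] = True
    interp = bad & ~still_missing
    if interp.any():
        good = ~bad
        xi = np.flatnonzero(interp)
        xg = np.flatnonzero(good)
        for col in [f"{bp}_{c}" for bp in BODYPARTS for c in ("x", "y")]:
            vals = df[col].to_numpy(dtype=float)
            vals[xi] = np.interp(xi, xg, vals[xg])
            df[col] = vals
    df["missing"] = still_missing
    logger.info(
        "%s: interpolated %d frames, %d left missing",
        track.animal_id,
        int(interp.sum()),
        int(still_missing.sum()),
    )
    return KeypointTrack(animal_id=track.animal_id, data=df)


def _center(track: KeypointTrack, which: str = "spine") -> np.ndarray:
    parts = SPINE_PARTS if which == "spine" else BODYPARTS
    stack = np.stack([track.xy(bp) for bp in parts])  # (p, n, 2)
    return stack.mean(axis=0)


def _direction_values(
    heading: np.ndarray, normal: np.ndarray, method: str
) -> np.ndarray:
    norms = np.linalg.norm(heading, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = (heading @ normal) / norms
    cosphi = np.clip(cosphi, -1.0, 1.0)
    if method == "cosine":
        vals = cosphi
    elif method == "linear":
        phi_deg = np.degrees(np.arccos(cosphi))
        vals = 1.0 - phi_deg / 90.0
    else:
        raise ValueError(f"unknown method {method!r}")
    vals[norms == 0] = np.nan
    return vals


def direction_to_divider(
    track: KeypointTrack,
    geometry: CageGeometry,
    method: str = "linear",
) -> VariableSeries:
    """Per-frame body orientation toward the divider, in [−1, +1].

    ``method='linear'`` rescales the unsigned heading/normal angle linearly
    (0° → +1, 90° → 0, 180° → −1); ``method='cosine'`` uses cos φ instead.
    Frames with a zero-length body axis (nose == tail base) are missing.
    """
    heading = track.xy("nose") - track.xy("tail_base")
    vals = _direction_values(heading, geometry.divider_normal, method)
    n_degenerate = int(np.sum(np.linalg.norm(heading, axis=1) == 0))
    if n_degenerate:
        logger.warning(
            "%s: %d zero-length body-axis frames set missing",
            track.animal_id,
            n_degenerate,
        )
    missing = track.data["missing"].to_numpy(bool) | np.isnan(vals)
    return VariableSeries(
        track.animal_id, "direction", vals, missing, track.data["clock_s"].to_numpy()
    )


def distance_to_divider(
    track: KeypointTrack,
    geometry: CageGeometry,
    center: str = "spine",
) -> VariableSeries:
    """Horizontal distance (cm) from the animal center to the divider line."""
    c = _center(track, center)
    vals = np.abs(c[:, 0] - geometry.divider_x) / geometry.px_per_cm
    x_min, _, x_max, _ = geometry.compartment_box
    outside = (c[:, 0] < x_min) | (c[:, 0] > x_max)
    if outside.any():
        logger.warning(
            "%s: %d frames with center outside compartment box",
            track.animal_id,
            int(outside.sum()),
        )
    missing = track.data["missing"].to_numpy(bool) | np.isnan(vals)
    return VariableSeries(
        track.animal_id, "distance_cm", vals, missing, track.data["clock_s"].to_numpy()
    )


def locomotion_speed(
    track: KeypointTrack,
    geometry: CageGeometry,
    center: str = "spine",
) -> VariableSeries:
    """Center displacement hypotenuse between consecutive frames, in cm/s.

    The value at frame n+1 is the displacement from frame n, scaled by the
    frame rate; the first frame is marked missing.
    """
    if len(track) < 2:
        raise ValueError("locomotion speed needs at least 2 frames")
    c = _center(track, center)
    step = np.hypot(*(np.diff(c, axis=0).T)) / geometry.px_per_cm
    vals = np.empty(len(track))
    vals[0] = np.nan
    vals[1:] = step * geometry.frame_rate_hz
    miss_track = track.data["missing"].to_numpy(bool)
    missing = miss_track.copy()
    missing[1:] |= miss_track[:-1]
    missing[0] = True
    missing |= np.isnan(vals)
    return VariableSeries(
        track.animal_id, "speed_cms", vals, missing, track.data["clock_s"].to_numpy()
    )


def decompose(
    track: KeypointTrack, geometry: CageGeometry, **kwargs
) -> dict[str, VariableSeries]:
    """All three variables for one animal, keyed by variable name."""
    return {
        "direction": direction_to_divider(track, geometry, **kwargs.get("direction_kwargs", {})),
        "distance_cm": distance_to_divider(track, geometry),
        "speed_cms": locomotion_speed(track, geometry),
    }


def dyad_mutual_variables(
    track_m: KeypointTrack,
    track_f: KeypointTrack,
    geometry: CageGeometry,
    method: str = "linear",
) -> tuple[VariableSeries, VariableSeries]:
    """Dyad-level mutual distance (cm) and mutual direction (in [−1, 1]).

    Mutual distance is the center-to-center distance.  Mutual direction is
    the mean of the two animals' orientation scores where each animal's
    reference axis points at the partner's center; it is symmetric under
    swapping the two animals.
    """
    if len(track_m) != len(track_f) or not np.allclose(
        track_m.data["clock_s"], track_f.data["clock_s"]
    ):
        raise AlignmentError("dyad tracks are not frame-synchronized")
    cm = _center(track_m)
    cf = _center(track_f)
    sep = cf - cm
    dist = np.linalg.norm(sep, axis=1) / geometry.px_per_cm

    vals = np.empty((2, len(track_m)))
    for i, (track, toward) in enumerate(((track_m, sep), (track_f, -sep))):
        heading = track.xy("nose") - track.xy("tail_base")
        norms_t = np.linalg.norm(toward, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = toward / norms_t[:, None]
        h_norm = np.linalg.norm(heading, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosphi = np.clip(np.einsum("ij,ij->i", heading, unit) / h_norm, -1, 1)
        if method == "cosine":
            v = cosphi
        else:
            v = 1.0 - np.degrees(np.arccos(cosphi)) / 90.0
        v[(h_norm == 0) | (norms_t == 0)] = np.nan
        vals[i] = v
    mutual_dir = vals.mean(axis=0)

    miss = (
        track_m.data["missing"].to_numpy(bool)
        | track_f.data["missing"].to_numpy(bool)
    )
    clock = track_m.data["clock_s"].to_numpy()
    dyad_id = f"{track_m.animal_id}+{track_f.animal_id}"
    return (
        VariableSeries(dyad_id, "mutual_distance_cm", dist, miss | np.isnan(dist), clock),
        VariableSeries(dyad_id, "mutual_direction", mutual_dir, miss | np.isnan(mutual_dir), clock),
    )
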