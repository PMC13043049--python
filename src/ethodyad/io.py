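"""Domain types, file readers/writers, and clock-time alignment.

All on-disk formats are plain comma-separated text with one header row
(a two-level ``bodypart,coordinate`` header is also accepted for keypoint
tables, matching common pose-tracker exports).  Recording clock metadata
lives in a YAML sidecar, not in filenames.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .vocab import RAW_CATEGORIES

logger = logging.getLogger(__name__)

#: The seven tracked body parts, nose to tail.
BODYPARTS = ("nose", "ear_left", "ear_right", "spine1", "spine2", "spine3", "tail_base")

SPINE_PARTS = ("spine1", "spine2", "spine3")


class FormatError(ValueError):
    """A file does not conform to the expected column layout."""


class DataError(ValueError):
    """A file parsed but contains invalid values."""


class AlignmentError(ValueError):
    """Segments or paired tracks cannot be placed on a common time axis."""


@dataclass(frozen=True)
class CageGeometry:
    """Pixel-space geometry of one animal's compartment.

    Parameters
    ----------
    compartment_box : tuple
        ``(x_min, y_min, x_max, y_max)`` in pixels, image convention
        (origin top-left, y increasing downward).
    divider_x : float
        x coordinate of the divider line; must coincide with one of the
        compartment's x edges.
    px_per_cm : float
        Scale factor, pixels per centimeter.
    frame_rate_hz : float
        Acquisition frame rate.
    cage_length_cm, cage_width_cm : float
        Physical dimensions of the full (undivided) cage.
    """

    compartment_box: tuple[float, float, float, float]
    divider_x: float
    px_per_cm: float
    frame_rate_hz: float
    cage_length_cm: float = 48.3
    cage_width_cm: float = 25.4

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        x_min, y_min, x_max, y_max = self.compartment_box
        if x_min >= x_max or y_min >= y_max:
            raise ValueError("compartment_box must have positive extent")
        if not (
            np.isclose(self.divider_x, x_min) or np.isclose(self.divider_x, x_max)
        ):
            raise ValueError("divider_x must lie on one x edge of compartment_box")

    @property
    def divider_normal(self) -> np.ndarray:
        """Unit vector pointing from inside the compartment toward the divider."""
        x_min, _, x_max, _ = self.compartment_box
        if np.isclose(self.divider_x, x_max):
            return np.array([1.0, 0.0])
        return np.array([-1.0, 0.0])


@dataclass(frozen=True)
class DyadRecord:
    """One opposite-sex dyad; conditions are Ctrl or ELSD, male named first."""

    dyad_id: str
    male_condition: str
    female_condition: str

    def __post_init__(self) -> None:
        for c in (self.male_condition, self.female_condition):
            if c not in ("Ctrl", "ELSD"):
                raise ValueError(f"condition must be Ctrl or ELSD, got {c!r}")

    @property
    def subtype(self) -> str:
        return f"{self.male_condition}-{self.female_condition}"

    @property
    def dyad_type(self) -> str:
        """'matched' iff both animals share the condition, else 'mixed'."""
        return "matched" if self.male_condition == self.female_condition else "mixed"


@dataclass
class KeypointTrack:
    """Per-frame 7-keypoint pose of one animal.

    ``data`` holds one row per frame with columns ``frame``, ``clock_s`` and
    ``<bp>_x``, ``<bp>_y``, ``<bp>_conf`` for each body part in
    :data:`BODYPARTS`; an optional boolean ``missing`` column marks frames
    whose pose could not be recovered.
    """

    animal_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["frame", "clock_s"] + [
            f"{bp}_{c}" for bp in BODYPARTS for c in ("x", "y", "conf")
        ]
        for col in required:
            if col not in self.data.columns:
                bp = col.rsplit("_", 1)[0]
                raise FormatError(f"keypoint table missing column {col!r} ({bp})")
        frames = self.data["frame"].to_numpy()
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise DataError("frame indices must be strictly increasing")
        conf_cols = [f"{bp}_conf" for bp in BODYPARTS]
        conf = self.data[conf_cols].to_numpy(dtype=float)
        valid = conf[~np.isnan(conf)]
        if valid.size and ((valid < 0).any() or (valid > 1).any()):
            raise DataError("keypoint confidences must lie in [0, 1]")
        if "missing" not in self.data.columns:
            self.data = self.data.assign(missing=False)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy(self, bodypart: str) -> np.ndarray:
        """(n, 2) pixel coordinates of one body part."""
        return self.data[[f"{bodypart}_x", f"{bodypart}_y"]].to_numpy(dtype=float)

    def conf(self, bodypart: str) -> np.ndarray:
        return self.data[f"{bodypart}_conf"].to_numpy(dtype=float)


@dataclass
class BehaviorScoreTable:
    """Per-frame per-category likelihoods in [0, 1] for one animal."""

    animal_id: str
    data: pd.DataFrame
    vocabulary: tuple[str, ...] = RAW_CATEGORIES

    def __post_init__(self) -> None:
        if "frame" not in self.data.columns:
            raise FormatError("score table missing 'frame' column")
        for cat in self.vocabulary:
            if cat not in self.data.columns:
                raise FormatError(f"score table missing category column {cat!r}")
        scores = self.data[list(self.vocabulary)].to_numpy(dtype=float)
        bad = np.where(np.nan_to_num(scores, nan=0.5) > 1.0)
        lo = np.where(np.nan_to_num(scores, nan=0.5) < 0.0)
        if bad[0].size or lo[0].size:
            idx = int(np.concatenate([bad[0], lo[0]]).min())
            frame = int(self.data["frame"].iloc[idx])
            raise DataError(f"likelihood outside [0, 1] at frame {frame}")

    def __len__(self) -> int:
        return len(self.data)

    def scores(self) -> np.ndarray:
        """(n_frames, n_categories) float array (NaN = missing detection)."""
        return self.data[list(self.vocabulary)].to_numpy(dtype=float)


@dataclass
class AnnotationTrack:
    """Per-frame manual attack annotations for one animal."""

    animal_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("frame", "attacking", "being_attacked"):
            if col not in self.data.columns:
                raise FormatError(f"annotation table missing column {col!r}")
        att = self.data["attacking"].to_numpy().astype(bool)
        rec = self.data["being_attacked"].to_numpy().astype(bool)
        both = att & rec
        if both.any():
            frame = int(self.data["frame"].to_numpy()[both][0])
            raise DataError(
                f"attacking and being_attacked both set at frame {frame}"
            )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class LabelStream:
    """Single categorical label per time bin for one animal.

    ``labels`` are integer codes into ``vocabulary`` with −1 marking
    missing bins.
    """

    animal_id: str
    bin_width_s: float
    vocabulary: tuple[str, ...]
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        k = len(self.vocabulary)
        if self.labels.size and (
            self.labels.max(initial=-1) >= k or self.labels.min(initial=0) < -1
        ):
            raise DataError("label code outside vocabulary")

    def __len__(self) -> int:
        return len(self.labels)

    def as_names(self) -> list[str]:
        return [
            self.vocabulary[c] if c >= 0 else "missing" for c in self.labels
        ]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _flatten_two_level(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse a (bodypart, coordinate) column MultiIndex to flat names."""
    cols = []
    for bp, coord in df.columns:
        coord = {"likelihood": "conf", "confidence": "conf"}.get(coord, coord)
        if str(bp).lower() in ("frame", "clock_s", "") or coord == "":
            cols.append(str(bp))
        else:
            cols.append(f"{bp}_{coord}")
    out = df.copy()
    out.columns = cols
    return out


def read_keypoint_table(
    path, geometry: CageGeometry, animal_id: str | None = None
) -> KeypointTrack:
    """Read one animal's keypoint CSV into a validated :class:`KeypointTrack`.

    A flat header ``frame,<bp>_x,<bp>_y,<bp>_conf`` is expected; a two-level
    ``bodypart / x|y|likelihood`` header is also accepted.  Rows with missing
    coordinates are flagged in the ``missing`` column, never dropped.
    """
    df = pd.read_csv(path, comment="#")
    expected = {f"{bp}_{c}" for bp in BODYPARTS for c in ("x", "y", "conf")}
    if not expected.issubset(df.columns):
        two = pd.read_csv(path, header=[0, 1], comment="#")
        if isinstance(two.columns, pd.MultiIndex):
            flat = _flatten_two_level(two)
            if expected.issubset(flat.columns):
                df = flat
    if "frame" not in df.columns:
        df.insert(0, "frame", np.arange(len(df)))
    if "clock_s" not in df.columns:
        df["clock_s"] = df["frame"] / geometry.frame_rate_hz
    coord_cols = [f"{bp}_{c}" for bp in BODYPARTS for c in ("x", "y")]
    for col in coord_cols:
        if col not in df.columns:
            bp = col.rsplit("_", 1)[0]
            raise FormatError(f"keypoint table missing column {col!r} ({bp})")
    missing = df[coord_cols].isna().any(axis=1)
    df["missing"] = missing.to_numpy()
    if missing.any():
        logger.warning(
            "%d rows with missing coordinates flagged in %s", missing.sum(), path
        )
    if animal_id is None:
        animal_id = str(path)
    return KeypointTrack(animal_id=animal_id, data=df)


def write_keypoint_table(track: KeypointTrack, path) -> None:
    track.data.to_csv(path, index=False)


def read_behavior_scores(
    path, vocabulary: tuple[str, ...] = RAW_CATEGORIES, animal_id: str | None = None
) -> BehaviorScoreTable:
    """Read a ``frame,<category>...`` likelihood CSV; out-of-range values raise."""
    df = pd.read_csv(path, comment="#")
    return BehaviorScoreTable(
        animal_id=animal_id or str(path), data=df, vocabulary=vocabulary
    )


def write_behavior_scores(table: BehaviorScoreTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_annotation_track(path, animal_id: str | None = None) -> AnnotationTrack:
    """Read a ``frame,attacking,being_attacked`` 0/1 CSV."""
    df = pd.read_csv(path, comment="#")
    for col in ("attacking", "being_attacked"):
        if col in df.columns:
            vals = df[col].to_numpy()
            if not np.isin(vals, (0, 1)).all():
                raise DataError(f"{col} must be 0/1")
            df[col] = vals.astype(bool)
    return AnnotationTrack(animal_id=animal_id or str(path), data=df)


def write_annotation_track(track: AnnotationTrack, path) -> None:
    out = track.data.copy()
    out["attacking"] = out["attacking"].astype(int)
    out["being_attacked"] = out["being_attacked"].astype(int)
    out.to_csv(path, index=False)


def read_metadata(path) -> dict:
    """Load the YAML sidecar (geometry, start time, segment order, dyads)."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if "dyads" in meta:
        meta["dyads"] = [
            DyadRecord(d["dyad_id"], d["male_condition"], d["female_condition"])
            for d in meta["dyads"]
        ]
    return meta


def write_metadata(meta: dict, path) -> None:
    out = dict(meta)
    if "dyads" in out:
        out["dyads"] = [
            {
                "dyad_id": d.dyad_id,
                "male_condition": d.male_condition,
                "female_condition": d.female_condition,
                "subtype": d.subtype,
                "dyad_type": d.dyad_type,
            }
            for d in out["dyads"]
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# segment alignment
# ---------------------------------------------------------------------------


def align_segments(
    segments: list[KeypointTrack],
    margin_s: float = 2.0,
    gap_tolerance_s: float = 1.0,
) -> KeypointTrack:
    """Concatenate multi-file recording segments onto one clock axis.

    Each segment's ``clock_s`` must be absolute seconds since session start
    (monotone, not reset at midnight).  ``margin_s`` of frames are trimmed
    from both ends of every segment (safety margins recorded around each
    file).  Overlap after trimming raises :class:`AlignmentError`; gaps
    larger than ``gap_tolerance_s`` are logged and retained as missing time.
    """
    if margin_s < 0:
        raise ValueError("margin_s must be >= 0")
    if not segments:
        raise ValueError("no segments")
    trimmed = []
    for seg in segments:
        df = seg.data
        t = df["clock_s"].to_numpy(dtype=float)
        if margin_s > 0 and len(t) > 1:
            dt = float(np.median(np.diff(t)))
            m = int(round(margin_s / dt))
            if 2 * m >= len(df):
                raise AlignmentError("margin trim would consume an entire segment")
            df = df.iloc[m : len(df) - m]
        trimmed.append(df)
    trimmed.sort(key=lambda d: float(d["clock_s"].iloc[0]))
    prev_end = None
    for df in trimmed:
        start = float(df["clock_s"].iloc[0])
        if prev_end is not None:
            if start <= prev_end:
                raise AlignmentError(
                    f"segments overlap after trimming at clock_s={start:g}"
                )
            gap = start - prev_end
            if gap > gap_tolerance_s:
                logger.warning(
                    "gap of %.2f s between segments retained as missing time", gap
                )
        prev_end = float(df["clock_s"].iloc[-1])
    out = pd.concat(trimmed, ignore_index=True)
    out["frame"] = np.arange(len(out))
    return KeypointTrack(animal_id=segments[0].animal_id, data=out)
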