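"""Synthetic dyad cohorts with known ground truth.

Two generators replace the study's raw video-derived data so that every
downstream stage is testable:

* :func:`generate_divided_cohort` — divided-cage cohabitation.  Each animal
  is a reflected random walk inside its compartment whose heading follows a
  mean-reverting (wrapped autoregressive) process; the stationary mean
  direction-to-divider equals the configured per-sex orientation bias, and
  speed is modulated by an exponentially decaying activity envelope
  (elevated early activity).  Seven keypoints are laid along the body axis
  with isotropic jitter and near-1 confidences.
* :func:`generate_undivided_cohort` — undivided cohabitation.  The dyad is
  a semi-Markov chain over *joint* states at a 1-s step: huddling and
  behaving-alone are mutual, chasing / attacking / pointing are role pairs
  (the actor carries the focal label, the partner the mirror label).
  Aggression hazards decay and the huddling entry hazard rises over the
  session; female aggression hazards are multiplied in mixed dyads.  The
  emitted artifacts mirror the real pipeline: per-frame one-hot raw
  likelihoods (with optional label-noise flips) plus a manual-annotation
  channel for attacks.

Dwell times are geometric at the 1-s step (memoryless) by default, with a
negative-binomial option for burstier bouts.  One global seed; per-dyad
substreams are split with ``numpy.random.SeedSequence`` so cohorts are
reproducible under any generation order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io import (
    BODYPARTS,
    AnnotationTrack,
    BehaviorScoreTable,
    CageGeometry,
    DyadRecord,
    write_annotation_track,
    write_behavior_scores,
    write_keypoint_table,
    write_metadata,
    KeypointTrack,
)
from .vocab import ACTIVE_CATEGORIES, DYAD_SUBTYPES, RAW_CATEGORIES, WORKING_CATEGORIES


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class DividedSimConfig:
    """Study conditions for the divided-cage simulation.

    Defaults are the scaled-down study conditions: 28 dyads (7, 8, 7, 6 per
    subtype), 2 h at 5 Hz (the full study is 72 h at 20 Hz), male
    orientation bias above female, activity elevated during the first sixth
    of the session.
    """

    n_dyads_per_subtype: tuple[int, int, int, int] = (7, 8, 7, 6)
    duration_s: float = 7200.0
    frame_rate_hz: float = 5.0
    #: mean direction-to-divider target per (sex, dyad_type)
    orientation_bias: dict = field(
        default_factory=lambda: {
            ("M", "matched"): 0.40,
            ("M", "mixed"): 0.55,
            ("F", "matched"): 0.0,
            ("F", "mixed"): 0.0,
        }
    )
    activity_amp: float = 1.5
    activity_tau_s: float | None = None  # default: duration / 6
    heading_persistence: float = 0.97
    heading_noise_deg: float = 22.0
    speed_scale_cms: float = 3.0
    keypoint_jitter_px: float = 0.5
    confidence_noise: float = 0.02
    confidence_dropout: float = 0.01
    body_length_cm: float = 10.0
    px_per_cm: float = 8.0
    circadian: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.orientation_bias.items():
            if not -1.0 <= v <= 1.0:
                raise ConfigError(f"orientation_bias{k} outside [-1, 1]")
        if not 0.0 <= self.heading_persistence < 1.0:
            raise ConfigError("heading_persistence must be in [0, 1)")
        for dt in ("matched", "mixed"):
            if self.orientation_bias[("M", dt)] < self.orientation_bias[("F", dt)]:
                raise ConfigError("default scenario requires male bias >= female")
        half_cage_px = self.px_per_cm * 48.3 / 2
        if self.body_length_cm * self.px_per_cm >= half_cage_px:
            raise ConfigError("compartment smaller than body length")

    @property
    def tau_s(self) -> float:
        return self.activity_tau_s if self.activity_tau_s else self.duration_s / 6.0


@dataclass
class UndividedSimConfig:
    """Study conditions for the undivided-cage semi-Markov simulation.

    Hazards are per-second entry rates into each joint state; aggression
    (chasing, attacking) decays with ``aggression_half_life_s`` and the
    huddling entry hazard rises with ``huddling_rise_half_life_s``, so
    aggression concentrates early and huddling dominates late.  In mixed
    dyads the female chasing/attacking hazards are multiplied by
    ``mixed_dyad_female_aggression_multiplier``.
    """

    n_dyads_per_subtype: tuple[int, int, int, int] = (7, 8, 7, 6)
    duration_s: float = 14400.0
    frame_rate_hz: float = 20.0
    step_s: float = 1.0
    chase_hazard: dict = field(default_factory=lambda: {"M": 0.0025, "F": 0.005})
    attack_hazard: dict = field(default_factory=lambda: {"M": 0.0012, "F": 0.0035})
    point_hazard: dict = field(default_factory=lambda: {"M": 0.010, "F": 0.010})
    alone_hazard: float = 0.040
    huddle_hazard: float = 0.030
    mixed_dyad_female_aggression_multiplier: float = 3.0
    aggression_half_life_s: float = 3600.0
    huddling_rise_half_life_s: float = 3600.0
    #: mean dwell (s) per category; geometric leave probability 1/dwell
    dwell_s: dict = field(
        default_factory=lambda: {
            "chasing": 3.0,
            "attacking": 2.0,
            "pointing": 5.0,
            "behaving_alone": 45.0,
            "huddling": 90.0,
        }
    )
    dwell_model: str = "geometric"
    negbin_r: float = 2.0
    label_noise: float = 0.02
    merge_artifact_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for h in (
            *self.chase_hazard.values(),
            *self.attack_hazard.values(),
            *self.point_hazard.values(),
            self.alone_hazard,
            self.huddle_hazard,
        ):
            if h < 0:
                raise ConfigError("hazards must be >= 0")
        if not 0.0 <= self.label_noise < 1.0:
            raise ConfigError("label_noise must be in [0, 1)")
        if self.mixed_dyad_female_aggression_multiplier <= 0:
            raise ConfigError("aggression multiplier must be > 0")


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests."""

    dyads: list[DyadRecord]
    #: per animal_id: dict of generating parameters (bias, envelope, ...)
    animal_params: dict = field(default_factory=dict)
    #: per animal_id: realized working-vocabulary label codes at the 1-s step
    label_streams: dict = field(default_factory=dict)
    #: per dyad_id: directional 5-category matrices {"male_to_female": ..., ...}
    directional_matrices: dict = field(default_factory=dict)
    #: per dyad_id: joint-state transition matrix (time-homogeneous reference)
    joint_matrices: dict = field(default_factory=dict)


def make_dyads(n_per_subtype=(7, 8, 7, 6)) -> list[DyadRecord]:
    """Default cohort arithmetic: 7+8 matched, 7+6 mixed = 28 dyads."""
    dyads = []
    i = 0
    for subtype, n in zip(DYAD_SUBTYPES, n_per_subtype):
        male, female = subtype.split("-")
        for _ in range(n):
            i += 1
            dyads.append(DyadRecord(f"d{i:02d}", male, female))
    return dyads


# ---------------------------------------------------------------------------
# divided cohort
# ---------------------------------------------------------------------------


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    w = hi - lo
    g = np.mod(x - lo, 2 * w)
    return lo + w - np.abs(g - w)


def _simulate_divided_animal(
    cfg: DividedSimConfig, geometry: CageGeometry, bias: float, rng: np.random.Generator
) -> pd.DataFrame:
    n = int(round(cfg.duration_s * cfg.frame_rate_hz))
    dt = 1.0 / cfg.frame_rate_hz
    t = np.arange(n) * dt

    # heading angle relative to the divider normal, degrees; AR(1) around
    # the angle whose linear orientation score equals the configured bias
    mu = (1.0 - bias) * 90.0
    rho = cfg.heading_persistence
    eps = rng.normal(0.0, cfg.heading_noise_deg, size=n)
    theta = np.empty(n)
    theta[0] = mu
    for i in range(1, n):
        theta[i] = mu + rho * (theta[i - 1] - mu) + eps[i]

    act = 1.0 + cfg.activity_amp * np.exp(-t / cfg.tau_s)
    if cfg.circadian:
        act *= 1.0 + 0.3 * np.sin(2 * np.pi * t / 86400.0)
    speed = cfg.speed_scale_cms * act * np.abs(rng.normal(0.0, 1.0, size=n))

    sign = 1.0 if geometry.divider_normal[0] > 0 else -1.0
    alpha = np.where(sign > 0, np.radians(theta), np.pi - np.radians(theta))
    step = (speed * dt * cfg.px_per_cm)[:, None] * np.column_stack(
        [np.cos(alpha), np.sin(alpha)]
    )
    x_min, y_min, x_max, y_max = geometry.compartment_box
    margin = 0.55 * cfg.body_length_cm * cfg.px_per_cm + 5 * cfg.keypoint_jitter_px
    lo = np.array([x_min + margin, y_min + margin])
    hi = np.array([x_max - margin, y_max - margin])
    if (hi <= lo).any():
        raise ConfigError("compartment smaller than body length")
    start = (lo + hi) / 2
    raw = start + np.cumsum(step, axis=0) - step[0]
    center = np.column_stack(
        [_reflect(raw[:, 0], lo[0], hi[0]), _reflect(raw[:, 1], lo[1], hi[1])]
    )

    u = np.column_stack([np.cos(alpha), np.sin(alpha)])
    p = np.column_stack([-np.sin(alpha), np.cos(alpha)])
    L = cfg.body_length_cm * cfg.px_per_cm
    offsets = {
        "nose": 0.5 * L * u,
        "ear_left": 0.32 * L * u + 0.12 * L * p,
        "ear_right": 0.32 * L * u - 0.12 * L * p,
        "spine1": 0.2 * L * u,
        "spine2": 0.0 * u,
        "spine3": -0.2 * L * u,
        "tail_base": -0.5 * L * u,
    }
    data = {"frame": np.arange(n), "clock_s": t}
    for bp in BODYPARTS:
        xy = center + offsets[bp]
        if cfg.keypoint_jitter_px > 0:
            xy = xy + rng.normal(0.0, cfg.keypoint_jitter_px, size=xy.shape)
        xy[:, 0] = np.clip(xy[:, 0], x_min, x_max)
        xy[:, 1] = np.clip(xy[:, 1], y_min, y_max)
        conf = np.ones(n)
        if cfg.confidence_noise > 0:
            conf = np.clip(1.0 - np.abs(rng.normal(0, cfg.confidence_noise, n)), 0, 1)
        if cfg.confidence_dropout > 0:
            drop = rng.random(n) < cfg.confidence_dropout
            conf[drop] = rng.uniform(0.0, 0.5, size=int(drop.sum()))
        data[f"{bp}_x"] = xy[:, 0]
        data[f"{bp}_y"] = xy[:, 1]
        data[f"{bp}_conf"] = conf
    return pd.DataFrame(data)


def divided_geometries(cfg: DividedSimConfig) -> tuple[CageGeometry, CageGeometry]:
    """(male, female) compartment geometries; divider at the cage center."""
    length_px = 48.3 * cfg.px_per_cm
    width_px = 25.4 * cfg.px_per_cm
    div = length_px / 2
    g_m = CageGeometry((0.0, 0.0, div, width_px), div, cfg.px_per_cm, cfg.frame_rate_hz)
    g_f = CageGeometry(
        (div, 0.0, length_px, width_px), div, cfg.px_per_cm, cfg.frame_rate_hz
    )
    return g_m, g_f


def simulate_divided_tracks(
    cfg: DividedSimConfig,
) -> tuple[dict, GroundTruth]:
    """In-memory divided cohort: {(dyad_id, sex): KeypointTrack} plus truth.

    Deterministic given ``cfg.seed``: per-dyad RNG substreams are derived by
    seed-sequence splitting, so the cohort is identical across runs and
    generation orders.
    """
    dyads = make_dyads(cfg.n_dyads_per_subtype)
    g_m, g_f = divided_geometries(cfg)
    truth = GroundTruth(dyads=dyads)
    tracks: dict = {}
    children = np.random.SeedSequence(cfg.seed).spawn(len(dyads))
    for dyad, ss in zip(dyads, children):
        rng_m, rng_f = [np.random.default_rng(s) for s in ss.spawn(2)]
        for sex, geom, rng in (("M", g_m, rng_m), ("F", g_f, rng_f)):
            bias = cfg.orientation_bias[(sex, dyad.dyad_type)]
            df = _simulate_divided_animal(cfg, geom, bias, rng)
            animal_id = f"{dyad.dyad_id}{sex}"
            tracks[(dyad.dyad_id, sex)] = KeypointTrack(animal_id, df)
            truth.animal_params[animal_id] = {
                "orientation_bias": bias,
                "activity_amp": cfg.activity_amp,
                "activity_tau_s": cfg.tau_s,
            }
    return tracks, truth


def generate_divided_cohort(
    cfg: DividedSimConfig, outdir: str | os.PathLike
) -> tuple[dict, GroundTruth]:
    """Write keypoint tables for every animal; return file map and truth."""
    os.makedirs(outdir, exist_ok=True)
    tracks, truth = simulate_divided_tracks(cfg)
    dyads = truth.dyads
    files: dict = {"keypoints": {}, "metadata": os.path.join(outdir, "metadata.yaml")}
    for (dyad_id, sex), track in tracks.items():
        path = os.path.join(outdir, f"keypoints_{dyad_id}{sex}.csv")
        write_keypoint_table(track, path)
        files["keypoints"][(dyad_id, sex)] = path
    meta = {
        "experiment": "divided",
        "frame_rate_hz": cfg.frame_rate_hz,
        "px_per_cm": cfg.px_per_cm,
        "duration_s": cfg.duration_s,
        "seed": cfg.seed,
        "start_clock_s": 0.0,
        "dyads": dyads,
    }
    write_metadata(meta, files["metadata"])
    with open(os.path.join(outdir, "ground_truth.yaml"), "w") as fh:
        yaml.safe_dump(
            {"animal_params": {k: v for k, v in truth.animal_params.items()}},
            fh,
            sort_keys=False,
        )
    return files, truth


# ---------------------------------------------------------------------------
# undivided cohort: joint-state semi-Markov chain
# ---------------------------------------------------------------------------

#: joint dyad states: mutual, or (category, actor-sex) role pairs
JOINT_STATES = (
    "huddling",
    "alone",
    "chase_M",
    "chase_F",
    "attack_M",
    "attack_F",
    "point_M",
    "point_F",
)

_STATE_CATEGORY = {
    "huddling": "huddling",
    "alone": "behaving_alone",
    "chase_M": "chasing",
    "chase_F": "chasing",
    "attack_M": "attacking",
    "attack_F": "attacking",
    "point_M": "pointing",
    "point_F": "pointing",
}

_W = {c: WORKING_CATEGORIES.index(c) for c in WORKING_CATEGORIES}

#: joint state -> (male working code, female working code)
STATE_LABELS = {
    "huddling": (_W["huddling"], _W["huddling"]),
    "alone": (_W["behaving_alone"], _W["behaving_alone"]),
    "chase_M": (_W["chasing"], _W["being_chased"]),
    "chase_F": (_W["being_chased"], _W["chasing"]),
    "attack_M": (_W["attacking"], _W["being_attacked"]),
    "attack_F": (_W["being_attacked"], _W["attacking"]),
    "point_M": (_W["pointing"], _W["being_pointed_at"]),
    "point_F": (_W["being_pointed_at"], _W["pointing"]),
}


def _entry_hazards(cfg: UndividedSimConfig, t: float, mixed: bool) -> np.ndarray:
    """Per-state entry hazards at session time t (seconds)."""
    decay = 0.5 ** (t / cfg.aggression_half_life_s)
    rise = 0.15 + 0.85 * (1.0 - 0.5 ** (t / cfg.huddling_rise_half_life_s))
    mult = cfg.mixed_dyad_female_aggression_multiplier if mixed else 1.0
    return np.array(
        [
            cfg.huddle_hazard * rise,
            cfg.alone_hazard,
            cfg.chase_hazard["M"] * decay,
            cfg.chase_hazard["F"] * mult * decay,
            cfg.attack_hazard["M"] * decay,
            cfg.attack_hazard["F"] * mult * decay,
            cfg.point_hazard["M"],
            cfg.point_hazard["F"],
        ]
    )


def joint_transition_matrix(
    cfg: UndividedSimConfig, mixed: bool, t: float = 0.0
) -> np.ndarray:
    """Row-stochastic one-step matrix over :data:`JOINT_STATES` at time t."""
    k = len(JOINT_STATES)
    T = np.zeros((k, k))
    h = _entry_hazards(cfg, t, mixed)
    for i, s in enumerate(JOINT_STATES):
        p_leave = 1.0 / cfg.dwell_s[_STATE_CATEGORY[s]]
        p_leave = min(p_leave, 1.0)
        others = np.array([h[j] if j != i else 0.0 for j in range(k)])
        tot = others.sum()
        if tot <= 0:
            T[i, i] = 1.0
            continue
        T[i] = p_leave * others / tot
        T[i, i] = 1.0 - p_leave
    return T


def directional_matrix_from_joint(T: np.ndarray, actor: str = "M") -> np.ndarray:
    """Expected actor→reactor 5-category transition matrix of a joint chain.

    Joint states are collapsed to the five interaction categories (the
    default mirror-role collapse) and weighted by the chain's stationary
    distribution: entry (a, r) is P(reactor category at t+1 = r | actor
    category at t = a) at stationarity.
    """
    k = len(JOINT_STATES)
    vals, vecs = np.linalg.eig(T.T)
    pi = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    pi = np.abs(pi) / np.abs(pi).sum()
    cat_idx = {c: i for i, c in enumerate(ACTIVE_CATEGORIES)}
    state_cat = np.array([cat_idx[_STATE_CATEGORY[s]] for s in JOINT_STATES])
    m = len(ACTIVE_CATEGORIES)
    out = np.zeros((m, m))
    for a in range(m):
        sel = state_cat == a
        w = pi[sel]
        if w.sum() == 0:
            continue
        flow = (w[:, None] * T[sel]).sum(axis=0)  # joint next-state distribution
        for r in range(m):
            out[a, r] = flow[state_cat == r].sum()
        out[a] /= out[a].sum()
    # actor symmetry: under the default collapse both animals share the
    # category stream, so the matrix is directionality-independent
    del actor, k
    return out


def _dwell_leave(cfg: UndividedSimConfig, cat: str, rng) -> float:
    p = min(1.0 / cfg.dwell_s[cat], 1.0)
    if cfg.dwell_model == "geometric":
        return p
    # negative-binomial dwell: thin the leave probability by a gamma mixer
    return min(p * rng.gamma(cfg.negbin_r, 1.0 / cfg.negbin_r), 1.0)


def _simulate_joint_stream(
    cfg: UndividedSimConfig, mixed: bool, rng: np.random.Generator
) -> np.ndarray:
    """Sequence of joint-state indices at the 1-s step."""
    n = int(round(cfg.duration_s / cfg.step_s))
    states = np.empty(n, dtype=int)
    s = JOINT_STATES.index("alone")
    for t in range(n):
        states[t] = s
        p_leave = _dwell_leave(cfg, _STATE_CATEGORY[JOINT_STATES[s]], rng)
        if rng.random() < p_leave:
            h = _entry_hazards(cfg, t * cfg.step_s, mixed)
            h = h.copy()
            h[s] = 0.0
            tot = h.sum()
            if tot > 0:
                s = int(rng.choice(len(JOINT_STATES), p=h / tot))
    return states


_RAW = {c: i for i, c in enumerate(RAW_CATEGORIES)}

#: working-label code -> candidate raw emission columns
_EMISSION = {
    _W["huddling"]: ("huddling",),
    _W["behaving_alone"]: ("moving_alone", "idling_alone"),
    _W["chasing"]: ("chasing",),
    _W["being_chased"]: ("being_chased",),
    _W["attacking"]: ("aggression",),
    _W["being_attacked"]: ("aggression",),
    _W["pointing"]: ("sniffing", "approaching"),
    _W["being_pointed_at"]: ("being_sniffed",),
}


def _emit_animal(
    labels_1s: np.ndarray,
    cfg: UndividedSimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame raw one-hot scores + attack flags from a 1-s label stream."""
    fpb = int(round(cfg.frame_rate_hz * cfg.step_s))
    frames = np.repeat(labels_1s, fpb)
    n = len(frames)
    scores = np.zeros((n, len(RAW_CATEGORIES)))
    for code, cands in _EMISSION.items():
        sel = frames == code
        if not sel.any():
            continue
        if len(cands) == 1:
            scores[sel, _RAW[cands[0]]] = 1.0
        else:
            pick = rng.integers(0, len(cands), size=int(sel.sum()))
            idx = np.flatnonzero(sel)
            for j, c in enumerate(cands):
                scores[idx[pick == j], _RAW[c]] = 1.0
    if cfg.label_noise > 0:
        flip = rng.random(n) < cfg.label_noise
        new_cat = rng.integers(0, len(RAW_CATEGORIES), size=int(flip.sum()))
        scores[flip] = 0.0
        scores[np.flatnonzero(flip), new_cat] = 1.0
    attacking = frames == _W["attacking"]
    being_attacked = frames == _W["being_attacked"]
    return scores, attacking, being_attacked


def simulate_undivided_streams(
    cfg: UndividedSimConfig,
) -> tuple[dict, GroundTruth]:
    """In-memory undivided cohort.

    Returns ``artifacts[(dyad_id, sex)] = (BehaviorScoreTable,
    AnnotationTrack)`` plus the ground truth.  Per dyad, the joint chain
    guarantees the dyadic constraints by construction: huddling and
    behaving-alone are mutual; chasing, attacking and pointing assign the
    focal role to one animal and the mirror role to the partner; the two
    animals are never both focal attackers.
    """
    dyads = make_dyads(cfg.n_dyads_per_subtype)
    truth = GroundTruth(dyads=dyads)
    artifacts: dict = {}
    children = np.random.SeedSequence(cfg.seed).spawn(len(dyads))
    for dyad, ss in zip(dyads, children):
        sub = ss.spawn(4)
        rng_chain = np.random.default_rng(sub[0])
        mixed = dyad.dyad_type == "mixed"
        joint = _simulate_joint_stream(cfg, mixed, rng_chain)
        lab = np.array([STATE_LABELS[JOINT_STATES[s]] for s in joint])
        streams = {"M": lab[:, 0], "F": lab[:, 1]}
        T0 = joint_transition_matrix(cfg, mixed, t=0.0)
        truth.joint_matrices[dyad.dyad_id] = T0
        truth.directional_matrices[dyad.dyad_id] = {
            "male_to_female": directional_matrix_from_joint(T0, "M"),
            "female_to_male": directional_matrix_from_joint(T0, "F"),
        }
        for sex, rng in (("M", np.random.default_rng(sub[2])), ("F", np.random.default_rng(sub[3]))):
            animal_id = f"{dyad.dyad_id}{sex}"
            truth.label_streams[animal_id] = streams[sex]
            scores, att, rec = _emit_animal(streams[sex], cfg, rng)
            frames = np.arange(len(scores))
            df = pd.DataFrame(scores, columns=list(RAW_CATEGORIES))
            df.insert(0, "frame", frames)
            table = BehaviorScoreTable(animal_id, df, RAW_CATEGORIES)
            ann = AnnotationTrack(
                animal_id,
                pd.DataFrame(
                    {"frame": frames, "attacking": att, "being_attacked": rec}
                ),
            )
            artifacts[(dyad.dyad_id, sex)] = (table, ann)
    return artifacts, truth


def generate_undivided_cohort(
    cfg: UndividedSimConfig, outdir: str | os.PathLike
) -> tuple[dict, GroundTruth]:
    """Write score tables and attack annotations per animal; return truth."""
    os.makedirs(outdir, exist_ok=True)
    artifacts, truth = simulate_undivided_streams(cfg)
    dyads = truth.dyads
    files: dict = {
        "scores": {},
        "annotations": {},
        "metadata": os.path.join(outdir, "metadata.yaml"),
    }
    merge_root = np.random.SeedSequence((cfg.seed, 911)).spawn(len(dyads))
    for dyad, mss in zip(dyads, merge_root):
        for sex in ("M", "F"):
            animal_id = f"{dyad.dyad_id}{sex}"
            table, ann = artifacts[(dyad.dyad_id, sex)]
            sp = os.path.join(outdir, f"scores_{animal_id}.csv")
            ap = os.path.join(outdir, f"annotations_{animal_id}.csv")
            write_behavior_scores(table, sp)
            write_annotation_track(ann, ap)
            files["scores"][(dyad.dyad_id, sex)] = sp
            files["annotations"][(dyad.dyad_id, sex)] = ap
        if cfg.merge_artifact_rate > 0:
            streams = {
                "M": truth.label_streams[f"{dyad.dyad_id}M"],
                "F": truth.label_streams[f"{dyad.dyad_id}F"],
            }
            _inject_merge_artifacts(
                files, dyad, streams, cfg, np.random.default_rng(mss)
            )
    meta = {
        "experiment": "undivided",
        "frame_rate_hz": cfg.frame_rate_hz,
        "duration_s": cfg.duration_s,
        "step_s": cfg.step_s,
        "seed": cfg.seed,
        "dyads": dyads,
    }
    write_metadata(meta, files["metadata"])
    return files, truth


def _inject_merge_artifacts(files, dyad, streams, cfg, rng) -> None:
    """Overwrite huddle frames with single-detection artifacts on disk.

    Emulates classifier identity merges: inside a huddle one animal's scores
    go missing while the partner is scored idling-alone.
    """
    fpb = int(round(cfg.frame_rate_hz * cfg.step_s))
    hud = _W["huddling"]
    sec_hud = streams["M"] == hud
    candidates = np.flatnonzero(sec_hud[1:] & sec_hud[:-1]) + 1  # not the 1st second
    hit = candidates[rng.random(len(candidates)) < cfg.merge_artifact_rate]
    if not len(hit):
        return
    victim = rng.integers(0, 2, size=len(hit))
    for sexes, sel in ((("M", "F"), victim == 0), (("F", "M"), victim == 1)):
        gone, kept = sexes
        secs = hit[sel]
        if not len(secs):
            continue
        fr = (secs[:, None] * fpb + np.arange(fpb)[None, :]).ravel()
        for sid, mode in ((gone, "nan"), (kept, "alone")):
            path = files["scores"][(dyad.dyad_id, sid)]
            df = pd.read_csv(path)
            if mode == "nan":
                df.loc[df.index[fr], list(RAW_CATEGORIES)] = np.nan
            else:
                df.loc[df.index[fr], list(RAW_CATEGORIES)] = 0.0
                df.loc[df.index[fr], "idling_alone"] = 1.0
            df.to_csv(path, index=False)
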