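"""Monte-Carlo recovery and calibration drivers.

These run the full simulate→analyze loop at small problem sizes and return
the quantities used to validate the pipeline: detection of the configured
sex and dyad-type effects, false-positive calibration under the null, and
transition-probability recovery error.  They are deterministic given the
base seed (per-repetition seeds are derived from it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .categorization import apply_dyad_rules, consolidate_categories, labelize
from .decomposition import direction_to_divider
from .simulate import (
    DividedSimConfig,
    UndividedSimConfig,
    divided_geometries,
    simulate_divided_tracks,
    simulate_undivided_streams,
)
from .timeseries import bin_and_smooth, binned_long, label_probabilities, rm_anova
from .transitions import binned_labels_exp2, transition_matrix
from .io import LabelStream
from .vocab import WORKING_CATEGORIES


def orientation_sex_effect_p(
    seed: int,
    n_dyads_per_subtype=(2, 2, 2, 2),
    duration_s: float = 7200.0,
    frame_rate_hz: float = 5.0,
    n_bins: int = 24,
    null: bool = False,
) -> float:
    """One divided cohort → within-dyad sex-effect p on binned direction.

    ``null=True`` equalizes the male and female orientation biases so the
    sex effect is absent by construction.
    """
    bias = (
        {(s, t): 0.2 for s in "MF" for t in ("matched", "mixed")}
        if null
        else DividedSimConfig().orientation_bias
    )
    cfg = DividedSimConfig(
        n_dyads_per_subtype=n_dyads_per_subtype,
        duration_s=duration_s,
        frame_rate_hz=frame_rate_hz,
        orientation_bias=bias,
        seed=seed,
    )
    tracks, _ = simulate_divided_tracks(cfg)
    g_m, g_f = divided_geometries(cfg)
    binned = {}
    meta_rows = []
    for (dyad_id, sex), track in tracks.items():
        geom = g_m if sex == "M" else g_f
        series = direction_to_divider(track, geom)
        binned[f"{dyad_id}{sex}"] = bin_and_smooth(series, cfg.duration_s / n_bins)
        meta_rows.append({"animal_id": f"{dyad_id}{sex}", "subject": dyad_id, "sex": sex})
    meta = pd.DataFrame(meta_rows).set_index("animal_id")
    res = rm_anova(binned_long(binned, meta), subject="subject", factor="sex")
    return float(res.effect("sex")["p"])


def aggression_dyad_type_p(
    seed: int,
    n_dyads_per_subtype=(2, 2, 2, 2),
    duration_s: float = 14400.0,
    frame_rate_hz: float = 1.0,
    n_bins: int = 80,
    category: str = "attacking",
) -> float:
    """One undivided cohort → dyad-type effect p on female category
    probability, through the full categorization pipeline."""
    cfg = UndividedSimConfig(
        n_dyads_per_subtype=n_dyads_per_subtype,
        duration_s=duration_s,
        frame_rate_hz=frame_rate_hz,
        seed=seed,
    )
    artifacts, truth = simulate_undivided_streams(cfg)
    binned = {}
    meta_rows = []
    for d in truth.dyads:
        sm, am = artifacts[(d.dyad_id, "M")]
        sf, af = artifacts[(d.dyad_id, "F")]
        cm, cf = apply_dyad_rules(consolidate_categories(sm), consolidate_categories(sf))
        stream_f = labelize(cf, af)
        binned[f"{d.dyad_id}F"] = label_probabilities(
            stream_f, cfg.frame_rate_hz, cfg.duration_s / n_bins, (category,)
        )[category]
        meta_rows.append(
            {"animal_id": f"{d.dyad_id}F", "subject": d.dyad_id, "dyad_type": d.dyad_type}
        )
    meta = pd.DataFrame(meta_rows).set_index("animal_id")
    res = rm_anova(binned_long(binned, meta), subject="subject", between="dyad_type")
    return float(res.effect("dyad_type")["p"])


def detection_rate(p_fn, base_seed: int, n_seeds: int = 20, alpha: float = 0.05, **kw) -> float:
    """Fraction of seeds in which ``p_fn(seed, **kw) < alpha``."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_seeds) % (2**31 - 1)
    hits = sum(p_fn(int(s), **kw) < alpha for s in seeds)
    return hits / n_seeds


def null_rejection_rate(
    base_seed: int,
    n_cohorts: int = 500,
    alpha: float = 0.05,
    n_dyads_per_subtype=(2, 2, 2, 2),
    duration_s: float = 240.0,
    frame_rate_hz: float = 2.0,
    n_bins: int = 6,
) -> float:
    """Sex-effect rejection rate over null divided cohorts (no simulated
    group difference), at a heavily scaled-down problem size."""
    seeds = np.random.SeedSequence((base_seed, 7)).generate_state(n_cohorts) % (2**31 - 1)
    rejections = 0
    for s in seeds:
        p = orientation_sex_effect_p(
            int(s),
            n_dyads_per_subtype=n_dyads_per_subtype,
            duration_s=duration_s,
            frame_rate_hz=frame_rate_hz,
            n_bins=n_bins,
            null=True,
        )
        rejections += p < alpha
    return rejections / n_cohorts


def transition_recovery_error(seed: int, duration_s: float = 100000.0) -> float:
    """Max |estimated − generating| directional transition probability for
    one long time-homogeneous stream from a known coupled chain.

    The chain is parameterized so all five categories are comparably
    occupied (every matrix row is well visited); dwell times and hazards
    are otherwise arbitrary known values.
    """
    cfg = UndividedSimConfig(
        n_dyads_per_subtype=(1, 0, 0, 0),
        duration_s=duration_s,
        frame_rate_hz=1.0,
        chase_hazard={"M": 0.02, "F": 0.02},
        attack_hazard={"M": 0.02, "F": 0.02},
        point_hazard={"M": 0.02, "F": 0.02},
        alone_hazard=0.04,
        huddle_hazard=0.04,
        dwell_s={
            "chasing": 6.0,
            "attacking": 5.0,
            "pointing": 6.0,
            "behaving_alone": 10.0,
            "huddling": 10.0,
        },
        aggression_half_life_s=1e12,
        huddling_rise_half_life_s=1e12,
        label_noise=0.0,
        seed=seed,
    )
    _, truth = simulate_undivided_streams(cfg)
    m = LabelStream("m", 0.0, WORKING_CATEGORIES, truth.label_streams["d01M"])
    f = LabelStream("f", 0.0, WORKING_CATEGORIES, truth.label_streams["d01F"])
    tm = transition_matrix(
        binned_labels_exp2(m, 1.0), binned_labels_exp2(f, 1.0)
    )
    gen = truth.directional_matrices["d01"]["male_to_female"]
    visited = ~tm.unvisited_rows
    return float(np.max(np.abs(tm.probabilities[visited] - gen[visited])))
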