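"""End-to-end orchestration: simulate → decompose/categorize → statistics.

The pipeline runs the full analysis on synthetic cohorts at a configurable
scale and writes every intermediate and final table under an output
directory.  Stage order: divided simulation → decomposition → time-binned
group ANOVA; undivided simulation → categorization → category-probability
ANOVA; cross-experiment profiles and correlations; directional transition
analysis for both experiments.  Each output table carries a header comment
with the tool version, seed and config hash; a run report summarizes row
counts per stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .categorization import apply_dyad_rules, consolidate_categories, labelize
from .correlation import build_profiles, group_correlations, profiles_frame
from .decomposition import decompose, interpolate_low_confidence
from .io import read_annotation_track, read_behavior_scores, read_keypoint_table
from .simulate import (
    DividedSimConfig,
    UndividedSimConfig,
    divided_geometries,
    generate_divided_cohort,
    generate_undivided_cohort,
)
from .timeseries import (
    binned_long,
    bin_and_smooth,
    ks_normality,
    label_probabilities,
    rm_anova,
    tukey_per_bin,
)
from .transitions import (
    average_graph,
    binned_labels_exp2,
    compare_transitions,
    discretize_exp1,
    graph_edge_list,
    transition_matrix,
)
from .vocab import ACTIVE_CATEGORIES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Scaled-down defaults: 2-h divided at 5 Hz, 30-min undivided at 5 Hz.

    Bin widths default to duration/72 (divided) and duration/80 (undivided)
    so the bin counts match the full-scale design at any scale.
    """

    outdir: str = "ethodyad_run"
    seed: int = 0
    scale: float = 1.0  # extra down-sampling on top of the scaled defaults
    n_dyads_per_subtype: tuple[int, int, int, int] = (7, 8, 7, 6)
    divided_duration_s: float = 7200.0
    divided_frame_rate_hz: float = 5.0
    undivided_duration_s: float = 1800.0
    undivided_frame_rate_hz: float = 5.0
    bin_width_exp1_s: float | None = None  # default duration/72
    bin_width_exp2_s: float | None = None  # default duration/80
    smoothing_window_bins: int = 6
    alpha: float = 0.05
    direction_threshold: float = 0.0
    distance_threshold_cm: float | None = None
    exp1_transition_window_fraction: float = 1.0 / 6.0  # first 12 h of 72 h
    divided_overrides: dict = field(default_factory=dict)
    undivided_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]


def _header(cfg: PipelineConfig) -> str:
    return f"# ethodyad {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"


def _write(df: pd.DataFrame, path: str, cfg: PipelineConfig, **kw) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, index=kw.pop("index", False))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; return the run report (also written to YAML)."""
    t0 = time.time()
    os.makedirs(cfg.outdir, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": {},
        "warnings": [],
    }
    s = cfg.scale

    # ---- stage 1: divided simulation + decomposition -------------------
    div_dir = os.path.join(cfg.outdir, "divided")
    dcfg = DividedSimConfig(
        n_dyads_per_subtype=cfg.n_dyads_per_subtype,
        duration_s=cfg.divided_duration_s * s,
        frame_rate_hz=cfg.divided_frame_rate_hz,
        seed=cfg.seed,
        **cfg.divided_overrides,
    )
    try:
        files_div, truth_div = generate_divided_cohort(dcfg, div_dir)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage simulate-divided failed: {e}") from e
    g_m, g_f = divided_geometries(dcfg)
    bw1 = cfg.bin_width_exp1_s or dcfg.duration_s / 72.0

    binned_dir = {}
    series_by_animal = {}
    meta_rows = []
    for (dyad_id, sex), path in files_div["keypoints"].items():
        geom = g_m if sex == "M" else g_f
        track = interpolate_low_confidence(read_keypoint_table(path, geom, f"{dyad_id}{sex}"))
        var = decompose(track, geom)
        series_by_animal[f"{dyad_id}{sex}"] = var
        for name, vs in var.items():
            binned_dir.setdefault(name, {})[f"{dyad_id}{sex}"] = bin_and_smooth(
                vs, bw1, cfg.smoothing_window_bins
            )
    dyad_of = {d.dyad_id: d for d in truth_div.dyads}
    for (dyad_id, sex) in files_div["keypoints"]:
        meta_rows.append(
            {
                "animal_id": f"{dyad_id}{sex}",
                "subject": dyad_id,
                "sex": sex,
                "dyad_type": dyad_of[dyad_id].dyad_type,
                "subtype": dyad_of[dyad_id].subtype,
            }
        )
    meta = pd.DataFrame(meta_rows).set_index("animal_id")
    report["stages"]["divided"] = {
        "n_animals": len(series_by_animal),
        "n_bins": len(next(iter(binned_dir["direction"].values()))),
    }

    # ---- stage 2: exp-1 statistics --------------------------------------
    stats_rows = []
    tukey_frames = []
    for varname, binned in binned_dir.items():
        long_df = binned_long(binned, meta)
        res = rm_anova(long_df, subject="subject", within="bin", factor="sex")
        for _, r in res.table.iterrows():
            stats_rows.append(
                {"experiment": 1, "variable": varname, "grouping": "all", **r.to_dict()}
            )
        tk = tukey_per_bin(long_df, group="sex", alpha=cfg.alpha)
        tk.insert(0, "variable", varname)
        tukey_frames.append(tk)
        ks = ks_normality(long_df)
        n_fail = int((ks["result"] == "fail").sum())
        if n_fail:
            report["warnings"].append(
                f"exp1 {varname}: {n_fail} bins fail KS normality (report only)"
            )
    exp1_stats = pd.DataFrame(stats_rows)
    _write(exp1_stats, os.path.join(cfg.outdir, "exp1_anova.csv"), cfg)
    _write(pd.concat(tukey_frames), os.path.join(cfg.outdir, "exp1_tukey.csv"), cfg)
    report["stages"]["exp1_stats"] = {"n_effects": len(exp1_stats)}

    # ---- stage 3: undivided simulation + categorization ------------------
    und_dir = os.path.join(cfg.outdir, "undivided")
    ucfg = UndividedSimConfig(
        n_dyads_per_subtype=cfg.n_dyads_per_subtype,
        duration_s=cfg.undivided_duration_s * s,
        frame_rate_hz=cfg.undivided_frame_rate_hz,
        seed=cfg.seed + 1,
        **cfg.undivided_overrides,
    )
    try:
        files_und, truth_und = generate_undivided_cohort(ucfg, und_dir)
    except Exception as e:  # noqa: BLE001
        raise RuntimeError(f"stage simulate-undivided failed: {e}") from e

    streams = {}
    for d in truth_und.dyads:
        sm = read_behavior_scores(files_und["scores"][(d.dyad_id, "M")], animal_id=f"{d.dyad_id}M")
        sf = read_behavior_scores(files_und["scores"][(d.dyad_id, "F")], animal_id=f"{d.dyad_id}F")
        am = read_annotation_track(files_und["annotations"][(d.dyad_id, "M")])
        af = read_annotation_track(files_und["annotations"][(d.dyad_id, "F")])
        cm, cf = apply_dyad_rules(consolidate_categories(sm), consolidate_categories(sf))
        streams[f"{d.dyad_id}M"] = labelize(cm, am)
        streams[f"{d.dyad_id}F"] = labelize(cf, af)
    report["stages"]["undivided"] = {"n_animals": len(streams)}

    bw2 = cfg.bin_width_exp2_s or ucfg.duration_s / 80.0
    stats_rows = []
    for cat in ACTIVE_CATEGORIES:
        binned = {
            aid: label_probabilities(
                st, ucfg.frame_rate_hz, bw2, (cat,), cfg.smoothing_window_bins
            )[cat]
            for aid, st in streams.items()
        }
        long_df = binned_long(binned, meta)
        res = rm_anova(long_df, subject="subject", within="bin", factor="sex")
        for _, r in res.table.iterrows():
            stats_rows.append(
                {"experiment": 2, "variable": cat, "grouping": "all", **r.to_dict()}
            )
    exp2_stats = pd.DataFrame(stats_rows)
    _write(exp2_stats, os.path.join(cfg.outdir, "exp2_anova.csv"), cfg)
    report["stages"]["exp2_stats"] = {"n_effects": len(exp2_stats)}

    # ---- stage 4: profiles + correlations --------------------------------
    profiles = build_profiles(series_by_animal, streams, meta)
    pf = profiles_frame(profiles)
    _write(pf.reset_index(), os.path.join(cfg.outdir, "profiles.csv"), cfg)
    corrs = group_correlations(profiles, alpha=cfg.alpha)
    for (sex, dtp), res in corrs.items():
        _write(
            res["R"].reset_index(),
            os.path.join(cfg.outdir, f"corr_R_{sex}_{dtp}.csv"),
            cfg,
        )
        _write(
            res["P"].reset_index(),
            os.path.join(cfg.outdir, f"corr_P_{sex}_{dtp}.csv"),
            cfg,
        )
    report["stages"]["correlations"] = {"n_groups": len(corrs), "n_profiles": len(profiles)}

    # ---- stage 5: transitions --------------------------------------------
    dyad_types = {d.dyad_id: d.dyad_type for d in truth_und.dyads}
    window = dcfg.duration_s * cfg.exp1_transition_window_fraction
    mats1 = {"male_to_female": [], "female_to_male": []}
    for d in truth_div.dyads:
        dm = discretize_exp1(
            series_by_animal[f"{d.dyad_id}M"]["direction"],
            series_by_animal[f"{d.dyad_id}M"]["distance_cm"],
            cfg.direction_threshold,
            cfg.distance_threshold_cm,
            window_s=window,
        )
        df_ = discretize_exp1(
            series_by_animal[f"{d.dyad_id}F"]["direction"],
            series_by_animal[f"{d.dyad_id}F"]["distance_cm"],
            cfg.direction_threshold,
            cfg.distance_threshold_cm,
            window_s=window,
        )
        mats1["male_to_female"].append(transition_matrix(dm, df_, d.dyad_id, "male_to_female"))
        mats1["female_to_male"].append(transition_matrix(df_, dm, d.dyad_id, "female_to_male"))

    mats2 = {"male_to_female": [], "female_to_male": []}
    for d in truth_und.dyads:
        bm = binned_labels_exp2(streams[f"{d.dyad_id}M"], ucfg.frame_rate_hz)
        bf = binned_labels_exp2(streams[f"{d.dyad_id}F"], ucfg.frame_rate_hz)
        mats2["male_to_female"].append(transition_matrix(bm, bf, d.dyad_id, "male_to_female"))
        mats2["female_to_male"].append(transition_matrix(bf, bm, d.dyad_id, "female_to_male"))

    import networkx as nx

    trans_rows = []
    for exp, mats in ((1, mats1), (2, mats2)):
        for direction, mlist in mats.items():
            for dtp in ("matched", "mixed"):
                grp = [m for m in mlist if dyad_types[m.dyad_id] == dtp]
                g = average_graph(grp)
                base = os.path.join(cfg.outdir, f"graph_exp{exp}_{direction}_{dtp}")
                nx.write_graphml(g, base + ".graphml")
                _write(graph_edge_list(g), base + "_edges.csv", cfg)
            from .anova import InsufficientDataError

            try:
                res = compare_transitions(mlist, dyad_types, alpha=cfg.alpha)
            except InsufficientDataError as e:
                report["warnings"].append(
                    f"transitions exp{exp} {direction}: {e} (comparison skipped)"
                )
                continue
            for _, r in res.table.iterrows():
                trans_rows.append(
                    {"experiment": exp, "directionality": direction, **r.to_dict()}
                )
    _write(pd.DataFrame(trans_rows), os.path.join(cfg.outdir, "transitions_anova.csv"), cfg)
    report["stages"]["transitions"] = {"n_effects": len(trans_rows)}

    report["elapsed_s"] = round(time.time() - t0, 2)
    with open(os.path.join(cfg.outdir, "run_report.yaml"), "w") as fh:
        yaml.safe_dump(report, fh, sort_keys=False)
    return report
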