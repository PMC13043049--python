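"""Cross-experiment behavioral profiles and group-wise correlation matrices.

Each animal is reduced to eight session averages — direction to divider,
distance to divider and locomotion speed from divided cohabitation, plus
the five behavior-category probabilities from undivided cohabitation — and
Pearson correlations among the eight are computed within each sex ×
dyad-type group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decomposition import VariableSeries
from .io import LabelStream
from .vocab import ACTIVE_CATEGORIES

logger = logging.getLogger(__name__)

PROFILE_VARIABLES = ("direction", "distance_cm", "speed_cms", *ACTIVE_CATEGORIES)


@dataclass
class AnimalProfile:
    """Eight session-averaged behavioral values for one animal."""

    animal_id: str
    sex: str
    dyad_type: str
    values: dict

    def __post_init__(self) -> None:
        missing = [v for v in PROFILE_VARIABLES if v not in self.values]
        if missing:
            raise ValueError(f"profile missing variables: {missing}")
        for cat in ACTIVE_CATEGORIES:
            v = self.values[cat]
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{cat} probability outside [0, 1]: {v}")


def build_profiles(
    exp1: dict[str, dict[str, VariableSeries]],
    exp2: dict[str, LabelStream],
    animal_meta: pd.DataFrame,
) -> list[AnimalProfile]:
    """Session means per animal across both experiments.

    ``exp1`` maps animal_id → {variable → VariableSeries}; ``exp2`` maps
    animal_id → frame- or bin-level label stream over the working
    vocabulary.  Animals missing either experiment are excluded and logged.
    Category probabilities are the fraction of non-missing frames carrying
    the focal label.
    """
    profiles = []
    for animal_id in animal_meta.index:
        if animal_id not in exp1 or animal_id not in exp2:
            logger.warning("%s missing one experiment; excluded from profiles", animal_id)
            continue
        vals = {}
        for var, series in exp1[animal_id].items():
            if var in PROFILE_VARIABLES:
                v = series.valid()
                vals[var] = float(np.mean(v)) if v.size else np.nan
        stream = exp2[animal_id]
        lab = stream.labels
        valid = lab >= 0
        denom = max(int(valid.sum()), 1)
        for cat in ACTIVE_CATEGORIES:
            code = stream.vocabulary.index(cat)
            vals[cat] = float(np.sum(lab[valid] == code)) / denom
        profiles.append(
            AnimalProfile(
                animal_id,
                animal_meta.loc[animal_id, "sex"],
                animal_meta.loc[animal_id, "dyad_type"],
                vals,
            )
        )
    return profiles


def profiles_frame(profiles: list[AnimalProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {"animal_id": p.animal_id, "sex": p.sex, "dyad_type": p.dyad_type, **p.values}
        )
    return pd.DataFrame(rows).set_index("animal_id")


def group_correlations(
    profiles: list[AnimalProfile],
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> dict:
    """Per sex × dyad-type group: 8×8 Pearson R and two-sided P matrices.

    Groups with fewer than 3 animals are skipped.  Zero-variance variables
    yield NaN (masked) rows/columns.  ``bh_correction`` applies a
    Benjamini–Hochberg adjustment to the off-diagonal P values before the
    significance listing (off by default: per-pair P values are reported
    uncorrected).
    """
    df = profiles_frame(profiles)
    out = {}
    k = len(PROFILE_VARIABLES)
    for (sex, dtp), chunk in df.groupby(["sex", "dyad_type"]):
        X = chunk[list(PROFILE_VARIABLES)].to_numpy(dtype=float)
        n = X.shape[0]
        if n < 3:
            logger.warning("group %s/%s has n=%d < 3; skipped", sex, dtp, n)
            continue
        R = np.full((k, k), np.nan)
        P = np.full((k, k), np.nan)
        for i in range(k):
            R[i, i] = 1.0
            P[i, i] = 0.0
            for j in range(i + 1, k):
                xi, xj = X[:, i], X[:, j]
                if np.std(xi) == 0 or np.std(xj) == 0:
                    continue
                r, p = stats.pearsonr(xi, xj)
                R[i, j] = R[j, i] = r
                P[i, j] = P[j, i] = p
        pairs = []
        pvals = []
        idx = []
        for i in range(k):
            for j in range(i + 1, k):
                if not np.isnan(P[i, j]):
                    pvals.append(P[i, j])
                    idx.append((i, j))
        if bh_correction and pvals:
            order = np.argsort(pvals)
            m = len(pvals)
            adj = np.empty(m)
            prev = 1.0
            for rank, oi in list(enumerate(order))[::-1]:
                prev = min(prev, pvals[oi] * m / (rank + 1))
                adj[oi] = prev
            pvals = list(adj)
        for (i, j), p in zip(idx, pvals):
            if p < alpha:
                pairs.append(
                    {
                        "var_a": PROFILE_VARIABLES[i],
                        "var_b": PROFILE_VARIABLES[j],
                        "R": R[i, j],
                        "p": p,
                        "sign": "+" if R[i, j] > 0 else "-",
                    }
                )
        out[(sex, dtp)] = {
            "R": pd.DataFrame(R, index=PROFILE_VARIABLES, columns=PROFILE_VARIABLES),
            "P": pd.DataFrame(P, index=PROFILE_VARIABLES, columns=PROFILE_VARIABLES),
            "n": n,
            "significant": pd.DataFrame(pairs),
        }
    return out
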