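"""Binning, smoothing, group statistics and bout structure.

Continuous decomposition variables are averaged into fixed-width time bins
(1-h bins over 72 h → 72 bins for divided cohabitation; 3-min bins over 4 h
→ 80 bins for undivided), then passed through a 6-bin centered moving mean.
Frame-level behavior labels are binned as per-category occupancy
probabilities (fraction of frames carrying the label).  Group comparisons
use the two-way repeated-measures ANOVA in :mod:`ethodyad.anova` followed by
Tukey honest-significant-difference tests per time bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .anova import AnovaResults, RepeatedMeasuresAnova
from .decomposition import VariableSeries
from .io import LabelStream

logger = logging.getLogger(__name__)


@dataclass
class BinnedSeries:
    """Per-bin means (or label probabilities) for one animal and variable."""

    animal_id: str
    variable: str
    bin_width_s: float
    values: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)


def n_bins_for(duration_s: float, bin_width_s: float) -> int:
    """floor(duration / bin width); the trailing partial bin is dropped."""
    return int(np.floor(duration_s / bin_width_s + 1e-9))


def bin_series(series: VariableSeries, bin_width_s: float) -> BinnedSeries:
    """Average a per-frame variable into fixed-width bins, ignoring missing
    frames.  Bins with no valid frame are NaN."""
    t = series.clock_s
    if len(t) < 2:
        raise ValueError("need at least 2 frames to bin")
    dt = float(np.median(np.diff(t)))
    duration = len(t) * dt
    nb = n_bins_for(duration, bin_width_s)
    if nb < 1:
        raise ValueError("bin width exceeds session duration")
    if abs(duration - nb * bin_width_s) > dt / 2:
        logger.warning(
            "%s/%s: %.1f s beyond the last full bin dropped",
            series.animal_id,
            series.variable,
            duration - nb * bin_width_s,
        )
    idx = np.floor((t - t[0]) / bin_width_s + 1e-9).astype(int)
    keep = (idx >= 0) & (idx < nb) & ~series.missing & ~np.isnan(series.values)
    sums = np.bincount(idx[keep], weights=series.values[keep], minlength=nb)
    counts = np.bincount(idx[keep], minlength=nb)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return BinnedSeries(series.animal_id, series.variable, bin_width_s, vals)


def moving_mean(binned: BinnedSeries, window_bins: int = 6) -> BinnedSeries:
    """Centered moving mean with shrinking windows at the edges.

    For an even window w the span is [i−w//2, i+w//2−1] shifted so that the
    extra element falls on the left (pandas ``rolling(center=True)``
    convention).  NaN bins are skipped within each window.
    """
    s = pd.Series(binned.values)
    sm = s.rolling(window=window_bins, center=True, min_periods=1).mean()
    return replace(binned, values=sm.to_numpy(), smoothed=True)


def bin_and_smooth(
    series: VariableSeries, bin_width_s: float, window_bins: int = 6
) -> BinnedSeries:
    """Per-bin mean followed by the moving-mean smoother."""
    return moving_mean(bin_series(series, bin_width_s), window_bins)


def label_probabilities(
    stream: LabelStream,
    frame_rate_hz: float,
    bin_width_s: float,
    categories: tuple[str, ...] | None = None,
    window_bins: int | None = 6,
) -> dict[str, BinnedSeries]:
    """Per-bin occupancy probability of each category for one animal.

    The probability is the fraction of non-missing frames in the bin whose
    label equals the category (focal roles only; mirror roles are distinct
    labels and are not folded in here).  ``window_bins=None`` skips
    smoothing.
    """
    cats = categories if categories is not None else stream.vocabulary
    labels = stream.labels
    n = len(labels)
    dt = 1.0 / frame_rate_hz
    duration = n * dt
    nb = n_bins_for(duration, bin_width_s)
    t = np.arange(n) * dt
    idx = np.floor(t / bin_width_s + 1e-9).astype(int)
    valid = (labels >= 0) & (idx < nb)
    denom = np.bincount(idx[valid], minlength=nb).astype(float)
    out: dict[str, BinnedSeries] = {}
    for cat in cats:
        code = stream.vocabulary.index(cat)
        hits = np.bincount(idx[valid & (labels == code)], minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(denom > 0, hits / np.maximum(denom, 1), np.nan)
        b = BinnedSeries(stream.animal_id, cat, bin_width_s, p)
        out[cat] = moving_mean(b, window_bins) if window_bins else b
    return out


# ---------------------------------------------------------------------------
# group-level statistics
# ---------------------------------------------------------------------------


def binned_long(
    binned: dict[str, BinnedSeries], meta: pd.DataFrame
) -> pd.DataFrame:
    """Stack per-animal binned series into a long DataFrame.

    ``meta`` is indexed by animal_id with whatever design columns are needed
    (subject/dyad, sex, dyad_type, ...); they are broadcast to every bin.
    """
    frames = []
    for animal_id, b in binned.items():
        df = pd.DataFrame({"bin": np.arange(len(b)), "value": b.values})
        df["animal_id"] = animal_id
        for col in meta.columns:
            df[col] = meta.loc[animal_id, col]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def rm_anova(
    long_df: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: str = "bin",
    factor: str | None = None,
    between: str | None = None,
    gg_correction: bool = False,
) -> AnovaResults:
    """Fit the two-way repeated-measures ANOVA on a long time-bin table."""
    model = RepeatedMeasuresAnova(
        long_df, dv=dv, subject=subject, within=within, factor=factor, between=between
    )
    return model.fit(gg_correction=gg_correction)


def tukey_per_bin(
    long_df: pd.DataFrame,
    group: str,
    dv: str = "value",
    within: str = "bin",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD between groups within every time bin.

    Returns one row per bin with the smallest pairwise Tukey p value, a
    ``significant`` flag at ``alpha`` and a ``degenerate`` flag for bins
    with zero pooled variance; bins with fewer than two values in any group
    are excluded (NaN p).
    """
    rows = []
    for b, chunk in long_df.groupby(within):
        samples = [
            g[dv].dropna().to_numpy() for _, g in chunk.groupby(group)
        ]
        if len(samples) < 2 or any(len(s) < 2 for s in samples):
            rows.append((b, np.nan, False, False))
            continue
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0 or all(np.ptp(s) == 0 for s in samples):
            degen = not np.allclose([s.mean() for s in samples], samples[0].mean())
            rows.append((b, np.nan, False, True if degen else False))
            continue
        with np.errstate(all="ignore"):
            res = stats.tukey_hsd(*samples)
        p = float(np.min(res.pvalue[~np.eye(len(samples), dtype=bool)]))
        rows.append((b, p, p < alpha, False))
    return pd.DataFrame(rows, columns=[within, "p", "significant", "degenerate"])


def ks_normality(
    long_df: pd.DataFrame,
    dv: str = "value",
    by: list[str] | tuple[str, ...] = ("bin",),
) -> pd.DataFrame:
    """One-sample Kolmogorov–Smirnov check against a fitted normal, per
    repeated measure.  Report only; never gates the ANOVA.  Measures with
    n < 3 or zero variance are skipped with a note."""
    rows = []
    for key, chunk in long_df.groupby(list(by)):
        x = chunk[dv].dropna().to_numpy()
        key = key if isinstance(key, tuple) else (key,)
        if len(x) < 3:
            rows.append((*key, len(x), np.nan, np.nan, "skipped: n < 3"))
            continue
        sd = x.std(ddof=1)
        if sd == 0:
            rows.append((*key, len(x), np.nan, np.nan, "skipped: constant"))
            continue
        stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
        rows.append((*key, len(x), stat, p, "pass" if p >= 0.05 else "fail"))
    return pd.DataFrame(rows, columns=[*by, "n", "stat", "p", "result"])


# ---------------------------------------------------------------------------
# bout structure
# ---------------------------------------------------------------------------


def run_lengths(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(values, lengths) of maximal runs of identical labels."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return labels[:0], np.zeros(0, dtype=int)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(labels)]))
    return labels[starts], ends - starts


def bout_statistics(
    stream: LabelStream,
    bin_width_s: float | None = None,
    min_duration_bins: int = 1,
) -> pd.DataFrame:
    """Run-length bout table: per category, bout count, duration stats and
    hourly rate.  A bout is a maximal run of identical labels; runs shorter
    than ``min_duration_bins`` are ignored."""
    w = bin_width_s if bin_width_s is not None else stream.bin_width_s
    vals, lens = run_lengths(stream.labels)
    total_h = len(stream.labels) * w / 3600.0 if w else np.nan
    rows = []
    for code, cat in enumerate(stream.vocabulary):
        sel = (vals == code) & (lens >= min_duration_bins)
        durs = lens[sel] * w
        n = int(sel.sum())
        rows.append(
            (
                cat,
                n,
                float(np.mean(durs)) if n else np.nan,
                float(np.median(durs)) if n else np.nan,
                float(np.sum(durs)),
                n / total_h if total_h and total_h > 0 else np.nan,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "category",
            "n_bouts",
            "mean_duration_s",
            "median_duration_s",
            "total_duration_s",
            "rate_per_h",
        ],
    )


def group_curves(
    long_df: pd.DataFrame, group: str, dv: str = "value", within: str = "bin"
) -> pd.DataFrame:
    """Mean ± standard error per group per bin (plot-ready)."""
    g = long_df.groupby([group, within])[dv]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out
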