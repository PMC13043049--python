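"""Sex-directional behavior-transition analysis.

Streams are discretized to 1-s bins, then each dyad yields two directional
transition matrices: rows are the *actor* animal's category at time t,
columns the *reactor* animal's category at t+1 (male→female and
female→male).  Matrices are row-normalized to probabilities, averaged into
directed graphs per group, and compared between dyad types with a mixed
two-way ANOVA using the off-diagonal behavior pairs as repeated measures.

Divided cohabitation uses four orientation states (toward/opposite ×
near/away), restricted by default to the initial 12 h of the session;
undivided cohabitation uses the five interaction categories (mirror roles
collapsed onto their interaction category by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .anova import AnovaResults
from .decomposition import VariableSeries
from .io import DataError, LabelStream
from .timeseries import bin_series, tukey_per_bin
from .vocab import (
    ACTIVE_CATEGORIES,
    MIRROR_TO_ACTIVE,
    MISSING_LABEL,
    ORIENTATION_STATES,
    WORKING_CATEGORIES,
)

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Directional actor→reactor transition counts and probabilities."""

    dyad_id: str
    directionality: str  # male_to_female | female_to_male
    vocabulary: tuple[str, ...]
    counts: np.ndarray
    probabilities: np.ndarray = field(init=False)
    unvisited_rows: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.vocabulary)
        if self.counts.shape != (k, k):
            raise ValueError("count matrix must be square over the vocabulary")
        row_sums = self.counts.sum(axis=1)
        self.unvisited_rows = row_sums == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            self.probabilities = np.where(
                row_sums[:, None] > 0, self.counts / np.maximum(row_sums, 1)[:, None], 0.0
            )

    def to_frame(self, kind: str = "probabilities") -> pd.DataFrame:
        arr = getattr(self, kind)
        return pd.DataFrame(arr, index=list(self.vocabulary), columns=list(self.vocabulary))


def discretize_exp1(
    direction: VariableSeries,
    distance: VariableSeries,
    direction_threshold: float = 0.0,
    distance_threshold_cm: float | None = None,
    usable_range_cm: float = 24.15,
    bin_width_s: float = 1.0,
    window_s: float | None = 43200.0,
    animal_id: str | None = None,
) -> LabelStream:
    """Four orientation states from binned direction and distance.

    Both variables are averaged into 1-s bins first; then ``toward`` iff
    binned direction > ``direction_threshold`` (strict, so exactly 0 is
    *opposite*) and ``near`` iff binned distance < ``distance_threshold_cm``
    (default: midpoint of the usable distance range).  Analysis is
    restricted to the first ``window_s`` seconds (default 12 h); pass
    ``window_s=None`` for the whole session.  Missing bins get label −1.
    """
    if distance_threshold_cm is None:
        distance_threshold_cm = usable_range_cm / 2.0
    bdir = bin_series(direction, bin_width_s)
    bdist = bin_series(distance, bin_width_s)
    nb = min(len(bdir), len(bdist))
    if window_s is not None:
        nb = min(nb, int(window_s // bin_width_s))
    d = bdir.values[:nb]
    r = bdist.values[:nb]
    toward = d > direction_threshold
    near = r < distance_threshold_cm
    labels = np.where(toward, 0, 1) + np.where(near, 0, 2)
    labels = np.where(np.isnan(d) | np.isnan(r), MISSING_LABEL, labels)
    return LabelStream(
        animal_id=animal_id or direction.animal_id,
        bin_width_s=bin_width_s,
        vocabulary=ORIENTATION_STATES,
        labels=labels,
    )


def binned_labels_exp2(
    stream: LabelStream,
    frame_rate_hz: float,
    bin_width_s: float = 1.0,
    mirror_collapse: str = "interaction",
) -> LabelStream:
    """Collapse mirror roles and take the modal label per 1-s bin.

    ``mirror_collapse='interaction'`` maps each recipient role onto its
    interaction category (a chase occupies *chasing* bins for both
    animals); ``'drop'`` turns recipient-role frames into missing frames.
    Modal ties are broken by vocabulary order and logged.
    """
    labels = stream.labels
    k_active = len(ACTIVE_CATEGORIES)
    remap = np.full(len(stream.vocabulary), MISSING_LABEL, dtype=int)
    for i, cat in enumerate(stream.vocabulary):
        if cat in ACTIVE_CATEGORIES:
            remap[i] = ACTIVE_CATEGORIES.index(cat)
        elif cat in MIRROR_TO_ACTIVE:
            if mirror_collapse == "interaction":
                remap[i] = ACTIVE_CATEGORIES.index(MIRROR_TO_ACTIVE[cat])
            elif mirror_collapse == "drop":
                remap[i] = MISSING_LABEL
            else:
                raise ValueError(f"unknown mirror_collapse {mirror_collapse!r}")
    active = np.where(labels >= 0, remap[labels], MISSING_LABEL)

    fpb = int(round(frame_rate_hz * bin_width_s))
    nb = len(active) // fpb
    chunk = active[: nb * fpb].reshape(nb, fpb)
    out = np.empty(nb, dtype=int)
    n_ties = 0
    for b in range(nb):
        row = chunk[b]
        row = row[row >= 0]
        if row.size == 0:
            out[b] = MISSING_LABEL
            continue
        counts = np.bincount(row, minlength=k_active)
        best = counts.max()
        if (counts == best).sum() > 1:
            n_ties += 1
        out[b] = int(counts.argmax())  # ties -> earliest in vocabulary
    if n_ties:
        logger.info("%s: %d modal ties broken by vocabulary order", stream.animal_id, n_ties)
    return LabelStream(
        animal_id=stream.animal_id,
        bin_width_s=bin_width_s,
        vocabulary=ACTIVE_CATEGORIES,
        labels=out,
    )


def transition_matrix(
    actor: LabelStream,
    reactor: LabelStream,
    dyad_id: str | None = None,
    directionality: str = "male_to_female",
) -> TransitionMatrix:
    """Count (actor label at t, reactor label at t+1) over all valid t."""
    if len(actor) != len(reactor):
        raise DataError("actor and reactor streams differ in length")
    if actor.vocabulary != reactor.vocabulary:
        raise DataError("actor and reactor streams differ in vocabulary")
    a = actor.labels[:-1]
    r = reactor.labels[1:]
    valid = (a >= 0) & (r >= 0)
    if valid.sum() < 1 or len(actor) < 2:
        raise DataError("fewer than 2 valid bins; cannot form transitions")
    k = len(actor.vocabulary)
    counts = np.zeros((k, k))
    np.add.at(counts, (a[valid], r[valid]), 1.0)
    tm = TransitionMatrix(
        dyad_id=dyad_id or actor.animal_id,
        directionality=directionality,
        vocabulary=actor.vocabulary,
        counts=counts,
    )
    if tm.unvisited_rows.any():
        logger.info(
            "%s/%s: unvisited rows %s left all-zero",
            tm.dyad_id,
            directionality,
            [actor.vocabulary[i] for i in np.flatnonzero(tm.unvisited_rows)],
        )
    return tm


def average_graph(matrices: list[TransitionMatrix]) -> nx.DiGraph:
    """Element-wise mean probability matrix as a weighted directed graph.

    Self-loops are included; edge attribute ``weight`` is the mean
    transition probability in [0, 1].
    """
    if not matrices:
        raise ValueError("no matrices to average")
    vocab = matrices[0].vocabulary
    if any(m.vocabulary != vocab for m in matrices):
        raise ValueError("matrices have mixed vocabularies")
    mean = np.mean([m.probabilities for m in matrices], axis=0)
    g = nx.DiGraph(directionality=matrices[0].directionality)
    g.add_nodes_from(vocab)
    for i, src in enumerate(vocab):
        for j, dst in enumerate(vocab):
            g.add_edge(src, dst, weight=float(mean[i, j]))
    return g


def graph_edge_list(g: nx.DiGraph) -> pd.DataFrame:
    rows = [(u, v, d["weight"]) for u, v, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def behavior_pairs(vocabulary: tuple[str, ...]) -> list[tuple[str, str]]:
    """Ordered off-diagonal (from, to) pairs: k(k−1) of them."""
    return [(a, b) for a in vocabulary for b in vocabulary if a != b]


def pair_table(matrices: list[TransitionMatrix], dyad_types: dict) -> pd.DataFrame:
    """Long dyad × behavior-pair table of off-diagonal probabilities.

    Rows with zero visits contribute missing (NaN) pairs, handled listwise
    downstream.
    """
    rows = []
    for m in matrices:
        for a, b in behavior_pairs(m.vocabulary):
            i, j = m.vocabulary.index(a), m.vocabulary.index(b)
            val = np.nan if m.unvisited_rows[i] else m.probabilities[i, j]
            rows.append((m.dyad_id, dyad_types[m.dyad_id], f"{a}->{b}", val))
    return pd.DataFrame(rows, columns=["dyad_id", "dyad_type", "pair", "value"])


def compare_transitions(
    matrices: list[TransitionMatrix],
    dyad_types: dict,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> AnovaResults:
    """Matched-vs-mixed comparison with behavior pairs as repeated measures.

    Self-loops are excluded; each dyad contributes a k(k−1)-vector of
    off-diagonal transition probabilities.  Mixed two-way ANOVA (dyad type
    between, pair within) followed by Tukey tests per pair, attached to the
    result as ``posthoc``.
    """
    from .anova import RepeatedMeasuresAnova

    long_df = pair_table(matrices, dyad_types)
    model = RepeatedMeasuresAnova(
        long_df, dv="value", subject="dyad_id", within="pair", between="dyad_type"
    )
    res = model.fit()
    if posthoc:
        res.posthoc = tukey_per_bin(
            long_df.dropna(subset=["value"]),
            group="dyad_type",
            within="pair",
            alpha=alpha,
        )
    return res
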