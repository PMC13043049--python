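"""Raw 9-category likelihoods → 5-category analysis labels.

Three stages, applied in order:

1. :func:`consolidate_categories` — category merges: the sniffing variants
   and approaching become *pointing*; moving/idling alone become *behaving
   alone*; the automated aggression likelihood is dropped (aggression enters
   later from the manual annotation channel).  Merges use ``max`` so
   likelihoods stay in [0, 1].
2. :func:`apply_dyad_rules` — full-dyad rules: *behaving alone* and
   *huddling* require both animals, so a frame where only one animal's
   winner is such a category has that likelihood zeroed.  An identity-merge
   correction re-classifies single-detection frames inside a huddle (one
   animal's scores missing, partner labeled behaving-alone, previous state
   huddling) back to mutual huddling.
3. :func:`labelize` — winner-takes-all argmax per frame, then manual
   attacking / being-attacked annotations are superimposed with precedence
   over everything.  Argmax ties are broken by vocabulary order and logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import AlignmentError, AnnotationTrack, BehaviorScoreTable, LabelStream
from .vocab import (
    CONSOLIDATED_CATEGORIES,
    RAW_CATEGORIES,
    WORKING_CATEGORIES,
)

logger = logging.getLogger(__name__)


def consolidate_categories(scores: BehaviorScoreTable) -> BehaviorScoreTable:
    """Merge raw categories into the consolidated working set.

    pointing = max(sniffing, approaching); being_pointed_at = being_sniffed;
    behaving_alone = max(moving_alone, idling_alone); chasing, being_chased
    and huddling pass through; aggression is dropped.
    """
    unknown = [c for c in scores.vocabulary if c not in RAW_CATEGORIES]
    if unknown:
        raise ValueError(f"unknown raw categories: {unknown}")
    df = scores.data
    out = pd.DataFrame({"frame": df["frame"]})
    out["chasing"] = df["chasing"]
    out["pointing"] = df[["sniffing", "approaching"]].max(axis=1)
    out["behaving_alone"] = df[["moving_alone", "idling_alone"]].max(axis=1)
    out["huddling"] = df["huddling"]
    out["being_chased"] = df["being_chased"]
    out["being_pointed_at"] = df["being_sniffed"]
    return BehaviorScoreTable(
        animal_id=scores.animal_id, data=out, vocabulary=CONSOLIDATED_CATEGORIES
    )


def _argmax_labels(scores: np.ndarray) -> np.ndarray:
    """Row argmax with NaN rows → −1 (missing detection)."""
    all_nan = np.isnan(scores).all(axis=1)
    filled = np.nan_to_num(scores, nan=-np.inf)
    lab = filled.argmax(axis=1)
    lab[all_nan] = -1
    return lab


def apply_dyad_rules(
    scores_m: BehaviorScoreTable, scores_f: BehaviorScoreTable
) -> tuple[BehaviorScoreTable, BehaviorScoreTable]:
    """Enforce full-dyad categories and correct identity-merge huddles."""
    if len(scores_m) != len(scores_f):
        raise AlignmentError("dyad score tables differ in length")
    vocab = scores_m.vocabulary
    if vocab != scores_f.vocabulary:
        raise ValueError("dyad score tables have different vocabularies")
    sm = scores_m.scores().copy()
    sf = scores_f.scores().copy()
    i_alone = vocab.index("behaving_alone")
    i_hud = vocab.index("huddling")

    lab_m = _argmax_labels(sm)
    lab_f = _argmax_labels(sf)

    # identity-merge correction: one animal undetected, partner argmax
    # behaving_alone, previous (post-rule) state huddling -> mutual huddling
    prev_hud = False
    for t in range(len(lab_m)):
        merged = None
        if lab_m[t] == -1 and lab_f[t] == i_alone:
            merged = t
        elif lab_f[t] == -1 and lab_m[t] == i_alone:
            merged = t
        if merged is not None and prev_hud:
            sm[t] = 0.0
            sf[t] = 0.0
            sm[t, i_hud] = 1.0
            sf[t, i_hud] = 1.0
            lab_m[t] = i_hud
            lab_f[t] = i_hud
        prev_hud = lab_m[t] == i_hud and lab_f[t] == i_hud

    # full-dyad zeroing on the (possibly corrected) labels
    for idx in (i_alone, i_hud):
        only_m = (lab_m == idx) & (lab_f != idx)
        only_f = (lab_f == idx) & (lab_m != idx)
        sm[only_m, idx] = 0.0
        sf[only_f, idx] = 0.0

    def rebuild(src: BehaviorScoreTable, arr: np.ndarray) -> BehaviorScoreTable:
        df = src.data.copy()
        df[list(vocab)] = arr
        return BehaviorScoreTable(src.animal_id, df, vocab)

    return rebuild(scores_m, sm), rebuild(scores_f, sf)


def labelize(
    scores: BehaviorScoreTable, annotations: AnnotationTrack | None = None
) -> LabelStream:
    """Winner-takes-all frame labels with the attack overlay.

    Returns a frame-level :class:`~ethodyad.io.LabelStream` over the working
    vocabulary (five analysis categories plus mirror roles).  Attack
    annotations overwrite whatever the likelihoods say.
    """
    arr = scores.scores()
    lab_local = _argmax_labels(arr)

    n_ties = int(
        np.sum((arr == np.nanmax(arr, axis=1, keepdims=True)).sum(axis=1) > 1)
    )
    if n_ties:
        logger.info(
            "%s: %d argmax ties broken by vocabulary order",
            scores.animal_id,
            n_ties,
        )

    # map local (consolidated) columns onto the working vocabulary codes
    code_of = {c: WORKING_CATEGORIES.index(c) for c in scores.vocabulary}
    mapping = np.array([code_of[c] for c in scores.vocabulary])
    labels = np.where(lab_local >= 0, mapping[lab_local], -1)

    if annotations is not None:
        if len(annotations) != len(scores):
            raise AlignmentError("annotation track differs in length")
        att = annotations.data["attacking"].to_numpy(bool)
        rec = annotations.data["being_attacked"].to_numpy(bool)
        labels[att] = WORKING_CATEGORIES.index("attacking")
        labels[rec] = WORKING_CATEGORIES.index("being_attacked")

    dt = 0.0
    return LabelStream(
        animal_id=scores.animal_id,
        bin_width_s=dt,  # frame-level stream; 0 marks "native frame rate"
        vocabulary=WORKING_CATEGORIES,
        labels=labels,
    )


def write_label_streams(
    stream_m: LabelStream, stream_f: LabelStream, path, seed=None
) -> None:
    """Write a per-dyad ``frame,label_m,label_f`` CSV with a vocabulary header."""
    with open(path, "w") as fh:
        fh.write(f"# vocabulary: {','.join(WORKING_CATEGORIES)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        pd.DataFrame(
            {
                "frame": np.arange(len(stream_m)),
                "label_m": stream_m.as_names(),
                "label_f": stream_f.as_names(),
            }
        ).to_csv(fh, index=False)
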