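# Methods

This note documents the models, numerical choices and limitations behind
`ethodyad`.  It covers what the code computes and why the defaults are what
they are; it states no empirical result beyond what the test suite and
`scripts/acceptance.py` compute at run time.

## Recording model and geometry

Coordinates are pixels in image convention (origin top-left, y downward);
conversion to centimeters happens only inside the decomposition step, via
`px_per_cm`.  A `CageGeometry` describes one animal's compartment: the
divider must coincide with one x-edge of the compartment box, and the
divider normal (the reference axis for orientation) points from the
compartment toward that edge.  Default physical cage: 48.3 × 25.4 cm,
divider at the center, 20 Hz acquisition.

Long recordings arrive as multiple files, each carrying safety margins at
both ends.  `align_segments` trims `margin_s` worth of frames (default 2 s)
from both ends of every segment, using the segment's own median frame
interval, and concatenates on the absolute clock (seconds since session
start, never reset at midnight).  Files are expected to overlap by their
margins so trimmed content abuts exactly; overlap after trimming is an
error, gaps beyond a tolerance are kept as missing time.  Clock metadata
lives in a YAML sidecar, not in filenames, because file-naming schemes are
tool-specific and fragile.

Low-confidence keypoints (any body part below 0.6 confidence, configurable)
are linearly interpolated from neighboring good frames up to 1 s; longer
gaps become missing frames that propagate as missing bin contributions,
never as zeros.

## Behavioral decomposition

* **Direction to divider.**  Heading is the tail-base→nose vector.  The
  unsigned angle φ to the divider normal is rescaled *linearly*:
  value = 1 − φ/90°, so 0 means parallel and the sign of rotation is
  irrelevant (mirror symmetry is a tested invariant).  A cosine variant is
  available behind `method="cosine"`; the linear map is the default because
  it places "parallel" exactly at 0 and is uniform in angle.
* **Animal center** is the centroid of the three spine keypoints — robust
  to nose/tail occlusion; the full 7-keypoint centroid is available via
  `center="all"`.
* **Distance to divider** uses only the x-coordinate of the center
  (horizontal distance), deliberately independent of the animal's position
  along the cage width.
* **Locomotion speed** is the frame-to-frame displacement hypotenuse of the
  center, multiplied explicitly by the frame rate to report cm/s, assigned
  to the later frame; the first frame is missing.
* **Mutual dyad variables**: center-to-center distance, and the mean of the
  two animals' orientation scores with each animal's reference axis
  pointing at the partner (symmetric under swapping animals).

The usable-range geometry of a real divided cage (divider assembly, food
placement) varies between setups, so the compartment box, divider position
and the near/away threshold are all configuration, not constants.

## Category pipeline (undivided cage)

Raw classifier vocabulary: aggression, chasing, being_chased, approaching,
sniffing, being_sniffed, moving_alone, idling_alone, huddling.  Merges use
`max` (not sum) so likelihoods stay in [0, 1]: pointing = max(sniffing,
approaching); behaving_alone = max(moving_alone, idling_alone); the
automated aggression likelihood is dropped because aggression enters from
the manual annotation channel instead.

Full-dyad rules operate on per-frame argmax labels: if only one animal's
winner is behaving_alone (or huddling), that likelihood is zeroed — both
are dyad-level categories by definition.  The argmax criterion (rather than
a likelihood threshold) is a deliberate choice: it is the same rule the
winner-takes-all step uses, so the two stages cannot disagree about what an
animal "is doing".

Identity-merge correction: when a classifier fuses two huddling animals
into one detection, the symptom is one animal's scores going missing while
the partner is scored as idling/behaving alone.  The detector used here is
exactly that symptom with one memory bit: missing scores for one animal
while the partner's argmax is behaving_alone and the previous (post-rule)
dyad state was mutual huddling → both animals re-classified huddling.  The
correction is applied before full-dyad zeroing and tracks its own output,
so multi-frame merge runs are repaired end to end.

Winner-takes-all ties are broken by fixed vocabulary order (chasing,
attacking, pointing, behaving_alone, huddling, then mirror roles) and
logged; determinism matters more than any particular tie policy at the
rates ties actually occur.  Attack annotations overwrite everything
(precedence is a tested invariant).

## Binning, smoothing and repeated-measures ANOVA

Bins are fixed-width in clock time; the count is floor(duration/width) and
a trailing partial bin is dropped with a warning.  Bin means ignore missing
frames; an all-missing bin is NaN and is excluded subject-wise (listwise
per effect) downstream.  Smoothing is a centered 6-bin moving mean with
shrinking windows at the edges; for the even default window the extra
element falls on the left (pandas `rolling(center=True)` convention, frozen
by an oracle test).

The two-way repeated-measures ANOVA is computed from balanced-design sums
of squares with each effect tested against its own error term:

* fully-within (sex × time, dyad = subject): sex (1, n−1); time and
  interaction (b−1), (b−1)(n−1).  Modeling sex as within-dyad is the only
  design consistent with an error df of n_dyads − 1 when both members of
  every dyad are measured.
* mixed (dyad type between × time): group (g−1, N−g); time and interaction
  against the bin × subject-within-group term, (b−1)(N−g).

No sphericity correction is applied by default, so the printed df follow
the closed forms exactly; a Greenhouse–Geisser option adjusts the p value
only.  Zero error variance yields a flagged degenerate effect (F = NaN)
instead of an exception.  The implementation is cross-checked against
pingouin (`rm_anova`, `mixed_anova`) in the test suite, including
unbalanced groups, and its null calibration (rejection rate at α = 0.05
over 500 simulated null cohorts) is verified to sit within [0.02, 0.10].

Post-hoc tests are Tukey HSD between groups within each bin
(scipy `tukey_hsd`); α defaults to 0.05 everywhere, with P < 0.01
additionally distinguishable in the written tables.  The one-sample KS
normality check (against a normal with the sample's mean and SD) is a
report only and never gates the ANOVA.  Bout statistics define a bout as a
maximal run of identical labels, with a configurable minimum duration
(default 1 bin).

## Transition analysis

Streams are discretized at 1 s.  For the divided cage: toward iff binned
direction > 0 (strict, so exactly 0 is "opposite"), near iff binned
distance < half the configured usable range; both thresholds are
CLI-settable because no principled universal value exists.  The analysis
window defaults to the first sixth of the session (the initial high-activity
period); it is configurable.  For the undivided cage, the modal label per
1-s bin is used, after mirror-role collapse.

**Mirror-role collapse** is the one genuinely open design point: an
animal's "being chased" bins must map into the five-category vocabulary.
The default maps each mirror role onto its interaction category, so a chase
occupies "chasing" bins for *both* animals.  A consequence worth flagging:
under this default the two animals' collapsed streams coincide in every
interaction state, so for generator output the male→female and female→male
matrices coincide as well.  Directional asymmetry is still real for the
divided-cage orientation states (each animal has its own stream), and an
alternative `mirror_collapse="drop"` mapping (mirror bins become missing)
preserves asymmetry in the undivided analysis at the cost of discarding
bins.

Transition matrices count (actor label at t, reactor label at t+1) over
valid bin pairs; rows are normalized to probabilities, unvisited rows stay
all-zero and flagged, and probabilities (not counts) are the quantity
compared across dyads.  Group comparison drops self-loops, treats the
k(k−1) off-diagonal pairs as repeated measures in a mixed ANOVA (dyad type
between), and runs Tukey per pair.  Missing pairs (unvisited rows) are
handled by the same listwise machinery as missing bins.

## Correlation analysis

Each animal contributes eight session averages (three decomposition
variables, five category probabilities).  Pearson correlation (the linear
choice) is computed per sex × dyad-type group with two-sided p values; no
multiple-testing correction by default, matching per-pair reporting
conventions, with a Benjamini–Hochberg option behind a flag.  Groups under
three animals are skipped; zero-variance variables are masked as NaN.

## Synthetic cohorts — what they emulate and what they do not

The generators define the study conditions.  Defaults: 28 dyads in four
subtypes (7 Ctrl-Ctrl, 8 ELSD-ELSD, 7 Ctrl-ELSD, 6 ELSD-Ctrl → 15 matched,
13 mixed).

**Divided cage.**  Position is a reflected random walk inside the
compartment (the reflection inset keeps all seven keypoints inside the box,
a tested invariant); heading is a mean-reverting AR(1) in the signed angle
to the divider normal, centered on the angle whose linear orientation score
equals the configured bias, with persistence 0.97 and 22° innovations at
the default 5 Hz.  Speed is Rayleigh-like, scaled by an activity envelope
1 + 1.5·exp(−t/τ) with τ = duration/6 — the analogue of elevated activity
during the first 12 h of a 72-h session.  Orientation-bias defaults
(matched males +0.40, mixed males +0.55, females 0.0) encode the two
qualitative targets — males orient toward the divider more than females,
and more so in mixed dyads.  No quantitative effect sizes exist to copy
(published reports give F statistics on unavailable animal data), so these
magnitudes are one-time calibration choices of plausible size; at zero
noise the binned orientation mean recovers the configured bias exactly.
Keypoints are laid along the body axis (10-cm body) with 0.5-px isotropic
jitter and near-1 confidences with a 1% dropout rate.  An optional
14:10-pattern sinusoidal activity multiplier exists but is off by default
at scaled-down durations, where a circadian period is meaningless.

**Undivided cage.**  The dyad is a semi-Markov chain over eight *joint*
states (mutual huddling, mutual behaving-alone, and chasing / attacking /
pointing × actor sex), stepped at 1 s.  Dyadic constraints therefore hold
by construction — the error mode "both animals focal attackers" cannot be
emitted.  Dwell times are geometric per category (memoryless per step;
means 3/2/5/45/90 s) with a negative-binomial option for burstier bouts.
Entry hazards are per-second rates; aggression hazards decay with a 1-h
half-life and the huddling entry hazard rises with the same half-life
(floored at 15% of its ceiling so early huddles are possible), producing
the canonical session shape: early chasing/attacking, late consolidated
huddling.  Female aggression hazards exceed male ones (0.005 vs 0.0025
chasing, 0.0035 vs 0.0012 attacking) and are multiplied by 3 in mixed
dyads — the female-initiated-aggression target.  Emission mirrors the real
artifacts: per-frame one-hot raw likelihoods (solitary and pointing states
choose uniformly among their raw synonyms, which the consolidation step
re-merges), a 2% label-noise flip rate by default, and attacks written to
the manual-annotation channel (the raw "aggression" column is emitted but
dropped by consolidation, exactly as in the real pipeline).  Optional
identity-merge artifacts overwrite huddle frames with the single-detection
symptom at a configurable rate (off by default).

Ground truth stores per-animal realized label streams, per-dyad generating
joint matrices at t = 0, and the implied directional 5-category matrices
(joint chain collapsed through its stationary distribution).  One global
seed; per-dyad substreams come from `SeedSequence` splitting, so cohorts
are byte-identical across runs and generation orders.

**What passing tests do and do not show.**  The generators produce
idealized kinematics (no grooming, rearing, wall-climbing, occlusion
structure, or identity switches beyond the scripted merge artifact) and
one-hot likelihoods rather than graded classifier uncertainty.  Recovery
results therefore validate the *analysis* — that the pipeline measures
what a generating process encodes — not the upstream tracker or
classifier, and detection rates on real data will be lower at equal effect
size.

## Problem sizes and Monte-Carlo settings

The default analysis scale is scaled down from the full study design: 2 h
at 5 Hz for the divided cage (full scale: 72 h at 20 Hz) and 4 h at a 1-s
step for the undivided chain, with bin widths chosen as duration/72 and
duration/80 so bin counts match the full design.  Recovery checks use 20
seeds (8-dyad cohorts); null calibration uses 500 miniature cohorts (8
dyads, 6 bins, 240 s at 2 Hz, equal biases); transition recovery uses one
100,000-step time-homogeneous chain parameterized so all five categories
are comparably occupied, making every matrix row well-visited.  These sizes
are the package's reproducibility settings and are stated here so the
numbers in `results/acceptance.json` are interpretable.

## Known limitations

* The ANOVA assumes balanced complete cases after listwise deletion; there
  is no mixed-effects alternative for heavily missing designs.
* Uncorrected repeated-measures df overstate precision under sphericity
  violations; the GG option corrects p but intentionally not the printed df.
* The default mirror-role collapse erases directional asymmetry in the
  undivided transition analysis (see above).
* Only two-animal dyads; no estrous/reproductive-state modeling; lag-1
  transitions only.
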