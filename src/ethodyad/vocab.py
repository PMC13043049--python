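"""Behavior-category vocabularies shared across the pipeline.

Ordering is load-bearing: winner-takes-all ties are broken by position,
so every module must agree on these tuples.
"""

#: Raw classifier output categories (per animal, per frame, likelihood 0-1).
RAW_CATEGORIES = (
    "aggression",
    "chasing",
    "being_chased",
    "approaching",
    "sniffing",
    "being_sniffed",
    "moving_alone",
    "idling_alone",
    "huddling",
)

#: Consolidated likelihood columns after category merges.  ``aggression`` is
#: dropped (replaced downstream by the manual attack-annotation channel) and
#: there is therefore no ``attacking`` likelihood column.
CONSOLIDATED_CATEGORIES = (
    "chasing",
    "pointing",
    "behaving_alone",
    "huddling",
    "being_chased",
    "being_pointed_at",
)

#: Full frame-label vocabulary: five analysis categories followed by the
#: mirror (recipient) roles, retained as metadata until role collapse.
WORKING_CATEGORIES = (
    "chasing",
    "attacking",
    "pointing",
    "behaving_alone",
    "huddling",
    "being_chased",
    "being_attacked",
    "being_pointed_at",
)

#: The five categories entering group statistics and transition analysis.
ACTIVE_CATEGORIES = ("chasing", "attacking", "pointing", "behaving_alone", "huddling")

#: Default mirror-role collapse: the recipient inherits the interaction
#: category, so a chase occupies "chasing" bins for both animals.
MIRROR_TO_ACTIVE = {
    "being_chased": "chasing",
    "being_attacked": "attacking",
    "being_pointed_at": "pointing",
}

#: Four orientation states for the divided-cage transition analysis.
ORIENTATION_STATES = ("toward-near", "opposite-near", "toward-away", "opposite-away")

#: Dyad subtypes, male condition named first.
DYAD_SUBTYPES = ("Ctrl-Ctrl", "ELSD-ELSD", "Ctrl-ELSD", "ELSD-Ctrl")

MISSING_LABEL = -1
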