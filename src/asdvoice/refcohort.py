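"""Reference clinical-cohort summary inputs and benchmark confusion tables.

These are the published summary numbers of the 39-infant clinical cohort
(10 ASD, 29 TD, ages 6-24 months) that this package's evaluation protocol
mirrors, kept here as plain data: per-subject ages, per-group vocalization
durations by category, and the pooled utterance-level confusion matrices of
the four benchmark classifiers.  They serve as fixed inputs for verifying
the summary and metric operations — no audio or frame-level data is
included or needed.
"""

from __future__ import annotations

# Ages in months at initial diagnosis, per diagnostic group.
ASD_AGES_MONTHS = [22, 17, 18, 24, 19, 19, 20, 15, 17, 21]
TD_AGES_MONTHS = [
    18, 18, 10, 13, 16, 17, 14, 18, 14, 12, 9, 18, 18, 12, 16,
    17, 16, 12, 17, 14, 16, 12, 15, 16, 13, 15, 13, 14, 14,
]

# Male/female counts per group.
GENDER_COUNTS = {"ASD": {"male": 4, "female": 6}, "TD": {"male": 19, "female": 10}}

# Total seconds of vocalization per category (0 one syllable, 1 two
# syllables/canonical babbling, 2 babbling, 3 first word, 4 atypical voice).
VOCALIZATION_SECONDS = {
    "ASD": {0: 80.134, 1: 314.405, 2: 33.241, 3: 8.311, 4: 333.400},
    "TD": {0: 267.897, 1: 443.498, 2: 34.766, 3: 57.286, 4: 266.794},
}

# Published per-category duration ratios within each group (used as the
# default vocalization-label mix of the synthetic generator).
VOCAL_LABEL_RATIOS = {
    "ASD": (0.104, 0.409, 0.043, 0.011, 0.433),
    "TD": (0.250, 0.414, 0.032, 0.054, 0.249),
}

# Pooled utterance-level confusion counts (tp, fn, fp, tn) with ASD as the
# positive class, for the four benchmark classifiers evaluated over five
# validation splits (1125 utterances total).
BENCHMARK_CONFUSIONS = {
    "svm": (62, 18, 413, 632),
    "blstm_egemaps54": (170, 103, 305, 547),
    "blstm_egemaps88": (196, 99, 279, 551),
    "blstm_ae_encoded": (215, 98, 260, 552),
}
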