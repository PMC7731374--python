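"""Synthetic infant-vocalization cohorts with controllable group structure.

The generator emulates the statistical shape of a clinical recording
cohort: two diagnostic groups (ASD/TD), per-subject collections of
utterances, and per-utterance sequences of 88 continuous acoustic features
sampled at a 10 ms hop.  Group signal is planted as a mean shift ``delta``
(in within-group SD units) on a chosen subset of "informative" feature
dimensions; all features carry first-order temporal autocorrelation within
an utterance, so 5-frame windows contain exploitable short-time structure.
Vocalization-type labels follow the published per-group category mix by
default, ages follow the published per-group age distributions, and
durations follow the 25 ms window / 10 ms hop frame accounting.

``summarize_ages`` and ``summarize_durations`` are the cohort-level summary
operations (group age mean +/- population SD; per-category duration totals
and ratios) and apply equally to synthetic and published metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import refcohort
from .features import GROUPS, UtteranceFeatures

# frame accounting: 25 ms analysis window advanced by 10 ms
FRAME_WINDOW_S = 0.025
FRAME_HOP_S = 0.010


@dataclass
class SyntheticCohortConfig:
    """All knobs of the synthetic cohort generator.

    delta is the ASD-vs-TD mean shift on the informative features, in units
    of the within-group feature SD (noise_sd); ar_coeff is the lag-1
    autocorrelation of features across frames within an utterance.
    """

    n_asd_subjects: int = 20
    n_td_subjects: int = 20
    utterances_per_subject: tuple[int, int] = (8, 12)
    frames_per_utterance: tuple[int, int] = (20, 50)
    n_features: int = 88
    n_informative: int = 20
    delta: float = 3.0
    vocal_label_probs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {g: refcohort.VOCAL_LABEL_RATIOS[g] for g in GROUPS})
    noise_sd: float = 1.0
    ar_coeff: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_asd_subjects < 1 or self.n_td_subjects < 1:
            raise ValueError("both groups need at least one subject")
        if not 0 < self.n_informative <= self.n_features:
            raise ValueError("n_informative must be in (0, n_features]")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        if not 0 <= self.ar_coeff < 1:
            raise ValueError("ar_coeff must be in [0, 1)")
        for g in GROUPS:
            p = np.asarray(self.vocal_label_probs[g], dtype=np.float64)
            if p.shape != (5,) or np.any(p < 0):
                raise ValueError(f"{g} vocal_label_probs must be 5 non-negative values")
            if abs(p.sum() - 1.0) > 1e-6:
                # published ratios are rounded to 3 decimals; renormalize
                self.vocal_label_probs[g] = tuple(p / p.sum())

    @property
    def informative_indices(self) -> np.ndarray:
        return np.arange(self.n_informative)


@dataclass
class CohortMetadata:
    """Per-subject and per-utterance metadata tables."""

    subjects: pd.DataFrame   # subject_id, group, age_months, gender
    utterances: pd.DataFrame  # utterance_id, subject_id, group, vocal_label, duration_s


# published per-group age distributions (months): mean, population SD
_AGE_DIST = {"ASD": (19.20, 2.52), "TD": (14.72, 2.45)}
_AGE_RANGE = (6.0, 24.0)
_MALE_FRAC = {g: refcohort.GENDER_COUNTS[g]["male"]
              / sum(refcohort.GENDER_COUNTS[g].values()) for g in GROUPS}


def _ar1_noise(rng: np.random.Generator, n_frames: int, n_features: int,
               rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise across frames with marginal SD `sd`."""
    eps = rng.standard_normal((n_frames, n_features)) * sd
    out = np.empty_like(eps)
    out[0] = eps[0]
    scale = np.sqrt(1.0 - rho * rho)
    for t in range(1, n_frames):
        out[t] = rho * out[t - 1] + scale * eps[t]
    return out


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[UtteranceFeatures], CohortMetadata]:
    """Draw a fully seed-deterministic synthetic cohort.

    TD informative-feature means sit at -delta/2 and ASD at +delta/2 (in
    noise_sd units), so the marginal pooled mean is centered; all other
    features are iid-across-features AR(1) noise identical in law between
    groups.
    """
    rng = np.random.default_rng(config.seed)
    utterances: list[UtteranceFeatures] = []
    subj_rows, utt_rows = [], []
    group_sizes = {"ASD": config.n_asd_subjects, "TD": config.n_td_subjects}
    shift = {"ASD": +config.delta / 2.0, "TD": -config.delta / 2.0}

    for group in GROUPS:
        mu_age, sd_age = _AGE_DIST[group]
        mean_vec = np.zeros(config.n_features)
        mean_vec[config.informative_indices] = shift[group] * config.noise_sd
        label_p = np.asarray(config.vocal_label_probs[group])
        for s in range(group_sizes[group]):
            subject_id = f"{group}{s:03d}"
            age = float(np.clip(rng.normal(mu_age, sd_age), *_AGE_RANGE))
            gender = "male" if rng.random() < _MALE_FRAC[group] else "female"
            subj_rows.append((subject_id, group, round(age, 2), gender))
            n_utt = int(rng.integers(config.utterances_per_subject[0],
                                     config.utterances_per_subject[1] + 1))
            for u in range(n_utt):
                utt_id = f"{subject_id}_u{u:03d}"
                n_frames = int(rng.integers(config.frames_per_utterance[0],
                                            config.frames_per_utterance[1] + 1))
                frames = mean_vec + _ar1_noise(rng, n_frames, config.n_features,
                                               config.ar_coeff, config.noise_sd)
                vocal_label = int(rng.choice(5, p=label_p))
                duration = FRAME_WINDOW_S + FRAME_HOP_S * (n_frames - 1)
                utterances.append(UtteranceFeatures(
                    utterance_id=utt_id, subject_id=subject_id, group=group,
                    vocal_label=vocal_label, frames=frames,
                    duration_s=round(duration, 3)))
                utt_rows.append((utt_id, subject_id, group, vocal_label,
                                 round(duration, 3)))

    meta = CohortMetadata(
        subjects=pd.DataFrame(subj_rows, columns=[
            "subject_id", "group", "age_months", "gender"]),
        utterances=pd.DataFrame(utt_rows, columns=[
            "utterance_id", "subject_id", "group", "vocal_label", "duration_s"]),
    )
    return utterances, meta


def summarize_ages(subjects: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Per-group age mean and population SD (months), rounded to 2 decimals.

    The population-SD convention (divide by n) matches the reference
    cohort's published summary.
    """
    out: dict[str, tuple[float, float]] = {}
    for group, sub in subjects.groupby("group"):
        ages = sub["age_months"].to_numpy(dtype=np.float64)
        if ages.size == 0:
            raise ValueError(f"empty group {group}")
        out[str(group)] = (round(float(ages.mean()), 2),
                           round(float(ages.std(ddof=0)), 2))
    if not out:
        raise ValueError("no subjects")
    return out


def summarize_durations(utterances: pd.DataFrame) -> dict[str, dict]:
    """Per-group, per-vocal-label duration totals (s) and within-group ratios.

    Ratios are reported to 3 decimals; totals keep full precision of the
    summed inputs.
    """
    out: dict[str, dict] = {}
    for group, sub in utterances.groupby("group"):
        total = float(sub["duration_s"].sum())
        per_label = {}
        for label, lsub in sub.groupby("vocal_label"):
            lsum = float(lsub["duration_s"].sum())
            per_label[int(label)] = {"seconds": lsum,
                                     "ratio": round(lsum / total, 3)}
        out[str(group)] = {"per_label": per_label, "total": total}
    return out
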