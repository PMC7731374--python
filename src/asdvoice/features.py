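"""Loading, normalization, grouping, and selection of frame-level acoustic features.

The unit of data is the *utterance*: one contiguous infant vocalization,
represented as an (n_frames x 88) matrix of eGeMAPS-style acoustic features
(one row per 25 ms frame at a 10 ms hop).  Normalization statistics are
always learned on the training partition and frozen; validation and test
frames are scaled with the training factors unchanged.  Frames are grouped
into consecutive non-overlapping 5-frame windows so sequence models see
short-time temporal context.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

N_EGEMAPS = 88
GROUPS = ("ASD", "TD")
VOCAL_LABELS = (0, 1, 2, 3, 4)  # one syllable, two syllables (canonical
# babbling), babbling, first word, atypical voice (scream/cry)


class SchemaError(ValueError):
    """Raised when a feature table does not match the expected columns."""


@dataclass
class TableSchema:
    """Column naming for delimited feature tables.

    Feature columns are ``{feature_prefix}000 .. {feature_prefix}087`` by
    default; metadata columns may be renamed to match external extractors
    via the run config.
    """

    utterance: str = "utterance_id"
    subject: str = "subject_id"
    group: str = "group"
    vocal_label: str = "vocal_label"
    duration: str = "duration_s"
    feature_prefix: str = "f"
    n_features: int = N_EGEMAPS

    def feature_columns(self) -> list[str]:
        return [f"{self.feature_prefix}{i:03d}" for i in range(self.n_features)]


@dataclass
class UtteranceFeatures:
    """One utterance's frame-by-feature matrix plus its metadata."""

    utterance_id: str
    subject_id: str
    group: str
    vocal_label: int
    frames: np.ndarray  # (n_frames, n_features)
    duration_s: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 2 or self.frames.shape[0] < 1:
            raise ValueError(f"{self.utterance_id}: frames must be a non-empty 2-D matrix")
        if self.group not in GROUPS:
            raise ValueError(f"{self.utterance_id}: group must be one of {GROUPS}")
        if self.vocal_label not in VOCAL_LABELS:
            raise ValueError(f"{self.utterance_id}: vocal_label must be in {VOCAL_LABELS}")
        if not self.duration_s > 0:
            raise ValueError(f"{self.utterance_id}: duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class NormStats:
    """Per-feature mean/SD (population convention) frozen from training frames."""

    mean: np.ndarray
    sd: np.ndarray
    epsilon: float = 1e-8

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D vectors of equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd entries must be non-negative")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    @property
    def divisor(self) -> np.ndarray:
        return np.maximum(self.sd, self.epsilon)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean.tolist(), "sd": self.sd.tolist(),
            "epsilon": self.epsilon,
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormStats":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["mean"]), np.array(d["sd"]), d["epsilon"])


@dataclass
class GroupedSequence:
    """Non-overlapping fixed-length frame windows from one utterance."""

    utterance_id: str
    group: str
    windows: np.ndarray  # (n_windows, group_size, n_features)
    too_short: bool = False

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


@dataclass
class FeatureSelection:
    """Feature indices ranked by ASD-vs-TD distributional dissimilarity."""

    selected_indices: list[int]
    u_statistics: np.ndarray
    p_values: np.ndarray

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "selected_indices": list(map(int, self.selected_indices)),
            "u_statistics": self.u_statistics.tolist(),
            "p_values": self.p_values.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSelection":
        d = json.loads(Path(path).read_text())
        return cls(d["selected_indices"], np.array(d["u_statistics"]),
                   np.array(d["p_values"]))


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def load_feature_table(path: str | Path,
                       schema: TableSchema | None = None) -> list[UtteranceFeatures]:
    """Read a delimited frame-level feature table into utterances.

    One row per frame; utterances are assembled in file order and frame
    order is preserved within each utterance.
    """
    schema = schema or TableSchema()
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    meta_cols = {schema.utterance, schema.subject, schema.group,
                 schema.vocal_label, schema.duration}
    missing_meta = meta_cols - set(df.columns)
    if missing_meta:
        raise SchemaError(f"missing metadata column(s): {sorted(missing_meta)}")
    expected = schema.feature_columns()
    present = [c for c in df.columns if c not in meta_cols]
    missing = sorted(set(expected) - set(present))
    extra = sorted(set(present) - set(expected))
    if missing:
        raise SchemaError(f"missing feature column(s): {missing[:5]}")
    if extra:
        raise SchemaError(f"unexpected column(s): {extra[:5]}")
    feat = df[expected].apply(pd.to_numeric, errors="coerce")
    bad = np.where(feat.isna().to_numpy())
    if bad[0].size:
        r, c = int(bad[0][0]), expected[int(bad[1][0])]
        raise ValueError(f"non-numeric feature value at row {r}, column {c!r}")

    utterances: list[UtteranceFeatures] = []
    # groupby(sort=False) keeps file order; frames stay in row order
    for utt_id, sub in df.groupby(schema.utterance, sort=False):
        meta = sub.iloc[0]
        utterances.append(UtteranceFeatures(
            utterance_id=str(utt_id),
            subject_id=str(meta[schema.subject]),
            group=str(meta[schema.group]),
            vocal_label=int(meta[schema.vocal_label]),
            frames=feat.loc[sub.index].to_numpy(),
            duration_s=float(meta[schema.duration]),
        ))
    return utterances


def write_feature_table(utterances: list[UtteranceFeatures], path: str | Path,
                        schema: TableSchema | None = None) -> None:
    """Write utterances to the delimited format `load_feature_table` reads."""
    schema = schema or TableSchema()
    rows = []
    for u in utterances:
        for frame in u.frames:
            rows.append((u.utterance_id, u.subject_id, u.group, u.vocal_label,
                         u.duration_s, *frame))
    cols = [schema.utterance, schema.subject, schema.group, schema.vocal_label,
            schema.duration] + schema.feature_columns()
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep_for(path), index=False)


def fit_normalizer(frames: np.ndarray, epsilon: float = 1e-8) -> NormStats:
    """Per-feature mean and population SD from training-partition frames."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 2 or frames.shape[0] == 0:
        raise ValueError("frames must be a non-empty 2-D matrix")
    return NormStats(mean=frames.mean(axis=0), sd=frames.std(axis=0, ddof=0),
                     epsilon=epsilon)


def apply_normalizer(frames: np.ndarray, stats: NormStats) -> np.ndarray:
    """Scale frames with frozen training statistics: (x - mean)/max(sd, eps)."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.shape[-1] != stats.mean.shape[0]:
        raise ValueError(
            f"feature count {frames.shape[-1]} != stats length {stats.mean.shape[0]}")
    return (frames - stats.mean) / stats.divisor


def group_frames(utt: UtteranceFeatures, group_size: int = 5) -> GroupedSequence:
    """Cut an utterance into consecutive non-overlapping `group_size`-frame
    windows; a trailing remainder shorter than `group_size` is discarded, and
    utterances shorter than one window are flagged ``too_short``."""
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    n_windows = utt.n_frames // group_size
    windows = utt.frames[: n_windows * group_size].reshape(
        n_windows, group_size, utt.frames.shape[1])
    return GroupedSequence(utt.utterance_id, utt.group, windows,
                           too_short=(n_windows == 0))


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (normal approximation, tie-corrected).

    Returns (U, p) where U counts pairs (xi, yj) with xi > yj, ties as 1/2.
    Identical samples give U = n*m/2 and p = 1.
    """
    x, y = np.asarray(x, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def select_features(frames_asd: np.ndarray, frames_td: np.ndarray,
                    k: int = 54) -> FeatureSelection:
    """Rank features by ASD-vs-TD Mann-Whitney dissimilarity; keep the top k.

    Ranking is by ascending p-value; ties broken by larger |U - nm/2| (more
    one-sided dominance), then by lower feature index, so selection is
    deterministic even for identical groups.
    """
    frames_asd = np.asarray(frames_asd, dtype=np.float64)
    frames_td = np.asarray(frames_td, dtype=np.float64)
    if frames_asd.shape[1] != frames_td.shape[1]:
        raise ValueError("group matrices must share the feature dimension")
    n_feat = frames_asd.shape[1]
    if k > n_feat:
        raise ValueError(f"k={k} exceeds feature count {n_feat}")
    n, m = frames_asd.shape[0], frames_td.shape[0]
    u_stats = np.empty(n_feat)
    p_vals = np.empty(n_feat)
    for j in range(n_feat):
        u_stats[j], p_vals[j] = mann_whitney_u(frames_asd[:, j], frames_td[:, j])
    dev = np.abs(u_stats - n * m / 2.0)
    order = sorted(range(n_feat), key=lambda j: (p_vals[j], -dev[j], j))
    return FeatureSelection(selected_indices=order[:k], u_statistics=u_stats,
                            p_values=p_vals)
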