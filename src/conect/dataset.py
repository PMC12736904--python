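"""Labeled containers shared by the feature, selection and evaluation stages.

A :class:`SegmentCohort` holds raw segments before feature extraction; a
:class:`LabeledDataset` holds the per-segment 15-feature rows together
with class labels and subject/channel grouping keys.  The on-disk form of
a feature table is CSV with header ``feat_01 ... feat_15, label, subject,
channel``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


def feature_column(index: int) -> str:
    """Column name of the 1-based feature ``index`` (``feat_01`` ...)."""
    if not 1 <= index <= 15:
        raise IndexError("feature indices are 1-based, 1..15")
    return f"feat_{index:02d}"


@dataclass
class SegmentCohort:
    """Raw labeled segments, one per (subject, channel)."""

    segments: list
    labels: list[str]
    groups: list[str]
    channel: list[str]

    def __post_init__(self) -> None:
        n = len(self.segments)
        if not (len(self.labels) == len(self.groups) == len(self.channel) == n):
            raise ValueError("segments, labels, groups and channel must align")

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class LabeledDataset:
    """Feature matrix with class labels and grouping keys.

    ``X`` is a DataFrame with columns ``feat_01`` .. ``feat_15`` (or any
    subset of them, in order); ``groups`` carries subject identifiers so
    that splits can keep whole subjects on one side.
    """

    X: pd.DataFrame
    labels: list[str]
    groups: list[str]
    channel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.X)
        if not self.channel:
            self.channel = [""] * n
        if not (len(self.labels) == len(self.groups) == len(self.channel) == n):
            raise ValueError("rows, labels, groups and channel must align")
        self.labels = [str(v) for v in self.labels]
        self.groups = [str(v) for v in self.groups]

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def columns_for(self, subset: Sequence[int]) -> np.ndarray:
        """Feature matrix restricted to 1-based feature indices."""
        if len(subset) == 0:
            raise ValueError("feature subset must be nonempty")
        return self.X[[feature_column(i) for i in subset]].to_numpy(dtype=float)

    def take(self, rows: Sequence[int]) -> "LabeledDataset":
        rows = list(rows)
        return LabeledDataset(
            X=self.X.iloc[rows].reset_index(drop=True),
            labels=[self.labels[r] for r in rows],
            groups=[self.groups[r] for r in rows],
            channel=[self.channel[r] for r in rows],
        )

    def filter_classes(self, classes: Sequence[str]) -> "LabeledDataset":
        keep = [r for r, lab in enumerate(self.labels) if lab in set(classes)]
        return self.take(keep)

    def to_csv(self, path) -> None:
        frame = self.X.copy()
        frame["label"] = self.labels
        frame["subject"] = self.groups
        frame["channel"] = self.channel
        frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LabeledDataset":
        frame = pd.read_csv(path)
        meta = [c for c in ("label", "subject", "channel") if c in frame.columns]
        if "label" not in meta or "subject" not in meta:
            raise ValueError(f"{path} lacks the label/subject columns of a feature table")
        feats = [c for c in frame.columns if c.startswith("feat_")]
        return cls(
            X=frame[feats],
            labels=frame["label"].astype(str).tolist(),
            groups=frame["subject"].astype(str).tolist(),
            channel=(frame["channel"].astype(str).tolist()
                     if "channel" in frame.columns else []),
        )
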