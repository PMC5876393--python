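"""Feature extraction: 2-s/50%-overlap moving-average smoothing and
reduction of each 30-s epoch to one mean concentration per channel and
chromophore, assembled into the per-participant trial x feature matrix
(20 x 64 for one block).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import Epoch

#: Moving-average window length, s, and fractional overlap.
WINDOW_S = 2.0
OVERLAP = 0.5

#: Chromophore block order in the feature vector: all HbO channels in
#: montage order, then all HbR channels.
CHROMOPHORE_ORDER = ("hbo", "hbr")


def moving_average(series: np.ndarray, fs: float, window_s: float = WINDOW_S,
                   overlap: float = OVERLAP) -> np.ndarray:
    """Means of sliding windows of ``floor(window_s * fs)`` samples.

    The hop is ``window * (1 - overlap)`` samples; only windows lying
    entirely inside the series are used (no padding).  Works on the
    last axis of an arbitrary-dimensional array.
    """
    series = np.asarray(series, dtype=float)
    wl = int(math.floor(window_s * fs))
    if wl < 1:
        raise ValueError("window shorter than one sample")
    hop = int(round(wl * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too large: hop below one sample")
    n = series.shape[-1]
    if n < wl:
        raise ValueError(f"series of {n} samples shorter than one "
                         f"{wl}-sample window")
    windows = np.lib.stride_tricks.sliding_window_view(series, wl, axis=-1)
    return windows[..., ::hop, :].mean(axis=-1)


def epoch_to_features(epoch: Epoch, *, strict: bool = True) -> np.ndarray:
    """Reduce one epoch to its 64-feature vector.

    Each (channel, chromophore) series is smoothed with the 2-s/50%
    moving average and the mean of the windowed means is the feature.
    Order: HbO for all channels, then HbR.
    """
    if strict and epoch.n_channels != 32:
        raise ValueError(f"expected 32 channels, got {epoch.n_channels}")
    hbo = moving_average(epoch.hbo, epoch.fs).mean(axis=-1)
    hbr = moving_average(epoch.hbr, epoch.fs).mean(axis=-1)
    return np.concatenate([hbo, hbr])


def feature_names(channel_names: list[str]) -> list[str]:
    """Column names ``ch<source>-<detector>_<hbo|hbr>``, HbO block first."""
    return [f"ch{name}_{chrom}" for chrom in CHROMOPHORE_ORDER
            for name in channel_names]


@dataclass
class TrialMatrix:
    """Trials x features matrix with per-trial labels and condition tags.

    One block gives a 20 x 64 matrix (rows in schedule order, 5/5/10
    positive/negative/neutral labels); concatenating the passive and
    active blocks gives 40 x 64.
    """

    values: np.ndarray
    labels: list[str]
    conditions: list[str]
    feature_names: list[str]
    participant_id: str

    def __post_init__(self):
        m, p = self.values.shape
        if len(self.labels) != m or len(self.conditions) != m:
            raise ValueError("label/condition count mismatch with rows")
        if len(self.feature_names) != p:
            raise ValueError("feature name count mismatch with columns")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def select(self, labels=None, conditions=None) -> "TrialMatrix":
        """Row subset by label and/or condition, preserving order."""
        keep = [i for i in range(self.m)
                if (labels is None or self.labels[i] in labels)
                and (conditions is None or self.conditions[i] in conditions)]
        return TrialMatrix(values=self.values[keep],
                           labels=[self.labels[i] for i in keep],
                           conditions=[self.conditions[i] for i in keep],
                           feature_names=list(self.feature_names),
                           participant_id=self.participant_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "participant", self.participant_id)
        df.insert(1, "condition", self.conditions)
        df.insert(2, "label", self.labels)
        return df

    @staticmethod
    def concatenate(matrices: list["TrialMatrix"]) -> "TrialMatrix":
        first = matrices[0]
        for tm in matrices[1:]:
            if tm.feature_names != first.feature_names:
                raise ValueError("feature spaces differ")
        return TrialMatrix(
            values=np.vstack([tm.values for tm in matrices]),
            labels=sum((tm.labels for tm in matrices), []),
            conditions=sum((tm.conditions for tm in matrices), []),
            feature_names=list(first.feature_names),
            participant_id=first.participant_id)


def build_trial_matrix(epochs: list[Epoch], participant_id: str,
                       channel_names: list[str] | None = None,
                       *, strict: bool = True) -> TrialMatrix:
    """Stack epoch feature vectors into a TrialMatrix, rows in epoch order."""
    if not epochs:
        raise ValueError("no epochs")
    rows = [epoch_to_features(e, strict=strict) for e in epochs]
    p = len(rows[0])
    if any(len(r) != p for r in rows):
        raise ValueError("inconsistent feature dimensionality across epochs")
    n_ch = epochs[0].n_channels
    if channel_names is None:
        channel_names = [f"c{i}" for i in range(n_ch)]
    return TrialMatrix(values=np.array(rows),
                       labels=[e.label for e in epochs],
                       conditions=[e.condition for e in epochs],
                       feature_names=feature_names(channel_names),
                       participant_id=participant_id)
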