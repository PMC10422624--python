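"""Facial-emotion time series: ingestion, dominant labels, feature join.

The facial-expression stage upstream produces, for every second, the
average probability of each of seven emotions over all detected faces.
The dominant collective emotion — the argmax of that vector — becomes
the class label y; the 17 per-second synchrony scores become the
feature matrix X.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .skeleton import PART_KEYS
from .synchrony import SynchronyVector

__all__ = [
    "EMOTIONS",
    "EmotionSample",
    "read_fer_csv",
    "write_fer_csv",
    "dominant_label",
    "JoinedDataset",
    "join",
]

log = logging.getLogger(__name__)

#: The seven emotion channels, in file-column order.
EMOTIONS: tuple[str, ...] = (
    "angry", "sad", "disgusted", "neutral", "happy", "surprised", "fearful",
)

SYNC_COLUMNS: tuple[str, ...] = tuple(f"synchrony_{k}" for k in PART_KEYS)


@dataclass
class EmotionSample:
    """Seven emotion probabilities for one second."""

    t: int
    probs: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(EMOTIONS) - set(self.probs)
        if missing:
            raise ValueError(f"missing emotion(s): {sorted(missing)}")
        for name, p in self.probs.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {name}={p} outside [0, 1]")

    @property
    def dominant(self) -> str:
        return dominant_label(self)


def dominant_label(sample: EmotionSample) -> str:
    """Argmax emotion; exact ties broken alphabetically.

    Invariant to multiplying all probabilities by a positive constant
    (the probabilities are averaged per-face scores and need not sum
    to 1).
    """
    return min(sample.probs, key=lambda name: (-sample.probs[name], name))


def read_fer_csv(path) -> list[EmotionSample]:
    """Read a per-second FER probability CSV (columns t + 7 emotions).

    Out-of-range probabilities raise; a missing emotion column raises a
    schema error naming it; an empty file yields an empty list with a
    warning.
    """
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"FER file {path!r} contains no rows", stacklevel=2)
        return []
    for col in ("t",) + EMOTIONS:
        if col not in df.columns:
            raise ValueError(f"FER CSV is missing required column {col!r}")
    samples = []
    for _, row in df.iterrows():
        samples.append(
            EmotionSample(int(row["t"]), {e: float(row[e]) for e in EMOTIONS})
        )
    return samples


def write_fer_csv(samples: Sequence[EmotionSample], path) -> None:
    rows = [{"t": s.t, **{e: s.probs[e] for e in EMOTIONS}} for s in samples]
    pd.DataFrame(rows, columns=["t", *EMOTIONS]).to_csv(path, index=False)


@dataclass
class JoinedDataset:
    """Per-second feature matrix X (17 synchrony columns) + label y.

    Rows are aligned one-to-one on the second index t; any second with
    a missing synchrony slot or no emotion sample has been dropped.
    """

    X: pd.DataFrame
    y: pd.Series
    t: pd.Series

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df.insert(0, "t", self.t.values)
        df["label"] = self.y.values
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "JoinedDataset":
        X = df[list(SYNC_COLUMNS)].reset_index(drop=True)
        return cls(X, df["label"].reset_index(drop=True),
                   df["t"].reset_index(drop=True))


def join(
    emotions: Sequence[EmotionSample],
    sync: Sequence[SynchronyVector] | pd.DataFrame,
) -> JoinedDataset:
    """Inner-join emotion labels with per-second synchrony features.

    Rows with any missing synchrony value are excluded (missing data
    points are removed rather than imputed); drop counts are logged.
    Duplicate seconds in either input, or zero overlap, raise.
    """
    if isinstance(sync, pd.DataFrame):
        sdf = sync.copy()
    else:
        rows = []
        for sv in sync:
            row = {"t": int(sv.timestamp)}
            row.update({f"synchrony_{k}": sv.scores[k] for k in PART_KEYS})
            rows.append(row)
        sdf = pd.DataFrame(rows)
    if sdf["t"].duplicated().any():
        raise ValueError("duplicate seconds in synchrony input")
    ets = [s.t for s in emotions]
    if len(set(ets)) != len(ets):
        raise ValueError("duplicate seconds in emotion input")

    edf = pd.DataFrame(
        {"t": ets, "label": [dominant_label(s) for s in emotions]}
    )
    merged = sdf.merge(edf, on="t", how="inner")
    if merged.empty:
        raise ValueError("emotion and synchrony series share no seconds")
    n_before = len(merged)
    complete = merged.dropna(subset=list(SYNC_COLUMNS))
    n_dropped = n_before - len(complete)
    if n_dropped:
        log.info("join: dropped %d/%d rows with missing synchrony values",
                 n_dropped, n_before)
    if complete.empty:
        raise ValueError("no complete rows after dropping missing synchrony")
    complete = complete.reset_index(drop=True)
    return JoinedDataset(
        X=complete[list(SYNC_COLUMNS)],
        y=complete["label"],
        t=complete["t"],
    )
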