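"""Per-body-part synchronization scores between persons.

The synchrony of one body part across two persons is a function of the
angle between their part vectors.  Two angle→score mappings are
provided:

* ``perpendicular`` — s = |1 − θ/90|: a 90° angle scores 0 (complete
  absence of synchronization) while both 0° and 180° score 1, so
  anti-phase alignment counts as synchrony.
* ``linear`` — s = 1 − θ/180: strictly decreasing, 180° scores 0.

A smooth ``cosine`` alternative (s = |cos θ|, same endpoint semantics as
perpendicular) is available behind the mapping switch.

Independently, the comparison can be *same-side* (right arm vs right
arm) or *opposite-side* (right arm vs mirrored left arm), the latter
treating mirror-image gestures of two people facing the camera as
perfect synchrony.  The four (mapping × sides) combinations form the
metric variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .skeleton import (
    BODY_PARTS,
    PART_KEYS,
    BodyPart,
    FrameSequence,
    Pose,
    body_part_vector,
    mirror_part,
)

__all__ = [
    "MetricVariant",
    "METRIC_VARIANTS",
    "UndefinedAngleError",
    "angle_between",
    "map_angle_to_score",
    "pair_part_synchrony",
    "SynchronyVector",
    "frame_synchrony",
    "synchrony_timeseries",
    "synchrony_dataframe",
]

_MAPPINGS = ("linear", "perpendicular", "cosine")
_SIDES = ("same", "opposite")


class UndefinedAngleError(ValueError):
    """The angle between vectors is undefined (zero-length operand)."""


@dataclass(frozen=True)
class MetricVariant:
    """One of the four synchronization metrics (mapping × sides)."""

    mapping: str = "perpendicular"
    sides: str = "same"

    def __post_init__(self) -> None:
        if self.mapping not in _MAPPINGS:
            raise ValueError(f"mapping must be one of {_MAPPINGS}")
        if self.sides not in _SIDES:
            raise ValueError(f"sides must be one of {_SIDES}")


#: The four canonical variants.
METRIC_VARIANTS: tuple[MetricVariant, ...] = tuple(
    MetricVariant(m, s) for m in ("linear", "perpendicular") for s in _SIDES
)


def angle_between(u: Sequence[float], v: Sequence[float]) -> float:
    """Angle between planar vectors in degrees, in [0, 180].

    Symmetric in its arguments.  Raises :class:`UndefinedAngleError` for
    a zero-length operand; callers treat the part as missing for that
    pair, since an undefined direction carries no synchrony information.
    """
    ux, uy = float(u[0]), float(u[1])
    vx, vy = float(v[0]), float(v[1])
    if (ux == 0.0 and uy == 0.0) or (vx == 0.0 and vy == 0.0):
        raise UndefinedAngleError("angle undefined for zero-length vector")
    dot = ux * vx + uy * vy
    cross = ux * vy - uy * vx
    # atan2 form: equals acos of the normalized dot product but is exact
    # for parallel, antiparallel and orthogonal operands
    return math.degrees(math.atan2(abs(cross), dot))


def map_angle_to_score(theta: float, mapping: str = "perpendicular") -> float:
    """Map an inter-vector angle (degrees) to a synchrony score in [0, 1]."""
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"angle {theta!r} outside [0, 180]")
    if mapping == "linear":
        return 1.0 - theta / 180.0
    if mapping == "perpendicular":
        return abs(1.0 - theta / 90.0)
    if mapping == "cosine":
        return abs(math.cos(math.radians(theta)))
    raise ValueError(f"mapping must be one of {_MAPPINGS}")


def pair_part_synchrony(
    pose_a: Pose,
    pose_b: Pose,
    part: BodyPart,
    metric: MetricVariant = MetricVariant(),
) -> float | None:
    """Synchrony score for one body part across one person pair.

    Same-side compares A's part with B's like part.  Opposite-side
    compares A's part with B's mirror part reflected about the vertical
    image axis (x negated), so that mirror-image gestures score 1.
    Returns None when either vector is absent or zero-length.
    """
    va = body_part_vector(pose_a, part)
    if metric.sides == "same":
        vb = body_part_vector(pose_b, part)
    else:
        vb = body_part_vector(pose_b, mirror_part(part))
        if vb is not None:
            vb = (-vb[0], vb[1])
    if va is None or vb is None:
        return None
    try:
        theta = angle_between(va, vb)
    except UndefinedAngleError:
        return None
    return map_angle_to_score(theta, metric.mapping)


@dataclass
class SynchronyVector:
    """The 17 per-part synchrony scores for one frame or second.

    ``scores`` maps each part key to a score in [0, 1] or None;
    ``n_pairs_used`` counts the person pairs that contributed to each
    part (a score is None iff its count is 0).
    """

    timestamp: float
    scores: dict[str, float | None]
    n_pairs_used: dict[str, int] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        """Scores in canonical part order; missing values as NaN."""
        return np.array(
            [math.nan if self.scores[k] is None else self.scores[k] for k in PART_KEYS]
        )

    def defined_mean(self) -> float:
        vals = [v for v in self.scores.values() if v is not None]
        return float(np.mean(vals)) if vals else math.nan


def frame_synchrony(
    poses: Sequence[Pose],
    metric: MetricVariant = MetricVariant(),
    timestamp: float = 0.0,
) -> SynchronyVector:
    """Per-part synchrony of a frame: mean over all unordered person pairs.

    With fewer than two poses every slot is missing (not an error).
    """
    scores: dict[str, float | None] = {}
    counts: dict[str, int] = {}
    n = len(poses)
    for part in BODY_PARTS:
        total, cnt = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                s = pair_part_synchrony(poses[i], poses[j], part, metric)
                if s is not None:
                    total += s
                    cnt += 1
        scores[part.key] = (total / cnt) if cnt else None
        counts[part.key] = cnt
    return SynchronyVector(timestamp, scores, counts)


def synchrony_timeseries(
    seq: FrameSequence, metric: MetricVariant = MetricVariant()
) -> list[SynchronyVector]:
    """Per-second synchrony: frame scores averaged within integer-second bins.

    The output covers every second from floor(first t) to floor(last t);
    seconds with no defined frames emit a vector of missing values, so
    the row count is preserved for downstream alignment.
    """
    if not seq.frames:
        raise ValueError("empty frame sequence")
    per_frame = [
        frame_synchrony(f.poses, metric, timestamp=f.t) for f in seq.frames
    ]
    t0 = math.floor(seq.frames[0].t)
    t1 = math.floor(seq.frames[-1].t)
    by_second: dict[int, list[SynchronyVector]] = {}
    for sv in per_frame:
        by_second.setdefault(math.floor(sv.timestamp), []).append(sv)
    out: list[SynchronyVector] = []
    for sec in range(t0, t1 + 1):
        group = by_second.get(sec, [])
        scores: dict[str, float | None] = {}
        counts: dict[str, int] = {}
        for key in PART_KEYS:
            vals = [sv.scores[key] for sv in group if sv.scores[key] is not None]
            scores[key] = float(np.mean(vals)) if vals else None
            counts[key] = sum(sv.n_pairs_used[key] for sv in group)
        out.append(SynchronyVector(float(sec), scores, counts))
    return out


def synchrony_dataframe(
    seq: FrameSequence, metric: MetricVariant = MetricVariant()
) -> pd.DataFrame:
    """Tidy per-second table: t, synchrony_<part> × 17, n_persons."""
    series = synchrony_timeseries(seq, metric)
    persons_by_second: dict[int, int] = {}
    for f in seq.frames:
        sec = math.floor(f.t)
        persons_by_second[sec] = max(persons_by_second.get(sec, 0), len(f.poses))
    rows = []
    for sv in series:
        row: dict[str, object] = {"t": int(sv.timestamp)}
        for key in PART_KEYS:
            row[f"synchrony_{key}"] = sv.scores[key]
        row["n_persons"] = persons_by_second.get(int(sv.timestamp), 0)
        rows.append(row)
    return pd.DataFrame(rows)
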