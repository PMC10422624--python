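"""Skeleton domain model: keypoints, poses, body parts, and stream I/O.

The skeleton follows the 18-keypoint convention of bottom-up pose
estimators (OpenPose family): an explicit neck joint plus nose, eyes,
ears, shoulders, elbows, wrists, hips, knees and ankles.  A *body part*
is the planar vector between two adjacent keypoints; 17 such parts are
defined (shoulder sections, arms, bodylines, legs, neck and face
sections) and are the unit on which synchrony is scored.

Coordinates are image-plane pixels, x right-positive and y
down-positive, as emitted by pose detectors.  Every angle-based quantity
downstream is convention-independent, so the convention only matters for
plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "KEYPOINT_NAMES",
    "DEFAULT_CONF_MIN",
    "Keypoint",
    "Pose",
    "BodyPart",
    "BODY_PARTS",
    "PART_KEYS",
    "part_by_key",
    "mirror_part",
    "body_part_vector",
    "Frame",
    "FrameSequence",
    "parse_keypoint_frames",
    "write_keypoint_frames",
    "frames_to_csv",
    "frames_from_csv",
    "SkeletonError",
    "ValidationError",
]

KEYPOINT_NAMES: tuple[str, ...] = (
    "nose", "neck",
    "r_sho", "r_elb", "r_wri",
    "l_sho", "l_elb", "l_wri",
    "r_hip", "r_knee", "r_ank",
    "l_hip", "l_knee", "l_ank",
    "r_eye", "l_eye", "r_ear", "l_ear",
)

#: Detector confidence below which a keypoint is treated as absent.
DEFAULT_CONF_MIN = 0.1


class SkeletonError(Exception):
    """Base class for skeleton-stream errors."""


class ValidationError(SkeletonError):
    """Input violates the keypoint-stream schema or its invariants."""


@dataclass(frozen=True)
class Keypoint:
    """One detected joint: image coordinates plus detector confidence.

    ``synthetic`` marks joints that were not detected but reconstructed
    (currently only the neck, as the shoulder midpoint, for inputs in
    the 17-keypoint convention).  Synthetic joints are never written
    back, so parse/write round-trips are exact.
    """

    x: float
    y: float
    confidence: float = 1.0
    synthetic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"keypoint confidence {self.confidence!r} outside [0, 1]"
            )


@dataclass
class Pose:
    """One person in one frame: the 18 named keypoint slots.

    Every name in :data:`KEYPOINT_NAMES` is a key of ``keypoints``; a
    slot is ``None`` when the joint was not reported.  A reported joint
    whose confidence is below ``c_min`` is *absent* as well — its stored
    coordinates carry no meaning and accessors hide it.
    """

    person_id: int | str
    keypoints: dict[str, Keypoint | None]
    c_min: float = DEFAULT_CONF_MIN

    def __post_init__(self) -> None:
        unknown = set(self.keypoints) - set(KEYPOINT_NAMES)
        if unknown:
            raise ValidationError(f"unknown keypoint name(s): {sorted(unknown)}")
        for name in KEYPOINT_NAMES:
            self.keypoints.setdefault(name, None)

    def keypoint(self, name: str) -> Keypoint | None:
        """Return the keypoint, or None if missing or below ``c_min``."""
        kp = self.keypoints[name]
        if kp is None or kp.confidence < self.c_min:
            return None
        return kp

    def present(self, name: str) -> bool:
        return self.keypoint(name) is not None

    def point(self, name: str) -> tuple[float, float] | None:
        kp = self.keypoint(name)
        return None if kp is None else (kp.x, kp.y)

    def translated(self, dx: float, dy: float) -> "Pose":
        """Copy of the pose with every stored keypoint shifted by (dx, dy)."""
        return Pose(
            self.person_id,
            {
                n: (None if kp is None else replace(kp, x=kp.x + dx, y=kp.y + dy))
                for n, kp in self.keypoints.items()
            },
            self.c_min,
        )

    def scaled(self, k: float) -> "Pose":
        """Copy with coordinates multiplied by k (camera-zoom model)."""
        return Pose(
            self.person_id,
            {
                n: (None if kp is None else replace(kp, x=kp.x * k, y=kp.y * k))
                for n, kp in self.keypoints.items()
            },
            self.c_min,
        )


@dataclass(frozen=True)
class BodyPart:
    """One of the 17 body parts: a directed tail→head keypoint vector."""

    name: str
    tail: str
    head: str
    side: str  # "left" | "right" | "center"

    @property
    def key(self) -> str:
        """Machine name, e.g. ``r_elb_to_r_wri``."""
        return f"{self.tail}_to_{self.head}"


BODY_PARTS: tuple[BodyPart, ...] = (
    BodyPart("Right Shoulder Section", "neck", "r_sho", "right"),
    BodyPart("Left Shoulder Section", "neck", "l_sho", "left"),
    BodyPart("Right Upper Arm", "r_sho", "r_elb", "right"),
    BodyPart("Right Lower Arm", "r_elb", "r_wri", "right"),
    BodyPart("Left Upper Arm", "l_sho", "l_elb", "left"),
    BodyPart("Left Lower Arm", "l_elb", "l_wri", "left"),
    BodyPart("Right Upper Bodyline", "neck", "r_hip", "right"),
    BodyPart("Right Upper Leg", "r_hip", "r_knee", "right"),
    BodyPart("Right Lower Leg", "r_knee", "r_ank", "right"),
    BodyPart("Left Upper Bodyline", "neck", "l_hip", "left"),
    BodyPart("Left Upper Leg", "l_hip", "l_knee", "left"),
    BodyPart("Left Lower Leg", "l_knee", "l_ank", "left"),
    BodyPart("Neck Section", "neck", "nose", "center"),
    BodyPart("Right Nose to Eye Section", "nose", "r_eye", "right"),
    BodyPart("Right Eye to Ear Section", "r_eye", "r_ear", "right"),
    BodyPart("Left Nose to Eye Section", "nose", "l_eye", "left"),
    BodyPart("Left Eye to Ear Section", "l_eye", "l_ear", "left"),
)

PART_KEYS: tuple[str, ...] = tuple(p.key for p in BODY_PARTS)
_PART_BY_KEY: dict[str, BodyPart] = {p.key: p for p in BODY_PARTS}
_PART_BY_NAME: dict[str, BodyPart] = {p.name: p for p in BODY_PARTS}


def part_by_key(key: str) -> BodyPart:
    try:
        return _PART_BY_KEY[key]
    except KeyError:
        raise KeyError(f"unknown body part key {key!r}") from None


def _swap_side(name: str) -> str:
    if name.startswith("r_"):
        return "l_" + name[2:]
    if name.startswith("l_"):
        return "r_" + name[2:]
    return name


def mirror_part(part: BodyPart) -> BodyPart:
    """Left/right counterpart of a part; center parts map to themselves.

    The mirror is an involution: mirror(mirror(p)) == p.
    """
    key = f"{_swap_side(part.tail)}_to_{_swap_side(part.head)}"
    return _PART_BY_KEY[key]


def body_part_vector(pose: Pose, part: BodyPart) -> tuple[float, float] | None:
    """Planar vector head − tail, or None if either endpoint is absent.

    A zero-length vector (coincident joints) is returned as-is; whether
    it carries synchrony information is decided by the scoring layer.
    """
    tail = pose.keypoint(part.tail)
    head = pose.keypoint(part.head)
    if tail is None or head is None:
        return None
    return (head.x - tail.x, head.y - tail.y)


@dataclass
class Frame:
    t: float
    poses: list[Pose]


@dataclass
class FrameSequence:
    """Ordered frames of multi-person poses with a nominal frame rate."""

    frames: list[Frame]
    fps: float = 5.0

    def __post_init__(self) -> None:
        ts = [f.t for f in self.frames]
        for a, b in zip(ts, ts[1:]):
            if b <= a:
                raise ValidationError(
                    f"timestamps must be strictly increasing (got {a} then {b})"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def duration(self) -> float:
        if not self.frames:
            return 0.0
        return self.frames[-1].t - self.frames[0].t


def _augment_neck(kp: dict[str, Keypoint | None]) -> None:
    """Reconstruct a missing neck as the shoulder midpoint (17-kp inputs)."""
    if kp.get("neck") is not None:
        return
    ls, rs = kp.get("l_sho"), kp.get("r_sho")
    if ls is None or rs is None:
        return
    kp["neck"] = Keypoint(
        (ls.x + rs.x) / 2.0,
        (ls.y + rs.y) / 2.0,
        min(ls.confidence, rs.confidence),
        synthetic=True,
    )


def parse_keypoint_frames(stream: str, c_min: float = DEFAULT_CONF_MIN,
                          fps: float | None = None) -> FrameSequence:
    """Parse a keypoint-JSON stream into a :class:`FrameSequence`.

    Schema: a JSON array of frame objects
    ``{"t": seconds, "persons": [{"id": pid, "kp": {name: [x, y, conf]}}]}``.
    Keypoints missing from the input, or with confidence below ``c_min``,
    are flagged absent.  Inputs without a neck but with both shoulders
    get a synthetic neck at the shoulder midpoint.

    Raises :class:`ValidationError` on unknown keypoint names or
    non-increasing timestamps, and ``json.JSONDecodeError`` (which names
    the character offset) on malformed JSON.
    """
    data = json.loads(stream)
    if not isinstance(data, list):
        raise ValidationError("top-level JSON value must be an array of frames")
    frames: list[Frame] = []
    inferred_fps = fps
    for i, obj in enumerate(data):
        try:
            t = float(obj["t"])
            persons = obj.get("persons", [])
        except (TypeError, KeyError) as exc:
            raise ValidationError(f"frame {i}: missing field {exc}") from None
        poses = []
        for j, person in enumerate(persons):
            pid = person.get("id", j)
            kp: dict[str, Keypoint | None] = {}
            for name, triple in person.get("kp", {}).items():
                if name not in KEYPOINT_NAMES:
                    raise ValidationError(
                        f"frame {i}, person {pid}: unknown keypoint name {name!r}"
                    )
                x, y, conf = triple
                kp[name] = Keypoint(float(x), float(y), float(conf))
            _augment_neck(kp)
            poses.append(Pose(pid, kp, c_min=c_min))
        frames.append(Frame(t, poses))
    if inferred_fps is None:
        if len(frames) >= 2:
            dt = (frames[-1].t - frames[0].t) / (len(frames) - 1)
            inferred_fps = 1.0 / dt if dt > 0 else 5.0
        else:
            inferred_fps = 5.0
    return FrameSequence(frames, fps=inferred_fps)


def write_keypoint_frames(seq: FrameSequence) -> str:
    """Serialize to the keypoint-JSON schema (inverse of parsing).

    Synthetic keypoints are skipped so that ``write(parse(x))``
    reproduces the original coordinates and absence pattern exactly.
    """
    out = []
    for frame in seq.frames:
        persons = []
        for pose in frame.poses:
            kp = {
                name: [k.x, k.y, k.confidence]
                for name, k in pose.keypoints.items()
                if k is not None and not k.synthetic
            }
            persons.append({"id": pose.person_id, "kp": kp})
        out.append({"t": frame.t, "persons": persons})
    return json.dumps(out)


def frames_to_csv(seq: FrameSequence) -> pd.DataFrame:
    """Wide-CSV dialect: one row per (frame, person), 3 columns per joint."""
    rows = []
    for frame in seq.frames:
        for pose in frame.poses:
            row: dict[str, object] = {"t": frame.t, "person": pose.person_id}
            for name in KEYPOINT_NAMES:
                kp = pose.keypoints[name]
                row[f"{name}_x"] = kp.x if kp else float("nan")
                row[f"{name}_y"] = kp.y if kp else float("nan")
                row[f"{name}_conf"] = kp.confidence if kp else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def frames_from_csv(df: pd.DataFrame, c_min: float = DEFAULT_CONF_MIN) -> FrameSequence:
    frames: list[Frame] = []
    for t, group in df.groupby("t", sort=True):
        poses = []
        for _, row in group.iterrows():
            kp: dict[str, Keypoint | None] = {}
            for name in KEYPOINT_NAMES:
                conf = float(row[f"{name}_conf"])
                x, y = float(row[f"{name}_x"]), float(row[f"{name}_y"])
                if conf > 0.0 and x == x:  # NaN-free
                    kp[name] = Keypoint(x, y, conf)
            poses.append(Pose(row["person"], kp, c_min=c_min))
        frames.append(Frame(float(t), poses))
    return FrameSequence(frames)


def assign_person_ids(seq: FrameSequence) -> FrameSequence:
    """Greedy frame-to-frame identity tracking by nearest hip center.

    Only used when the input stream carries no stable ids.  Each pose is
    matched to the closest previous hip center; unmatched poses receive
    fresh ids.  Anonymous per-frame analysis works without this step,
    since synchrony is computed over all unordered pairs per frame.
    """
    from .distance import hip_center  # local import to avoid a cycle

    next_id = 0
    prev: list[tuple[int, tuple[float, float]]] = []
    for frame in seq.frames:
        centers = [(p, hip_center(p)) for p in frame.poses]
        taken: set[int] = set()
        new_prev = []
        for pose, c in centers:
            best = None
            if c is not None:
                for pid, pc in prev:
                    if pid in taken:
                        continue
                    d2 = (c[0] - pc[0]) ** 2 + (c[1] - pc[1]) ** 2
                    if best is None or d2 < best[1]:
                        best = (pid, d2)
            if best is not None:
                pose.person_id = best[0]
                taken.add(best[0])
            else:
                pose.person_id = next_id
                next_id += 1
            if c is not None:
                new_prev.append((pose.person_id, c))
        prev = new_prev
        next_id = max([next_id] + [int(p.person_id) + 1 for p in frame.poses
                                   if isinstance(p.person_id, int)])
    return seq
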