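"""Seedable generators for multi-person keypoint streams and emotions.

The real-world data this package targets — multi-camera recordings of
a rehearsing music ensemble — cannot be shipped, so every downstream
stage is exercised on synthetic streams with known ground truth.

Each simulated person is a rigid-segment 2-D skeleton (fixed canonical
segment lengths, so body height has a closed form) whose joint angles
follow

    angle(t) = base + amplitude * [rho * shared(t) + (1 - rho) * private(t)]
               + jitter,

where ``shared`` is one smooth sinusoidal program common to the whole
group, ``private`` is an independent program per person, and ``rho``
(the synchrony level) interpolates between fully independent and fully
synchronized motion.  At rho = 1 with no jitter every person performs
the identical gesture and all same-side synchrony scores are exactly 1.

The emotion generator draws a per-second 7-emotion probability vector
via a softmax over linear scores in group synchrony: a baseline label
process reproduces a prescribed happy/sad/angry imbalance, and a
``coupling`` weight shifts probability mass toward happy when synchrony
is high and toward sad/angry/disgusted/surprised when it is low —
mirroring the negative synchrony-disgust/surprise associations this
kind of data exhibits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .skeleton import KEYPOINT_NAMES, Frame, FrameSequence, Keypoint, Pose
from .synchrony import SynchronyVector
from .emotions import EMOTIONS, EmotionSample

__all__ = [
    "SEGMENT_LENGTHS",
    "SyncScenario",
    "generate_pose_sequence",
    "generate_emotion_series",
    "DEFAULT_CLASS_PROPS",
]

#: Canonical segment lengths in pixels (adult proportions at a mid-shot
#: camera distance).  body_height on a generated pose is the closed form
#: torso + (upper_leg + lower_leg) + head = 50 + 80 + 20 = 150 px.
SEGMENT_LENGTHS: dict[str, float] = {
    "torso": 50.0,        # neck -> hip center
    "hip_half": 10.0,     # hip center -> each hip
    "shoulder": 18.0,     # neck -> each shoulder
    "upper_arm": 30.0,
    "lower_arm": 25.0,
    "upper_leg": 40.0,
    "lower_leg": 40.0,
    "head": 20.0,         # neck -> nose
    "eye": 6.0,           # nose -> eye
    "ear": 6.0,           # eye -> ear
}

# Animated degrees of freedom: (base angle deg, amplitude deg).
_DOFS: dict[str, tuple[float, float]] = {
    "trunk": (0.0, 8.0),
    "shoulder_line": (0.0, 6.0),
    "head": (0.0, 20.0),
    "r_arm": (20.0, 55.0),
    "r_elbow": (25.0, 45.0),
    "l_arm": (-20.0, 55.0),
    "l_elbow": (-25.0, 45.0),
    "r_leg": (5.0, 18.0),
    "r_knee": (10.0, 25.0),
    "l_leg": (-5.0, 18.0),
    "l_knee": (-10.0, 25.0),
}

DEFAULT_CLASS_PROPS: dict[str, float] = {"happy": 0.54, "sad": 0.42, "angry": 0.04}

_ARM_KEYS = ("neck_to_r_sho", "neck_to_l_sho", "r_sho_to_r_elb",
             "r_elb_to_r_wri", "l_sho_to_l_elb", "l_elb_to_l_wri")
_LEG_KEYS = ("neck_to_r_hip", "r_hip_to_r_knee", "r_knee_to_r_ank",
             "neck_to_l_hip", "l_hip_to_l_knee", "l_knee_to_l_ank")
_HEAD_KEYS = ("neck_to_nose", "nose_to_r_eye", "r_eye_to_r_ear",
              "nose_to_l_eye", "l_eye_to_l_ear")


@dataclass(frozen=True)
class SyncScenario:
    """Parameters of one simulated session.

    ``sync_level`` is the shared-motion weight rho in [0, 1];
    ``jitter_deg`` the per-joint per-frame angular noise SD in degrees;
    ``dropout`` a per-keypoint absence probability (scalar, or a mapping
    from keypoint name to probability for targeted occlusion).
    """

    n_persons: int = 3
    n_seconds: int = 60
    fps: float = 5.0
    sync_level: float = 0.5
    jitter_deg: float = 3.0
    dropout: float | Mapping[str, float] = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not (0.0 <= self.sync_level <= 1.0):
            raise ValueError("sync_level must lie in [0, 1]")
        if self.jitter_deg < 0:
            raise ValueError("jitter_deg must be non-negative")
        rates = (self.dropout.values() if isinstance(self.dropout, Mapping)
                 else [self.dropout])
        for p in rates:
            if not (0.0 <= p <= 1.0):
                raise ValueError("dropout probabilities must lie in [0, 1]")

    def dropout_for(self, name: str) -> float:
        if isinstance(self.dropout, Mapping):
            return float(self.dropout.get(name, 0.0))
        return float(self.dropout)


def _unit(deg: float) -> tuple[float, float]:
    """Unit vector at `deg` degrees from straight down (+y), toward +x."""
    r = math.radians(deg)
    return (math.sin(r), math.cos(r))


def _build_pose(person_id: int, root: tuple[float, float],
                a: Mapping[str, float]) -> dict[str, tuple[float, float]]:
    """Forward kinematics: joint angles -> the 18 keypoint positions."""
    L = SEGMENT_LENGTHS
    pts: dict[str, tuple[float, float]] = {}
    hx, hy = root
    trunk_up = 180.0 + a["trunk"]
    ux, uy = _unit(trunk_up)
    neck = (hx + L["torso"] * ux, hy + L["torso"] * uy)
    # hip line perpendicular to the trunk
    px, py = _unit(trunk_up + 90.0)
    pts["r_hip"] = (hx + L["hip_half"] * px, hy + L["hip_half"] * py)
    pts["l_hip"] = (hx - L["hip_half"] * px, hy - L["hip_half"] * py)
    # shoulder line, with its own small tilt
    sx, sy = _unit(trunk_up + 90.0 + a["shoulder_line"])
    pts["r_sho"] = (neck[0] + L["shoulder"] * sx, neck[1] + L["shoulder"] * sy)
    pts["l_sho"] = (neck[0] - L["shoulder"] * sx, neck[1] - L["shoulder"] * sy)
    for side in ("r", "l"):
        arm = a[f"{side}_arm"]
        ex, ey = _unit(arm)
        sho = pts[f"{side}_sho"]
        elb = (sho[0] + L["upper_arm"] * ex, sho[1] + L["upper_arm"] * ey)
        wx, wy = _unit(arm + a[f"{side}_elbow"])
        pts[f"{side}_elb"] = elb
        pts[f"{side}_wri"] = (elb[0] + L["lower_arm"] * wx,
                              elb[1] + L["lower_arm"] * wy)
        leg = a[f"{side}_leg"]
        lx, ly = _unit(leg)
        hip = pts[f"{side}_hip"]
        knee = (hip[0] + L["upper_leg"] * lx, hip[1] + L["upper_leg"] * ly)
        kx, ky = _unit(leg + a[f"{side}_knee"])
        pts[f"{side}_knee"] = knee
        pts[f"{side}_ank"] = (knee[0] + L["lower_leg"] * kx,
                              knee[1] + L["lower_leg"] * ky)
    head_dir = 180.0 + a["head"]
    nx, ny = _unit(head_dir)
    nose = (neck[0] + L["head"] * nx, neck[1] + L["head"] * ny)
    pts["neck"] = neck
    pts["nose"] = nose
    for side, sign in (("r", -1.0), ("l", +1.0)):
        ex, ey = _unit(head_dir + sign * 60.0)
        eye = (nose[0] + L["eye"] * ex, nose[1] + L["eye"] * ey)
        ax_, ay_ = _unit(head_dir + sign * 95.0)
        pts[f"{side}_eye"] = eye
        pts[f"{side}_ear"] = (eye[0] + L["ear"] * ax_, eye[1] + L["ear"] * ay_)
    return pts


def _program_params(rng: np.random.Generator) -> tuple[float, float]:
    """One sinusoid: frequency 0.1-0.5 Hz, uniform phase."""
    return (rng.uniform(0.1, 0.5), rng.uniform(0.0, 2.0 * math.pi))


def generate_pose_sequence(scenario: SyncScenario) -> FrameSequence:
    """Simulate a multi-person keypoint stream under the scenario.

    Deterministic for a given scenario (identical seed, identical
    output, byte for byte after serialization).
    """
    rng = np.random.default_rng(scenario.seed)
    dof_names = list(_DOFS)
    # shared programs: one sinusoid per DOF, common to the group
    shared = {d: _program_params(rng) for d in dof_names}
    # private programs: one per (person, DOF)
    private = [
        {d: _program_params(rng) for d in dof_names}
        for _ in range(scenario.n_persons)
    ]
    rho = scenario.sync_level
    n_frames = int(round(scenario.n_seconds * scenario.fps))
    dt = 1.0 / scenario.fps
    frames: list[Frame] = []
    for k in range(n_frames):
        t = k * dt
        poses = []
        for i in range(scenario.n_persons):
            angles: dict[str, float] = {}
            for d in dof_names:
                base, amp = _DOFS[d]
                fs, ps = shared[d]
                fp, pp = private[i][d]
                s = math.sin(2.0 * math.pi * fs * t + ps)
                p = math.sin(2.0 * math.pi * fp * t + pp)
                noise = (rng.normal(0.0, scenario.jitter_deg)
                         if scenario.jitter_deg > 0 else 0.0)
                angles[d] = base + amp * (rho * s + (1.0 - rho) * p) + noise
            root = (220.0 + 260.0 * i, 320.0)
            pts = _build_pose(i, root, angles)
            kp: dict[str, Keypoint | None] = {}
            for name in KEYPOINT_NAMES:
                x, y = pts[name]
                p_drop = scenario.dropout_for(name)
                dropped = p_drop > 0.0 and rng.random() < p_drop
                kp[name] = Keypoint(x, y, 0.0 if dropped else 0.9)
            poses.append(Pose(i, kp))
        frames.append(Frame(t, poses))
    return FrameSequence(frames, fps=scenario.fps)


def _group_mean(sv: SynchronyVector, keys: Sequence[str]) -> float:
    vals = [sv.scores[k] for k in keys if sv.scores.get(k) is not None]
    return float(np.mean(vals)) if vals else 0.5


# Baseline softmax scores: the drawn label gets _Z_SELECTED, the rest
# their resting level.  The 2.5 gap dominates the score noise, so at
# coupling = 0 the dominant label equals the drawn label almost surely.
_Z_SELECTED = 1.5
_Z_REST = {"angry": -1.0, "sad": -1.0, "happy": -1.0,
           "neutral": -3.0, "disgusted": -2.0, "surprised": -2.0,
           "fearful": -4.0}
_SCORE_NOISE_SD = 0.15


def generate_emotion_series(
    sync: Sequence[SynchronyVector] | Sequence[float],
    coupling: float = 0.0,
    class_props: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[EmotionSample]:
    """Per-second 7-emotion probabilities coupled to group synchrony.

    ``sync`` is the per-second synchrony series (vectors, or plain mean
    scores).  With ``coupling`` = 0 the dominant labels follow
    ``class_props`` over {happy, sad, angry}; a positive coupling shifts
    softmax scores by linear terms in group synchrony — happy rises with
    overall synchrony, sadness/disgust fall with leg and head synchrony,
    anger/surprise fall with arm synchrony — so strong coupling makes
    the label essentially a function of the synchrony pattern.

    Synchrony enters the scores standardized within the series (z-score
    of each group mean over the session), i.e. the emotional response
    tracks being more or less synchronized *than the session norm*; the
    absolute level of the scores depends on the metric variant and would
    otherwise saturate the coupling.
    """
    if coupling < 0:
        raise ValueError("coupling must be non-negative")
    props = dict(DEFAULT_CLASS_PROPS if class_props is None else class_props)
    if set(props) != {"happy", "sad", "angry"}:
        raise ValueError("class_props must cover exactly {happy, sad, angry}")
    total = sum(props.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"class_props must sum to 1 (got {total})")

    rng = np.random.default_rng(seed)
    labels = list(props)
    weights = np.array([props[l] for l in labels])

    ts: list[int] = []
    groups = {"all": [], "arms": [], "legs": [], "head": []}
    for idx, sv in enumerate(sync):
        if isinstance(sv, SynchronyVector):
            ts.append(int(sv.timestamp))
            m = sv.defined_mean()
            groups["all"].append(0.5 if math.isnan(m) else m)
            groups["arms"].append(_group_mean(sv, _ARM_KEYS))
            groups["legs"].append(_group_mean(sv, _LEG_KEYS))
            groups["head"].append(_group_mean(sv, _HEAD_KEYS))
        else:
            ts.append(idx)
            for g in groups:
                groups[g].append(float(sv))

    def zscore(vals: list[float]) -> np.ndarray:
        a = np.asarray(vals)
        sd = a.std()
        if sd < 1e-12:
            return np.zeros_like(a)
        return np.clip((a - a.mean()) / sd, -3.0, 3.0)

    zs = {g: zscore(v) for g, v in groups.items()}
    samples: list[EmotionSample] = []
    for idx, t in enumerate(ts):
        drawn = labels[rng.choice(len(labels), p=weights / weights.sum())]
        z = {e: (_Z_SELECTED if e == drawn else _Z_REST[e]) for e in EMOTIONS}
        c_all = float(zs["all"][idx])
        c_arms = float(zs["arms"][idx])
        c_legs = float(zs["legs"][idx])
        c_head = float(zs["head"][idx])
        # happy tracks the body mean (legs+arms), so whenever sad and
        # angry are both suppressed happy is boosted: one of the three
        # coupled classes always has a non-negative drive and the
        # dominant set stays {happy, sad, angry}.  disgusted/surprised
        # share their driver (and coefficient) with sad/angry but sit a
        # full unit lower, so their probability rises when synchrony
        # falls — the negative synchrony-disgust/surprise association —
        # while staying a fixed factor e below the dominant channel.
        body = (c_legs + c_arms) / 2.0
        z["happy"] += coupling * body
        z["sad"] -= coupling * c_legs
        z["angry"] -= coupling * c_arms
        z["disgusted"] -= coupling * c_legs
        z["surprised"] -= coupling * c_arms
        for e in EMOTIONS:
            z[e] += rng.normal(0.0, _SCORE_NOISE_SD)
        score_vec = np.array([z[e] for e in EMOTIONS])
        probs = np.exp(score_vec - score_vec.max())
        probs /= probs.sum()
        samples.append(EmotionSample(t, dict(zip(EMOTIONS, probs))))
    return samples
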