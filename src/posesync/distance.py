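"""Inter-person distance and the entanglement record E = {S, d}.

Distance between two people is measured between their hip centers —
the most stable reference point on a moving body — and made
dimensionless by the normalization factor H, the sum of the two
persons' pose-independent body heights.  Body height is a sum of
segment lengths (torso + mean leg chain + neck-to-nose allowance), so
it does not change when limbs articulate.

The entanglement record bundles the pair's 17-part synchrony vector S
with the normalized distance d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .skeleton import Pose
from .synchrony import MetricVariant, SynchronyVector, frame_synchrony

__all__ = [
    "hip_center",
    "BodyHeight",
    "body_height",
    "pair_distance",
    "EntanglementRecord",
    "entanglement_record",
]


def hip_center(pose: Pose) -> tuple[float, float] | None:
    """Midpoint of l_hip and r_hip; None if either hip is absent."""
    l = pose.point("l_hip")
    r = pose.point("r_hip")
    if l is None or r is None:
        return None
    return ((l[0] + r[0]) / 2.0, (l[1] + r[1]) / 2.0)


def _seg(pose: Pose, a: str, b: str) -> float | None:
    pa, pb = pose.point(a), pose.point(b)
    if pa is None or pb is None:
        return None
    return math.hypot(pb[0] - pa[0], pb[1] - pa[1])


@dataclass(frozen=True)
class BodyHeight:
    """Articulation-invariant body height in pixels, with its components."""

    h: float
    components: dict[str, float] = field(default_factory=dict)


def body_height(pose: Pose) -> BodyHeight | None:
    """Pose-independent body height from segment lengths.

    h = |neck → hip_center| + mean over available sides of
    (|hip → knee| + |knee → ankle|) + |neck → nose|.

    Because each term is a segment length (or a fixed chain of them),
    bending a knee or tilting the head leaves h unchanged.  Returns
    None when the torso segment or both leg chains are unavailable; the
    head allowance is omitted when the nose is absent.
    """
    hc = hip_center(pose)
    neck = pose.point("neck")
    if hc is None or neck is None:
        return None
    torso = math.hypot(hc[0] - neck[0], hc[1] - neck[1])
    legs = []
    for side in ("r", "l"):
        upper = _seg(pose, f"{side}_hip", f"{side}_knee")
        lower = _seg(pose, f"{side}_knee", f"{side}_ank")
        if upper is not None and lower is not None:
            legs.append(upper + lower)
    if not legs:
        return None
    components = {"torso": torso, "leg": sum(legs) / len(legs)}
    head = _seg(pose, "neck", "nose")
    if head is not None:
        components["head"] = head
    h = sum(components.values())
    return BodyHeight(h, components)


def pair_distance(
    pose_a: Pose, pose_b: Pose, normalization: str = "divide"
) -> float | None:
    """Hip-center distance between two persons in body-height units.

    d = ‖hip_center(A) − hip_center(B)‖ / H with H = h_A + h_B, which is
    dimensionless and invariant to camera zoom.  ``normalization=
    "multiply"`` multiplies by H instead (units px²), kept only for
    compatibility with conventions that scale rather than normalize.
    Returns None when a hip center or a body height is unavailable.
    """
    ca, cb = hip_center(pose_a), hip_center(pose_b)
    ha, hb = body_height(pose_a), body_height(pose_b)
    if ca is None or cb is None or ha is None or hb is None:
        return None
    raw = math.hypot(ca[0] - cb[0], ca[1] - cb[1])
    H = ha.h + hb.h
    if normalization == "divide":
        return raw / H
    if normalization == "multiply":
        return raw * H
    raise ValueError("normalization must be 'divide' or 'multiply'")


@dataclass
class EntanglementRecord:
    """E = {S, d} for one person pair: synchrony vector plus distance."""

    S: SynchronyVector
    d: float | None
    pair: tuple[int | str, int | str]


def entanglement_record(
    pose_a: Pose,
    pose_b: Pose,
    metric: MetricVariant = MetricVariant(),
    normalization: str = "divide",
) -> EntanglementRecord:
    """Bundle the pair-level synchrony vector and normalized distance.

    The two components are independent: a pose with no hips still gets
    its synchrony scored, and vice versa.
    """
    S = frame_synchrony([pose_a, pose_b], metric)
    d = pair_distance(pose_a, pose_b, normalization=normalization)
    return EntanglementRecord(S, d, (pose_a.person_id, pose_b.person_id))
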