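import json

import pytest

from posesync.skeleton import KEYPOINT_NAMES, Keypoint, Pose


def make_pose(points, person_id=0, conf=0.9, c_min=0.1):
    """Pose from a {keypoint: (x, y)} mapping; unlisted joints absent."""
    kp = {name: None for name in KEYPOINT_NAMES}
    for name, (x, y) in points.items():
        kp[name] = Keypoint(float(x), float(y), conf)
    return Pose(person_id, kp, c_min=c_min)


#: A complete upright skeleton with closed-form geometry:
#: torso 50, hips +-10, each upper leg 40, lower leg 40, neck->nose 20.
UPRIGHT = {
    "neck": (0.0, 0.0),
    "nose": (0.0, -20.0),
    "r_eye": (5.0, -24.0), "l_eye": (-5.0, -24.0),
    "r_ear": (10.0, -22.0), "l_ear": (-10.0, -22.0),
    "r_sho": (18.0, 0.0), "l_sho": (-18.0, 0.0),
    "r_elb": (24.0, 28.0), "l_elb": (-24.0, 28.0),
    "r_wri": (26.0, 52.0), "l_wri": (-26.0, 52.0),
    "r_hip": (10.0, 50.0), "l_hip": (-10.0, 50.0),
    "r_knee": (10.0, 90.0), "l_knee": (-10.0, 90.0),
    "r_ank": (10.0, 130.0), "l_ank": (-10.0, 130.0),
}


@pytest.fixture
def upright_pose():
    return make_pose(UPRIGHT)


def mirrored_points(points, axis=150.0):
    """Mirror-image partner: positions reflected about x = axis AND the
    left/right joint names swapped (a person mirroring your gesture moves
    the opposite limb)."""
    def swap(name):
        if name.startswith("r_"):
            return "l_" + name[2:]
        if name.startswith("l_"):
            return "r_" + name[2:]
        return name

    return {swap(k): (2.0 * axis - x, y) for k, (x, y) in points.items()}


@pytest.fixture
def pose_pair():
    a = make_pose(UPRIGHT, person_id=0)
    b = make_pose({k: (x + 300.0, y) for k, (x, y) in UPRIGHT.items()},
                  person_id=1)
    return a, b


def frames_json(frames):
    """Serialize [(t, [{kp_name: (x, y, conf)}...])...] to the JSON schema."""
    out = []
    for t, persons in frames:
        out.append({
            "t": t,
            "persons": [
                {"id": i, "kp": {k: list(v) for k, v in kp.items()}}
                for i, kp in enumerate(persons)
            ],
        })
    return json.dumps(out)
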