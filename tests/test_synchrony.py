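"""Synchrony engine: angle math, score mappings, aggregation, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from posesync.skeleton import BODY_PARTS, Frame, FrameSequence, part_by_key
from posesync.synchrony import (
    METRIC_VARIANTS,
    MetricVariant,
    UndefinedAngleError,
    angle_between,
    frame_synchrony,
    map_angle_to_score,
    pair_part_synchrony,
    synchrony_dataframe,
    synchrony_timeseries,
)

from conftest import UPRIGHT, make_pose


class TestAngleBetween:
    @pytest.mark.parametrize("u,v,expected", [
        ((1, 0), (0, 1), 90.0),
        ((1, 0), (-1, 0), 180.0),
        ((1, 0), (1, 1), 45.0),
        ((2, 0), (6, 0), 0.0),
    ])
    def test_reference_angles(self, u, v, expected):
        assert angle_between(u, v) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(UndefinedAngleError):
            angle_between((0, 0), (1, 0))

    @given(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
           st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)))
    @settings(deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, u, v):
        if math.hypot(*u) < 1e-9 or math.hypot(*v) < 1e-9:
            return
        a, b = angle_between(u, v), angle_between(v, u)
        assert a == pytest.approx(b, abs=1e-9)
        assert 0.0 <= a <= 180.0


class TestScoreMapping:
    @pytest.mark.parametrize("theta,mapping,expected", [
        (90.0, "perpendicular", 0.0),
        (180.0, "perpendicular", 1.0),
        (0.0, "perpendicular", 1.0),
        (180.0, "linear", 0.0),
        (0.0, "linear", 1.0),
        (45.0, "linear", 0.75),
    ])
    def test_endpoint_semantics(self, theta, mapping, expected):
        assert map_angle_to_score(theta, mapping) == pytest.approx(expected)

    def test_out_of_domain_angle_rejected(self):
        with pytest.raises(ValueError):
            map_angle_to_score(-1.0)
        with pytest.raises(ValueError):
            map_angle_to_score(180.5)

    @given(st.floats(0.0, 180.0))
    @settings(deadline=None, derandomize=True)
    def test_perpendicular_symmetric_about_90(self, theta):
        assert map_angle_to_score(theta, "perpendicular") == pytest.approx(
            map_angle_to_score(180.0 - theta, "perpendicular"), abs=1e-12
        )

    def test_linear_strictly_decreasing(self):
        grid = np.linspace(0.0, 180.0, 181)
        scores = [map_angle_to_score(t, "linear") for t in grid]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_cosine_variant_same_endpoints_as_perpendicular(self):
        for theta in (0.0, 90.0, 180.0):
            assert map_angle_to_score(theta, "cosine") == pytest.approx(
                map_angle_to_score(theta, "perpendicular"), abs=1e-12
            )


class TestPairPartSynchrony:
    def test_identical_poses_score_one(self, pose_pair):
        a, b = pose_pair
        for part in BODY_PARTS:
            for metric in METRIC_VARIANTS:
                if metric.sides == "same":
                    s = pair_part_synchrony(a, b, part, metric)
                    assert s == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_arm_scores_zero_perpendicular(self):
        a = make_pose({"r_sho": (0, 0), "r_elb": (1, 0)})
        b = make_pose({"r_sho": (0, 0), "r_elb": (0, 1)}, person_id=1)
        part = part_by_key("r_sho_to_r_elb")
        s = pair_part_synchrony(a, b, part, MetricVariant("perpendicular", "same"))
        assert s == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mapping", ["linear", "perpendicular"])
    def test_mirror_poses_score_one_opposite_side(self, mapping):
        # A's right upper arm (1,-1); B's left upper arm (-1,-1): reflecting
        # B's mirrored vector about the vertical axis aligns them exactly.
        a = make_pose({"r_sho": (0, 0), "r_elb": (1, -1)})
        b = make_pose({"l_sho": (10, 0), "l_elb": (9, -1)}, person_id=1)
        part = part_by_key("r_sho_to_r_elb")
        s = pair_part_synchrony(a, b, part, MetricVariant(mapping, "opposite"))
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_missing_vector_gives_missing_score(self):
        a = make_pose({"r_sho": (0, 0)})  # no elbow
        b = make_pose({"r_sho": (0, 0), "r_elb": (0, 1)}, person_id=1)
        part = part_by_key("r_sho_to_r_elb")
        assert pair_part_synchrony(a, b, part) is None

    def test_zero_length_vector_gives_missing_score(self):
        a = make_pose({"r_sho": (2, 2), "r_elb": (2, 2)})
        b = make_pose({"r_sho": (0, 0), "r_elb": (0, 1)}, person_id=1)
        part = part_by_key("r_sho_to_r_elb")
        assert pair_part_synchrony(a, b, part) is None

    def test_pair_symmetry(self, pose_pair):
        a, b = pose_pair
        b = b.translated(5.0, -3.0)
        for metric in METRIC_VARIANTS:
            for part in BODY_PARTS:
                assert pair_part_synchrony(a, b, part, metric) == pytest.approx(
                    pair_part_synchrony(b, a, part, metric), abs=1e-12
                )


def brute_force_frame(poses, metric):
    """Independent double loop over pairs and parts (the oracle)."""
    out = {}
    for part in BODY_PARTS:
        vals = []
        for i in range(len(poses)):
            for j in range(i + 1, len(poses)):
                s = pair_part_synchrony(poses[i], poses[j], part, metric)
                if s is not None:
                    vals.append(s)
        out[part.key] = sum(vals) / len(vals) if vals else None
    return out


def random_pose(rng, person_id, dropout=0.0):
    pts = {}
    for name, (x, y) in UPRIGHT.items():
        if rng.random() < dropout:
            continue
        pts[name] = (x + rng.normal(0, 30), y + rng.normal(0, 30))
    return make_pose(pts, person_id=person_id)


class TestFrameSynchrony:
    def test_two_identical_poses_all_scores_one(self, pose_pair):
        sv = frame_synchrony(list(pose_pair), MetricVariant())
        assert len(sv.scores) == 17
        for key, score in sv.scores.items():
            assert score == pytest.approx(1.0, abs=1e-12)
            assert sv.n_pairs_used[key] == 1

    def test_three_person_mean_matches_pairwise_mean(self):
        rng = np.random.default_rng(42)
        poses = [random_pose(rng, i) for i in range(3)]
        sv = frame_synchrony(poses, MetricVariant("linear", "same"))
        oracle = brute_force_frame(poses, MetricVariant("linear", "same"))
        for key in oracle:
            assert sv.scores[key] == pytest.approx(oracle[key], abs=1e-12)

    def test_single_person_all_missing(self, upright_pose):
        sv = frame_synchrony([upright_pose])
        assert all(v is None for v in sv.scores.values())
        assert all(c == 0 for c in sv.n_pairs_used.values())

    @pytest.mark.parametrize("metric", METRIC_VARIANTS,
                             ids=lambda m: f"{m.mapping}-{m.sides}")
    def test_oracle_equivalence_random_frames(self, metric):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            poses = [random_pose(rng, i, dropout=0.15) for i in range(n)]
            sv = frame_synchrony(poses, metric)
            oracle = brute_force_frame(poses, metric)
            for key in oracle:
                if oracle[key] is None:
                    assert sv.scores[key] is None
                else:
                    assert sv.scores[key] == pytest.approx(oracle[key], abs=1e-12)

    def test_person_order_invariance(self):
        rng = np.random.default_rng(3)
        poses = [random_pose(rng, i) for i in range(4)]
        sv1 = frame_synchrony(poses, MetricVariant())
        sv2 = frame_synchrony(poses[::-1], MetricVariant())
        for key in sv1.scores:
            assert sv1.scores[key] == pytest.approx(sv2.scores[key], abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        poses = [random_pose(rng, i) for i in range(3)]
        shifted = [poses[0].translated(123.4, -56.7)] + poses[1:]
        sv1 = frame_synchrony(poses, MetricVariant())
        sv2 = frame_synchrony(shifted, MetricVariant())
        for key in sv1.scores:
            assert sv1.scores[key] == pytest.approx(sv2.scores[key], abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        poses = [random_pose(rng, i) for i in range(3)]
        scaled = [poses[0].scaled(3.7)] + poses[1:]
        sv1 = frame_synchrony(poses, MetricVariant())
        sv2 = frame_synchrony(scaled, MetricVariant())
        for key in sv1.scores:
            assert sv1.scores[key] == pytest.approx(sv2.scores[key], abs=1e-9)

    def test_rotating_one_person_shifts_every_angle_by_phi(self):
        # rotate one pose rigidly by phi: every same-side inter-vector
        # angle changes by exactly phi (modulo the [0, 180] fold)
        phi = 30.0
        a = make_pose(UPRIGHT, person_id=0)
        c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))
        rotated = {k: (x * c - y * s, x * s + y * c) for k, (x, y) in UPRIGHT.items()}
        b = make_pose(rotated, person_id=1)
        for part in BODY_PARTS:
            s_lin = pair_part_synchrony(a, b, part, MetricVariant("linear", "same"))
            # baseline angle is 0 (identical poses), so rotated angle == phi
            assert s_lin == pytest.approx(1.0 - phi / 180.0, abs=1e-9)

    def test_global_rotation_of_both_leaves_scores_unchanged(self):
        rng = np.random.default_rng(6)
        poses = [random_pose(rng, i) for i in range(2)]
        phi = 77.0
        c, s = math.cos(math.radians(phi)), math.sin(math.radians(phi))

        def rot(pose):
            pts = {}
            for name in UPRIGHT:
                p = pose.point(name)
                if p is not None:
                    pts[name] = (p[0] * c - p[1] * s, p[0] * s + p[1] * c)
            return make_pose(pts, person_id=pose.person_id)

        sv1 = frame_synchrony(poses, MetricVariant("linear", "same"))
        sv2 = frame_synchrony([rot(p) for p in poses], MetricVariant("linear", "same"))
        for key in sv1.scores:
            if sv1.scores[key] is None:
                assert sv2.scores[key] is None
            else:
                assert sv1.scores[key] == pytest.approx(sv2.scores[key], abs=1e-9)


class TestTimeseries:
    def seq_with_scores(self):
        frames = []
        for k in range(10):  # 5 fps, 2 seconds
            t = k * 0.2
            a = make_pose(UPRIGHT, person_id=0)
            b = make_pose({k_: (x + 200, y) for k_, (x, y) in UPRIGHT.items()},
                          person_id=1)
            frames.append(Frame(t, [a, b]))
        return FrameSequence(frames, fps=5)

    def test_constant_scores_average_to_constant(self):
        series = synchrony_timeseries(self.seq_with_scores(), MetricVariant())
        assert len(series) == 2
        for sv in series:
            for v in sv.scores.values():
                assert v == pytest.approx(1.0, abs=1e-12)

    def test_mean_ignores_missing_frames(self):
        # second 0 has frames where one pose lacks the right wrist
        part = part_by_key("r_elb_to_r_wri")
        base = {"r_elb": (0, 0), "r_wri": (0, 10)}
        f0 = Frame(0.0, [make_pose(base), make_pose({"r_elb": (5, 0), "r_wri": (5, 10)}, 1)])
        f1 = Frame(0.2, [make_pose(base), make_pose({"r_elb": (5, 0)}, 1)])  # missing
        f2 = Frame(0.4, [make_pose(base), make_pose({"r_elb": (5, 0), "r_wri": (15, 0)}, 1)])
        series = synchrony_timeseries(FrameSequence([f0, f1, f2], fps=5),
                                      MetricVariant("linear", "same"))
        # defined frame scores: 1.0 and 0.5 -> mean 0.75
        assert series[0].scores[part.key] == pytest.approx(0.75, abs=1e-12)

    def test_empty_second_emits_missing_row(self):
        a = make_pose(UPRIGHT)
        b = make_pose(UPRIGHT, person_id=1)
        frames = [Frame(0.1, [a, b]), Frame(2.1, [a, b])]  # nothing in second 1
        series = synchrony_timeseries(FrameSequence(frames, fps=5))
        assert len(series) == 3
        assert all(v is None for v in series[1].scores.values())

    def test_dataframe_columns(self):
        df = synchrony_dataframe(self.seq_with_scores(), MetricVariant())
        assert list(df.columns)[0] == "t"
        assert list(df.columns)[-1] == "n_persons"
        assert sum(c.startswith("synchrony_") for c in df.columns) == 17
        assert "synchrony_r_knee_to_r_ank" in df.columns
        assert (df["n_persons"] == 2).all()
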