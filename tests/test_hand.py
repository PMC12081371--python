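"""Synthetic hand generator: gesture encoding, geometry, sampling, datasets."""

import math

import numpy as np
import pytest

from gsfan.hand import (
    FINGER_NAMES,
    HandShapeParams,
    build_hand_surface,
    decode_gesture,
    encode_gesture,
    generate_dataset,
    hand_primitives,
    sample_gesture,
    subject_shape,
)

# ---------------------------------------------------------------------------
# independent geometric oracles


def oracle_area(states, shape):
    """Surface area recomputed from primitive geometry with closed forms."""
    total = 0.0
    for prim in hand_primitives(states, shape):
        if prim[0] == "roundedbox":
            a, b, c = prim[1]
            rho = prim[2]
            total += (
                8 * (a * b + b * c + c * a)
                + 8 * math.pi * rho * (a + b + c)
                + 4 * math.pi * rho**2
            )
        else:
            _, p0, p1, r = prim
            L = np.linalg.norm(np.asarray(p1) - np.asarray(p0))
            total += 2 * math.pi * r * L + 4 * math.pi * r**2
    return total


def oracle_surface_distance(points, states, shape):
    """Distance from each point to the union of hand surface primitives."""

    def capsule_dist(p, p0, p1, r):
        p0, p1 = np.asarray(p0), np.asarray(p1)
        d = p1 - p0
        t = np.clip(np.dot(p - p0, d) / np.dot(d, d), 0.0, 1.0)
        return abs(np.linalg.norm(p - (p0 + t * d)) - r)

    def rounded_box_dist(p, half_core, rho):
        q = np.abs(p) - np.asarray(half_core)
        outside = np.linalg.norm(np.maximum(q, 0.0))
        inside = min(q.max(), 0.0)
        return abs(outside + inside - rho)

    prims = hand_primitives(states, shape)
    out = np.empty(len(points))
    for i, p in enumerate(points):
        best = np.inf
        for prim in prims:
            if prim[0] == "roundedbox":
                d = rounded_box_dist(p, prim[1], prim[2])
            else:
                d = capsule_dist(p, prim[1], prim[2], prim[3])
            best = min(best, d)
        out[i] = best
    return out


# ---------------------------------------------------------------------------
# gesture encoding


class TestGestureEncoding:
    def test_all_extended_is_class_zero(self):
        assert encode_gesture([False] * 5) == 0

    def test_all_bent_is_class_31(self):
        assert encode_gesture([True] * 5) == 31

    def test_thumb_is_least_significant_bit(self):
        assert encode_gesture([True, False, False, False, False]) == 1
        assert encode_gesture([False, False, False, False, True]) == 16

    def test_enumeration_gives_exactly_32_distinct_classes(self):
        ids = {
            encode_gesture([bool(b >> f & 1) for f in range(5)]) for b in range(32)
        }
        assert ids == set(range(32))

    @pytest.mark.parametrize("class_id", range(32))
    def test_round_trip(self, class_id):
        assert encode_gesture(decode_gesture(class_id)) == class_id

    def test_decode_trivial_cases(self):
        assert decode_gesture(0) == (False,) * 5
        assert decode_gesture(31) == (True,) * 5

    @pytest.mark.parametrize("bad", [[True] * 4, [True] * 6, []])
    def test_wrong_length_rejected(self, bad):
        with pytest.raises(ValueError):
            encode_gesture(bad)

    @pytest.mark.parametrize("bad", [-1, 32, 100])
    def test_out_of_range_id_rejected(self, bad):
        with pytest.raises(ValueError):
            decode_gesture(bad)


# ---------------------------------------------------------------------------
# surface construction


class TestHandSurface:
    @pytest.mark.parametrize("class_id", [0, 9, 31])
    def test_point_count_matches_density_times_area(self, class_id):
        shape = HandShapeParams()
        states = decode_gesture(class_id)
        density = 5e4
        pts = build_hand_surface(states, shape, density)
        expected = density * oracle_area(states, shape)
        assert abs(pts.shape[0] - expected) <= 0.10 * expected

    def test_deterministic_for_same_arguments(self):
        a = build_hand_surface(decode_gesture(7), density=2e4)
        b = build_hand_surface(decode_gesture(7), density=2e4)
        np.testing.assert_array_equal(a, b)

    def test_all_points_finite(self):
        pts = build_hand_surface(decode_gesture(13), density=2e4)
        assert np.all(np.isfinite(pts))

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            build_hand_surface(decode_gesture(0), density=0)

    def test_extended_index_reaches_farther_than_bent(self):
        shape = HandShapeParams()
        hx = shape.palm_extent[0] / 2
        extended = build_hand_surface(decode_gesture(0), shape, 1e5)
        bent_index = build_hand_surface(
            decode_gesture(encode_gesture([False, True, False, False, False])),
            shape,
            1e5,
        )
        # restrict to the index-finger column (clear of middle/ring/little)
        win = lambda pts: pts[pts[:, 0] > 0.5 * hx]
        assert win(extended)[:, 1].max() > win(bent_index)[:, 1].max()

    def test_points_lie_on_analytic_surface(self):
        shape = HandShapeParams()
        states = decode_gesture(21)
        pts = build_hand_surface(states, shape, 3e4)
        dists = oracle_surface_distance(pts[::17], states, shape)
        assert dists.max() < 1e-9


# ---------------------------------------------------------------------------
# gesture sampling


class TestSampleGesture:
    def test_noise_free_points_lie_on_surface(self):
        shape = HandShapeParams()
        cloud = sample_gesture(11, n_points=120, noise_sd=0.0,
                               pose_jitter=(0.0, 0.0), shape=shape, seed=4)
        dists = oracle_surface_distance(cloud.coords, decode_gesture(11), shape)
        assert dists.max() < 1e-9

    def test_same_seed_reproduces_cloud_exactly(self):
        a = sample_gesture(5, n_points=200, seed=42)
        b = sample_gesture(5, n_points=200, seed=42)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_exact_point_count_and_label(self):
        cloud = sample_gesture(17, n_points=256, seed=0)
        assert cloud.coords.shape == (256, 3)
        assert cloud.label == 17

    def test_oversampling_draws_with_replacement(self):
        cloud = sample_gesture(3, n_points=20000, noise_sd=0.0, seed=1,
                               base_density=1e4)
        assert cloud.coords.shape[0] == 20000

    def test_invalid_class_propagates(self):
        with pytest.raises(ValueError):
            sample_gesture(40, n_points=10, seed=0)

    def test_noise_perturbs_points(self):
        clean = sample_gesture(2, n_points=100, noise_sd=0.0,
                               pose_jitter=(0.0, 0.0), seed=9)
        noisy = sample_gesture(2, n_points=100, noise_sd=1e-3,
                               pose_jitter=(0.0, 0.0), seed=9)
        deltas = np.linalg.norm(noisy.coords - clean.coords, axis=1)
        assert 1e-5 < np.median(deltas) < 5e-3


# ---------------------------------------------------------------------------
# dataset generation


class TestGenerateDataset:
    def test_one_cloud_per_class_single_subject(self):
        ds = generate_dataset(n_per_class=1, n_subjects=1, n_points=32, seed=0)
        assert len(ds) == 32
        assert sorted(c.label for c in ds) == list(range(32))

    def test_counts_and_balance(self):
        ds = generate_dataset(n_per_class=3, n_subjects=2, n_points=16, seed=1)
        assert len(ds) == 32 * 3 * 2
        labels = np.array([c.label for c in ds])
        counts = np.bincount(labels, minlength=32)
        assert np.all(counts == 6)

    def test_subject_morphologies_differ_pairwise(self):
        shapes = [subject_shape(s, seed=7) for s in range(4)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert shapes[i].finger_lengths != shapes[j].finger_lengths

    def test_dataset_is_pure_function_of_arguments(self):
        a = generate_dataset(n_per_class=1, n_subjects=2, n_points=24, seed=5)
        b = generate_dataset(n_per_class=1, n_subjects=2, n_points=24, seed=5)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.coords, cb.coords)
            assert (ca.label, ca.subject_id) == (cb.label, cb.subject_id)

    def test_invalid_shape_parameters_rejected(self):
        with pytest.raises(ValueError):
            HandShapeParams(finger_lengths=(0.05,) * 4)
        with pytest.raises(ValueError):
            HandShapeParams(bend_angle=0.0)
        with pytest.raises(ValueError):
            HandShapeParams(palm_extent=(0.09, -0.08, 0.02))
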