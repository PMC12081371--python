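"""Synthetic articulated-hand surface point clouds.

The gesture vocabulary treats each of the five fingers (thumb, index,
middle, ring, little) as an independent binary variable — extended or
bent — giving ``2**5 = 32`` gesture classes.  Real recordings of such
gestures come from depth/LiDAR sensors; this module emulates them with a
parametric articulated hand:

* the palm is a rounded box (a box Minkowski-summed with a sphere),
* each finger is a chain of capsules attached at a fixed palm socket,
* a *bent* finger has every joint rotated by a fixed flexion angle about
  its knuckle axis, curling the finger toward the palm.

Surface points are drawn area-uniformly from the union of primitives
(no self-occlusion culling), then measurement noise and a random rigid
sensor pose are applied per cloud.  Subjects differ by hand morphology:
every shape parameter is perturbed within +/-15% per subject.

All randomness flows through explicit seeds; dataset generation is a
pure function of its arguments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "FINGER_NAMES",
    "N_CLASSES",
    "HandShapeParams",
    "LabeledCloud",
    "encode_gesture",
    "decode_gesture",
    "build_hand_surface",
    "hand_surface_area",
    "sample_gesture",
    "subject_shape",
    "generate_dataset",
]

FINGER_NAMES = ("thumb", "index", "middle", "ring", "little")
N_CLASSES = 32

#: segment length fractions per finger; the thumb has two phalanges
#: visible outside the palm, the other fingers three.
_SEGMENT_FRACTIONS = {
    "thumb": (0.55, 0.45),
    "index": (0.45, 0.32, 0.23),
    "middle": (0.45, 0.32, 0.23),
    "ring": (0.45, 0.32, 0.23),
    "little": (0.45, 0.32, 0.23),
}

#: finger socket x-positions as fractions of the palm half-width
#: (thumb handled separately on the radial side of the palm).
_FINGER_X_FRACTION = {"index": 0.70, "middle": 0.25, "ring": -0.25, "little": -0.70}

_BASE_SURFACE_SEED = 0x5F3A  # internal; makes build_hand_surface deterministic
_DEFAULT_BASE_DENSITY = 1.5e5  # points per m^2 for the dense base sampling


@dataclass(frozen=True)
class HandShapeParams:
    """Morphological parameters of one subject's hand (meters/radians)."""

    palm_extent: tuple[float, float, float] = (0.09, 0.08, 0.02)
    finger_lengths: tuple[float, ...] = (0.055, 0.075, 0.080, 0.073, 0.058)
    finger_radii: tuple[float, ...] = (0.010, 0.009, 0.009, 0.0085, 0.007)
    bend_angle: float = math.radians(100.0)
    subject_id: int = 0

    def __post_init__(self) -> None:
        if len(self.finger_lengths) != 5 or len(self.finger_radii) != 5:
            raise ValueError("finger_lengths and finger_radii need 5 entries")
        if any(v <= 0 for v in self.palm_extent):
            raise ValueError("palm_extent entries must be positive")
        if any(v <= 0 for v in self.finger_lengths + self.finger_radii):
            raise ValueError("finger lengths/radii must be positive")
        if not 0.0 < self.bend_angle < math.pi:
            raise ValueError("bend_angle must lie in (0, pi)")


@dataclass
class LabeledCloud:
    """One hand-surface point cloud with its gesture label and subject."""

    coords: np.ndarray
    label: int | None = None
    subject_id: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# gesture encoding


def encode_gesture(states) -> int:
    """Map a 5-vector of finger states (True = bent) to a class id in [0, 31].

    Bit order: thumb is the least-significant bit.
    """
    states = list(states)
    if len(states) != 5:
        raise ValueError(f"expected 5 finger states, got {len(states)}")
    return int(sum(int(bool(s)) << f for f, s in enumerate(states)))


def decode_gesture(class_id: int) -> tuple[bool, ...]:
    """Inverse of :func:`encode_gesture`."""
    class_id = int(class_id)
    if not 0 <= class_id < N_CLASSES:
        raise ValueError(f"gesture class id must be in [0, {N_CLASSES - 1}], got {class_id}")
    return tuple(bool((class_id >> f) & 1) for f in range(5))


# ---------------------------------------------------------------------------
# geometric primitives

# A primitive is described by ("capsule", p0, p1, r) or
# ("roundedbox", half_core (3,), rho); the rounded box is centred at the
# origin and axis-aligned.


def _capsule_area(length: float, r: float) -> float:
    return 2.0 * math.pi * r * length + 4.0 * math.pi * r * r


def _rounded_box_area(half_core: np.ndarray, rho: float) -> float:
    a, b, c = half_core
    faces = 8.0 * (a * b + b * c + c * a)
    edges = 8.0 * math.pi * rho * (a + b + c)
    corners = 4.0 * math.pi * rho * rho
    return faces + edges + corners


def _sample_capsule(rng: np.random.Generator, p0, p1, r, n: int) -> np.ndarray:
    """Area-uniform points on a capsule from p0 to p1 with radius r."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = float(np.linalg.norm(axis))
    d = axis / length if length > 0 else np.array([0.0, 0.0, 1.0])
    a_cyl = 2.0 * math.pi * r * length
    a_caps = 4.0 * math.pi * r * r
    on_cyl = rng.random(n) < a_cyl / (a_cyl + a_caps)
    pts = np.empty((n, 3))
    # orthonormal frame around d
    helper = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)

    n_cyl = int(on_cyl.sum())
    if n_cyl:
        t = rng.random(n_cyl) * length
        phi = rng.random(n_cyl) * 2.0 * math.pi
        radial = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
        pts[on_cyl] = p0 + t[:, None] * d + r * radial
    n_cap = n - n_cyl
    if n_cap:
        u = rng.normal(size=(n_cap, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # hemisphere at p1 for directions with positive component along d,
        # hemisphere at p0 otherwise: exactly area-uniform over both caps.
        at_tip = u @ d > 0
        centers = np.where(at_tip[:, None], p1, p0)
        pts[~on_cyl] = centers + r * u
    return pts


def _sample_rounded_box(rng: np.random.Generator, half_core, rho, n: int) -> np.ndarray:
    """Area-uniform points on the Minkowski sum of a box and a sphere."""
    a, b, c = (float(v) for v in half_core)
    half = np.array([a, b, c])
    areas = []
    kinds = []  # ("face", axis, sign) | ("edge", axis, s1, s2) | ("corner", sx, sy, sz)
    for ax in range(3):
        others = [half[i] for i in range(3) if i != ax]
        face_area = 4.0 * others[0] * others[1]
        for sign in (-1.0, 1.0):
            kinds.append(("face", ax, sign))
            areas.append(face_area)
    for ax in range(3):
        edge_len = 2.0 * half[ax]
        area = (math.pi / 2.0) * rho * edge_len
        for s1 in (-1.0, 1.0):
            for s2 in (-1.0, 1.0):
                kinds.append(("edge", ax, s1, s2))
                areas.append(area)
    corner_area = 4.0 * math.pi * rho * rho / 8.0
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            for sz in (-1.0, 1.0):
                kinds.append(("corner", sx, sy, sz))
                areas.append(corner_area)
    areas = np.asarray(areas)
    probs = areas / areas.sum()
    counts = rng.multinomial(n, probs)
    out = []
    for kind, cnt in zip(kinds, counts):
        if cnt == 0:
            continue
        if kind[0] == "face":
            _, ax, sign = kind
            o1, o2 = [i for i in range(3) if i != ax]
            p = np.empty((cnt, 3))
            p[:, ax] = sign * (half[ax] + rho)
            p[:, o1] = rng.uniform(-half[o1], half[o1], cnt)
            p[:, o2] = rng.uniform(-half[o2], half[o2], cnt)
            out.append(p)
        elif kind[0] == "edge":
            _, ax, s1, s2 = kind
            o1, o2 = [i for i in range(3) if i != ax]
            theta = rng.uniform(0.0, math.pi / 2.0, cnt)
            p = np.empty((cnt, 3))
            p[:, ax] = rng.uniform(-half[ax], half[ax], cnt)
            p[:, o1] = s1 * (half[o1] + rho * np.cos(theta))
            p[:, o2] = s2 * (half[o2] + rho * np.sin(theta))
            out.append(p)
        else:
            _, sx, sy, sz = kind
            u = rng.normal(size=(cnt, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            u = np.abs(u) * np.array([sx, sy, sz])
            corner = np.array([sx * a, sy * b, sz * c])
            out.append(corner + rho * u)
    return np.concatenate(out, axis=0)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis."""
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * K + (1.0 - math.cos(angle)) * (K @ K)


def _finger_chain(name: str, bent: bool, shape: HandShapeParams):
    """Capsule segments (p0, p1, r) of one finger in the palm frame."""
    f = FINGER_NAMES.index(name)
    hx, hy, hz = (e / 2.0 for e in shape.palm_extent)
    length = shape.finger_lengths[f]
    r = shape.finger_radii[f]
    if name == "thumb":
        base = np.array([hx * 0.95, -0.1 * hy, 0.0])
        d0 = np.array([math.cos(math.radians(40)), math.sin(math.radians(40)), 0.0])
    else:
        base = np.array([_FINGER_X_FRACTION[name] * hx, hy * 0.98, 0.0])
        d0 = np.array([0.0, 1.0, 0.0])
    palm_normal = np.array([0.0, 0.0, 1.0])
    bend_axis = np.cross(palm_normal, d0)  # curls the finger toward -z
    bend_axis /= np.linalg.norm(bend_axis)
    segments = []
    p = base
    d = d0
    for frac in _SEGMENT_FRACTIONS[name]:
        if bent:
            d = _rotation_about(bend_axis, -shape.bend_angle) @ d
        q = p + frac * length * d
        segments.append((p, q, r))
        p = q
    return segments


def hand_primitives(states, shape: HandShapeParams):
    """All surface primitives of the hand in a given finger configuration."""
    states = list(states)
    if len(states) != 5:
        raise ValueError(f"expected 5 finger states, got {len(states)}")
    hx, hy, hz = (e / 2.0 for e in shape.palm_extent)
    rho = hz  # palm rounding radius: full thickness comes from the rounding
    half_core = np.array([hx - rho, hy - rho, 0.0])
    if np.any(half_core < 0):
        raise ValueError("palm thickness exceeds its width/length")
    prims = [("roundedbox", half_core, rho)]
    for name, bent in zip(FINGER_NAMES, states):
        for p0, p1, r in _finger_chain(name, bool(bent), shape):
            prims.append(("capsule", p0, p1, r))
    return prims


def hand_surface_area(states, shape: HandShapeParams | None = None) -> float:
    """Total surface area (sum over primitives, overlaps not subtracted)."""
    shape = shape or HandShapeParams()
    total = 0.0
    for prim in hand_primitives(states, shape):
        if prim[0] == "roundedbox":
            total += _rounded_box_area(prim[1], prim[2])
        else:
            _, p0, p1, r = prim
            total += _capsule_area(float(np.linalg.norm(p1 - p0)), r)
    return total


def build_hand_surface(states, shape: HandShapeParams | None = None,
                       density: float = _DEFAULT_BASE_DENSITY) -> np.ndarray:
    """Sample points on the articulated hand surface.

    ``density`` is in points per square meter; each primitive receives
    ``round(density * area)`` points (at least one).  The sampling RNG is
    internally seeded, so the same arguments always give the same points.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    shape = shape or HandShapeParams()
    return _build_hand_surface_cached(tuple(bool(s) for s in states), shape, float(density))


@lru_cache(maxsize=256)
def _build_hand_surface_cached(states: tuple[bool, ...], shape: HandShapeParams,
                               density: float) -> np.ndarray:
    rng = np.random.default_rng(_BASE_SURFACE_SEED)
    clouds = []
    for prim in hand_primitives(states, shape):
        if prim[0] == "roundedbox":
            _, half_core, rho = prim
            n = max(1, int(round(density * _rounded_box_area(half_core, rho))))
            clouds.append(_sample_rounded_box(rng, half_core, rho, n))
        else:
            _, p0, p1, r = prim
            n = max(1, int(round(density * _capsule_area(float(np.linalg.norm(p1 - p0)), r))))
            clouds.append(_sample_capsule(rng, p0, p1, r, n))
    return np.concatenate(clouds, axis=0)


# ---------------------------------------------------------------------------
# cloud sampling with sensor effects

DEFAULT_NOISE_SD = 1e-3  # 1 mm, consumer-LiDAR scale
DEFAULT_POSE_JITTER = (math.radians(15.0), 0.05)  # +/-15 deg, +/-5 cm


def _random_pose(rng: np.random.Generator, rot_range: float, trans_range: float):
    angles = rng.uniform(-rot_range, rot_range, size=3)
    R = (
        _rotation_about(np.array([0.0, 0.0, 1.0]), angles[0])
        @ _rotation_about(np.array([0.0, 1.0, 0.0]), angles[1])
        @ _rotation_about(np.array([1.0, 0.0, 0.0]), angles[2])
    )
    t = rng.uniform(-trans_range, trans_range, size=3)
    return R, t


def sample_gesture(
    class_id: int,
    n_points: int = 256,
    noise_sd: float = DEFAULT_NOISE_SD,
    pose_jitter: tuple[float, float] = DEFAULT_POSE_JITTER,
    shape: HandShapeParams | None = None,
    seed: int = 0,
    base_density: float = _DEFAULT_BASE_DENSITY,
) -> LabeledCloud:
    """Draw one labeled cloud of a gesture as a depth sensor would see it.

    ``n_points`` points are subsampled (with replacement if the dense base
    sampling is smaller) from the analytic hand surface, isotropic Gaussian
    noise of standard deviation ``noise_sd`` is added, and a random rigid
    transform bounded by ``pose_jitter = (max |rotation|, max |translation|)``
    is applied.  Reproducible for a fixed seed.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    shape = shape or HandShapeParams()
    states = decode_gesture(class_id)
    base = build_hand_surface(states, shape, base_density)
    rng = np.random.default_rng(seed)
    idx = rng.choice(base.shape[0], size=n_points, replace=n_points > base.shape[0])
    pts = base[idx]
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    rot_range, trans_range = pose_jitter
    if rot_range > 0 or trans_range > 0:
        R, t = _random_pose(rng, rot_range, trans_range)
        pts = pts @ R.T + t
    return LabeledCloud(coords=pts, label=int(class_id), subject_id=shape.subject_id)


SUBJECT_VARIATION = 0.15  # +/-15% morphological spread across subjects


def subject_shape(subject_id: int, seed: int = 0) -> HandShapeParams:
    """Shape parameters for one subject: defaults perturbed within +/-15%."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, int(subject_id), 0x5A]))
    base = HandShapeParams()

    def jitter(values):
        v = np.asarray(values, float)
        return tuple(float(x) for x in v * rng.uniform(1 - SUBJECT_VARIATION, 1 + SUBJECT_VARIATION, v.shape))

    return replace(
        base,
        palm_extent=jitter(base.palm_extent),
        finger_lengths=jitter(base.finger_lengths),
        finger_radii=jitter(base.finger_radii),
        bend_angle=float(base.bend_angle * rng.uniform(1 - SUBJECT_VARIATION, 1 + SUBJECT_VARIATION)),
        subject_id=int(subject_id),
    )


def generate_dataset(
    n_per_class: int = 10,
    n_subjects: int = 4,
    n_points: int = 256,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    pose_jitter: tuple[float, float] = DEFAULT_POSE_JITTER,
) -> list[LabeledCloud]:
    """Generate a balanced labeled dataset of 32*n_per_class*n_subjects clouds.

    Each subject gets its own morphology from :func:`subject_shape`; class
    counts are exactly balanced.  Pure function of its arguments.
    """
    if n_per_class < 1 or n_subjects < 1:
        raise ValueError("n_per_class and n_subjects must be >= 1")
    clouds: list[LabeledCloud] = []
    for subject in range(n_subjects):
        shape = subject_shape(subject, seed=seed)
        for class_id in range(N_CLASSES):
            child = np.random.SeedSequence([seed, subject, class_id])
            rep_seeds = child.generate_state(n_per_class)
            for rep in range(n_per_class):
                clouds.append(
                    sample_gesture(
                        class_id,
                        n_points=n_points,
                        noise_sd=noise_sd,
                        pose_jitter=pose_jitter,
                        shape=shape,
                        seed=int(rep_seeds[rep] % (2**31)),
                    )
                )
    return clouds
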