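"""Synthetic reach-to-grasp scenes and dataglove-like kinematics.

This module generates the stimuli the gaze model observes: 2D hand
trajectories with 16 joint-angle channels (3 per finger plus the wrist),
rendered as short 6-frame movies in which an actor's hand moves from a rest
position to one of two objects (a big ball grasped with a power grasp, or a
small ball grasped with a precision grip).  In half of the movies the hand
preshapes into the grip from movement onset; in the other half it travels as
a closed fist, so the hand configuration carries no information about the
goal.

Conventions
-----------
* Image coordinates are normalized to the unit square, origin at the top
  left, x rightward, y downward.  Full-resolution frames are 128x128,
  row-major (row = y, column = x).
* A trial has exactly 6 frames; frame ``k`` (1-based) is the frame visible
  during saccade epoch ``k``.
* The transport path follows a quadratic Bezier curve through a common
  via point with a minimum-jerk time profile.  The shared early transport
  phase is what makes hand *position* uninformative about the target side
  during the first frames, mirroring the counterbalanced recordings the
  movies stand in for; the paths only fork toward the targets in the second
  half of the movement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_FRAMES = 6
N_ANGLES = 16
FULL_RES = 128

#: Index of the joint-angle channel used as the thumb-index aperture proxy
#: (index-finger MCP flexion; extension = smaller angle = open aperture).
APERTURE_CHANNEL = 3

# Joint-angle templates in degrees.  Channel order: thumb (3 joints), index,
# middle, ring, little (3 joints each), wrist.  The closed fist is the rest
# posture; the power grasp opens the whole hand (large excursion on every
# finger channel) whereas the precision grip reconfigures mainly thumb and
# index and stays much closer to the fist -- the motor fact that makes the
# precision preshape the subtler, more confusable cue.
ANGLE_TEMPLATES: dict[str, np.ndarray] = {
    "FIST": np.array(
        [55.0, 50.0, 45.0, 60.0, 55.0, 50.0, 60.0, 55.0, 50.0,
         60.0, 55.0, 50.0, 60.0, 55.0, 50.0, 0.0]
    ),
    "POW": np.array(
        [20.0, 15.0, 10.0, 15.0, 12.0, 10.0, 15.0, 12.0, 10.0,
         15.0, 12.0, 10.0, 15.0, 12.0, 10.0, 15.0]
    ),
    "PRE": np.array(
        [30.0, 25.0, 20.0, 25.0, 20.0, 15.0, 55.0, 50.0, 45.0,
         58.0, 53.0, 48.0, 58.0, 53.0, 48.0, 5.0]
    ),
}

GRIPS = ("POW", "PRE")
#: grip -> the object it is directed to
GRIP_TARGET = {"POW": "big", "PRE": "small"}

_START_POS = np.array([0.5, 0.8])
# The reach is a common transport curve (quadratic Bezier up the midline)
# blended per frame toward the target with weights GAMMA: the hand travels
# the same corridor for both goals and only forks decisively in the final
# approach (frames 5-6), emulating the counterbalanced recordings in which
# the trajectory itself is uninformative about the goal until late.  The
# frame-5 blend is drawn per trial (reach durations vary by roughly +-100 ms
# around the nominal movement time), so on fast reaches the hand is already
# on the target at frame 5 while slow reaches only arrive at frame 6.
_VIA = np.array([0.5, 0.62])
_TRANSPORT_END = np.array([0.5, 0.40])
_GAMMA = np.array([0.0, 0.01, 0.03, 0.15, 0.7, 1.0])
_GAMMA5_RANGE = (0.45, 0.95)

# Base object placements for the four layouts: big on the left in layouts
# 1 and 3, on the right in 2 and 4, so that pooled over layouts the side of
# the hand path is uninformative about the target.
_LAYOUT_BASES = {
    1: (np.array([0.30, 0.35]), np.array([0.70, 0.35])),
    2: (np.array([0.70, 0.35]), np.array([0.30, 0.35])),
    3: (np.array([0.36, 0.28]), np.array([0.64, 0.28])),
    4: (np.array([0.64, 0.28]), np.array([0.36, 0.28])),
}

MIN_SEPARATION = 0.2


@dataclass(frozen=True)
class SceneLayout:
    """Placement of the two target objects and the hand rest point."""

    big_pos: np.ndarray
    small_pos: np.ndarray
    start_pos: np.ndarray
    layout_id: int

    def __post_init__(self) -> None:
        for name in ("big_pos", "small_pos", "start_pos"):
            p = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, p)
            if p.shape != (2,) or np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} must lie in the unit square, got {p}")
        pts = [self.big_pos, self.small_pos, self.start_pos]
        for i in range(3):
            for j in range(i + 1, 3):
                if np.linalg.norm(pts[i] - pts[j]) < MIN_SEPARATION:
                    raise ValueError(
                        "layout points closer than the minimum separation "
                        f"{MIN_SEPARATION}"
                    )

    def object_pos(self, which: str) -> np.ndarray:
        return self.big_pos if which == "big" else self.small_pos


@dataclass(frozen=True)
class KinematicTrajectory:
    """One executed reach-to-grasp: 6 frames of hand position and 16 angles."""

    positions: np.ndarray          # (6, 2) normalized image coords
    angles: np.ndarray             # (6, 16) degrees
    aperture_class: tuple[str, ...]
    grip: str                      # "POW" | "PRE"
    preshape: bool
    layout_id: int
    actor_id: int
    seed: int

    @property
    def target(self) -> str:
        return GRIP_TARGET[self.grip]


@dataclass
class TrainingSet:
    """Collection of executed grasps used to fit the forward sub-models."""

    trajectories: list[KinematicTrajectory]
    n_actors: int
    n_moves_per_actor: int
    seed: int

    def by_grip(self, grip: str) -> list[KinematicTrajectory]:
        return [t for t in self.trajectories if t.grip == grip]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, traj in enumerate(self.trajectories):
            for k in range(N_FRAMES):
                row = {
                    "trial_id": tid,
                    "actor_id": traj.actor_id,
                    "grip": traj.grip,
                    "layout_id": traj.layout_id,
                    "frame": k + 1,
                    "x": traj.positions[k, 0],
                    "y": traj.positions[k, 1],
                }
                for c in range(N_ANGLES):
                    row[f"angle_{c:02d}"] = traj.angles[k, c]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, layouts: dict[int, SceneLayout] | None = None
                 ) -> "TrainingSet":
        df = pd.read_csv(path)
        trajs = []
        angle_cols = [f"angle_{c:02d}" for c in range(N_ANGLES)]
        for (tid, actor, grip, lid), grp in df.groupby(
            ["trial_id", "actor_id", "grip", "layout_id"], sort=True
        ):
            grp = grp.sort_values("frame")
            trajs.append(
                KinematicTrajectory(
                    positions=grp[["x", "y"]].to_numpy(),
                    angles=grp[angle_cols].to_numpy(),
                    aperture_class=tuple([grip] * N_FRAMES),
                    grip=grip,
                    preshape=True,
                    layout_id=int(lid),
                    actor_id=int(actor),
                    seed=-1,
                )
            )
        n_actors = df["actor_id"].nunique()
        per = len(trajs) // max(1, 2 * n_actors)
        return cls(trajs, n_actors=n_actors, n_moves_per_actor=per, seed=-1)


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk progress profile s(tau) = 10 t^3 - 15 t^4 + 6 t^5."""
    tau = np.asarray(tau, dtype=float)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def make_layout(layout_id: int, seed: int) -> SceneLayout:
    """Return one of the four counterbalanced target layouts.

    The base placements are fixed; the seed adds a small (+-0.015) jitter to
    the object positions so distinct recording sessions are not pixel
    identical.  Deterministic given ``(layout_id, seed)``.
    """
    if layout_id not in _LAYOUT_BASES:
        raise ValueError(f"layout_id must be in 1..4, got {layout_id!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), layout_id]))
    big, small = _LAYOUT_BASES[layout_id]
    jitter = rng.uniform(-0.015, 0.015, size=(2, 2))
    return SceneLayout(
        big_pos=big + jitter[0],
        small_pos=small + jitter[1],
        start_pos=_START_POS.copy(),
        layout_id=layout_id,
    )


def _bezier2(p0, p1, p2, s: np.ndarray) -> np.ndarray:
    s = s[:, None]
    return (1 - s) ** 2 * p0 + 2 * s * (1 - s) * p1 + s**2 * p2


def generate_trajectory(
    grip: str,
    preshape: bool,
    layout: SceneLayout,
    noise_sd: float,
    seed: int,
    *,
    pos_noise: float = 0.015,
    actor_angle_offset: np.ndarray | None = None,
    actor_via_offset: np.ndarray | None = None,
    actor_id: int = 0,
) -> KinematicTrajectory:
    """Simulate one reach-to-grasp execution.

    The hand follows the shared transport curve with minimum-jerk timing,
    blended toward the condition's target by the late-rising per-frame
    weights ``_GAMMA``, so the trajectories of the two goals overlap until
    the final approach.  Joint angles interpolate linearly from the fist
    rest posture toward the grip template when ``preshape`` is true and stay
    at the fist template (plus sensor noise) otherwise.  Positional noise is
    modulated by a sin(pi*tau) envelope: zero at onset (the hand starts
    exactly at rest) and at contact (the hand ends on the target).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if grip not in GRIPS:
        raise ValueError(f"grip must be one of {GRIPS}, got {grip!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 17]))
    target = layout.object_pos(GRIP_TARGET[grip])
    off = actor_via_offset if actor_via_offset is not None else 0.0
    tau = np.arange(N_FRAMES) / (N_FRAMES - 1)
    s = minimum_jerk(tau)
    transport = _bezier2(layout.start_pos, _VIA + off, _TRANSPORT_END + off, s)
    gamma = _GAMMA.copy()
    gamma[4] = rng.uniform(*_GAMMA5_RANGE)   # per-trial reach duration
    gamma = gamma[:, None]
    positions = (1 - gamma) * transport + gamma * target
    envelope = np.sin(np.pi * tau)[:, None]
    positions = positions + envelope * rng.normal(0.0, pos_noise, (N_FRAMES, 2))

    rest = ANGLE_TEMPLATES["FIST"]
    offset = actor_angle_offset if actor_angle_offset is not None else 0.0
    if preshape:
        alpha = tau[:, None]
        template = rest + alpha * (ANGLE_TEMPLATES[grip] - rest)
        labels = tuple([grip] * N_FRAMES)
    else:
        template = np.tile(rest, (N_FRAMES, 1))
        labels = tuple(["FIST"] * N_FRAMES)
    angles = template + offset + rng.normal(0.0, noise_sd, (N_FRAMES, N_ANGLES))

    return KinematicTrajectory(
        positions=positions,
        angles=angles,
        aperture_class=labels,
        grip=grip,
        preshape=preshape,
        layout_id=layout.layout_id,
        actor_id=actor_id,
        seed=int(seed),
    )


def actor_profiles(
    n_actors: int,
    seed: int,
    *,
    actor_angle_sd: float = 6.0,
    actor_via_sd: float = 0.03,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Systematic per-actor offsets: (joint-angle offset, via-point offset).

    Deterministic given the seed; :func:`generate_training_set` draws its
    actors from here, so held-out executions by the *same* actors can be
    generated for calibration checks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)).spawn(1)[0])
    out = []
    for _ in range(n_actors):
        out.append((rng.normal(0.0, actor_angle_sd, N_ANGLES),
                    rng.normal(0.0, actor_via_sd, 2)))
    return out


def generate_training_set(
    n_actors: int = 6,
    n_moves_per_actor: int = 50,
    seed: int = 0,
    *,
    noise_sd: float = 2.5,
    pos_noise: float = 0.015,
    actor_angle_sd: float = 6.0,
    actor_via_sd: float = 0.03,
) -> TrainingSet:
    """Generate the grasp-execution corpus used to train the sub-models.

    Each of ``n_actors`` actors performs ``n_moves_per_actor`` power grasps
    to the big object and as many precision grips to the small object (all
    with natural preshaping, as in the dataglove recordings these emulate),
    rotating through the four layouts.  Actors carry systematic joint-angle
    offsets and an idiosyncratic transport via point, so between-actor
    variability ends up in the fitted models' predictive variance.
    """
    if n_actors < 1 or n_moves_per_actor < 1:
        raise ValueError("actor and movement counts must be positive")
    root = np.random.SeedSequence(int(seed))
    profiles = actor_profiles(
        n_actors, seed,
        actor_angle_sd=actor_angle_sd, actor_via_sd=actor_via_sd,
    )
    trial_seeds = np.random.default_rng(root.spawn(2)[1]).integers(
        0, 2**31 - 1, size=n_actors * n_moves_per_actor * 2
    )
    trajectories: list[KinematicTrajectory] = []
    i = 0
    for actor in range(n_actors):
        angle_off, via_off = profiles[actor]
        for move in range(n_moves_per_actor):
            layout = make_layout((actor * n_moves_per_actor + move) % 4 + 1,
                                 seed=int(seed))
            for grip in GRIPS:
                trajectories.append(
                    generate_trajectory(
                        grip,
                        True,
                        layout,
                        noise_sd,
                        int(trial_seeds[i]),
                        pos_noise=pos_noise,
                        actor_angle_offset=angle_off,
                        actor_via_offset=via_off,
                        actor_id=actor,
                    )
                )
                i += 1
    return TrainingSet(trajectories, n_actors, n_moves_per_actor, int(seed))


# --- rendering -------------------------------------------------------------

_OBJ_BIG_SD = 0.045
_OBJ_SMALL_SD = 0.022
_HAND_PALM_SD = 0.03
_FINGER_SD = 0.015


def _grid_coords(res: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(res) + 0.5) / res
    return np.meshgrid(c, c)  # xs (cols), ys (rows)


def _blob(xs, ys, center, sd, amp):
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
    return amp * np.exp(-d2 / (2 * sd**2))


def hand_extension(angles: np.ndarray) -> float:
    """Mean fractional finger extension relative to the fist posture.

    0 for a closed fist, ~0.9 for the fully open power grasp, ~0.3 for a
    precision grip.  Drives the rendered aperture pattern.
    """
    rest = ANGLE_TEMPLATES["FIST"][:15]
    span = rest - ANGLE_TEMPLATES["POW"][:15]
    ext = (rest - np.asarray(angles)[:15]) / span
    return float(np.clip(np.mean(ext), 0.0, 1.2))


def render_frame(
    traj: KinematicTrajectory,
    frame_idx: int,
    layout: SceneLayout,
    res: int = FULL_RES,
) -> np.ndarray:
    """Render one movie frame as a ``res x res`` intensity grid in [0, 1].

    Three blobs: the big object, the small object, and the hand.  The hand
    is a palm blob flanked by two finger blobs whose separation grows with
    finger extension, so a wide power grasp, a narrow precision grip and a
    closed fist produce linearly distinguishable local patterns.
    """
    if not 1 <= frame_idx <= N_FRAMES:
        raise ValueError(f"frame_idx must be in 1..{N_FRAMES}, got {frame_idx}")
    xs, ys = _grid_coords(res)
    img = _blob(xs, ys, layout.big_pos, _OBJ_BIG_SD, 1.0)
    img += _blob(xs, ys, layout.small_pos, _OBJ_SMALL_SD, 0.85)

    hand = traj.positions[frame_idx - 1]
    ext = hand_extension(traj.angles[frame_idx - 1])
    sep = 0.015 + 0.05 * ext
    img += _blob(xs, ys, hand, _HAND_PALM_SD, 0.9)
    img += _blob(xs, ys, hand + np.array([sep / 2, -0.02]), _FINGER_SD, 0.6)
    img += _blob(xs, ys, hand + np.array([-sep / 2, -0.02]), _FINGER_SD, 0.6)
    return np.clip(img, 0.0, 1.0)


def sample_foveal_patch(
    frame: np.ndarray,
    gaze_center: np.ndarray,
    window_sd: float = 0.08,
) -> tuple[np.ndarray, np.ndarray]:
    """Weight the frame by a Gaussian foveal window centred on the gaze.

    Returns ``(weighted, weights)`` flattened row-major; the weights sum to
    one.  A gaze outside the unit square is clipped (with a log warning),
    mimicking the physical limit of the oculomotor range.
    """
    gaze = np.asarray(gaze_center, dtype=float)
    if np.any(gaze < 0) or np.any(gaze > 1):
        logger.warning("gaze %s outside unit square; clipping", gaze)
        gaze = np.clip(gaze, 0.0, 1.0)
    res = frame.shape[0]
    xs, ys = _grid_coords(res)
    w = np.exp(-((xs - gaze[0]) ** 2 + (ys - gaze[1]) ** 2)
               / (2 * window_sd**2))
    w /= w.sum()
    return (w * frame).ravel(), w.ravel()
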