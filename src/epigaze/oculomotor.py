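"""Saccade selection and execution, and the per-epoch inference loop.

A trial unfolds as a fixed clock of saccade epochs: each epoch the observer
samples the current movie frame at its fixation, updates its beliefs,
rebuilds the salience map and executes one saccade to the most salient
coarse-grid cell.  A saccade takes a fixed 16 iterations of 12 ms (192 ms):
gaze integrates a discrete proportional controller that suppresses the
proprioceptive error between the selected target and the current fixation,
the discrete surrogate of the classical reflex arc.  The trial's decision
is the first (non-forced) saccade that lands on one of the two objects —
there is no confidence threshold anywhere in the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import hypothesis_inference as hi
from . import salience_map as sm
from .config import RunConfig
from .esgp import ESGPModel, predict_next, predictive_loglik
from .hypothesis_inference import BeliefState
from .scene_kinematics import ANGLE_TEMPLATES, SceneLayout


@dataclass
class GazeState:
    """Oculomotor state during one saccade."""

    gaze_pos: np.ndarray
    prop_error: np.ndarray
    epoch: int
    iteration: int


@dataclass
class SaccadeEvent:
    """One executed saccade."""

    k: int
    from_pos: np.ndarray
    to_pos: np.ndarray
    target_kind: str            # HAND | BIG | SMALL | OTHER
    onset_ms: int
    duration_ms: int
    excluded: bool = False      # forced first saccade, ignored in analysis


@dataclass
class TrialDynamics:
    """Mutable per-trial state threaded through the epochs."""

    belief: BeliefState
    gaze_pos: np.ndarray
    R_prev: np.ndarray | None = None
    pos_hist: list[np.ndarray] = field(default_factory=list)
    shape_hist: dict[str, list[np.ndarray]] = field(
        default_factory=lambda: {"SMALL": [], "BIG": []}
    )
    events: list[SaccadeEvent] = field(default_factory=list)
    belief_trace: list[BeliefState] = field(default_factory=list)
    decision: str = "NONE"
    last_grid: sm.SalienceGrid | None = None
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


def select_target(
    coarse: np.ndarray, current_gaze: np.ndarray | None = None
) -> tuple[tuple[int, int], np.ndarray]:
    """Pick the argmax cell of the coarse map; ties break row-major.

    Returns ``((row, col), point)`` with the point at the cell centre in
    image coordinates.  An all-zero map means nothing is salient: gaze
    stays put (the current gaze is returned with a sentinel cell).
    """
    coarse = np.asarray(coarse, dtype=float)
    if not np.all(np.isfinite(coarse)):
        raise ValueError("coarse map contains non-finite values")
    if coarse.max() <= 0.0:
        gaze = (np.array([0.5, 0.5]) if current_gaze is None
                else np.asarray(current_gaze, dtype=float))
        return (-1, -1), gaze
    idx = int(np.argmax(coarse))          # first maximum, row-major
    n = coarse.shape[0]
    row, col = divmod(idx, coarse.shape[1])
    point = np.array([(col + 0.5) / coarse.shape[1], (row + 0.5) / n])
    return (row, col), point


def execute_saccade(
    gaze_pos: np.ndarray,
    target: np.ndarray,
    k: int,
    *,
    n_iterations: int = 16,
    ms_per_iteration: int = 12,
    gain: float = 0.35,
) -> tuple[np.ndarray, SaccadeEvent, list[GazeState]]:
    """Drive gaze to the target with a proportional reflex-arc controller.

    Per iteration the gaze moves by ``gain`` times the remaining error, so
    the error decays geometrically as ``(1 - gain)^i``; with the defaults
    the saccade completes (error < 0.01) within the fixed 16 x 12 = 192 ms.
    The event consumes the full duration even for a zero-length saccade.
    """
    target = np.asarray(target, dtype=float)
    if np.any(target < 0) or np.any(target > 1):
        raise ValueError(f"saccade target {target} outside the unit square")
    gaze = np.asarray(gaze_pos, dtype=float).copy()
    start = gaze.copy()
    states = []
    for i in range(1, n_iterations + 1):
        gaze = gaze + gain * (target - gaze)
        states.append(GazeState(gaze.copy(), target - gaze, k, i))
    event = SaccadeEvent(
        k=k, from_pos=start, to_pos=gaze.copy(), target_kind="OTHER",
        onset_ms=(k - 1) * n_iterations * ms_per_iteration,
        duration_ms=n_iterations * ms_per_iteration,
    )
    return gaze, event, states


def classify_landing(
    point: np.ndarray,
    layout: SceneLayout,
    hand_pos: np.ndarray,
    decision_radius: float,
    hand_radius: float,
) -> str:
    """Label a landing point: an object (decision precedence), the hand, other."""
    if np.linalg.norm(point - layout.big_pos) <= decision_radius:
        return "BIG"
    if np.linalg.norm(point - layout.small_pos) <= decision_radius:
        return "SMALL"
    if np.linalg.norm(point - hand_pos) <= hand_radius:
        return "HAND"
    return "OTHER"


def check_decision(
    event: SaccadeEvent, layout: SceneLayout, decision_radius: float
) -> str:
    """Decision = a non-forced saccade landing within reach of an object.

    Layout invariants (object separation >= 0.2 > two decision radii)
    guarantee the landing cannot be within radius of both objects.
    """
    if event.excluded:
        return "NONE"
    if np.linalg.norm(event.to_pos - layout.big_pos) <= decision_radius:
        return "BIG"
    if np.linalg.norm(event.to_pos - layout.small_pos) <= decision_radius:
        return "SMALL"
    return "NONE"


def _pos_row(pos: np.ndarray, layout: SceneLayout) -> np.ndarray:
    return np.concatenate([pos, layout.big_pos, layout.small_pos])


def run_epoch(
    k: int,
    frame_pos: np.ndarray,
    frame_angles: np.ndarray,
    layout: SceneLayout,
    models: dict[tuple[str, str], ESGPModel],
    dyn: TrialDynamics,
    cfg: RunConfig,
    next_frame_pos: np.ndarray | None = None,
) -> SaccadeEvent:
    """Run one saccade epoch against movie frame ``k``.

    Order of operations: (1) sample the frame at the current fixation —
    hand position is read out peripherally (with visual noise), the hand's
    joint configuration only when the fovea covers the hand; (2) update the
    shape and full posteriors; (3) rebuild the salience map from the
    refreshed forward predictions; (4) select and execute saccade ``k``.
    The first saccade of every trial is forced to the hand rest position
    (the fixation-cross instruction) and flagged as excluded from analysis.
    ``next_frame_pos`` (the hand position when the saccade lands, i.e. at
    frame ``k + 1``) is used only to label the landing; frame ``k`` is used
    when it is not supplied.
    """
    if not 1 <= k <= cfg.n_frames:
        raise ValueError(f"epoch {k} outside 1..{cfg.n_frames}")
    true_hand = np.asarray(frame_pos, dtype=float)
    hand = np.clip(
        true_hand + dyn.rng.normal(0.0, cfg.obs_pos_noise, 2), 0.0, 1.0
    )
    angles = (np.asarray(frame_angles, dtype=float)
              + dyn.rng.normal(0.0, cfg.obs_angle_noise, len(frame_angles)))
    fovea_on_hand = np.linalg.norm(dyn.gaze_pos - hand) <= 2.0 * cfg.fovea_sd
    rest = ANGLE_TEMPLATES["FIST"]
    hyps = hi.HYPOTHESES
    angle_var = cfg.obs_angle_noise**2
    pos_var = cfg.obs_pos_noise**2

    # (2) belief updates: likelihoods of frame k under each hypothesis,
    # conditioned on the history up to frame k-1.
    pos_ll = None
    shape_ll = None
    if k >= 2:
        # the first position transition is washed out: the reservoir
        # transient there is regression bias, not goal evidence
        if len(dyn.pos_hist) > cfg.washout:
            pos_ll = np.array([
                predictive_loglik(models[("POSITION", g)],
                                  np.array(dyn.pos_hist), hand,
                                  obs_var=pos_var)
                for g in hyps
            ])
        if fovea_on_hand:
            shape_ll = np.array([
                hi.shape_loglik(
                    models[("SHAPE", g)], np.array(dyn.shape_hist[g]), angles,
                    rest_template=rest, mix_rest=cfg.mix_rest,
                    obs_var=angle_var,
                )
                for g in hyps
            ])
            dyn.belief = hi.update_shape_belief(
                dyn.belief, angles,
                {g: models[("SHAPE", g)] for g in hyps},
                {g: np.array(dyn.shape_hist[g]) for g in hyps},
                rest_template=rest, mix_rest=cfg.mix_rest,
                obs_var=angle_var, beta=cfg.beta,
                sigma_min=cfg.sigma_obj_min, sigma_max=cfg.sigma_obj_max,
            )
    dyn.belief = hi.update_full_posterior(
        dyn.belief, pos_ll, shape_ll, beta=cfg.beta,
        sigma_min=cfg.sigma_obj_min, sigma_max=cfg.sigma_obj_max,
    )
    dyn.belief_trace.append(dyn.belief)

    # extend histories with what was actually seen (imputing the unseen
    # hand configuration with each hypothesis's own expectation)
    dyn.pos_hist.append(_pos_row(hand, layout))
    for g in hyps:
        if fovea_on_hand:
            dyn.shape_hist[g].append(angles)
        elif dyn.shape_hist[g]:
            pred = predict_next(models[("SHAPE", g)],
                                np.array(dyn.shape_hist[g])).mean
            dyn.shape_hist[g].append(pred)
        else:
            dyn.shape_hist[g].append(rest.copy())

    # (3) forward predictions and the salience map
    pos_in = np.array(dyn.pos_hist)
    hand_pred, shape_pred = {}, {}
    for g in hyps:
        pm = models[("POSITION", g)]
        hand_pred[g] = np.clip(predict_next(pm, pos_in).mean, 0.0, 1.0)
        shape_pred[g] = predict_next(
            models[("SHAPE", g)], np.array(dyn.shape_hist[g])
        ).mean
    grid = sm.build_salience_grid(
        dyn.belief, hand_pred, shape_pred, hand, layout, dyn.R_prev, k,
        res=cfg.full_res, grid=cfg.grid, rho_sd=cfg.rho_sd,
        decay_a=cfg.decay_a, fovea_sd=cfg.fovea_sd, bg_floor=cfg.bg_floor,
        softmax_sd=cfg.shape_softmax_sd,
    )
    dyn.R_prev = grid.R_prev
    dyn.last_grid = grid

    # (4) select and execute the saccade
    if k == 1:
        target = layout.start_pos
    else:
        _, target = select_target(grid.coarse, dyn.gaze_pos)
    gaze, event, _ = execute_saccade(
        dyn.gaze_pos, target, k,
        n_iterations=cfg.iterations_per_saccade,
        ms_per_iteration=cfg.ms_per_iteration, gain=cfg.gain,
    )
    dyn.gaze_pos = gaze
    event.excluded = k == 1
    hand_at_landing = (true_hand if next_frame_pos is None
                       else np.asarray(next_frame_pos, dtype=float))
    event.target_kind = ("HAND" if event.excluded else classify_landing(
        event.to_pos, layout, hand_at_landing,
        cfg.decision_radius, cfg.hand_radius))
    dyn.events.append(event)
    decision = check_decision(event, layout, cfg.decision_radius)
    if decision != "NONE":
        dyn.decision = decision
    return event
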