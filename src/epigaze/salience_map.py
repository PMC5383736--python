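"""Belief-weighted salience maps for saccade selection.

The map that drives each saccade is assembled in four steps:

1. an *epistemic value* base map ``S``: for every candidate fixation the
   expected reduction in posterior entropy over the two goal hypotheses,
   i.e. the mutual information between the hypothesis and the foveal sample
   obtained there.  The sample space is a discrete 6-symbol alphabet
   (hand-as-power-grasp, hand-as-precision-grip, hand-as-fist, big object,
   small object, background) with emission probabilities derived from the
   forward models' predictions, so the map is exact, non-negative and
   bounded by the current posterior entropy;
2. the *differential salience* ``S_k = S - min(S)``;
3. a *component enhancement* ``R_k = sum_j w_j G(.; c_j) + a R_{k-1}``:
   unit-peak Gaussian bumps at the predicted hand positions under the two
   hypotheses (weighted by the shape posterior) and at the two object
   positions (weighted by the full posterior gated by predicted hand-object
   proximity), plus an exponentially fading trace of previous maps.  The
   fading trace is what lets a *static* object accumulate salience across
   epochs while the moving hand leaves its own trace behind -- the dynamics
   from which the decision (a saccade landing on an object) emerges without
   any threshold;
4. the combined map ``S-bar_k = S_k + R_k`` is passed through on-off
   centre-surround (difference-of-Gaussians) filtering and block-averaged
   onto the 16 x 16 sensor grid from which the saccade target is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import ndimage

from .hypothesis_inference import HYPOTHESES, BeliefState
from .scene_kinematics import ANGLE_TEMPLATES, FULL_RES, SceneLayout

#: discrete observation alphabet of the epistemic channel
SYMBOLS = ("POW", "PRE", "FIST", "BIG_OBJ", "SMALL_OBJ", "BG")

COARSE_GRID = 16
RHO_SD = 1.0 / 16.0          # sd of the component bumps, image units
DECAY_A = 0.5                # fading weight of the previous enhancement map
FOVEA_SD = 0.05              # sd of the foveal detection window
BG_FLOOR = 0.2               # unnormalized background emission score
SHAPE_SOFTMAX_SD = 15.0      # deg; bandwidth of the shape-symbol read-out


@dataclass
class SalienceGrid:
    """Maps for one saccade epoch."""

    full_res: np.ndarray     # combined map S-bar_k, (H, W)
    coarse: np.ndarray       # 16 x 16 downsampled map
    k: int                   # saccade index
    R_prev: np.ndarray       # enhancement map carried to the next epoch


@lru_cache(maxsize=4)
def _coords(res: int) -> tuple[np.ndarray, np.ndarray]:
    c = (np.arange(res) + 0.5) / res
    xs, ys = np.meshgrid(c, c)
    return xs, ys


def gaussian_bump(center: np.ndarray, sd: float, res: int = FULL_RES
                  ) -> np.ndarray:
    """Unit-peak isotropic Gaussian bump over the image grid."""
    xs, ys = _coords(res)
    d2 = (xs - center[0]) ** 2 + (ys - center[1]) ** 2
    return np.exp(-d2 / (2 * sd**2))


def shape_symbol_probs(
    predicted_angles: np.ndarray, softmax_sd: float = SHAPE_SOFTMAX_SD
) -> np.ndarray:
    """Probabilities of reading the hand as POW / PRE / FIST.

    Softmax over the mean squared distance between a predicted joint-angle
    vector and the three aperture templates; the bandwidth sets how early a
    partial preshape becomes legible.
    """
    scores = np.array([
        np.exp(-np.mean((predicted_angles - ANGLE_TEMPLATES[c]) ** 2)
               / (2 * softmax_sd**2))
        for c in ("POW", "PRE", "FIST")
    ])
    return scores / scores.sum()


def emission_probs(
    hand_pred: dict[str, np.ndarray],
    shape_pred: dict[str, np.ndarray],
    layout: SceneLayout,
    res: int = FULL_RES,
    *,
    fovea_sd: float = FOVEA_SD,
    bg_floor: float = BG_FLOOR,
    softmax_sd: float = SHAPE_SOFTMAX_SD,
) -> np.ndarray:
    """Per-hypothesis emission model of the foveal channel.

    Returns ``p[g, o, i, j]`` — the probability of sampling symbol ``o``
    when fixating pixel ``(i, j)`` given hypothesis ``g`` — built from the
    hypothesis-conditional predicted hand position (Gaussian detection
    window), the predicted hand configuration (template read-out) and the
    fixed object positions.  Rows sum to one over the alphabet.
    """
    xs, ys = _coords(res)
    o_big = np.exp(-((xs - layout.big_pos[0]) ** 2
                     + (ys - layout.big_pos[1]) ** 2) / (2 * fovea_sd**2))
    o_small = np.exp(-((xs - layout.small_pos[0]) ** 2
                       + (ys - layout.small_pos[1]) ** 2) / (2 * fovea_sd**2))
    p = np.empty((2, len(SYMBOLS), res, res))
    for gi, g in enumerate(HYPOTHESES):
        hp = hand_pred[g]
        detect = np.exp(-((xs - hp[0]) ** 2 + (ys - hp[1]) ** 2)
                        / (2 * fovea_sd**2))
        q = shape_symbol_probs(shape_pred[g], softmax_sd)
        p[gi, 0] = detect * q[0]
        p[gi, 1] = detect * q[1]
        p[gi, 2] = detect * q[2]
        p[gi, 3] = o_big
        p[gi, 4] = o_small
        p[gi, 5] = bg_floor
        p[gi] /= p[gi].sum(axis=0)
    return p


def epistemic_value_map(
    belief: BeliefState,
    hand_pred: dict[str, np.ndarray],
    shape_pred: dict[str, np.ndarray],
    layout: SceneLayout,
    res: int = FULL_RES,
    **emission_kwargs,
) -> np.ndarray:
    """Expected information gain (bits) of fixating each pixel.

    ``S(eta) = H(w3, w4) - E[ H(posterior | sample at eta) ]`` computed
    exactly over the discrete alphabet; identically zero under a degenerate
    posterior (nothing left to resolve), and everywhere bounded by the
    posterior entropy.
    """
    w = belief.full_posterior
    if w.min() <= 0.0:
        return np.zeros((res, res))
    p = emission_probs(hand_pred, shape_pred, layout, res, **emission_kwargs)
    pw = w[:, None, None, None] * p          # joint p(g, o | eta)
    po = pw.sum(axis=0)                      # marginal p(o | eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.sum(np.where(pw > 0, pw * np.log2(p / po), 0.0), axis=(0, 1))
    return np.clip(mi, 0.0, None)


def differential_salience(S: np.ndarray) -> np.ndarray:
    """Shift the map so its minimum is exactly zero (order preserving)."""
    S = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(S)):
        raise ValueError("salience map contains non-finite values")
    return S - S.min()


def object_weights(
    belief: BeliefState,
    hand_pos,
    layout: SceneLayout,
    sigma_obj: float | None = None,
) -> np.ndarray:
    """Effective weights of the two object component maps ``(w3', w4')``.

    Each is the full posterior of the hypothesis multiplied by a unit-peak
    Gaussian in the current hand-object distance, with dispersion
    ``sigma_obj`` (defaults to the belief's entropy-derived value, which
    widens as uncertainty resolves): under uncertainty an object only
    becomes salient when the hand is about to reach it, whereas a resolved
    hypothesis projects salience onto its goal object from any distance.
    ``hand_pos`` may be a single point or a per-hypothesis
    ``{"SMALL": ..., "BIG": ...}`` mapping.
    """
    sigma = belief.sigma_obj if sigma_obj is None else float(sigma_obj)
    if isinstance(hand_pos, dict):
        pos = {g: np.asarray(hand_pos[g], dtype=float) for g in HYPOTHESES}
    else:
        p = np.asarray(hand_pos, dtype=float)
        pos = {g: p for g in HYPOTHESES}
    out = np.empty(2)
    for gi, (g, obj) in enumerate(
        zip(HYPOTHESES, (layout.small_pos, layout.big_pos))
    ):
        d2 = float(np.sum((pos[g] - obj) ** 2))
        out[gi] = belief.full_posterior[gi] * np.exp(-d2 / (2 * sigma**2))
    return out


def component_enhancement(
    c_points: np.ndarray,
    weights: np.ndarray,
    R_prev: np.ndarray | None,
    *,
    rho_sd: float = RHO_SD,
    decay_a: float = DECAY_A,
    res: int = FULL_RES,
) -> np.ndarray:
    """Enhancement map ``R_k = sum_j w_j G(.; c_j, rho_sd) + a R_{k-1}``.

    ``c_points`` holds the four component centres (predicted hand position
    under SMALL and BIG, then the small and big object) and ``weights`` the
    matching ``(w1, w2, w3', w4')``.
    """
    c_points = np.asarray(c_points, dtype=float).reshape(-1, 2)
    weights = np.asarray(weights, dtype=float)
    if not 0.0 <= decay_a < 1.0:
        raise ValueError("decay must lie in [0, 1)")
    if rho_sd <= 0:
        raise ValueError("rho_sd must be positive")
    R = np.zeros((res, res))
    for c, w in zip(c_points, weights):
        if w != 0.0:
            R += w * gaussian_bump(c, rho_sd, res)
    if R_prev is not None:
        R = R + decay_a * np.asarray(R_prev, dtype=float)
    return R


def compose_enhanced(S_k: np.ndarray, R_k: np.ndarray) -> np.ndarray:
    """Combined map ``S-bar_k = S_k + R_k`` (elementwise)."""
    if S_k.shape != R_k.shape:
        raise ValueError(f"shape mismatch: {S_k.shape} vs {R_k.shape}")
    return S_k + R_k


def downsample_center_surround(
    full: np.ndarray, grid: int = COARSE_GRID
) -> np.ndarray:
    """On-off centre-surround downsampling onto the ``grid x grid`` sensors.

    Difference of Gaussians (centre sd = half a coarse cell, surround sd =
    twice the centre), rectified at zero, then block-averaged.  A constant
    map yields exactly zero (centre and surround cancel).
    """
    full = np.asarray(full, dtype=float)
    h, w = full.shape
    if h % grid or w % grid:
        raise ValueError(
            f"map of shape {full.shape} not divisible into a "
            f"{grid}x{grid} tiling"
        )
    cell = h // grid
    centre_sd = cell / 2.0
    centre = ndimage.gaussian_filter(full, centre_sd, mode="reflect")
    surround = ndimage.gaussian_filter(full, 2.0 * centre_sd, mode="reflect")
    dog = np.clip(centre - surround, 0.0, None)
    return dog.reshape(grid, cell, grid, cell).mean(axis=(1, 3))


def build_salience_grid(
    belief: BeliefState,
    hand_pred: dict[str, np.ndarray],
    shape_pred: dict[str, np.ndarray],
    hand_now: np.ndarray,
    layout: SceneLayout,
    R_prev: np.ndarray | None,
    k: int,
    *,
    res: int = FULL_RES,
    grid: int = COARSE_GRID,
    rho_sd: float = RHO_SD,
    decay_a: float = DECAY_A,
    fovea_sd: float = FOVEA_SD,
    bg_floor: float = BG_FLOOR,
    softmax_sd: float = SHAPE_SOFTMAX_SD,
) -> SalienceGrid:
    """Assemble the full epoch map: epistemic base, enhancement, coarse grid.

    ``hand_pred`` are the next-frame predicted hand positions (the c1/c2
    component centres), ``shape_pred`` the predicted joint-angle vectors and
    ``hand_now`` the currently observed hand position that gates the object
    components by hand-object distance.  The coarse map is renormalized to
    peak 1 (argmax invariant) before target selection.
    """
    S = epistemic_value_map(
        belief, hand_pred, shape_pred, layout, res,
        fovea_sd=fovea_sd, bg_floor=bg_floor, softmax_sd=softmax_sd,
    )
    S_k = differential_salience(S)
    w_obj = object_weights(belief, hand_now, layout)
    c_points = np.array([
        hand_pred["SMALL"], hand_pred["BIG"],
        layout.small_pos, layout.big_pos,
    ])
    weights = np.array([belief.w1, belief.w2, w_obj[0], w_obj[1]])
    R_k = component_enhancement(
        c_points, weights, R_prev, rho_sd=rho_sd, decay_a=decay_a, res=res
    )
    sbar = compose_enhanced(S_k, R_k)
    coarse = downsample_center_surround(sbar, grid)
    peak = coarse.max()
    if peak > 0:
        coarse = coarse / peak
    return SalienceGrid(full_res=sbar, coarse=coarse, k=k, R_prev=R_k)
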