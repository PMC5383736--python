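"""Sequential Bayesian inference over the two goal hypotheses.

The observer entertains two hypotheses about the actor's goal: SMALL (a
precision grip to the small object) and BIG (a power grasp to the big
object).  Two posteriors are tracked in lockstep:

* the *shape* posterior ``(w1, w2) = p(G | hShape(1:t))`` — updated only
  from hand-configuration evidence, available when the fovea is on the hand;
* the *full* posterior ``(w3, w4) = p(G | OBS(1:t))`` — updated from both
  hand-position and hand-configuration evidence.

Updates are plain Bayes in log space with max-subtraction for stability.
The shape likelihood under each hypothesis is a two-component mixture:
with probability ``1 - mix_rest`` the hand preshapes as the hypothesis's
forward model predicts, with probability ``mix_rest`` it stays at the fist
rest posture (the observer knows that half of the movements hide the
preshape).  The mixture is what keeps fist movements uninformative -- both
hypotheses explain them through their rest component -- while a genuine
preshape is decisive.  It also produces the asymmetry by which the power
grasp is recognized faster: the subtle precision preshape stays close to
the fist, so the wrong (BIG) model can partially explain it away via its
rest component, whereas a wide-open power-grasp hand is inconsistent with
both the rest posture and the precision template.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .esgp import ESGPModel, predictive_loglik

logger = logging.getLogger(__name__)

HYPOTHESES = ("SMALL", "BIG")

#: bounds of the object-map dispersion (image units).  The dispersion is the
#: reach of the Gaussian window through which a goal hypothesis projects
#: salience onto its object: narrow under maximal uncertainty (only imminent
#: hand-object contact makes the object informative) and wide once the
#: posterior is resolved (a confident observer saccades to the inferred goal
#: well before the hand arrives).
SIGMA_OBJ_MIN = 0.12
SIGMA_OBJ_MAX = 0.9


@dataclass(frozen=True)
class BeliefState:
    """Posterior beliefs about the actor's goal at frame ``t``.

    ``shape_posterior`` and ``full_posterior`` are ``(p_SMALL, p_BIG)``
    pairs; ``entropy_full`` is the binary entropy of the full posterior in
    bits and ``sigma_obj`` the dispersion of the object-salience Gaussian
    derived from it.
    """

    shape_posterior: np.ndarray
    full_posterior: np.ndarray
    t: int
    entropy_full: float
    sigma_obj: float

    @property
    def w1(self) -> float:  # p(SMALL | shape)
        return float(self.shape_posterior[0])

    @property
    def w2(self) -> float:  # p(BIG | shape)
        return float(self.shape_posterior[1])

    @property
    def w3(self) -> float:  # p(SMALL | all observations)
        return float(self.full_posterior[0])

    @property
    def w4(self) -> float:  # p(BIG | all observations)
        return float(self.full_posterior[1])


def binary_entropy(p: np.ndarray) -> float:
    """Entropy of a two-point distribution in bits."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def belief_entropy(belief: BeliefState) -> float:
    """Binary entropy (bits) of the full posterior."""
    return binary_entropy(belief.full_posterior)


def sigma_from_entropy(
    entropy_bits: float,
    sigma_min: float = SIGMA_OBJ_MIN,
    sigma_max: float = SIGMA_OBJ_MAX,
) -> float:
    """Object-map dispersion as a bounded function of uncertainty.

    ``sigma_obj = sigma_min + (sigma_max - sigma_min) * (1 - H)^2`` — the
    window widens monotonically (and accelerating) as the posterior entropy
    ``H`` (bits) drops, so only a genuinely resolved hypothesis projects
    salience onto its goal object from far away, while an uncertain one
    requires near hand-object contact.
    """
    h = float(np.clip(entropy_bits, 0.0, 1.0))
    return sigma_min + (sigma_max - sigma_min) * (1.0 - h) ** 2


def _make_state(shape_post, full_post, t, sigma_min, sigma_max) -> BeliefState:
    h = binary_entropy(full_post)
    return BeliefState(
        shape_posterior=np.asarray(shape_post, dtype=float),
        full_posterior=np.asarray(full_post, dtype=float),
        t=t,
        entropy_full=h,
        sigma_obj=sigma_from_entropy(h, sigma_min, sigma_max),
    )


def init_belief(
    prior_big: float = 0.5,
    *,
    biased: bool = False,
    rng: np.random.Generator | None = None,
    sigma_min: float = SIGMA_OBJ_MIN,
    sigma_max: float = SIGMA_OBJ_MAX,
) -> BeliefState:
    """Initial belief.

    With ``biased=True`` the BIG prior is drawn from a Gaussian centred on
    0.57 with variance 0.01, clipped to (0.01, 0.99) — the perceptual
    default-to-big prior probed in the robustness analysis.
    """
    if biased:
        rng = rng if rng is not None else np.random.default_rng()
        prior_big = float(np.clip(rng.normal(0.57, 0.1), 0.01, 0.99))
    if not 0.0 < prior_big < 1.0:
        raise ValueError(f"prior_big must lie in the open (0, 1), got {prior_big}")
    prior = np.array([1.0 - prior_big, prior_big])
    return _make_state(prior, prior.copy(), 0, sigma_min, sigma_max)


def _bayes(prior: np.ndarray, logliks: np.ndarray) -> np.ndarray:
    """Stable log-space Bayes update of a two-point prior."""
    logliks = np.asarray(logliks, dtype=float)
    if np.all(np.isneginf(logliks)):
        logger.warning("all hypotheses have zero likelihood; uniform fallback")
        return np.array([0.5, 0.5])
    with np.errstate(divide="ignore"):
        logpost = np.log(prior) + (logliks - logliks.max())
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    return post / post.sum()


def shape_loglik(
    model: ESGPModel,
    history: np.ndarray,
    shape_obs: np.ndarray,
    *,
    rest_template: np.ndarray | None = None,
    mix_rest: float = 0.5,
    obs_var: float = 0.0,
) -> float:
    """Shape evidence under one hypothesis, with the rest-posture mixture.

    ``log[(1 - pi) N(obs; model prediction) + pi N(obs; rest posture)]``
    where both components use the model's fitted noise variance plus the
    visual read-out variance ``obs_var``.  With ``mix_rest = 0`` (or no
    rest template) this is the plain predictive log-likelihood.
    """
    ll_model = predictive_loglik(model, history, shape_obs, obs_var)
    if rest_template is None or mix_rest <= 0.0:
        return ll_model
    r = np.asarray(shape_obs, dtype=float) - rest_template
    var = model.noise_var + obs_var
    ll_rest = float(-0.5 * np.sum(r**2 / var + np.log(var) + np.log(2 * np.pi)))
    return float(
        logsumexp([np.log1p(-mix_rest) + ll_model, np.log(mix_rest) + ll_rest])
    )


def update_shape_belief(
    belief: BeliefState,
    shape_obs: np.ndarray,
    shape_models: dict[str, ESGPModel],
    histories: dict[str, np.ndarray],
    *,
    rest_template: np.ndarray | None = None,
    mix_rest: float = 0.5,
    obs_var: float = 0.0,
    beta: float = 1.0,
    sigma_min: float = SIGMA_OBJ_MIN,
    sigma_max: float = SIGMA_OBJ_MAX,
) -> BeliefState:
    """Update the shape posterior ``(w1, w2)`` from one preshape observation.

    ``histories[h]`` is the angle history fed to hypothesis ``h``'s forward
    model.  ``beta`` tempers the likelihood.  The frame counter ``t`` is
    advanced by :func:`update_full_posterior`, which is called in lockstep.
    """
    lls = np.array([
        shape_loglik(shape_models[h], histories[h], shape_obs,
                     rest_template=rest_template, mix_rest=mix_rest,
                     obs_var=obs_var)
        for h in HYPOTHESES
    ])
    post = _bayes(belief.shape_posterior, beta * lls)
    return _make_state(post, belief.full_posterior, belief.t,
                       sigma_min, sigma_max)


def update_full_posterior(
    belief: BeliefState,
    pos_loglik: np.ndarray | None,
    shape_loglik_pair: np.ndarray | None,
    *,
    beta: float = 1.0,
    sigma_min: float = SIGMA_OBJ_MIN,
    sigma_max: float = SIGMA_OBJ_MAX,
) -> BeliefState:
    """Update the full posterior ``(w3, w4)`` and advance the frame counter.

    ``pos_loglik`` and ``shape_loglik_pair`` are the per-hypothesis log
    likelihoods ``(SMALL, BIG)`` of the current frame's position and shape
    observation; either may be ``None`` when the corresponding evidence is
    unavailable (the hand out of the fovea yields no shape evidence).
    """
    total = np.zeros(2)
    seen = False
    for lls in (pos_loglik, shape_loglik_pair):
        if lls is not None:
            total += np.asarray(lls, dtype=float)
            seen = True
    post = (_bayes(belief.full_posterior, beta * total)
            if seen else belief.full_posterior.copy())
    return _make_state(belief.shape_posterior, post, belief.t + 1,
                       sigma_min, sigma_max)
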