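"""Echo State Gaussian Process forward models.

Each goal hypothesis (SMALL -> precision grip, BIG -> power grasp) owns two
forward sub-models: one predicting the next-frame hand *position* and one
predicting the next-frame hand *shape* (the 16 joint angles).  A sub-model
is a fixed random recurrent reservoir (echo state network) whose states
feed a Bayesian linear readout; the readout posterior yields a Gaussian
predictive distribution over the next frame, so every prediction comes with
a calibrated variance that the salience and belief machinery can consume.

The Bayesian ridge readout is the finite-feature special case of a
Gaussian-process readout over reservoir states: with features
``phi = [state, input, 1]`` and a spherical prior, the predictive mean and
variance are exact in closed form, which keeps desk-scale simulation fast
and the unit tests checkable against hand-computed ridge solutions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))

MODALITIES = ("POSITION", "SHAPE")
HYPOTHESES = ("SMALL", "BIG")


@dataclass(frozen=True)
class ReservoirSpec:
    """Hyperparameters of the fixed random reservoir."""

    n_units: int = 100
    spectral_radius: float = 0.9
    leak_rate: float = 0.5
    input_scaling: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if not 0.0 <= self.spectral_radius < 1.0:
            raise ValueError(
                "spectral_radius must be in [0, 1) for the echo-state "
                f"property, got {self.spectral_radius}"
            )
        if not 0.0 < self.leak_rate <= 1.0:
            raise ValueError("leak_rate must be in (0, 1]")


@dataclass(frozen=True)
class PredictiveDistribution:
    """Diagonal Gaussian over the next frame of one modality."""

    mean: np.ndarray
    var: np.ndarray
    modality: str

    def loglik(self, observed: np.ndarray, obs_var: float = 0.0) -> float:
        """Gaussian log density, optionally inflated by observation noise."""
        observed = np.asarray(observed, dtype=float)
        if not np.all(np.isfinite(observed)):
            raise ValueError("observation contains non-finite values")
        var = self.var + obs_var
        r = observed - self.mean
        return float(-0.5 * np.sum(r**2 / var + np.log(var) + LOG2PI))


def init_reservoir(
    spec: ReservoirSpec, n_inputs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the fixed recurrent and input weights for a reservoir.

    The recurrent matrix is rescaled so its spectral radius equals
    ``spec.spectral_radius`` to within 1e-6 (exactly zero when the target
    radius is zero).  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    W = rng.normal(0.0, 1.0, (spec.n_units, spec.n_units))
    radius = np.max(np.abs(np.linalg.eigvals(W)))
    if spec.spectral_radius == 0.0 or radius == 0.0:
        W = np.zeros_like(W)
    else:
        W *= spec.spectral_radius / radius
    W_in = rng.uniform(-1.0, 1.0, (spec.n_units, n_inputs)) * spec.input_scaling
    return W, W_in


def run_reservoir(
    W: np.ndarray,
    W_in: np.ndarray,
    leak_rate: float,
    inputs: np.ndarray,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Leaky-integrator reservoir update over an input sequence.

    ``x_t = (1 - a) x_{t-1} + a * tanh(W x_{t-1} + W_in u_t)``.  States are
    componentwise bounded by the tanh range.  Returns states for every input
    step, shape ``(T, n_units)``.
    """
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    if inputs.shape[1] != W_in.shape[1]:
        raise ValueError(
            f"input dimension {inputs.shape[1]} does not match reservoir "
            f"input weights ({W_in.shape[1]})"
        )
    n = W.shape[0]
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    states = np.empty((inputs.shape[0], n))
    for t, u in enumerate(inputs):
        x = (1 - leak_rate) * x + leak_rate * np.tanh(W @ x + W_in @ u)
        states[t] = x
    return states


@dataclass
class ESGPModel:
    """Trained forward sub-model for one (modality, hypothesis) pair."""

    spec: ReservoirSpec
    W: np.ndarray
    W_in: np.ndarray
    in_mean: np.ndarray
    in_std: np.ndarray
    readout: np.ndarray        # (n_features, n_outputs) posterior mean
    A_inv: np.ndarray          # (n_features, n_features) scaled posterior cov
    noise_var: np.ndarray      # (n_outputs,) observation noise per channel
    modality: str
    hypothesis: str
    ridge_lam: float

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if np.any(self.noise_var <= 0):
            raise ValueError("noise variance must be positive")

    # internal: scale raw inputs to reservoir units
    def _scale(self, inputs: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(inputs) - self.in_mean) / self.in_std


def _features(states: np.ndarray, scaled_inputs: np.ndarray) -> np.ndarray:
    ones = np.ones((states.shape[0], 1))
    return np.hstack([states, scaled_inputs, ones])


def fit_readout(
    spec: ReservoirSpec,
    inputs_list: list[np.ndarray],
    targets_list: list[np.ndarray],
    *,
    modality: str,
    hypothesis: str,
    ridge_lam: float = 1.0,
    washout: int = 0,
) -> ESGPModel:
    """Fit the Bayesian linear readout on next-frame prediction pairs.

    Each element of ``inputs_list`` is a ``(T, d_in)`` input sequence and
    the matching element of ``targets_list`` the ``(T, d_out)`` next-frame
    targets; the reservoir is reset between sequences.  A ridge prior with
    precision ``ridge_lam`` guarantees a solution even for degenerate
    (constant) state sequences; the per-channel noise variance is the
    residual variance, floored away from zero.
    """
    if len(inputs_list) < 2:
        raise ValueError("need at least 2 training sequences")
    if len(inputs_list) != len(targets_list):
        raise ValueError("inputs and targets must pair up")
    stacked = np.vstack([np.atleast_2d(s) for s in inputs_list])
    in_mean = stacked.mean(axis=0)
    in_std = stacked.std(axis=0)
    in_std[in_std < 1e-8] = 1.0

    W, W_in = init_reservoir(spec, stacked.shape[1])
    phis, ys = [], []
    for inputs, targets in zip(inputs_list, targets_list):
        scaled = (np.atleast_2d(inputs) - in_mean) / in_std
        states = run_reservoir(W, W_in, spec.leak_rate, scaled)
        phi = _features(states, scaled)
        phis.append(phi[washout:])
        ys.append(np.atleast_2d(targets)[washout:])
    Phi = np.vstack(phis)
    Y = np.vstack(ys)

    A = Phi.T @ Phi + ridge_lam * np.eye(Phi.shape[1])
    n_units = spec.n_units
    if float(Phi[:, :n_units].std(axis=0).max()) < 1e-10:
        logger.warning(
            "degenerate (constant) reservoir states for %s/%s; ridge prior "
            "keeps the readout solvable", modality, hypothesis,
        )
    A_inv = np.linalg.inv(A)
    readout = A_inv @ Phi.T @ Y
    resid = Y - Phi @ readout
    noise_var = np.maximum(resid.var(axis=0), 1e-8)
    return ESGPModel(
        spec=spec, W=W, W_in=W_in, in_mean=in_mean, in_std=in_std,
        readout=readout, A_inv=A_inv, noise_var=noise_var,
        modality=modality, hypothesis=hypothesis, ridge_lam=ridge_lam,
    )


def predict_next(model: ESGPModel, history: np.ndarray) -> PredictiveDistribution:
    """Gaussian predictive distribution of the next frame given the history.

    The variance is the fitted noise floor plus the readout weight
    uncertainty term ``noise_var * phi' A^-1 phi``, so it can never fall
    below the noise floor.
    """
    history = np.atleast_2d(np.asarray(history, dtype=float))
    if history.shape[0] == 0:
        raise ValueError("history must be non-empty")
    scaled = model._scale(history)
    states = run_reservoir(model.W, model.W_in, model.spec.leak_rate, scaled)
    phi = _features(states[-1:], scaled[-1:])[0]
    mean = phi @ model.readout
    weight_term = float(phi @ model.A_inv @ phi)
    var = model.noise_var * (1.0 + weight_term)
    return PredictiveDistribution(mean=mean, var=var, modality=model.modality)


def predictive_loglik(
    model: ESGPModel,
    history: np.ndarray,
    observed_next: np.ndarray,
    obs_var: float = 0.0,
) -> float:
    """Gaussian log density of ``observed_next`` under ``predict_next``.

    ``obs_var`` adds measurement noise (e.g. the visual read-out of joint
    angles) on top of the model's predictive variance.
    """
    return predict_next(model, history).loglik(observed_next, obs_var)


def unroll_mean(
    model: ESGPModel,
    history: np.ndarray,
    n_steps: int,
    to_input=None,
) -> np.ndarray:
    """Iterate the predictive mean ``n_steps`` frames into the future.

    ``to_input`` maps a predicted output vector to the next input row (used
    by the position models to re-append the static object coordinates);
    identity when omitted.  Returns the final predicted output.
    """
    history = np.atleast_2d(np.asarray(history, dtype=float)).copy()
    out = None
    for _ in range(max(0, n_steps)):
        out = predict_next(model, history).mean
        nxt = out if to_input is None else to_input(out)
        history = np.vstack([history, nxt])
    if out is None:
        out = predict_next(model, history).mean
    return out


# --- serialization ---------------------------------------------------------

def model_to_arrays(model: ESGPModel, prefix: str) -> dict[str, np.ndarray]:
    spec = model.spec
    return {
        f"{prefix}_W": model.W,
        f"{prefix}_W_in": model.W_in,
        f"{prefix}_in_mean": model.in_mean,
        f"{prefix}_in_std": model.in_std,
        f"{prefix}_readout": model.readout,
        f"{prefix}_A_inv": model.A_inv,
        f"{prefix}_noise_var": model.noise_var,
        f"{prefix}_meta": np.array(
            [spec.n_units, spec.spectral_radius, spec.leak_rate,
             spec.input_scaling, spec.seed, model.ridge_lam]
        ),
    }


def model_from_arrays(
    data, prefix: str, modality: str, hypothesis: str
) -> ESGPModel:
    meta = data[f"{prefix}_meta"]
    spec = ReservoirSpec(
        n_units=int(meta[0]), spectral_radius=float(meta[1]),
        leak_rate=float(meta[2]), input_scaling=float(meta[3]),
        seed=int(meta[4]),
    )
    return ESGPModel(
        spec=spec,
        W=data[f"{prefix}_W"], W_in=data[f"{prefix}_W_in"],
        in_mean=data[f"{prefix}_in_mean"], in_std=data[f"{prefix}_in_std"],
        readout=data[f"{prefix}_readout"], A_inv=data[f"{prefix}_A_inv"],
        noise_var=data[f"{prefix}_noise_var"],
        modality=modality, hypothesis=hypothesis, ridge_lam=float(meta[5]),
    )
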