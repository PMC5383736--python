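# Methods

This note documents the model implemented in `epigaze`: its assumptions,
the parameters that matter, what the synthetic world does and does not
emulate, and the numerical choices a maintainer would want to know about.

## 1. The task and the stated world

An observer watches a 6-frame movie of a reach-to-grasp directed at one of
two objects: a big ball (taken with a power grasp, POW) or a small ball
(taken with a precision grip, PRE). In half of the movies the hand
preshapes into the grip from movement onset; in the other half it travels
as a closed fist, so the hand configuration is uninformative. Four target
layouts counterbalance the objects' left/right placement so that early
hand position carries no goal information. The observer must infer the
goal and, as in the human paradigm this emulates, its decision is read
from gaze: the first saccade that lands on an object.

### Scene geometry

Coordinates are normalized to the unit square (origin top-left, x
rightward, y downward); frames are rendered at 128 × 128. The hand rests
at (0.5, 0.8); objects sit near y ≈ 0.3–0.35 at mirrored x positions,
pairwise separations ≥ 0.2. Layout bases are jittered ±0.015 by seed.
In layouts 3/4 both objects are equidistant from the transport corridor —
an asymmetric placement would leak a systematic proximity bias toward the
nearer object into the decision stage.

### Kinematics

The reach follows a common transport curve — a quadratic Bezier up the
midline with minimum-jerk timing — blended per frame toward the target
with late-rising weights γ = (0, 0.01, 0.03, 0.15, γ₅, 1), γ₅ ~ U(0.45,
0.95) drawn per trial. Three properties follow, each mirroring the human
stimuli:

- frames 1–2 are identical across goals (counterbalancing: a mutual
  information test over pooled layouts gives < 0.01 bits about target side);
- the trajectory forks mildly at frame 4 (separation ≈ 0.06) and
  decisively at frame 5;
- reach duration varies: on fast trials (γ₅ ≳ 0.7) the hand is on the
  target at frame 5, on slow trials only at frame 6. On the 192-ms epoch
  clock the hand therefore lands at 960 or 1152 ms.

A straight minimum-jerk line start→target was rejected during development:
movement *direction* then reveals the target side from frame 2, destroying
the counterbalancing the paradigm depends on.

Joint angles (16 channels: 3 per finger + wrist, in degrees) interpolate
linearly from the fist rest posture toward the grip template under
preshape, and stay at the fist otherwise. The templates encode a motor
fact that matters downstream: the power grasp opens the whole hand (large
excursions on all finger channels) while the precision grip reconfigures
mainly thumb and index and stays much closer to the fist.

Noise model, chosen once: sensor noise 2.5° per channel per frame;
positional noise 0.015 modulated by sin(πτ) (zero at onset and contact);
between-actor variability as per-actor angle offsets (sd 6°) and an
idiosyncratic via point (sd 0.03). The training corpus is 6 actors × 50
movements per grip = 300 trajectories per sub-model.

## 2. Forward models (echo-state Gaussian processes)

Each (modality, hypothesis) pair owns a sub-model: a fixed random
reservoir (100 leaky tanh units, spectral radius 0.9, leak 0.5, input
scaling 0.5; inputs z-scored) with a Bayesian ridge readout over features
[state, input, 1]. The readout posterior gives Gaussian predictions with
variance `noise_var · (1 + φᵀA⁻¹φ)`; the noise floor is the per-channel
residual variance. This is the finite-feature special case of a
Gaussian-process readout: predictive means and variances are exact and the
unit tests check them against hand-computed ridge solutions.

- SHAPE models regress next-frame angles from the angle history. Their
  predictive sd (~2.5–3°) is small because the actor's systematic offsets
  are visible in the input history and the readout passes them through;
  calibration is therefore checked on held-out executions by the
  *training* actors (standardized residual variance 1.00 ± 0.2). New
  actors are out-of-population by construction.
- POSITION models regress the next hand position from the position history
  augmented with the (visible, static) object coordinates, so each
  hypothesis's model learns to home in on its own target across layouts.

Reservoir hyperparameters are declared, not fitted; 100 units is desk
scale and the echo-state (fading-memory) property is tested explicitly.

## 3. Belief updates

Two posteriors over G ∈ {SMALL, BIG} are maintained with plain Bayes in
log space (max-subtraction): the shape posterior (w1, w2) from
configuration evidence and the full posterior (w3, w4) from position plus
configuration evidence. Evidence gating follows the fovea: hand position
is read out peripherally on every frame (visual noise sd 0.02), the joint
configuration only when gaze is within 2 foveal sd (0.10) of the hand
(visual noise sd 8°). Observation noise enters both the samples and the
likelihood variances.

Two deliberate departures from naive per-model Gaussian likelihoods:

- **Rest-posture mixture.** The observer knows half the movements hide the
  preshape, so the shape likelihood under each hypothesis is
  0.5·N(model prediction) + 0.5·N(fist posture). Fist movies are thereby
  explained equally well by both hypotheses (no spurious drift), while a
  genuine preshape is decisive. The mixture also produces the asymmetry by
  which the power grasp is recognized earlier: the subtle precision
  preshape stays close to the fist, so the wrong (BIG) hypothesis can
  partially explain it through its rest component, whereas a wide-open
  power-grasp hand is inconsistent with everything the SMALL hypothesis
  offers. The big-before-small effect is thus a consequence of template
  geometry, not of hand-tuned model variances.
- **Position washout.** The first position transition is never scored: the
  prediction from a one-frame history reflects the reservoir's transient,
  and its systematic component masquerades as goal evidence. The shape
  stream is scored from the first transition because the preshape signal
  is genuinely present from movement onset.

## 4. The salience map

Per epoch, after the belief update:

1. **Epistemic value.** For every pixel η, S(η) = H(w3, w4) −
   E[H(posterior | sample at η)], computed exactly over a 6-symbol
   alphabet {hand-POW, hand-PRE, hand-FIST, big object, small object,
   background}. Emissions per hypothesis combine a Gaussian hand-detection
   window (sd 0.05) at the predicted hand position, a template read-out of
   the predicted configuration (softmax bandwidth 15°), the fixed object
   windows, and a background floor (0.2). S is non-negative, bounded by
   the posterior entropy, and identically zero under certainty; a
   brute-force loop oracle confirms it to 1e-9.
2. **Differential salience** S_k = S − min S.
3. **Enhancement** R_k = w1·ρ(c1) + w2·ρ(c2) + w3′·ρ(c3) + w4′·ρ(c4) +
   a·R_{k−1}, with a = 1/2, unit-peak Gaussian bumps of sd 1/16, c1/c2 the
   next-frame position predictions under the two hypotheses, c3/c4 the
   object positions. The fading trace is the decision engine: a static
   object accumulates salience across epochs (toward 2× its per-step
   weight) while the moving hand leaves its trace behind.
4. **Object weights.** w_j′ = posterior_j × exp(−d_j²/2σ_obj²) with d_j
   the current hand–object distance and σ_obj = 0.12 + (0.9 − 0.12)(1 −
   H)²: the window *opens* as the posterior entropy H falls. Under
   uncertainty an object becomes salient only at near contact; a resolved
   hypothesis projects salience onto its goal from any distance — the
   mechanism behind proactive saccades. (The inverse convention, narrowing
   the window with confidence, was tried first and provably cannot produce
   a proactive saccade: a gated object weight ≤ 1 never beats the hand
   components, whose weights sum to 1, before contact.)
5. **Combination and read-out.** S̄_k = S_k + R_k is centre-surround
   filtered (difference of Gaussians, centre sd = half a coarse cell,
   surround 2×, rectified) and block-averaged onto the 16 × 16 grid,
   renormalized to peak 1 (argmax-invariant).

## 5. Oculomotor loop and decision

The argmax cell (ties row-major) is the saccade target; gaze reaches it
through 16 iterations of a proportional controller (gain 0.35/iteration,
error < 0.01 at completion), each iteration 12 ms — 192 ms per saccade, 6
epochs per trial. The first saccade is forced to the hand rest position
(the fixation-instruction of the human paradigm) and excluded from
analysis. A non-forced saccade landing within 0.06 (≈ one coarse cell) of
an object is the decision; belief and map updating stop there. There is no
confidence threshold: decided trials exist with posterior confidence well
below 0.95.

## 6. Experiment and read-outs

The 2 × 2 design (preshape × target) runs n trials per condition with
layouts rotated and per-trial seeds shared across conditions (a paired
design). Arrival time = eye landing (saccade onset + 192) − hand landing
(first frame within 0.06 of the target, on the epoch clock), negative when
the eye leads. Undecided trials are excluded from arrival means but
reported. Contrasts use Welch's t-test.

Typical behaviour at the defaults (n = 50/condition): preshaped power
grasps decided at epoch 3 (arrival ≈ −460 ms on average), preshaped
precision grips at epochs 3–4 (≈ −320 ms), fist movements at epochs 4–5
(≈ −200 ms) with ~80% anticipatory fraction against ~97–100% under
preshape. The biased default-to-big prior (Gaussian 0.57, variance 0.01,
clipped) leaves all contrasts qualitatively unchanged.

## 7. What the synthetic world does not emulate

- Rendered frames are three Gaussian blobs with a parametric aperture
  pattern, not video; the belief updates consume the kinematic channels
  directly (gated by gaze), with the renderer serving visualization,
  foveal-sampling tests and map export. A green suite therefore
  establishes the inference-and-gaze dynamics, not visual recognition.
- Kinematics are a stylized transport-plus-approach blend; real grasp
  kinematics have richer structure (grip-aperture overshoot, wrist
  rotation) that the 16 templates do not attempt.
- Two hypotheses only; the belief machinery is binary by construction in
  the shipped experiment.
- The oculomotor plant is a noiseless proportional controller: no
  saccadic noise, no smooth pursuit, no inhibition of return (the fading
  trace makes previously sampled locations less salient on its own).
- The epoch clock quantizes all times to 192 ms; arrival times are
  multiples of it.

## 8. Numerical conventions

- Seeding: every entry point takes a seed; substreams are spawned via
  `numpy.random.SeedSequence` so data generation, reservoir construction
  and trials are independently reproducible. Identical config + seed give
  byte-identical CSVs.
- Log-space Bayes with max-subtraction; a double −∞ likelihood falls back
  to uniform with a warning.
- Ridge prior (λ = 1) keeps the readout solvable for degenerate state
  sequences (warned when states are constant).
- Spectral radius is rescaled exactly (eigenvalue-based) at init; radius
  ≥ 1 is rejected to preserve the echo-state property.
- The coarse map's all-zero corner case keeps gaze in place rather than
  inventing a target.
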