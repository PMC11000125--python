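# Methods

This note documents the models behind `bciadapt`, the parameters that
matter, and what the synthetic experiments can and cannot say about real
recordings.

## 1. The closed-loop BCI simulator

### Synthetic population

Real BCI experiments of this kind decode from a few dozen motor-cortical
units whose true tuning is unknown. The stand-in here is the minimal
population compatible with a linear observation model: cosine tuning with
a multiplicative speed gain,

    rate_i(v) = b_i + m_i · g · |v| · cos(φ_v − p_i),

with baseline rates `b_i ~ U(5, 25)` Hz, modulation depths
`m_i ~ U(5, 15)` Hz, preferred directions `p_i` uniform on the circle,
speed gain `g = 0.1 s/unit` and a speed ceiling of 10 units/s (modulation
is clipped at construction so no intent can drive a rate negative).
Because `|v| cos(φ_v − p_i)` is the projection of the intended velocity on
the preferred axis, expected rates are *exactly linear* in intended
velocity — a cosine-tuned population is the case in which the Kalman
observation model `y = Cx + q` is correct rather than approximate. Spike
counts are Poisson per 100 ms bin; no refractoriness, bursting, unit
dropout or cross-session instability is modeled. Default population size
is 40 units (configurable).

### Decoder

State `x = (px, py, vx, vy, 1)`. The kinematic prior `Ã` integrates
velocity into position over the bin and damps velocity by α = 0.8 per bin;
process noise `W` is isotropic on the velocity block (variance 1.0) and
zero elsewhere (position is a deterministic integral; the constant never
varies). `C` and `Q` are fit by least squares on passive-observation data:
prescribed straight constant-speed trajectories to each target (20 per
target, cruise speed 6 units/s, 3 stationary hold bins at the endpoint).
The steady-state gain comes from iterating the discrete Riccati recursion
from `Σ₀ = W` to a 1e-10 Frobenius fixed point, then
`K = ΣCᵀ(CΣCᵀ + Q)⁻¹`, and `A = (I − KC)Ã`.

Observations are **mean-centered** before decoding: the decoder stores the
passive-set mean count vector and subtracts it in every update, so the
fitted constant column of `C` is near zero. This matters only under
rotation: rotating the gain against uncentered counts also rotates the
large baseline contribution `K·ȳ`, which injects a constant cursor drift
`(R(θ) − I)K·ȳ` that *no* re-aiming strategy can null (we verified the
fraction-1 agent loses control of the cursor in that regime). Centering is
an affine reparameterization — the decoder equations are unchanged with
`y` read as centered counts — and is standard practice in Kalman BCI
implementations. `center_observations=False` restores raw-count decoding.

The rotation perturbation multiplies `K·y` by the 5×5 block-diagonal
matrix with `R(θ)` on the position and velocity blocks and 1 on the
constant. θ is accepted in signed degrees at every public interface
(counter-clockwise positive; encodings like 310° normalize to −50°).

### Task and agent

Eight targets at 45° spacing, distance 10, acceptance radius 1.5, hold 2
consecutive bins, 100-bin (10 s) timeout. These values are free
parameters chosen so baseline reaches last roughly 1–3 s. The simulated
subject is a feedback policy: each bin it aims from the current cursor
position toward the target at cruise speed (zero intent inside the
target), then rotates that aim by `−c·θ` where `c` is the compensation
fraction. `c = 1` models the fully adapted subject; `c = 0` the naive one.
The re-aim plus feedback loop is what produces success-rate parity across
rotations and the −θ centroid displacement; no trial-by-trial learning
curve is modeled (the analysis concerns the post-compensation steady
state).

Residual imperfection is expected: `KC` does not commute with the block
rotation exactly (the population is finite and heterogeneous), so pure
re-aiming leaves direction-dependent errors of a few degrees that the
feedback aim corrects online. This is visible as per-target displacement
scatter of a few degrees around −θ.

## 2. The RL analog

The virtual task uses dimensionless dynamics `v' = 0.1·v + a`,
`x' = x + Δt·v'` with `Δt = 1`, targets at distance 10 with radius 1, a
100-step limit, and reward `[20 on reach] − 0.5·Δd − |a|²`. The position
update uses the *post-action* velocity so actions take effect within the
step (the update is otherwise ambiguous; `position_uses_new_velocity=False`
switches to the pre-action convention). The observation is
(position, velocity, target − position) — six numbers, scaled by 0.1
inside the networks; actions are clipped to magnitude 5. The rotated
variant multiplies the agent's action by `R(θ)` — the perturbation acts on
the produced velocity, mirroring the decoder-side rotation, not on the
observations.

PPO is implemented in numpy: separate policy and value tanh MLPs
(6→128→128→out, orthogonal init), diagonal Gaussian policy with learnable
state-independent log-std, GAE(γ = 0.99, λ = 0.95), clip 0.2, 2048-step
rollouts, 10 epochs of 64-sample minibatches, Adam at 3e-4. Defaults are
the standard PPO values; only network width is pinned at 2×128. Baseline
training runs 150k–300k steps and must reach ≥ 95% success over 200
evaluation episodes (it typically saturates at 100% before 50k).

Retraining in a rotated environment resets the policy log-std to its
initial value first: after baseline convergence the policy is nearly
deterministic (log-std ≈ −3.4) and, being confidently wrong under a large
rotation, cannot find the new solution within a 50k-step budget; with the
exploration reset every tested rotation re-converges to 100% within 50k
steps. Activations for the manifold analysis are the post-tanh outputs of
the policy network's second hidden layer, recorded during deterministic
rollouts (stochastic rollouts are available but add variance without
changing the conclusions).

## 3. Manifold analysis

PCA is the SVD of the units × observations matrix after subtracting the
mean observation; the analysis lives in the PC1–PC2 plane (the task is
two-dimensional and the projected activity is isomorphic to it).
Observations are all bins of successful trials in the analyzed block;
failed trials are excluded by default (configurable).

Conventions and numerical choices:

* Component signs are fixed by the largest-|loading|-positive rule;
  similarity comparisons additionally use absolute cosines, so no
  conclusion depends on sign conventions.
* **Orientation.** An SVD basis is defined up to per-component sign, so
  the *handedness* of the PC1–PC2 plane is arbitrary: a −θ rotation in
  direction space can appear as +θ in a mirrored embedding. Real subjects
  carry one cortex across sessions, which fixes a consistent handedness;
  synthetic sessions redraw the population every seed, so each shared
  basis is oriented to the task before displacement comparisons (PC2 is
  flipped if the baseline centroids run clockwise with respect to target
  order). Displacement regressions presuppose this orientation.
* Angular displacement is the circular difference (after − before) mapped
  to (−180°, 180°]; the across-target mean is a circular mean, since
  per-target values near ±180° would corrupt an arithmetic mean.
* Adjacent gaps are consecutive differences of the sorted centroid angles
  and always sum to 360°; consequently the pooled per-session mean gap is
  45° by construction whenever all 8 centroids are distinct — the
  informative quantities are the spread and the near-gaussian shape.
* The normalized activity difference
  `d_i = (f̄_b,i − f̄_r,i) / mean_j(f̄_b,j)` is extended to the
  singular-value-scaled PCs with the session-mean *absolute* baseline
  loading as denominator (loadings are signed); summaries report the mean
  of |d_i| by default, with the signed mean also available.
* Cosine similarity of the scaled components cannot differ from that of
  the unscaled ones (scaling a vector never changes its direction); the
  scaling is kept because the *normalized-difference* statistics do depend
  on it.
* Separate-basis mode (PCA fit independently before and after rotation)
  is the preservation test; shared-basis mode is used for centroid
  geometry and displacement.

## 4. What the synthetic experiments show — and don't

The generator realizes the idealized mechanism the adaptation hypothesis
posits: a *fixed* tuning map re-aimed at a counter-rotated direction.
Passing tests therefore demonstrate that the analysis pipeline correctly
*detects* within-manifold re-aiming (displacement ≈ −θ, slope ≈ −1,
similarities ≈ 1) and correctly *distinguishes* it from the retrained RL
agent's weight changes (mean-activation similarity far below 1). They do
not demonstrate that real cortex adapts this way — the synthetic
population has no latent dynamics, no noise correlations, no
cross-session nonstationarity, and its manifold is 2-D and linear by
construction. The RL side is likewise one draw from a training-trajectory
distribution; the qualitative contrast (manifold modified vs preserved)
is robust across seeds, but quantities like the RL displacement slope are
not reproducible constants and are reported without acceptance tolerances.

## 5. Problem sizes and determinism

Default experiment sizes: 10 baseline sessions for gap distributions;
3 sessions per rotation over θ ∈ {±50°, ±90°, ±110°} for the displacement
regression; 20 trials per target per block; 150k baseline + 50k
per-rotation retraining steps for the RL contrast (these sizes give
stable statistics — the regression slope varies by < 0.01 across master
seeds — while keeping a full run in the minutes range on one CPU). Every
stochastic stage consumes an explicit integer seed; the pipeline derives
per-stage seeds from one master seed, and fixed-seed runs are
bit-reproducible (the PPO implementation is pure numpy, and weight
matrices are kept C-contiguous so serialization round trips preserve BLAS
results exactly).
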