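# Methods

This note documents the models, estimation procedures, numerical choices,
and the limits of what the synthetic validation establishes.

## 1. Discrete POMDP layer

The finite model holds the transition kernel P(s'|s,a), observation
likelihood P(x|s), nonnegative cost table c(s,a), and discount γ ∈ [0, 1).
It plays two roles: a usable small-scale model, and the exact oracle layer
against which everything else is verified.

Choices:

- **Filtering is linear-space** with explicit renormalization at each step.
  State counts are small by construction, so log-space stability machinery
  would buy nothing and cost clarity.
- **Zero-mass observations raise** an `ImpossibleObservationError` naming
  the (action, observation) pair rather than silently renormalizing: a
  zero-probability observation means the model is misspecified for the
  data, and hiding that invites silent garbage downstream.
- **The first visit conditions a uniform prior** on the first observation
  (a caller-supplied prior is honored). Some convention is needed for t=1;
  conditioning on x_1 makes the one-observation history consistent with the
  recursive update.
- **Planning oracle only.** The optimal-policy problem is implemented as a
  finite-horizon brute-force search over open-loop action sequences (ties
  break lexicographically). Its role is to certify other components on
  instances small enough to enumerate, not to compete as a solver;
  alpha-vector / point-based methods are deliberately out of scope.
- `expected_policy_cost` is exact, not sampled: open-loop plans propagate
  the state distribution; belief-feedback policies are evaluated by
  enumerating observation branches with their probability masses.

## 2. Latent dynamics with shared prototypes

Latent states are continuous (s ∈ R^d) and evolve deterministically:
s_{t+1} = σ(T_p[:,:,a_t] s_t), where the patient tensor T_p = Σ_j z_j T_j
mixes k shared prototypes through a simplex embedding z. Observations are
x_t = W_p s_t + ε with W_p and the noise covariance Σ_p mixed by the same z.

Choices:

- **z lives on the probability simplex.** "Convex combination" is read
  literally; the simplex is the minimal constraint making it true, and it
  guarantees the mixed covariance stays positive semidefinite.
- **σ defaults to tanh** (bounded, odd, fixes the origin); `identity` and
  `relu` are selectable. The identity option defines the linear regime
  where closed-form estimation and identifiability arguments apply.
- **Spectral clipping at ρ = 0.95.** Randomly drawn prototype slices are
  rescaled so every action slice has spectral norm ≤ 0.95. With a
  1-Lipschitz activation fixing the origin this gives ‖s_{t+1}‖ ≤ ρ‖s_t‖,
  so simulated trajectories cannot diverge. Nothing in the model structure
  forces stability, so the generator imposes it.
- **The Tucker path is optional.** The 4-way bank (d×d×m×k) may be stored
  dense or factored; both must induce identical dynamics at full rank
  (tested to 1e-10). The decomposition is truncated higher-order SVD
  refined by orthogonal iteration (HOOI), which starts at the HOSVD
  solution and is monotone, so the reduced-rank error is never worse than
  the HOSVD oracle. Factor ranks are plain configuration; no optimality
  claim is made for any particular rank.
- **Initial latent state defaults to zero** when not supplied; the
  generator draws it N(0, 0.25·I) so trajectories start inside the
  contraction basin.
- Covariance bases are stored as full symmetric PSD matrices; the
  generator's default is isotropic noise_sd²·I with an optional full-
  covariance mode.

## 3. Fitting

The generative structure implies no complete likelihood, so fitting uses
penalized least squares — equivalent to a Gaussian negative log-likelihood
with covariance fixed up to scale — plus two separate penalties:

- a **model-consistency penalty** Σ_t ‖s_{t+1} − σ(T_p s_t)‖² tying the
  estimated latent path to the deterministic dynamics (weight
  `consistency_weight`, default 1), and
- the **literal step-smoothness penalty** Σ_t ‖s_{t+1} − s_t‖² (weight
  `smooth_weight`, default 0), available because temporal coherence of the
  raw path is a meaningful prior in its own right.

During training both penalties act on the *inferred* latent paths (the
alternative — penalizing re-simulated paths — is expressible through the
standalone smoother but is not the training default).

Estimation is alternating minimization with three blocks: (bank, emission
bases) given latents and embeddings; per-patient embeddings; per-patient
latent paths. Under the identity activation every block is exactly
solvable — bank and emission are ordinary least squares on kron(z, s_t)
features, latent paths solve a positive semidefinite quadratic program, and
embeddings solve a small simplex-constrained program (SLSQP). Nonlinear
activations replace the non-quadratic blocks with backtracking gradient
steps. A block update is accepted only if the global objective does not
increase, making the objective trace non-increasing by construction; runs
are deterministic given the config seed.

**Identifiability.** From observations alone, (W, s) are identified only up
to an invertible linear map, and prototypes only up to relabeling of the
mixture components. Consequences adopted here:

- All recovery metrics match prototypes to ground truth by minimum-cost
  (Hungarian) assignment on pairwise Frobenius errors, permuting embeddings
  consistently.
- The **standard recovery benchmark fixes the emission bases at their true
  values** ("known-emission" regime, the usual device in state-space
  recovery studies) so the latent basis is anchored and permutation
  matching is meaningful. Embeddings and latent paths are still estimated
  from the noisy observations. The benchmark uses the identity activation:
  recovery claims are made in the regime where they are interpretable.
- Embedding estimation minimizes one-step-ahead observation prediction
  error; a simplex-lattice grid search is the oracle and a softmax-
  reparameterized gradient descent the default. When prototypes are
  indistinguishable the objective is flat; the estimate is still a valid
  simplex point and is flagged non-identifiable.

## 4. Policy recalibration

Each planning window compares the policy's H-step rollout with the path
inferred retrospectively once the window's observations have arrived —
future observations cannot exist at decision time, so recalibration is
inherently after-the-fact. The minimized objective is

L = Σ_c w_c Δ^(c) + λ Σ_τ E[c(s_τ, a_τ)] + β · mean-KL(π_new ‖ π_old),

with Δ^(c) the per-condition mismatch. Notes:

- **Sign convention.** The surrogate is written in minimized form. An
  ascent formulation on −Δ + λΣE[c] would *maximize* intervention cost;
  minimizing Δ + λΣE[c] matches the stated intent of balancing alignment
  against cumulative cost.
- **Cost on continuous states** is a PSD quadratic sᵀQs (deviation from the
  healthy origin) plus a per-action cost vector; no canonical form exists
  for continuous latent burden, and this is the simplest interpretable one.
- **Where the KL is evaluated:** averaged over the window's inferred latent
  states, and always against the window-start policy, so β bounds the total
  movement per window (KL ≤ initial-loss / β at any accepted iterate).
- **Soft vs hard rollouts.** Gradients flow through the soft rollout
  s_{τ+1} = σ(Σ_a π(a|s_τ) T_a s_τ); hard (argmax, ties to the lowest
  index) rollouts are used for evaluation and for reporting the mismatch in
  `mode="hard"`. Gradients are exact reverse-mode, hand-derived, and tested
  against central finite differences at 1e-4 relative tolerance.
- **Optimization** is gradient descent with backtracking halving; steps
  that cannot decrease the objective are rejected and counted, so the
  objective trace is non-increasing even on non-improvable instances.
- **Uniform policy initialization** uses a random first layer with a zero
  output layer: the action distribution is exactly uniform while the
  gradient path into the output weights stays alive (an all-zero network is
  a saddle where only the output bias can move).
- Per-condition weights w_c default to uniform and are configuration, not
  learned; severity-adaptive weighting is the caller's responsibility.

## 5. Synthetic cohorts

The generator emulates cohorts of encoder-output-like observation vectors:
prototypes drawn with clipped spectral norms and a pairwise Frobenius
separation floor (default 0.3, redrawn up to 100 times) so mixtures are
identifiable; embeddings from Dirichlet(concentration) sweeping
prototype-pure (0.1) to fully mixed (100); behavior policies uniform,
fixed-sequence, or ε-greedy around a supplied policy. All randomness flows
through counter-based Philox streams keyed (seed, patient), so adding
patients never perturbs existing ones and cohorts are pure functions of
their config.

Defaults state the benchmark world: 50 patients, 8–12 visits, d=4, k=3,
m=3, q=6, isotropic observation noise 0.1, Dirichlet(1) embeddings.

What the generator does **not** emulate: raw clinical modalities (text,
imaging, waveforms), missingness, irregular visit timing, measurement
batch effects, or process noise in the latent dynamics. A green test
establishes internal correctness of the algorithms on data that obey the
model's own assumptions — not clinical validity, and not robustness to the
model misspecification real cohorts would bring.

## 6. Numerical conventions

- Probability vectors validated to 1e-12; simplex embeddings to 1e-9;
  covariance symmetry/PSD to 1e-10.
- Indexing is 0-based internally; file formats carry explicit integer IDs.
- CSV floats are written with 17 significant digits and read with
  round-trip parsing, making cohort round trips bit-exact for float64.
- Checkpoints are a `manifest.json` plus named arrays in `arrays.npz`; all
  file formats carry a `format_version` and readers reject unknown majors.
- Ties in argmax action selection break toward the lowest action index;
  every stochastic path takes an explicit seed.

## 7. Known limitations

- The discrete and continuous layers are two regimes, not one model: the
  POMDP is stochastic with discrete observations, the prototype-mixture
  dynamics are deterministic with continuous observations. No stochastic
  continuous hybrid is attempted.
- The alternating fit finds local optima; nothing guarantees global
  recovery outside the linear known-emission regime, and nonlinear-
  activation fitting uses inexact gradient blocks.
- The embedding map is a per-patient free parameter, not a function of
  covariates; generalization to unseen patients requires re-estimation.
- Policy recalibration is local gradient adjustment within a trust region;
  it is not an optimal controller and offers no safety guarantees beyond
  the KL constraint.
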