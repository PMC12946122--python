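# chronodyn

Personalized chronic-disease dynamics at desk scale: a discrete POMDP with
Bayesian belief filtering, a mixture-of-prototypes latent state-space model
of patient-specific disease progression, and a trajectory-aligned,
KL-regularized treatment-policy recalibration loop — all validated on
synthetic cohorts with known ground truth.

## Who this is for

Researchers in biostatistics and computational epidemiology who want a
small, fully inspectable testbed for personalized dynamic-treatment-regime
ideas: every component is exact or oracle-checked, every dataset is
generated with known ground truth, and every run is reproducible from its
seed. It is a modeling laboratory, not a clinical tool.

## The models

**Discrete POMDP.** A patient's health is a latent state s in a finite set,
evolving under interventions a through a kernel P(s'|s,a) and observed only
through noisy findings x with likelihood P(x|s). The information state is
the belief b_t(s) = P(s_t = s | history), updated by the filter

    b_{t+1}(s') ∝ P(x_{t+1}|s') Σ_s P(s'|s,a_t) b_t(s)

and plans are scored by the discounted burden Σ_t γ^{t-1} c(s_t, a_t).
Filtering is verified against exhaustive latent-path enumeration, and a
brute-force open-loop planner serves as the planning oracle.

**Mixture-of-prototypes latent dynamics.** A cohort shares k prototype
transition tensors T_j ∈ R^{d×d×m} and k emission bases (W_j, Σ_j). Each
patient has a simplex embedding z ∈ Δ^{k-1}; their dynamics and emission
are the convex combinations

    s_{t+1} = σ(Σ_j z_j T_j[:,:,a_t] · s_t),   x_t = (Σ_j z_j W_j) s_t + ε_t

with ε_t ~ N(0, Σ_j z_j Σ_j). The global 4-way prototype bank may be stored
Tucker-factored (core × four factor matrices, computed by higher-order SVD
with orthogonal-iteration refinement). Multimorbidity is a block structure
on the latent vector: each condition's sub-vector evolves under its own
tensor. Fitting is alternating penalized least squares over (bank,
emission), embeddings, and latent paths, with a model-consistency penalty
and an optional step-smoothness penalty Σ_t ‖s_{t+1} − s_t‖².

**Trajectory-aligned recalibration.** A softmax policy π(a|s) =
softmax(g_ω(s)) (two-layer perceptron) is rolled forward H steps through
the patient's dynamics; the predicted path is compared with the path
inferred retrospectively once the window's observations arrive, via the
mismatch Δ = Σ_τ ‖ŝ_τ − s_τ‖². Policy weights descend the objective

    L = Σ_c w_c Δ^{(c)} + λ Σ_τ E[c(s_τ, a_τ)] + β · KL(π_new ‖ π_old)

with exact reverse-mode gradients through a soft (policy-expected) rollout;
β is a trust region keeping updates conservative.

## Worked example

```python
import numpy as np
from chronodyn.pomdp import Belief, DiscretePOMDP, belief_update

model = DiscretePOMDP(
    trans=np.array([[[0.9, 0.1]], [[0.2, 0.8]]]),  # P(s'|s,a)
    obs_lik=np.array([[0.7, 0.3], [0.3, 0.7]]),    # P(x|s)
    cost=np.array([[1.0], [3.0]]),
    gamma=0.9,
)
b = belief_update(Belief(np.array([0.5, 0.5])), action=0, obs=0, model=model)
print(b.probs)
```

prints `[0.74038462 0.25961538]`: starting undecided between the healthy
and diseased state, the predicted distribution after one treated transition
is [0.55, 0.45], and observing the healthy-leaning finding (emitted with
probability 0.7 from the healthy state) pulls the posterior to about 74%
healthy.

The full pipeline at cohort scale:

```bash
chronodyn simulate --n-patients 20 --seed 1 --out runs/cohort
chronodyn fit runs/cohort --known-emission --out runs/fit
chronodyn recalibrate runs/fit/checkpoint runs/cohort --horizon 3 --beta 0.1 --out runs/recal
chronodyn evaluate runs/cohort runs/fit/checkpoint --out runs/eval
```

Each command echoes its resolved configuration into the output directory,
so a run is reproducible from its own artifacts.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end pipeline from scratch — generates the
standard synthetic benchmark cohort (50 patients, k=3 prototypes, d=4
latent dimensions, q=6 observed features, observation noise 0.1), fits the
dynamics model in the known-emission recovery regime, recalibrates a
uniform-initialized policy over rolling 3-step windows of the first ten
patients, and scores prototype/embedding recovery, one-step predictive
error, and cumulative alignment. A summary is printed to stderr; for seed 1
it prints a predictive MSE of ≈0.023 (against a 0.01 noise floor), an
embedding recovery error of ≈0.51, and a cumulative alignment loss of
≈0.69 across the recalibrated windows.

The validation criteria themselves are property-based and live in
`tests/test_acceptance.py`: belief-filter oracle equivalence, Tucker
fidelity against the truncated higher-order SVD, the block-decomposition
identity, closed-form parameter recovery in the linear regime, the
prototype-recovery consistency trend, the achievable-target recalibration
benchmark, trust-region behavior, gradient correctness against finite
differences, and bit-exact determinism of all round trips.
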