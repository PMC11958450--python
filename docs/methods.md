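# Methods

## Model

`dagaf` treats a continuous tabular dataset X ∈ ℝ^{n×d} as observations of
a functional causal model (FCM): a directed acyclic graph G over the d
variables together with structural equations X_j = f_j(Pa_j, Z_j), where
Pa_j are the graph parents of X_j and Z_j is exogenous noise. Three
semi-parametric families are supported, each identifiable under its
standard assumptions:

* **LiNGAM** — X_j = linear(Pa_j) + Z_j with non-Gaussian independent noise;
* **ANM** — X_j = f_j(Pa_j) + Z_j with nonlinear f_j and Gaussian noise;
* **PNL** — X_j = g_j(f_j(Pa_j) + Z_j) with g_j invertible; a superset of
  the other two.

### Step 1 — structure learning

Each mechanism f_j is a small multilayer perceptron: a first ("structure")
layer L0 mapping all d inputs to h latent units, followed by locally
connected layers private to node j. The diagonal block of L0 is masked at
every forward pass so f_j never reads X_j. The weighted adjacency is read
off L0 as the ridge norm

    A[j,k] = sqrt( Σ_m W⁽¹⁾[j,k,m]² ),

the L2 norm of the weights connecting input k to node j's latent units.
Acyclicity is imposed through the smooth functional
h(A) = tr(exp(A∘A)) − d, which is zero exactly on matrices whose support
is acyclic.

The training objective combines, per generator update,

* a Wasserstein-1 adversarial loss with gradient penalty (a critic
  d→64→64→1 with LeakyReLU(0.2) scores real rows against reconstructions;
  the penalty (‖∇D‖−1)² is evaluated at per-row uniform interpolates),
* the reconstruction MSE (1/n)Σ‖X−X̃‖²,
* a KL location prior ½Σ_j μ_j² on the per-variable means of X̃ (dropped
  under LiNGAM, whose noise is non-Gaussian),
* the maximum mean discrepancy with an RBF kernel, computed exactly as the
  1/n-normalised i≠j estimator, and
* under PNL, an extra reconstruction term ‖g⁻¹(X) − f(Pa)‖² coupling a
  separate inverse network (widths [d, 10d, 10d, 10d, d], ReLU,
  near-identity initialisation) to the mechanisms.

The constrained problem min L s.t. h(A)=0 is solved with an augmented
Lagrangian: inner phases of Adam updates at fixed (λ, c) on
L + λh + (c/2)h², then λ ← λ + c·h, and c ← 10c whenever h fails to drop
below a quarter of its previous value; the loop stops at h ≤ 1e−8, c >
1e16, or the outer budget. Finally the weighted adjacency is thresholded
at τ = 0.3 (strictly greater-than, so boundary weights drop — erring
toward fewer false discoveries) and any residual near-zero cycle is
repaired by removing its weakest edge.

Reconstructions X̃ from Step 1 are diagnostics only and are never emitted
as synthetic data: the reconstruction pressure shrinks their spread, so
they have high fidelity but poor diversity.

### Step 2 — synthesis

The learned L0 is copied into a fresh generator and frozen (its entries
define the structural equations; Step 2 must not move them). Only the
per-node hidden layers train, adversarially against a fresh critic with
the same Wasserstein-GP loss. Generation is ancestral and noise-driven:
Z_j ~ N(0, 1) per node, columns realized in a topological order of the
thresholded DAG, each mechanism seeing only its DAG parents (all other
inputs zeroed). Under PNL a forward post-nonlinearity g is needed at
generation time but Step 1 only learns g⁻¹; g is therefore fitted after
Step 1 by minimizing ‖g(g⁻¹(x)) − x‖². The shared inverse/forward network
is applied per-variable during ancestral generation (the per-node reading
of the shared [d,10d,10d,10d,d] MLP).

## Numerical engine

All networks run on a small reverse-mode automatic-differentiation engine
over numpy arrays (`dagaf.autodiff`). Its vector-Jacobian products are
themselves built from traced operations, so gradients can be
differentiated again — required for the gradient-penalty term, whose
derivative with respect to the critic parameters is a second-order
quantity. The acyclicity node tr(exp(B)) uses the exact adjoint (e^B)ᵀ
via `scipy.linalg.expm` and is used first-order only. All arithmetic is
float64; gradient-norm square roots are stabilized with a 1e−12 shift.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| lr | 3e−3 | Adam step size for every network (reference setting) |
| batch | 1000 | minibatch rows (reference setting) |
| critic weight decay | 1e−6 | ridge regularisation of both critics (reference setting) |
| threshold τ | 0.3 | edge-pruning threshold on the weighted adjacency (reference setting) |
| h (latent width) | 10 | per-node latent units; the convention of the MLP architecture the generator borrows |
| gp coefficient | 10 | standard gradient-penalty weight |
| n_critic | 5 | critic updates per generator update (WGAN-GP convention) |
| w_mse | 1.0 | reconstruction is the primary structure-learning signal |
| w_adv, w_mmd, w_kld | 0.05 | the distributional terms act as weak regularizers (see below) |
| w_pnl | 1.0 | the inverse-reconstruction coupling under PNL |
| l1 (on L0) | 0.01 | sparsity pressure on the implicit adjacency |
| l2 | 0.01 | ridge on generator parameters |
| epochs / warm_epochs / k_max_iter | 300 / — / 20 | inner and outer budgets |
| h_tol, c_max | 1e−8, 1e16 | augmented-Lagrangian stopping rules |

**Loss-combination weights.** The relative weighting of the five loss
terms is a genuinely open design choice. Experiments during development
showed that the reconstruction+acyclicity core recovers simulated
structures accurately, while weighting the adversarial and MMD terms as
strongly as the MSE injects enough gradient noise to flip edge
orientations (reconstruction mode gives the critic a nearly
deterministic target, so its early gradients are dominated by
finite-sample noise). The package therefore defaults the distributional
terms to 0.05 — active as regularizers, subordinate to reconstruction —
and exposes all weights in `LossWeights` for users who want the ablation
knobs. KLD is structurally excluded under LiNGAM.

**Warm start.** The first augmented-Lagrangian phase may run longer than
later ones (`warm_epochs`): mechanisms fitted well before the penalty
ramps are much less likely to lock in reversed edges.

**MMD batching.** The quadratic-cost MMD is evaluated on a 256-row
subsample of each minibatch with a median-heuristic bandwidth computed
once per epoch; the estimator itself is exact on that subsample.

## Synthetic benchmark

`simulate` draws Erdős–Rényi DAGs (edge probability expected_degree/(d−1)
below a random permutation's diagonal, hence acyclic by construction) and
generates data from five structural-equation families — linear,
A·cos(X+1)+Z, 2·sin(A(X+0.5))+A(X+0.5)+Z, and post-nonlinear sinh/tanh
wrappings of the latter two — column-by-column in topological order.
Defaults are the study conditions: expected degree 3, n = 5000 samples,
five repetitions per cell, d ∈ {10, 20, 50, 100}. Edge weights are drawn
uniformly from ±[0.5, 2.0], a standard choice for this benchmark family;
the dead zone around zero keeps true edges detectable at τ = 0.3.
Linear/LiNGAM
data takes Uniform(−1, 1) noise (non-Gaussianity is required for
identifiability; the law itself is a standard benchmark choice,
configurable to exponential/Laplace/Gumbel); the nonlinear families take
N(0, 1) as their model assumptions state.

What the generator does **not** emulate: heavy-tailed marginals, mixed
discrete/continuous columns, missingness, latent confounding,
selection bias, or non-i.i.d. sampling. Passing the simulated-recovery
tests therefore demonstrates correctness of the optimization and the
identifiability machinery under the stated assumptions, not robustness on
messy real-world data.

## Evaluation

Structure recovery is scored with the structural Hamming distance under
the directed convention: reversal costs 1; TPR/FDR/FPR count a reversed
edge as both a false positive and a miss. Data quality diagnostics
compare correlation matrices (max absolute discrepancy), pooled 2-PC PCA
scores, per-feature marginal histograms, and per-feature importances from
a seeded random-forest regressor predicting each column from the rest.

## Problem sizes used by the test-suite and acceptance script

Training at the full reference budgets (300 inner epochs × up to 20 outer
iterations, five repetitions per cell, d up to 100) is a multi-hour
computation. The package's own verification runs choose smaller budgets
that the recovery experiments above showed to be sufficient at small d:
d = 5 recovery uses warm_epochs 150–200, epochs 40–50, k_max_iter 10,
n_critic 1; the scaled benchmark grid runs at d = 10 with reduced inner
budgets and fewer repetitions. The defaults in `TrainConfig` remain the
paper-scale settings.

## Known limitations

* Reconstruction-mode adversarial training (Step 1) gives the critic a
  target correlated with its input; the Wasserstein trace is a diagnostic,
  not an unbiased distance estimate.
* The augmented Lagrangian drives h to ~1e−4–1e−8 but the thresholded
  graph occasionally retains a weak 2-cycle, resolved greedily.
* PNL synthesis depends on the quality of the fitted forward g; a
  monotone numerical inversion of g⁻¹ is the configurable alternative.
* The tanh-wrapped post-nonlinear family compresses every column into
  (−1, 1), flattening the signal the ridge-norm adjacency thresholds on;
  recovery on that family at expected degree 3 is markedly worse than on
  the others and does not improve with longer budgets.
* CPU-only, float64; d ≫ 100 is outside the intended envelope.
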