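# Methods

## Model

For each node *i* of an *n*-node network, the steady-state global
response row `R_i` (over the `n_pi` perturbation experiments that do
not directly target *i*) is modeled as a linear combination of the
candidate regulators' response rows `R_pr(i)`:

```
R_i = ρ_i · R_sel + ε,          ε_k ~ N(0, σ²) iid,
```

where `R_sel` is the submatrix of `R_pr(i)` selected by the binary edge
configuration `A_i`.  The priors are

- `ρ_i | σ² ~ N(0, V)` with `V = c σ² (R_sel R_selᵀ + λI)⁻¹`
  (a g-prior whose covariance follows the data Gram matrix, kept
  positive definite by the ridge `λI` even when `n_pi < n_ki`);
- `σ² ~ InverseGamma(α, β)`;
- `A_ij ~ Bernoulli(θ)` with `θ ~ Beta(a, b)` shared across edges of
  the subnetwork — marginally, a configuration with `n_ki` edges has
  prior mass `B(a + n_ki, b + (n−1) − n_ki) / B(a, b)`, a proper
  distribution over all `2^(n−1)` configurations.

Both `ρ_i` and `σ²` integrate out in closed form.  Up to a constant
shared by all configurations of one subnetwork,

```
P(A_i | R) ∝ c^(−n_ki/2) · |G + λI|^{1/2} / |K⁻¹ + G|^{1/2}
             · b1^(−(α + n_pi/2)) · B(a + n_ki, b + n − 1 − n_ki)/B(a, b),
b1 = β + ½ (R_i R_iᵀ − R_i R_selᵀ (K⁻¹ + G)⁻¹ R_sel R_iᵀ),
```

with `G = R_sel R_selᵀ` and `K⁻¹ = (G + λI)/c`.  The derivation is the
module's contract; unit tests check posterior odds against brute-force
numeric integration of the likelihood over `(ρ, σ²)` (tensor-product
Gauss–Legendre quadrature with a log substitution in `σ²`), agreeing to
well under 0.5% relative error.

Scores are evaluated in log space via Cholesky factorizations of the
small (`n_ki × n_ki`) matrices; `b1 ≥ β` is enforced as a numerical
floor (mathematically the subtracted term is a projection).  A
per-subproblem memo cache keyed by bit pattern makes Gibbs sweeps over
small candidate sets cost at most `2^(n−1)` distinct evaluations.

## Default hyperparameters

| parameter | default | meaning / rationale |
|---|---|---|
| a, b | 1, 2 | Beta shapes of the sparsity prior; a < b favors sparse nets |
| α, β | 1, 1 | weak inverse-gamma prior on the noise variance |
| c | n_pi | unit-information g-prior scale (one observation's worth) |
| λ | 0.1 | ridge; any value in (0, 1) behaves comparably, enforced range |

Row standardization before inference uses the population standard
deviation (divide by n); the choice is recorded in run metadata.  The
standardization is applied to the full response matrix before the
per-node column exclusion.  Constant rows raise an error naming the
node (an uninformative node, not a recoverable condition).

## Posterior approximation

Exhaustive enumeration is exact and is the default arbiter up to a cap
of 20 candidates.  The Gibbs sampler resamples each indicator from its
Bernoulli full conditional `1/(1 + exp(log p0 − log p1))` in fixed
ascending candidate order (random-scan available as an option), records
one sample per full sweep, and runs 5 parallel chains initialized with
independent fair coin flips.  Default sweep counts: 200 for clean
simulated data, 500 for noisy data, 2000 for real data.  Edge
probabilities average the post-burn-in samples (20% burn-in) over all
chains.  Convergence checking is advisory: the report compares chains'
post-burn-in mean log scores and flags gaps above a tolerance (default
2 nats) without attempting remediation.  Small-instance tests verify
the sweep kernel's stationary distribution (4×4 eigen-analysis) equals
the enumerated posterior to 1e−10 and that chains are seed-reproducible
bit for bit.

## Thresholding

Edges are called where `P_ij ≥ p_th` (ties called present).  The
default scheme sets `p_th` to the mean off-diagonal posterior
probability; collinear perturbation responses systematically depress
the probabilities of true edges, so a data-driven threshold outperforms
the fixed `p_th = 0.5` of the Median Probability Model, which is also
provided.  Diagonals are never modeled and serialize as `NA`.

## Baselines

**TLS MRA** solves each node's orthogonality system by total least
squares: the smallest right singular vector of the stacked system
`[R_prᵀ | R_iᵀ]` (full SVD, so the null vector is available in the
exactly determined case), normalized to the MRA convention `r_ii = −1`.
It requires rank ≥ n−1 of the admissible system and raises a
rank-deficiency error otherwise — the stated limitation the Bayesian
method removes.  **Stochastic MRA** draws Gaussian response matrices
around the measured means, solves each by TLS, trims the configured
outlier fraction (half per tail, by count), flags coefficients with
post-trim variance above a cutoff as unidentifiable, Z-tests the rest
and applies Benjamini–Hochberg.  Two defaults the literature leaves
open are documented as this package's own: the unidentifiability cutoff
(25× the median post-trim variance, with a tiny absolute floor for
degenerate noise-free runs) and the Z statistic (mean divided by the
Monte-Carlo standard deviation — the spread of the realization
distribution, not the standard error of its mean, which would reject
everything at large realization counts).  Default 10,000 realizations
(configurable; production analyses historically used 10⁶).

## Synthetic data

The simulator emulates module-level knockdown experiments.  Node
dynamics use generic saturating kinetics:

```
dx_i/dt = T_i v_i · (b_i + Σ_act w_ij s(x_j)) / (1 + Σ_inh w_ij s(x_j)) − d_i x_i,
s(x) = x / (K + x),
```

with production proportional to capacity `T_i` and linear decay, so an
isolated constitutive node's steady state scales exactly with its
capacity: a knockdown of efficiency *e* scales `T_i` to `(1−e) T_i`
(80% efficiency → 20% residual for the isolated case), and `e = 1` is a
knockout.  Steady states are found by ODE relaxation (LSODA in doubling
time chunks) to `max |dx/dt| / |x| < 1e−9`.  Intrinsic noise, when
enabled, integrates `dx = f(x) dt + σ_sde x dW` with the Milstein
update (Itô reading; the wording that motivated it is ambiguous between
Itô and Stratonovich, and the drift-corrected variant differs only at
O(σ²_sde)), reflecting at zero, and returns the time average over the
second half of the horizon.

The **MAPK-cascade fixture** implements the six-module topology
receptor → adapter → initiator → MAP3K → MAP2K → MAPK with three
inhibitory feedbacks from the terminal module onto adapter, MAP3K and
MAP2K.  Two fixture-level choices matter and are deliberate:

- the terminal module's half-saturation constant keeps the feedback
  interactions in their sensitive range, giving feedback local-response
  coefficients ≈ −0.33, comparable to the cascade edges (0.19–0.32) —
  strong negative feedback is the defining property of this pathway,
  and a fixture with functionally invisible feedback would test
  nothing;
- concentrations sit at a scale of ~100 arbitrary units, representative
  of quantitative proteomic intensities, so that in the measurement
  error model `σ_e² = α_b + β_s e^(−Y)` (log-scale variance, `Y` the
  log intensity) the background term `α_b` is the dominant noise floor
  for strong signals and the `β_s` term matters for weak ones; at unit
  scale the `β_s` term would dominate everywhere, which is not the
  regime that model describes.

Measurement error is applied to the perturbation measurements; the
unperturbed reference column is by default the model's exact baseline
(it still fluctuates when intrinsic noise is enabled), because in a
simulation study the reference state is known rather than re-measured.
A noisy shared reference would add a per-node offset that row
standardization amplifies into spurious correlations between otherwise
unrelated weakly-responding rows; the `noisy_baseline=True` option
reproduces that regime for study.  These are the generator's fixed
conditions; what passing tests show is that the method recovers this
kind of smooth, module-level steady-state data — they say nothing about
unmodeled features of real screens such as cell-to-cell variability,
batch structure, or missing values.

## Evaluation

Predictions are scored over ordered off-diagonal pairs (self-edges
excluded everywhere).  Threshold sweeps use the 0-to-1 grid in steps of
0.01 for probability matrices (unique absolute values for unbounded
score matrices), always augmented with the unique achieved scores and
an above-maximum sentinel so that trapezoidal integration of the ROC
curve equals the midrank Mann–Whitney statistic exactly (cross-checked
against an independent implementation to 1e−9).  Ties therefore
contribute ½.  The zero-prediction end of the PR curve uses the
conventional precision of 1.  Repeated-run summaries report mean and
sample standard deviation (ddof = 1) of AUROC and AUPR with the run
count.

## Study protocols and problem sizes

The bundled protocols (`bvsa.study`) fix the simulation-study designs:
the clean study repeats Gibbs inference (5 chains × 200 sweeps) on the
fixed noise-free 18-perturbation dataset 100 times, so the reported
spread isolates Monte-Carlo approximation error; the noise study runs
50 replicates per `(α_b, β_s)` setting with fresh measurement errors on
shared deterministic steady states and 5 × 500 sweeps; the
incomplete-perturbation study (three single 80% knockdowns, no
replicates, `α_b = 0.01`, `β_s = 0.1`) uses exact enumeration per node,
since at six modules the full posterior costs 32 evaluations and the
design is information-poor enough that sampler noise would blur an
already-narrow margin.  These sizes are the package's reporting
defaults; all are arguments.

## Known limitations

- Only binary topology is inferred; connection-coefficient magnitudes
  and signs are left to the baselines (or post-hoc regression).
- Highly collinear perturbation responses spread posterior mass across
  correlated candidates; the mean-probability threshold mitigates but
  does not remove this.
- The incomplete-perturbation regime close to rank deficiency yields
  AUROC only modestly above chance — that is the honest information
  content of such designs, not a solver artifact.
- The surrogate fixture's kinetics are generic saturating module
  dynamics, not a fitted mechanistic model of any specific pathway
  dataset.
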