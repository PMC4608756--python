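# Methods

## Model

Muscle tension under signal-dependent noise (SDN) is modelled per trial as
`T_i = e_i (1 + α_i Z)` with `Z ~ N(0,1)`: the commanded input `e_i` sets
both the mean and, through the coefficient of variation `α_i`, the spread.
An isometric plant maps tensions to torque linearly, `τ = A·T`, with `A`
constant (no muscle or activation dynamics, no kinematics — the package
deliberately covers only the isometric case, where the task map is a fixed
matrix).

A redundant task observed over trials may mix several commanded inputs, so
each muscle's marginal tension distribution is a Gaussian mixture whose
components all obey the SDN law: component `k` has mean `μ_k` and SD
`α_i μ_k`.  Removing the SDN contribution means rescaling each component's
spread to one common, signal-independent value `β` while keeping its mean;
the responsibility-weighted form

    T̂ = T + Σ_k γ_k (T − μ_k) (β/(α_i μ_k) − 1)

is an affine map per component, soft-assigned by the converged EM
responsibilities `γ_k`.  `β` is the unweighted mean of `α_i μ_k` over all
muscles and components (a `π`-weighted variant is available via
`compute_beta(..., pi_weighted=True)`; the unweighted form is the
default).  Note two approximations inherent to the construction: the
soft-assignment overlap between components, and the fact that at the
SDN-constrained MLE the quantity `α_i μ_k` matches the empirical
responsibility-weighted component SD only up to sampling error — so the
transformed component SD equals `β` to that same accuracy, not exactly.

Coordination is then quantified by the uncontrolled-manifold (UCM)
decomposition against the null space of `A`: per-dimension variances
`V_UCM` (parallel) and `V_ORT` (orthogonal), raw index
`ΔV = (V_UCM − V_ORT)/V_TOT`, and its Fisher-Z transform
`ΔV* = ln((ΔV + n/d)/(n/(n−d) − ΔV))` for Gaussian-friendly inference.
`ΔV*` at `ΔV = 0` (no coordination) is `ln((n/d)/(n/(n−d)))`, computed
from `(n, d)` rather than hard-coded — it is `ln 7 ≈ 1.9459` only for
`n = 8, d = 1`.

## Estimation choices

**EM with closed-form M-step.**  The constrained M-step for `μ_k`
maximizes the expected log-likelihood in closed form as the positive root
of `α² N_k μ² + S₁ μ − S₂ = 0` (`S₁ = Σ γ_nk x_n`, `S₂ = Σ γ_nk x_n²`);
this is exact, fast, and testable against 1-D grid search.  Mixing weights
update as `N_k/N`.  The log-likelihood is checked to be non-decreasing at
every iteration and any decrease beyond rounding raises an error.
Convergence: absolute log-likelihood change `< 1e-8` (default), cap 500
iterations.

**Initialization and restarts.**  Initial means are the `(k+1/2)/K`
quantiles of the data with ±5 % seeded multiplicative jitter; model
selection refits each `K` from 5 seeded restarts and keeps the best
likelihood.  Components whose effective count drops below `1e-6·N` are
removed with a warning.

**Model selection.**  BIC `= −2 log L + (2K − 1) ln N`; the `2K − 1`
counts `K` means and `K − 1` free mixing weights.  Default `K_max = 5`.
Ties favour the smaller `K` (strictly-smaller-BIC comparison).

**Data domain.**  The mixture requires strictly positive observations
(the component mean must stay positive for the SDN density to make
sense); non-positive values are rejected.  The additive SDN law itself
has a small sub-zero tail at weakly commanded muscles (mass ~2·10⁻⁵ at
`e·α` ratios used here), so the simulation-experiment runner floors
simulated tensions at 10⁻⁶ tension units before fitting; the simulator
itself leaves negatives untouched by default (an optional flag clips at
zero), preserving the plain additive-Gaussian reading of the SDN law.

**Variance convention.**  UCM variances divide by `N` (population
convention), consistent with the responsibility-weighted variance used in
the transform's derivation; `ddof=1` is available.  At an index bound
(`ΔV = −n/d` or `n/(n−d)`) the Fisher-Z transform returns signed infinity
with a warning rather than clipping.

**Null-space basis.**  Orthonormal (SVD-based), sign-fixed so each basis
vector's first non-negligible coordinate is positive.  The decomposition
is invariant to the basis choice and to invertible recombinations of the
rows of `A` (tested).

**CV estimation.**  `α` is the OLS slope of EMG SD on EMG mean, with an
intercept by default; the pure SDN model implies a zero intercept, so a
through-origin variant is exposed.  Pearson R is computed on the raw
pairs (defined as 0 for exactly flat SDs, where the correlation is
formally undefined and the linear association is nil).

## The default demonstration plant

The plant the demonstrations run on is a two-elbow, eight-muscle model
with scalar performance variable (total elbow torque): `A` is one signed
row — flexors positive, extensors negative, biarticular muscles counted at
their own elbow — with magnitudes fixed in [1, 3] N·m per unit tension.
Two entries are solved exactly so that the three coordinated demonstration
inputs are torque-equivalent, i.e. genuinely lie on a single UCM; without
that, between-input variability would leak into `V_ORT` and the
"coordinated" condition would not mean what it claims.  Per-muscle CVs are
a single frozen draw from the empirically observed range [0.082, 0.246],
deliberately heterogeneous with the largest CV on the strongly activated,
low-leverage extensor: this heterogeneity is what makes the SDN ellipsoid
of a *single* input lie along the UCM and produce a clearly positive
apparent synergy of raw tensions — the artifact the method removes.
A near-homogeneous draw would make the demonstration vacuous (measured
index ≈ no-coordination from the start).

Study conditions for the simulation experiments: 300 trials per session
for single-input conditions; 100 trials per input for the three pooled
coordinated inputs (300 total); 10 sessions per condition; session indices
tested against the no-coordination value with a two-sided one-sample
t-test at α = 0.05.

The negative-synergy generator builds a single input concentrating
commanded tension on the muscle with the largest `|A_i|·α_i` leverage, so
tension variability loads onto the torque-affecting direction: the
measured index falls below no-coordination while the normalized index
returns to it.

## What the synthetic data do and do not show

The generators reproduce the statistical structure the method is built
for: SDN-lawful tensions (exact mean/SD scaling, Gaussian trial noise,
independent muscles given the command) and mean/SD EMG summaries with
`SD = α·mean` plus measurement noise.  They do not emulate real EMG
features — cross-talk and electrode noise, non-Gaussian tails,
trial-order drift or fatigue, within-trial dynamics, or correlated
command noise.  Passing tests therefore validate the estimator chain
under its own model assumptions; they do not establish robustness to
violations of the SDN law or of component Gaussianity in measured data.

## Problem sizes and tolerances in the tests

Unit and property tests run at small n (tens to hundreds of trials);
Monte-Carlo checks use 3-standard-error bands.  The simulation-experiment
checks use the study conditions above (10 sessions × 300 trials), and the
mixture-recovery check uses 100 replicate seeds of a 300-point
two-component sample at `μ = 0.1, 0.4`, `α = 0.13` with a ≥90 % success
requirement — sizes chosen to keep the whole suite in a few minutes while
leaving the statistical conclusions stable across seeds.  The
tracking-task machinery (target trajectories, feedback gain schedule,
time-out-of-margin scoring) is exercised arithmetically; no closed-loop
human-like tracking is simulated.

## Known limitations

- The transform is one-shot; no re-fit after normalization, and no exact
  deconvolution of overlapping components (soft assignment as printed).
- `β` shared across all muscles is an assumption, not an estimate; its
  validity for a given dataset is not testable inside the method.
- Only the isometric, constant-`A` case is covered; kinematic motor
  elements (joint angles/velocities) would need a different noise model.
- The mixture assumes the commanded inputs are few and well separated
  relative to `α·μ`; heavily overlapping inputs are absorbed into fewer
  components by BIC, which biases the normalized index toward the
  measured one.
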