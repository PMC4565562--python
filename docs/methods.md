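# Methods

## The modeling problem

`grnfit` studies parameter estimation ("reverse engineering") of small
gene-regulatory networks (GRNs) from expression time courses, with a focus
on one question: how large does the search interval for the regulation
weights ω need to be?  Each gene *i* has a transcript concentration
*x_i(t)* governed by one of two semi-mechanistic rate laws:

**Hill law**

    dx_i/dt = α_i Σ_j ω_ij · r_ij(x_j) − β_i x_i
    r_ij(x) = x^n_ij / (x^n_ij + γ_i^n_ij)   if ω_ij > 0   (activation)
            = 1 / (1 + (x/γ_i)^n_ij)          if ω_ij < 0   (repression)

**ANN (sigmoidal) law**

    dx_i/dt = α_i · σ(Σ_j ω_ij x_j − γ_i) − β_i x_i,   σ(u) = 1/(1+e^(−u))

α_i > 0 is the maximal synthesis rate (concentration·time⁻¹), β_i > 0 the
first-order degradation constant (time⁻¹), γ_i the activation/repression
threshold (positive for Hill, any real for ANN), n_ij > 0 the Hill
coefficient of edge (i, j), and ω_ij the signed regulation weight of gene
*j* on gene *i*.  sign(ω) *is* the network topology; |ω| is a regulation
strength.  Both laws take additive inputs and linear degradation; basal
synthesis, multiplicative inputs, delays and nonlinear degradation are out
of scope.  An ω_ij = 0 contributes exactly zero synthesis (the regulation
function is only defined for nonzero weights, and multiplying by zero
annihilates either branch).

Because the rate laws contain compensating scale parameters (above all
α_i), only the *relative* magnitudes of the ω_ij should matter: a model
with weights rescaled into ω ∈ [−1, +1] can in principle reproduce the
behavior of a system built with |ω| = 20 by adjusting α.  The package's
experiment harness re-tests exactly this interval-invariance claim on
self-generated benchmark systems.

## Simulation

The reference integrator is SciPy's adaptive RK45 (`rtol 1e−6`,
`atol 1e−9`, switchable to a stiff method by argument).  Concentrations are
physical quantities: the right-hand side is evaluated at states clamped at
zero, and a trajectory that reaches zero with net-negative synthesis (a
possibility under the Hill law, whose repressive terms subtract) sticks at
the floor rather than going negative.  Integration failures are flagged
in-band (`meta['failed']`), never raised into the optimizer loop.

The inference objective evaluates thousands of candidate models per
optimizer iteration, so it uses a classical RK4 with a fixed number of
sub-steps per observed interval (default 8), vectorized over the entire
particle population: one step advances every candidate at once.  The kernel
reproduces the adaptive reference to well below the data noise scale (the
worst case, trajectories crossing the zero floor, contributes < 0.01
NRMSE at default resolution; the kernel converges to the adaptive solution
as sub-steps grow — both properties are under test).  Candidates whose
state blows up (non-finite or |x| > 1e8) are marked failed and scored with
a penalty of 10³, far above any attainable NRMSE but finite, so the swarm
keeps moving.

The default synthetic time grid is 16 uniformly spaced points on [0, 15]
in arbitrary time units — the benchmark fixes the count, not the horizon;
both are configurable.

## Synthetic benchmark systems

Three 5-gene topologies (A: 5 activating + 3 repressing influences; B and
C: 6 + 1 with distinct edge sets) and an 11-gene cell-cycle-like topology
(15 + 14) are hard-coded as fixed representative edge sets: the published
benchmark specifies the counts and signs, not the exact wiring, and the
interval-invariance question concerns sign/count-level structure.
`random_topology` generates alternatives for sensitivity checks.

A generating system sets ω_ij = sign_ij × m for a magnitude
m ∈ {1, 5, 10, 20} — systems use only the three values {−m, 0, +m},
whereas *inferred models* may take any ω in the search interval.  Kinetic
parameters are drawn uniformly: α, β ~ U[0.5, 2], Hill γ ~ U[0.3, 1.5],
Hill n ~ U[1, 4], ANN γ ~ U[−1, 1], initial conditions x₀ ~ U[0.1, 1].
These keep the dynamics in an order-one, numerically benign range; every
dataset records its sampled ground truth.  If a draw yields an
unintegrable system the kinetics are re-drawn (bounded retries).

Training and validation series come from the *same* system with
independently drawn initial conditions; the validation error therefore
measures genuine predictive power, not re-fit quality.

**Noise.**  Measurements get independent zero-mean Gaussian noise whose
scale is tied to the global range R = max − min of the clean values over
all genes and time points.  The default follows the benchmark's literal
convention — noise *variance* = 0.15 · R — with a `scale_mode="sd"`
alternative (σ = 0.15 · R) since many benchmarks mean the latter and the
literal phrase is dimensionally unusual.  Noisy values are clamped at zero
(concentrations are non-negative); the clamp is recorded in metadata.
Under variance mode the attainable NRMSE floor is √(0.15·R)/R' ≈
√(0.15/R), so it varies with the system's amplitude; comparisons are
always made within a configuration (same data), never across floors.

What the generator does *not* emulate: multiplicative or heteroscedastic
platform noise, missing values, unobserved genes, and non-uniform sampling.
Passing tests therefore demonstrate correct behavior of the machinery and
the interval-invariance property on well-specified systems, not
performance on real microarray data.

## Inference

`GRNModel` (training data + rate law + limits + optional known topology)
follows the statsmodels Model/Results idiom; `fit()` minimizes the
training NRMSE with multi-swarm PSO and returns `GRNResults`.

**Objective.**  NRMSE = RMSE over all genes and time points divided by the
observed data's global range (a per-gene-range variant is available by
flag; the global-range convention matches the noise model's use of the
global range).  Candidates are simulated from the training set's first row.

**Search space.**  Parameters are flattened to a box.  With a known
topology only the support's ω (and Hill-n) entries are searched — a 5-gene
Hill model drops from 65 to 31 dimensions for topology A — and by default
each searched ω_ij is confined to the half-interval matching its known
sign (`constrain_signs=False` relaxes to fixing zeros only).  Strictly
positive scale parameters (α, β, Hill γ, Hill n) are searched in log
space; ω and the ANN threshold γ are searched linearly.  Default limits:
ω ∈ [−1, 1] (the experimental factor; widened per experiment), β ∈
[0.1, 5], Hill γ ∈ [0.05, 3], Hill n ∈ [0.5, 8], ANN γ ∈ [−5, 5], and
α ∈ [0.1, 50].  The generous α ceiling is deliberate: interval-invariance
hinges on α absorbing ω rescaling, so a model confined to ω ∈ [−1, +1]
facing data from an |ω| = 20 system needs roughly 20× the generating α —
capping α near the generating range would handicap narrow ω intervals for
a reason extraneous to the question under study.

**Optimizer.**  Multi-swarm PSO with Pedersen-guideline coefficients
(inertia 0.3925, cognitive 2.5586, social 1.3358), ring migration that
swaps 2 random particles between adjacent swarms every 50 iterations,
velocities clamped at half the box width, positions clipped to the box.
The default geometry is 2 swarms of 40 particles: with the evaluation
budgets used here (2–5 × 10⁴), fewer, larger swarms give each particle
more iterations and measurably better and more consistent final training
errors on these estimation problems than four swarms of 25, while
preserving the diversity benefit of migration; the geometry remains
configurable.  The error threshold ε defaults to 0, i.e.
runs are budget-limited, matching the observed behavior that errors
plateau near the noise floor rather than reaching a preset target.

## Evaluation and the experiment harness

Group summaries report the arithmetic mean x̄ and the sample (n−1)
standard deviation s; singleton groups report s = 0 with a flag.  A
roll-up averages the per-interval means and standard deviations for every
system-law × model-law configuration.

The harness enumerates the factorial systems × generating laws ×
magnitudes × model laws × ω-intervals × replications.  Every cell's seed
derives deterministically from the master seed and the cell's coordinates,
so cells are order-independent, resumable (JSON checkpoints), and
individually re-runnable.  Replications redraw the optimizer seed by
default; `resample_noise=True` additionally redraws the noise realization.
Profiles: `smoke` (2 cells, minutes), `desk` (3 systems × magnitudes
{1, 20} × intervals {[−1,1], [−20,20]} × 2 replications at 20 000
evaluations — the hypothesis's extremes at desk scale), `full` (the complete
24-dataset / 192-cell geometry at 50 000 evaluations, long-running).

The CLI's `experiment --config` accepts a YAML mapping whose keys are the
`ExperimentConfig` fields, overriding the chosen profile, e.g.:

```yaml
systems: [A, C]
magnitudes: [1, 10]
omega_intervals: [[-1, 1], [-10, 10]]
n_replications: 3
budget: 30000
noise_mode: sd
```

Outputs: `records.tsv` (one inference cell per row),
`summary_training_error.tsv` / `summary_validation_error.tsv`
(benchmark-style pivots: systems × magnitudes as rows, model law ×
ω-interval as columns), per-cell JSON checkpoints, and the invariance
report.

**Invariance report.**  For each configuration the report orders the
ω-interval columns by width and declares "no systematic decrease" when the
narrowest interval's mean validation error is within k·s (default k = 2,
s = the wider column's within-cell standard deviation, with a pooled
floor for single-replication cells) of every wider interval's mean.  The
check is one-sided: a narrow interval that does *better* than wide ones is
still "no decrease".  The overall verdict requires ≥ 75% of configurations
to be invariant.

## Numerical and degenerate-input choices

- States within −1e−9 of zero are treated as zero inside the rate laws
  (solver round-off); more negative inputs raise.
- Hill regulation is computed as t/(1+t) with t = (x/γ)^n, with t = ∞
  mapped to 1, so extreme states cannot produce NaNs.
- The ANN sigmoid uses `scipy.special.expit` (saturates, never overflows).
- NRMSE of constant observed data is undefined and raises.
- Encoding rejects parameters outside their limits; decoding never
  produces out-of-box values because positions are clipped.
- PSO stops at `max_evaluations` (never more than one extra batch) or as
  soon as the best error drops below ε.

## Known limitations

- Fixed-step objective integration can mis-score extremely stiff
  candidates (they are penalized as failures rather than integrated
  implicitly); the adaptive reference integrator with a stiff method is
  available but not vectorized.
- The hard-coded topologies are representative instantiations of the
  published edge *counts*, not the exact published wiring.
- PSO is stochastic; per-cell results are exactly reproducible only under
  the recorded seeds.
- Known-topology inference only; structure inference (sparsity penalties,
  topology search) is out of scope.
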