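# Methods

## The partition and its graph semantics

A blanket partition assigns every state one of four roles: internal (μ),
sensory (s), active (a), external (η). The partition is admissible when the
flow of each state depends only on the roles its row of the template
allows —

| flow of | may depend on |
|---------|----------------|
| μ       | μ, s, a        |
| a       | μ, s, a        |
| s       | η, s, a        |
| η       | η, s, a        |

— equivalently, when none of the four forbidden dependency classes
(μ→s, μ→η, η→a, η→μ) occurs. Every state's flow always depends on that
state itself; this self-dependence is universal, carries no information,
and is therefore *implicit*: dependency graphs never store self-loops, and
`unroll_one_step` reinstates them as `x@t → x@t+1` edges.

Conditional independence for a cyclic flow graph is defined on its
one-step unrolled two-slice graph (dynamic-Bayesian-network semantics):
current-slice states are roots, next-slice states have their flow parents
plus themselves. This is a deliberate choice: Jacobian sparsity constrains
the *flow*, and stationary-density independence does not follow from it in
general. The stationary partial correlation between μ and η given the
blanket is therefore computed and reported as a diagnostic only, never as
a pass/fail criterion.

`d_separated` implements Bayes-ball reachability (with ancestors of the
conditioning set precomputed for collider activation) and is cross-checked
against networkx's `is_d_separator` in the unit tests. `pearl_blanket`
(parents ∪ children ∪ co-parents) is verified against an independent
oracle that enumerates conditioning sets in increasing size and returns
the unique smallest d-separating set — exhaustively over all 5-node DAG
structures (the 1024 DAGs whose edges respect a fixed vertex order; every
labelled DAG is isomorphic to one of these and blanket computation
commutes with relabelling) and on random 10-node DAGs.

Classification of a blanket node looks only at its parents: internal
parents only → active; external parents only → sensory; both → reported as
violations (no assignment can satisfy the template, one violation per
offending edge); neither → ambiguous. Ambiguous nodes are reported rather
than silently assigned; `nested_blankets` resolves them to sensory by
default (configurable) so that each rung yields a complete partition. The
classification is label-symmetric: swapping internal with external swaps
sensory with active, so every assignment is equally valid reversed.

The cross-scale soundness check (`macro_ci_check`) verifies *both*
one-step autonomy statements on the unrolled micro graph: (μ∪a)@t+1 is
d-separated from η@t given the rest of the t-slice, and (η∪s)@t+1 from
μ@t likewise. The conjunction holds iff no micro edge crosses any of the
four forbidden role pairs. A single internal-versus-external statement
would be too weak: a gained η→a edge victimises a blanket state and is
invisible to it.

## The model zoo

All conductance-based models use mV, ms, mS/cm², µA/cm², µF/cm²;
neural-mass gains are unitless.

**Hodgkin–Huxley variant.** Voltage with three gated currents, one gating
state per channel: ȧ = (I − g_K n⁴(v−v_K) − g_Na m³(v−v_Na) −
g_l m_l(v−v_l))/C, each gate following α(v)(1−x) − β(v)x kinetics. Two
departures from the classic 1952 model are intentional: the sodium channel
has a single cubed activation gate with no inactivation, and the leak
current carries a gating state. The classic m³h formulation ships
alongside (`hodgkin_huxley_classic`). Rate functions default to the
classic voltage-dependent forms for Na and K; the leak gate's rates are
voltage-independent constants (α_l = β_l = 0.1/ms, pinning the gate near
1/2), so the leak gate has *no* voltage parent in the declared graph —
declaring one would make the declared sparsity unfalsifiable by probing.
Supplying voltage-dependent leak rates restores the edge. The gate flow
form confines gates to [0, 1] for any initial condition inside it.

**FitzHugh–Nagumo.** v̇ = v − v³/3 − w + I, ẇ = (v + α − βw)/τ with
defaults (τ, α, β) = (12.5, 0.7, 0.8); dimensionless time, default
dt = 0.001.

**Morris–Lecar.** Standard Hopf-regime constants. The calcium activation
is instantaneous (a function of voltage itself), so the voltage's declared
parents are only the drive and the potassium gate; the gate relaxes to
½(1+tanh((v−V3)/V4)) with rate φ·cosh((v−V3)/(2V4)).

**Neural-mass units.** First-order in voltage and conductance with linear
decay: v̇ᵢ = gᵢ − κ_v vᵢ, ġᵢ = Σⱼ Wᵢⱼ σ(vⱼ) − κ_g gᵢ, σ the logistic
function (slope 0.56/mV, threshold 0 mV). The decay constants (κ_v = 1,
κ_g = 0.5) guarantee a stable operating point at weak coupling. The
functional form is a design choice — the dependency contract (voltage sees
only its own conductance; conductance collects presynaptic voltages) is
the tested surface, not the algebra.

**Canonical microcircuit.** Four populations per column (spiny stellate
SS, superficial pyramidal SP, inhibitory interneurons II, deep pyramidal
DP), each a neural-mass unit. Intrinsic default edges: SS→SP, SS→II,
SP→II, SP→DP, II→{SS, SP, DP} (inhibitory), DP→II; fully overridable, and
intrinsic edges never cross columns. Extrinsic edges: forward SP_i →
{SS, II}_{i+1} (a config switch adds DP targeting), backward DP_{i+1} →
{SP, II}_i. Because SS and II never project outside their column, the
pyramidal populations are the blanket: with column-1 SS/II internal and
column-2 SS/II external, SP₁/DP₁ classify active and SP₂/DP₂ sensory. The
printed role recovery is stated at the per-population macro graph; at the
raw-state level the voltage states of blanket populations see only their
own population's conductance and are reported ambiguous, which is exactly
what the ambiguity mechanism is for.

**Spring–mass chain.** q̇ᵢ = pᵢ/mᵢ, ṗᵢ = k(q_{i+1}−qᵢ) − k(qᵢ−q_{i−1}),
free ends by default. From any particle's perspective (momentum internal,
own position active, neighbour positions sensory) the role-collapsed
dependency graph instantiates the same four-role template as the neural
models — the Newtonian mirror of the voltage/conductance asymmetry. The
free chain conserves total momentum exactly and total energy to RK4
accuracy; both serve as integrator benchmarks.

## Simulation

Fixed-step RK4 for deterministic models; Euler–Maruyama when any diffusion
amplitude is nonzero. Noise is additive, diagonal, Gaussian — the simplest
model under which the verifier's regression is correctly specified — drawn
as standard-normal blocks of shape (steps, n_states) consumed row by row
in state-label order, so identical (model, init, dt, seed) reproduces
bit-identical trajectories regardless of chunking. Euler–Maruyama is used
deliberately rather than a higher-order scheme: its one-step update
Δx = f(x)dt + σ√dt ε is *exactly* the regression model the
conditional-independence test fits, so the test's null needs no
discretisation correction. With additive noise the scheme attains strong
order 1 (verified on the scalar Ornstein–Uhlenbeck benchmark); RK4 shows
its fourth-order convergence on exponential decay. Linear models carry
their drift matrix, enabling an explicit-Euler stability warning
(dt·ρ(J) ≥ 2) and the analytic stationary covariance via the continuous
Lyapunov equation JΣ + ΣJᵀ + Q = 0 (`scipy.linalg.solve_continuous_lyapunov`),
which is required to agree with a 10⁶-step empirical covariance within 5%
relative Frobenius error.

## Statistical verification

`dynamic_ci_test` fits, for each internal state, an OLS regression of its
increment on the current internal + blanket states, and compares against
the same regression augmented with the external states via the F statistic
on residual sums of squares. Under linear dynamics, Gaussian diagonal
noise and the Euler–Maruyama chain, each per-equation F is
correctly specified; the per-equation p-values are independent across
equations (independent noises, common design) and are combined by
Fisher's method, which remains valid for unequal per-state noise
amplitudes where a single stacked F would not. The mirror direction swaps
the roles of internal and external. An empty far side degenerates to an
accept with p = 1. Within a report the two directions are
Bonferroni-corrected (α/2 each).

One honest caveat: the null is exact only *conditionally* on a strictly
exogenous design, and an autoregressive design is not strictly exogenous —
the regression errors are martingale differences that enter future design
rows. The residual finite-sample size inflation this causes is kept small
(≈ half a percentage point at the default operating point) by making the
calibration fixtures mix fast, see below. The test reports this operating
point: reports flag when the linearization at the operating point is not
stable, since for nonlinear models the F-test's null is only approximately
valid in a small-noise regime around a stable fixed point.

## Synthetic fixtures and calibration

`random_blanket_system` (default sizes 3 internal / 2 sensory / 2 active /
4 external, echoing the many-external asymmetry of real synaptic
convergence) draws Gaussian couplings (sd 0.5) inside the allowed template
blocks, zeroes the forbidden blocks exactly, and places an explicit
self-decay of −2.0 on every diagonal entry; draws whose eigenvalues do not
all satisfy Re λ ≤ −0.1 are rejected and redrawn. The self-decay matters:
merely shifting the spectrum until the largest real part touches the
margin leaves weakly damped oscillatory modes (Re −0.1 with order-unity
imaginary parts) whose discrete-time autocorrelation spans most of a
2000-step trajectory — a near-unit-root regression that measurably
inflates the test's size. With the decay, every mode's autocorrelation
time is a few dozen steps and the test calibrates: across pilot batches of
500 null replicates the rejection rate at α = 0.05 was 0.046–0.068 with
Kolmogorov–Smirnov uniformity p-values above 0.05, and power against a
gained external→internal edge of weight 0.5 at 5000 steps was 1.0. The
fixture's default simulation step is dt = 0.1 (noise amplitude 1 per
state), frozen after that pilot.

`perturb_add_edge` gains exactly one seeded edge between two roles. For
linear systems the weight is written into the drift matrix; if the gained
edge tips the spectrum past the stability margin the diagonal is shifted
back (restabilisation touches only the implicit self-dependence, never the
cross-state structure under test) — an unstable control would diverge
along one eigendirection, collinearise the regression design, and measure
nothing. A weight-zero edge is structurally present but statistically
null, and the test's type-I behaviour is unchanged by it.

The generators are deterministic given their seeds; every CLI run echoes
its resolved configuration, and reports/trajectories regenerate
byte-identically from it.

## What the synthetic data does and does not show

The fixtures are linear, Gaussian, additively driven and stationary;
calibration and power results transfer to real neural recordings only
insofar as a linearisation around a stable operating point governs the
fluctuations. Nonlinear zoo models are covered by structural checks
(declared sparsity vs finite-difference probing) plus small-noise CI tests;
limit-cycle or bursting regimes, state-dependent noise, measurement noise
and unobserved states are all outside what a passing suite demonstrates.
The brain-wide network fixture is a static dependency sketch with no
dynamics attached. No structure learning is attempted anywhere: the
package verifies proposed partitions, it does not discover them.

## Numerical choices

- Finite differences: central, step 1e-5 (linearization and probing);
  probe threshold 1e-8 on |∂f_i/∂x_j|.
- Probe points: 20 per model, uniform within per-state physiological
  ranges stored on the model.
- Integration defaults: dt = 0.01 ms for conductance models, 0.001 for
  FitzHugh–Nagumo and the spring chain, 0.1 for the linear fixtures.
- Degenerate inputs: empty external (or internal) set → CI test accepts
  with p = 1; constant states are named in a rank error; the rank check
  runs on the column-normalised design so magnitude disparities cannot
  mask collinearity; non-finite states abort integration naming the first
  bad time and label.
- Problem sizes in the shipped checks (chosen to keep the full suite
  around a minute and a half on one CPU): 500 replicates for calibration,
  100 for power, 10⁶ steps for covariance agreement, 10⁵ RK4 steps for
  energy drift, chains up to 6 columns for multiscale soundness.

## Known limitations

- The conditional-independence test assumes the Euler–Maruyama sampling
  grid; testing data simulated with another scheme (or subsampled) changes
  the null.
- Fisher's combination assumes diagonal noise; correlated process noise
  across internal states would require a multivariate (Wilks) statistic.
- `structural_graph` can only refute declared sparsity, not confirm it:
  a dependency whose derivative vanishes at all probe points is missed.
- Coarse-graining is existential on edges; it deliberately discards
  weights, so a macro edge says nothing about interaction strength.
- d-separation requires the unrolled graph; no verdicts are offered for
  stationary densities of cyclic graphs (the partial-correlation
  diagnostic exists precisely because that question is open).
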