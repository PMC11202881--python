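# Methods

This note documents the models, the numerical choices behind them, the
synthetic-data generator, and the design decisions that were genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Behavioral probability pipeline

Delegation ratings (0–100) are binarized at an inclusive threshold of
75: a rating of exactly 75 counts as a delegation decision.  Per
enforced response time, probabilities are trial-level proportions pooled
across all participants at that timing (the default); a per-participant
aggregation mode (`by_participant=True`) averages within-participant
proportions first and is provided for unbalanced designs, but is not
the default because the reference analysis pools trials.

The violation statistic is signed as *no-choice minus choice*:
`violation = Pr(Del) − TP(Del)`.  With the observed 5 s row this gives
−0.0519 (the no-choice group delegates less than total probability
predicts), which fixes the sign convention.

Uncertainty for the table statistics comes from a percentile bootstrap
that resamples *participants* (within condition, with replacement),
preserving the within-participant trial structure.  Replicates in which
a conditioning cell comes up empty are dropped rather than imputed.

The threshold is a parameter everywhere; only 75 has published
reference values, so tests pin nothing at other thresholds.

## Markov and quantum walks

Both walks live on a delegation-strength lattice whose index increases
with delegation strength.

* **Intensity matrix** K: tridiagonal, sub-diagonal rates σ_M + μ_M
  (toward higher delegation), super-diagonal σ_M − μ_M, diagonals the
  negated column sums.  The constructive diagonal definition is the
  only one that makes every column sum to zero including the corner
  entries, so it is used for all dimensions.  Feasibility requires
  σ_M ≥ |μ_M|; the constructor rejects anything else.
* **Hamiltonian** H: tridiagonal Hermitian with diagonal drift
  potential μ_Q(x) = a·x + b·x² + c over lattice coordinates x = 1…dim
  and constant coupling σ_Q off the diagonal.  The linear form
  (b = c = 0) is the default and the only one exercised by the fitted
  parameter values; μ_Q in the fitted bundle is the *slope* a.

The 4-state joint models (basis |A,D⟩, |A,¬D⟩, |Dis,D⟩, |Dis,¬D⟩) use a
dim-4 instance of the same tridiagonal templates.  The reference
formulation specifies the template but not the 4×4 instance; using the
lattice template over this basis ordering is a modeling choice of this
package.  The delegate projector is the diagonal 0/1 mask on indices
{0, 2}.

Transition matrices are matrix exponentials (`scipy.linalg.expm`);
correctness is accepted when the Chapman–Kolmogorov semigroup property
holds within 1e−9, which the property tests enforce on random time
pairs.  For two-level systems both walks are additionally checked
against closed forms ((1 ± e^(−2σt))/2 and cos²/sin²).

Decision-only predictions: the Markov model mixes the two conditional
predictions with the implicit agree probability, hence satisfies the
law of total probability exactly; the quantum model propagates the
maintained superposition φ_A·Φ_A + φ_Dis·Φ_Dis and decomposes the
resulting probability into classical part + interference.  Amplitudes
for decision-only runs are taken real and non-negative
(φ = √p), pushing all relative phase into the propagated vectors; the
interference phase is then cos θ = Re⟨Φ_D|A, Φ_D|Dis⟩ / |⟨Φ_D|A, Φ_D|Dis⟩|.
Back-solving cos θ from an observed row checks feasibility and raises
rather than clipping when |cos θ| > 1: such a row cannot be captured by
the 2-level parameterization, and silently saturating would hide that.

## Open-system model

The master equation dρ/dt = −i(1−α)[H, ρ] + α·L(ρ) uses elementary jump
operators L_ij = |i⟩⟨j| with rates γ_ij.  This is the only jump-operator
reading under which the dissipator's diagonal dynamics reduce to the
classical master equation dp_k/dt = Σ_j γ_kj p_j − (Σ_i γ_ik) p_k, which
is the α = 1 oracle the tests enforce to 1e−8.

Two rate modes:

* `intensity` (default): γ_ij = K_ij for i ≠ j.  Off-diagonals of K are
  non-negative by the σ_M ≥ |μ_M| constraint, so the negativity problem
  that a raw intensity matrix poses for Lindblad rates never arises.
  This mode is the default because it reproduced the reference dynamics
  best in the exploratory analysis the model follows.
* `transition_eps`: γ_ij = T_ij(ε)/ε with T = exp(Kε), diagonal zeroed.
  Its ε → 0 limit recovers intensity mode (tested); larger ε damps
  off-diagonals faster.

**Initial states.**  The no-choice condition starts in the *pure
uniform superposition* (ψ_k = 1/√dim, so every entry of ρ is 1/dim):
the intermediate judgment is never elicited and ontic uncertainty is
maintained.  The choice condition starts *dephased*: a diagonal ρ
carrying the post-choice distribution (default uniform) — the judgment
resolved the superposition, leaving only epistemic uncertainty.  Both
have mean delegation 50 under the linear value map, and they evolve
differently for α < 1, which is how one parameter set yields two
condition-specific trajectories.  This is one consistent reading of the
condition semantics, not the only one; it is isolated in
`initial_state` so alternatives are one function away.

**Observables.**  The value map is linear (`linspace(0, 100, dim)`):
state k of an n-state lattice carries delegation strength 100·k/(n−1).
Mean delegation is the value-weighted diagonal;
delegate probability is the diagonal tail sum from the first state
whose value reaches 75 (0-based index 15 at dim 21).

**Time scale.**  Experiment seconds are multiplied by `time_scale`
before propagation.  The fitted drift/diffusion magnitudes (μ_Q ≈ 390
per unit time at dim 21) imply a model time unit much finer than an
experiment second: at unit scale every probed timing sits deep in the
steady state and the timing axis carries no information.  The default
is 0.01, which places the 5–35 s probe window inside the dynamically
informative range; it is a fittable parameter like the others.

**Propagation.**  The generator is assembled as a sparse
dim² × dim² superoperator on row-major-vectorized ρ.  The Hamiltonian
part is −i(1−α)(H⊗I − I⊗Hᵀ); the dissipator reduces for elementary
jumps to (Dρ)_ab = −½(r_a + r_b)ρ_ab + δ_ab Σ_j γ_aj ρ_jj with exit
rates r_j = Σ_i γ_ij, assembled directly without materializing the
operator sum (the operator-sum form is kept as a brute-force oracle in
the tests).  Trajectories use one dense eigendecomposition of the
generator per parameter set, after which additional time points are
essentially free — this is what makes the fitting loop affordable at
dim 21 (~0.3 s per parameter evaluation).  Each propagated state is
validated (Hermiticity 1e−10, trace 1e−9, minimum eigenvalue ≥ −1e−8)
*before* the residual eig round-off asymmetry is scrubbed by
symmetrization, so the checks are informative; violations raise with
the offending time.  Agreement with `expm_multiply` was at the 1e−12
level during development and the classical/quantum limits are enforced
by oracles in the suite.

## Fitting

The objective is the sum of squared errors in delegation-strength units
(squared 0–100 units) over the 7 timings of each supplied condition;
with both conditions the objective is the sum of the two SSEs (a
separate-objective mode falls out of passing one condition at a time).
The search is seeded multi-start bounded local optimization (Powell;
for a single varied parameter, bounded scalar minimization) over a
user-chosen subset of parameters, with best-so-far tracking across all
evaluations so a larger budget can never return a worse objective.
When μ_M varies with σ_M fixed, its box is intersected with the
σ_M ≥ |μ_M| constraint; when both vary, infeasible proposals receive a
penalty sloped back toward the feasible region (a flat penalty stalls
Powell on the plateau).  Fits are bit-reproducible given the seed.

The sklearn estimator (`LindbladDelegationModel`) carries the search
specification in its constructor so `get_params`/`clone` round-trip the
whole fit definition; `X` is (timing_s, condition-code) rows.

**Parameter recovery** is generate-then-fit: noiseless model means plus
i.i.d. Gaussian observation noise, refit, summarize bias/RMSE.  The
default noise SD in the recovery checks is 1.5 delegation-strength
units — the standard error of a per-timing condition mean implied by
the study design (rating SD ≈ 25 on the bimodal 0–100 scale over
96 participants × 3 trials per timing cell: 25/√288 ≈ 1.5).  The
headline recovery check varies α (the regime-interpolation parameter,
the model's focal quantity) with the remaining parameters held at their
generating values; joint (α, μ_M) recovery is exercised at dim 9 in the
unit suite, where each fit is cheap.

The reference SSE values for the original study data are not
reproducible here because the underlying per-timing mean delegation
strengths were published only as figure points; self-consistency
(SSE ≤ 1e−6 on the model's own noiseless output) and parameter recovery
stand in for them.

## Synthetic-data generator

The generator emulates the study design, not just its marginals:

* 2 between-subject conditions × 7 timings; 96 participants per
  condition by default (N = 192); 21 trials each, i.e. 3 per timing.
* AI accuracy is a *fixed-count* schedule — round(0.48 · 21) = 10
  correct annotations per participant in seeded random order — matching
  a calibrated accuracy rather than i.i.d. coin flips.  The annotation
  correctness is recorded but does not influence ratings by default
  (participants never saw the accuracy, and no learning model is
  assumed).
* Ratings come from a two-component truncated-normal mixture on
  [0, 100] (low component loc 30/scale 16, high component loc 85/scale
  10), giving the bimodal shape with the delegation-leaning bulk above
  55.  For each cell the high-component weight is solved so that
  P(rating ≥ 75) equals the requested conditional probability; targets
  outside the mixture's attainable tail range raise a spec error at
  construction.
* The default per-timing probabilities are the observed study values,
  so a large synthetic replicate pushed through the analysis pipeline
  recovers them within binomial Monte-Carlo error (tested at 3σ).

What the generator does **not** emulate: participant heterogeneity in
response style (all participants share the cell probabilities), serial
dependence or learning across trials, slider digit preferences, and any
coupling between AI correctness and ratings.  Passing round-trip tests
therefore show that the *pipeline arithmetic* is right under the
design's sampling structure — not that real data meet these
assumptions.

## Problem sizes and runtimes

The suite runs the property checks at lattice dimensions 2–8 (100
random draws per propagator family; 50 random open-system
trajectories), the limit oracles at dim 5–6, fitting unit tests at
dim 5, and the headline self-consistency/recovery checks at the full
dim 21 with 20 recovery replicates — sizes chosen so the whole suite
and the acceptance script each complete in a few minutes on one CPU
while still exercising the full-dimensional model.

## Known limitations

* The open-system likelihood is implicit (SSE on means); no
  distributional model of ratings links the density matrix to the
  binarized probabilities, so the pipeline and the dynamical model are
  connected through means only.
* (1−α)·H and α·γ enter the generator as products; rescaling H against
  (1−α) is nearly degenerate, so α is well identified only with the
  generator magnitudes (or their bounds) pinned.  The recovery harness
  makes that conditioning explicit.
* Response-time distributions and stopping rules are out of scope; the
  walks model state evolution between enforced decision times only.
* The α = 0 limit conserves purity exactly but the eigendecomposition
  of the non-normal generator can lose accuracy for extremely long
  horizons; the validation layer raises rather than silently degrading.
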