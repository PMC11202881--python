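# qtrust

Models of trust dynamics in AI-supported decision-making, built around a
two-stage delegation experiment: a participant reviews an AI-annotated
image, either makes an intermediate judgment about the AI's advice
(agree/disagree — the *choice* condition) or merely acknowledges it
(*no-choice*), and then rates on a 0–100 slider how likely they would be
to delegate such decisions to the AI.  The rating ("delegation
strength") operationalizes trust; the enforced response time is varied
over 5–35 s in 5 s steps.

The package is for computational cognitive scientists and human–AI
interaction researchers who want to (a) run the behavioral probability
pipeline that exposes violations of the law of total probability in
such experiments, and (b) model the delegation dynamics with classical,
quantum, and quantum-open-system random walks.

## The science in brief

**Behavioral pipeline.** Ratings are binarized at a delegation threshold
(≥ 75).  Per timing, the choice condition yields Pr(A), Pr(Dis),
Pr(Del|A), Pr(Del|Dis) and hence the total probability

    TP(Del) = Pr(A)·Pr(Del|A) + Pr(Dis)·Pr(Del|Dis),

which classically must equal the no-choice Pr(Del).  The signed
difference Pr(Del) − TP(Del) is the empirical interference term; it is
reliably nonzero in the data this package models.

**Markov model.** A continuous-time Markov chain on a delegation
lattice, generated by a tridiagonal intensity matrix K (drift μ_M,
diffusion σ_M), propagated by T(t) = exp(Kt).  Its decision-only
prediction is a convex mixture of the conditionals, so it satisfies the
law of total probability identically — it *cannot* produce the observed
violations.

**Quantum model.** A quantum walk generated by a tridiagonal Hermitian
Hamiltonian H (drift potential μ_Q(x) = a·x, coupling σ_Q), propagated
by U(t) = exp(−iHt) with doubly stochastic |U_ij|².  When the
intermediate judgment is never elicited the agree/disagree superposition
is maintained and the delegation probability gains an interference term
2·φ_A·φ_Dis·|⟨Φ_D|A, Φ_D|Dis⟩|·cos θ, violating total probability
whenever cos θ ≠ 0.

**Open-system model.** The two regimes interpolate in one GKSL (Lindblad)
master equation on density matrices,

    dρ/dt = −i(1−α)[H, ρ] + α·L(ρ),    0 ≤ α ≤ 1,

with elementary jump operators rated by the classical intensity matrix.
α = 0 is the purity-conserving oscillatory quantum walk, α = 1 the
classical master equation; intermediate α yields oscillations that
dissipate to a steady state.  The behavioral observable is the mean
delegation strength under a linear 0–100 value map, fitted to
per-timing condition means by SSE.

## Worked example

```python
import numpy as np
import qtrust as qt

# --- the 5 s probability row and its violation -----------------------
cell = qt.REPORTED_CONDITION_PROBABILITIES[5]
tp = qt.total_probability(cell["pr_agree"], cell["pr_del_given_agree"],
                          1 - cell["pr_agree"], cell["pr_del_given_dis"])
print(round(tp, 4))                          # 0.4637
print(round(cell["pr_del_nochoice"] - tp, 4))  # -0.0519

# --- open-system trajectory at the fitted parameters ------------------
params = qt.OpenSystemParams()   # dim 21, mu_q 390.45, sigma_q 30.12,
                                 # mu_m 5.95, sigma_m 19.62, alpha 0.21
timings = np.array([5, 10, 15, 20, 25, 30, 35])
rho0 = qt.initial_state("no_choice", params.dim)
traj = qt.evolve_density(rho0, params, timings * params.time_scale)
print(np.round(traj.mean_delegation, 2))
# [51.78 51.6  52.58 52.92 53.55 54.07 54.58]
```

The first two numbers are the choice-condition total probability of
delegation at the 5 s timing and the (negative) violation: the no-choice
group delegates *less* than the law of total probability predicts —
destructive interference, back-solvable as cos θ ≈ −0.199 via
`qt.solve_interference_phase`.  The trajectory is the model's mean
delegation strength (0–100) for the no-choice condition at the seven
probed timings.

The same workflow is available from the shell:

```sh
qtrust simulate --seed 3 --out trials.csv      # synthetic study replicate
qtrust analyze trials.csv --out table.csv      # per-timing probability table
qtrust evolve --out traj.csv                   # model trajectories
qtrust fit observed.csv --vary alpha --out fit.yaml
```

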