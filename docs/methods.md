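# Methods

## The model

`xlqg` solves finite-horizon stochastic optimal control problems of the
extended linear-quadratic-Gaussian (LQG) family.  The plant, sensor and
internal estimator are, for t = 1..n−1,

    x_{t+1}    = A x_t + B u_t + ξ_t + Σ_i ε_t^i C_i u_t
    y_t        = H x_t + ω_t + Σ_i ϵ_t^i D_i x_t
    x̂_{t+1}   = A x̂_t + B u_t + K_t (y_t − H x̂_t) + η_t

with additive Gaussian noises ξ ~ N(0, Ω^ξ), ω ~ N(0, Ω^ω),
η ~ N(0, Ω^η), and i.i.d. scalar standard-normal multipliers ε^i, ϵ^i.
The C_i terms are control-dependent (signal-dependent) noise — motor
noise whose standard deviation scales with the command — and the D_i
terms state-dependent observation noise.  The cost is
Σ_t (x_t' Q_t x_t + u_t' R u_t) with Q_t ⪰ 0 and R ≻ 0.  The control is
restricted to u_t = −L_t x̂_t.

Because the multiplicative noise couples the control and estimation
problems, neither a Riccati pass nor a Kalman pass alone is optimal.
The backward controller recursion (`control_synthesis`) takes the filter
gains as given; the forward filter recursion (`filter_synthesis`) takes
the control gains as given; `coordinate_descent.solve` alternates the
two until the total expected cost

    J = x̂_1' S^x_1 x̂_1 + tr{(S^x_1 + S^e_1) Σ_1} + s_1

changes by less than a relative tolerance (default 1e−15).  Each
iteration updates the filter first (the very first pass therefore runs
the classic Kalman filter of the uncontrolled system) and the controller
second, so the reported cost always belongs to the mutually consistent
gain pair returned.  In the classic-LQG limit (no C/D terms) the two
passes decouple, the second iteration reproduces the first exactly, and
the solver stops after two iterations — the separation principle.

## Exact moment propagation

The package's central feature is that, for fixed gain sequences, the
closed loop is linear in (x, x̂, e = x − x̂) with random coefficients, so
the nine first/second-moment sequences (three means, three variances,
three cross-covariances) obey closed-form deterministic update equations
(`moment_propagation.propagate_moments`).  The multiplicative-noise
contributions enter through the *raw* second moments
Σ^x̂ = var[x̂] + E[x̂]E[x̂]' and Σ^x = var[x] + E[x]E[x]', recomputed at
every step from the propagated quantities; the recursion is therefore
exact for arbitrary, even suboptimal, gain sequences.  This replaces
Monte Carlo averaging: one deterministic sweep over the horizon gives
what would otherwise require tens of thousands of simulated trials.

Initial conditions take the initial estimate as deterministic and the
initial error as carrying the prior covariance: E[x_1] = E[x̂_1] = x̂_1,
var[x_1] = var[e_1] = cov[x,e]_1 = Σ_1, all other second moments zero.
This matches the filter recursion's initialisation (Σ^e_1 = Σ_1,
Σ^x̂_1 = x̂_1 x̂_1') and makes the structural identities hold from t = 1.

Two identities are used as live consistency checks at every step, since
the mean and variance recursions of x, x̂ and e are mutually redundant:

    E[x] = E[x̂] + E[e]
    var[x] = var[x̂] + var[e] + cov[x̂,e] + cov[x̂,e]'

Additionally, at a converged optimum the filter recursion's error second
moment Σ^e and the propagated var[e] coincide; the test suite measures
this at 1e−6 relative (observed agreement on the reaching task is at
machine precision, ~1e−15 relative).

## The reaching task

The packaged application is a one-dimensional point-to-point reaching
movement: a unit point mass (m = 1 kg) driven by a force produced from
the control through two cascaded first-order muscle filters
(τ₁ = τ₂ = 40 ms), discretised at Δt = 10 ms over t_end = 0.5 s
(n = 51 state epochs, 50 control epochs).  The 5-dimensional state is
[p, ṗ, f, ḟ, p*] with the target p* = 0.2 m carried as a constant fifth
state so the terminal cost can penalise p − p* through a linear form.
The sensor reports position, velocity and force.  Cost: Q_t = 0 except
the terminal Q_n = pp' + vv' + ff' with p = [1,0,0,0,−1]',
v = [0,0.2,0,0,0]', f = [0,0,0.02,0,0]'; R = r = 1e−10, so end-point
accuracy dominates and the control penalty is nearly negligible.

Noise scales (defaults): σ_c = 1.5 (control-dependent, C₁ = B σ_c) with
σ_ξ = σ_ω = σ_d = σ_η = 0 — i.e. the default configuration has
control-dependent noise only.  Observation scale constants
ω_p = 0.02, ω_v = 0.2, ω_f = 1.0 set both the D_i matrices
(D_i = σ_d ω_i e_i e_i') and Ω^ω = (σ_ω diag[ω_p, ω_v, ω_f])².
Ω^ξ = σ_ξ² I₅ and Ω^η = σ_η² I₅.  Σ_1 = 0: the initial state is known
exactly, which together with Ω^ω = 0 and D = 0 forces K_1 = 0.

With these defaults the solved movement shows the signature phenomena of
signal-dependent motor noise: a near bell-shaped speed profile whose
peak shifts relative to the noise-free mid-movement timing, positional
variability that rises to a peak past mid-movement and then falls
(feedback "cleans up" end-point error), undershoot growing with noise,
and a monotone speed–accuracy trade-off in σ_c.

## Numerical choices

- **Singular innovation moments.**  The filter-gain denominator
  H Σ^e H' + Ω^ω + Σ_i D_i (…) D_i' is exactly singular for the default
  reaching configuration (Ω^ω = 0, D = 0, Σ^e of low rank).  The gain is
  computed with a Moore–Penrose pseudoinverse, relative singular-value
  cutoff 1e−12.  The gain numerator A Σ^e H' shares its range with Σ^e,
  so the pseudoinverse gives the least-squares optimal gain on the
  observable subspace and reduces to the plain inverse when the
  denominator is regular.  Results are insensitive to cutoffs across
  [1e−14, 1e−10] (tested; the converged cost agrees to ~10 digits).
- **Linear solves, not inverses**, for the controller-gain system; the
  system matrix is symmetric positive definite whenever R is.
- **Symmetrisation** of every cost-to-go and covariance matrix after
  each update (S ← (S + S')/2) to suppress floating-point asymmetry;
  downstream traces and quadratic forms assume symmetry.
- **Covariance square roots** in the simulator via symmetric
  eigendecomposition with negative eigenvalues clipped at −1e−12
  (relative); the noise covariances are often exactly singular by design.
- **Convergence rule**: |J_k − J_{k−1}| / |J_{k−1}| < 1e−15, with
  J_{k−1} = 0 converging iff J_k = 0; `max_iter` = 500 with explicit
  non-convergence signalling.  For some intermediate control-noise
  scales (e.g. σ_c ≈ 0.2–1.0) the alternation settles into a tiny limit
  cycle with relative cost change ~4e−11 — stable to ten digits but
  never below 1e−15; sweeps record this per value rather than aborting.
- **Peak times** are located by arg-max with earliest-index
  tie-breaking; "speed" is the signed mean velocity E[ṗ] (the task is
  one-dimensional and essentially monotone, so E[ṗ], |E[ṗ]| and E[|ṗ|]
  differ negligibly away from degenerate cases).
- **Divergence guards**: the filter pass raises if Σ^e develops an
  eigenvalue below −1e−8 (relative), moment propagation raises on
  non-finite entries.

## The Monte Carlo oracle

`monte_carlo_oracle.simulate_trials` simulates the closed loop trial by
trial with a documented draw order (initial states; then per step ξ, ω,
η, the ε's, the ϵ's) from a seeded generator, and estimates the same
nine moment sequences empirically with unbiased (1/(N−1)) covariance
normalisation.  It exists purely to verify the analytic propagation;
agreement within Monte Carlo error on randomised problems is the
package's core correctness evidence.

Standard errors of empirical standard deviations are computed
distribution-free from the fourth central moment,
SE(s²) = √((m₄ − s⁴(N−3)/(N−1))/N), SE(s) = SE(s²)/(2s), rather than
with the Gaussian shortcut s/√(2(N−1)).  This matters: multiplicative
noise makes closed-loop states strongly leptokurtic (excess kurtosis of
30–70 is typical on the reaching task's force-derivative channel), and
the Gaussian formula understates the true sampling error several-fold
there.  Even the fourth-moment estimator is itself noisy on that extreme
channel at moderate trial counts, which is why the reaching-task
verification targets the position and velocity channels (moderate
kurtosis, well-calibrated SEs); the full nine-sequence comparison runs
on the randomised small-system suite, where all channels are tame.

Verification problem sizes: the reaching task is checked against 20,000
trials; a suite of 25 seeded random systems (nx ≤ 4, horizon ≤ 20, one
or two C/D scalings, random PSD noise covariances including
near-singular ones) against 50,000 trials each, all nine sequences
within four standard errors.

## What the synthetic conditions do and do not show

The random fixture suite exercises the full recursion structure —
multiplicative terms of both kinds, singular covariances, cross-moment
bookkeeping — on systems small enough for tight Monte Carlo bands, and
the reaching task exercises a realistic ill-conditioned cost
(r = 1e−10 against a rank-3 terminal cost).  Passing these shows the
moment equations are implemented exactly for linear dynamics with the
stated noise structure.  It does not say anything about nonlinear or
multi-joint biomechanics, delayed or history-dependent feedback,
non-Gaussian noise, or fitting to human kinematic data — all outside the
model class.

## Sweep grids

The σ_c grid {0, 0.2, 0.5, 1.0, 1.5, 3.0} is the standard set for this
task.  The remaining default grids are package choices (the literature
does not fix them), picked once so each noise source spans "off" to
"positional variability comparable to the control-dependent baseline"
while staying in the regime where its characteristic signature is clean:

| parameter | default grid | rationale |
|---|---|---|
| σ_d | 0, 0.1, 0.2, 0.4 | delays the speed peak and grows late-movement SD while leaving the first half nearly unchanged |
| r | 1e−10 … 1e−5 (log) | shifts the speed peak later and reshapes mid-movement SD with little end-point change |
| σ_ξ | 0, 0.002, 0.005, 0.01 | in metres of per-step position noise; 0.01 roughly triples end-point SD without touching the speed profile |
| σ_ω | 0, 0.5, 1.0 | σ_ω = 1 means position observation noise of SD ω_p = 2 cm; inflates late SD only |
| σ_η | 0, 0.002, 0.005 | estimation noise in state units; inflates late SD only |

## Known limitations

- The coordinate descent has no convergence proof; the limit-cycle
  behaviour above is reported, not repaired.
- Means and (co)variances only; higher moments (skewness, kurtosis) of
  the closed loop are not propagated, although they are demonstrably
  far from Gaussian under multiplicative noise.
- The pseudoinverse treatment of singular innovation moments is a
  regularisation choice; alternatives (e.g. observable-subspace
  projection) would differ only off the numerator's range, but this is
  verified numerically, not proven, for the shipped configurations.
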