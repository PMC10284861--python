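# Methods

## The model class

An implicit learning-to-optimize (L2O) model defines its inference as the
solution of a data-dependent optimization problem,

    N_Θ(d) = argmin_{x ∈ C_Θ(d)} f_Θ(x; d),

computed as the limit of a tunable iteration x^{k+1} = T_Θ(x^k; d).  The
iteration map is built from proximal and gradient blocks, so prior knowledge
(sparsity, measurement fidelity, pixel bounds) enters the architecture
directly, and properties of the limit are guaranteed rather than hoped for.
Convergence rests on T_Θ being *averaged*: T = (1−α)·Id + α·Q with Q
1-Lipschitz and α ∈ (0,1).  Every block we use is nonexpansive by
construction — soft-thresholding and the projections are proxes, and the
learned proximal is spectrally normalized (below) — so the composed
iterations converge on the problems in scope.

Three concrete models share this shape:

* **Sparse recovery** — `T(x) = η_θ(x − W(Ax − d))` with weights (W, θ, τ):
  a learned proximal-gradient (ISTA-like) operator.  With W = cA^T and
  θ = cτ, c < 1/‖A‖², it is exactly ISTA for the lasso, which our tests use
  as an independent oracle.
* **Implicit dictionary model (IDM)** — `argmin ‖Kx‖₁ s.t. Ax = d` with a
  learned square transform K.  If K⁻¹ exists it is a dictionary and Kx the
  sparse code.  Solved by linearized ADMM (L-ADMM).
* **CT reconstruction** — `argmin_{x∈[0,1]^n} f_Ω(Kx) s.t. ‖Ax − d‖ ≤ δ`
  with a learned proximal for the regularizer f_Ω, the Radon system matrix
  A, and the pixel box encoded as the final update, so bounds hold
  bit-exactly at any iteration count.

## Linearized ADMM

For `min f(Kx) + h(x) s.t. ‖Mx − d‖ ≤ δ` the iteration updates the tuple
(p, w, ν₁, ν₂, x), with the primal x last:

    p   <- prox_{λf}( p + λ(ν₁ + α(Kx − p)) )
    w   <- proj_{B(d,δ)}( w + λ(ν₂ + α(Mx − w)) )
    ν₁  <- ν₁ + α(Kx − p)
    ν₂  <- ν₂ + α(Mx − w)
    r   =  K^T(2ν₁⁺ − ν₁) + M^T(2ν₂⁺ − ν₂)
    x   <- prox_{βh}( x − βr )

At a fixed point the KKT conditions of the constrained problem hold
(ν₁ ∈ ∂f(p), ν₂ normal to the ball, primal stationarity via r).

**Step sizes.**  Only "appropriate step sizes" are required in principle; we
fix them by an empirical stability rule.  A bisection study on random
basis-pursuit instances located the divergence boundary at
αβ(‖K‖² + ‖M‖²) ≈ 1; the default therefore sets

    β = sqrt(0.45 / (‖K‖² + ‖M‖²)),   λ = α = 2β,

i.e. the product αβ at 0.9 of the boundary with the dual steps running at
twice the primal step.  Operator norms come from power iteration with a 1.01
safety factor.  All three scalars are overridable per problem.

**Stopping.**  The residual is the norm of the change of the *packed* tuple
(p, w, ν₁, ν₂, x), relative form `res ≤ tol·(1 + ‖state‖)`; using the full
tuple avoids premature stops when only x stalls.  Hitting the iteration cap
flags the state unconverged (the flag propagates to the convergence
certificate) rather than raising.

**Feasibility at finite iteration counts.**  The box constraint holds
bit-exactly because the x-update ends in a clamp.  The fidelity ball is
enforced with a 2% safety margin: the solver uses radius δ(1 − margin), so
the advertised constraint ‖Ax − d‖ ≤ δ holds exactly once the solve is
within margin·δ of feasibility — this is the mechanism by which the box and
fidelity certificates pass *by construction*.  For small problems a
feasibility slack of 1e-6 absolute is also verified in tests.

**Batching.**  All updates are columnwise, so independent problems sharing
(K, M) iterate in lockstep as column-stacked matrices; this is how training
batches and test sets are processed at matrix-multiply speed.

## The learned proximal

The data-driven regularizer is represented by its prox directly:
`x ↦ ½x + ½g(x)` with `g(x) = V₂ tanh(V₁x + b₁) + b₂` and both affine
layers spectrally normalized to unit norm.  g is then 1-Lipschitz and the
map is averaged with α = ½, which is what the convergence theory needs;
normalization is re-applied after every optimizer step so the certificate
survives training.  V₂ is initialized to zero, so an untrained prox is
`x ↦ x/2` — the prox of the quadratic ½‖·‖², a gentle pull toward zero.
The proximal residual ‖x − prox(x)‖ doubles as the regularization property
value: it vanishes exactly at local minima of the learned regularizer.

## Training: Jacobian-free backpropagation

Unrolled backpropagation through a fixed-point solve stores one graph per
iteration — memory linear in depth.  We instead run the fixed-point phase
with no derivative tracking and backpropagate through a *single* application
of T_Θ at the approximate fixed point (JFB).  The package ships a minimal
reverse-mode autodiff tape (`implicitl2o.autodiff`) covering exactly the
primitives appearing in one iteration (linear maps, soft-threshold, clamp,
ball projection, tanh, MSE); the derivative-graph node count is observable
via `graph_size` and is constant in the iteration count, which tests assert
directly.  The JFB update is a preconditioned gradient: it under-weights
directions in which the iteration contracts slowly, which in practice makes
IDM training favor many moderate epochs over aggressive schedules (see
limitations).

Training uses mean-squared-error loss and Adam (our own small
implementation over the parameter dict), batch shuffling from a private
seeded generator (bit-reproducible histories), an optional multiplicative
per-epoch learning-rate decay, and constraint restoration after every step
(threshold clipped at 0; spectral renormalization).  A diverging forward
solve skips the batch with a warning rather than aborting.

Defaults (the study settings never state epochs, learning rates or batch
sizes, so these are declared choices): Adam with lr 1e-3 generally; the
reduced dictionary experiment uses lr 1e-2, batch 50, and inner solves at
tolerance 1e-8 capped at 800 iterations — deeper inner solves during
training measurably lower the reachable loss floor.

## Certificates

Each property value function maps an inference to a nonnegative scalar
(sparsity count, ℓ₁ of the code Kx, relative measurement error, distance to
the box or fidelity ball, anisotropic total variation, iterate residual,
proximal residual).  Calibration evaluates a property over model inferences
on training data (or ground truths; provenance is recorded) and stores the
sorted samples; the empirical CDF counts ties inclusively,
`CDF(α) = #{αᵢ ≤ α}/N`.  Labels cut the CDF at probabilities
(p_pass, p_warn, p_fail), stored as exact rationals; the default policy is
(0.95, 0, 0.05).

**Tie handling.**  Labels are derived from the strict count
`#{αᵢ < α}/N` — "fail means worse than 95% of calibration values".  For
continuous property distributions the two counts agree almost surely; they
differ exactly for properties that hold by construction (box distance and
ball distance are identically zero), where the strict form correctly yields
a pass and the inclusive form would brand every perfect inference a
failure.  Certificates record both values, so labels remain re-derivable.

The degenerate case d = 0 makes relative measurement error undefined and is
rejected rather than given a convention.

## Synthetic data

* Dictionary instances: one hidden transform M (n×r, unit-norm Gaussian
  columns) and one measurement matrix A (m×n, N(0, 1/m) entries) per
  dataset; codes have `sparsity` uniform-support nonzeros with standard
  normal magnitudes.  Full-scale defaults n=250, r=50, m=100; the packaged
  reduced experiment uses n=60, r=12, m=24 with 500 training and 100 test
  samples.  Sparsity defaults to 5 nonzeros.  Because m ≥ r, the true
  signal is identified by its subspace: the generator makes recovery
  possible, while plain least squares still fails badly (asserted in
  tests), so structural knowledge is genuinely required.
* CT instances: random-ellipse phantoms in [0,1] (they emulate the
  piecewise-smooth, bounded structure of chest-CT phantoms, not anatomy),
  parallel-beam sinograms from an explicit sparse Radon matrix, and
  per-beam multiplicative Gaussian noise, `out = sino·(1 + ε)`,
  ε ~ N(0, level²), level 0.015.  The stated noise level is read as
  relative per-beam noise (the alternative — a fraction of the sinogram's
  dynamic range — is not used).  Geometry presets: "full"
  (128 px, 30 angles, 183 beams; 5490×16384 system) and "desk"
  (32 px, 10 angles, 47 beams) for routine runs.

What passing tests on these generators do *not* show: performance on real
chest CT (anatomical texture, beam hardening, non-Gaussian noise) or on
signals whose representation is only approximately sparse.

## Radon discretization

Exact pixel–line intersection lengths (Siddon traversal): rays are
parameterized per (angle, beam), crossing parameters with all grid lines are
merged, and each inter-crossing segment lies in exactly one pixel.  Angles
are equally spaced on [0, π); beam offsets are equally spaced across the
image diagonal (endpoints inclusive); pixels are unit squares with centers
at half-integer offsets, the image centered at the origin, flattened
row-major.  The resulting sparse matrix is deterministic for a fixed
geometry, and the adjoint (unfiltered backprojection) is its exact
transpose.  Corner beams whose rays miss the image square produce zero
rows — this is a property of diagonal-width detector coverage, not a bug.

## Numerical choices

* `sign(0) = 0` in the soft-threshold keeps it continuous.
* Sparsity counts use a scale-invariant default tolerance
  `1e-6·max(1, ‖x‖_∞)` (L-ADMM limits are approximate); the dictionary
  experiment's code-sparsity metric uses the fixed tolerance 1e-3.
* CT inference starts from clamped, intensity-rescaled backprojection; the
  rescale factor is fit by least squares in measurement space (no access to
  ground truth).  IDM starts from zero; L-ADMM auxiliaries start at their
  consistency values (p = Kx⁰, w = Mx⁰, ν = 0).
* δ for CT defaults to 0.015·‖d‖ per sinogram (discrepancy principle at the
  configured noise level); overridable.
* Power-iteration norm estimates get a 1.01 safety factor before entering
  step-size rules.
* Oracle-agreement checks run L-ADMM at tolerance 1e-8 with a 250k
  iteration cap: a minority of random basis-pursuit instances are
  near-degenerate LPs whose primal iterates converge slowly even though the
  objective converges quickly (empirically, x-error tracks ~100x the state
  residual there), and they need the deeper budget to match the LP solution
  to 1e-3.  Typical instances stop after a few thousand iterations.

## Problem sizes used by the shipped experiments

The packaged runs are deliberately reduced-scale so that the full pipeline
(generation, training, inference, certification) completes in minutes on a
single CPU: the dictionary experiment uses the n=60 reduced setting above,
and the CT certificate study runs the "desk" geometry with 50 calibration
and 50 test instances and an untrained reconstructor (the box and fidelity
certificates are by-construction properties, so training is irrelevant to
them).  The full-scale geometry (5490×16384) is exercised where cheap —
system-matrix construction and shape checks.

## Known limitations

* JFB's preconditioning under-weights slowly-contracting directions of
  L-ADMM; at the reduced scale the IDM reaches accurate signal recovery,
  but driving the learned code magnitudes below a fixed absolute threshold
  (full sparsification of Kx̂) requires far more optimization than the
  packaged budgets spend.  The experiment reports both the recovery
  fraction and the code-sparsity reduction so the effect is visible.
* Exact implicit differentiation is deliberately not provided; JFB is the
  only training path.
* Fan-beam/cone-beam geometries, filtered backprojection, and acceleration
  or restarting schemes for the solvers are out of scope.
* Learnable L-ADMM step sizes are supported as plain overridable scalars;
  they are frozen during training by default.
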