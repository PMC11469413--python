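# Methods

## The circuit

ORGaNICs ("oscillatory recurrent gated neural integrator circuits") are
rate-based recurrent circuit models with two neuron types per channel: a
principal neuron with membrane potential `y_i` and a modulator neuron with
potential `a_i`, both relative to a threshold taken to be zero.  Firing
rates are rectified power functions of the potentials: the principal
channel is carried by a complementary pair with rates `y± = ⌊±y⌋²` (only
one of the pair fires at a time; the sign of the shared potential selects
which, so `y⁺ − y⁻` recovers sign information and `y⁺ + y⁻ = y²` is the
channel's contrast energy), and the modulator rate is `a⁺ = ⌊a⌋`.

The dynamics implemented here (vectors length `n`, `⊙` elementwise):

- principal, general recurrence:
  `τy ⊙ ẏ = −y + b⊙z + (1 − a⁺) ⊙ (W_r y)`
- principal, identity recurrence (`W_r = I`, algebraically equivalent):
  `τy ⊙ ẏ = −a⁺⊙y + b⊙z`
- principal, rectified recurrence:
  `τy ⊙ ẏ = −y + b⊙z + (1 − a⁺) ⊙ (W_r ⌊y⌋)`
- modulator (shared by all variants):
  `τa ⊙ ȧ = −a + sqrt(b0²⊙σ² + W(y² ⊙ a⁺²))`

`z = W_zx x` is the input drive, `b, b0` input gains, `σ` semisaturation,
`W ≥ 0` the normalization pool, and `1 − a⁺` the recurrent gain through
which the modulators gate lateral input.  The square root's argument is
bounded below by `b0²⊙σ² > 0`, so the dynamics are globally defined.

Two conventions deserve note, both fixed once and enforced by tests:

- **Modulator exponent.**  The modulator drive uses `W(y² ⊙ a⁺²)` — the
  pool collects `(y⁺+y⁻) ⊙ a⁺²` — which is the unique convention under
  which the closed-form fixed point below is exact and the
  quadratic-eigenvalue reduction reproduces the Jacobian spectrum.
- **Rectification corner.**  `⌊·⌋` takes the one-sided value 0 at 0, and
  the differentiable cell uses subgradient 0 there.

The **rectified variant** routes the recurrent drive through the rectified
rate `⌊y⌋`, keeping lateral input nonnegative and interpretable as firing;
its modulator equation is unchanged.  This is the variant discretized for
sequence training, because (see below) it has no unstable fixed point for
positive input in the 2D analysis.

## Fixed points

For `W_r = I` the normalization fixed point is closed-form:

    a_s = sqrt(b0²⊙σ² + W(b²⊙z²)),    y_s = (b⊙z) ⊘ a_s

and when `b = b0 = const·1` the steady firing rates satisfy the divisive
normalization equation exactly: `y_s⁺ = ⌊z⌋² ⊘ (σ² + W(⌊z⌋² + ⌊−z⌋²))`.

For general `W_r` the steady state is found by an alternating scheme in
which each half-step is an exact solve:

1. given `a`: solve `(I − D(1−a⁺) W_r) y = b⊙z` (linear);
2. given `y`: the modulator steady state with `a > 0` satisfies
   `a² = b0²⊙σ² + W(y²⊙a²)`, linear in `q = a²`; solve
   `(I − W D(y²)) q = b0²⊙σ²` and take `a = √q` when `q > 0` elementwise
   (a damped one-step map is the fallback otherwise).

The iterate starts at the identity-recurrence closed form and stops when
the max-norm residual of the full right-hand side falls below `tol`.
Under the sweep constraints (max singular value of `W_r` at 1, `‖z‖ ≤ 1`)
the measured outer-iteration count at `tol = 1e−6`, `n = 50`, is 1–5
(mean ≈ 2.3) over 200 random circuits; the count includes the final
iteration at which the tolerance is met.  Non-convergence is returned as
a flagged best iterate, never silently.

In 2D (`n = 1`) every fixed point satisfies `a = b0σ/√(1 − w y²)`, which
confines `y` to `|y| < 1/√w` when `w > 0`.  The enumerator therefore scans
the scalar steady-state equation densely on that intrinsic interval
(log-refined near the endpoints, where the equation diverges), polishes
each sign change by bisection to 1e−12, dedupes, and classifies each root
by the 2×2 Jacobian (stable iff max real eigenvalue < −1e−9; `|·| < 1e−9`
is labeled marginal/None).  For `w = 0` a generous finite bracket
`|y| ≤ 10·max(|bz|, 1)/max(|1 − w_r(1 − min(b0σ, 1))|, 1e−6)` is used.
This enumeration realizes the proven 2D structure: one stable fixed point
whose sign follows the input always exists; for expansive recurrence
(`w_r > 1`) with `b0σ < 1 − 1/w_r` up to two additional fixed points of
unguaranteed stability can appear on the opposite branch; and the
rectified variant has no unstable fixed point for `z > 0` (a negative-`y`
fixed point would need `y = bz > 0`, a contradiction).

## Stability certificates

Linearizing the identity-recurrence circuit at its fixed point and
eliminating the modulator block reduces the characteristic polynomial to
a quadratic eigenvalue problem `det(λ²I + λB + K) = 0` — a coupled damped
harmonic oscillator `Iẍ + Bẋ + Kx = 0` — with

    K  = D(a_s ⊘ (τy⊙τa))                    (positive diagonal stiffness)
    B  = D(1⊘τa) + D(a_s⊘τy) − D(1⊘τa) W D(y_s²)   (damping)

The implemented Jacobian is derived analytically from the right-hand
sides (each variant has its own blocks; finite differences must agree to
1e−6 relative, which a test enforces); its spectrum coincides with the
QEP spectrum through the diagonal similarity `B̃ = D(a_s)⁻¹ B D(a_s)`,
checked as a multiset match to 1e−6 over random circuits rather than
assumed.  The certificate chain:

- `B` is a **Z-matrix** (off-diagonals ≤ 0) by construction (`W ≥ 0`).
- The regular splitting `B = M − N`, `M = B1 + B2` (positive diagonal),
  `N = B3 ≥ 0`, is **convergent**: `S = M⁻¹N` has the saturating form
  `D(t) W D(u ⊘ (v + Wu))` with `u = b²⊙z²`, `v = b0²⊙σ² > 0` and
  `0 < t < 1`, whose spectral radius is below 1 for every admissible
  parameter set and input — including the large-input limit (`z` scaled
  by 1e6), which a test exercises.
- `B` is therefore a nonsingular M-matrix, hence **Lyapunov diagonally
  stable**.  The witness is constructed, not assumed: `u = B⁻¹1`,
  `v = B⁻ᵀ1` (both elementwise positive for a nonsingular M-matrix),
  `T = D(v ⊘ u)`, and the minimum eigenvalue of `TB + BᵀT` is computed
  and reported; `witness_ok` is its positivity.

Together these certify that the normalization fixed point of the
identity-recurrence circuit is locally asymptotically stable for *all*
parameters and inputs.  The acceptance suite drives 1000 random circuits
(n = 20, pool scale varied log-uniformly over [0.1, 10]) through the full
chain; any single failure fails the build.

When `W = α·E` (all-ones pool) with scalar parameters, `B` is
diagonal-plus-rank-one (`B = cI − (α/τa)·1·(y_s²)ᵀ`, `K = kI`), and the
QEP decouples into `n` scalar quadratics: `λ² + cλ + k = 0` with
multiplicity `n − 1` and `λ² + (c − (α/τa)Σy_s²)λ + k = 0` once.  The
closed form is validated against the generic companion-form solver to
1e−8 (the exact printed expressions for this special case were not
available; the construction is verified numerically instead).

Eigenvalue conventions: stability threshold −1e−9 on the max real part;
multiset matching sorts by (Re, Im) with per-root tolerance
`tol·(1 + |λ|)`.

## Lyapunov energy

Eliminating `δa` from the linearized identity-recurrence system shows
that `δy` obeys `δÿ + B°δẏ + Kδy = 0` with `B° = ΔBΔ⁻¹`,
`Δ = D(y_s ⊘ (τy⊙a_s))`.  In the coordinate `x = Δ⁻¹δy` the damping is
exactly `B`, so the classical Lyapunov function `ẋᵀTẋ + xᵀTKx` of the
oscillator system applies, with `V̇ = −ẋᵀ(TB + BᵀT)ẋ ≤ 0`.  Pulled back
through the circuit's own equation (`τy⊙ẏ = −(a⁺⊙y − b⊙z)`), it reads

    V(y, a) = Σᵢ (tᵢ a_sᵢ²/y_sᵢ²) · [ (aᵢyᵢ − bᵢzᵢ)²
                                      + (τyᵢ/τaᵢ)·a_sᵢ·(yᵢ − y_sᵢ)² ]

a per-neuron sum of an **input-matching residual** (the instantaneously
reconstructed gated drive `a y` versus the input `b z`) and a
**normalization penalty** (deviation from the divisively-normalized
steady state), with the ratio of time constants `τy/τa` and the
steady-state modulator level setting their relative weight: since the
normalization coefficient grows like `a_s(z)` while the matching
coefficient stays fixed, weaker inputs weight input matching and stronger
inputs increasingly engage normalization.  At `n = 1` the bracket is
exactly the 2D energy
`(τy/τa)·√(b0²σ² + w b²z²)·(y − bz/√(b0²σ² + w b²z²))² + (ay − bz)²`.

The printed n-dimensional form this parsing corresponds to had lost its
radicals and exponents in transcription; the implemented form is pinned
by three requirements, all enforced as tests: it reduces to the 2D energy
at `n = 1` up to a positive constant, `V̇ ≤ 0` holds *exactly* for the
linearized flow (verified as a matrix inequality, residual ~1e−16
relative), and along the nonlinear flow started within 1% of the fixed
point `V` decays below 1e−8 of its initial value.  Because the decrease
is only semidefinite (`V̇` vanishes wherever `ẋ = 0`), strict
monotonicity is asserted for the linearized flow, and decay-to-zero for
the nonlinear flow.  Channels with `y_sᵢ = 0` (zero input drive) have no
oscillator coordinate; their terms are skipped with a warning.

## Numerical experiments

**Integration** is fixed-step explicit Euler or classical RK4.  A step
above `min(τ)/2` triggers a stiffness warning; a state norm above 1e12 or
a non-finite entry truncates the trajectory with a `diverged` flag.
Nullclines for the 2D portraits are extracted by sign-change
interpolation of the sampled vector field along both grid axes.

**Random-circuit sampler** (the exact protocol behind the published
sweeps was not available; this one is documented so the sweep is a
falsifiable stand-in): `τy, τa` log-uniform on [1, 100] ms; `b, b0, σ`
log-uniform on [0.1, 2]; `W` entries `|N(0,1)|/n` (optionally scaled);
`W_r` entries `N(0,1)/√n` rescaled so its maximum singular value equals
`smax` exactly; `z` uniform in direction with radius uniform on [0, 1].
Draws are deterministic functions of an integer seed.

**Stability sweep.**  Per trial: sample a circuit, locate a fixed point
by the alternating iteration; if it fails to converge *or* lands on an
unstable equilibrium (with expansive recurrence the circuit can have
several, and the claim under test concerns the existence of a stable
one), fall back to integrating from rest and Newton-polishing the
endpoint.  A trial counts stable only if a located, converged fixed point
has max real Jacobian eigenvalue < −1e−9; diverged and non-converged
trials count as unstable, which biases the estimate *against* the
stability claim.  At n = 20 with 1000 trials: 100% stable at smax = 1;
≈98% at smax = 2 (the handful of failures are draws whose three located
equilibria are all unstable — the dynamics orbit a limit cycle — a
behavior of this sampler's tail, reported as-is); clearly below 100% at
smax = 3.  Problem sizes (n = 20, 1000/200 trials) are the package's
standard configuration for these sweeps.

## The discrete-time cell

The trainable cell is the explicit-Euler discretization of the rectified
model with dynamic input gains: per step, `(y, a)` advance under the
rectified right-hand sides with the *current* gains, and the gains relax
toward `f(W_bx x + W_by y + W_ba a)` (and the `b0` analogue) with their
own time constants.  Open choices, fixed as follows:

- **Gain nonlinearity `f`:** logistic sigmoid, range (0, 1) — gains stay
  positive and bounded, mirroring the recurrent-gain convention `1 − a⁺`;
  swappable in principle.
- **Nonnegative pool under training:** `W = W_raw²` elementwise, so the
  square root's argument stays nonnegative whatever gradient descent does.
- **Learnable time constants:** `τ = dt + softplus(θ)`, lower-bounded by
  the step size (the discretization's stability floor).
- **Initialization:** `y, a ~ U[0, 0.1]`; gains start at `f(0) = 1/2`;
  weight matrices `N(0,1)/√fan-in`; `W_r = I` (the provably stable
  point); `τ` spread uniformly over [2, 8]·dt so units integrate at mixed
  timescales.
- **Discretization:** plain (not exponential) Euler, `dt = 1 ms` default.

The toy trainer's default step size is lr = 0.01 (plain SGD, batch 32).
The choice matters: much larger steps let gradient descent drive the
recurrent spectral norm into the strongly expansive regime faster than
the gains adapt, at which point the *forward* Euler dynamics — not the
gradients — can overflow, the stiffness failure mode flagged under
limitations below.  At the default, 2000 steps of 32-step delayed recall
complete with every gradient finite and bounded.

Gradients flow through a small reverse-mode tape written over numpy
(`organics.autodiff`), each primitive validated against central finite
differences.  Training is raw SGD — no gradient clipping, scaling,
momentum, or adaptive steps anywhere on the path — and every gradient is
checked finite at every step, since bounded naive-BPTT gradients are the
property under test.  The synthetic tasks (delayed recall of a 4-way
token over 32 noisy steps; sign of a running sum) exercise retention over
the full unroll at desk scale; they do not emulate the statistics,
length, or difficulty of image-classification benchmarks, so passing them
demonstrates the *training-stability* mechanism (finite, bounded
gradients; monotone-ish loss descent), not benchmark-level accuracy.

## Known limitations

- Global stability is certified only through the local linearization;
  for `W_r ≠ I` stability is empirical (and the 2D case exhaustive), not
  proven, and the sweep fractions depend on the documented sampler.
- The energy is a vicinity-of-fixed-point Lyapunov function; no global
  claim is made, and zero-input channels are excluded from it.
- The rectified variant's n-dimensional form is this package's
  definition (recurrent drive through `⌊y⌋`); it reproduces the
  qualitative 2D structure but was not checked against an external
  reference formulation.
- Explicit fixed-step integration can go unstable for stiff parameter
  draws if `dt` is not small relative to `min(τ)`; the integrator warns
  and flags divergence rather than adapting its step.
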