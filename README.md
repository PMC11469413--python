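# organics

A tested Python implementation of **ORGaNICs** — oscillatory recurrent
gated neural integrator circuits — a biologically plausible recurrent
cortical circuit model that implements **divisive normalization (DN)**
dynamically through recurrent gain modulation.  The package is for
computational neuroscientists and ML researchers who want to simulate the
circuit, compute and certify its fixed points, evaluate its Lyapunov
energy, reproduce its randomized stability sweeps and 2D phase portraits,
or train its discrete-time cell by naive backpropagation through time.

## The model

Each of `n` channels pairs a principal neuron `y_i` with a modulator
neuron `a_i` (membrane potentials relative to threshold).  Firing rates
are rectified powers: the principal pair fires `y± = ⌊±y⌋²`
(complementary receptive fields; `y⁺ + y⁻ = y²`), the modulator `a⁺ = ⌊a⌋`.
With input drive `z = W_zx x`, the dynamics are

    τy ⊙ ẏ = −y + b⊙z + (1 − a⁺) ⊙ (W_r y)
    τa ⊙ ȧ = −a + sqrt(b0²⊙σ² + W(y² ⊙ a⁺²))

where `W ≥ 0` is the normalization pool, `σ` the semisaturation, `b, b0`
input gains, and `1 − a⁺` the recurrent gain through which modulators
gate lateral input.  For identity recurrence (`W_r = I`) the steady state
is closed-form,

    a_s = sqrt(b0²⊙σ² + W(b²⊙z²)),    y_s = (b⊙z) ⊘ a_s ,

and when `b = b0` are uniform the steady firing rates obey the DN
equation exactly: `y_s⁺ = ⌊z⌋² ⊘ (σ² + W(⌊z⌋² + ⌊−z⌋²))`.

Three executable results sit at the core:

1. **Unconditional local stability at `W_r = I`.**  Linearization reduces
   to the quadratic eigenvalue problem `det(λ²I + λB + K) = 0` of a
   coupled damped harmonic oscillator with positive diagonal stiffness
   `K = D(a_s ⊘ (τy⊙τa))` and damping
   `B = D(1⊘τa) + D(a_s⊘τy) − D(1⊘τa) W D(y_s²)`.  `B` is a Z-matrix with
   a convergent regular splitting (`ρ(M⁻¹N) < 1`), hence a nonsingular
   M-matrix, hence Lyapunov diagonally stable (`TB + BᵀT ≻ 0` for a
   positive diagonal `T`) — for *every* admissible parameter set and
   input.  The package computes each certificate explicitly.
2. **A Lyapunov energy.**  Near the fixed point the circuit minimizes
   `V = Σᵢ cᵢ[(aᵢyᵢ − bᵢzᵢ)² + (τyᵢ/τaᵢ)a_sᵢ(yᵢ − y_sᵢ)²]`: an
   input-matching residual plus a divisive-normalization penalty per
   neuron, with stronger inputs weighting normalization more.
3. **Stability beyond identity recurrence.**  The 2D circuit is
   enumerated exhaustively (a stable fixed point with the input's sign
   always exists); high-dimensional circuits with the recurrent weights'
   maximum singular value pinned at 1 are probed by randomized sweeps and
   are stable in 100% of trials.  This stability is what lets the
   discrete-time cell train by *naive* BPTT — no gradient clipping.

## Worked example

```python
import numpy as np
from organics import (CircuitParams, analytic_fixed_point, firing_rates,
                      normalization_response, qep_matrices, splitting_certificate)

params = CircuitParams(n=3, b=1.0, b0=1.0, sigma=0.5, W=np.full((3, 3), 1/3))
z = np.array([1.0, -0.5, 0.25])

fp = analytic_fixed_point(params, z)
print(fp.y_s)                        # [ 1.206045 -0.603023  0.301511]
print(firing_rates(fp.state).y_plus) # [1.454545 0.       0.090909]
print(normalization_response(params, z)[0])  # identical: DN holds exactly

cert = splitting_certificate(qep_matrices(params, z))
print(cert.rho, cert.witness_ok)     # 0.3479001..., True
```

The steady response of the first channel, `y⁺ = 1.4545`, is its input
energy `1.0` divided by the pooled contrast energy plus semisaturation
`(0.25 + (1 + 0.25 + 0.0625)/3) = 0.6875` — divisive normalization
computed by the circuit's own dynamics (the residual of the ODEs at the
reported point is 0).  The certificate line says the damping matrix's
splitting is convergent and the diagonal Lyapunov witness checks out, so
this fixed point is provably locally asymptotically stable — as it is for
any other parameter draw.

Short narrative scripts in `examples/` cover each capability
(normalization fixed points, the certificate chain, 2D phase portraits,
energy dissipation, BPTT training, stability sweeps); each prints the
numbers it computes and what they mean.  A thin CLI mirrors them:

```bash
organics fixedpoints params.json --z-file z.csv --out fp.json
organics sweep --n 20 --n-trials 100 --smax 2.0 --seed 42
organics train-toy --task delayed-recall --n 16 --steps 2000 --seed 0
```

For example, `examples/06_stability_sweep.py` prints (seed 42, 100
trials per level):

    smax(W_r) = 1.0:  stable 100/100 (100.0%)   worst max-Re eigenvalue = -0.0076
    smax(W_r) = 2.0:  stable  99/100 ( 99.0%)   worst max-Re eigenvalue = -0.0016
    smax(W_r) = 3.0:  stable  78/100 ( 78.0%)   worst max-Re eigenvalue = +0.1017

and `examples/05_train_toy_bptt.py` trains the cell for 2000 raw-SGD
steps on 32-step delayed recall: loss 1.3865 → 0.0158, held-out accuracy
1.000, every gradient finite, gradient norms within [2.7e−2, 1.4e+1] —
no clipping anywhere.

See `docs/methods.md` for the model conventions, solver details, the
energy derivation, sampler distributions, and known limitations.

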