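# Methods

Models, assumptions, default parameters and numerical choices behind
`stsnorm`. Symbols follow the module docstrings.

## 1. Skeletal model and dynamics

**Chain.** A planar (sagittal) four-link serial chain grounded at the
ankle: shank → thigh → pelvis → HAT (head + arms + trunk), connected by
the ankle, knee, hip and lumbar joints. The feet are treated as fixed
ground; no foot segment or center-of-pressure model.

**Angle convention.** `theta[k]` is chain-relative (segment `k` against
segment `k−1`; segment 0 against the vertical), counterclockwise positive
with the subject facing +x. Increasing angle means ankle dorsiflexion,
knee extension, hip flexion and lumbar flexion. The absolute inclination
is `phi[k] = Σ_{j≤k} theta[j]`; a segment spans `L (sin φ, cos φ)`. This
single uniform convention (rather than "extension positive" at every
joint) keeps the chain equations sign-free; the default moment-arm table
encodes the matching signs, and the static moment-balance oracle in the
test suite pins the overall sign structure.

**Equation of motion.**

```
I(Θ, Θ̇) Θ̈ + H(Θ, Θ̇) + g(Θ) + Ψ(Θ, Θ̇) = T_jnt + Φ(Θ)
```

is assembled in closed Lagrangian form over the absolute angles: with
COM-lever matrix `r` (`r[i, j]` = length of segment j below COM i, COM
offset on its own segment, zero above), `A = rᵀ diag(m) r` and gravity
levers `b = m r`, the mass matrix is `M_jk = A_jk cos(φ_j − φ_k) + I_j
δ_jk`, the velocity term `Σ_k A_jk sin(φ_j − φ_k) φ̇_k²` and gravity
`−g b_j sin φ_j`. Relative-coordinate torques follow by the transpose of
the lower-triangular angle map (a reverse cumulative sum). The form is
exact for a planar serial chain and vectorizes over time.

**Joint resistance Ψ.** Ankle/knee/hip: viscous `d_k θ̇_k` (default
0.5 N·m·s/rad each). Lumbar: angle-proportional with separate
extension/flexion coefficients (default 10 N·m/rad) and a dead zone
`|θ₄| ≤ 0.0314` rad where `Ψ₄ = 0`. The piecewise lumbar law is taken as
printed and is therefore *discontinuous* at the dead-zone edges; no
continuity correction is applied.

**External forces Φ.** Only the seat (hip) reaction, applied at a point
half-way along the pelvis segment (configurable fraction), produces a
generalized torque; it enters through the position Jacobian
`∂p/∂φ_j = lever_j (cos φ_j, −sin φ_j)` and is set to zero from seat-off
onward. Foot-plate reactions act at ground-fixed points below the
grounded ankle and contribute no generalized torque; they are filtered
and carried as data.

**Anthropometry.** `defaults/body.yaml` ships literature-order
anthropometric fractions (per segment: mass, length, COM position and radius of gyration
as fractions of subject mass/height), scaled by subject height and mass
and fully overridable. These defaults are study conditions, not tuned
values.

## 2. Hill-type muscle model

Eleven muscles: TA, SOL, GAS, RF, VAS, BFL, BFS, GMAX, RA, ES carry
surface EMG; the iliopsoas (IL) is deep and has no EMG channel. Each
muscle produces `F = F_CE + F_PE` with

```
F_CE = Fmax · f_fl(l̂) · f_fv(v̂) · m̂,   m̂ ∈ [0, 1]
f_fl(l̂) = exp(−(l̂ − 1)²)
f_fv(v̂) = 1 + tanh(3 v̂)               (v̂ > 0 = shortening)
F_PE     = 0                 for l̂ < 1
         = Fmax e^{10(l̂−1)}/e⁵  for 1 ≤ l̂ ≤ 1.5
         = Fmax               for l̂ > 1.5
```

`F_PE` is continuous at `l̂ = 1.5` (the exponential reaches exactly Fmax)
but has a small jump of `Fmax e⁻⁵` at `l̂ = 1`, kept as printed. Muscle
paths use a constant-moment-arm linearization, `l = l_ref − Σ_k r_k (θ_k −
θ_ref,k)` and `v = Σ_k r_k θ̇_k`, normalized by `l_opt` and `v_max`; `l̂`
is floored at 0.1 with a warning. Joint torques are `τ_k = Σ_i r_ki F_i`.
Pennation, tendon elasticity and activation dynamics are not modeled.
`defaults/muscles.yaml` holds literature-order `Fmax`, `l_opt`, `v_max`
and signed moment arms (biarticular GAS, RF and BFL span two joints); the
reference posture is near upright standing.

At fixed kinematics the simulated torque is **affine in activation**,
`τ(t) = P(t) + G(t) m̂(t)` with `G[t, k, i] = r_ki Fmax_i f_fl f_fv`; both
the normalizer and the static-optimization baseline exploit this
precomputed basis.

## 3. Torque-matching normalization

Measured envelopes are scaled, `m̂_i = α_i e_i`, which enforces Pearson
r = 1 and preserves relative-threshold on/off timing exactly (scale
invariance). IL, lacking an envelope, uses a Gaussian hip-flexion-phase
template (center 35 %, width 12 % of motion progress) with its scale a
free bounded variable; IL is excluded from all accuracy metrics. The
objective compares per-joint torque extrema over the 3-s window:

```
Z(α) = ‖T_max − τ_max(α)‖² + ‖T_min − τ_min(α)‖²
```

subject to `0 < α_i ≤ 1 / max_t e_i(t)` (activation bound). With 11
unknowns and 8 extremum equations the problem can be under-determined; a
tiny regularizer `ε ‖α − 1‖²` (ε = 1e-6) makes the reported scales
reproducible without moving the optimum appreciably. The solver is a
deterministic multi-start bounded Powell search: a fixed lattice of
fractions (0.1, 0.3, 0.6, 0.9) of the per-muscle upper bounds, the unit
vector, and six seeded log-uniform draws; best final Z wins, ties broken
by smaller ‖α‖.

**Static-optimization baseline.** Per time step, minimize `Σ_i m_i²`
subject to `G(t) m = T(t) − P(t)`, `0 ≤ m ≤ 1` (SLSQP; infeasible steps
fall back to bounded least squares and are flagged). Because SO
redistributes effort at every step, its activations correlate imperfectly
with the envelopes (mean r ≈ 0.8 on synthetic trials), which is the
qualitative advantage of the scaling method.

## 4. Preprocessing

EMG: 40–400 Hz zero-lag 4th-order Butterworth band-pass → full-wave
rectification → 4 Hz low-pass, clipped at zero. Pre-enveloped recordings
(`emg_domain: envelope`, used by the synthetic generator, whose raw
interference-pattern synthesis is out of scope) skip the band-pass and
rectification and receive only the 4 Hz smoothing. Forces: 20 Hz zero-lag
low-pass. Seat-off: first sample of the *filtered* hip vertical force
below 10 N, requiring a ≥ 0.2 s loaded prefix. Trials are the 3-s window
from 1 s before to 2 s after seat-off, resampled to a common 100 Hz base
(301 samples) and a 101-point 0–100 % motion-progress grid.

## 5. Synergy analysis and longitudinal statistics

NNMF uses hand-rolled Lee–Seung multiplicative updates (Frobenius
objective; per-iteration error trace is monotone non-increasing, asserted
in tests), 20 seeded restarts, up to 2000 iterations, relative tolerance
1e-6, best final error wins. W columns are normalized to unit maximum
with the scale absorbed into C. Reconstruction quality is the global
variance accounted for, `100 (1 − ‖M − WC‖²_F / ‖M‖²_F)`, with 90 % as
the adequacy threshold; sit-to-stand data are well described by N = 4
synergies (body flexion, hip raise, body extension, posture control).
Extracted synergies are aligned across trials by greedy cosine-similarity
matching to phase templates dominated by RA, TA, VAS+ES and SOL
respectively. Feature distributions (per-trial maximum muscle tension,
synergy peak level) grouped by measurement day are compared with the
two-sided Wilcoxon rank-sum test (two days) or Kruskal–Wallis (three or
more); percent change uses per-day means of per-trial values
(significance flags: p < 0.001 for tensions, p < 0.05 for synergy peaks).

## 6. Synthetic generator: realism and limits

The generator produces fully self-consistent trials with known ground
truth. Joint trajectories are minimum-jerk quintics from a sitting to a
standing posture (closed-form derivatives; the lumbar joint adds a C²
flexion-then-extension excursion peaking before seat-off). Activations
follow the four-synergy model with Gaussian temporal bumps (centers
15/35/60/85 %, widths 8/8/10/10 %), clipped to [0, 1]; envelopes are exact
positive rescalings `e = m̂*/α*` with optional multiplicative Gaussian
noise (scale-invariant, matching the estimand). The seat force unloads
along a quintic ramp crossing the 10 N threshold exactly at the
configured seat-off; feet carry the quasi-static remainder of body
weight.

Known limits, by design:

* Reaction forces satisfy *quasi-static* vertical balance only, not full
  dynamic consistency; inverse-dynamics torques from generated streams
  therefore differ from the Hill-model target torques (honest non-zero
  %RE in the end-to-end pipeline). Exact dynamic consistency is enforced
  only in the dedicated forward–inverse property test, which bypasses the
  generator.
* `torques_target` is defined as the forward Hill-model torque at the
  true activations, making the normalization problem exactly
  self-consistent (Z < 1e-10 at α = α*); it is *not* the inverse-dynamics
  torque of the generated streams.
* Activation clipping at 1 bounds the regime where synergy amplitude
  growth maps linearly onto extracted peak levels; longitudinal power
  tests use amplitudes small enough to stay unclipped.
* EMG is emitted in the envelope domain; raw interference patterns are
  not synthesized.

## 7. Numerical choices

* **Differentiation of measured angles:** second-order central
  differences after an optional 5-sample moving average (the default in
  the pipeline), trading a little bias for noise suppression in Θ̈.
* **Forward re-integration check:** the sit-to-stand chain with small
  damping is an unstable inverted multi-pendulum (local exponential
  divergence rate ≈ 15 s⁻¹), so over 3 s roundoff alone is amplified by
  ≈ e⁴⁵ and *no* integrator can track the inverse-dynamics trajectory;
  additionally the lumbar dead zone makes the torque series discontinuous
  at dead-zone crossings, which spline interpolation of sampled torques
  cannot represent. The dynamics-residual test therefore runs on a
  well-damped configuration (30 N·m·s/rad at ankle/knee/hip, 200 N·m/rad
  lumbar) with a smooth trajectory whose lumbar angle stays above the
  dead zone; the same equations then re-integrate to ≈ 3e-9 rad over 3 s
  (bound: 1e-3). RK45 with rtol 1e-9 / atol 1e-11 and cubic-spline
  torque/force interpolants.
* **Optimizer determinism:** all random starts (normalizer) and restarts
  (NNMF) flow from explicit seeds; synthetic per-trial seeds derive from
  `SeedSequence([seed, day, trial])` reduced below 2³¹.
* **Filtering:** `scipy.signal.butter` + `sosfiltfilt` (zero-lag,
  numerically robust second-order sections).
* **I/O:** floats serialized with 12 significant digits — lossless at
  analysis precision — and locale-independent parsing.
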