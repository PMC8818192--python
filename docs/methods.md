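# Methods

## The kinetic model

`hepakin` implements the dual-input, reversible two-tissue-compartment
model of hepatic ¹⁸F-FDG kinetics. The liver is supplied by both the
hepatic artery and the portal vein, so the effective blood input is the
perfusion-weighted mixture

    C_B(t) = HPI · A(t) + (1 − HPI) · P(t),

where `A` and `P` are the arterial and portal-vein activity curves and
`HPI ∈ [0, 1]` is the hepatic arterial perfusion index. Tracer exchanges
between blood and a free-tracer pool (k1 in ml/min/ml in, k2 in 1/min
out), is phosphorylated into a trapped pool (k3) and dephosphorylated
back (k4 > 0: hepatocytes express glucose-6-phosphatase, so the model is
reversible). The tissue curve is the convolution

    C_T(t) = K1/(α2−α1) · [(k3+k4−α1) e^{−α1 t} + (α2−k3−k4) e^{−α2 t}] ⊗ C_B(t)

with macro rates `α1 ≤ α2`, the roots of `x² − (k2+k3+k4)x + k2k4 = 0`.
For non-negative rates the discriminant is `≥ (k2−k4)² ≥ 0`, so the roots
are always real. The model has no fractional-blood-volume or spillover
term; the estimated vector is exactly `(k1, k2, k3, k4, HPI)`.

Assumptions: rates are constant over the 5-minute acquisition
(steady-state kinetics); the measured tissue value is the frame-duration
*average* of `C_T` (PET frames integrate activity), not a midpoint
sample; ROI extraction details (SUVmax vs mean) are upstream of this
package — the model predicts a concentration-scale curve and the data
are taken at face value in SUV units.

## Numerical implementation

* Rates are per minute; time grids are in seconds, converted at the model
  boundary. The dense grid is uniform with Δt = 0.1 s over the 300 s scan
  — two decades below the fastest plausible time constant (~20 s at
  3/min).
* The convolution is the trapezoid rule, computed per exponential mode by
  the algebraically identical one-pole recursion
  `y[n] = E·y[n−1] + Δt/2·(x[n] + E·x[n−1])`, `E = e^{−αΔt}` (O(n) per
  mode). A startup correction keeps `y[0] = 0` when the input does not
  start at zero. Against a stiff ODE integration of the underlying
  two-compartment system, the analytic path agrees to ~1e-5 relative.
* When `α2 − α1 < 1e−9`/min (repeated root, e.g. k3 = 0 with k2 = k4)
  the singular `1/(α2−α1)` form is replaced by its analytic limit
  `K1·[1 + (k3+k4−α)t]e^{−αt}`, whose `t e^{−αt}` term is convolved via
  `(r e^{−αr}) ⊗ x = t·(e ⊗ x) − e ⊗ (t x)`.
* Frame values are curve averages over `[start, start+duration]`,
  computed from the cumulative trapezoid integral (exact for the
  piecewise-linear stored curve).

## Synthetic cohorts

The generator emulates 5-minute dynamic liver studies on the 16-frame
schedule (12 × 5 s + 4 × 60 s):

* **Arterial input** — an idealized bolus: power-law rise `(t/t_p)²` to
  its single peak (default 20 SUV at 25 s), then a bi-exponential washout
  (2.0/min fast, 0.01/min slow, slow fraction 0.2). This is a compact
  Feng-style surrogate chosen so the peak location and amplitude
  linearity are exact by construction. Per-subject amplitudes are
  jittered log-normally (σ = 0.1).
* **Portal-vein input** — the arterial curve convolved with the unit-area
  dispersion kernel `k e^{−kt}` (default k = 1.5/min, i.e. a ~40 s gut
  transit), the standard liver-model device. The kernel filter is
  discretised with an exponential integrator (piecewise-linear input,
  exact kernel integrals) so it remains well-behaved in the stiff
  delta-kernel limit.
* **Groups** — subjects are drawn from truncated normal distributions per
  parameter. The default anchors place the HCC group at
  (0.651, 0.592, 0.137, 0.064, 0.667) and background liver at
  (0.628, 0.620, 0.075, 0.090, 0.310): the tumour group has higher
  transport (k1), phosphorylation (k3) and arterial fraction (HPI) and
  lower dephosphorylation (k4), and background liver is predominantly
  portal-fed — the clinically expected pattern at clinically plausible
  scales. Draws are truncated to the fitters' search bounds.
* **Noise** — per-frame zero-mean Gaussian with
  `sd = noise_level · value / sqrt(duration / 5 s)`, so 60 s frames are
  √12 ≈ 3.5× less noisy than 5 s frames (count-integration scaling).
  The default `noise_level = 0.05` (5% on short frames) is a realistic
  scale for SUVmax-derived TACs; it is a free modelling knob, not a
  measured value. No Poisson/count or reconstruction simulation is
  attempted, and there is no motion, partial-volume or spillover effect:
  passing tests demonstrate correctness of the estimation chain under
  this idealized noise model, not robustness to real scanner physics.

## Fitters

All three fitters minimise the sum of squared per-frame residuals over
`(k1, k2, k3, k4, HPI)` within box bounds (defaults: k1, k2 ∈ [0, 3],
k3 ∈ [0, 1], k4 ∈ [0, 0.5], HPI ∈ [0, 1]; HPI is a free fifth dimension).

**NLLS** — bounded trust-region least squares (`scipy.optimize
.least_squares`, `trf`), by default restarted from 10 uniform draws;
a single start reproduces the classic initial-value sensitivity.

**GSA** — a population of N candidate vectors carries fitness-derived
masses (best = 1, worst = 0, normalized to sum 1; uniform masses when all
fitness values tie). Each particle is pulled toward the `Kbest` fittest
particles with force `G(t)·M_i M_j/(R_ij+ε)·(x_j − x_i)`, acceleration
`F/M_i` (the `M_i` factors cancel analytically, which also defines the
zero-mass worst particle's motion — the ε-substitution limit), velocity
`v ← rand·v + a` and position `x ← x + v`. `G(t) = G0 e^{−αt/T}` with
the classic defaults G0 = 100, α = 20; Kbest shrinks linearly from N to
1; positions are clipped to bounds with the violating velocity component
zeroed. One random force weight is drawn per (i, j) pair per iteration
(per-dimension draws are available as an option), and the velocity's
random factor is drawn per particle, following the update equations'
indexing.

**DCGSA** — two modifications aimed at slowing premature convergence:
a *dynamic* gravitational constant
`G′(t) = G0 exp(−α_dyn (t/T^{1.5})(rand_t + t/T))` with `rand_t`
uniform(0,1) drawn once per iteration, and a velocity/position update
`v ← W(t)·v + a`, `x ← x + v·c(i)` with the linearly decaying inertia
weight `W(t) = ω_max − (ω_max−ω_min)t/T` (ω_max = 0.7, ω_min = 0.1) and
a per-particle chaotic factor `c(i)` from the logistic map
`x ← 4x(1−x)` (one independent stream per particle, advanced once per
iteration; seeds are drawn away from the map's degenerate orbits at
0, 0.25, 0.5, 0.75, 1).

Because the dynamic exponent is bounded by `α_dyn(1 + t/T)/√T`, the two
schedules' decay constants live on different scales: with a single α the
dynamic constant would stay within a factor ~e² of G0 over the whole run
and the algorithm would never enter its intended small-step phase.
`α_dyn` therefore defaults to `(2/3)·α·√T`, which equates the *expected*
total decay of the dynamic schedule at t = T with the classic one
(`E[rand_t + 1] = 3/2`) while keeping G′ larger than G early (more
exploration) and randomly fluctuating throughout (escape kicks) — the
behaviour the schedule is designed to produce. Both α and α_dyn are
configurable.

Determinism: a fixed config seed makes GSA/DCGSA runs bit-identical;
NLLS is deterministic given its starts.

## Evaluation layer

* **AIC/BIC** use the Gaussian least-squares forms
  `AIC = n ln(RSS/n) + 2p`, `BIC = n ln(RSS/n) + p ln n` with n = 16
  frames and p = 5 free parameters; additive constants are dropped since
  only within-data comparisons are meaningful.
* **Group comparison** is the two-sided pooled-variance Student's t-test
  (Welch available as an option).
* **ROC analysis** reports the empirical (Mann–Whitney, ties = ½) AUC
  with a DeLong-variance Wald CI; scores are oriented so the reported
  AUC ≥ 0.5, with the direction recorded (some parameters are *lower* in
  tumours). Correlated AUCs from different fitters on the same subjects
  are compared with the DeLong test (implemented here; verified against
  R's `pROC::roc.test` to ~1e-10).

## Statistical simulation sizes

The package's own calibration experiments use scaled-down designs chosen
to estimate each property with adequate precision: null-pipeline type-I
error over 200 cohorts of 8 subjects per group at 5% noise with
single-start NLLS (the t-test's null calibration is estimator-agnostic —
both groups share one generating distribution); directional power over
50 cohorts of 20 per group with 3-start NLLS in the noise-free limit,
which isolates the generate→fit→test chain's directional correctness
from estimator noise; and repeat-fit variance over 50 seeds per method
on one fixed noisy TAC.

## Known limitations

* **Identifiability is sloppy.** With 16 frames over 5 minutes the
  five-parameter model is a strongly correlated valley: profile analysis
  on a noiseless default-cohort subject shows that holding k1 5% off its
  true value and refitting the rest leaves a residual SSE of only
  ~3.5e-5 (k3: ~3e-7) against frame values of order 1–6. Consequently
  even small measurement noise moves the *global* least-squares optimum
  far along the k3/k4 exchange direction, and group-level k3 inference
  degrades quickly with noise.
* **Swarm fitters do not reach the valley floor.** GSA and DCGSA contract
  onto a single point (inter-particle forces vanish as the swarm
  coincides) before traversing the flat valley, stalling at SSE
  ~1e-2–1e-3 where multi-start NLLS reaches ~1e-25. The same mechanism
  limits them on the 2-D Rosenbrock function (final distance to the
  optimum typically 0.01–0.25; DCGSA's median ≈ 0.055 is about 2.5×
  better than GSA's ≈ 0.146, consistent with its design goal). This is
  the canonical behaviour of gravitational search — it has no elitist
  re-injection — and is why the swarm fitters' strength on this problem
  is *consistency* (tight repeat-fit spread) rather than verified
  pointwise accuracy.
* The synthetic cohort inherits every idealization listed above; results
  on it bound what the code does under the stated model, not what any
  estimator would do on patient data.
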