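# Methods

This note documents the models, estimators and design choices behind
`gaitrisk`, in the spirit of a statistical package's methods appendix: what
is computed, under which assumptions, with which defaults, and what the
shipped synthetic data can and cannot tell you.

## 1. The metastable walker as an absorbing Markov chain

A perturbed walking system is reduced to a discrete-time Markov chain over
start-of-step states. The chain is built in two stages:

1. **Deterministic mesh.** For every discretized start-of-step state and
   every perturbation on a uniform grid (−0.200 … +0.200 m/s, 0.002 m/s
   spacing, 201 values — the perturbation is a horizontal impulsive push
   expressed as a velocity change), one step is simulated and the end state
   recorded, snapped to the nearest grid state (ties to the lower sorted
   index; non-failed states beyond the grid edge snap to the boundary
   state). When several perturbations give the same (start, end) pair, the
   trajectory stored for that transition is the one for the median
   perturbation (lower middle for an even count). A step fails when the
   post-step state leaves the failure band; failure is absorbing.
2. **Stochastic weighting.** Perturbations are N(0, 0.013²) m/s. Each grid
   value receives the Gaussian probability mass of its half-open grid cell
   (cell edges at midpoints between grid values; the two boundary cells
   absorb the tails, so masses sum to exactly one — no renormalization
   fudge). `Q[i, j]` sums the masses of perturbations sending state *i* to
   state *j*; `R[i]` sums the failing ones.

**First-passage statistics.** `λ₂` is the largest-modulus eigenvalue of
`Q` (complex values enter by modulus), and `mfpt_eigen = −1/log λ₂`. The
fundamental matrix `N = (I − Q)⁻¹` is obtained by a dense linear solve
(never an explicit inverse); its first row `n₁ᵢ` holds the expected visits
to each state starting from the nominal step, and `mfpt_exact = Σᵢ n₁ᵢ`,
which counts the absorbing step itself (a single state with survival *p*
gives exactly 1/(1−p)). Both estimates are always reported; downstream
code uses the eigenvalue form as the "true MFPT" and falls back to the
exact form when the eigenvalue is numerically unresolvable (see §7).

## 2. The synthetic walker

No external gait data is used; every analysis runs on data from a synthetic
walker designed to have the statistical structure the pipeline assumes.

**Step-to-step dynamics.** A 1-D affine-plus-saturation return map

    x⁺ = x* + c·tanh((a (x − x*) + b s) / c)

with contraction *a*, input gain *b* (scaled by the perturbation-timing
condition), fixed point *x**, saturation scale *c* = 0.25 m/s and failure
when |x⁺| exceeds the failure boundary. Under Gaussian perturbations this
is an AR(1)-like process with stationary spread σₓ ≈ b·0.013/√(1−a²) and a
fall probability per step controlled by the boundary-to-spread ratio; the
MFPT consequently spans many orders of magnitude across presets.

**Perturbation timing.** Three conditions (`DS0`, `SS0`, `SS0.5`: a push at
the start of double support, at the start of single support, or halfway
through single support) scale the input gain (1.0 / 0.92 / 0.82 — a later
push has less of the step left to act on) and phase-shift the
perturbation-driven waveform deformation toward the end of the step.

**Within-step trajectories.** Each step is 100 samples of 28 channels: six
joint angles and the hip position (q₁…q₈), their velocities, the stance
contact point, the normal ground reaction force, the ankle force and
torque, and the foot geometry points. Channels are parametric template
waveforms linearly modulated by the start state and the perturbation, with
per-walker "style" multipliers (template amplitudes and deformation gains
drawn deterministically from the preset seed) so that distinct walkers
have distinct waveforms, the way distinct gaits do. Step duration and
length respond linearly to state and perturbation; speed is their ratio.
The kinetic channels are mutually consistent only where the metrics
require it: the foot is treated as massless (`F_g = 0`) and the vertical
ankle force balances the normal force, which makes the foot rotation index
behave exactly like a center of pressure and renders it invariant to
horizontal translation. They are *not* the output of rigid-body dynamics.

**What the generator does not emulate.** Multi-dimensional state spaces,
kinematic/kinetic consistency (velocities are not exact derivatives of the
deformed positions), double-support mechanics, and any feedback control.
Passing tests therefore demonstrate the correctness of the *estimators*
(chain construction, weighted statistics, divergence slopes, model
selection) on data with realistic statistical structure — not fidelity to
any particular biped.

**The preset bank.** 20 training and 6 validation presets plus a fragile
cross-check walker. Presets vary along four axes: contraction
(0.30 … 0.97, setting the observable noise amplitude), failure boundary
(0.0665 … 0.076 m/s, ±5% — deliberately *invisible* to the per-step
metrics, so any metric-based fall-risk model carries an irreducible
residual, as it does for real walkers whose basin geometry is not
observable from steady gait), a small fixed-point offset (±0.004 … ±0.012
m/s, shifting the mean metrics between walkers), and the waveform style
seed. Nominal gait scale is common to all presets (step duration 1 s, step
length 1 m, leg 1.16 m, mass 86.7 kg, g = 9.81 m/s²): the bank isolates
stability differences at a matched nominal gait. Across presets and
timings the MFPT runs from ~10 to ~10¹² steps (≈9 orders within the
training bank); per-step fall probabilities below ~10⁻¹³ would be
unresolvable in double precision and are avoided by design.

Per-step spatiotemporal variability (duration sensitivity 0.5 s per m/s of
state, ~1–3% per-step SD) and the small between-preset offsets were chosen
together so that segment estimates of the mean metrics need a few hundred
steps to converge to the chain values at the 0.5-normalized-unit level —
the regime reported for spatiotemporal SDs in comparable studies — while
50-step segments already estimate the SD-type metrics usably.

## 3. Metrics

All 49 metrics and their conventions:

* **XCoM / FRI (4).** Per-sample XCoM = (x₇ − x_st) + ẋ₇·√(ℓ/g) with ℓ the
  hip-to-contact distance; per-sample FRI = ([OG×F_g − OA×F_a]_z − τ_a)/F_n
  − x_st (moment balance about the origin; F_n must be positive). The
  per-step maximum is taken, then mean and sample SD over steps. The FRI
  expression is typographically ambiguous in the literature regarding the
  grouping of the division and the −x_st term; the moment-balance form
  above is used, which reduces to the center of pressure for a foot in
  static equilibrium.
* **Spatiotemporal (6).** Mean and sample SD of speed, step length, step
  duration.
* **Lyapunov exponents (24).** Per coordinate (q₁…q₆ and velocities), the
  concatenated 100-sample steps form one series; a 5-dimensional delay
  embedding with delay τ = 15 samples is built; each point's nearest
  neighbour outside a ±50-sample exclusion window is found (Euclidean
  distance, exact ties to the smaller index, search across step
  boundaries); the mean log divergence y(i) = (1/Δt)⟨ln d_j(i)⟩ is
  averaged over all pairs still inside the series at lag *i*, with
  distances floored at 10⁻⁷; λ_S and λ_L are least-squares slopes over
  i ∈ [1, 200] (0–1 strides) and i ∈ [801, 2000] (4–10 strides). Δt
  defaults to 0.01 stride-normalized units, so exponents are per
  (0.01-stride); because every step is resampled to 100 points, temporal
  information about duration variability is removed, and the absolute
  scale of the exponents is not comparable to wall-clock-sampled values.
  At least 50 steps are required; with fewer, the entries are flagged
  missing.
* **Joint variability (15).** For q₁…q₆, q₈ and all eight velocities
  (horizontal hip position excluded — the walker moves forward, so it is
  not cyclic): the sample SD across steps at each of the 100 time points,
  floored at 10⁻⁷ before the log (perfectly periodic gaits otherwise give
  −∞), logged, and averaged over the step.

Sample SDs use the n−1 convention everywhere a plain SD over steps or
segments is taken. Normalization records (per-metric center and scale) are
fitted on the chain metrics of the training conditions — scale is the
sample SD across conditions; zero-variance metrics get scale 1 with a
warning — and the same frozen record is applied to brute-force metrics.

## 4. Chain-side metric estimation

For a step-level quantity ρᵢⱼ (its value on the stored trajectory of
transition i→j), per-state probability-weighted moments

    μᵢ = Σⱼ P(sᵢⱼ) ρᵢⱼ / Σⱼ P(sᵢⱼ),   σᵢ² = Σⱼ P(sᵢⱼ)(ρᵢⱼ − μᵢ)² / Σⱼ P(sᵢⱼ)

run over *surviving* transitions only (a falling walker completes no step;
the failing mass is excluded from numerator and denominator, and a state
with no surviving mass is excluded with a warning). The overall moments
pool per-state moments with the expected visit counts as frequency
weights:

    μ = Σᵢ n₁ᵢ μᵢ / Σᵢ n₁ᵢ,   σ² = Σᵢ n₁ᵢ(σᵢ² + (μᵢ − μ)²) / Σᵢ n₁ᵢ

— the exact mean/variance of the visit-weighted mixture (law of total
variance), verified against full enumeration on small chains. Max-per-step
quantities (XCoM, FRI) use the step maximum as ρᵢⱼ. Joint variability runs
the same two-stage machinery per time point (ρᵢⱼ is the 100-sample
coordinate vector), then logs and time-averages the pooled σ(t), mirroring
the brute-force definition.

**Chain-sampled Lyapunov exponents.** Sequences are required, so from each
of the 20 most-visited states (largest n₁ᵢ), 20 random 50-step
trajectories are sampled through the chain (400 total), each appending the
stored median-perturbation trajectories of the realized transitions.
Divergence slopes are computed per trajectory with the 10⁻⁷ distance floor
(chain trajectories can repeat a step exactly, giving zero distances), and
averaged with weights n₁ᵢ·(1/20), normalized to sum to one. A trajectory
absorbed before 50 steps is redrawn up to 5 times, then dropped with the
weights renormalized and a warning. Tests use reduced trajectory counts
(6 start states × 2–3 vectors); the estimator is the same.

The short-term exponents estimated this way do **not** agree with
brute-force values (the mesh discretization maps a range of true
trajectories onto one stored transition and introduces step-boundary
discontinuities that dominate the 0–1-stride divergence); the long-term
exponents, integrating over 4–10 strides, do agree. The test suite asserts
precisely this asymmetry; no attempt is made to rescue short-term
agreement by refining the discretization.

## 5. Validating the chain metrics and the convergence law

**Agreement study.** For each preset, brute-force trials (a fresh
perturbation drawn every step; trials extended until 200 disjoint 50-step
segments exist) give 200 values per metric; the chain value "matches" when
it lies within one sample SD of that distribution's mean. Matches are
pooled over presets and non-Lyapunov metrics, with per-type aggregates
(coordinates combined for variability and Lyapunov metrics): % match,
median absolute normalized error, median brute SD. The study uses the
eight presets with contraction 0.30–0.84: beyond that, the step-to-step
correlation length (1+a)/(1−a) approaches the 50-step segment length, and
the brute-force segment statistics are themselves biased (the sample SD of
strongly correlated steps under-estimates the marginal SD) — the 1-SD
criterion then measures segment-length artifacts, not chain accuracy. The
model pipeline still uses all presets.

**Convergence.** Trials are cut into disjoint n-step segments for
n ∈ {10, 20, …, 100, 200, 300, 500, 1000} (segments never span a fall;
remainders are discarded), and the percentage of (segment, metric) errors
below 0.1 and 0.5 normalized units — pooled over presets and the six
spatiotemporal metrics — is fitted with p = α₁ ln n + α₀. The
steps-to-90% estimate is exp((90 − α₀)/α₁), rounded up and floored at 10;
a non-positive slope reports "unattainable", and estimates beyond 10× the
largest observed n are flagged as extrapolated. All 14 grid points enter
the fit with equal weight; plateauing metrics show up as reduced R² rather
than being special-cased.

## 6. Fall-risk models

The target is y = ln MFPT (raw MFPTs span too many orders of magnitude to
regress on).

**Individual models.** ŷ = β₀ + β₁ρ + β₂ρ² per metric, ordinary least
squares, at least 4 conditions, rank-deficiency (constant metric) is an
error. Higher polynomial orders amplify metric noise and are deliberately
not offered.

**Combined models.** Metrics are normalized, projected onto the first 15
principal components (SVD; components ordered by explained variance; sign
fixed so the largest-magnitude loading is positive; the transform is
frozen after fitting and reused for brute-force inputs), and a quadratic
form in the scores (30 candidate terms: each score and its square, no
interactions) is selected by consensus stepwise regression:

* 10 repetitions, each removing 3 whole condition groups (whole walker
  presets in the shipped study) at random;
* bidirectional stepwise per repetition: the forward step admits the best
  candidate only if its p-value survives a Bonferroni correction over the
  scanned candidates (best-of-30 selection would otherwise admit a noise
  term in most null datasets); the backward step drops terms with p > 0.10;
* terms selected in ≥ 3 repetitions are pooled and a final stepwise pass
  over the pool (on the full data) fixes the model. Everything is
  deterministic given the seed.

Two variants: `no_lyap` (25 metrics) and `with_lyap` (25 + the 12
long-term exponents). Short-term exponents enter neither — they are not
reliably computable from the chain (§4).

**Goodness of fit.** RMSE, MAE, MAPE (y = 0 cases excluded with a count),
RAAE = mean |error| / SD of the *predictions*, maximum absolute error, the
percentage of predictions within ±3.3 on ln MFPT (10% of the designed
log-range; recomputable from any dataset's own range), the calibration
line ŷ = α₁y + α₀ with its R² (written Re²), and the mean over conditions
of the within-condition error SD (the trial-to-trial precision).

In the shipped study the training bank (60 conditions) yields an adjusted
R² around 0.94 with 3–6 selected terms; on 300-step segments of the 18
held-out validation conditions the calibration slope is near 1 and Re²
around 0.7, with MAE decreasing and the within-tolerance share increasing
monotonically as segments grow from 30 to 1000 steps. (These figures are
recomputed, not stored: run `scripts/acceptance.py`.)

## 7. Numerical choices and degenerate inputs

* **Snapping ties** go to the lower sorted grid index; the mirror symmetry
  of a symmetric walker is preserved to machine precision away from exact
  cell midpoints.
* **λ₂ at the precision limit.** For extremely metastable chains the true
  λ₂ is 1 − O(10⁻¹³) and eigensolver round-off can report ≥ 1. The chain is
  rejected as non-absorbing only when λ₂ > 1 + 10⁻⁸ or the failure column
  is exactly zero; otherwise the eigenvalue MFPT is reported as NaN and
  consumers fall back to the fundamental-matrix value.
* **Distance/SD floor** 10⁻⁷ before every log (divergence curves, joint
  variability) keeps perfectly periodic synthetic gaits finite.
* **Nearest-neighbour ties** break toward the smaller index; the search
  spans the whole embedded series, including across step boundaries (the
  exclusion window is what guarantees neighbours come from different
  steps).
* **"Exactly zero" SDs** of identical synthetic steps hold only to float
  summation round-off (~10⁻¹⁶).
* **Brute steps-to-fall** counts the failing step: completed steps + 1,
  matching the fundamental-matrix convention.
* Serialization: HDF5 for array containers (mesh, chain, trials), JSON for
  models/normalizations/manifests, CSV at 17 significant digits (exact
  double round-trip) for metric tables; every container carries a schema
  tag and unknown schemas raise instead of migrating silently.

## 8. Problem sizes used by the tests and the acceptance script

Chain construction and non-Lyapunov chain metrics run at full size (41
states × 201 perturbations; 60 training conditions). The agreement study
uses the full 200 × 50-step design on 8 presets. Lyapunov comparisons use
reduced trajectory counts (6 × 2–3 chain trajectories, 15–30 brute
segments) — the estimator is identical, only the averaging is lighter.
Held-out model evaluation uses 10 segments per condition per segment
length. The full test suite runs in a few minutes; the acceptance script
in about one.

## 9. Known limitations

* The walker state is 1-D; multi-dimensional basins, which the source
  style of analysis supports in principle, are not implemented.
* Lyapunov magnitudes are in resampled, stride-normalized units and not
  comparable to wall-clock literature values.
* The kinetic channels are template-based; FRI behaves like a center of
  pressure only because the generator enforces the vertical force balance.
* The boundary axis of the preset bank fixes the achievable model accuracy
  by construction; with a different unobservable-axis spread the held-out
  Re² would shift accordingly.
* Consensus stepwise controls, but cannot eliminate, selection of
  walker-identity (style) directions when the training bank is small;
  banks below ~15 presets noticeably degrade held-out calibration.
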