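# Methods

## The model

`neuroipc` treats a single brain region as an information-processing unit
with two capacities: a **processing capacity** `p` (bit/s), the maximal rate
at which the region can process arriving information, and an **input storage
capacity** `m` (bits), the amount of input it can hold while waiting to be
processed. Writing `I(t)` for the cumulative information delivered to the
region, `I_p(t)` for the part already processed and `I_m(t)` for the part
still in storage, a lossless region satisfies the conservation identity
`I = I_p + I_m` at every instant; a lossy region retains only a fraction
`c ∈ [0, 1]`, giving `c·I = I_p + I_m`.

The measurable neuronal activity `x(t)` (in practice: the region-averaged
BOLD-derived response) is assumed proportional both to the current processing
rate (`x = H_p / p`, where `H_p = dI_p/dt`) and to the stored amount
(`x = I_m / m`). Differentiating the conservation identity under these two
definitions yields a first-order linear ODE:

    dx/dt = −(p/m)·x(t) + (c/m)·H(t),        H(t) = dI/dt,

with decay rate `k = p/m` and time constant `T_c = m/p` — formally an RC
circuit with resistance `m` and capacitance `1/p`. An impulse delivery of
`α` bits (`H = α·δ(t)`) produces an instantaneous jump to `x(0) = α/m`
followed by exponential decay — the phasic onset response. The same equation
re-parameterized as `dx/dt = −σx + βe(t)` is the single-region dynamic
causal model; the mapping is `σ = p/m`, `β = c/m` (`dynamics.sdcm_map`).

Assumptions worth keeping in mind:

- **Adiabatic capacities.** `p`, `m`, `c` are constant over a trial (the
  tasks modelled are a few seconds long).
- **Single state.** One activity level summarizes the region; storage and
  processing draw on the same activity.
- **Impulse information arrival.** A briefly presented stimulus delivers its
  information content at once; the incongruent condition of a flanker-type
  task carries more bits than the congruent one (α_IC > α_C).
- **Identifiability.** With impulse arrival only the *ratios* α/m and p/m
  are identifiable from response shape. All outputs are therefore relative:
  `p/α = k/a`, `m/α = 1/a` and `T_c = 1/k`, normalized by the fitted
  amplitude `a` of a designated reference condition (by convention the
  congruent condition, whose encoded input is assumed comparable across
  groups). The reporting layer refuses to emit absolute `p`, `m`, `α`.

## The two-state response

Within a trial, the fitted neuronal response is a sum of three decaying
exponentials sharing the decay rate `k`:

    x(t) = a·e^{−kt}·u(t) + c_amp·e^{−k(t−2T)}·u(t−T1) − b·e^{−k(t−T)}·u(t−T0)

a primary excitatory onset response, a delayed inhibitory control signal
(onset `T0`, the negative feedback that clears the previous input), and a
secondary excitatory input (onset `T1 ≥ T0`). Following the convention used
for TR-sampled data, `b` and `c_amp` are amplitudes referenced at the
sampling period `T = T_ref` (default 2.5 s) and at `2·T_ref`, even when the
onsets differ from those references; `TwoStateParams.onset_amplitudes()`
converts to onset-referenced values.

## Forward simulation

The synthetic-data generator (`paradigm`) emulates a rapid event-related
selective-attention experiment: 4 runs × 164 volumes at TR = 2.5 s, a 10 s
fixation baseline per run, and 32 trials per condition (C, IC, N) per run at
randomized TR-multiple onsets — a geometry whose mean onset-to-onset
interval (total acquisition time over trial count) is 4.27 s. Since "mean
ISI" is ambiguous between onset-to-onset intervals and stimulus-end-to-onset
gaps, `Paradigm` reports both (`mean_isi_onset_to_onset`, `mean_isi_gap`).

Each trial delivers an excitatory impulse of α_cond bits at onset, an
inhibitory impulse of `beta_frac·α` at onset + `t_inhib` (default 2.5 s) and
a secondary excitatory impulse of `gamma_frac·α` at onset + `t_second`
(default 5 s); defaults `beta_frac = 0.5`, `gamma_frac = 0.2` give a clearly
biphasic response without driving the activity negative. Default amounts
α_C = 1.0, α_IC = 1.3 bits encode the higher information load of the
incongruent condition; the neutral condition is scheduled but carries no
modelled load. The activity ODE is integrated with the **exact exponential
propagator** on a fine grid (dt = 0.1 s, 25× finer than TR): the ODE is
linear with constant coefficients, so the one-step update
`x_{n+1} = x_n·e^{−k·dt} + jumps` is exact and discretization error is
removed as a confound from recovery experiments. BOLD is the causal
discrete convolution of `x` with a double-gamma HRF

    h(t) = A·[g(t; α₁, β₁) − c·g(t; α₂, β₂)]

(defaults α₁ = 6, α₂ = 16, β₁ = β₂ = 1 s⁻¹, undershoot ratio c = 1/6,
kernel support truncated at 32 s where it is < 1e−6 of peak; ∫h = A(1−c)
exactly). A `peak_normalized` helper rescales `A` for a unit positive peak
so that fitted response amplitudes are interpretable across HRF shapes.
Runs are simulated independently (no bleed across run boundaries), sampled
at TR, and white or AR(1) Gaussian noise is added (the measurement-noise
law is a modelling choice; trial-averaged fMRI noise is temporally
correlated, hence the AR(1) option, but white noise is the default).

Two designs matter for validation. The **paper-like** rapid design overlaps
trial responses: the BOLD response to one trial (activity decay plus the
32 s kernel) extends ~45 s past onset, so trial-averaged responses are
contaminated by neighbours — a real property of rapid event-related data,
documented here as a source of bias. The **isolated** mode (`min_isi_s ≥
50`) spaces trials so responses die out completely; recovery experiments use
it to separate model error from design-induced bias.

What the generator does *not* emulate: physiological noise and drift
(assumed removed upstream), voxel-level heterogeneity, HRF variability
within a dataset, behavioral errors (an error-rate trial-dropping option
exists only as scheduling, not behavior). Passing recovery tests therefore
demonstrate correctness of the inversion under the model's own assumptions,
not robustness to every property of real data.

## Inversion

Three steps, mirroring the forward chain:

1. **Trial averaging.** Samples at offsets {0, TR, …, 15 s} from each onset
   are averaged per condition — 7 points at TR 2.5 s. Trials whose window
   crosses a run end are dropped with a logged count.
2. **Deconvolution and upsampling.** `deconvolve_ls` solves
   `min_x ‖y − Cx‖² + λ‖x‖²` for the activity at TR resolution on a 15 s
   support. Two forward operators are provided: the classical TR-sampled
   convolution matrix (`"riemann"`, exact when the data were produced by
   TR-grid convolution), and a convolution-consistent operator (`"spline"`)
   whose columns push cardinal cubic splines of each knot through the
   fine-grid convolution — the operator actually consistent with how BOLD
   arises, and the one the pipeline uses. Default λ = 0 (plain least
   squares, minimum-norm via SVD) with an automatic fallback to
   λ = 1e−6·tr(CᵀC)/n when the condition number exceeds 1e10; this fallback
   is routine for a support equal to the data window, because `h(0) = 0`
   makes the first BOLD sample uninformative and the system rank-deficient.
   The estimate is upsampled to 0.1 s by a not-a-knot cubic spline (the
   conventional "standard" spline; it reproduces cubics exactly and needs
   ≥ 4 knots).
3. **Two-state fit and scoring.** `fit_two_state` fits the response family
   to the upsampled activity estimate (activity-space fit). The *final*
   parameters, however, come from `fit_two_state_bold`: the same family
   convolved with the HRF and compared to the observed BOLD samples —
   i.e., the fit minimizes the BOLD-domain MSE, the same criterion used for
   HRF selection and model validation. This matters because the activity
   estimate from step 2 is a least-squares representative, not the true
   activity: the true response has a jump at the inhibition onset that no
   spline through 7 knots can represent, so the knots carry an irreducible
   representation bias (measured at 20–40% in relative ℓ2). Fitting in BOLD
   space removes that intermediary: on noise-free isolated-trial data the
   generating parameters are recovered to ~1e−5 relative (onsets to the
   0.1 s search grid). Both estimates are reported; the activity-space fit
   lives in the result's diagnostics.

### The fitting algorithm

For fixed `(k, T0, T1)` the three amplitudes enter linearly and are solved
by non-negative least squares (NNLS); the residual as a function of the
remaining three parameters is explored deterministically:

- onsets on a coarse grid (0.5 s) over `T0 ∈ [0, 2T_ref]`,
  `T1 ∈ [T_ref, 4T_ref]` with `T0 ≤ T1`; **each pair is ranked by its own
  near-optimal SSE** (13-point log bracket in `k ∈ [0.01, 10] s⁻¹` plus a
  local bounded minimization). Ranking pairs under a shared sparse k-grid
  instead was observed to promote aliased basins whose SSE (~1e−7) is far
  above the true basin's (~1e−12) — with 7 samples and 6 parameters the
  surface is genuinely multimodal;
- the top 4 candidate pairs are refined on the 0.1 s onset grid (each fine
  pair again gets a bounded 1-D k search), ties broken toward the earliest
  onsets; the winner's k is polished to xatol 1e−9.

`fit_shared_k` fits several conditions jointly under the assumption that
`p` and `m` — hence `k` — are condition-independent within a dataset:
stage 1 fits each condition independently to fix its onsets, stage 2
minimizes the pooled SSE over a single shared `k`, re-solving amplitudes
per condition. A per-condition independent fit remains available for
diagnostics.

HRF selection (`select_hrf`) runs the full pipeline per candidate kernel
and keeps the MSE-minimizing one; `fit_group` applies it in **fixed** mode
(select on a designated reference dataset, conventionally the older group's
incongruent condition, then apply everywhere) or **flexible** mode (each
dataset selects its own).

## Group level

The "overall" analysis averages BOLD series across members *before* fitting
(fit-the-average); averaging fitted parameters instead is not equivalent
except in the noise-free identical-member case, and is not what this layer
does. `capacity_table` tabulates `p/α`, `m/α`, `T_c`, time-to-peak and —
when behavioral response times are supplied — the ratio `T_r / T_c` per
(group, condition) cell, reports the descending `T_c` ordering, and
annotates any cell whose fitted peak activity is below half the maximum
across cells: low activity alone does not imply high processing capacity,
so those cells warrant caution rather than automatic interpretation.

## Numerical choices and degenerate inputs

- Impulses snap to the nearest simulation grid point and produce
  right-continuous jumps (`x(τ)` is the post-jump value), matching
  `x(0⁻) = 0`, `x(0) = α/m`.
- Onset steps in the two-state response switch on at the first grid point
  at/after the onset (tolerance 1e−6·dt); the fitting bases use the same
  convention, referenced at the snapped grid time, so that the response
  evaluator and the fitters agree to rounding.
- `information_accounting` integrates the processed information with an
  exact per-step exponential rule by default (consistent with the
  propagator; conservation residuals are then at rounding level, ~1e−14·α);
  a trapezoidal option exists for traces not produced by the simulator, with
  the documented O(k²dt²) residual.
- Zero fit targets raise a degenerate-input error; an empty HRF candidate
  set, over-subscribed trial schedules, mismatched grids and non-numeric
  TSV cells raise typed errors.
- All randomness flows from explicit integer seeds; identical seeds give
  byte-identical simulation outputs.

## Problem sizes used in validation

Recovery and comparison experiments are sized for precision rather than
bulk: isolated-trial subjects use 1–2 runs of 4 trials per condition (50 s
spacing); the noise calibration of the activity-space fit uses 100 replicate
seeds at 2% of peak noise (median decay-rate error ≈ 1.5%); the group
ordering experiment uses 100 replicates of two groups (T_c = 0.8 s vs
1.25 s), each group the average of 8 subjects at noise σ = 0.01 on unit-peak
BOLD, fitted with the shared-k model. Conservation checks integrate 60 s at
dt = 0.005 s.

## Known limitations

- The rapid (paper-like) design biases trial averages through response
  overlap; the pipeline quantifies but does not correct it (no overlap-aware
  GLM averaging).
- With 7 BOLD samples and six free parameters the two-state fit is exactly
  determined; under noise, single-subject estimates of `k` are volatile, and
  stable conclusions require group averaging (as the validation experiments
  do). Longer averaging windows help when the design allows them.
- Time-varying capacities, multi-region coupling, nonlinear (Balloon-type)
  hemodynamics and voxelwise analysis are out of scope.
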