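# Methods

## Models

### TPM assembly traces

A tether's state is summarized by the Brownian-motion amplitude
`BM = sqrt(var(x) + var(y))`, the combined-axis sample SD of the bead
centroid over a 20-frame sliding window (one-frame advance, timestamp at
the window center, windows touching invalid frames dropped).  The
combined-axis form is the common TPM convention and is unit-consistent with
nanometre amplitudes; whether a per-axis SD was historically used instead is
not documented, so the definition is a package choice, not a claim.

The generative model for an assembly time course is piecewise: BM at
`baseline_bm` until a nucleation time drawn from Exp(nucleation rate),
a linear rise to `final_bm` over `extension_time_per_monomer × (nt/3)`
seconds, then a plateau.  Centroids are isotropic Gaussians whose per-axis
scatter is `target_BM/√2`, plus additive per-axis centroid measurement
noise (default 3 nm).  The timeline mirrors acquisition: 30 s of valid
bare-tether recording, 30 s of flow dead time flagged invalid, then the
post-addition observation (600 s); analysis skips invalid frames and
measures nucleation from the end of the dead time.

Segmentation is threshold-based and parameter-transparent: nucleation is
the first time BM exceeds `baseline + rise_k·SD(baseline)` (rise_k = 3) and
*stays* above it for `min_run` spans of full windows.  Persistence is
counted in spans of `window` values because one-frame-slide BM values share
19 of 20 frames: a single noise excursion persists across ~20 correlated
values, so five *consecutive values* would be no protection at all, while
five *window spans* (100 values ≈ 3.3 s) cannot be produced by one
excursion.  The extension ends at the first sustained crossing of
`baseline + 0.9·(plateau − baseline)`, with the plateau level taken from
the final 10% of windows.  Because both crossings are biased (the 3σ
crossing fires well into the ramp, the 90% crossing before its end), the
default `refine=True` step uses them only to initialize a local
least-squares fit of the three-segment model (flat baseline, linear ramp
between free breakpoints t0/t1, flat plateau; Nelder–Mead on the two
breakpoints over a neighborhood of the anchors).  On synthetic cohorts this
removes the threshold bias: recovered per-monomer extension times are
within ~3% of the generating 0.75 s and 3.02 s values, versus tens of
percent for the raw crossings.

Tethers with no sustained crossing are right-censored at the observation
span and enter the nucleation-rate MLE in the denominator; discarding them
would bias rates upward.  The censored-exponential MLE is
`k̂ = d / Σ tᵢ` (d uncensored events; all observed times, censored
included); its SE is the SD of the MLE over 1000 bootstrap resamples of
whole molecules.  Traces whose extension had not plateaued (or degenerate
step-like rises) are flagged and excluded from extension-time averages.

### smFRET traces

The state dynamics are a continuous-time two-state Markov (telegraph)
process: unbound→bound at k_f, bound→unbound at k_d, simulated with
Gillespie exponential holding times and binned to 50 ms frames by majority
occupancy (avoids discretization bias; with coarse frames the ground-truth
event count can only exceed the frame-path count).  Emissions are
`donor = (1−E)·I_total + ε`, `acceptor = E·I_total + ε` with independent
Gaussian channel noise (no gamma factor or crosstalk, since no correction
factors are documented for this assay class); the default
`I_total = 1000`, `σ = 100` counts gives an efficiency noise SD ≈ 0.08 at
the default levels `e_high = 0.75` (bare ssDNA) and `e_low = 0.15` (bound).
The per-frame efficiency `E = I_A/(I_D+I_A)` is uncorrected; as a ratio
estimator it carries a second-order bias of order `E·(σ/I)² ≈ 0.01`, which
is irrelevant to two-state discrimination.  Photobleaching is off by
default (most fluorophores survive a 200 s window); when enabled, a single
exponential bleach time drops both channels to background and analysis can
truncate there.

Cohorts derive per-trace seeds as `master ⊕ index`.  The
`active_fraction` parameter makes a random subset of molecules inert
(k_f = 0), emulating molecule-to-molecule heterogeneity in whether any
binding occurs within the window.  This is required to match observed
cohort tables: a homogeneous process with a 74% binder fraction in 200 s
pins k_f at ~6.7×10⁻³ s⁻¹, which caps the expected event count at ~1.3 per
trace, far below the ~13 events per binder implied by the corresponding
nucleation frequency; binder/non-binder heterogeneity reconciles the two.
For frequency-recovery studies the calibration fixes k_d = 0.2 s⁻¹
(bound dwells of 5 s, two orders above the frame time), solves k_f from
the renewal expectation
`E[N] = k_f k_d T/(k_f+k_d) + (k_f/(k_f+k_d))²(1−e^{−(k_f+k_d)T})` so that
`E[N]/P(N≥1)` equals the target events-per-binder, and sets
`active_fraction = fraction / P(N≥1 | active)`.

### Two-state HMM idealization

Per-molecule Baum–Welch with Gaussian emissions and two states (the assay
is explicitly two-state).  Initialization: means at the 10th/90th
percentiles of E, SDs at half the inter-percentile spread, transition
diagonal 0.95, uniform start — robust to the low-occupancy regime of
weakly binding molecules, where one state may occupy a few percent of
frames.  Termination when the log-likelihood improves by < 1e−6
(non-decreasing by construction; asserted in tests) or at 500 iterations;
an emission-SD floor of 1e−3 prevents variance collapse.  States are always
relabelled so state 0 is the low-E (bound) state, making downstream results
invariant to initialization label order.  The idealized path is the Viterbi
MAP path with ties broken toward staying in the current state.

One-level traces (a molecule that never binds, or one stably bound
throughout) are a degenerate input for a two-state EM: it will split the
single emission peak into two nearby pseudo-states whose Viterbi path
flickers.  A fit whose relabelled means differ by less than
`min_separation = 0.2` E-units (one third of the 0.6 separation of the
generating levels, several times the emission noise) is therefore flagged
low-evidence and idealized as a constant path, classified bound when the
trace mean E is below `bound_threshold = 0.45` (the midpoint of the
default levels) and unbound otherwise.  The same separation guard is
applied to the two-Gaussian histogram fit.  On 967 simulated never-binding
traces this produced zero spurious binding events while leaving genuinely
dynamic traces untouched.

### Dwells and cohort statistics

Viterbi runs shorter than 2 frames (100 ms) are merged into the longer
neighbor before dwell extraction, suppressing single-frame noise flips.
The first dwell of a trace is left-censored and the last right-censored;
both enter the censored-exponential denominator but not the event count
(the standard conservative treatment, also applied to left-censored dwells
even though memorylessness would allow treating their visible part as
complete).  A single-run trace contributes only to the binding fraction.
Rate fits require ≥ 5 complete dwells, otherwise the condition is reported
N.D.  k_f^app comes from unbound dwells, k_d from bound dwells, and
K_eq = k_f^app/k_d; for stationary cohorts this agrees with the
low-/high-E mixture-weight ratio of the pooled FRET histogram within 20%
across K_eq = 0.1–10 (asserted in tests).

Binding fraction: molecules with ≥ 1 unbound→bound transition within the
200 s window, over molecules whose trace covers the window.  A trace
already bound at its first frame counts as a binder with one event (its
initial dwell is left-censored) — binding occurred within the flow dead
time.  Apparent nucleation frequency: mean events per binder × binding
fraction × 3600/window, which telescopes to (total events/molecule) ×
3600/window; this identity is asserted exactly on hand-built paths.  Note
that under this printed formula a cohort of stably bound molecules (one
dead-time event each, 100% binding) yields 18 hr⁻¹, not the ~1 hr⁻¹
conventionally quoted for saturating substrates; the package follows the
formula and leaves the convention to the caller.  Spreads are SDs across
experiment groups when ≥ 2 group labels are present (mirroring the ≥3
independent-experiments convention), else molecule-bootstrap SDs.

## Problem sizes and tolerances

Recovery studies use cohorts a single bench session would produce: 100 TPM
tethers per extension-time condition (recovery within 15%), 300 waiting
times for nucleation rates (within 3 bootstrap SE), 500 smFRET traces for
the binding fraction (within 3 binomial SE) and the high-activity
nucleation frequency (within 3 SE), and 2000 traces for the low-activity
cohort, where only ~3% of molecules bind and ~70 events total are expected
(agreement within a factor of 2).  Cross-route K_eq checks use 50
stationary traces per rate pair.  The bootstrap default is 1000 replicates.

## Known limitations

* The BM model is phenomenological: no bead-diffusion physics, no drift,
  no excluded-volume tether model; the nm→monomer conversion of BM
  increments is left as a configurable identity map, since extension
  durations (not amplitudes) carry the per-monomer time.
* Emission noise is Gaussian and channel-independent; real EMCCD noise is
  signal-dependent and the two channels share registration error.  Passing
  recovery tests on this generator therefore demonstrates correctness of
  the estimators under the stated model, not robustness to every camera
  artifact.
* The HMM assumes time-homogeneous rates within a trace; slow photophysics
  (blinking) would masquerade as extra transitions.
* ≥3-state models and model selection are out of scope by design.
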