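# smassembly

Kinetic inference for single-molecule assays of RecA nucleoprotein filament
assembly on ssDNA, with a synthetic-trajectory generator that stands in for
raw microscope data.

Recombinase filament assembly proceeds in two phases: a rate-limiting
*nucleation* step, in which a small cluster of monomers forms on the ssDNA,
and a fast *extension* step in which monomers add until the filament
saturates (one RecA per 3 nt).  Two assays resolve these phases at the
single-molecule level:

* **Tethered particle motion (TPM).**  A bead on a (dT)₆₀ gapped-DNA tether
  reports the effective tether length through its Brownian-motion amplitude
  *BM*, the standard deviation of the bead centroid over a 20-frame sliding
  window (33 ms/frame).  An assembly time course shows (i) a baseline dwell
  until nucleation, (ii) a continuous BM rise during extension, and (iii) a
  plateau.  Nucleation waiting times across tethers are exponential; the
  censored-exponential MLE `k̂ = d / Σtᵢ` (d uncensored events, all observed
  times in the denominator) gives the nucleation rate with a
  molecule-bootstrap SE, and the extension duration divided by the number of
  monomers at saturation (nt/3) gives the per-monomer extension time.
* **smFRET.**  On short 3′-(dT)ₙ overhangs (9–40 nt) a donor/acceptor pair
  reads nucleation-cluster formation directly: bare flexible ssDNA gives a
  high FRET efficiency *E = I_A/(I_D+I_A)*, a bound (stretched) overhang a
  low one.  Each trace (50 ms/frame, 200 s window) is idealized with a
  two-state Gaussian-emission hidden Markov model (Baum–Welch + Viterbi);
  censored-exponential fits of the unbound/bound dwell times give the
  apparent cluster formation and dissociation rate constants *k_f^app* and
  *k_d*, and cohorts yield the binding fraction (molecules with ≥1 binding
  event in the window), the apparent nucleation frequency (events per
  molecule per hour), and the association equilibrium constant
  *K_eq = k_f^app / k_d* — cross-checked against the low-/high-E population
  ratio of a two-Gaussian mixture fit to the pooled FRET histogram.

Because no raw traces are deposited for this class of experiment, the
package includes a first-class generator: TPM traces with exponential
nucleation, linear BM rise and Gaussian centroid noise, and smFRET traces as
a continuous-time telegraph process (Gillespie holding times, majority-vote
frame binning) with Gaussian channel noise, optional photobleaching, and
binder/non-binder cohort heterogeneity.  Every simulated object carries its
ground truth, so all estimators are validated by parameter recovery.

## Worked example

```python
import smassembly as sm

params = sm.FretSimParams(k_f=0.1, k_d=0.2, seed=7, initial_state="unbound")
trace, truth = sm.simulate_fret_trace(params)

model = sm.TwoStateHMM(trace.efficiency, frame_interval=0.05)
res = model.fit()
print(res.summary())

path = res.viterbi(trace.efficiency)
dwells = sm.extract_dwells(path)
kf = sm.fit_dwell_exponential(dwells, sm.UNBOUND, seed=0)
kd = sm.fit_dwell_exponential(dwells, sm.BOUND, seed=0)
print(kf.summary())
print(f"K_eq = {sm.keq_from_rates(kf.rate, kd.rate):.3f}")
```

prints

```
Two-state Gaussian HMM (Baum-Welch)
--------------------------------------------
state 0 (bound/low-E):    mu=  0.1423  sd= 0.0914
state 1 (unbound/high-E): mu=  0.7539  sd= 0.0816
transition/frame:  [[0.99008 0.00992]
                    [0.00541 0.99459]]
start prob: [0.0000 1.0000]
log-likelihood 4023.8388  iter 4  converged=True

Censored-exponential MLE
----------------------------------------
rate                0.100425 s^-1
bootstrap SE       0.0303775 s^-1  (n_boot=1000)
mean lifetime        9.95769 s
observations        15  (events: 13, censored: 2)

K_eq = 0.506
```

The fitted emission levels recover the generating FRET states (0.15/0.75),
the unbound-dwell MLE recovers the generating formation rate 0.1 s⁻¹ within
its bootstrap SE, and K_eq ≈ k_f/k_d = 0.5.

The same objects drive cohort analyses (`binding_fraction`,
`apparent_nucleation_frequency`, `build_length_series`) and the TPM side
(`compute_bm`, `detect_assembly_phases`, `extension_time_per_monomer`,
`bootstrap_rate`).  A `smassembly` CLI exposes `simulate-tpm`,
`simulate-fret`, `analyze-tpm`, `analyze-fret`, `summarize` and
`reproduce-acceptance` over plain-TSV trace files and manifests.

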