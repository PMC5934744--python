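# Methods

## Model

### Spiking stage

The neuron is a modified leaky integrate-and-fire unit.  EPSPs and
IPSPs arrive as Poisson events at mean rates `i_re` and `i_ri`
(defaults 292 Hz each, balanced); each event deflects the synaptic
potential V_syn by ±2 mV, and V_syn decays with a 3.5-ms half-life.
The membrane potential is

    V = V_rest + V_syn − HAP − AHP,      V_rest = −56 mV

and a spike is emitted whenever V strictly exceeds V_thresh = −50 mV.
A spike increments two hyperpolarising variables that decay
exponentially: the HAP (30 mV per spike, 7.5-ms half-life), which
produces tens of milliseconds of refractoriness, and the AHP (1 mV,
350 ms), which accumulates over seconds of activity and provides
rate-stabilising negative feedback.  There is no explicit voltage reset;
the HAP is the effective reset.  A spike occupies exactly one 1-ms step
and its increments take effect from the next step.

A CCK injection adds an extra EPSP rate I_rCCK which ramps up linearly
for the 20-s injection duration and decays with CCK's 230-s plasma
half-life.  The dose-to-drive mapping is
`peak I_rCCK ≈ drive_gain × dose` with `drive_gain = 6.3` Hz per µg/kg.
The gain was calibrated once so that the standard protocol (292-Hz
input, 20 µg/kg) reproduces the reference-data response of a
1.46 spikes/s increase in the 5-minute mean rate, and then validated
against measurements not used in the calibration: the no-AHP
configuration (203.5 Hz, 7 µg/kg) yields 1.34 spikes/s; the
second-by-second CVs of rate and secretion in the matched AHP/no-AHP
scenarios come out at 0.45/0.56 and 0.62/0.82 against reference values
0.43/0.54 and 0.60/0.81; and the signal-detection error rates reproduce
(below).  The drive equation without this gain (peak ≈ dose in Hz)
produces a response ~6× too small at every dose and in both AHP
conditions, so the gain is treated as part of the dose mapping.
A known residual: the 25-s post-peak response increments at 20 µg/kg
(about 2.1 spikes/s from a 1-spike/s basal) remain below the ~3.5
spikes/s seen in reference analyses — the reference response waveform is
peakier than a drive with these ramp/decay constants can produce —
while 5-minute means, CVs and detection statistics all agree.

### Secretion stage

Terminal state variables b (spike broadening), c (cytosolic Ca²⁺) and
e (submembrane Ca²⁺) decay with half-lives 2 s, 20 s and 100 ms.  On
each spike, Ca²⁺ entry is computed from the pre-increment values,

    Ca_ent = e_inhib(e) · c_inhib(c) · (b + 0.5),

where each inhibition is an inverted Hill function
`1 − vⁿ/(vⁿ+θⁿ)` with θ_c = 0.14, θ_e = 12, n = 5; then
b += 0.021, c += 0.0003·Ca_ent, e += 1.5·Ca_ent.  Secretion is
`s = e^φ · α · p` with φ = 2 and α = 0.003 s⁻¹.  Pools are held in
pg — p_max = 5000 pg, r_max = 10⁶ pg — which is the only unit reading
under which 100 spikes at 50 Hz release ≈ 2.27 ng as the milk-ejection
calibration requires; α's published "pg/s" annotation is read as
describing s.  The pool transfer β·r/r_max (β = 120 pg/s) runs only
while p < p_max and is clipped so that p + r + cumulative secretion is
exactly conserved.  A vasopressin parameter set
(`vasopressin_secretion_params()`: k_b = 0.05, θ_e = 2.8, θ_c = 0.07,
φ = 3, β = 50) is included for the fatigue comparisons.

The model terminal represents the whole neural lobe, so secretion and
pool sizes are population-scale; per-cell numbers would be ~9000× lower.
Secretion is a deterministic rate, best read as the instantaneous
exocytosis probability summed over terminals; vesicle-level
stochasticity is not modelled.

### Plasma stage

Plasma mass x gains the secretion/injection inflow, is cleared at
x/τ_clr, and exchanges `DiffRate = (x/C_plasma − x_EVF/C_EVF) ·
(C_plasma+C_EVF)/2` at rate DiffRate/τ_diff with the extravascular
compartment.  Defaults: clearance half-life 68 s (135 s and 188 s for
the organ-clamped variants), diffusion half-life 61 s, volumes
8.5/9.75 mL for a 250-g rat; doses given per 100 g body weight are
scaled by the configured weight.

## Numerical scheme

All stages advance on a fixed 1-ms grid with forward Euler
(per-step decay factor 1 − dt/τ); an exact-exponential option
(`decay_mode="exact"`) is available everywhere.  Euler is the default
because it reproduces the reference firing-rate calibration curve
(165 Hz → 1.0, 210 → 1.5, 292 → 2.4, 348 → 3.0, 583 → 5.0,
895 → 7.1 spikes/s); the exact stepper decays V_syn slightly slower and
runs ~8% above that curve.  PSP input is drawn per step from a Poisson
distribution with mean rate·dt, which at 1-ms resolution is
statistically equivalent to drawing exponential arrival gaps (an
event-time generator is included and cross-validated in the tests).
Stochastic protocols draw every run's generator from a master seed via
numpy's seed-sequence spawning, so all results are exactly reproducible.

## Measurement conventions

* **Firing-rate responses** — two summaries are reported and must be
  selected explicitly by the caller: the 5-minute post-injection mean
  minus the basal mean (basal = 4 min before injection), and the mean
  over the 25 s following the peak of the averaged 1-s-binned response
  (peak located after 5-point smoothing).
* **Second-by-second CV** — the CV across the repeated runs at each
  1-s bin, averaged over a window of 50 s before plus 300 s after the
  injection.  The per-run temporal CV is also available
  (`*_cv_per_run`); it runs ~10% higher because the response drift
  contributes variance.
* **Apparent plasma half-life** — the library default
  (`apparent_half_life`) is the interpolated time for concentration to
  fall to 50% of its value at a reference time: infusion protocols
  reference the moment infusion stops; bolus protocols reference 60 s
  after injection.  Because the decline is bi-exponential, a
  single-exponential fit gives different (longer) values; the bolus
  calibration quantity is measured as that fit over 60–180 s post
  injection, emulating how the reference bioassay experiments measured
  their "apparent half-life" from the first minutes of decline
  (window sensitivity: fits over 60/120/180 s give 72/91/107 s).  The
  bolus peak concentration is read at t = 62 s — one minute after the
  2-s injection ends.
* **Milk-ejection release** — reported as the release during the 2-s
  50-Hz train (2.31 ng); including a 1-s post-train tail adds ~0.08 ng.
* **13-Hz consistency** — quantified as the experiment measured it:
  total release for separate 18/36/54/72-s trains from rest, which
  stays within 17% of proportionality to the 18-s response.  Successive
  18-s windows of one continuous train drift up to ~32% below the first
  as cytosolic-Ca inhibition accumulates; the duration-totals form is
  the protocol-faithful measure.
* **Index of dispersion** — variance/mean of binned spike counts (the
  Fano factor; Poisson baseline 1 at every width).  A rate-based
  variant (variance/mean of the binned rate, = Fano/width) sits behind
  `mode="rate"`.
* **Detection errors** — episodes of equal duration alternate
  basal/challenge EPSP rates (both calibrated by bisection on long
  averaged runs); a challenge whose total secretion does not exceed the
  immediately preceding basal episode counts as an error, ties
  included.  Percentages pool episodes within each 100-min run and are
  averaged over runs.

## Problem sizes

Calibration quantities are computed at the sizes the protocols define:
10 × 2000-s runs for the spontaneous rate; 20 runs for the CV
scenarios; 23 runs for CCK averages; 5 × 100-min schedules per AHP
condition for detection (with rate calibration by ~20-step bisection on
5 × 500-s runs).  The numba-compiled loops advance ~10⁸ steps per
second, so the full acceptance script completes in well under a minute.

## Synthetic populations

`sample_population` draws per-neuron balanced PSP rates and CCK
sensitivities from log-normal distributions parameterised by their
arithmetic mean and SD (σ² = ln(1+(SD/mean)²), µ = ln mean − σ²/2);
the defaults (mean = SD = 292 Hz; mean = SD = 20 µg/kg) reproduce the
heterogeneity needed to match in-vivo across-neuron variability.  A
fixed 23-neuron table with the published per-neuron values ships as
`data/population_params.csv` in five scenarios (with/without AHP ×
fixed/randomised rate and CCK sensitivity).  Population runs use
independent PSP noise per neuron; correlated input noise — likely in
vivo, where neurons share presynaptic populations — is not modelled, so
the across-neuron SD here is a lower bound on what shared noise would
produce.

## Known limitations and discrepancies

* The post-infusion apparent half-lives of the plasma stage measured as
  50% crossings are 113 s (normal) and 262 s (clearance slowed to
  135 s), versus reference values of 126 s and 379 s.  The 379-s value
  is unreachable under the stated equations and volumes: even with
  infinitely fast diffusion the decay half-life is bounded by
  λ_clr·V_tot/V_plasma = 290 s, and slower diffusion only shortens it.
  No measurement convention we tried (crossing, sparse sampling,
  exponential fits over any window, clamped-experiment volumes)
  reproduces 126/379/479 together, so these are reported as measured.
* The three reference infusion peak concentrations are mutually
  consistent only up to a ~5.5 pg/mL offset (the model is linear in
  infusion rate); the pure-protocol peaks are reported, which sit
  0.5–2% below the two larger reference values.
* The model neuron is a point process: no dendritic structure, no
  depolarising afterpotential, no bursting mechanism — milk-ejection
  bursts enter only as imposed spike trains.  Secretion omits opioid
  and purinergic modulation and treats the vesicle pools as two
  homogeneous compartments.  Clearance is linear and un-saturable, with
  rat-typical defaults only.
* What passing tests show: the chain reproduces population-scale means
  and variability statistics of the reference system under the stated
  protocols.  They do not certify single-cell secretion dynamics (the
  terminal is gland-scale), responses outside the calibrated dose and
  rate ranges, or species other than rat.
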