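# Methods

This note documents the models behind `ipsckit`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not establish about real recordings.

## Receptor gating model

The channel model is a seven-node Markov scheme of the Jones–Westbrook
family: unbound (U), mono- and bi-liganded closed (B1, B2), open (O1, O2)
and desensitized (D1, D2) states, with binding steps U→B1 and B1→B2
proportional to the agonist concentration (rate coefficients in M⁻¹s⁻¹) and
all other transitions first order (s⁻¹). The literature on this receptor
family sometimes counts such schemes as "six-state" by merging a pair of
states; we keep all seven nodes explicit because the enumerated state list
(one unbound, two bound, two open, two desensitized) requires them.

Default rate constants are literature-plausible magnitudes (fast
bi-liganded opening, prominent bi-liganded desensitization, slow
mono-liganded desensitization). They are deliberately *not* treated as
quantitative: the contract is `calibrate_scheme`, which scales rates until
the macroscopic decay after a 1-ms, 1-mM pulse matches a target time
constant within 5%:

* `vary="all"` multiplies every rate by one factor — a time rescaling of
  the kinetics (exact up to the fixed 1-ms pulse width). Used to hit the
  fast target, the mean fast evoked-IPSC component (37.45 ms).
* `vary="binding_unbinding_only"` scales only the unbinding rates and
  leaves every other rate at its base value. Scaling binding *and*
  unbinding together cannot reach slow targets — weakening binding also
  empties the bound pool during the brief pulse, and the decay saturates
  near 80 ms — whereas slowing unbinding alone prolongs the decay without
  bound (the bound/open/desensitized manifold equilibrates and drains
  arbitrarily slowly). The slow target is the mean slow evoked component
  (214.95 ms). The factor is found by bracket expansion plus Brent root
  finding on the log scale; failures to bracket raise `CalibrationError`.

Macroscopic currents integrate the master equation dp/dt = Qᵀp with an
adaptive 8th-order Runge–Kutta scheme (DOP853, rtol 10⁻⁸, atol 10⁻¹²),
segment by segment across the piecewise-constant concentration profile.
State occupancies are checked to sum to one within 10⁻⁶ at every sample; a
matrix-exponential propagator serves as an independent oracle in the tests.
Stochastic channels use per-channel Gillespie simulation with exact
waiting times inside each concentration segment (waiting times are simply
redrawn at segment boundaries — memorylessness makes this exact), summed
onto the output grid. The mean open fraction of ≥ 2000 channels agrees
with the deterministic open occupancy within three binomial standard
errors pointwise.

Unitary current defaults to −1 pA per open channel; it is a display scale,
not a fitted quantity.

## Synthetic recordings

Mini trains place Poisson-timed events (default 0.15 Hz, the published
mini frequency in excitatory cells) with lognormal amplitudes (default
mean 19.5 pA, the published mini amplitude; SD 6 pA) and monoexponential
decays drawn from a three-component Gaussian mixture (the published
decay-constant decomposition). Event rise is a saturating exponential
(default τ ≈ 0.5 ms) truncated at five rise constants and normalized so
the peak equals the nominal amplitude; from the peak onward the decay is
exactly exponential, which makes round-trip fitting assertions exact.
Mixture draws at τ ≤ 0 are rejected and redrawn.

Noise is white Gaussian passed through a 4th-order Butterworth low-pass at
3 kHz applied forward–backward (zero phase; the effective magnitude
response is the square of the 4th-order filter, giving ≥ 20 dB attenuation
above 4 kHz at 10-kHz sampling) and then rescaled to the requested sample
SD exactly. The default 2-pA SD is a typical whole-cell noise floor.

What the generator does *not* emulate: series-resistance filtering of the
events themselves, baseline drift and seal instability, overlapping
multiquantal bursts, and amplitude–kinetics correlations. Detection and
recovery results on these trains therefore bound what the pipeline can do
under ideal stationarity, not what any particular rig achieves.

## Event detection

Detection follows the conventional criterion — threshold at 3× the RMS
noise (robust MAD estimate by default) — with three declared additions
where the convention is silent:

* the baseline is a rolling median (2-s window on a decimated grid) with
  supra-1×RMS excursions excluded under a dilated mask and re-estimated;
  without the exclusion, slow events (τ ≈ 300 ms) drag a centered median
  up by several pA and get missed;
* the accept/reject decision uses a 0.8-ms boxcar-smoothed copy of the
  residual and the peak-to-local-baseline amplitude on that smoothed
  signal (local baseline: median over 6–0.5 ms before the onset). This
  suppresses both sub-millisecond noise crossings and re-crossings riding
  on the decay tail of a previous event, whose local amplitude is only
  noise-sized. All reported measurements come from the raw residual;
* supra-threshold runs are split where an interior minimum is followed by
  a re-rise of at least one threshold — two events closer than their decay
  never dip below threshold between peaks. Events whose peak follows the
  previous peak by < 20 ms are flagged `compound` and excluded from decay
  analysis rather than merged.

Onset is the walk-back point where the signal falls to 10% of the event
amplitude above local baseline; rise time interpolates the 10% and 90%
crossings linearly (at 0.1-ms sampling, higher-order interpolation changes
nothing); charge is the trapezoidal integral from onset to a sustained
return to baseline or a caller-specified window. Measured operating
characteristics on synthetic trains: recall 1.0 and precision ≥ 0.98 at
five noise SDs (five seeds, 600 s each).

## Decay fitting

Decays are fitted as Σ Aᵢ exp(−t/τᵢ) (no offset term: the baseline is
subtracted beforehand, and a fitted offset would redefine τ_w). The search
runs over log time constants only; for any candidate τs the amplitudes are
solved exactly by non-negative linear least squares (variable projection),
which removes amplitude initialisation as a failure mode. Starting points
are deterministic — τ at 10% and 60% of the segment length, plus a second
start at 2% and 20% with the lower-SSE solution kept, because a single
length-scaled start stalls in a local minimum when both true constants are
far below the fit window. Time constants pinned at the search bounds and
vanishing amplitudes are flagged; pure-noise segments either fail loudly
or come back flagged, never silently.

The weighted time constant is τ_w = Σ Aᵢτᵢ / Σ Aᵢ, the identity for
single-exponential fits, and always lies between τ₁ and τ₂.

One vs two exponentials is decided by the extra-sum-of-squares F-test,
F = ((SSE₁ − SSE₂)/2) / (SSE₂/ν₂) against F(2, ν₂). For regression
residuals that are independent noise this statistic is exact under the
null, and at the strict default α = 10⁻⁴ the measured false-biexponential
rate on noisy monoexponential data is ≲ 10⁻⁴ (0/100 in the unit test).

## Mixture decomposition of decay distributions

The empirical CDF at the order statistics (P = k/N; ties collapse to the
highest rank) is fitted by the erf-sum cumulative model by least squares
at the sample points — the procedure operates on the cumulative
probability plot itself, not on binned histograms and not by maximum
likelihood, because that is the analysis this toolkit standardizes.
Weights live on the simplex via an (n−1)-parameter softmax; σ is bounded
below at half the median sample spacing; ten multi-starts from
quantile-stratified means (seeded perturbations) keep the fit
deterministic per seed. Degenerate outcomes are flagged: σ at its floor,
weights below 10⁻³ (collapse) or 0.08 (the signature of an
over-parameterized fit; genuinely three-component samples of N = 2000
never produced a fitted weight below 0.15 across seeds), and adjacent
components closer than the smaller of their SDs.

Two statistics are reported per fit:

* `chi2` — the unweighted least-squares objective (the quantity the fit
  minimizes), with ν = N − (3n − 1);
* `gof_chi2` — the same residuals weighted by the binomial variance of
  each CDF ordinate, F̂(1−F̂)/N with F̂ = k/(N+1). This is a discrete
  Anderson–Darling-type statistic: ≈ 0.2 per degree of freedom for a
  correct model (below the nominal 1 because least squares absorbs part of
  the sampling bridge) and ≥ 3 per degree of freedom when a genuine
  component is missing.

**Model comparison.** `f_test_extra_component` reports the improvement of
the reduced chi-square from one extra component,
F = (χ²ν,simple − χ²ν,complex)/χ²ν,complex with df = (3, ν_complex),
mirroring how curve-fitting practice in this field phrases the question
("did the additional component improve the reduced chi-square?").

**Order selection.** Automatic selection does *not* chain that F-test.
Empirical-CDF residuals are strongly autocorrelated (a sampling bridge,
not white noise), and simulation shows the consequence: the raw
extra-sum-of-squares form fires on essentially every single-Gaussian null
sample, while the reduced-improvement form is simultaneously too weak to
add the second component on genuinely three-component data (the 1→2
improvement factor ≈ 5 sits inside the null's own range) and adding
lookahead inflates the null rate to tens of percent. No ratio of fit
errors separates the two situations; the absolute (binomial-weighted)
goodness of fit does, cleanly. `select_mixture_order` therefore returns
the smallest n whose weighted goodness of fit is not rejected at the
strict critical level α = 10⁻⁴ — the same parsimony level, used in its
natural role. Orders beyond n are attempted only while N ≥ 10·(3n − 1)
(≈ 10 points per free parameter), which also keeps ν positive for small
samples. Measured operating characteristics: 0/200 false extra components
on a single-Gaussian null at N = 1000; the three-component generative
model identified as n = 3 in ≥ 90% of seeds at N = 2000.

The two-sample Kolmogorov–Smirnov comparison wraps the standard asymptotic
statistic.

## Charge-transfer analysis

Events partition at τ_w = 100 ms — the interface between the intermediate
and slow Gaussian components — into fast and slow categories; a value
exactly at the boundary goes to fast (a declared tie rule of measure
zero). Δ charge is the ratio of summed per-event charge (drug/control)
per category over equal-duration windows (default 600 s), reported
together with frequency, mean-amplitude and mean-τ_w ratios; when
categories do not migrate, Δ charge factorizes into frequency ratio ×
mean per-event charge ratio, which the tests verify. A category with zero
control charge reports an undefined ratio flag instead of infinity. When
both event tables carry an `event_id` column, events whose τ_w crosses the
boundary between conditions are counted — apparent frequency effects can
arise from migration alone.

## Passive cable model

The ball-and-stick cell is a spherical soma (default 10 μm — small lamina
II somata; unstated in the source problem, so declared here) coupled to a
single unbranched dendrite: diameter 1.5 μm, axial resistivity 300 Ω·cm,
membrane capacitance 1 μF/cm², leak 0.2 mS/cm², voltage clamp through a
30-MΩ series resistance. Leak reversal defaults to the holding potential
(zero holding current); the synaptic reversal defaults to 0 mV with a
−70 mV hold, i.e. a 70-mV driving force, and the synaptic waveform is a
recorded-like fast event (10–90% rise 1.2 ms, decay 27.3 ms) normalized to
a 1-nS peak. With these passives the length constant is 250 μm, so the
1000-μm dendrite spans four length constants; compartments are capped at
0.05 λ (default 100 compartments) and the constructor rejects coarser
grids.

Integration is Crank–Nicolson on the tridiagonal conductance structure
(banded solve per step, default dt = 0.02 ms) — implicit, so the stiff
clamp node is harmless; the cable mathematics is implemented directly
because the model is a handful of parameters and a tridiagonal matrix.
Convergence: doubling the compartment count and halving dt changes the
measured rise and decay by < 1%. Checks: a zero-length dendrite reproduces
the bare RC step response τ = R_s·C_soma within 2%; with negligible series
resistance and leak, the somatic charge equals the synaptic charge
computed with the *actual* local driving force within 2% (the local
driving force collapses markedly for distal synapses — part of what the
somatic clamp cannot see). Rise and decay of the somatic current are
non-decreasing in synapse distance; sensitivity to soma size is modest
(a larger soma adds clamp filtering at distance 0 but does not change the
distal decay conclusion).

## Pipeline and reproducibility

A single config (`RunConfig`, YAML round-trippable) drives the composite
experiments. The global seed expands into per-module child seeds through
`numpy.random.SeedSequence(seed, spawn_key=(module_index,))` with a fixed
module table, so stages can be re-run in isolation; identical configs give
bit-identical traces, tables and reports.

`run_recovery_experiment` chains generation → detection → per-event decay
fits (compound events excluded; monoexponential, matching the generative
events) → three-component CDF decomposition, and reports recall/precision
plus recovered-vs-generative mixture errors. `run_markov_population`
calibrates fast and slow schemes as above, simulates 100 + 100 miniature
events from 20 stochastic channels each, adds band-limited noise and fits
every decay. Each sweep is fitted from the *ensemble* peak time: selecting
each sweep's own noisy argmax picks momentary spikes of the few-channel
open count and biases the fitted decays fast by ~20%. Population medians
land within 20% of the calibration targets; with 2000 channels the spread
collapses onto the macroscopic value.

## Problem sizes and defaults used in validation

Mixture-recovery checks use N = 2000 decay constants and 20 seeds;
order-selection characteristics use 200 single-Gaussian replicates at
N = 1000; detection checks use 600-s trains at 0.1–0.15 Hz; the MC/ODE
comparison uses 2000 channels over 300 ms; cable sweeps use five distances
over 0–1000 μm at dt = 0.02 ms. These sizes give comfortable statistical
margins for every assertion while keeping the full suite fast.

## Known limitations

* The Markov scheme's absolute rate constants are calibrated, not
  identified; only the macroscopic decay is constrained, so open-state
  occupancy scale (and hence absolute current amplitudes) are model
  choices.
* Mixture decomposition assumes Gaussian components on the τ scale;
  heavy-tailed or lognormal subpopulations would bias weights near
  component boundaries.
* The goodness-of-fit reference distribution (χ²_ν) for the weighted
  statistic ignores residual correlation; this makes the adequacy test
  conservative (the null sits near 0.2/dof), which is the safe direction
  for parsimony but means its p-values are not calibrated tail
  probabilities.
* The cable model is a single unbranched dendrite under ideal-square
  conductance drive; branched morphologies and space-clamp interactions
  beyond series resistance are out of scope.
* Compound (overlapping) events are flagged and excluded, not decomposed;
  very high event rates will bias recovered mixtures toward isolated
  events.
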