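# Methods

`fastnose` couples a physics-grounded simulator of a high-speed,
temperature-modulated MOx electronic nose (and the olfactometer that drives
it) with the signal-processing and decoding algorithms the instrument class
is built around.  This note documents the models, the default parameters and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions.

## Stimulus construction

The olfactometer model has two valve manifolds, each holding one odor valve
and one always-open mineral-oil carrier valve.  Valve commands are built on a
10 kHz master clock and gated by a 500 Hz PWM ("shattering") whose duty cycle
sets the delivered concentration (20 samples per shatter period, so duty
steps of 5% are exact).  Within a stimulus each carrier opens on the exact
sample-wise complement of its manifold's odor valve, so the total expected
open fraction equals the pre-trial level (2.0 manifold-open units) at every
sample — flow compensation is exact bookkeeping, and the conservation
invariant holds to better than 1e-9 per 2 ms bin by construction.

Three stimulus kinds are supported: square pulses (one odor valve shattered
for the stimulus duration), correlated pulse trains (both odor valves share
the on-half of a square wave at 2–60 Hz) and anticorrelated trains (the
second valve's on-phase shifted by half a period, so the two phase
indicators are disjoint and tile the stimulus).

Transport to the sensing site: the shattered valve trace is first averaged
over each shatter period (the 500 Hz pulses mix to their duty mean in the
delivery line — the reason shattering preserves temporal fidelity), then
delayed (default 10 ms, the upper-bound arrival time observed with a fast
photoionization detector), relaxed through an asymmetric first-order filter
(rise 5 ms; purge 30 ms) and scaled by the odorant's relative headspace
strength (vapor pressure × dilution, normalized so the strongest odorant at
full duty is 1.0 a.u.; the mineral-oil blank is exactly zero).  The purge
constant is chosen so that delivery retains usable modulation up to tens of
hertz — the regime the instrument exists for — while the 4σ purge bound at
the PID still lands above 100 ms and the sensor-side recovery takes a few
hundred milliseconds.  A PID ground-truth channel applies a 5 ms first-order
response and white noise to the summed concentration.

The full delivery inventory mirrors the standard protocol table: 300
one-second full-concentration pulses (split equally over four odors and two
solvent vials), 80 pulses per reduced concentration, 20 per short duration,
and correlated/anticorrelated trains per frequency — 1280 trials, presented
in fully randomized order with 30 s recovery; a chi-square test of per-bin
odor counts over consecutive time bins verifies the randomization.

## Sensor and hotplate physics

Film resistance combines an exponential temperature baseline with a
Langmuir-style gas term,

    R = R_ref · exp(−β (T − T_ref)) / (1 + Σ_i s_i θ_i)^α,

with fractional coverages θ_i integrated (exact exponential stepping at
1 kHz) from first-order adsorption/desorption kinetics with Arrhenius rate
constants k(T) = k0·exp(−E/(T+273.15 K)).  Defaults (per sensor type, in
`data/sensor_defaults.yaml`): β = 0.01/°C over T_ref = 400 °C; E_a = 1500 K,
E_d = 1800 K; prefactors set so that desorption at 400 °C runs at ~12/s
(clean-sensor recovery in one–two hundred ms) and the Langmuir term sits
near half-saturation at full concentration, giving the compressive
concentration response (≈ c^0.3) characteristic of real MOx films.  The
output is low-passed with τ_film = 25 ms, plus a 20 ms first-order "housing"
filter on the gas seen by the film: the sensors are simulated with their
packages on (as operated), and the package limits gas exchange — this is
what places classifier onset latencies in the observed 50–150 ms band.

The array tiles four synthetic sensor types (ester-tuned, broadband,
ether-tuned, ketone-tuned; the real devices' analyte spectra are not
published) twice, with deterministic ±20% jitter per physical sensor.
Baseline resistances differ per type (12–150 kΩ), as they do across real
sensor models; this order-of-magnitude spread is what makes naive Euclidean
classification on raw resistance features fragile and motivates the
max-scaled normalization.  Sensitivity coefficients are scaled roughly
inversely to headspace strength so full-concentration responses are
comparable across odors and the four classes are linearly separable.

The hotplate is a lumped thermal mass, C_th dT/dt = P_heat − (T −
T_amb)·airflow/R_th, with the quasi-linear heater law R_heat = R_h0(1 + α_h
(T − T_amb)) and a 10 Ω sense divider; explicit Euler at 10 kHz (the thermal
time constant is 3 ms, consistent with millisecond-scale MEMS hotplates and
with holding 25 ms temperature steps to <1 °C at the plateaus).

Converters: gas channels are quantized to 24 bits over 10 MΩ with 30 Ω
additive Gaussian noise; heater voltages to 12 bits over 3 V (≈0.73 mV
steps).  Clipping is counted and reported, never silent.  Baselines drift
log-linearly at 0.4/h — a desk-scale compression of the multi-hour sessions
the protocol emulates (sessions here run tens of minutes, so the hourly rate
is scaled up to preserve the total within-session drift).

### Trial-to-trial variability

Real delivery and real MOx films vary from trial to trial, and without that
variability every deterministic micro-difference between stimuli (e.g. the
half-period envelope shift of the second odor in an anticorrelated train) is
perfectly learnable, which would make correlation decoding trivially perfect
at every frequency.  The generator therefore draws, per trial: odorant
amplitude factors (lognormal, σ=5%; flow fluctuation), independent transport
delays per manifold (Gaussian, σ=5 ms; turbulent arrival times through the
two delivery lines — this is the mechanism that scrambles relative odor
timing at high modulation frequency while leaving it intact at low
frequency), per-sensor adsorption/desorption rate scalings (lognormal,
σ=25%; surface-state variability, shifting the response time constant
without moving the steady state), per-sensor response-amplitude scalings
(lognormal, σ=20%) and per-sensor clean-air baseline scalings (lognormal,
σ=10%).  These values were chosen to reproduce the qualitative phenomenology
the instrument class exhibits — perfect decoding at low modulation
frequency collapsing to chance at 60 Hz, concentration-graded static
accuracy, raw-feature fragility — and then frozen.

What the simulator does **not** emulate: turbulent plume structure (stimuli
are clean square envelopes), humidity/pressure effects, cross-sensor
electrical crosstalk, PID saturation, sensor poisoning/aging beyond the
log-linear drift, or the real devices' chemical selectivity patterns.
Passing tests therefore demonstrate that the algorithms are implemented
correctly and behave as described under plausible physics — not that a
physical device built from these parts would reach the same numbers.

## Heater read-out and control

The heater resistance is estimated from the divider as z = (V_DAC −
V_sense)·R_sense/V_sense.  The sample acquired immediately after a DAC step
carries a settling transient (modelled as −0.3·ΔV_DAC on V_sense), so a
scalar random-walk Kalman filter tracks R_heat with measurement variance
r = r0(1 + κ|dV_DAC/dt|); with r0 = 0.5 Ω² and κ = 2 s/V, a plateau-sized
step inflates r by >2000×, effectively ignoring the corrupted sample while
ordinary samples are tracked closely (q = 10 Ω² per 1 ms step tracks the
intra-cycle resistance swing).

Calibration holds five log-spaced DAC voltages to their thermal plateaus,
pairs the plateau resistance with the nominal temperature implied by the
datasheet thermal resistance, fits the linear map T = a·R_heat + b by least
squares, and caches a monotone (PCHIP) feed-forward lookup V_DAC(T_target).
With the linear heater law this inverts the true tempco to machine
precision.

Control = feed-forward plus an integral correction: the temperature error
is accumulated into the control voltage at 0.1 V·°C⁻¹·s⁻¹.  Two details
matter numerically: (i) anti-windup — the correction is not updated for
12 ms after a target step, since the thermal transient is not a tracking
error and integrating it produces a limit cycle that biases the plateaus by
>10 °C; (ii) constant-heat mode freezes the DAC code during each stimulus
and applies corrections only in between, keeping 12-bit quantization
transients out of the signal band.  Cycled mode alternates 25 ms at 150 °C
and 25 ms at 400 °C; experiments are configured as: A — all eight sensors
cycled; B — sensors 1–4 constant at 400 °C, 5–8 cycled; C — as B with
200 ms cycles on 5–8.

## Features

**Phase-locked windows.** Gas channels are chopped into 50 ms chunks whose
starts snap to the heater-cycle grid (anchored at recording start; stimulus
onsets are deliberately not synchronized with the heater phase, and the
residual phase ρ is recorded).  The normalized variant applies, per sensor,
log then max-scaling to the window at t and to a pre-stimulus window at
t_pre = −5 s, and takes the vector difference — exactly invariant under
power-law rescaling of resistance, and cancelling the first-order baseline
(drift, baseline wander).  Simulated resistances stay far above 1 Ω, so the
sign ambiguity of max-scaling a negative log never arises.

**Labelling.** With the upper-bound stimulus delay d = 10 ms, windows fully
inside [onset+d, offset+d) carry the stimulus odor; windows entirely before
onset or at least one recovery margin (300 ms, configurable — the purge
constant plus slack) after the delayed offset are blank; everything
straddling a transition is rejected — excluded from training but still
scored at evaluation time, where ground truth is unknown.

**Spectral triplets.** For constant-temperature sensors the trace over
[onset, offset + 100 ms] is log-transformed, differentiated (first
difference × f_s, natural log), Fourier-transformed with no taper, and the
(frequency, magnitude, phase) triplet of the maximum-magnitude positive-
frequency bin kept per sensor (DC excluded; ties resolve to the lowest
bin).  Four sensors give the 12-dimensional feature.  For hotplate-
temperature or PID control analyses the log transform is omitted.

**PID bounds.** Onset bound = first crossing of baseline mean + 4σ after
the commanded onset; purge bound = first sustained (20 ms) return below
threshold after the commanded offset, so isolated noise excursions in the
exponential tail do not inflate the estimate.

## Decoding protocols

*Static*: k-NN with k = 5 (the number of classes) on pooled windows
500–1000 ms into 1 s pulses, five-fold CV over contiguous batches, 60/40
trial-level split (no trial contributes windows to both sides); tested
across concentrations with the blank class omitted at test time.

*Dynamic*: five RBF-kernel SVMs (C = 1e3, γ = 1e−4, balanced class
weights), one per fold of a stratified five-fold split of the training
windows, combined by majority vote with ties reading as "no odor".  Each
member z-scores its features first: the published working point for C and γ
presumes standardized inputs — on the raw max-scaled log features the
squared distances are ~1e−3 and the kernel is degenerate.  Per-trial score:
most-predicted non-blank class (ties score incorrect); onset latency = time
from odor onset to the end of the first non-blank window; offset latency =
time from odor offset to the end of the first blank window.

*Temporal*: ten random forests (100 trees, balanced class weights) from a
stratified ten-fold split of the spectral features, majority vote with ties
to the lowest class index.  Training/validation data come from one session
(experiment B), test data from an independent session (experiment C).
Three tasks on the same feature: multiclass frequency decoding, pairwise
frequency vs the 20 Hz reference (f ∈ {2, 5, 10, 40, 60}), and
correlated-vs-anticorrelated per frequency; accuracies are reported as mean
± SD over ensembles retrained with different seeds (10 by default).

The go/no-go behavioral index ((Hit/S⁺) + (CR/S⁻))/2 is provided for
comparing machine accuracies with animal performance on the same tasks.

## Problem sizes

The bundled task presets run desk-scale versions of the protocol: the
static preset uses 20 trials per class at the trained concentration and 8
per odor per reduced concentration; the dynamic preset trains on 6 trials
per (odor, concentration) cell plus 12 blanks and tests 10 trials per
duration per odor; the temporal preset uses one odor pair (IA–EB, the
mouse-comparison subset) with 10 training and 6–8 test trials per
(frequency, mode) cell.  Recordings are ~9 s (pulse tasks, to include the
−5 s baseline window) or ~4 s (temporal tasks); one heater co-simulation
per heater configuration is shared across a protocol's trials, exactly as a
physical heater runs continuously.

## Known limitations

- The frequency tasks at 20–60 Hz score lower here than the real instrument
  (which retains more usable high-frequency response); the simulator's
  variability model was tuned to the low-frequency/collapse endpoints, not
  to the intermediate cells.
- Raw-feature accuracy curves are noisy at desk scale (a few dozen trials
  per concentration); only the normalized-variant claims are stable.
- The Kalman/controller defaults (q, r0, κ, settle window) are documented
  choices, not identified from hardware.
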