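# fastnose

Simulation and decoding stack for **high-speed, temperature-modulated
metal-oxide (MOx) electronic noses** — the class of instrument that resolves
odor pulses of tens of milliseconds and temporal structure of odor pairs
switching at up to 60 Hz.

Conventional MOx gas sensing is slow (seconds to minutes). Two ingredients
change that: (i) MEMS micro-hotplates whose temperature can be cycled
between 150 °C and 400 °C every 50 ms under feed-forward + closed-loop
control with a Kalman-filtered resistance read-out, and (ii) data features
designed for the resulting signals. `fastnose` implements the full
computational stack for such an instrument and pairs it with a
physics-grounded simulator of the sensors and of the high-fidelity
olfactometer that drives them, so every algorithm is exercisable end to end
with no hardware and no downloads.

## What is implemented

**Simulator** — olfactometer valve schedules with 500 Hz PWM "shattering"
(duty cycle = concentration) and exact flow compensation; square pulses
(10 ms – 1 s, 20–100%) and correlated/anticorrelated two-odor pulse trains
(2–60 Hz); gas transport (delay + asymmetric rise/purge); Langmuir
adsorption kinetics with Arrhenius rates on an exponential
resistance–temperature baseline; lumped hotplate thermal model; 24-bit
ADC / 12-bit DAC quantization, noise, drift, and realistic trial-to-trial
variability; 1 kHz lockstep multichannel recordings with PID ground truth.

**Heater control** — scalar Kalman filter on the heater resistance with
measurement uncertainty scaled by |dV/dt| (ignores post-step settling
transients); power-step calibration to a linear resistance→temperature map
with a cached feed-forward inverse; integral closed-loop correction
(0.1 V °C⁻¹ s⁻¹) with constant-heat in-stimulus freezing; an open- vs
closed-loop airflow-perturbation ablation.

**Features** — heater-phase-locked 50 ms windows with log + max-scale
baseline normalization against a −5 s pre-stimulus window; odor / blank /
rejected window labelling around stimulus transitions; dominant-peak
spectral triplets (frequency, magnitude, phase per sensor, a 12-dim
feature) from the differentiated log resistance; 4σ PID onset/offset
bounds; olfactometer fidelity statistic (peak−trough)/(peak−baseline).

**Decoding** — the three protocols: static odor identification (k-NN, k=5)
across concentrations; time-resolved pulse classification (ensemble of five
RBF-SVMs, C=1e3, γ=1e−4, balanced, majority vote, ties → "no odor") with
prediction-over-time rasters and onset/offset latencies; temporal-structure
decoding (ensembles of ten 100-tree random forests) for modulation
frequency (multiclass and pairwise vs 20 Hz) and correlated-vs-
anticorrelated discrimination; plus the go/no-go behavioral index
((Hit/S⁺)+(CR/S⁻))/2 for comparison with animal performance.

## Worked example

Olfactometer delivery fidelity of a simulated single-odor pulse train,
straight from the command line:

```
$ fastnose fidelity --frequency 20 --n-pulses 10 --seed 0
fidelity at 20 Hz over 10 pulses: 0.481 +/- 0.003
$ fastnose fidelity --frequency 60 --n-pulses 10 --seed 0
fidelity at 60 Hz over 10 pulses: 0.038 +/- 0.030
```

Fidelity is the per-pulse (peak − trough)/(peak − baseline) of the PID
trace: 0.48 at 20 Hz means each pulse trough gives back about half the
excursion before the next pulse arrives; by 60 Hz the transport dynamics
barely modulate the delivered concentration.

The heater-control ablation (airflow stepped up for two seconds, identical
seeds):

```
$ fastnose ablate-control --seed 0
open_loop: mean |T error| perturbed window 67.05 degC, overall 22.59 degC
closed_loop: mean |T error| perturbed window 32.19 degC, overall 12.63 degC
```

The closed-loop correction halves the temperature error under the
perturbation; in the unperturbed plateaus it holds both temperature steps
to under 1 °C (see `tests/test_control.py`).

The decoding protocols run end to end from the library:

```python
import fastnose.pipeline as pl

rep = pl.run_static_task(pl.StaticTaskConfig(seed=1))
print(rep["accuracy_by_concentration"]["normalized_cycled"])
```

```
{100.0: 1.0, 80.0: 1.0, 60.0: 1.0, 40.0: 1.0, 20.0: 0.946875}
```

The k-NN trained on normalized features of full-concentration 1 s pulses
identifies held-out full-concentration pulses perfectly and degrades
gracefully as the tested concentration drops to 20% — while the raw cycled
feature (same run, `rep["accuracy_by_concentration"]["raw_cycled"]`) falls
off much faster, which is the point of the baseline normalization.

See `docs/methods.md` for the models, parameter choices and their
rationale, and what the simulator does and does not emulate.

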