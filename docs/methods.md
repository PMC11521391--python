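# Methods

## Neuron model and the modulation knob

Cells are single-compartment conductance-based neurons with fast sodium
(instantaneous activation, inactivation gate `h`), delayed-rectifier
potassium (`n`), leak, and a slow non-inactivating M-type potassium
current gated by `z` with a fixed 75 ms time constant. The membrane
capacitance is 1 µF/cm², so currents in µA/cm² enter the voltage
equation directly. The M-current conductance `g_Ks` is the single
modulation knob: `g_Ks = 0` represents full muscarinic blockade (high
acetylcholine) and yields Type I excitability, `g_Ks = 1.5` mS/cm²
an intact current (low acetylcholine) and Type II excitability. The
same equations serve excitatory and inhibitory populations; only
`g_Ks` and the external drive differ between them. The slow `z` gate
also produces spike-frequency adaptation, which is why strongly driven
Type II interneurons can adapt into silence under fluctuating synaptic
drive.

Two gate-kinetics time constants (`τ_h`, `τ_n`) are implemented in the
standard logistic form `a + b / (1 + exp((V − V₀)/k))` of this model
lineage; the values (a, b, V₀, k) are (0.37, 2.78, −40.5, 6) and
(0.37, 1.85, −27, 15). Published typesettings of these expressions are
ambiguous; the form above is the one that reproduces the documented
phenomenology (spontaneous Type I firing at zero drive, silence at
−0.2 µA/cm², the Type I/II I–F and PRC signatures), which we verify in
the test suite.

## Integration

All dynamics advance with a fixed-step classical Runge–Kutta (RK4)
scheme, default `dt = 0.05` ms, implemented once in a numba-jitted
kernel shared by single-cell and network runs. The test suite verifies
fourth-order error scaling on smooth trajectories and spike-time
self-convergence under step halving. Spikes are upward crossings of
0 mV — safely between threshold and the sodium overshoot — with a 2 ms
refractory lockout, timestamped at the end of the crossing step (spike
times are therefore multiples of `dt`).

Synapses follow the double-exponential conductance kernel
`exp(−(t−s)/τ_d) − exp(−(t−s)/τ_r)` summed over all presynaptic spikes
`s`, with `τ_r = 0.2` ms everywhere, `τ_d = 3.0` ms (excitatory) and
5.5 ms (inhibitory), reversal potentials 0 and −75 mV. (An excitatory
decay of 3 seconds, as sometimes printed for this parameter set, is
dynamically and physiologically inconsistent with a PING loop operating
against a 5.5 ms inhibitory decay; we read it as 3.0 ms and flag the
discrepancy here rather than silently.) The spike sum is maintained by
two exponential accumulators per postsynaptic cell and incoming class,
incremented by exactly 1 per presynaptic spike (no peak normalization)
and decayed analytically each step — algebraically identical to the
explicit sum, which a brute-force oracle test enforces to 1e−9.
Within one RK4 step the accumulators are frozen at their step-start
values while the driving force `(V − E_syn)` is re-evaluated per stage;
since `τ_r, τ_d ≫ dt` the freeze is a second-order-small approximation,
and the step-halving test bounds its effect on burst timing below 2 ms.
Spike increments reach their targets from the following step.

Network runs last 1500 ms from random initial conditions (`V` uniform in
[−62, −22] mV, `h, n` in [0.2, 0.8], `z` in [0.15, 0.25]); synaptic
transmission is disabled for the first 100 ms so initial transients
decay before the network couples. Raster spikes during the warmup are
recorded; all measures use only the final second, so this choice is
inert downstream.

## Network construction and drive calibration

Wiring is Bernoulli per directed pair (inter-population 50 %,
intra-population 30 %, self-synapses excluded — the convention for
sparse random networks), one maximal conductance per synapse class,
varied jointly as `g_EI = g_IE = g_inter` and `g_EE = g_II / 4` (the
factor 4 offsets the 4:1 excess of excitatory over inhibitory cells).

Excitatory drive heterogeneity targets a 10 Hz spread of intrinsic
rates: the currents producing isolated-cell rates of 45 and 55 Hz are
found by bisection on the steady I–F relation (brackets [0, 5] µA/cm²
for Type I, [0, 10] for Type II; tolerance 0.1 Hz; at most 60
iterations; results memoized — the procedure is deterministic), and
each cell draws uniformly between them. Steady rate is measured as
(spike count − 1)/(last − first spike) over the final 1.5 s of a 2 s
run, which discards the adaptation transient. Inhibitory cells draw
from `U(0.95·IA, 1.05·IA)` (interval endpoints ordered numerically for
negative `IA`): `IA = −0.2` µA/cm² holds otherwise-spontaneous Type I
interneurons just below threshold, `IA = +1.0` brings the less
excitable Type II interneurons near theirs; neither fires without
excitatory input, which the suite checks.

## Excitability characterization

The I–F curve integrates all grid currents as one vectorized uncoupled
population. The PRC uses the direct perturbation protocol: establish the
steady period `T₀` from late interspike intervals of a 1.6 s baseline
(undefined if the cell is silent or the ISI coefficient of variation
exceeds 2 %), deliver a 0.5 ms square pulse at 25–50 evenly spaced
phases of a late cycle, and report `(T₀ − T_perturbed)/T₀` (advances
positive). PRC runs use `dt = 0.01` ms so quantization (~5×10⁻⁴ in
normalized shift) stays well below the structure of interest. Because
the Type I/II PRC distinction is expressed near firing onset, the
characterization drives each type to ~10 Hz (Type I: −0.05 µA/cm²,
Type II: 1.5 µA/cm²); pulse amplitudes of 1–2 µA/cm² put the peak
advance in the 0.02–0.1 range where the first-order PRC reading is
valid. A shift measured exactly at phase 0 overlaps the reference spike
and can read ~−0.01 even for a pure-advance cell; the Type I
"all-advance" property is therefore asserted with a −0.01 floor.

## Measures

The synchrony measure convolves each cell's spikes with a Gaussian
kernel, averages the resulting traces, and divides the time-variance of
the population-average trace by the mean per-cell time-variance.
Identical trains give exactly 1; independent trains give O(1/√N). Cells
silent in the analysis window are excluded ("synchrony of active
cells"); including them as zero-variance traces would make the
denominator collapse. With no active cell, or a zero denominator, the
measure is NaN with an explicit `defined` flag.

The kernel width for synchrony is not independently specified anywhere,
so the burst-detection kernel `exp(−(t−c)²/1.6)` (σ² = 0.8 ms²) is
reused for consistency and exposed as a parameter. Both traces are
sampled on a 0.1 ms grid (≈ σ/9); kernels are truncated at 9 σ, where a
single spike's contribution is below 3×10⁻¹⁸ — far beneath the 1e−9
agreement the direct-definition oracle tests require. Bursts are
maximal grid intervals with summed population activity at or above
threshold: 40 for the full 800-cell excitatory population and 10 for
200 inhibitory cells, scaled proportionally (`40·N/800`, `10·N/200`)
for other sizes — an extrapolation that keeps the per-cell activity
criterion fixed. "Repetitive bursting" requires at least two bursts in
the window; burst frequency (1000 / mean center spacing in ms) and mean
width are reported only then.

## Sweep pipeline and the desk-scale preset

A sweep runs every (inter, intra) grid cell for each requested
excitatory/inhibitory type combination, with `repetitions` independent
wirings and initial conditions. Per-repetition seeds derive from the
base seed and the cell coordinates through `SeedSequence` spawn keys, so
any single repetition is reproducible in isolation, and ablation sweeps
(g_IE forced to 0 after wiring) reuse the intact sweep's wiring seeds
bit for bit. Aggregation follows the majority rule: synchrony and
active-cell counts average over all repetitions, burst statistics only
over detecting repetitions and only when detections exceed half, with a
qualitative flag ('all' / 'majority-partial' / 'minority' / 'none')
recording detection robustness.

Two size presets exist. `full` is the 800E/200I network at the quoted
conductances. `scaled` (200E/50I, the default for desk work and the
test suite) preserves the 4:1 population ratio and all connection
probabilities and multiplies the four class conductances by the size
ratio 4, so the expected aggregate synaptic conductance per cell — mean
in-degree × g — matches the full-size network; this is the standard
g ∝ 1/N compensation for down-sized sparse random networks. Grid values
are therefore always quoted on the full-size scale. Default grids are
anchored at the three documented reference configurations
(inter/I–I, mS/cm²): high-inter (0.00175, 0.00025), intra-dominant
(0.00025, 0.0005), both-strong (0.002, 0.015), with E–E = I–I/4.

The end-to-end tests run the scaled preset with 3 repetitions per
condition and 1500 ms runs — sizes chosen so the whole suite completes
in a few minutes while every assertion (bursting in all four type
combinations under high inter-connectivity; excitatory-type-controlled
bursting under dominant intra-connectivity; loss of Type I excitatory
bursting under I→E ablation with wiring held fixed; retention of
Type II intra-driven synchrony) is made on majority behavior across
seeds, not single runs.

## What the synthetic fixtures do and do not emulate

The fixture generators produce packet rasters (per-cell Bernoulli
participation per packet, Gaussian timing jitter, Poisson background)
and fully asynchronous Poisson rasters. They share the raster container
with the simulator, so the measures layer is exercised against known
ground truth — packet times, participation, jitter level — without any
membrane dynamics. They do not emulate burst-internal structure the
simulator produces (drive-ordered firing within a burst, adaptation,
refractoriness), so fixture-based tests validate the *measures*, while
claims about *network dynamics* rest on the simulator tests.

## Numerical choices and degenerate inputs

* Non-finite states abort integration with the offending step and cell
  index.
* A degenerate rate band (e.g. 50–50 Hz) gives every cell the single
  calibrated current; a target rate outside the bisection bracket
  raises a calibration error rather than extrapolating.
* Fixture spike trains are sorted, clipped to the run, and exact ties
  are nudged apart by 1 ns rather than dropped.
* Empty rasters yield zero bursts and an undefined synchrony marker.
* Voltage/gate traces are recorded only on request
  (`record_traces`); at full network size they occupy
  ~1 GB per 1500 ms run.

## Known limitations

* No synaptic delays, short-term plasticity, channel noise, or
  multi-compartment morphology; acetylcholine acts only through
  `g_Ks`.
* Spike times are quantized to the integration step; measures that need
  sub-step precision (the PRC) use a finer step instead of
  interpolating crossings.
* The chaotic network makes long-horizon trajectories
  integrator-step-sensitive even when all statistics converge;
  convergence checks therefore compare burst timing over short
  post-warmup horizons and statistics elsewhere.
* Full-size five-repetition heatmap grids are supported but
  computationally heavy (the published-style figures were cluster-scale
  work); the package's own validation uses the scaled preset and
  corner configurations.
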