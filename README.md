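# eisync

Simulation and analysis of how cholinergic neuromodulation interacts with
network connectivity structure to control synchronous bursting in
excitatory–inhibitory (E–I) spiking networks.

Acetylcholine blocks the slow M-type potassium current of cortical
pyramidal cells and many interneurons through muscarinic receptors.
Blocking the current (conductance `g_Ks = 0` mS/cm²) gives a neuron
**Type I** excitability — a continuous current–frequency (I–F) curve with
arbitrarily low onset rate and a phase response curve (PRC) showing only
phase advances; an intact current (`g_Ks = 1.5` mS/cm²) gives **Type II**
excitability — a nonzero minimum firing rate and an early-phase delay
lobe in the PRC, a combination that favours synchronization. `eisync`
puts both cell variants into randomly wired E–I networks and asks when
the excitatory population produces synchronous population bursts, as the
strengths of the *inter*-population synapses (E→I, I→E) and the
*intra*-population synapses (E→E, I→I) are varied: strong
inter-connectivity generates bursting through the PING
(pyramidal–interneuron network gamma) loop regardless of cell type,
while intra-dominated networks burst only when the excitatory cells are
the synchrony-prone Type II variant.

The package is intended for computational neuroscientists studying
neuromodulation, PING rhythms, or synchrony measures, and for anyone who
needs a fast, tested conductance-based E–I network simulator with
reproducible wiring and drive heterogeneity.

## The model

Each cell is a single-compartment Hodgkin–Huxley-type neuron with
instantaneous sodium activation (state `V, h, n, z`):

```
C dV/dt = − g_Na m∞(V)³ h (V−E_Na) − g_Kd n⁴ (V−E_K)
          − g_Ks z (V−E_K) − g_L (V−E_L) + I_app − I_syn
dX/dt   = (X∞(V) − X) / τ_X(V)          X ∈ {h, n, z},  τ_z = 75 ms
```

with `g_Na = 24`, `g_Kd = 3`, `g_L = 0.02` mS/cm², `E_Na = 55`,
`E_K = −90`, `E_L = −60` mV. Synapses follow a double-exponential
conductance kernel (rise 0.2 ms; decay 3.0 ms excitatory / 5.5 ms
inhibitory; reversal 0 / −75 mV), summed over all presynaptic spikes and
evaluated incrementally by exponential accumulators inside a fixed-step
RK4 integrator (default `dt = 0.05` ms, jitted with numba).

Networks default to 800 excitatory / 200 inhibitory cells with Bernoulli
wiring (inter 50 %, intra 30 %, no self-synapses). Each excitatory cell
receives a constant drive drawn uniformly over the current interval whose
endpoints make an isolated cell fire at 45 and 55 Hz (endpoints found by
bisection); inhibitory cells sit just below threshold
(`U(0.95·IA, 1.05·IA)` with `IA = −0.2` µA/cm² for Type I, `+1.0` for
Type II).

Dynamics are quantified over the final second of each 1500 ms run by

* the variance-ratio **synchrony measure**
  `S = var(⟨V_i⟩_i) / ⟨var V_i⟩_i` of Gaussian-convolved spike trains
  (1 = perfect synchrony, →0 asynchronous),
* **burst detection**: thresholding the population activity trace
  `Σ exp(−(t−c)²/1.6)` (threshold 40 for 800 E cells, 10 for 200 I
  cells, proportional for other sizes), with burst frequency = inverse
  mean spacing of burst centers,
* **active-cell counts**.

## Worked example

```python
import numpy as np
from eisync import (NetworkConfig, SimulationSettings, build_network,
                    measure_report, run_simulation)

# desk-scale (200E/50I) PING-regime network: conductances are the
# full-size values 0.00175 / 0.00025 mS/cm² times the 4x size compensation
config = NetworkConfig(n_exc=200, n_inh=50, exc_type="I", inh_type="II",
                       g_inter=0.007, g_ii=0.001, seed=8)
net = build_network(config)
raster = run_simulation(net, SimulationSettings(seed=9))
rep = measure_report(raster)
print(f"excitatory synchrony S = {rep.s_exc:.3f}")
print(f"active E cells         = {rep.active_exc}/{config.n_exc}")
print(f"bursting detected      = {rep.bursting_exc}")
print(f"burst frequency        = {rep.burst_freq_exc:.1f} Hz")
print(f"burst width            = {rep.burst_width_exc:.1f} ms")
```

prints

```
excitatory synchrony S = 0.222
active E cells         = 200/200
bursting detected      = True
burst frequency        = 34.4 Hz
burst width            = 10.4 ms
```

i.e. in the strong-inter regime all excitatory cells join repetitive
~34 Hz gamma-band population bursts even though Type I excitatory cells
have no intrinsic propensity to synchronize — the PING signature. Swap
to the intra-dominated regime (`g_inter=0.001, g_ii=0.002`) and the same
Type I network fires asynchronously (`S ≈ 0.004`, no bursts), while a
Type II excitatory network keeps bursting.

A CLI mirrors the library: `eisync characterize` (I–F and PRC tables),
`eisync simulate` (YAML network → HDF5/CSV raster), `eisync measure`
(raster → report CSV + burst table), and `eisync sweep` (YAML grid →
CSV matrices, PNG heatmaps, JSON manifest).

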