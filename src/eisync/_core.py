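"""JIT-compiled fixed-step RK4 integration core.

A single kernel advances an arbitrary set of conductance-based neurons,
optionally coupled through double-exponential conductance synapses.  Design
points, shared by every caller (single neurons, I-F grids, full networks):

* Synaptic gating is maintained incrementally as two exponential
  accumulators per postsynaptic cell and per incoming synapse class
  (excitatory input, inhibitory input).  Each presynaptic spike adds 1 to
  both accumulators of its targets; each step both decay analytically.
  Their difference equals the sum of double-exponential kernels over all
  past spikes, so no spike list is ever re-scanned.
* Within one RK4 step the accumulators are frozen at their step-start
  values (synaptic time constants are much longer than the step), while
  the voltage-dependent driving force (V - Esyn) is re-evaluated at every
  stage.
* Spikes are detected as upward crossings of 0 mV at the end of a step,
  with a 2 ms refractory lockout; the spike time is the end-of-step time.
  Accumulator increments take effect from the following step, and only
  once the synaptic-silence warmup has elapsed.
"""

import numpy as np
from numba import njit

SPIKE_THRESHOLD_MV = 0.0
REFRACTORY_MS = 2.0
TAU_Z_MS = 75.0


@njit(cache=True)
def _deriv(V, h, n, z, gNa, gKd, gKs, gL, ENa, EK, EL, I_eff,
           ge, gi, se, si, Es_e, Es_i):
    """Time derivatives of (V, h, n, z) for one cell.

    ``se``/``si`` are the frozen excitatory/inhibitory synaptic gate sums;
    ``ge``/``gi`` the per-class maximal conductances seen by this cell.
    """
    m_inf = 1.0 / (1.0 + np.exp(-(V + 30.0) / 9.5))
    h_inf = 1.0 / (1.0 + np.exp((V + 53.0) / 7.0))
    n_inf = 1.0 / (1.0 + np.exp(-(V + 30.0) / 10.0))
    z_inf = 1.0 / (1.0 + np.exp(-(V + 39.0) / 5.0))
    tau_h = 0.37 + 2.78 / (1.0 + np.exp((V + 40.5) / 6.0))
    tau_n = 0.37 + 1.85 / (1.0 + np.exp((V + 27.0) / 15.0))

    I_syn = ge * (V - Es_e) * se + gi * (V - Es_i) * si
    dV = (-gNa * m_inf ** 3 * h * (V - ENa)
          - gKd * n ** 4 * (V - EK)
          - gKs * z * (V - EK)
          - gL * (V - EL)
          + I_eff - I_syn)
    dh = (h_inf - h) / tau_h
    dn = (n_inf - n) / tau_n
    dz = (z_inf - z) / TAU_Z_MS
    return dV, dh, dn, dz


@njit(cache=True)
def integrate(V, h, n, z,
              gNa, gKd, gKs, gL, ENa, EK, EL,
              Iapp,
              indptr, targets, is_exc,
              g_in_exc, g_in_inh,
              tau_r, tau_d_exc, tau_d_inh, Es_exc, Es_inh,
              dt, n_steps, syn_onset,
              pulse_amp, pulse_t0, pulse_t1,
              spike_times, spike_counts,
              record, traces):
    """Advance all cells ``n_steps`` fixed RK4 steps of size ``dt`` ms.

    State arrays are modified in place.  ``indptr``/``targets`` give the
    postsynaptic targets of each cell in CSR layout; ``g_in_exc[j]`` /
    ``g_in_inh[j]`` are the conductances applied to cell j's excitatory /
    inhibitory input accumulators.  A square current pulse of amplitude
    ``pulse_amp`` is applied to every cell for t in [pulse_t0, pulse_t1).

    Returns (-1, -1) on success, else (step, cell) of the first
    non-finite voltage.
    """
    n_cells = V.shape[0]
    ae_d = np.zeros(n_cells)
    ae_r = np.zeros(n_cells)
    ai_d = np.zeros(n_cells)
    ai_r = np.zeros(n_cells)
    dec_ed = np.exp(-dt / tau_d_exc)
    dec_id = np.exp(-dt / tau_d_inh)
    dec_r = np.exp(-dt / tau_r)
    last_spike = np.full(n_cells, -1.0e9)
    spk_buf = np.empty(n_cells, dtype=np.int64)
    max_spikes = spike_times.shape[1]

    if record:
        for j in range(n_cells):
            traces[0, j, 0] = V[j]
            traces[1, j, 0] = h[j]
            traces[2, j, 0] = n[j]
            traces[3, j, 0] = z[j]

    half = 0.5 * dt
    for step in range(n_steps):
        t0 = step * dt
        t_mid = t0 + half
        t1 = t0 + dt
        I_p0 = pulse_amp if (pulse_t0 <= t0 < pulse_t1) else 0.0
        I_pm = pulse_amp if (pulse_t0 <= t_mid < pulse_t1) else 0.0
        I_p1 = pulse_amp if (pulse_t0 <= t1 < pulse_t1) else 0.0

        n_spk = 0
        for j in range(n_cells):
            se = ae_d[j] - ae_r[j]
            si = ai_d[j] - ai_r[j]
            ge = g_in_exc[j]
            gi = g_in_inh[j]
            gNaj = gNa[j]
            gKdj = gKd[j]
            gKsj = gKs[j]
            gLj = gL[j]
            Ij = Iapp[j]

            Vj = V[j]
            hj = h[j]
            nj = n[j]
            zj = z[j]

            k1V, k1h, k1n, k1z = _deriv(
                Vj, hj, nj, zj, gNaj, gKdj, gKsj, gLj, ENa, EK, EL,
                Ij + I_p0, ge, gi, se, si, Es_exc, Es_inh)
            k2V, k2h, k2n, k2z = _deriv(
                Vj + half * k1V, hj + half * k1h, nj + half * k1n,
                zj + half * k1z, gNaj, gKdj, gKsj, gLj, ENa, EK, EL,
                Ij + I_pm, ge, gi, se, si, Es_exc, Es_inh)
            k3V, k3h, k3n, k3z = _deriv(
                Vj + half * k2V, hj + half * k2h, nj + half * k2n,
                zj + half * k2z, gNaj, gKdj, gKsj, gLj, ENa, EK, EL,
                Ij + I_pm, ge, gi, se, si, Es_exc, Es_inh)
            k4V, k4h, k4n, k4z = _deriv(
                Vj + dt * k3V, hj + dt * k3h, nj + dt * k3n,
                zj + dt * k3z, gNaj, gKdj, gKsj, gLj, ENa, EK, EL,
                Ij + I_p1, ge, gi, se, si, Es_exc, Es_inh)

            sixth = dt / 6.0
            V_new = Vj + sixth * (k1V + 2.0 * k2V + 2.0 * k3V + k4V)
            h_new = hj + sixth * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
            n_new = nj + sixth * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
            z_new = zj + sixth * (k1z + 2.0 * k2z + 2.0 * k3z + k4z)

            if not np.isfinite(V_new):
                return step, j

            if (Vj < SPIKE_THRESHOLD_MV and V_new >= SPIKE_THRESHOLD_MV
                    and t1 - last_spike[j] >= REFRACTORY_MS):
                last_spike[j] = t1
                c = spike_counts[j]
                if c < max_spikes:
                    spike_times[j, c] = t1
                    spike_counts[j] = c + 1
                if t1 >= syn_onset:
                    spk_buf[n_spk] = j
                    n_spk += 1

            V[j] = V_new
            h[j] = h_new
            n[j] = n_new
            z[j] = z_new

        for j in range(n_cells):
            ae_d[j] *= dec_ed
            ae_r[j] *= dec_r
            ai_d[j] *= dec_id
            ai_r[j] *= dec_r

        for k in range(n_spk):
            p = spk_buf[k]
            if is_exc[p]:
                for idx in range(indptr[p], indptr[p + 1]):
                    tgt = targets[idx]
                    ae_d[tgt] += 1.0
                    ae_r[tgt] += 1.0
            else:
                for idx in range(indptr[p], indptr[p + 1]):
                    tgt = targets[idx]
                    ai_d[tgt] += 1.0
                    ai_r[tgt] += 1.0

        if record:
            for j in range(n_cells):
                traces[0, j, step + 1] = V[j]
                traces[1, j, step + 1] = h[j]
                traces[2, j, step + 1] = n[j]
                traces[3, j, step + 1] = z[j]

    return -1, -1


def empty_adjacency(n_cells: int):
    """CSR adjacency with no synapses (decoupled cells)."""
    return (np.zeros(n_cells + 1, dtype=np.int64),
            np.zeros(0, dtype=np.int64))
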