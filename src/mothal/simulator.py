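"""Forward-Euler integration of the coupled membrane/conductance dynamics.

Membrane potentials follow conductance-based integrate-and-fire dynamics
(explicit Euler, default step 0.1 ms).  Synaptic and stimulus conductances
are alpha-kernel sums (instantaneous rise 1/tau, exponential decay), which
are maintained exactly as single decaying accumulators with per-event jumps
S/tau; the accumulator decay uses the exact factor exp(-dt/tau) (stable for
any dt), while the membrane update is plain Euler.

The SK auto-inhibitory current of PNs uses a non-exponential kernel
(sigmoidal rise over 2*tau_rise = 50 ms, then exponential decay, tau 250 ms).
It is evaluated exactly by splitting each own-spike's contribution: spikes
younger than 2*tau_rise are summed explicitly via a table of the sigmoid
branch on the dt grid; the moment a spike's age exceeds 2*tau_rise its
remaining contribution is a pure exponential and is folded into a single
decaying accumulator.  No truncation is involved.

Spikes fire when V crosses threshold at the end of a step (no sub-step
interpolation); the voltage is reset and clamped at V_L for the refractory
period.  Spikes generated in step k reach postsynaptic conductances in step
k+1 (one-step latency, removing within-step order dependence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .network import Network
from .params import NetworkParams
from .stimulus import StimulusProtocol, rate_matrix

__all__ = ["alpha_kernel", "sk_kernel", "SimState", "SimResult",
           "step", "run"]


# ----------------------------------------------------------------------
# kernels
# ----------------------------------------------------------------------

def alpha_kernel(t_since, tau: float):
    """Exponential synaptic kernel: (1/tau) exp(-t/tau) for t >= 0, else 0.

    Unit integral; value 1/tau at onset.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    t = np.asarray(t_since, dtype=float)
    out = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau) / tau, 0.0)
    return out if out.ndim else float(out)


def sk_kernel(t_since, tau_SK: float = 250.0, tau_rise: float = 25.0):
    """SK kernel beta(t): sigmoidal rise, then exponential decay.

    For 0 <= t <= 2*tau_rise (inclusive, as the piecewise definition is
    printed): (1/tau_SK) * e^{5(t-tau_rise)/tau_rise} / (1 + e^{...});
    for t > 2*tau_rise: (1/tau_SK) * exp(-(t - 2*tau_rise)/tau_SK);
    0 for t < 0.  The kernel has a small discontinuity at t = 2*tau_rise
    (sigmoid reaches e^5/(1+e^5) ~ 0.9933 of 1/tau_SK), kept as printed.
    """
    if tau_SK <= 0 or tau_rise <= 0:
        raise ValueError("tau_SK and tau_rise must be > 0")
    t = np.asarray(t_since, dtype=float)
    z = 5.0 * (t - tau_rise) / tau_rise
    sig = np.exp(z) / (1.0 + np.exp(z)) / tau_SK
    dec = np.exp(-np.clip(t - 2.0 * tau_rise, 0, None) / tau_SK) / tau_SK
    out = np.where(t < 0, 0.0, np.where(t <= 2.0 * tau_rise, sig, dec))
    return out if out.ndim else float(out)


# ----------------------------------------------------------------------
# compiled core
# ----------------------------------------------------------------------

@njit(cache=True)
def _poisson_counts(lam, seed):
    """Per-bin external event counts: Poisson with mean lam[step, neuron]."""
    np.random.seed(seed)
    out = np.empty(lam.shape, dtype=np.int64)
    for i in range(lam.shape[0]):
        for j in range(lam.shape[1]):
            out[i, j] = np.random.poisson(lam[i, j])
    return out


@njit(cache=True)
def _core(k0, n_steps, dt, is_pn, pn_idx, indptr, targets,
          jump_exc, jump_inh, jump_slow, jump_stim,
          sk_eff, sig_table, mature_val,
          f_fast, f_slow, f_sk,
          inv_tau_V, vL, vThres, vExc, vStim, vInh, vSK, refr_steps,
          ext_counts,
          V, refr, g_exc, g_inh, g_slow, g_stim, A_sk,
          sk_buf, sk_head, sk_cnt, spiked, gsk,
          rec_idx, tr_V, tr_gexc, tr_ginh, tr_gslow, tr_gstim, tr_gsk,
          out_n, out_k):
    n = V.shape[0]
    n_pn = A_sk.shape[0]
    buflen = sk_buf.shape[1]
    mature_age = sig_table.shape[0]  # ages >= this are on the exponential tail
    cap = out_n.shape[0]
    ns = 0
    for kk in range(n_steps):
        k = k0 + kk
        # 1. exact exponential decay of all conductance accumulators
        for i in range(n):
            g_exc[i] *= f_fast
            g_inh[i] *= f_fast
            g_stim[i] *= f_fast
            g_slow[i] *= f_slow
        for p in range(n_pn):
            A_sk[p] *= f_sk
        # 2. jumps from spikes of the previous step (one-step latency)
        for i in range(n):
            if spiked[i]:
                if is_pn[i]:
                    for jj in range(indptr[i], indptr[i + 1]):
                        t = targets[jj]
                        g_exc[t] += jump_exc[t]
                else:
                    for jj in range(indptr[i], indptr[i + 1]):
                        t = targets[jj]
                        g_inh[t] += jump_inh[t]
                        g_slow[t] += jump_slow[t]
        # 3. external Poisson events of this bin
        for i in range(n):
            c = ext_counts[kk, i]
            if c > 0:
                g_stim[i] += c * jump_stim[i]
        # 4. SK conductance: mature old spikes, sum the sigmoid window
        for p in range(n_pn):
            while sk_cnt[p] > 0 and k - sk_buf[p, sk_head[p]] >= mature_age:
                A_sk[p] += mature_val
                sk_head[p] = (sk_head[p] + 1) % buflen
                sk_cnt[p] -= 1
            s = A_sk[p]
            for q in range(sk_cnt[p]):
                age = k - sk_buf[p, (sk_head[p] + q) % buflen]
                if age >= 0:
                    s += sig_table[age]
            gsk[p] = sk_eff[p] * s
        # 5. traces: state at time k*dt
        for r in range(rec_idx.shape[0]):
            i = rec_idx[r]
            tr_V[kk, r] = V[i]
            tr_gexc[kk, r] = g_exc[i]
            tr_ginh[kk, r] = g_inh[i]
            tr_gslow[kk, r] = g_slow[i]
            tr_gstim[kk, r] = g_stim[i]
            tr_gsk[kk, r] = gsk[pn_idx[i]] if is_pn[i] else 0.0
        # 6. Euler membrane update, threshold, reset
        for i in range(n):
            fired = False
            if refr[i] > 0:
                refr[i] -= 1
                V[i] = vL
            else:
                v = V[i]
                dv = (-(v - vL) * inv_tau_V
                      - g_stim[i] * (v - vStim)
                      - g_exc[i] * (v - vExc)
                      - g_inh[i] * (v - vInh)
                      - g_slow[i] * (v - vInh))
                if is_pn[i]:
                    dv -= gsk[pn_idx[i]] * (v - vSK)
                v = v + dt * dv
                if not np.isfinite(v):
                    return 2, i, k, ns
                if v >= vThres:
                    if ns >= cap:
                        return 3, i, k, ns
                    out_n[ns] = i
                    out_k[ns] = k
                    ns += 1
                    v = vL
                    refr[i] = refr_steps
                    fired = True
                    if is_pn[i]:
                        p = pn_idx[i]
                        if sk_cnt[p] >= buflen:
                            return 4, i, k, ns
                        sk_buf[p, (sk_head[p] + sk_cnt[p]) % buflen] = k + 1
                        sk_cnt[p] += 1
                V[i] = v
            spiked[i] = fired
    return 0, -1, -1, ns


_CORE_ERRORS = {
    2: "non-finite membrane potential",
    3: "spike buffer overflow",
    4: "SK spike buffer overflow",
}


# ----------------------------------------------------------------------
# state container and python-facing stepping
# ----------------------------------------------------------------------

@dataclass
class SimState:
    """Mutable per-neuron dynamical state on the integration grid.

    Conductances are the decaying accumulators (units 1/ms); ``A_sk`` is the
    matured (exponential-tail) part of the SK kernel sum; ``sk_buf`` holds
    the recent own-spike step indices of each PN still on the sigmoid rise;
    ``spiked`` flags the neurons that fired on the previous step.
    """

    step: int
    V: np.ndarray
    refr: np.ndarray
    g_exc: np.ndarray
    g_inh: np.ndarray
    g_slow: np.ndarray
    g_stim: np.ndarray
    A_sk: np.ndarray
    sk_buf: np.ndarray
    sk_head: np.ndarray
    sk_cnt: np.ndarray
    spiked: np.ndarray

    @classmethod
    def initial(cls, network: Network, dt: float = 0.1) -> "SimState":
        """Rest state: V = V_L, all conductances zero, no spike history."""
        p = network.params
        n, n_pn = p.n_neurons, p.n_PN
        refr_steps = max(int(round(p.tau_ref / dt)), 1)
        mature_age = int(round(2.0 * p.tau_SK_rise / dt)) + 1
        buflen = mature_age // refr_steps + 4
        return cls(
            step=0,
            V=np.full(n, p.V_L),
            refr=np.zeros(n, dtype=np.int64),
            g_exc=np.zeros(n), g_inh=np.zeros(n),
            g_slow=np.zeros(n), g_stim=np.zeros(n),
            A_sk=np.zeros(n_pn),
            sk_buf=np.zeros((n_pn, buflen), dtype=np.int64),
            sk_head=np.zeros(n_pn, dtype=np.int64),
            sk_cnt=np.zeros(n_pn, dtype=np.int64),
            spiked=np.zeros(n, dtype=np.bool_),
        )


def _compile_inputs(network: Network, dt: float):
    """Static per-network arrays consumed by the compiled core."""
    p = network.params
    n, n_pn, n_ln = p.n_neurons, p.n_PN, p.n_LN
    is_pn = np.zeros(n, dtype=np.bool_)
    is_pn[:n_pn] = True
    pn_idx = np.full(n, -1, dtype=np.int64)
    pn_idx[:n_pn] = np.arange(n_pn)

    # CSR over presynaptic global id: PN rows -> excitatory targets,
    # LN rows -> inhibitory targets (fast and slow share the synapse).
    rows = []
    for i in range(n_pn):
        rows.append(np.concatenate([
            np.flatnonzero(network.a_PN_PN[i]),
            np.flatnonzero(network.a_PN_LN[i]) + n_pn]))
    for i in range(n_ln):
        rows.append(np.concatenate([
            np.flatnonzero(network.a_LN_PN[i]),
            np.flatnonzero(network.a_LN_LN[i]) + n_pn]))
    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum([r.size for r in rows])
    targets = (np.concatenate(rows) if indptr[-1] else
               np.zeros(0)).astype(np.int64)

    def per_post(val_pn, val_ln):
        out = np.empty(n)
        out[:n_pn] = val_pn
        out[n_pn:] = val_ln
        return out

    jump_exc = per_post(p.S_PN_to_PN, p.S_PN_to_LN) * p.scale_exc / p.tau_exc
    jump_inh = per_post(p.S_inh_PN, p.S_inh_LN) * p.scale_inh / p.tau_inh
    jump_slow = per_post(p.S_slow_PN, p.S_slow_LN) * p.scale_slow / p.tau_slow
    jump_stim = per_post(p.S_stim_PN, p.S_stim_LN) * p.scale_stim / p.tau_stim

    # sk_strength already carries scale_SK (applied at network build).
    sk_eff = network.sk_strength.astype(float)

    mature_age = int(round(2.0 * p.tau_SK_rise / dt)) + 1
    ages = np.arange(mature_age) * dt
    z = 5.0 * (ages - p.tau_SK_rise) / p.tau_SK_rise
    sig_table = np.exp(z) / (1.0 + np.exp(z)) / p.tau_SK
    mature_val = np.exp(-dt / p.tau_SK) / p.tau_SK

    return dict(
        is_pn=is_pn, pn_idx=pn_idx, indptr=indptr, targets=targets,
        jump_exc=jump_exc, jump_inh=jump_inh, jump_slow=jump_slow,
        jump_stim=jump_stim, sk_eff=sk_eff, sig_table=sig_table,
        mature_val=mature_val,
        f_fast=np.exp(-dt / p.tau_exc), f_slow=np.exp(-dt / p.tau_slow),
        f_sk=np.exp(-dt / p.tau_SK),
        inv_tau_V=1.0 / p.tau_V, vL=p.V_L, vThres=p.V_thres,
        vExc=p.V_exc, vStim=p.V_stim, vInh=p.V_inh, vSK=p.V_SK,
        refr_steps=max(int(round(p.tau_ref / dt)), 1),
    )


def _advance(network, state, ext_counts, dt, rec_idx, static=None):
    """Run the compiled core over ``ext_counts.shape[0]`` steps in place."""
    st = static if static is not None else _compile_inputs(network, dt)
    n = network.n_neurons
    n_steps = ext_counts.shape[0]
    m = rec_idx.size
    tr = [np.zeros((n_steps, m)) for _ in range(6)]
    cap = n * (n_steps // st["refr_steps"] + 2)
    out_n = np.empty(cap, dtype=np.int64)
    out_k = np.empty(cap, dtype=np.int64)
    gsk = np.zeros(network.n_PN)
    status, bad_i, bad_k, ns = _core(
        state.step, n_steps, dt, st["is_pn"], st["pn_idx"], st["indptr"],
        st["targets"], st["jump_exc"], st["jump_inh"], st["jump_slow"],
        st["jump_stim"], st["sk_eff"], st["sig_table"], st["mature_val"],
        st["f_fast"], st["f_slow"], st["f_sk"], st["inv_tau_V"], st["vL"],
        st["vThres"], st["vExc"], st["vStim"], st["vInh"], st["vSK"],
        st["refr_steps"], ext_counts,
        state.V, state.refr, state.g_exc, state.g_inh, state.g_slow,
        state.g_stim, state.A_sk, state.sk_buf, state.sk_head, state.sk_cnt,
        state.spiked, gsk, rec_idx, tr[0], tr[1], tr[2], tr[3], tr[4],
        tr[5], out_n, out_k)
    if status != 0:
        raise RuntimeError(
            f"simulation aborted: {_CORE_ERRORS[status]} "
            f"(neuron {bad_i}, step {bad_k})")
    state.step += n_steps
    return out_n[:ns].copy(), out_k[:ns].copy(), tr


def step(network: Network, state: SimState, ext_counts: np.ndarray,
         dt: float = 0.1) -> np.ndarray:
    """Advance the network by one Euler step in place.

    ``ext_counts`` is the per-neuron external event count for this bin.
    Returns the global ids of neurons that fired on this step.  Repeated
    calls are bit-identical to a single :func:`run` over the same inputs
    (both drive the same compiled kernel).
    """
    counts = np.asarray(ext_counts, dtype=np.int64).reshape(1, -1)
    ids, _, _ = _advance(network, state, counts, dt,
                         np.zeros(0, dtype=np.int64))
    return ids


# ----------------------------------------------------------------------
# results
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SimResult:
    """Spike raster plus optional per-neuron state traces.

    ``neuron_ids``/``times`` form the raster (times in ms, spike assigned
    to the end of the step on which threshold was crossed).  ``traces``
    maps a recorded global neuron id to a DataFrame with columns
    time_ms, V, g_inh, g_slow, g_SK, I_inh, I_slow, I_SK (currents are
    g * (V - V_rev), positive = hyperpolarizing for the inhibitory terms).
    """

    neuron_ids: np.ndarray
    times: np.ndarray
    duration: float
    dt: float
    network_seed: int
    stim_seed: int
    traces: dict[int, pd.DataFrame] | None = None
    ext_event_totals: np.ndarray | None = None  # external events per neuron

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def spikes_of(self, neuron_id: int) -> np.ndarray:
        """Sorted spike times (ms) of one neuron."""
        return np.sort(self.times[self.neuron_ids == neuron_id])

    def raster_frame(self, network: Network | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"neuron_id": self.neuron_ids,
                           "time_ms": self.times})
        if network is not None:
            df["glomerulus"] = network.glomerulus[self.neuron_ids]
            df["cell_class"] = np.where(self.neuron_ids < network.n_PN,
                                        "PN", "LN")
            df = df[["neuron_id", "glomerulus", "cell_class", "time_ms"]]
        return df


def run(network: Network, protocol: StimulusProtocol, *,
        stim_seed: int, dt: float = 0.1,
        record: tuple[int, ...] = (),
        rates: np.ndarray | None = None,
        ext_counts: np.ndarray | None = None) -> SimResult:
    """Simulate a full trial: sample the stimulus, integrate, collect spikes.

    Deterministic given (network, stim_seed).  ``record`` lists global
    neuron ids whose state traces (V and the inhibitory/SK conductances and
    currents) are stored every step.  ``rates`` may carry a precomputed
    rate matrix for the protocol (reused across trials in sweeps).  If
    ``ext_counts`` (per-bin, per-neuron external event counts) is given it
    is used verbatim instead of Poisson sampling.
    """
    p = network.params
    n_steps = int(protocol.duration / dt + 1e-9)
    if abs(n_steps * dt - protocol.duration) > 1e-6:
        warnings.warn(
            f"duration {protocol.duration} ms is not a multiple of "
            f"dt={dt}; truncating to {n_steps * dt} ms", stacklevel=2)
    state = SimState.initial(network, dt)
    rec_idx = np.asarray(sorted(record), dtype=np.int64)
    if ext_counts is None:
        if rates is None:
            rates = rate_matrix(network, protocol, dt)
        ext_counts = _poisson_counts(rates[:n_steps] * dt,
                                     int(stim_seed) % (2 ** 32))
    else:
        ext_counts = np.ascontiguousarray(ext_counts[:n_steps],
                                          dtype=np.int64)
    ids, ks, tr = _advance(network, state, ext_counts, dt, rec_idx)
    ext_total = ext_counts.sum(axis=0)
    times = (ks + 1) * dt

    traces = None
    if rec_idx.size:
        tgrid = np.arange(n_steps) * dt
        traces = {}
        for r, i in enumerate(rec_idx):
            v = tr[0][:, r]
            df = pd.DataFrame({
                "time_ms": tgrid, "V": v,
                "g_exc": tr[1][:, r], "g_inh": tr[2][:, r],
                "g_slow": tr[3][:, r], "g_stim": tr[4][:, r],
                "g_SK": tr[5][:, r],
                "I_inh": tr[2][:, r] * (v - p.V_inh),
                "I_slow": tr[3][:, r] * (v - p.V_inh),
                "I_SK": tr[5][:, r] * (v - p.V_SK),
            })
            traces[int(i)] = df
    return SimResult(neuron_ids=ids, times=times, duration=n_steps * dt,
                     dt=dt, network_seed=network.seed, stim_seed=stim_seed,
                     traces=traces, ext_event_totals=ext_total)
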