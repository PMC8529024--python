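import numpy as np
import pytest

from mothal import (NetworkParams, PulseSchedule, StimulusProtocol,
                    alpha_kernel, build_network, run, sk_kernel, step)
from mothal.simulator import SimState, _poisson_counts
from mothal.stimulus import rate_matrix


def _protocol(scenario, duration, schedule=None):
    schedule = schedule or PulseSchedule.single(500.0, 50.0)
    return StimulusProtocol.make(scenario, schedule, duration)


# ----------------------------------------------------------------------
# kernels
# ----------------------------------------------------------------------

@pytest.mark.parametrize("t,tau,expected", [
    (0.0, 2.0, 0.5),
    (2.0, 2.0, 0.5 * np.exp(-1)),
    (-0.1, 2.0, 0.0),
])
def test_alpha_kernel_values(t, tau, expected):
    assert alpha_kernel(t, tau) == pytest.approx(expected, rel=1e-12)


def test_alpha_kernel_unit_integral():
    t = np.linspace(0, 100, 2_000_001)
    assert np.trapezoid(alpha_kernel(t, 2.0), t) == pytest.approx(1.0, abs=1e-6)


def test_sk_kernel_branches():
    # sigmoid half-rise: beta(tau_rise) = 1/(2*tau_SK)
    assert sk_kernel(25.0) == pytest.approx(0.002, rel=1e-12)
    # at the branch point the printed piecewise keeps the sigmoid value
    assert sk_kernel(50.0) == pytest.approx(
        np.exp(5) / (1 + np.exp(5)) / 250.0, rel=1e-12)
    # just past it, the exponential branch starts at 1/tau_SK
    assert sk_kernel(50.0 + 1e-9) == pytest.approx(1 / 250.0, rel=1e-6)
    # one decay constant later
    assert sk_kernel(50.0 + 250.0) == pytest.approx(
        np.exp(-1) / 250.0, rel=1e-9)
    assert sk_kernel(-1.0) == 0.0


# ----------------------------------------------------------------------
# stepping semantics
# ----------------------------------------------------------------------

def test_leak_only_decay_matches_closed_form(tiny_pair):
    state = SimState.initial(tiny_pair)
    state.V[:] = 0.5
    zeros = np.zeros(2, dtype=np.int64)
    for _ in range(200):  # 20 ms at dt = 0.1
        step(tiny_pair, state, zeros)
    assert state.V[0] == pytest.approx(0.5 * np.exp(-1), abs=5e-4)


def test_refractory_clamp_after_spike(tiny_pair):
    """After a spike, V is held at V_L for tau_ref = 2 ms regardless of
    input, and interspike intervals never fall below tau_ref."""
    prot = _protocol("background", 500.0)
    # hammer the PN with strong deterministic input: 5 events per bin
    counts = np.zeros((5000, 2), dtype=np.int64)
    counts[:, 0] = 5
    res = run(tiny_pair, prot, stim_seed=0, ext_counts=counts, record=(0,))
    t_spk = res.spikes_of(0)
    assert t_spk.size > 10
    assert np.diff(t_spk).min() >= tiny_pair.params.tau_ref
    v = res.traces[0].V.to_numpy()
    for t in t_spk[t_spk < 495.0]:
        k = int(round(t / 0.1))  # trace row k holds V(k * dt)
        assert np.all(v[k: k + 21] == 0.0)


def test_kernel_sum_equivalence(tiny_pair):
    """Incremental conductance accumulators match the direct evaluation of
    sum S*alpha (and S_SK*beta) over all spike/event times, step by step."""
    p = tiny_pair.params
    rng = np.random.default_rng(3)
    n_steps = 4000
    counts = rng.poisson(0.5, size=(n_steps, 2))
    prot = _protocol("background", n_steps * 0.1)
    res = run(tiny_pair, prot, stim_seed=0, ext_counts=counts,
              record=(0, 1))
    tgrid = np.arange(n_steps) * 0.1

    def direct(event_times, S, tau):
        g = np.zeros(n_steps)
        for s in event_times:
            m = tgrid >= s - 1e-12
            g[m] += S / tau * np.exp(-(tgrid[m] - s) / tau)
        return g

    pn_spk, ln_spk = res.spikes_of(0), res.spikes_of(1)
    ev = {i: np.repeat(tgrid, counts[:, i]) for i in (0, 1)}

    for nid, tr in res.traces.items():
        post_pn = nid == 0
        S_stim = p.S_stim_PN if post_pn else p.S_stim_LN
        assert np.allclose(tr.g_stim, direct(ev[nid], S_stim, p.tau_stim),
                           rtol=1e-10, atol=1e-14)
    # PN -> LN excitation onto the LN
    assert np.allclose(res.traces[1].g_exc,
                       direct(pn_spk, p.S_PN_to_LN, p.tau_exc),
                       rtol=1e-10, atol=1e-14)
    # LN -> PN fast and slow inhibition onto the PN
    assert np.allclose(res.traces[0].g_inh,
                       direct(ln_spk, p.S_inh_PN, p.tau_inh),
                       rtol=1e-10, atol=1e-14)
    assert np.allclose(res.traces[0].g_slow,
                       direct(ln_spk, p.S_slow_PN, p.tau_slow),
                       rtol=1e-10, atol=1e-14)
    # SK: own-spike beta-kernel sum (sigmoid window + exponential tail).
    # The kernel is discontinuous at t_since = 2*tau_rise; snap float
    # round-off at that branch point so both evaluations take the same side.
    g_sk_direct = np.zeros(n_steps)
    for s in pn_spk:
        m = tgrid >= s - 1e-12
        t_since = tgrid[m] - s
        t_since = np.where(np.abs(t_since - 2 * p.tau_SK_rise) < 1e-6,
                           2 * p.tau_SK_rise, t_since)
        g_sk_direct[m] += tiny_pair.sk_strength[0] * sk_kernel(
            t_since, p.tau_SK, p.tau_SK_rise)
    assert np.allclose(res.traces[0].g_SK, g_sk_direct,
                       rtol=1e-10, atol=1e-14)


def test_step_sequence_matches_single_run(network):
    """Chunked stepping is bit-identical to one run over the same inputs."""
    prot = _protocol("odor_only", 300.0, PulseSchedule.single(100.0, 100.0))
    rates = rate_matrix(network, prot, 0.1)
    counts = _poisson_counts(rates * 0.1, 42)
    res = run(network, prot, stim_seed=0, ext_counts=counts)
    state = SimState.initial(network)
    ids, times = [], []
    for k in range(counts.shape[0]):
        fired = step(network, state, counts[k])
        ids.extend(fired)
        times.extend([(k + 1) * 0.1] * len(fired))
    assert np.array_equal(np.array(ids), res.neuron_ids)
    assert np.allclose(np.array(times), res.times)


def test_run_determinism(network):
    prot = _protocol("additive", 1000.0)
    a = run(network, prot, stim_seed=123)
    b = run(network, prot, stim_seed=123)
    c = run(network, prot, stim_seed=124)
    assert np.array_equal(a.neuron_ids, b.neuron_ids)
    assert np.array_equal(a.times, b.times)
    assert not np.array_equal(a.times, c.times)


def test_background_activity_regression(network):
    """Baseline activity is sparse, present in both classes, and
    reproducible (seed-pinned)."""
    prot = _protocol("background", 2000.0)
    res = run(network, prot, stim_seed=11)
    pn_rate = (res.neuron_ids < 60).sum() / 60 / 2.0
    ln_rate = (res.neuron_ids >= 60).sum() / 36 / 2.0
    assert 1.0 < pn_rate < 40.0
    assert 0.5 < ln_rate < 30.0
    again = run(network, prot, stim_seed=11)
    assert np.array_equal(res.times, again.times)


def test_voltage_bounded_between_reversals(network):
    """V stays within [V_inh, V_exc] (up to single-step Euler overshoot)
    during strong additive stimulation."""
    prot = _protocol("additive", 800.0, PulseSchedule.single(200.0, 400.0))
    res = run(network, prot, stim_seed=5, record=tuple(range(96)))
    lo, hi = -2.0 / 3.0, 14.0 / 3.0
    for tr in res.traces.values():
        assert tr.V.min() >= lo - 0.05
        assert tr.V.max() <= hi + 0.05


def test_refractory_never_violated_in_full_network(network):
    prot = _protocol("additive", 2000.0,
                     PulseSchedule.train(300.0, 7.0, 10))
    res = run(network, prot, stim_seed=9)
    for nid in np.unique(res.neuron_ids):
        isi = np.diff(res.spikes_of(nid))
        if isi.size:
            assert isi.min() >= network.params.tau_ref


def test_stronger_slow_inhibition_never_increases_pn_spiking(params):
    """On a fixed input realization, doubling scale_slow cannot increase
    the total PN spike count."""
    prot = _protocol("odor_only", 1500.0, PulseSchedule.single(300.0, 300.0))
    net1 = build_network(params, 4)
    net2 = build_network(params.replace(scale_slow=2.0), 4)
    rates = rate_matrix(net1, prot, 0.1)
    counts = _poisson_counts(rates * 0.1, 77)
    n1 = (run(net1, prot, stim_seed=0, ext_counts=counts).neuron_ids < 60).sum()
    n2 = (run(net2, prot, stim_seed=0, ext_counts=counts).neuron_ids < 60).sum()
    assert n2 <= n1


def test_single_neuron_isi_matches_fine_grid_oracle():
    """A PN driven by a deterministic periodic input train fires with an
    interspike interval matching an independent dt = 0.001 ms integration
    of the same dynamics."""
    from mothal.network import Network
    p = NetworkParams(n_glomeruli=1, n_PN_per_glom=1, n_LN_per_glom=1)
    net = Network(params=p, seed=0,
                  glom_PN=np.zeros(1, dtype=int),
                  glom_LN=np.zeros(1, dtype=int),
                  a_PN_PN=np.zeros((1, 1), dtype=bool),
                  a_PN_LN=np.zeros((1, 1), dtype=bool),
                  a_LN_PN=np.zeros((1, 1), dtype=bool),
                  a_LN_LN=np.zeros((1, 1), dtype=bool),
                  sk_strength=np.zeros(1))
    dt = 0.1
    n_steps = 3000
    counts = np.zeros((n_steps, 2), dtype=np.int64)
    counts[:, 0] = 1  # one external event per bin: strong steady drive
    prot = _protocol("background", n_steps * dt)
    res = run(net, prot, stim_seed=0, ext_counts=counts)
    isi_coarse = np.diff(res.spikes_of(0))[5:]  # steady regime
    assert isi_coarse.size > 5
    # periodic input -> near-regular firing (ISI quantized to the grid)
    assert np.ptp(isi_coarse) <= 0.1 + 1e-9

    # independent fine-grid integrator (same physics, dt = 0.001 ms)
    dt_f = 0.001
    sub = int(round(dt / dt_f))
    g = 0.0
    v = 0.0
    refr = 0.0
    decay = np.exp(-dt_f / p.tau_stim)
    spikes = []
    for k in range(n_steps * sub):
        g *= decay
        if k % sub == 0:  # event at each coarse bin boundary
            g += p.S_stim_PN / p.tau_stim
        if refr > 0:
            refr -= dt_f
            v = 0.0
            continue
        v += dt_f * (-(v) / p.tau_V - g * (v - p.V_stim))
        if v >= p.V_thres:
            spikes.append((k + 1) * dt_f)
            v = 0.0
            refr = p.tau_ref
    isi_fine = np.diff(np.array(spikes))[5:]
    assert abs(isi_coarse.mean() - isi_fine.mean()) / isi_fine.mean() < 0.03


def test_nonfinite_state_aborts_with_diagnostic(tiny_pair):
    """Absurd parameters that make the explicit Euler step diverge raise,
    naming the neuron and step.  (A divergent *inhibitory* conductance is
    the dangerous case: runaway excitation is absorbed by threshold/reset,
    while an unstable inhibitory oscillation overflows.)"""
    p = tiny_pair.params.replace(S_inh_PN=1e305)
    net_bad = type(tiny_pair)(
        params=p, seed=0, glom_PN=tiny_pair.glom_PN,
        glom_LN=tiny_pair.glom_LN, a_PN_PN=tiny_pair.a_PN_PN,
        a_PN_LN=tiny_pair.a_PN_LN, a_LN_PN=tiny_pair.a_LN_PN,
        a_LN_LN=tiny_pair.a_LN_LN, sk_strength=tiny_pair.sk_strength)
    counts = np.zeros((200, 2), dtype=np.int64)
    counts[:, 1] = 20  # drive the LN so it spikes onto the PN
    prot = _protocol("background", 20.0)
    with pytest.raises(RuntimeError, match="neuron"):
        run(net_bad, prot, stim_seed=0, ext_counts=counts)


def test_duration_rounding_warns(network):
    sched = PulseSchedule.single(10.0, 20.0)
    prot = StimulusProtocol.make("background", sched, 100.05)
    with pytest.warns(UserWarning, match="not a multiple"):
        run(network, prot, stim_seed=0)
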