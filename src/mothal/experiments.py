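"""In-silico experiment drivers: pulse-length sweeps, conductance-strength
sweeps, pulse-train frequency sweeps, graded-odor tuning, and the
synthetic-raster generators used by the metric tests.

Conventions (the package's declared defaults):

* standard odor target set: glomeruli 0-2 ("odor-receiving"); glomeruli
  3-5 receive no odor in the standard paradigm;
* probe cells: the first PN of glomerulus 0 (odor-receiving probe) and the
  first PN of glomerulus 3 (non-odor probe);
* single-pulse protocols: 500 ms pre-stimulus, pulse, 1500 ms post;
* pulse trains: 50 ms pulses over a 3000 ms pulse window (so every
  frequency >= 1 Hz yields >= 3 pulses), 500 ms pre, 1500 ms post;
* grids: pulse lengths 25-500 ms step 25; frequencies 1-12 Hz step 1;
  conductance multipliers 0-3 step 0.25;
* seed policy: the structural (network) seed is fixed within an
  experiment; each (condition, trial) gets a fresh stimulus seed derived
  from the experiment base seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from . import analysis
from .analysis import MetricSeries, pulse_following_index, response_length
from .network import Network, build_network, fixed_sk_network
from .params import ConfigError, NetworkParams
from .simulator import run
from .stimulus import PulseSchedule, StimulusProtocol, rate_matrix

__all__ = [
    "ODOR_GLOMERULI", "GRADED_GAINS", "PULSE_LENGTH_GRID", "FREQUENCY_GRID",
    "MULTIPLIER_GRID", "odor_probe", "non_odor_probe",
    "single_pulse_protocol", "train_protocol", "derive_seed",
    "run_length_sweep", "run_conductance_sweep", "run_frequency_experiment",
    "run_graded_odor", "run_ahp_experiment", "make_synthetic_raster",
]

ODOR_GLOMERULI = (0, 1, 2)
GRADED_GAINS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
PULSE_LENGTH_GRID = tuple(np.arange(25.0, 501.0, 25.0))
FREQUENCY_GRID = tuple(np.arange(1.0, 13.0))
MULTIPLIER_GRID = tuple(np.arange(0.0, 3.01, 0.25))

_SCALE_FIELD = {"SK": "scale_SK", "fast_inh": "scale_inh",
                "slow_inh": "scale_slow"}


def odor_probe(network: Network) -> int:
    """First PN of the first odor-receiving glomerulus."""
    return network.pn_id(ODOR_GLOMERULI[0], 0)


def non_odor_probe(network: Network) -> int:
    """First PN of the first non-odor glomerulus (standard paradigm)."""
    return network.pn_id(len(ODOR_GLOMERULI), 0)


def derive_seed(*keys: int) -> int:
    """Stable stimulus seed from (base, condition, trial) keys, < 2**31."""
    ss = np.random.SeedSequence(list(keys))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def single_pulse_protocol(scenario: str, pulse_ms: float,
                          pre_ms: float = 500.0, post_ms: float = 1500.0,
                          n_glomeruli: int = 6,
                          odor_gain: Sequence[float] | None = None,
                          ) -> StimulusProtocol:
    schedule = PulseSchedule.single(pre_ms, pulse_ms)
    return StimulusProtocol.make(
        scenario, schedule, pre_ms + pulse_ms + post_ms,
        n_glomeruli=n_glomeruli, odor_glomeruli=ODOR_GLOMERULI,
        odor_gain=odor_gain)


def train_protocol(scenario: str, frequency_hz: float,
                   pulse_ms: float = 50.0, pre_ms: float = 500.0,
                   train_ms: float = 3000.0, post_ms: float = 1500.0,
                   n_glomeruli: int = 6,
                   odor_gain: Sequence[float] | None = None,
                   ) -> StimulusProtocol:
    """Regular pulse-train protocol covering a ``train_ms`` pulse window."""
    n_pulses = int(round(train_ms * frequency_hz / 1000.0))
    if n_pulses < 2:
        raise ConfigError(
            f"frequency {frequency_hz} Hz over {train_ms} ms yields "
            f"{n_pulses} pulse(s); need at least 2")
    schedule = PulseSchedule.train(pre_ms, frequency_hz, n_pulses, pulse_ms)
    return StimulusProtocol.make(
        scenario, schedule, pre_ms + train_ms + post_ms,
        n_glomeruli=n_glomeruli, odor_glomeruli=ODOR_GLOMERULI,
        odor_gain=odor_gain)


def _probe_trains(result, network: Network, probe) -> list[np.ndarray]:
    """Spike trains for a probe: a neuron id, or ('glom', g) pooling the
    glomerulus's PNs."""
    if isinstance(probe, (int, np.integer)):
        return [result.spikes_of(int(probe))]
    kind, g = probe
    if kind != "glom":
        raise ConfigError(f"unknown probe spec {probe!r}")
    return [result.spikes_of(int(i)) for i in network.pn_ids_of_glom(g)]


# ----------------------------------------------------------------------
# sweeps
# ----------------------------------------------------------------------

def run_length_sweep(network: Network, scenario: str,
                     probe: int, *, seed: int,
                     pulse_lengths: Sequence[float] = PULSE_LENGTH_GRID,
                     n_trials: int = 50, pre_ms: float = 500.0,
                     post_ms: float = 1500.0, dt: float = 0.1,
                     ) -> MetricSeries:
    """Response length of a probe PN vs single-pulse length.

    Fresh stimulus seed per (pulse length, trial); the probe and network
    are fixed across trials.
    """
    values = np.empty((len(pulse_lengths), n_trials))
    for li, length in enumerate(pulse_lengths):
        protocol = single_pulse_protocol(scenario, length, pre_ms, post_ms,
                                         network.params.n_glomeruli)
        rates = rate_matrix(network, protocol, dt)
        for trial in range(n_trials):
            res = run(network, protocol, dt=dt, rates=rates,
                      stim_seed=derive_seed(seed, li, trial))
            values[li, trial] = response_length(res.spikes_of(probe), pre_ms)
    return MetricSeries(np.asarray(pulse_lengths, dtype=float), values,
                        x_name="pulse_length_ms",
                        metric_name="response_length_ms")


def run_frequency_experiment(network: Network, scenario: str,
                             probes: Mapping[str, object], *, seed: int,
                             frequencies: Sequence[float] = FREQUENCY_GRID,
                             n_trials: int = 50, pulse_ms: float = 50.0,
                             pre_ms: float = 500.0, train_ms: float = 3000.0,
                             post_ms: float = 1500.0, dt: float = 0.1,
                             bin_ms: float = analysis.DEFAULT_BIN_MS,
                             ) -> dict[str, MetricSeries]:
    """Pulse-following index vs pulse frequency for one or more probes.

    Each probe (neuron id or ('glom', g) aggregate) gets a MetricSeries of
    per-trial indices; its pulse-following rate follows by applying
    :func:`analysis.pulse_following_rate` to the series.
    """
    freqs = np.asarray(frequencies, dtype=float)
    out = {name: np.empty((freqs.size, n_trials)) for name in probes}
    for fi, f in enumerate(freqs):
        protocol = train_protocol(scenario, f, pulse_ms, pre_ms, train_ms,
                                  post_ms, network.params.n_glomeruli)
        rates = rate_matrix(network, protocol, dt)
        trials = {name: [] for name in probes}
        for trial in range(n_trials):
            res = run(network, protocol, dt=dt, rates=rates,
                      stim_seed=derive_seed(seed, fi, trial))
            for name, probe in probes.items():
                trials[name].append(_probe_trains(res, network, probe))
        for name in probes:
            _, per_trial = pulse_following_index(
                trials[name], protocol.schedule, bin_ms=bin_ms,
                return_trials=True)
            out[name][fi] = per_trial
    return {name: MetricSeries(freqs, vals, x_name="frequency_hz",
                               metric_name="pulse_following_index")
            for name, vals in out.items()}


def run_conductance_sweep(params: NetworkParams, target: str, metric: str,
                          scenario: str, *, net_seed: int, seed: int,
                          multipliers: Sequence[float] = MULTIPLIER_GRID,
                          probe_glom: int | None = None,
                          n_trials: int = 50,
                          pulse_lengths: Sequence[float] = PULSE_LENGTH_GRID,
                          frequencies: Sequence[float] = FREQUENCY_GRID,
                          dt: float = 0.1) -> MetricSeries:
    """Response slope or pulse-following rate vs conductance multiplier.

    ``target`` is one of SK / fast_inh / slow_inh; the multiplier scales
    the corresponding strength(s) uniformly in both cell classes, with 1
    the standard strength.  Slope sweeps use the standard network
    (per-PN Gaussian SK, rescaled); rate sweeps use the fixed-SK network
    variant.  Each grid point rebuilds the network with the same
    structural seed, so connectivity is identical across the sweep.
    """
    if target not in _SCALE_FIELD:
        raise ConfigError(f"target must be one of {sorted(_SCALE_FIELD)}")
    if metric not in ("slope", "rate"):
        raise ConfigError("metric must be 'slope' or 'rate'")
    mults = np.asarray(multipliers, dtype=float)
    if (mults < 0).any():
        raise ConfigError("conductance multipliers must be >= 0")

    rows = []
    for mi, m in enumerate(mults):
        p = params.replace(**{_SCALE_FIELD[target]: float(m)})
        if metric == "slope":
            network = build_network(p, net_seed)
            probe = network.pn_id(probe_glom, 0) if probe_glom is not None \
                else odor_probe(network)
            slopes = np.empty(n_trials)
            for trial in range(n_trials):
                lengths = np.empty(len(pulse_lengths))
                for li, length in enumerate(pulse_lengths):
                    protocol = single_pulse_protocol(
                        scenario, length, n_glomeruli=p.n_glomeruli)
                    res = run(network, protocol, dt=dt,
                              stim_seed=derive_seed(seed, mi, li, trial))
                    lengths[li] = response_length(res.spikes_of(probe), 500.0)
                slopes[trial] = analysis.response_slope(pulse_lengths, lengths)
            rows.append(slopes)
        else:
            network = fixed_sk_network(p, net_seed)
            probe = network.pn_id(probe_glom, 0) if probe_glom is not None \
                else odor_probe(network)
            series = run_frequency_experiment(
                network, scenario, {"probe": probe}, seed=derive_seed(seed, mi),
                frequencies=frequencies, n_trials=n_trials, dt=dt)["probe"]
            rows.append(np.array([analysis.pulse_following_rate(series)]))
    values = np.stack(rows)
    return MetricSeries(mults, values, x_name="multiplier",
                        metric_name="response_slope" if metric == "slope"
                        else "pulse_following_rate_hz")


def run_graded_odor(network: Network, scenario: str, *, seed: int,
                    frequencies: Sequence[float] = FREQUENCY_GRID,
                    n_trials: int = 50, dt: float = 0.1,
                    gains: Sequence[float] = GRADED_GAINS,
                    ) -> dict[int, MetricSeries]:
    """Glomerulus-aggregate index curves under graded odor gains.

    Odor is delivered to every glomerulus with gains (0, 0.2, ..., 1.0) --
    the summed drive equals the standard three-glomerulus paradigm's --
    with mechanosensory input absent (odor_only) or global (additive).
    Each glomerulus's index pools its PN trains per trial.
    """
    if scenario not in ("odor_only", "additive"):
        raise ConfigError("graded-odor paradigm uses odor_only or additive")
    freqs = np.asarray(frequencies, dtype=float)
    n_glom = network.params.n_glomeruli
    out = {g: np.empty((freqs.size, n_trials)) for g in range(n_glom)}
    for fi, f in enumerate(freqs):
        protocol = train_protocol(scenario, f, n_glomeruli=n_glom,
                                  odor_gain=gains)
        rates = rate_matrix(network, protocol, dt)
        trials = {g: [] for g in range(n_glom)}
        for trial in range(n_trials):
            res = run(network, protocol, dt=dt, rates=rates,
                      stim_seed=derive_seed(seed, fi, trial))
            for g in range(n_glom):
                trials[g].append(_probe_trains(res, network, ("glom", g)))
        for g in range(n_glom):
            _, per_trial = pulse_following_index(
                trials[g], protocol.schedule, return_trials=True)
            out[g][fi] = per_trial
    return {g: MetricSeries(freqs, vals, x_name="frequency_hz",
                            metric_name="pulse_following_index")
            for g, vals in out.items()}


def run_ahp_experiment(network: Network, *, seed: int, scenario: str = "odor_only",
                       frequency_hz: float = 4.0, n_trials: int = 50,
                       pre_ms: float = 4000.0, train_ms: float = 3000.0,
                       post_ms: float = 3000.0, dt: float = 0.1,
                       probe: int | None = None) -> dict:
    """Post-train after-hyperpolarization: suppression of probe-PN firing.

    Runs an odor-containing 50 ms pulse train and measures, from the
    trial-pooled probe raster, how long after the final pulse offset the
    windowed firing rate stays below the equilibrated pre-stimulus
    baseline.  The pre window is 4000 ms (several times the 750 ms
    slow-inhibition decay constant) so baseline activity -- read from the
    final 1000 ms of the pre window -- is at steady state; the post window
    leaves ample room for recovery.
    """
    protocol = train_protocol(scenario, frequency_hz, pre_ms=pre_ms,
                              train_ms=train_ms, post_ms=post_ms,
                              n_glomeruli=network.params.n_glomeruli)
    if probe is None:
        probe = odor_probe(network)
    rates = rate_matrix(network, protocol, dt)
    trains = []
    for trial in range(n_trials):
        res = run(network, protocol, dt=dt, rates=rates,
                  stim_seed=derive_seed(seed, 0, trial))
        trains.append(res.spikes_of(probe))
    final_offset = protocol.schedule.t_off[-1]
    duration = analysis.suppression_duration(
        trains, final_offset, baseline_window=(pre_ms - 1000.0, pre_ms),
        t_max=protocol.duration)
    return {"suppression_ms": duration, "trains": trains,
            "final_offset": final_offset, "protocol": protocol}


# ----------------------------------------------------------------------
# synthetic rasters (metric test fixtures)
# ----------------------------------------------------------------------

def make_synthetic_raster(kind: str, schedule: PulseSchedule | None, *,
                          seed: int, duration: float,
                          rate_hz: float = 150.0,
                          n_trains: int = 1) -> list[np.ndarray]:
    """Spike trains with known tracking structure, for metric unit tests.

    * ``pulse_locked``: Poisson bursts at ``rate_hz`` during each pulse,
      silence between -- maximal pulse periodicity;
    * ``tonic`` / ``poisson``: homogeneous Poisson over [0, duration] at
      the given rate (for ``tonic`` the rate is matched to the
      pulse-locked duty cycle) -- no pulse periodicity;
    * ``empty``: no spikes.

    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    trains: list[np.ndarray] = []
    for _ in range(n_trains):
        if kind == "empty":
            trains.append(np.empty(0))
        elif kind == "pulse_locked":
            if schedule is None:
                raise ConfigError("pulse_locked raster needs a schedule")
            parts = []
            for t_on, t_off in zip(schedule.t_on, schedule.t_off):
                n = rng.poisson(rate_hz / 1000.0 * (t_off - t_on))
                parts.append(rng.uniform(t_on, t_off, n))
            trains.append(np.sort(np.concatenate(parts)))
        elif kind in ("tonic", "poisson"):
            rate = rate_hz
            if kind == "tonic" and schedule is not None:
                duty = (schedule.pulse_duration * schedule.n_pulses
                        / duration)
                rate = rate_hz * duty
            n = rng.poisson(rate / 1000.0 * duration)
            trains.append(np.sort(rng.uniform(0.0, duration, n)))
        else:
            raise ConfigError(f"unknown raster kind {kind!r}")
    return trains
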