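"""External drive: pulse schedules, temporal envelopes, Poisson input trains.

Every cell receives external input as an inhomogeneous Poisson process of
incoming spike events.  The total rate for cell j is

    lambda_tot_j(t) = lambda_back
                      + sum over pulses [ gain(glom_j) * lambda_odor_max * O_j(t)
                                          + mech * lambda_mech_max * M_j(t) ]

where O (odor) and M (mechanosensory) are per-pulse temporal envelopes in
[0, 1] whose rise style depends on the cell class:

* odor:  PN rise sigmoidal (half-rise 35 ms), LN rise instantaneous;
* mech:  PN rise instantaneous, LN rise sigmoidal (half-rise 300 ms);
* both decay exponentially after pulse offset with tau = 384 ms, the
  decay branch starting from 1 regardless of the value the rise had
  attained by offset.

For pulses shorter than twice the half-rise time the last point makes the
envelope jump up at offset.  The jump is kept deliberately: for the LN
mechanosensory envelope (600 ms full rise vs the standard 50 ms pulses)
it means the global LN population effectively receives its mechanosensory
drive right after each pulse ends, so fast LN inhibition cannot smother
the PN onset burst, while the delayed surge of LN activity -- acting
through the slowly accumulating inhibitory synapses -- truncates PN
firing between pulses.  That delayed global inhibition is what makes
mechanosensory responses brief and able to follow fast pulse trains.

Envelope tails of earlier pulses persist and superpose across later pulses;
this superposition is what degrades tracking of high-frequency trains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import LN, PN, Network
from .params import ConfigError, NetworkParams

__all__ = [
    "PulseSchedule", "StimulusProtocol", "InputTrain",
    "odor_envelope", "mech_envelope", "total_rate",
    "rate_matrix", "sample_counts", "sample_input_train",
    "SCENARIOS",
]

# Envelope time constants (ms).
ODOR_RISE_PN = 35.0
MECH_RISE_LN = 300.0
ENV_DECAY = 384.0

SCENARIOS = ("background", "odor_only", "mech_only", "additive")


@dataclass(frozen=True)
class PulseSchedule:
    """A sorted sequence of stimulus pulses given as (t_on, t_off) pairs, ms."""

    t_on: tuple[float, ...]
    t_off: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.t_on) != len(self.t_off):
            raise ConfigError("t_on and t_off must have equal length")
        for a, b in zip(self.t_on, self.t_off):
            if not a < b:
                raise ConfigError(f"pulse with t_on={a} >= t_off={b}")
        ons = np.asarray(self.t_on)
        if (np.diff(ons) <= 0).any():
            raise ConfigError("pulse onsets must be strictly increasing")
        # Pulses themselves may not overlap (envelope tails may).
        if any(self.t_off[i] > self.t_on[i + 1] for i in range(len(ons) - 1)):
            raise ConfigError("pulses overlap in onset order")

    @classmethod
    def single(cls, t_on: float, length_ms: float) -> "PulseSchedule":
        return cls((t_on,), (t_on + length_ms,))

    @classmethod
    def train(cls, t_first: float, frequency_hz: float, n_pulses: int,
              pulse_ms: float = 50.0) -> "PulseSchedule":
        """Regular pulse train: onsets every 1000/frequency ms."""
        if frequency_hz <= 0 or n_pulses < 1:
            raise ConfigError("frequency_hz must be > 0 and n_pulses >= 1")
        period = 1000.0 / frequency_hz
        if pulse_ms > period:
            raise ConfigError(
                f"pulse_ms={pulse_ms} exceeds period {period:.1f} ms")
        ons = tuple(t_first + k * period for k in range(n_pulses))
        return cls(ons, tuple(t + pulse_ms for t in ons))

    @property
    def n_pulses(self) -> int:
        return len(self.t_on)

    @property
    def pulse_duration(self) -> float:
        """Common pulse duration, ms (requires uniform pulses)."""
        durs = {round(b - a, 9) for a, b in zip(self.t_on, self.t_off)}
        if len(durs) != 1:
            raise ConfigError("schedule has non-uniform pulse durations")
        return durs.pop()

    @property
    def period(self) -> float:
        """Common onset-to-onset period, ms (requires >= 2 regular pulses)."""
        if self.n_pulses < 2:
            raise ConfigError("period undefined for fewer than 2 pulses")
        gaps = np.diff(self.t_on)
        if not np.allclose(gaps, gaps[0]):
            raise ConfigError("schedule is not a regular train")
        return float(gaps[0])


@dataclass(frozen=True)
class StimulusProtocol:
    """Scenario + pulse schedule + per-glomerulus odor gains + duration.

    ``odor_gain`` multiplies lambda_odor_max per glomerulus (standard odor
    paradigm: gain 1 for glomeruli 0-2, 0 elsewhere); the mechanosensory
    component is active iff the scenario includes it, and is global.
    """

    scenario: str
    schedule: PulseSchedule
    odor_gain: tuple[float, ...]
    duration: float

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"scenario must be one of {SCENARIOS}, got {self.scenario!r}")
        if any(not 0.0 <= g <= 1.0 for g in self.odor_gain):
            raise ConfigError("odor_gain entries must lie in [0, 1]")
        if self.scenario in ("background", "mech_only") and any(
                g != 0.0 for g in self.odor_gain):
            raise ConfigError(
                f"odor_gain must be all zero in the {self.scenario} scenario")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")

    @property
    def mech_active(self) -> bool:
        return self.scenario in ("mech_only", "additive")

    @property
    def odor_active(self) -> bool:
        return self.scenario in ("odor_only", "additive")

    @classmethod
    def make(cls, scenario: str, schedule: PulseSchedule, duration: float,
             n_glomeruli: int = 6,
             odor_glomeruli: Sequence[int] = (0, 1, 2),
             odor_gain: Sequence[float] | None = None) -> "StimulusProtocol":
        """Build a protocol; the standard odor target set is glomeruli 0-2."""
        if odor_gain is not None:
            gains = tuple(float(g) for g in odor_gain)
            if len(gains) != n_glomeruli:
                raise ConfigError("odor_gain must have one entry per glomerulus")
        elif scenario in ("odor_only", "additive"):
            gains = tuple(1.0 if g in set(odor_glomeruli) else 0.0
                          for g in range(n_glomeruli))
        else:
            gains = (0.0,) * n_glomeruli
        return cls(scenario, schedule, gains, duration)


@dataclass(frozen=True)
class InputTrain:
    """Per-neuron external event times (ms) and the generating seed."""

    times: tuple[np.ndarray, ...]
    duration: float
    seed: int

    def __post_init__(self) -> None:
        for t in self.times:
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError("event times outside [0, duration]")


def _sigmoid_rise(dt_on: np.ndarray, tau_rise: float) -> np.ndarray:
    z = 5.0 * (dt_on - tau_rise) / tau_rise
    return np.exp(z) / (1.0 + np.exp(z))


def _envelope(t, t_on: float, t_off: float, tau_rise: float | None):
    """Generic pulse envelope: 0 before onset; sigmoidal rise (or plateau
    1 once complete) while the pulse is on; exponential decay
    e^{-(t - t_off)/384} for all t > t_off, the decay branch starting at
    1 as the piecewise model defines it.  A cell class with instantaneous
    rise has tau_rise None.

    For pulses shorter than the full rise the decay branch makes the
    envelope jump up at offset (see the module docstring for why this
    idealization is kept)."""
    if not t_off > t_on:
        raise ConfigError(f"t_off={t_off} must exceed t_on={t_on}")
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    during = (t >= t_on) & (t <= t_off)
    if tau_rise is None:
        out[during] = 1.0
    else:
        td = t[during]
        out[during] = np.where(td - t_on <= 2.0 * tau_rise,
                               _sigmoid_rise(td - t_on, tau_rise), 1.0)
    after = t > t_off
    out[after] = np.exp(-(t[after] - t_off) / ENV_DECAY)
    return out if out.ndim else float(out)


def odor_envelope(t, t_on: float, t_off: float, cell_class: str):
    """Odor envelope O(t) in [0, 1]: PN sigmoidal rise (35 ms half-rise),
    LN instantaneous rise; exponential decay (384 ms) after offset."""
    tau_rise = ODOR_RISE_PN if cell_class == PN else None
    return _envelope(t, t_on, t_off, tau_rise)


def mech_envelope(t, t_on: float, t_off: float, cell_class: str):
    """Mechanosensory envelope M(t): PN instantaneous rise, LN sigmoidal
    rise (300 ms half-rise); exponential decay (384 ms) after offset."""
    tau_rise = MECH_RISE_LN if cell_class == LN else None
    return _envelope(t, t_on, t_off, tau_rise)


def total_rate(cell_class: str, glomerulus: int, t,
               protocol: StimulusProtocol,
               params: NetworkParams | None = None):
    """Total external Poisson rate lambda_tot (spikes/ms) for one cell.

    Background plus, for every scheduled pulse, the odor term (scaled by
    the cell's glomerular gain) and the mechanosensory term (if active);
    envelope tails from earlier pulses are summed.
    """
    params = params or NetworkParams()
    t = np.asarray(t, dtype=float)
    rate = np.full_like(t, params.lambda_back)
    gain = protocol.odor_gain[glomerulus]
    for t_on, t_off in zip(protocol.schedule.t_on, protocol.schedule.t_off):
        if protocol.odor_active and gain > 0:
            rate = rate + gain * params.lambda_odor_max * odor_envelope(
                t, t_on, t_off, cell_class)
        if protocol.mech_active:
            rate = rate + params.lambda_mech_max * mech_envelope(
                t, t_on, t_off, cell_class)
    return rate if rate.ndim else float(rate)


def rate_matrix(network: Network, protocol: StimulusProtocol,
                dt: float = 0.1) -> np.ndarray:
    """Per-neuron rate lambda_tot on the integration grid.

    Returns an array of shape (n_steps, n_neurons); row k holds the rate at
    bin start time k*dt.  Envelope sums are evaluated once per cell class
    and broadcast across neurons (cells differ only via class and gain).
    """
    p = network.params
    n_steps = int(round(protocol.duration / dt))
    t = np.arange(n_steps) * dt

    osum = {c: np.zeros(n_steps) for c in (PN, LN)}
    msum = {c: np.zeros(n_steps) for c in (PN, LN)}
    for t_on, t_off in zip(protocol.schedule.t_on, protocol.schedule.t_off):
        for c in (PN, LN):
            if protocol.odor_active:
                osum[c] += odor_envelope(t, t_on, t_off, c)
            if protocol.mech_active:
                msum[c] += mech_envelope(t, t_on, t_off, c)

    gains = np.asarray(protocol.odor_gain)[network.glomerulus]
    rates = np.empty((n_steps, network.n_neurons))
    cls = np.array([PN] * network.n_PN + [LN] * network.n_LN)
    for c in (PN, LN):
        cols = np.flatnonzero(cls == c)
        rates[:, cols] = (p.lambda_back
                          + p.lambda_odor_max * osum[c][:, None] * gains[cols]
                          + p.lambda_mech_max * msum[c][:, None])
    if (rates < 0).any():
        raise RuntimeError("negative stimulus rate (envelope bug)")
    return rates


def sample_counts(rates: np.ndarray, dt: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Poisson event count per (step, neuron) bin with mean rate*dt."""
    return rng.poisson(rates * dt).astype(np.int16)


def sample_input_train(rate_fn, duration: float, dt: float,
                       seed: int) -> InputTrain:
    """Realize one cell's Poisson input train on the integration grid.

    ``rate_fn(t)`` gives the rate (spikes/ms) at the bin-start times; a
    Poisson count with mean rate*dt is drawn per bin and that many events
    are placed at the bin start.  Reproducible per seed.
    """
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    rates = np.asarray(rate_fn(t), dtype=float)
    if rates.shape != t.shape:
        rates = np.broadcast_to(rates, t.shape).astype(float)
    if (rates < 0).any():
        raise RuntimeError("negative stimulus rate (envelope bug)")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates * dt)
    times = np.repeat(t, counts)
    return InputTrain((times,), duration, seed)
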