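"""Response metrics: response length, response slope, pulse-following
index, pulse-following rate, and trial aggregation.

The pulse-following index quantifies how well a spike raster tracks a
periodic pulse train.  The raster (one PN's train per trial, or the
pooled trains of a glomerulus) is binned from the first pulse onset and
the correlogram of the trial-pooled raster is evaluated -- restricted to
its cross-trial terms, so that only modulation locked to the pulse train
survives while rhythms with trial-random phase cancel.  The index is the
correlogram peak near the period lag minus the trough at the lags between
bursts, floored at 0.  Tonic firing scores ~0; a raster that bursts once
per pulse scores high.  A cell's pulse-following rate is the highest pulse
frequency at which its index stays at or above the 0.05 cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import PulseSchedule

__all__ = ["MetricSeries", "response_length", "response_slope",
           "pulse_following_index", "pulse_following_rate",
           "firing_rate_curve", "suppression_duration"]

DEFAULT_BIN_MS = 5.0
DEFAULT_CUTOFF = 0.05


@dataclass(frozen=True)
class MetricSeries:
    """Metric values on a grid of an independent variable, over trials.

    ``values`` has shape (len(x), n_trials); ``mean``/``sd`` are per-x
    trial statistics.  ``x_name`` documents the grid (pulse length ms,
    pulse frequency Hz, conductance multiplier, ...).
    """

    x: np.ndarray
    values: np.ndarray
    x_name: str = "x"
    metric_name: str = "value"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[0] != x.size:
            raise ValueError("values must have one row per grid point")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "values", v)

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=1)

    @property
    def sd(self) -> np.ndarray:
        return self.values.std(axis=1, ddof=1 if self.n_trials > 1 else 0)

    def tidy_frame(self) -> pd.DataFrame:
        """Long-format (x, trial, value) table."""
        nx, nt = self.values.shape
        return pd.DataFrame({
            self.x_name: np.repeat(self.x, nt),
            "trial": np.tile(np.arange(nt), nx),
            self.metric_name: self.values.ravel(),
        })

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.x_name: self.x, "mean": self.mean, "sd": self.sd,
            "n": self.n_trials,
        })


def response_length(spike_times: np.ndarray, stim_onset: float) -> float:
    """Duration (ms) of the spiking response that follows stimulus onset.

    Spikes at or after ``stim_onset`` form the induced train.  The response
    ends at the spike preceding the first interspike interval strictly
    exceeding three times the mean of the train's first three ISIs (or at
    the last spike if none does); the length is end minus first spike time.
    Trains with fewer than four spikes fall back to last minus first spike
    (0 for at most one spike), keeping the metric continuous as spiking
    fades in sweeps.
    """
    t = np.sort(np.asarray(spike_times, dtype=float))
    t = t[t >= stim_onset]
    if t.size <= 1:
        return 0.0
    if t.size < 4:
        return float(t[-1] - t[0])
    isis = np.diff(t)
    threshold = 3.0 * isis[:3].mean()
    over = np.flatnonzero(isis > threshold)
    end = t[over[0]] if over.size else t[-1]
    return float(end - t[0])


def response_slope(pulse_lengths: Sequence[float],
                   response_lengths: Sequence[float]) -> float:
    """OLS slope of response length against pulse length (dimensionless).

    ~1 means the response duration faithfully encodes pulse duration;
    ~0 means it carries no pulse-length information.
    """
    x = np.asarray(pulse_lengths, dtype=float)
    y = np.asarray(response_lengths, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 grid points for a slope")
    if np.ptp(x) == 0:
        raise ValueError("pulse lengths are all equal; slope undefined")
    return float(stats.linregress(x, y).slope)


def _binned_acf(counts: np.ndarray) -> np.ndarray:
    """Normalized, mean-subtracted autocorrelation (acf[0] = 1)."""
    x = counts.astype(float) - counts.mean()
    denom = float(x @ x)
    if denom == 0.0:
        return np.zeros(counts.size)
    full = np.correlate(x, x, mode="full")
    return full[counts.size - 1:] / denom


def _as_trial_list(trains) -> list[list[np.ndarray]]:
    """Normalize input to a list of trials, each a list of spike arrays
    that are pooled before binning."""
    if isinstance(trains, np.ndarray):
        return [[trains]]
    trains = list(trains)
    if trains and isinstance(trains[0], np.ndarray):
        return [[t] for t in trains]
    return [list(t) for t in trains]


def _binned_counts(trains, schedule: PulseSchedule, bin_ms: float,
                   window_end: float | None = None) -> np.ndarray:
    """Per-trial binned spike counts (n_trials, n_bins), binned from the
    first pulse onset to ``window_end`` (default: last onset plus one
    period); each trial's spike arrays are pooled."""
    trial_list = _as_trial_list(trains)
    t0 = schedule.t_on[0]
    t1 = (window_end if window_end is not None
          else schedule.t_on[-1] + schedule.period)
    n_bins = int(round((t1 - t0) / bin_ms))
    if n_bins < 4:
        raise ValueError("analysis window shorter than 4 bins")
    rows = []
    for trial in trial_list:
        pooled = np.concatenate([np.asarray(t, dtype=float) for t in trial]
                                or [np.empty(0)])
        pooled = pooled[(pooled >= t0) & (pooled < t1)]
        counts, _ = np.histogram(pooled, bins=n_bins,
                                 range=(t0, t0 + n_bins * bin_ms))
        rows.append(counts)
    return np.vstack(rows)


def raster_acf(trains, schedule: PulseSchedule,
               bin_ms: float = DEFAULT_BIN_MS,
               window_end: float | None = None) -> np.ndarray:
    """Per-trial normalized autocorrelations of the binned raster.

    Returns an array (n_trials, n_bins); trials with no spikes
    contribute an all-zero row.
    """
    counts = _binned_counts(trains, schedule, bin_ms, window_end)
    return np.vstack([_binned_acf(c) for c in counts])


def _acf_windows(period: float, pulse_ms: float, bin_ms: float,
                 n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag-bin index windows for the ACF peak (around the pulse period)
    and trough (between bursts)."""
    w = max(min(pulse_ms, period / 2.0 - bin_ms), bin_ms)
    lags = np.arange(n_bins) * bin_ms
    peak = np.flatnonzero((lags >= period - w) & (lags <= period + w))
    trough = np.flatnonzero((lags >= w) & (lags <= period - w))
    if trough.size == 0:
        trough = np.array([int(round(period / 2.0 / bin_ms))])
    if peak.size == 0:
        raise ValueError("raster window too short to reach the pulse period")
    return peak, trough


def pulse_following_index(trains, schedule: PulseSchedule,
                          bin_ms: float = DEFAULT_BIN_MS,
                          window_end: float | None = None,
                          pulse_ms: float | None = None,
                          return_trials: bool = False):
    """Autocorrelation peak-minus-trough pulse-tracking index (>= 0).

    ``trains`` is a single spike-time array, a list of per-trial arrays,
    or a list of trials each holding several arrays to pool (e.g. the PNs
    of one glomerulus).  Each trial's raster is binned from the first
    pulse onset and z-scored; the correlogram is the mean cross-trial
    correlation over distinct trial pairs (symmetrized over lag sign) --
    exactly the cross terms of the trial-pooled raster's autocorrelation.
    Pooling across trials isolates stimulus-locked periodicity: firing
    rhythms with trial-random phase (e.g. intrinsic adaptation cycles)
    cancel, and only modulation locked to the pulse train survives.  The
    index is the correlogram's peak within one pulse duration of the
    period lag minus its trough at the intermediate lags (between
    bursts), floored at 0.  With a single trial the plain within-trial
    autocorrelation is used.  With ``return_trials`` the per-trial
    contributions at the selected lags (trial i vs the rest) are
    returned; their mean equals the unfloored index.  Empty rasters
    give 0.
    """
    period = schedule.period  # requires >= 2 regular pulses
    if period <= 2.0 * bin_ms:
        raise ValueError(
            f"period {period} ms unresolvable at bin {bin_ms} ms")
    if pulse_ms is None:
        pulse_ms = schedule.pulse_duration
    counts = _binned_counts(trains, schedule, bin_ms, window_end)
    n_trials, n_bins = counts.shape
    # z-score per trial; silent/constant trials contribute zero vectors
    mu = counts.mean(axis=1, keepdims=True)
    sd = counts.std(axis=1, keepdims=True)
    x = np.where(sd > 0, (counts - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    if n_trials == 1:
        full = np.correlate(x[0], x[0], mode="full")
        curves = full[None, n_bins - 1:] / n_bins
    else:
        total = x.sum(axis=0)
        curves = np.empty((n_trials, n_bins))
        for i in range(n_trials):
            full = np.correlate(x[i], total - x[i], mode="full")
            sym = 0.5 * (full[n_bins - 1:] + full[n_bins - 1::-1])
            curves[i] = sym / n_bins / (n_trials - 1)
    mean_curve = curves.mean(axis=0)
    peak_w, trough_w = _acf_windows(period, pulse_ms, bin_ms, n_bins)
    peak_lag = peak_w[np.argmax(mean_curve[peak_w])]
    trough_lag = trough_w[np.argmin(mean_curve[trough_w])]
    per_trial = curves[:, peak_lag] - curves[:, trough_lag]
    index = float(max(0.0, per_trial.mean()))
    if return_trials:
        return index, per_trial
    return index


def pulse_following_rate(frequencies_hz: Sequence[float] | MetricSeries,
                         mean_indices: Sequence[float] | None = None,
                         cutoff: float = DEFAULT_CUTOFF) -> float:
    """Highest tested frequency (Hz) whose mean index >= cutoff; 0 if none.

    Accepts a MetricSeries (frequency grid + per-trial indices) or two
    parallel sequences.  Frequencies must be sorted ascending.  A value
    exactly at the cutoff counts as following.
    """
    if isinstance(frequencies_hz, MetricSeries):
        freqs = frequencies_hz.x
        idx = frequencies_hz.mean
    else:
        freqs = np.asarray(frequencies_hz, dtype=float)
        idx = np.asarray(mean_indices, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if (np.diff(freqs) <= 0).any():
        raise ValueError("frequencies must be sorted ascending")
    passing = np.flatnonzero(idx >= cutoff)
    return float(freqs[passing[-1]]) if passing.size else 0.0


def firing_rate_curve(trains: Sequence[np.ndarray], t_eval: np.ndarray,
                      window_ms: float = 200.0) -> np.ndarray:
    """Trial-averaged firing rate (spikes/s) in a sliding window.

    The rate at t is the pooled spike count in [t, t + window) divided by
    (window * n_trials).
    """
    pooled = np.sort(np.concatenate([np.asarray(t) for t in trains]
                                    or [np.empty(0)]))
    lo = np.searchsorted(pooled, t_eval)
    hi = np.searchsorted(pooled, t_eval + window_ms)
    return (hi - lo) / (window_ms / 1000.0) / max(len(trains), 1)


def suppression_duration(trains: Sequence[np.ndarray], final_offset: float,
                         baseline_window: tuple[float, float],
                         window_ms: float = 200.0,
                         recovery_tol: float = 0.1,
                         t_max: float | None = None) -> float:
    """Duration (ms) of post-train firing suppression (the AHP phase).

    ``trains`` are one probe neuron's spike times over trials.  The
    baseline rate is the mean rate over ``baseline_window`` (which must
    cover equilibrated pre-stimulus activity -- the slow-inhibition
    conductance needs a few times its 750 ms decay constant to reach
    steady state).  After the final pulse offset the decaying stimulus
    tail still drives firing above baseline; the suppressed phase begins
    when the trial-averaged rate (non-overlapping ``window_ms`` windows)
    first drops below baseline and ends at the first *sustained* return
    to baseline (two consecutive windows within ``recovery_tol`` of it,
    so a single noisy window cannot terminate the phase, and hovering at
    baseline counts as recovered).  The returned duration runs from
    ``final_offset`` to that recovery time (stimulus-decay phase plus
    suppressed phase); it extends to the end of the available window if
    the rate never recovers.
    """
    b0, b1 = baseline_window
    if b1 - b0 < window_ms:
        raise ValueError("baseline window shorter than the rate window")
    n_tr = max(len(trains), 1)
    pooled = np.concatenate([np.asarray(t) for t in trains] or [np.empty(0)])
    n_base = ((pooled >= b0) & (pooled < b1)).sum()
    baseline = n_base / ((b1 - b0) / 1000.0) / n_tr
    if t_max is None:
        t_max = max((np.max(t) for t in trains if len(t)), default=final_offset)
    te = np.arange(final_offset, t_max - window_ms + 1e-9, window_ms)
    if te.size == 0:
        return 0.0
    rates = firing_rate_curve(trains, te, window_ms)
    below = np.flatnonzero(rates < baseline)
    if below.size == 0:
        return 0.0  # never suppressed
    recovered = rates >= baseline * (1.0 - recovery_tol)
    for j in range(below[0], rates.size):
        if recovered[j] and (j + 1 >= rates.size or recovered[j + 1]):
            return float(te[j] - final_offset)
    return float(te[-1] + window_ms - final_offset)
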