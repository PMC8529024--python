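"""Model constants for the antennal-lobe network.

All scalars of the reduced integrate-and-fire model live in one validated,
immutable record (:class:`NetworkParams`).  Voltages are non-dimensional
(leak/reset at 0, spike threshold at 1, excitatory reversal 14/3,
inhibitory reversal -2/3); times are in milliseconds; Poisson input rates
are in spikes per millisecond; conductances carry units of 1/ms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["NetworkParams", "ConfigError"]


class ConfigError(ValueError):
    """Invalid model or experiment configuration (names the offending field)."""


@dataclass(frozen=True)
class NetworkParams:
    """Every scalar constant of the neuron model, network and stimulus.

    Defaults are the standard operating point of the model; the ``scale_*``
    multipliers implement the conductance-strength sweeps (a value of 1 is
    the standard strength).
    """

    # --- membrane ---
    tau_V: float = 20.0          # leak time constant, ms
    V_L: float = 0.0             # leak/reset potential (non-dimensional)
    V_thres: float = 1.0         # spike threshold
    tau_ref: float = 2.0         # refractory period, ms
    V_exc: float = 14.0 / 3.0    # excitatory reversal
    V_stim: float = 14.0 / 3.0   # stimulus reversal
    V_inh: float = -2.0 / 3.0    # inhibitory reversal
    V_SK: float = -2.0 / 3.0     # SK (potassium) reversal

    # --- synaptic coupling strengths (post-cell class selects the value) ---
    S_PN_to_PN: float = 0.01     # PN -> PN excitation
    S_PN_to_LN: float = 0.006    # PN -> LN excitation
    S_inh_PN: float = 0.0169     # fast (GABA_A-like) inhibition onto PNs
    S_inh_LN: float = 0.015      # fast inhibition onto LNs
    S_slow_PN: float = 0.0338    # slow (GABA_B-like) inhibition onto PNs
    S_slow_LN: float = 0.04      # slow inhibition onto LNs
    S_stim_PN: float = 0.004     # external-input jump onto PNs
    S_stim_LN: float = 0.0031    # external-input jump onto LNs

    # --- kernel time constants ---
    tau_exc: float = 2.0         # ms
    tau_inh: float = 2.0         # ms
    tau_stim: float = 2.0        # ms
    tau_slow: float = 750.0      # ms
    tau_SK: float = 250.0        # SK decay, ms
    tau_SK_rise: float = 25.0    # SK sigmoidal half-rise, ms

    # --- SK strength distribution across PNs ---
    SK_mu: float = 0.5
    SK_sigma: float = 0.2

    # --- architecture ---
    n_glomeruli: int = 6
    n_PN_per_glom: int = 10
    n_LN_per_glom: int = 6

    # --- connection probabilities ---
    p_PN_PN: float = 0.75        # intra-glomerular
    p_PN_LN: float = 0.75        # intra-glomerular
    p_LN_PN_intra: float = 0.38
    p_LN_LN: float = 0.25        # intra-glomerular
    p_LN_PN_cross: float = 0.38  # the only cross-glomerular synapse class

    # --- external Poisson input rates, spikes/ms ---
    lambda_back: float = 3.6
    lambda_odor_max: float = 3.6
    lambda_mech_max: float = 1.8

    # --- sweep multipliers (1 = standard strength) ---
    scale_SK: float = 1.0
    scale_inh: float = 1.0
    scale_slow: float = 1.0
    scale_exc: float = 1.0
    scale_stim: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_V", "tau_ref", "tau_exc", "tau_inh", "tau_stim",
                     "tau_slow", "tau_SK", "tau_SK_rise"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("p_PN_PN", "p_PN_LN", "p_LN_PN_intra", "p_LN_LN",
                     "p_LN_PN_cross"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        for name in ("lambda_back", "lambda_odor_max", "lambda_mech_max",
                     "SK_sigma", "scale_SK", "scale_inh", "scale_slow",
                     "scale_exc", "scale_stim"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("n_glomeruli", "n_PN_per_glom", "n_LN_per_glom"):
            n = getattr(self, name)
            if not isinstance(n, int) or n <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {n}")
        if not self.V_L < self.V_thres < self.V_exc:
            raise ConfigError(
                f"require V_L < V_thres < V_exc, got {self.V_L}, "
                f"{self.V_thres}, {self.V_exc}")
        if not self.V_inh < self.V_L:
            raise ConfigError(f"require V_inh < V_L, got V_inh={self.V_inh}")

    # --- derived sizes ---
    @property
    def n_PN(self) -> int:
        return self.n_glomeruli * self.n_PN_per_glom

    @property
    def n_LN(self) -> int:
        return self.n_glomeruli * self.n_LN_per_glom

    @property
    def n_neurons(self) -> int:
        return self.n_PN + self.n_LN

    def replace(self, **changes: Any) -> "NetworkParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "NetworkParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkParams":
        """Load parameters from a YAML document mirroring the field names."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: expected a mapping of parameter names")
        return cls.from_dict(doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
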