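"""Network realization: neurons, frozen random connectivity, SK strengths.

Neuron indexing convention used throughout the package: PNs occupy global
ids ``0 .. n_PN-1`` (glomerulus-major: PNs of glomerulus g are
``g*n_PN_per_glom .. (g+1)*n_PN_per_glom - 1``), followed by LNs
``n_PN .. n_PN+n_LN-1`` in the same glomerulus-major order.

Connectivity rules: PN->PN, PN->LN and LN->LN synapses exist only within a
glomerulus; LN->PN synapses exist both within (p_LN_PN_intra) and across
(p_LN_PN_cross) glomeruli.  Each ordered candidate pair is drawn
independently; autapses are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ConfigError, NetworkParams

__all__ = ["Network", "build_network", "fixed_sk_network"]

PN, LN = "PN", "LN"


@dataclass(frozen=True)
class Network:
    """A realized (and thereafter frozen) antennal-lobe network.

    Adjacency maps are boolean, presynaptic x postsynaptic, indexed by
    within-class indices (PN index 0..n_PN-1, LN index 0..n_LN-1).
    ``sk_strength`` holds the per-PN SK coupling S_SK (>= 0), drawn from
    N(SK_mu, SK_sigma) and clamped at zero, or fixed to SK_mu * scale_SK
    for the fixed-SK variant.
    """

    params: NetworkParams
    seed: int
    glom_PN: np.ndarray       # (n_PN,) glomerulus index per PN
    glom_LN: np.ndarray       # (n_LN,) glomerulus index per LN
    a_PN_PN: np.ndarray       # (n_PN, n_PN) bool
    a_PN_LN: np.ndarray       # (n_PN, n_LN) bool
    a_LN_PN: np.ndarray       # (n_LN, n_PN) bool
    a_LN_LN: np.ndarray       # (n_LN, n_LN) bool
    sk_strength: np.ndarray   # (n_PN,) float, >= 0

    def __post_init__(self) -> None:
        p = self.params
        if self.glom_PN.shape != (p.n_PN,) or self.glom_LN.shape != (p.n_LN,):
            raise ValueError("glomerulus label arrays have wrong shape")
        if (self.sk_strength < 0).any():
            raise ValueError("sk_strength entries must be >= 0")
        for arr in (self.a_PN_PN, self.a_PN_LN, self.a_LN_PN, self.a_LN_LN,
                    self.glom_PN, self.glom_LN, self.sk_strength):
            arr.setflags(write=False)

    # --- sizes and id helpers ---
    @property
    def n_PN(self) -> int:
        return self.params.n_PN

    @property
    def n_LN(self) -> int:
        return self.params.n_LN

    @property
    def n_neurons(self) -> int:
        return self.params.n_neurons

    @property
    def is_PN(self) -> np.ndarray:
        """Boolean mask over global neuron ids."""
        out = np.zeros(self.n_neurons, dtype=bool)
        out[: self.n_PN] = True
        return out

    @property
    def glomerulus(self) -> np.ndarray:
        """Glomerulus index per global neuron id."""
        return np.concatenate([self.glom_PN, self.glom_LN])

    def pn_id(self, glom: int, k: int = 0) -> int:
        """Global id of the k-th PN of a glomerulus."""
        if not 0 <= glom < self.params.n_glomeruli:
            raise ConfigError(f"glomerulus index {glom} out of range")
        return glom * self.params.n_PN_per_glom + k

    def pn_ids_of_glom(self, glom: int) -> np.ndarray:
        return np.flatnonzero(self.glom_PN == glom)

    # --- tabular export ---
    def neuron_table(self) -> pd.DataFrame:
        """One row per neuron: id, class, glomerulus, sk_strength (NaN for LNs)."""
        sk = np.full(self.n_neurons, np.nan)
        sk[: self.n_PN] = self.sk_strength
        return pd.DataFrame({
            "id": np.arange(self.n_neurons),
            "cell_class": [PN] * self.n_PN + [LN] * self.n_LN,
            "glomerulus": self.glomerulus,
            "sk_strength": sk,
        })

    def edge_table(self) -> pd.DataFrame:
        """Edge list (pre_id, post_id, synapse_class) over global ids."""
        off = self.n_PN
        blocks = []
        for adj, pre_off, post_off, cls in (
            (self.a_PN_PN, 0, 0, "PN->PN"),
            (self.a_PN_LN, 0, off, "PN->LN"),
            (self.a_LN_PN, off, 0, "LN->PN"),
            (self.a_LN_LN, off, off, "LN->LN"),
        ):
            pre, post = np.nonzero(adj)
            blocks.append(pd.DataFrame({
                "pre_id": pre + pre_off,
                "post_id": post + post_off,
                "synapse_class": cls,
            }))
        return pd.concat(blocks, ignore_index=True)

    def to_csv(self, directory: str | Path) -> None:
        """Write ``neurons.csv`` and ``edges.csv`` into a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.neuron_table().to_csv(directory / "neurons.csv", index=False)
        self.edge_table().to_csv(directory / "edges.csv", index=False)


def _glom_labels(n_glom: int, per_glom: int) -> np.ndarray:
    return np.repeat(np.arange(n_glom), per_glom)


def _draw_adjacency(params: NetworkParams, rng: np.random.Generator):
    glom_PN = _glom_labels(params.n_glomeruli, params.n_PN_per_glom)
    glom_LN = _glom_labels(params.n_glomeruli, params.n_LN_per_glom)
    same_pp = glom_PN[:, None] == glom_PN[None, :]
    same_pl = glom_PN[:, None] == glom_LN[None, :]
    same_lp = glom_LN[:, None] == glom_PN[None, :]
    same_ll = glom_LN[:, None] == glom_LN[None, :]
    no_aut_pp = ~np.eye(params.n_PN, dtype=bool)
    no_aut_ll = ~np.eye(params.n_LN, dtype=bool)

    # Fixed draw order => reproducibility for a given (params, seed).
    a_PN_PN = (rng.random(same_pp.shape) < params.p_PN_PN) & same_pp & no_aut_pp
    a_PN_LN = (rng.random(same_pl.shape) < params.p_PN_LN) & same_pl
    p_lp = np.where(same_lp, params.p_LN_PN_intra, params.p_LN_PN_cross)
    a_LN_PN = rng.random(same_lp.shape) < p_lp
    a_LN_LN = (rng.random(same_ll.shape) < params.p_LN_LN) & same_ll & no_aut_ll
    return glom_PN, glom_LN, a_PN_PN, a_PN_LN, a_LN_PN, a_LN_LN


def build_network(params: NetworkParams, seed: int) -> Network:
    """Construct the standard network: random connectivity, Gaussian SK.

    Each candidate synapse is an independent Bernoulli draw with its class
    probability; each PN's S_SK ~ N(SK_mu, SK_sigma) clamped at 0, then
    multiplied by ``scale_SK`` (the SK-strength sweep multiplier is applied
    here, once, so ``sk_strength`` is the effective coupling used by the
    simulator).  Identical (params, seed) yields a byte-identical network.
    """
    if seed < 0:
        raise ConfigError(f"seed must be non-negative, got {seed}")
    rng = np.random.default_rng(seed)
    glom_PN, glom_LN, *adj = _draw_adjacency(params, rng)
    sk = np.clip(rng.normal(params.SK_mu, params.SK_sigma, params.n_PN), 0.0, None)
    sk *= params.scale_SK
    return Network(params, seed, glom_PN, glom_LN, *adj, sk_strength=sk)


def fixed_sk_network(params: NetworkParams, seed: int) -> Network:
    """As :func:`build_network`, but every PN gets S_SK = SK_mu * scale_SK.

    Used for the conductance-strength sweeps of the pulse-following rate,
    where SK strength is uniform across PNs and the standard value is the
    mean of the Gaussian used in the standard network.
    """
    if seed < 0:
        raise ConfigError(f"seed must be non-negative, got {seed}")
    rng = np.random.default_rng(seed)
    glom_PN, glom_LN, *adj = _draw_adjacency(params, rng)
    sk = np.full(params.n_PN, params.SK_mu * params.scale_SK)
    return Network(params, seed, glom_PN, glom_LN, *adj, sk_strength=sk)
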