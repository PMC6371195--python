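"""Network topology builders: dense recurrent nets and 3-D LSM reservoirs.

Two topologies are used by the experiments:

* a fully connected recurrent network (every ordered pair of distinct
  neurons connected) with i.i.d. uniform weights and a sparse, strong
  (+/-8) input wiring — the setting for the 100-neuron network run;
* a liquid-state-machine reservoir on an integer 3-D grid, where the
  probability of a synapse from neuron a to b is
  ``C_base[type(a)type(b)] * exp(-(D(a,b)/lambda)^2)`` with Euclidean
  grid distance D, an 80/20 excitatory/inhibitory split, and fixed
  weights +1 (E source) / -1 (I source).

Self-connections are excluded in both builders, and "fully connected" is
read as all ordered (directed) pairs.  Everything is reproducible from
(spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frtf import NeuronParams
from .sim import Network

__all__ = ["ReservoirSpec", "build_lsm_reservoir", "build_dense_network",
           "network_to_csv", "network_from_csv"]

_SYN_TYPES = ("EE", "EI", "IE", "II")


@dataclass(frozen=True)
class ReservoirSpec:
    """Parameters of the distance-dependent LSM reservoir.

    nx, ny, nz : grid dimensions (one neuron per grid point);
    lam : connectivity length scale lambda in grid units;
    c_base : base connection probability per synapse type, keyed
    'EE'/'EI'/'IE'/'II' (first letter = presynaptic type);
    excitatory_fraction : probability a neuron is excitatory;
    w_fixed : fixed synaptic weight per type;
    n_inputs / input_fanout / input_weight : each input channel is wired
    to ``input_fanout`` distinct reservoir neurons (sampled without
    replacement) with weight +/- input_weight, sign equiprobable.
    """

    nx: int = 3
    ny: int = 3
    nz: int = 5
    lam: float = 3.0
    c_base: dict = field(default_factory=lambda: {"EE": 0.3, "EI": 0.2, "IE": 0.4, "II": 0.1})
    excitatory_fraction: float = 0.8
    w_fixed: dict = field(default_factory=lambda: {"EE": 1.0, "EI": 1.0, "IE": -1.0, "II": -1.0})
    n_inputs: int = 30
    input_fanout: int = 16
    input_weight: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("grid dimensions must be positive")
        if not 0 <= self.excitatory_fraction <= 1:
            raise ValueError("excitatory_fraction must be in [0, 1]")
        for t in _SYN_TYPES:
            if t not in self.c_base:
                raise ValueError(f"c_base missing synapse type {t}")
            if not 0 <= self.c_base[t] <= 1:
                raise ValueError(f"c_base[{t}] must be a probability")
            if t not in self.w_fixed:
                raise ValueError(f"w_fixed missing synapse type {t}")
        if self.input_fanout > self.nx * self.ny * self.nz:
            raise ValueError("input_fanout exceeds reservoir size")

    @property
    def n(self) -> int:
        return self.nx * self.ny * self.nz


def build_lsm_reservoir(spec: ReservoirSpec, params: NeuronParams | None = None) -> Network:
    """Build the 3-D grid reservoir with distance-dependent connectivity.

    Neurons sit on the integer grid (0-based coordinates); each ordered
    pair (a, b), a != b, is connected with probability
    ``c_base[type] * exp(-(D(a,b)/lam)**2)``.  All outgoing weights of an
    excitatory neuron are positive, of an inhibitory one negative.
    """
    if params is None:
        params = NeuronParams()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    grid = np.indices((spec.nx, spec.ny, spec.nz)).reshape(3, -1).T.astype(float)
    is_exc = rng.random(n) < spec.excitatory_fraction

    # pairwise squared Euclidean distance in grid units
    d2 = np.sum((grid[:, None, :] - grid[None, :, :]) ** 2, axis=-1)
    decay = np.exp(-d2 / spec.lam**2)

    c = np.empty((n, n))
    w = np.empty((n, n))
    for pre_exc in (True, False):
        for post_exc in (True, False):
            t = ("E" if pre_exc else "I") + ("E" if post_exc else "I")
            mask = np.outer(is_exc == pre_exc, is_exc == post_exc)
            c[mask] = spec.c_base[t]
            w[mask] = spec.w_fixed[t]
    # c[a, b] is the probability of a synapse from a (pre, row) to b (post)
    prob = c * decay
    connected = rng.random((n, n)) < prob
    np.fill_diagonal(connected, False)
    # Network convention is w_rec[post, pre], so transpose the pre-major draw
    w_rec = (connected * w).T

    w_in = np.zeros((n, spec.n_inputs))
    for j in range(spec.n_inputs):
        targets = rng.choice(n, size=spec.input_fanout, replace=False)
        signs = rng.choice([-1.0, 1.0], size=spec.input_fanout)
        w_in[targets, j] = signs * spec.input_weight

    return Network(
        w_rec=w_rec, w_in=w_in, params=params, is_excitatory=is_exc,
        positions=grid,
        meta={"builder": "lsm", "seed": spec.seed,
              "spec": {k: (dict(v) if isinstance(v, dict) else v)
                       for k, v in spec.__dict__.items()}},
    )


def build_dense_network(
    n: int = 100,
    weight_range: tuple[float, float] = (-1.0, 1.0),
    n_inputs: int = 30,
    input_fanout: int = 30,
    input_weight: float = 8.0,
    seed: int = 0,
    params: NeuronParams | None = None,
) -> Network:
    """Fully connected recurrent network with U(weight_range) synapses.

    All n*(n-1) ordered pairs are connected (no self-connections); each
    input channel is wired to ``input_fanout`` distinct neurons with
    weight +/- input_weight, sign equiprobable.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = NeuronParams()
    rng = np.random.default_rng(seed)
    w_rec = rng.uniform(*weight_range, size=(n, n))
    np.fill_diagonal(w_rec, 0.0)

    w_in = np.zeros((n, n_inputs))
    for j in range(n_inputs):
        targets = rng.choice(n, size=input_fanout, replace=False)
        signs = rng.choice([-1.0, 1.0], size=input_fanout)
        w_in[targets, j] = signs * input_weight

    return Network(
        w_rec=w_rec, w_in=w_in, params=params,
        is_excitatory=np.ones(n, dtype=bool),
        meta={"builder": "dense", "seed": seed, "n": n,
              "weight_range": list(weight_range), "n_inputs": n_inputs,
              "input_fanout": input_fanout, "input_weight": input_weight},
    )


def network_to_csv(net: Network, edge_path, header_path) -> None:
    """Serialize a network: edge-list CSV + JSON header.

    Edge list columns: (pre_id, post_id, weight, type) where type is
    'rec' for recurrent and 'in' for input synapses; the JSON header
    carries the builder metadata, seed, and shared neuron parameters.
    """
    post, pre = np.nonzero(net.w_rec)
    rows = pd.DataFrame({
        "pre_id": pre, "post_id": post,
        "weight": net.w_rec[post, pre], "type": "rec",
    })
    post_i, pre_i = np.nonzero(net.w_in)
    rows_in = pd.DataFrame({
        "pre_id": pre_i, "post_id": post_i,
        "weight": net.w_in[post_i, pre_i], "type": "in",
    })
    pd.concat([rows, rows_in], ignore_index=True).to_csv(edge_path, index=False)

    header = {
        "n": net.n, "n_in": net.n_in,
        "is_excitatory": net.is_excitatory.astype(int).tolist(),
        "params": {"v_th": net.params.v_th, "t_r": net.params.t_r,
                   "r": net.params.r, "tau_m": net.params.tau_m,
                   "bounds_r": list(net.params.bounds_r),
                   "bounds_tau": list(net.params.bounds_tau)},
        "meta": net.meta,
    }
    with open(header_path, "w") as fh:
        json.dump(header, fh, indent=1)


def network_from_csv(edge_path, header_path) -> Network:
    """Rebuild a network from its edge-list CSV + JSON header."""
    with open(header_path) as fh:
        header = json.load(fh)
    p = header["params"]
    params = NeuronParams(v_th=p["v_th"], t_r=p["t_r"], r=p["r"], tau_m=p["tau_m"],
                          bounds_r=tuple(p["bounds_r"]), bounds_tau=tuple(p["bounds_tau"]))
    n, n_in = header["n"], header["n_in"]
    w_rec = np.zeros((n, n))
    w_in = np.zeros((n, n_in))
    df = pd.read_csv(edge_path)
    rec = df[df["type"] == "rec"]
    w_rec[rec["post_id"].to_numpy(int), rec["pre_id"].to_numpy(int)] = rec["weight"].to_numpy()
    inp = df[df["type"] == "in"]
    w_in[inp["post_id"].to_numpy(int), inp["pre_id"].to_numpy(int)] = inp["weight"].to_numpy()
    return Network(
        w_rec=w_rec, w_in=w_in, params=params,
        is_excitatory=np.asarray(header["is_excitatory"], dtype=bool),
        meta=header.get("meta", {}),
    )
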