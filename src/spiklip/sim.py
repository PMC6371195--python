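"""Discrete-time LIF neuron and network simulation (1 ms lockstep).

All neuronal activity is evaluated in lockstep on a fixed grid of step
``dt`` (default 1 ms).  The membrane equation tau_m dV/dt = -V + R x is
advanced with its exact solution for piecewise-constant input,

    V <- R x + (V - R x) exp(-dt / tau_m),

so the stepper stays well behaved even when intrinsic plasticity drives
tau_m down toward its lower bound, where forward Euler at dt = 1 ms would
degenerate (Euler remains available for comparison).  On V >= V_th a spike
is emitted, V resets to 0 mV and the membrane is clamped at 0 for the
refractory period t_r.

The continuous-valued output firing rate of a spiking neuron is measured
through an intracellular calcium trace: the concentration jumps by one
unit per output spike and decays with time constant tau_cal, and the rate
estimate is y(t) = C_cal(t) / tau_cal.  The discrete scheme adds the spike
increment and then applies the decay within the same step, which keeps the
estimate strictly below 1 KHz under dt = 1 ms even when the neuron fires
on every step.

Event order within one step: gather synaptic currents -> integrate
membranes -> threshold/reset -> calcium -> intrinsic-plasticity update
(taking effect on the next step).  Recurrent spikes reach their targets on
the following step.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .frtf import NeuronParams
from .ip import IPConfig, VTIPConfig, spikl_ip_update_arrays

__all__ = [
    "SimConfig",
    "NeuronState",
    "SpikeTrain",
    "Network",
    "SimResult",
    "lif_step",
    "calcium_step",
    "poisson_spike_train",
    "synaptic_current",
    "simulate",
    "spike_trains_to_csv",
    "spike_trains_from_csv",
]


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings shared by every stepper.

    dt : step (ms); tau_cal : calcium time constant (ms); tau_syn :
    exponential synaptic-kernel time constant (ms), used only when
    ``kernel == "exp"``; duration (ms); seed for every random draw;
    kernel : spike-to-current conversion ("rect" = one-step rectangular
    pulse of amplitude w mA, "exp" = exponential kernel of amplitude
    w/tau_syn); integrator : "exact" or "euler".
    """

    dt: float = 1.0
    tau_cal: float = 64.0
    tau_syn: float = 4.0
    duration: float = 1000.0
    seed: int = 0
    kernel: str = "rect"
    integrator: str = "exact"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_cal < self.dt:
            raise ValueError("tau_cal must be >= dt")
        if self.kernel not in ("rect", "exp"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.integrator not in ("exact", "euler"):
            raise ValueError(f"unknown integrator {self.integrator!r}")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class NeuronState:
    """Per-neuron dynamic state; fields may be scalars or aligned arrays.

    v : membrane potential (mV), held at 0 while refractory;
    refr_left : remaining refractory time (ms); c_cal : calcium
    concentration (unitless spike accumulation), always >= 0.
    """

    v: float = 0.0
    refr_left: float = 0.0
    c_cal: float = 0.0


def _membrane_update(v, refr_left, x_t, r, tau_m, v_th, t_r, dt, integrator="exact"):
    """Advance membranes one step; returns (v, refr_left, spiked).

    Works elementwise on scalars or arrays.  Refractory neurons are held
    at 0 mV and ignore input while the countdown runs.
    """
    v = np.asarray(v, dtype=float)
    refr_left = np.asarray(refr_left, dtype=float)
    drive = np.asarray(r, dtype=float) * np.asarray(x_t, dtype=float)
    tau_m = np.asarray(tau_m, dtype=float)

    refractory = refr_left > 0
    if integrator == "exact":
        v_new = drive + (v - drive) * np.exp(-dt / tau_m)
    else:  # forward Euler, for comparison only
        v_new = v + (dt / tau_m) * (-v + drive)
    v_new = np.where(refractory, 0.0, v_new)
    refr_new = np.where(refractory, refr_left - dt, 0.0)

    spiked = (~refractory) & (v_new >= v_th)
    v_new = np.where(spiked, 0.0, v_new)
    refr_new = np.where(spiked, t_r, refr_new)
    return v_new, refr_new, spiked.astype(np.int8)


def _calcium_update(c_cal, spiked, dt, tau_cal):
    """Add-then-decay calcium step; returns (c_cal, y)."""
    c_new = (np.asarray(c_cal, dtype=float) + spiked) * np.exp(-dt / tau_cal)
    return c_new, c_new / tau_cal


def lif_step(s: NeuronState, x_t: float, p: NeuronParams, cfg: SimConfig):
    """One membrane step for a single neuron: returns (new state, spiked)."""
    v, refr, spiked = _membrane_update(
        s.v, s.refr_left, x_t, p.r, p.tau_m, p.v_th, p.t_r, cfg.dt, cfg.integrator
    )
    new = NeuronState(v=float(v), refr_left=float(refr), c_cal=s.c_cal)
    return new, int(spiked)


def calcium_step(s: NeuronState, spiked: int, cfg: SimConfig):
    """One calcium-trace step: returns (new state, rate estimate y in KHz)."""
    c_new, y = _calcium_update(s.c_cal, spiked, cfg.dt, cfg.tau_cal)
    new = NeuronState(v=s.v, refr_left=s.refr_left, c_cal=float(c_new))
    return new, float(y)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (ms) of one source on the lockstep grid."""

    times: np.ndarray
    duration: float
    source_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (np.any(np.diff(t) < 0) or t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("spike times must be non-decreasing within [0, duration)")

    def to_dense(self, dt: float = 1.0) -> np.ndarray:
        """0/1 spike-count vector with one bin per dt step."""
        n = int(round(self.duration / dt))
        dense = np.zeros(n, dtype=np.int8)
        idx = np.round(self.times / dt).astype(int)
        np.add.at(dense, idx, 1)
        return dense


def poisson_spike_train(
    rate: float,
    duration: float,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    source_id: int = 0,
) -> SpikeTrain:
    """Poisson spike train at ``rate`` KHz: Bernoulli(rate*dt) per bin.

    Reproducible under a fixed ``cfg.seed`` when no generator is passed.
    Rejects rate*dt > 1 (more than one spike per bin cannot be represented
    on the lockstep grid).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate * cfg.dt > 1:
        raise ValueError(f"rate*dt = {rate * cfg.dt} > 1: unrepresentable on the grid")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(duration / cfg.dt))
    fired = rng.random(n) < rate * cfg.dt
    times = np.nonzero(fired)[0] * cfg.dt
    return SpikeTrain(times=times, duration=duration, source_id=source_id)


def synaptic_current(
    trains: Sequence[SpikeTrain],
    weights: Sequence[float],
    cfg: SimConfig,
    n_steps: Optional[int] = None,
) -> np.ndarray:
    """Summed current trace (mA per step) from weighted presynaptic trains.

    Rectangular kernel: each spike of weight w injects w mA for exactly
    one dt step.  Exponential kernel: amplitude w/tau_syn at the spike
    step, decaying with tau_syn.  Contributions superpose linearly.
    """
    if n_steps is None:
        n_steps = int(round(max(tr.duration for tr in trains) / cfg.dt))
    x = np.zeros(n_steps, dtype=float)
    for tr, w in zip(trains, weights):
        dense = tr.to_dense(cfg.dt)[:n_steps].astype(float)
        if cfg.kernel == "rect":
            x += w * dense
        else:
            decay = np.exp(-cfg.dt / cfg.tau_syn)
            state = 0.0
            out = np.empty(n_steps)
            for t in range(n_steps):
                state = state * decay + (w / cfg.tau_syn) * dense[t]
                out[t] = state
            x += out
    return x


def spike_trains_to_csv(trains: Sequence[SpikeTrain], path) -> None:
    """Write an event-list CSV with columns (source_id, t_ms)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "t_ms"])
        for tr in trains:
            for t in tr.times:
                writer.writerow([tr.source_id, f"{t:g}"])


def spike_trains_from_csv(path, duration: float) -> list[SpikeTrain]:
    """Read an event-list CSV written by :func:`spike_trains_to_csv`."""
    df = pd.read_csv(path)
    trains = []
    for sid, grp in df.groupby("source_id", sort=True):
        trains.append(
            SpikeTrain(times=np.sort(grp["t_ms"].to_numpy(float)),
                       duration=duration, source_id=int(sid))
        )
    return trains


@dataclass
class Network:
    """A recurrent LIF population with typed synapses and input wiring.

    w_rec : (n, n) recurrent weight matrix, zero diagonal (no
    self-connections); entry [post, pre] is the current amplitude (mA per
    spike) injected into ``post`` when ``pre`` fires.  w_in : (n, n_in)
    input wiring with the same convention.  is_excitatory labels neuron
    types; builders enforce the sign discipline (all outgoing weights of
    an inhibitory neuron negative, of an excitatory one positive).
    ``params`` carries the shared (v_th, t_r, bounds); ``r`` and ``tau_m``
    are the per-neuron intrinsic parameters that plasticity adapts.
    """

    w_rec: np.ndarray
    w_in: np.ndarray
    params: NeuronParams
    r: np.ndarray = None  # type: ignore[assignment]
    tau_m: np.ndarray = None  # type: ignore[assignment]
    is_excitatory: np.ndarray = None  # type: ignore[assignment]
    positions: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w_rec = np.asarray(self.w_rec, dtype=float)
        self.w_in = np.asarray(self.w_in, dtype=float)
        n = self.w_rec.shape[0]
        if self.w_rec.shape != (n, n):
            raise ValueError("w_rec must be square")
        if np.any(np.diag(self.w_rec) != 0):
            raise ValueError("self-connections are not allowed")
        if self.w_in.shape[0] != n:
            raise ValueError("w_in row count must equal neuron count")
        if self.r is None:
            self.r = np.full(n, self.params.r, dtype=float)
        if self.tau_m is None:
            self.tau_m = np.full(n, self.params.tau_m, dtype=float)
        if self.is_excitatory is None:
            self.is_excitatory = np.ones(n, dtype=bool)

    @property
    def n(self) -> int:
        return self.w_rec.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]


@dataclass
class SimResult:
    """Per-millisecond records of a lockstep run.

    Arrays are (n_steps, n): spikes (0/1), rates (KHz), v (mV), and — when
    plasticity is active — r_traj (Ohm), tau_traj (ms), v_th_traj (mV).
    """

    dt: float
    spikes: np.ndarray
    rates: np.ndarray
    v: np.ndarray
    r_traj: Optional[np.ndarray] = None
    tau_traj: Optional[np.ndarray] = None
    v_th_traj: Optional[np.ndarray] = None

    @property
    def n_steps(self) -> int:
        return self.spikes.shape[0]

    def trace_frame(self, neurons: Optional[Sequence[int]] = None) -> pd.DataFrame:
        """Long-format trace (t_ms, neuron_id, V_mV, y_khz) for CSV export."""
        n = self.spikes.shape[1]
        ids = list(range(n)) if neurons is None else list(neurons)
        frames = []
        t = np.arange(self.n_steps) * self.dt
        for i in ids:
            frames.append(pd.DataFrame({
                "t_ms": t, "neuron_id": i,
                "V_mV": self.v[:, i], "y_khz": self.rates[:, i],
            }))
        return pd.concat(frames, ignore_index=True)

    def adaptation_frame(self, neurons: Optional[Sequence[int]] = None) -> pd.DataFrame:
        """Per-step adaptation log (t_ms, neuron_id, R_ohm, tau_m_ms, y_khz)."""
        if self.r_traj is None:
            raise ValueError("run had no intrinsic-plasticity binding")
        n = self.spikes.shape[1]
        ids = list(range(n)) if neurons is None else list(neurons)
        t = np.arange(self.n_steps) * self.dt
        frames = []
        for i in ids:
            frames.append(pd.DataFrame({
                "t_ms": t, "neuron_id": i,
                "R_ohm": self.r_traj[:, i], "tau_m_ms": self.tau_traj[:, i],
                "y_khz": self.rates[:, i],
            }))
        return pd.concat(frames, ignore_index=True)


def _input_current_matrix(net: Network, inputs, cfg: SimConfig, n_steps: int) -> np.ndarray:
    """Resolve external inputs to an (n_steps, n) current matrix (mA)."""
    if inputs is None:
        return np.zeros((n_steps, net.n))
    if isinstance(inputs, np.ndarray):
        if inputs.shape != (n_steps, net.n):
            raise ValueError(
                f"current trace shape {inputs.shape} != {(n_steps, net.n)}"
            )
        return np.asarray(inputs, dtype=float)
    # sequence of SpikeTrain, one per input channel
    trains = list(inputs)
    if len(trains) != net.n_in:
        raise ValueError(f"{len(trains)} spike trains for {net.n_in} input channels")
    dense = np.stack([tr.to_dense(cfg.dt)[:n_steps] for tr in trains], axis=1).astype(float)
    if cfg.kernel == "rect":
        return dense @ net.w_in.T
    decay = np.exp(-cfg.dt / cfg.tau_syn)
    filt = np.zeros_like(dense)
    state = np.zeros(dense.shape[1])
    for t in range(n_steps):
        state = state * decay + dense[t] / cfg.tau_syn
        filt[t] = state
    return filt @ net.w_in.T


def simulate(
    net: Network,
    inputs,
    cfg: SimConfig,
    ip: Optional[IPConfig] = None,
    vth_ip: Optional[VTIPConfig] = None,
    state: Optional[NeuronState] = None,
    v_th: Optional[np.ndarray] = None,
) -> SimResult:
    """Run the lockstep loop over ``cfg.duration``.

    Per step: gather currents (external plus recurrent, the latter from
    the previous step's spikes) -> membrane update -> threshold/reset ->
    calcium rate estimate -> optional per-neuron plasticity update
    (SpiKL-IP on (R, tau_m), or the Voltage-Threshold baseline on V_th),
    taking effect on the next step.

    ``inputs`` is either a sequence of :class:`SpikeTrain` (one per input
    channel of ``net.w_in``) or an (n_steps, n) current matrix in mA.
    Passing ``state`` (and ``v_th`` for the baseline rule) continues a
    previous run; ``net.r`` / ``net.tau_m`` are updated in place by
    SpiKL-IP so convergence carries across passes.
    """
    n_steps = cfg.n_steps
    n = net.n
    x_ext = _input_current_matrix(net, inputs, cfg, n_steps)

    if state is None:
        v = np.zeros(n)
        refr = np.zeros(n)
        c_cal = np.zeros(n)
    else:
        v = np.array(np.broadcast_to(state.v, (n,)), dtype=float)
        refr = np.array(np.broadcast_to(state.refr_left, (n,)), dtype=float)
        c_cal = np.array(np.broadcast_to(state.c_cal, (n,)), dtype=float)

    r = net.r
    tau_m = net.tau_m
    p = net.params
    if v_th is None:
        v_th = np.full(n, p.v_th, dtype=float)
    else:
        v_th = np.array(v_th, dtype=float)

    spikes = np.zeros((n_steps, n), dtype=np.int8)
    rates = np.zeros((n_steps, n))
    v_rec = np.zeros((n_steps, n))
    r_traj = np.zeros((n_steps, n)) if ip is not None else None
    tau_traj = np.zeros((n_steps, n)) if ip is not None else None
    vth_traj = np.zeros((n_steps, n)) if vth_ip is not None else None

    decay_syn = np.exp(-cfg.dt / cfg.tau_syn)
    syn_state = np.zeros(n)
    prev_spikes = np.zeros(n)

    for t in range(n_steps):
        if cfg.kernel == "rect":
            x_t = x_ext[t] + net.w_rec @ prev_spikes
        else:
            syn_state = syn_state * decay_syn + (net.w_rec @ prev_spikes) / cfg.tau_syn
            x_t = x_ext[t] + syn_state

        v, refr, spiked = _membrane_update(
            v, refr, x_t, r, tau_m, v_th, p.t_r, cfg.dt, cfg.integrator
        )
        c_cal, y = _calcium_update(c_cal, spiked, cfg.dt, cfg.tau_cal)

        if ip is not None:
            r, tau_m = spikl_ip_update_arrays(y, r, tau_m, p.v_th, p.t_r, ip)
            np.clip(r, *p.bounds_r, out=r)
            np.clip(tau_m, *p.bounds_tau, out=tau_m)
            r_traj[t] = r
            tau_traj[t] = tau_m
        if vth_ip is not None:
            v_th = v_th + vth_ip.eta * (spiked - vth_ip.k / vth_ip.N)
            vth_traj[t] = v_th

        spikes[t] = spiked
        rates[t] = y
        v_rec[t] = v
        prev_spikes = spiked.astype(float)

    net.r = r
    net.tau_m = tau_m
    # persist continuation state on the result for multi-pass runs
    result = SimResult(
        dt=cfg.dt, spikes=spikes, rates=rates, v=v_rec,
        r_traj=r_traj, tau_traj=tau_traj, v_th_traj=vth_traj,
    )
    result.final_state = NeuronState(v=v, refr_left=refr, c_cal=c_cal)  # type: ignore[attr-defined]
    result.final_v_th = v_th  # type: ignore[attr-defined]
    return result
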