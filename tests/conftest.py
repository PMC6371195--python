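"""Shared fixtures and independent brute-force oracles.

The oracles here integrate the membrane ODE directly (forward Euler at a
fine step) and never touch the closed-form transfer function they are
used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spiklip import NeuronParams

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params() -> NeuronParams:
    """The reference neuron: V_th=20 mV, t_r=2 ms, R=64 Ohm, tau_m=64 ms."""
    return NeuronParams()


def brute_force_isi(x0: float, p: NeuronParams, dt: float = 0.001) -> float:
    """First-spike ISI by Euler integration of tau_m dV/dt = -V + R*x0.

    Integrates from V=0 until threshold crossing, then adds the
    refractory period.  Fails the calling test if no spike occurs within
    10 s (sub-threshold drive).
    """
    v = 0.0
    t = 0.0
    drive = p.r * x0
    while t < 10_000.0:
        v += dt * (-v + drive) / p.tau_m
        t += dt
        if v >= p.v_th:
            return t + p.t_r
    raise AssertionError("no threshold crossing within 10 s: sub-threshold drive")


def brute_force_rates(
    x: np.ndarray, r: np.ndarray, tau: np.ndarray, p: NeuronParams,
    dt: float = 0.01, duration: float = 3000.0,
) -> np.ndarray:
    """Spike rates of LIF neurons under constant drive, by direct fine-step
    Euler simulation (vectorised over parameter combinations).

    Rate is measured as (n_spikes - 1) / (t_last - t_first), which removes
    the boundary quantisation of plain spike counting.
    """
    x = np.asarray(x, float)
    r = np.asarray(r, float)
    tau = np.asarray(tau, float)
    n = x.size
    v = np.zeros(n)
    refr = np.zeros(n)
    count = np.zeros(n, int)
    t_first = np.full(n, np.nan)
    t_last = np.full(n, np.nan)
    drive = r * x
    n_steps = int(round(duration / dt))
    for k in range(n_steps):
        active = refr <= 0
        v[active] += dt * (-v[active] + drive[active]) / tau[active]
        refr[~active] -= dt
        spiked = active & (v >= p.v_th)
        if np.any(spiked):
            t_now = (k + 1) * dt
            v[spiked] = 0.0
            refr[spiked] = p.t_r
            first = spiked & (count == 0)
            t_first[first] = t_now
            t_last[spiked] = t_now
            count[spiked] += 1
    rates = np.zeros(n)
    measurable = count > 1
    rates[measurable] = (count[measurable] - 1) / (t_last[measurable] - t_first[measurable])
    return rates
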