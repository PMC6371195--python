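"""Firing-rate transfer function (FR-TF) of the leaky integrate-and-fire neuron.

Under a constant input current x0 the LIF membrane equation

    tau_m dV/dt = -V + R * x0

integrates in closed form, and the interspike interval of a neuron with
threshold ``V_th``, refractory period ``t_r``, leaky resistance ``R`` and
membrane time constant ``tau_m`` is

    T_isi = t_r + tau_m * ln( R*x0 / (R*x0 - V_th) ),   R*x0 > V_th

so the steady firing rate is y = 1 / T_isi.  This module provides that
transfer function, its analytic partial derivatives with respect to the
input and the two tunable intrinsic parameters, and the inversion from a
measured rate back to the supra-threshold drive W = R*x - V_th used by the
input-free form of the SpiKL-IP rule.

Unit system (package-wide): time in ms, rate in KHz (1/ms), voltage in mV,
current in mA, resistance in Ohm — so Ohm * mA = mV and every parameter
value quoted in the experiment configurations is usable verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DomainError",
    "NeuronParams",
    "isi_constant_input",
    "frtf_rate",
    "frtf_gradients",
    "w_from_rate",
    "tuning_curve",
]


class DomainError(ValueError):
    """Raised when an operation is evaluated outside its firing domain."""


@dataclass(frozen=True)
class NeuronParams:
    """Intrinsic LIF parameters, the quantities intrinsic plasticity adapts.

    Parameters
    ----------
    v_th : float
        Firing threshold (mV). Must be positive; the resting/reset
        potential is fixed at 0 mV.
    t_r : float
        Absolute refractory period (ms), >= 0.
    r : float
        Effective leaky resistance (Ohm).
    tau_m : float
        Membrane time constant (ms); tau_m = R*C, so the implied membrane
        capacitance is the derived quantity ``c`` and is never stored.
    bounds_r, bounds_tau : tuple of float
        Closed tuning intervals for ``r`` and ``tau_m`` with positive
        lower ends. Plasticity rules clip into these.
    """

    v_th: float = 20.0
    t_r: float = 2.0
    r: float = 64.0
    tau_m: float = 64.0
    bounds_r: tuple[float, float] = (1.0, 1024.0)
    bounds_tau: tuple[float, float] = (1.0, 1024.0)

    def __post_init__(self) -> None:
        if not self.v_th > 0:
            raise ValueError(f"v_th must be positive, got {self.v_th}")
        if self.t_r < 0:
            raise ValueError(f"t_r must be non-negative, got {self.t_r}")
        for name, (lo, hi) in (("bounds_r", self.bounds_r),
                               ("bounds_tau", self.bounds_tau)):
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if not (self.bounds_r[0] <= self.r <= self.bounds_r[1]):
            raise ValueError(f"r={self.r} outside bounds_r={self.bounds_r}")
        if not (self.bounds_tau[0] <= self.tau_m <= self.bounds_tau[1]):
            raise ValueError(f"tau_m={self.tau_m} outside bounds_tau={self.bounds_tau}")

    @property
    def c(self) -> float:
        """Implied membrane capacitance, tau_m / R (derived, never stored)."""
        return self.tau_m / self.r

    def with_intrinsics(self, r: float, tau_m: float) -> "NeuronParams":
        """Copy with new (r, tau_m), hard-clipped to the tuning bounds."""
        r = float(np.clip(r, *self.bounds_r))
        tau_m = float(np.clip(tau_m, *self.bounds_tau))
        return replace(self, r=r, tau_m=tau_m)


def isi_constant_input(x0: float, p: NeuronParams) -> float:
    """Interspike interval (ms) under constant input current ``x0`` (mA).

    Raises
    ------
    DomainError
        If R*x0 <= V_th: the membrane asymptote never reaches threshold,
        so the neuron never fires and no ISI exists.
    """
    drive = p.r * x0
    if drive <= p.v_th:
        raise DomainError(
            f"R*x0 = {drive} mV <= V_th = {p.v_th} mV: neuron never fires"
        )
    return p.t_r + p.tau_m * np.log(drive / (drive - p.v_th))


def frtf_rate(x0, p: NeuronParams):
    """Steady output firing rate (KHz) under constant input ``x0`` (mA).

    Total function of the input: sub-threshold drive (R*x0 <= V_th) maps to
    exactly 0 so tuning-curve sweeps need no domain bookkeeping. Accepts
    scalars or arrays; strictly increasing in ``x0`` and in ``R`` on the
    firing domain and bounded above by 1/t_r.
    """
    x0 = np.asarray(x0, dtype=float)
    drive = p.r * x0
    with np.errstate(divide="ignore", invalid="ignore"):
        isi = p.t_r + p.tau_m * np.log(drive / (drive - p.v_th))
        y = np.where(drive > p.v_th, 1.0 / isi, 0.0)
    if y.ndim == 0:
        return float(y)
    return y


def frtf_gradients(x0: float, p: NeuronParams) -> tuple[float, float, float]:
    """Analytic partials (dy/dx, dy/dR, dy/dtau_m) of the FR-TF at ``x0``.

    Closed forms on the firing domain::

        dy/dx     = y^2 tau_m V_th / (x (R x - V_th))
        dy/dR     = y^2 tau_m V_th / (R (R x - V_th))
        dy/dtau_m = (t_r y^2 - y) / tau_m

    The first two satisfy x * dy/dx == R * dy/dR, and dy/dtau_m < 0
    whenever 0 < y < 1/t_r.

    Raises
    ------
    DomainError
        If R*x0 <= V_th.
    """
    w = p.r * x0 - p.v_th
    if w <= 0:
        raise DomainError(f"R*x0 - V_th = {w} mV <= 0: not on the firing domain")
    y = frtf_rate(x0, p)
    dy_dx = y * y * p.tau_m * p.v_th / (x0 * w)
    dy_dr = y * y * p.tau_m * p.v_th / (p.r * w)
    dy_dtau = (p.t_r * y * y - y) / p.tau_m
    return dy_dx, dy_dr, dy_dtau


def w_from_rate(y, p: NeuronParams):
    """Invert the FR-TF: supra-threshold drive W = R*x - V_th (mV) from rate.

    W = V_th / (exp((1/tau_m) * (1/y - t_r)) - 1), defined for
    0 < y < 1/t_r strictly.  Callers feeding measured (e.g. calcium-based)
    rates must clamp into that open interval first — transient estimates
    can reach 1/t_r, which would drive W through infinity to a negative
    branch and destabilise the update that divides by W.

    Raises
    ------
    DomainError
        If y <= 0 or y >= 1/t_r (scalar input only; arrays are the
        caller's responsibility to pre-clamp).
    """
    y_arr = np.asarray(y, dtype=float)
    if y_arr.ndim == 0:
        yf = float(y_arr)
        y_max = np.inf if p.t_r == 0 else 1.0 / p.t_r
        if yf <= 0 or yf >= y_max:
            raise DomainError(
                f"rate y={yf} KHz outside (0, {y_max}) "
                "— clamp measured rates before inversion"
            )
    with np.errstate(over="ignore"):  # deep sub-rate inputs underflow W to 0
        w = p.v_th / np.expm1((1.0 / p.tau_m) * (1.0 / y_arr - p.t_r))
    if y_arr.ndim == 0:
        return float(w)
    return w


def tuning_curve(x_values, p: NeuronParams):
    """FR-TF sweep as a DataFrame with columns (x_mA, R_ohm, tau_m_ms, y_khz).

    One row per input level; the CSV written from this reproduces the
    rate-vs-current tuning curves at fixed intrinsic parameters.
    """
    import pandas as pd

    x = np.asarray(x_values, dtype=float)
    return pd.DataFrame(
        {
            "x_mA": x,
            "R_ohm": np.full_like(x, p.r),
            "tau_m_ms": np.full_like(x, p.tau_m),
            "y_khz": frtf_rate(x, p),
        }
    )
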