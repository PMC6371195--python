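"""Intrinsic-plasticity rules: SpiKL-IP and the Voltage-Threshold baseline.

SpiKL-IP tunes a LIF neuron's leaky resistance R and membrane time constant
tau_m online so that the distribution of its output firing rate y converges
to an exponential distribution with target mean mu — the maximum-entropy
distribution of a non-negative variable at fixed mean, i.e. maximum
information transfer at a fixed metabolic budget.  The rule performs
stochastic gradient descent on the per-step surrogate loss

    L_hat = -log(dy/dx) + y / mu

which is the per-observation Kullback-Leibler divergence from the target
exponential to the output-rate distribution, up to terms independent of
(R, tau_m).  Three forms are provided:

* :func:`spikl_ip_step_basic` — the raw gradient step, which needs the
  instantaneous input current x.  Direct use is ineffective when the input
  fluctuates faster than the firing-rate transfer function's constant-input
  assumption allows; it is kept for validation and ablation.
* :func:`spikl_ip_step` — the production rule.  The input is eliminated by
  substituting the supra-threshold drive W = R*x - V_th with its
  FR-TF-consistent expression in y, so the update depends on the measured
  output rate only; a low-rate branch (y <= delta) nudges R up and tau_m
  down by fixed increments to revive silent neurons.
* :func:`voltage_threshold_ip_step` — a baseline that shifts the firing
  threshold by a fixed-size step toward a target spike fraction k/N; it
  controls the mean rate but not the distribution's shape.

Updates are hard-clipped into the tuning bounds carried by
:class:`~spiklip.frtf.NeuronParams`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .frtf import DomainError, NeuronParams, frtf_gradients, frtf_rate

__all__ = [
    "IPConfig",
    "VTIPConfig",
    "LossTerms",
    "spikl_ip_step",
    "spikl_ip_step_basic",
    "spikl_ip_update_arrays",
    "voltage_threshold_ip_step",
    "surrogate_loss",
]

#: Fractional margin keeping the clamped rate strictly below 1/t_r before
#: the W-inversion (the inversion diverges at exactly 1/t_r).
_RATE_CLAMP_MARGIN = 1e-6


@dataclass(frozen=True)
class IPConfig:
    """SpiKL-IP hyperparameters.

    Attributes
    ----------
    mu : float
        Target mean of the exponential output-rate distribution (KHz).
    eta1, eta2 : float
        Learning rates for R and tau_m (dimensionless).
    alpha1 : float
        Low-rate recovery increment for R (Ohm per eta1 unit).
    alpha2 : float
        Low-rate recovery decrement for tau_m (ms per eta2 unit).
    delta : float
        Low-rate threshold (KHz) below which the recovery branch engages;
        default 0.001 KHz = 1 Hz.
    max_step : float or None
        Trust-region cap on one update: |Delta R| <= max_step (Ohm) and
        |Delta tau_m| <= max_step (ms).  The gradient branch divides by
        W(y), which vanishes exponentially fast as y approaches delta
        from above, so the raw update magnitude is unbounded in that
        boundary layer; the cap (default 1.0, roughly 30x a typical
        mid-range update and of the order of the low-rate rescue step)
        leaves ordinary updates untouched while keeping the boundary
        layer from slamming parameters to their bounds.  ``None``
        disables the cap and recovers the literal rule.
    """

    mu: float = 0.2
    eta1: float = 5.0
    eta2: float = 5.0
    alpha1: float = 0.1
    alpha2: float = 0.1
    delta: float = 0.001
    max_step: Optional[float] = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.eta1 <= 0 or self.eta2 <= 0:
            raise ValueError("learning rates must be positive")
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("recovery increments must be positive")
        if not (0 < self.delta < self.mu):
            raise ValueError("delta must satisfy 0 < delta < mu")
        if self.max_step is not None and self.max_step <= 0:
            raise ValueError("max_step must be positive or None")


@dataclass(frozen=True)
class VTIPConfig:
    """Voltage-Threshold IP baseline parameters.

    The rule drives a neuron to spike on average k out of N simulation
    steps: V_th += eta * (spiked - k/N).
    """

    eta: float = 0.01
    k: int = 1
    N: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.k < self.N):
            raise ValueError("require 0 < k < N")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


@dataclass(frozen=True)
class LossTerms:
    """Monitoring quantities: per-step surrogate loss and, when a sample
    is available, a KL-divergence estimate (nats)."""

    l_hat: float
    d: Optional[float] = None


def _clamp_rate(y, t_r: float, delta: float):
    """Clamp a measured rate into [delta, (1 - margin)/t_r] before inversion."""
    hi = np.inf if t_r == 0 else (1.0 - _RATE_CLAMP_MARGIN) / t_r
    return np.clip(y, delta, hi)


def spikl_ip_update_arrays(y, r, tau_m, v_th, t_r, c: IPConfig):
    """Vectorised SpiKL-IP update on raw parameter arrays (no clipping).

    Computes the two-branch update for every element of ``y`` given
    matching arrays (or scalars) ``r`` and ``tau_m``; returns the new
    (r, tau_m) arrays.  Bound clipping is the caller's job — the network
    stepper applies its own per-neuron bounds.  This is the numerical core
    shared by the scalar API and the simulator.
    """
    y = np.asarray(y, dtype=float)
    r = np.asarray(r, dtype=float)
    tau_m = np.asarray(tau_m, dtype=float)

    y_c = _clamp_rate(y, t_r, c.delta)
    # W underflows to exactly 0 deep in the low-rate boundary layer; the
    # resulting infinite raw step is tamed by the trust region / bounds.
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        w = v_th / (np.expm1((1.0 / tau_m) * (1.0 / y_c - t_r)))
        num_r = 2.0 * y * tau_m * v_th - w - v_th - (1.0 / c.mu) * tau_m * v_th * y * y
        dr_high = c.eta1 * num_r / (r * w)
    dtau_high = c.eta2 * (2.0 * t_r * y - 1.0 - (1.0 / c.mu) * (t_r * y * y - y)) / tau_m

    low = y <= c.delta
    dr = np.where(low, c.eta1 * c.alpha1, dr_high)
    dtau = np.where(low, -c.eta2 * c.alpha2, dtau_high)
    if c.max_step is not None:
        dr = np.clip(dr, -c.max_step, c.max_step)
        dtau = np.clip(dtau, -c.max_step, c.max_step)
    return r + dr, tau_m + dtau


def spikl_ip_step(y: float, p: NeuronParams, c: IPConfig) -> NeuronParams:
    """One SpiKL-IP update from a measured output rate ``y`` (KHz).

    Uses only the output rate, never the instantaneous input.  If
    ``y > delta`` the gradient branch fires, with the measured rate clamped
    into [delta, (1-1e-6)/t_r] before the W-inversion; otherwise R is
    raised by eta1*alpha1 and tau_m lowered by eta2*alpha2 to lift a
    silent neuron back into the firing regime.  The result is hard-clipped
    into the tuning bounds.
    """
    if y < 0:
        raise ValueError(f"rate must be non-negative, got {y}")
    new_r, new_tau = spikl_ip_update_arrays(y, p.r, p.tau_m, p.v_th, p.t_r, c)
    return p.with_intrinsics(float(new_r), float(new_tau))


def spikl_ip_step_basic(x: float, y: float, p: NeuronParams, c: IPConfig) -> NeuronParams:
    """One raw gradient-descent step using the instantaneous input ``x`` (mA).

    R -= eta1 * dL/dR and tau_m -= eta2 * dL/dtau_m with the closed-form
    gradients of the surrogate loss.  Requires R*x > V_th.  Algebraically
    identical to the high-rate branch of :func:`spikl_ip_step` whenever
    ``y`` equals the FR-TF rate at ``x``.  Kept for validation; direct use
    under fast-varying input does not converge, which is what motivates
    the input-free form.
    """
    w = p.r * x - p.v_th
    if w <= 0:
        raise DomainError(f"R*x - V_th = {w} mV <= 0: basic rule undefined")
    dl_dr = ((y * y / c.mu - 2.0 * y) * p.tau_m * p.v_th + p.r * x) / (p.r * w)
    dl_dtau = (1.0 + (p.t_r * y * y - y) / c.mu - 2.0 * p.t_r * y) / p.tau_m
    dr, dtau = -c.eta1 * dl_dr, -c.eta2 * dl_dtau
    if c.max_step is not None:  # same trust region as the input-free form
        dr = float(np.clip(dr, -c.max_step, c.max_step))
        dtau = float(np.clip(dtau, -c.max_step, c.max_step))
    return p.with_intrinsics(p.r + dr, p.tau_m + dtau)


def voltage_threshold_ip_step(v_th_i: float, spiked: int, c: VTIPConfig) -> float:
    """Voltage-Threshold IP baseline: V_th += eta * (spiked - k/N)."""
    return v_th_i + c.eta * (spiked - c.k / c.N)


def surrogate_loss(x: float, y: float, p: NeuronParams, c: IPConfig) -> LossTerms:
    """Per-step surrogate loss L_hat = -log(dy/dx) + y/mu (monitoring only).

    ``dy/dx`` is the FR-TF sensitivity at the instantaneous input; finite
    for any firing point.  Raises :class:`DomainError` sub-threshold.
    """
    dy_dx, _, _ = frtf_gradients(x, p)  # raises DomainError sub-threshold
    return LossTerms(l_hat=float(-np.log(dy_dx) + y / c.mu))
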