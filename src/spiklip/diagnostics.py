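"""Distributional diagnostics for recorded firing-rate samples.

The plasticity rule's target is an exponential output-rate distribution
with mean mu — the maximum-entropy distribution of a non-negative variable
at fixed mean, written here f(y) = (1/mu) exp(-y/mu).  This module
quantifies how close an empirical rate sample comes to that target:

* maximum-likelihood exponential fit (the sample mean),
* a histogram plug-in estimate of KL(empirical || Exp(mean mu)) in nats,
* a binned differential-entropy estimate in nats.

Binning is fixed (50 equal-width bins, range [0, max(sample max, 5*mu)])
so results are reproducible; empirical bin masses get additive smoothing
eps = 1e-12 and reference masses are integrated exactly per bin, which
keeps the estimate non-negative.  Diagnostics exclude an initial burn-in
window (default the first 20% of recorded steps) so convergence rather
than the transient is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RateSample",
    "ExpFit",
    "fit_exponential_mle",
    "kl_to_exponential",
    "entropy_estimate",
    "exp_fit",
    "histogram_frame",
]

_N_BINS = 50
_EPS = 1e-12
_DEFAULT_BURN_IN_FRAC = 0.2


@dataclass(frozen=True)
class RateSample:
    """A recorded rate trace (KHz) with a burn-in boundary index."""

    values: np.ndarray
    burn_in: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not 0 <= self.burn_in <= v.size:
            raise ValueError("burn_in index out of range")

    @classmethod
    def from_trace(cls, values, burn_in_frac: float = _DEFAULT_BURN_IN_FRAC) -> "RateSample":
        v = np.asarray(values, dtype=float)
        return cls(values=v, burn_in=int(round(burn_in_frac * v.size)))

    @property
    def post(self) -> np.ndarray:
        """Post-burn-in values — what every diagnostic operates on."""
        return self.values[self.burn_in:]


@dataclass(frozen=True)
class ExpFit:
    """Summary of one sample: MLE mean, KL to the fit, entropy (nats)."""

    mu_hat: float
    kl: float
    entropy_hat: float


def _as_post_values(s) -> np.ndarray:
    v = s.post if isinstance(s, RateSample) else np.asarray(s, dtype=float)
    if v.size == 0:
        raise ValueError("empty rate sample")
    if np.any(v < 0):
        raise ValueError("rate sample contains negative values")
    return v


def fit_exponential_mle(s) -> float:
    """MLE of the exponential mean: the post-burn-in sample mean (KHz)."""
    return float(np.mean(_as_post_values(s)))


def _bin_edges(v: np.ndarray, mu: float) -> np.ndarray:
    top = max(float(v.max()), 5.0 * mu)
    if top <= 0:
        top = 5.0 * mu
    return np.linspace(0.0, top, _N_BINS + 1)


def kl_to_exponential(s, mu: float) -> float:
    """Histogram plug-in KL(empirical || Exp(mean mu)) in nats.

    Both the empirical and the exact per-bin exponential masses are
    smoothed by eps and renormalised over the shared bins, so the
    estimate is >= 0 (Gibbs' inequality at bin level).  A perfect
    exponential sample does not score exactly 0 — the estimator has a
    small positive binning floor (about 0.01 nats at n = 1e5).
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    v = _as_post_values(s)
    edges = _bin_edges(v, mu)
    counts, _ = np.histogram(v, bins=edges)
    p = counts.astype(float) / counts.sum() + _EPS
    p /= p.sum()
    q = np.exp(-edges[:-1] / mu) - np.exp(-edges[1:] / mu) + _EPS
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def entropy_estimate(s) -> float:
    """Binned differential-entropy plug-in estimate (nats).

    Same 50-bin scheme over [0, sample max]; for a point-mass-like sample
    the estimate sits near the binning floor ln(width) of one occupied
    bin.  Exponential samples score highest among same-mean samples
    (maximum-entropy property).
    """
    v = _as_post_values(s)
    top = float(v.max())
    if top <= 0:  # all-zero sample: a point mass at the origin
        top = 1.0
    edges = np.linspace(0.0, top, _N_BINS + 1)
    width = edges[1] - edges[0]
    counts, _ = np.histogram(v, bins=edges)  # top edge inclusive in last bin
    p = counts.astype(float) / counts.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])) + np.log(width))


def exp_fit(s) -> ExpFit:
    """Fit, divergence and entropy of one sample in a single summary."""
    mu_hat = fit_exponential_mle(s)
    return ExpFit(
        mu_hat=mu_hat,
        kl=kl_to_exponential(s, mu_hat),
        entropy_hat=entropy_estimate(s),
    )


def histogram_frame(s, mu: float) -> pd.DataFrame:
    """Figure-style histogram table.

    Columns (bin_left_khz, bin_right_khz, empirical_mass, exp_fit_mass):
    the empirical bin masses of the sample next to the exact per-bin
    masses of Exp(mean mu), for plotting the histogram against the fitted
    red curve.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    v = _as_post_values(s)
    edges = _bin_edges(v, mu)
    counts, _ = np.histogram(v, bins=edges)
    return pd.DataFrame({
        "bin_left_khz": edges[:-1],
        "bin_right_khz": edges[1:],
        "empirical_mass": counts / counts.sum(),
        "exp_fit_mass": np.exp(-edges[:-1] / mu) - np.exp(-edges[1:] / mu),
    })
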