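"""Circular arithmetic and densities on the 180-degree orientation space.

Orientation stimuli are periodic with period 180 deg (a grating rotated by
180 deg is identical to itself), so all circular statistics are computed on
the doubled-angle circle: an orientation ``theta`` in degrees is mapped to
the angle ``2 * theta * pi / 180`` radians, summary statistics are computed
there, and results are mapped back to orientation degrees.  All public
functions take and return orientation degrees.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

__all__ = [
    "wrap_ori",
    "ori_diff",
    "wrapped_normal_pdf",
    "wrapped_normal_rvs",
    "circ_mean_sd",
    "CircSummary",
]

#: Orientation period in degrees.
PERIOD = 180.0

# Resultant lengths below this are treated as "no preferred direction".
_RESULTANT_EPS = 1e-12


def wrap_ori(theta, period: float = PERIOD):
    """Wrap orientation(s) into ``[0, period)``.  Idempotent."""
    theta = np.asarray(theta, dtype=float)
    out = np.mod(theta, period)
    # np.mod can return `period` itself for tiny negative inputs
    out = np.where(out >= period, out - period, out)
    if out.ndim == 0:
        return float(out)
    return out


def ori_diff(a, b, period: float = PERIOD):
    """Signed acute-equivalent difference ``a - b`` wrapped into [-period/2, period/2).

    For the default 180-deg period the result lies in ``[-90, 90)``;
    the boundary tie (a difference of exactly +/-90) maps to -90.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("ori_diff requires finite inputs")
    half = period / 2.0
    d = np.mod(a - b + half, period) - half
    if d.ndim == 0:
        return float(d)
    return d


def wrapped_normal_pdf(x, mu, sigma: float, period: float = PERIOD):
    """Wrapped normal density on a circle of circumference ``period``.

    Evaluates ``sum_k N(x; mu + k * period, sigma)`` with the wrap sum
    truncated once additional terms are negligible (< 1e-12 of the peak).

    Parameters
    ----------
    x, mu : array_like, degrees
    sigma : float, degrees (> 0)
    period : float, 180 for orientation, 360 for direction
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(f"sigma must be positive and finite, got {sigma}")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    d = np.mod(x - mu, period)  # in [0, period)
    # number of wraps needed on each side: terms at distance k*period from the
    # mean fall below 1e-12 of the peak once (k*period)^2/(2 sigma^2) > 28
    n_wrap = int(np.ceil(np.sqrt(2.0 * 28.0) * sigma / period)) + 1
    n_wrap = min(max(n_wrap, 2), 200)
    k = np.arange(-n_wrap, n_wrap + 1, dtype=float) * period
    dd = d[..., None] + k  # distances to all wrapped copies of mu
    dens = np.exp(-0.5 * (dd / sigma) ** 2).sum(axis=-1)
    dens /= sigma * np.sqrt(2.0 * np.pi)
    if dens.ndim == 0:
        return float(dens)
    return dens


def wrapped_normal_rvs(mu, sigma: float, size=None, rng=None, period: float = PERIOD):
    """Draw wrapped-normal variates: ``wrap(mu + N(0, sigma))``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    rng = np.random.default_rng(rng)
    mu = np.asarray(mu, dtype=float)
    if size is None:
        size = mu.shape
    return wrap_ori(mu + rng.normal(0.0, sigma, size=size), period=period)


class CircSummary(NamedTuple):
    """Circular mean/SD of orientations, plus the doubled-angle resultant length.

    ``mean`` is NaN (and ``mean_defined`` False) when the resultant length
    vanishes, e.g. for orientations spread uniformly.
    """

    mean: float
    sd: float
    resultant: float

    @property
    def mean_defined(self) -> bool:
        return bool(np.isfinite(self.mean))


def circ_mean_sd(values, weights=None, period: float = PERIOD) -> CircSummary:
    """Circular mean and circular SD of orientations, in degrees.

    Computed on the doubled-angle circle and mapped back, so e.g. the values
    {179, 1} have mean 0, not 90.  The circular SD is
    ``sqrt(-2 ln R)`` (R = mean resultant length) converted back to
    orientation degrees; for wrapped-normal data it estimates the generating
    sigma.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("circ_mean_sd requires a non-empty sequence")
    ang = values * (2.0 * np.pi / period)
    if weights is None:
        z = np.exp(1j * ang).mean()
    else:
        w = np.asarray(weights, dtype=float)
        sw = w.sum()
        if sw <= 0:
            raise ValueError("weights must have positive sum")
        z = (w * np.exp(1j * ang)).sum() / sw
    resultant = float(np.abs(z))
    if resultant < _RESULTANT_EPS:
        return CircSummary(mean=float("nan"), sd=float("inf"), resultant=resultant)
    mean = wrap_ori(np.angle(z) * (period / (2.0 * np.pi)), period=period)
    sd = np.sqrt(-2.0 * np.log(resultant)) * (period / (2.0 * np.pi))
    return CircSummary(mean=float(mean), sd=float(sd), resultant=resultant)
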