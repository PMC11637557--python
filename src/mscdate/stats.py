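"""Proposal kernels, reflection, HPD intervals and effective sample sizes."""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "bactrian_laplace",
    "reflect",
    "hpd_interval",
    "effective_sample_size",
]

_SQRT_HALF = math.sqrt(0.5)


def bactrian_laplace(rng: np.random.Generator, m: float = 0.95, size=None):
    """Draw from the unit-variance Bactrian-Laplace proposal kernel.

    The kernel is a two-component mixture centred at +/- m with a Laplace
    spread scaled so the mixture has variance one; the bimodality avoids
    tiny steps and improves random-walk mixing.
    """
    sign = rng.integers(0, 2, size=size) * 2 - 1
    spread = math.sqrt(1.0 - m * m)
    lap = rng.laplace(0.0, _SQRT_HALF, size=size)
    return sign * m + spread * lap


def reflect(x: float, lo: float, hi: float) -> float:
    """Fold x into (lo, hi) by reflecting at the boundaries.

    Either bound may be infinite (reflection then happens only at the finite
    one).  Used for sliding-window proposals, which stay symmetric under
    reflection.
    """
    if lo > hi:
        raise ValueError("reflect: lo > hi")
    if math.isinf(lo) and math.isinf(hi):
        return x
    if math.isinf(hi):
        return lo + abs(x - lo)
    if math.isinf(lo):
        return hi - abs(hi - x)
    width = hi - lo
    if width == 0.0:
        return lo
    y = (x - lo) % (2.0 * width)
    if y > width:
        y = 2.0 * width - y
    return lo + y


def hpd_interval(samples, mass: float = 0.95):
    """Shortest contiguous interval containing ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    m = max(1, int(math.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1 :] - x[: n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def effective_sample_size(x) -> float:
    """ESS via Geyer's initial monotone sequence on the autocorrelation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        return float(n)
    v = np.var(x)
    if v == 0.0:
        return float(n)
    xc = x - x.mean()
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Geyer: sums of adjacent pairs, kept while positive and nonincreasing
    max_pairs = (n - 1) // 2
    tau = -rho[0]  # = -1
    prev = math.inf
    for mp in range(max_pairs):
        g = rho[2 * mp] + rho[2 * mp + 1]
        if g <= 0.0:
            break
        g = min(g, prev)
        prev = g
        tau += 2.0 * g
    tau = max(tau, 1.0 / n)
    return float(n / tau)
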