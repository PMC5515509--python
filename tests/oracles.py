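"""Independent reference implementations used as test oracles.

These deliberately take different computational routes from the package
(periodogram instead of Welch, scipy cdist instead of the numba kernel,
explicit cumulative-sum loops instead of vectorised searches) so that
agreement between the two is informative.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import periodogram
from scipy.spatial.distance import cdist


def band_power_periodogram(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Integrated periodogram power (µV²) in the closed band [lo, hi]."""
    freqs, power = periodogram(x, fs=fs)
    mask = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(power[mask], freqs[mask]))


def sef_bruteforce(
    freqs: np.ndarray, power: np.ndarray, f_low: float, f_high: float, r: float
) -> float:
    """Spectral edge frequency by an explicit cumulative-sum loop."""
    total = 0.0
    in_band = []
    for f, p in zip(freqs, power):
        if f_low <= f <= f_high:
            in_band.append((f, p))
            total += p
    if total <= 0:
        raise ValueError("zero in-band power")
    threshold = (r / 100.0) * total
    running = 0.0
    for f, p in in_band:
        running += p
        if running >= threshold:
            return f
    return in_band[-1][0]


def fuzzy_entropy_reference(
    x: np.ndarray, m: int = 2, n: float = 2.0, r_coef: float = 0.15
) -> float:
    """O(N²) fuzzy entropy via full Chebyshev distance matrices.

    Same definition as the package kernel — SD-normalised series,
    de-meaned templates, N-m-1 templates for both embedding dimensions,
    self-matches excluded — but computed through scipy's cdist rather
    than the numba pair loop.
    """
    x = np.asarray(x, dtype=np.float64)
    z = x / x.std()

    def phi(k: int, n_templates: int) -> float:
        idx = np.arange(n_templates)[:, None] + np.arange(k)[None, :]
        t = z[idx]
        t = t - t.mean(axis=1, keepdims=True)
        d = cdist(t, t, metric="chebyshev")
        sim = np.exp(-(d**n) / r_coef)
        total = sim.sum() - np.trace(sim)  # exclude self-matches
        return total / (n_templates * (n_templates - 1))

    n_templates = z.size - m - 1
    return float(np.log(phi(m, n_templates)) - np.log(phi(m + 1, n_templates)))
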