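"""Haemodynamic response function kernels."""

from __future__ import annotations

import numpy as np
from scipy import stats as _stats

HRF_KINDS = ("gamma", "double_gamma")

# Gamma shape/scale chosen so the positive lobe peaks at 5.5 s, inside the
# conventional 5-7 s window; the second gamma produces the post-peak undershoot.
_PEAK_SHAPE = 6.0
_UNDERSHOOT_SHAPE = 16.0
_SCALE = 1.1
_UNDERSHOOT_RATIO = 6.0


def make_hrf(kind: str = "double_gamma", dt: float = 0.1, duration: float = 32.0) -> np.ndarray:
    """Sample an HRF kernel on a regular grid.

    Parameters
    ----------
    kind : {"gamma", "double_gamma"}
        Single-gamma kernel (no undershoot) or canonical double-gamma
        (difference of two gammas, with undershoot).
    dt : float
        Sampling interval in seconds, must be positive.
    duration : float
        Kernel support in seconds.

    Returns
    -------
    ndarray
        Kernel sampled at ``t = 0, dt, 2*dt, ...`` and normalised to unit peak.
    """
    if kind not in HRF_KINDS:
        raise ValueError(f"unknown HRF kind {kind!r}; expected one of {HRF_KINDS}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    return _evaluate(kind, t) / _peak_value(kind)


def _evaluate(kind: str, t: np.ndarray) -> np.ndarray:
    h = _stats.gamma.pdf(t, _PEAK_SHAPE, scale=_SCALE)
    if kind == "double_gamma":
        h = h - _stats.gamma.pdf(t, _UNDERSHOOT_SHAPE, scale=_SCALE) / _UNDERSHOOT_RATIO
    return h


def _peak_value(kind: str) -> float:
    # analytic (fine-grid) peak, so normalisation is independent of dt and a
    # coarsely sampled kernel equals the decimated fine-grid kernel exactly
    fine = np.arange(0, 32.0, 1e-3)
    return float(_evaluate(kind, fine).max())


def make_hrf_derivative(kind: str = "double_gamma", dt: float = 0.1, duration: float = 32.0) -> np.ndarray:
    """Temporal derivative of the HRF kernel (finite differences on the grid)."""
    h = make_hrf(kind, dt, duration)
    return np.gradient(h, dt)
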