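"""Canonical hemodynamic response function and event-regressor construction.

The canonical HRF is the usual difference of two gamma densities (response
peak at 6 s, undershoot peaking at 16 s, undershoot ratio 1/6, 32 s support),
evaluated on a 0.1 s microtime grid and normalized to unit peak. Condition
regressors are built by convolving a microtime impulse train of event onsets
with this kernel (or its temporal / dispersion derivatives) and sampling the
result at volume-acquisition times (multiples of the TR).

Modelling events as impulses at the onset of the initial stimulus trajectory
mirrors standard rapid event-related practice: trial durations here (well
under a second) are negligible relative to the HRF width.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "MICROTIME_DT",
    "HRF_LENGTH",
    "canonical_hrf",
    "hrf_basis",
    "event_regressor",
]

MICROTIME_DT = 0.1  # s, microtime resolution
HRF_LENGTH = 32.0  # s, kernel support

_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def _double_gamma(t: np.ndarray, peak_disp: float = 1.0) -> np.ndarray:
    """Unnormalized double-gamma impulse response at times ``t`` (s)."""
    peak = _gamma.pdf(t, _PEAK_DELAY / peak_disp, scale=peak_disp)
    under = _gamma.pdf(t, _UNDERSHOOT_DELAY, scale=1.0)
    return peak - _UNDERSHOOT_RATIO * under


def canonical_hrf(dt: float = MICROTIME_DT) -> np.ndarray:
    """Canonical HRF sampled every ``dt`` s over [0, 32) s, unit peak."""
    t = np.arange(0.0, HRF_LENGTH, dt)
    h = _double_gamma(t)
    return h / h.max()


def hrf_basis(dt: float = MICROTIME_DT) -> np.ndarray:
    """Return the (3, n) informed basis: HRF, temporal and dispersion derivative.

    The temporal derivative is the backward difference of the canonical
    kernel under a 1 s onset shift; the dispersion derivative is the
    numerical derivative with respect to the peak dispersion parameter.
    Both are scaled by the canonical kernel's peak so the three regressors
    live on comparable scales.
    """
    t = np.arange(0.0, HRF_LENGTH, dt)
    h = _double_gamma(t)
    scale = h.max()

    shift = 1.0  # s
    h_shift = _double_gamma(np.clip(t - shift, 0.0, None)) * (t >= shift)
    d_temporal = (h - h_shift) / shift

    d_disp_step = 0.01
    h_disp = _double_gamma(t, peak_disp=1.0 + d_disp_step)
    d_dispersion = (h - h_disp) / d_disp_step

    return np.vstack([h, d_temporal, d_dispersion]) / scale


def event_regressor(
    onsets: np.ndarray,
    n_volumes: int,
    tr: float,
    kernel: np.ndarray | None = None,
    dt: float = MICROTIME_DT,
    amplitudes: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve impulse events with an HRF kernel; sample at the TR grid.

    Parameters
    ----------
    onsets : array of event onsets in seconds from run start.
    n_volumes : number of volumes in the run.
    tr : repetition time in seconds.
    kernel : microtime kernel (defaults to the canonical HRF).
    amplitudes : optional per-event amplitudes (defaults to 1).
    """
    if kernel is None:
        kernel = canonical_hrf(dt)
    onsets = np.asarray(onsets, dtype=float)
    if amplitudes is None:
        amplitudes = np.ones_like(onsets)
    n_micro = int(np.ceil(n_volumes * tr / dt)) + 1
    train = np.zeros(n_micro)
    idx = np.round(onsets / dt).astype(int)
    keep = idx < n_micro
    np.add.at(train, idx[keep], np.asarray(amplitudes, dtype=float)[keep])
    conv = np.convolve(train, kernel)[:n_micro]
    # volume k is acquired at t = k * tr
    sample_idx = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[sample_idx]
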