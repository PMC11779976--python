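"""Vasomotion: spontaneous ~0.1 Hz arteriolar diameter oscillations.

The analysis chain: linearly detrend the diameter trace, estimate Welch's
power spectral density with segments long enough for 0.01 Hz resolution,
interpolate onto a common 0-1 Hz grid, and read out the power at the grid
point nearest 0.1 Hz.  "Relative power" is that value divided by the total
power at or below 1 Hz, making the readout unit-free across vessels.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from nvp.core import DiameterTrace, PowerSpectrum

#: common frequency grid: 0 .. 1 Hz inclusive at the design resolution
GRID_DF = 0.01
COMMON_GRID = np.round(np.arange(0.0, 1.0 + GRID_DF / 2, GRID_DF), 10)


def vasomotion_power(trace: DiameterTrace, target_freq: float = 0.1,
                     max_freq: float = 1.0,
                     df: float = GRID_DF) -> tuple[PowerSpectrum, float]:
    """Power spectrum of a diameter trace and the relative power at 0.1 Hz.

    Welch parameters: segment length = sample_rate / df (i.e. 1/df seconds,
    giving df frequency resolution), 50% overlap, Hann taper.  NaN frames
    are filled by linear interpolation before analysis.  Raises if the
    trace is shorter than two (half-overlapping) segments.

    Returns (PowerSpectrum truncated to <= max_freq on the common grid,
    relative power = P(nearest grid point to target_freq) / sum of grid
    power <= max_freq).
    """
    fs = trace.frame_rate
    y = trace.values.astype(float).copy()
    n = len(y)
    bad = ~np.isfinite(y)
    if bad.all():
        raise ValueError("diameter trace has no valid frames")
    if bad.any():
        idx = np.arange(n)
        y[bad] = np.interp(idx[bad], idx[~bad], y[~bad])

    nperseg = int(round(fs / df))
    min_len = int(round(1.5 * nperseg))  # two segments at 50% overlap
    if n < min_len:
        raise ValueError(
            f"trace of {n / fs:.1f} s too short for {1 / df:.0f} s Welch "
            f"segments (need >= {min_len / fs:.1f} s)")

    y = signal.detrend(y, type="linear")
    freqs, pxx = signal.welch(y, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend=False)
    grid = np.round(np.arange(0.0, max_freq + df / 2, df), 10)
    p_grid = np.interp(grid, freqs, pxx)
    spec = PowerSpectrum(freqs=grid, power=p_grid, source_length_s=n / fs)

    total = p_grid.sum()
    if total <= 0:
        return spec, 0.0
    i = int(np.argmin(np.abs(grid - target_freq)))
    return spec, float(p_grid[i] / total)
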