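"""Per-subject voxel time-series preparation: trim, detrend, band-pass, z-score.

The pipeline order is fixed: discard initial volumes, remove the per-voxel
least-squares linear trend, band-pass to 0.01-0.1 Hz, then z-transform each
voxel.  All steps operate independently per subject and per voxel.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import signal as ssignal

logger = logging.getLogger(__name__)

__all__ = [
    "PreparedSeries",
    "trim_initial_volumes",
    "linear_detrend",
    "bandpass",
    "zscore",
    "prepare",
]


@dataclasses.dataclass
class PreparedSeries:
    """Voxels x time matrix ready for phase analysis.

    Every retained row has mean ~0 and population standard deviation ~1.
    ``excluded`` lists row indices (into the input matrix) dropped because
    their variance was zero at some stage.
    """

    data: np.ndarray
    tr_s: float
    excluded: tuple[int, ...] = ()


def trim_initial_volumes(series: np.ndarray, k: int, time_axis: int = -1) -> np.ndarray:
    """Drop the first ``k`` volumes along ``time_axis``."""
    n = series.shape[time_axis]
    if not 0 <= k < n:
        raise ValueError(f"cannot trim {k} of {n} volumes")
    idx = [slice(None)] * series.ndim
    idx[time_axis] = slice(k, None)
    return series[tuple(idx)]


def linear_detrend(rows: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from each row (last axis is time)."""
    rows = np.asarray(rows, dtype=float)
    if rows.shape[-1] < 3:
        raise ValueError("detrending needs at least 3 samples")
    return ssignal.detrend(rows, axis=-1, type="linear")


def bandpass(
    rows: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    method: str = "ideal",
    order: int = 4,
) -> np.ndarray:
    """Zero-phase band-pass along the last axis.

    ``ideal`` (default) applies a rectangular mask on the discrete real
    spectrum, keeping bins with low_hz <= f <= high_hz; DC is always removed
    since low_hz > 0.  ``butterworth`` applies a forward-backward Butterworth
    filter of the given order as an alternative with smooth roll-off.
    """
    rows = np.asarray(rows, dtype=float)
    nyquist = 1.0 / (2.0 * tr_s)
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz must be below Nyquist ({nyquist} Hz)")
    if method == "ideal":
        n = rows.shape[-1]
        spectrum = np.fft.rfft(rows, axis=-1)
        freqs = np.fft.rfftfreq(n, d=tr_s)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spectrum[..., ~keep] = 0.0
        return np.fft.irfft(spectrum, n=n, axis=-1)
    if method == "butterworth":
        sos = ssignal.butter(
            order, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_s, output="sos"
        )
        return ssignal.sosfiltfilt(sos, rows, axis=-1)
    raise ValueError(f"unknown bandpass method {method!r}")


def zscore(rows: np.ndarray) -> np.ndarray:
    """z-transform each row with the population (n) denominator.

    Rows with zero variance raise; callers that tolerate flat voxels should
    go through :func:`prepare`, which excludes and reports them.
    """
    rows = np.asarray(rows, dtype=float)
    sd = rows.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance row cannot be z-scored")
    return (rows - rows.mean(axis=-1, keepdims=True)) / sd


def prepare(
    series: np.ndarray,
    tr_s: float,
    n_trim: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    bandpass_method: str = "ideal",
) -> PreparedSeries:
    """Full preparation of a voxels x time matrix.

    Zero-variance voxels (flat before or after filtering) are excluded from
    the output with a logged warning; downstream group analyses intersect
    exclusions across subjects so every subject contributes every voxel.
    """
    mat = np.asarray(series, dtype=float)
    if mat.ndim != 2:
        raise ValueError("prepare expects a voxels x time matrix")
    mat = trim_initial_volumes(mat, n_trim)
    sd_in = mat.std(axis=-1)
    if bandpass_method == "ideal":
        # detrend + ideal filter as one orthogonal projection: filter, then
        # remove the in-band component of the drift basis [1, t].  A single
        # projection makes the whole preparation exactly idempotent (up to
        # the re-normalisation), which sequential detrend-then-filter is not.
        mat = bandpass(mat, tr_s, low_hz=low_hz, high_hz=high_hz, method="ideal")
        n = mat.shape[-1]
        drift = np.stack([np.ones(n), np.arange(n, dtype=float)])
        drift_in_band = bandpass(drift, tr_s, low_hz=low_hz, high_hz=high_hz)
        q, r = np.linalg.qr(drift_in_band.T)
        q = q[:, np.abs(np.diag(r)) > 1e-10 * n]
        mat = mat - (mat @ q) @ q.T
    else:
        mat = linear_detrend(mat)
        mat = bandpass(mat, tr_s, low_hz=low_hz, high_hz=high_hz, method=bandpass_method)
    sd = mat.std(axis=-1)
    flat = np.flatnonzero((sd_in == 0) | (sd <= 1e-10 * np.maximum(sd_in, 1.0)))
    if flat.size:
        logger.warning("excluding %d zero-variance voxel(s)", flat.size)
        keep = np.ones(mat.shape[0], dtype=bool)
        keep[flat] = False
        mat = mat[keep]
        sd = sd[keep]
    mat = (mat - mat.mean(axis=-1, keepdims=True)) / sd[:, None]
    return PreparedSeries(data=mat, tr_s=tr_s, excluded=tuple(int(i) for i in flat))
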