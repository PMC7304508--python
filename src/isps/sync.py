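"""Inter-subject phase synchronization (ISPS).

Each prepared voxel time series is turned into an analytic signal via the
Hilbert transform; its angle is the instantaneous phase theta_s(t).  Across
N subjects, synchronization at a (voxel, timepoint) is the mean resultant
length

    R(t) = | (1/N) sum_s exp(i * theta_s(t)) |,

i.e. 1 minus the circular variance of the N phase angles.  R = 1 means all
subjects share the same instantaneous phase; R = 0 means complete phase
dispersion.  This single group-level statistic replaces the pairwise average
angular-distance measure of earlier work; the pairwise form is kept here
only as an independent verification oracle, linked to R by the identity

    R^2 = 1/N + ((N-1)/N) * mean_{s != s'} cos(theta_s - theta_s').
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import signal as ssignal

__all__ = [
    "analytic_phase",
    "sync_at_timepoint",
    "sync_map",
    "pairwise_sync_oracle",
]

_ZERO_MEAN_TOL = 1e-6


def analytic_phase(prepared: np.ndarray) -> np.ndarray:
    """Instantaneous phase of each row via the discrete Hilbert transform.

    Input rows must be (numerically) zero mean — the phase of a signal with
    an offset is not meaningful.  All-zero rows are rejected: their phase is
    undefined.
    """
    x = np.atleast_2d(np.asarray(prepared, dtype=float))
    if np.any(np.ptp(x, axis=-1) == 0):
        raise ValueError("phase undefined for a constant (e.g. all-zero) row")
    scale = np.maximum(np.abs(x).max(axis=-1), 1.0)
    if np.any(np.abs(x.mean(axis=-1)) > _ZERO_MEAN_TOL * scale):
        raise ValueError("analytic_phase requires zero-mean rows (run prep first)")
    analytic = ssignal.hilbert(x, axis=-1)
    out = np.angle(analytic)
    return out if np.asarray(prepared).ndim > 1 else out[0]


def sync_at_timepoint(phases: Sequence[float]) -> float:
    """Synchronization (1 - circular variance) of N phase angles, in [0, 1]."""
    theta = np.asarray(phases, dtype=float)
    if theta.size < 2:
        raise ValueError("synchronization needs at least 2 subjects")
    return float(np.abs(np.exp(1j * theta).mean()))


def sync_map(group_phases: Sequence[np.ndarray]) -> np.ndarray:
    """Voxels x time synchronization matrix across subjects.

    ``group_phases`` holds one voxels x time phase matrix per subject, all
    of identical shape.  The result is the mean resultant length at every
    (voxel, timepoint), clipped into [0, 1] against rounding.
    """
    if len(group_phases) < 2:
        raise ValueError("synchronization needs at least 2 subjects")
    shapes = {p.shape for p in map(np.asarray, group_phases)}
    if len(shapes) != 1:
        raise ValueError(f"phase matrices differ in shape: {sorted(shapes)}")
    resultant = np.zeros(group_phases[0].shape, dtype=complex)
    for p in group_phases:  # streaming sum keeps memory at one subject
        resultant += np.exp(1j * np.asarray(p))
    r = np.abs(resultant) / len(group_phases)
    return np.clip(r, 0.0, 1.0)


def pairwise_sync_oracle(phases: Sequence[float]) -> float:
    """Mean cos(theta_s - theta_s') over ordered pairs s != s'.

    Verification oracle only: tied to the resultant length by
    R^2 = 1/N + ((N-1)/N) * pairwise.
    """
    theta = np.asarray(phases, dtype=float)
    n = theta.size
    if n < 2:
        raise ValueError("pairwise synchronization needs at least 2 subjects")
    diffs = np.cos(theta[:, None] - theta[None, :])
    return float((diffs.sum() - n) / (n * (n - 1)))
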