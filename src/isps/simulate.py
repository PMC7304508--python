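"""Synthetic multi-subject 4D data with planted synchronized networks.

Each subject's series is a sum of condition-locked network responses plus
AR(1) Gaussian noise, on an implicit zero baseline:

    y_v(t) = sum_k [v in mask_k] * A_k * (1 + eta_s) * ref_k(t; delta_s) + e_v(t)

where ref_k is the gamma-HRF-convolved boxcar of network k's condition set,
delta_s ~ N(0, latency_jitter_sd_s) shifts all of subject s's block onsets
(per-subject response latency), eta_s ~ N(0, amplitude_jitter_sd) scales the
response, and e_v is an AR(1) process with stationary standard deviation
``noise_sd`` and lag-1 coefficient ``ar1_coef``, independent across voxels
and subjects.

Latency jitter is the generator's model of inter-subject response
heterogeneity: it destroys the phase alignment that inter-subject
synchronization measures while leaving the GLM-detectable response amplitude
largely intact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .design import BlockDesign, boxcar_from_blocks, build_default_design, hrf_kernel, write_events

__all__ = [
    "Network",
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "simulate_subject",
    "simulate_group",
    "write_dataset",
]


@dataclasses.dataclass(frozen=True)
class Network:
    """A planted synchronized network: where, when, and how strongly."""

    mask: np.ndarray  # boolean volume, shape = grid_dims
    condition_set: frozenset[str]
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    grid_dims: tuple[int, int, int] = (12, 12, 12)
    n_subjects: int = 24
    networks: tuple[Network, ...] = ()
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    latency_jitter_sd_s: float = 0.0
    amplitude_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must be in [0, 1)")
        for net in self.networks:
            if net.mask.shape != tuple(self.grid_dims):
                raise ValueError(
                    f"network mask shape {net.mask.shape} != grid {self.grid_dims}"
                )


@dataclasses.dataclass
class GroundTruth:
    """What was planted: one entry per network plus realized subject factors."""

    networks: tuple[Network, ...]
    latency_shifts_s: np.ndarray  # per subject
    amplitude_factors: np.ndarray  # per subject, multiplies every amplitude


def _cube_mask(grid: tuple[int, int, int], corner: tuple[int, int, int], side: int) -> np.ndarray:
    m = np.zeros(grid, dtype=bool)
    x, y, z = corner
    m[x : x + side, y : y + side, z : z + side] = True
    return m


def default_spec(
    latency_jitter_sd_s: float = 0.0,
    amplitude: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_subjects: int = 24,
    amplitude_jitter_sd: float = 0.1,
    ar1_coef: float = 0.3,
) -> SyntheticSpec:
    """Desk-scale fixture: 12x12x12 grid, 24 subjects, three disjoint 4-cube
    networks locked to physical pain, affective pain and physical control."""
    grid = (12, 12, 12)
    networks = (
        Network(_cube_mask(grid, (0, 0, 0), 4), frozenset({"physical_pain"}), amplitude),
        Network(_cube_mask(grid, (8, 8, 0), 4), frozenset({"affective_pain"}), amplitude),
        Network(_cube_mask(grid, (0, 8, 8), 4), frozenset({"physical_control"}), amplitude),
    )
    return SyntheticSpec(
        grid_dims=grid,
        n_subjects=n_subjects,
        networks=networks,
        noise_sd=noise_sd,
        ar1_coef=ar1_coef,
        latency_jitter_sd_s=latency_jitter_sd_s,
        amplitude_jitter_sd=amplitude_jitter_sd,
        seed=seed,
    )


def _subject_factors(spec: SyntheticSpec, subject_index: int) -> tuple[float, float]:
    rng = np.random.default_rng([spec.seed, 7919, subject_index])
    delta = rng.normal(0.0, spec.latency_jitter_sd_s) if spec.latency_jitter_sd_s else 0.0
    eta = rng.normal(0.0, spec.amplitude_jitter_sd) if spec.amplitude_jitter_sd else 0.0
    return float(delta), float(eta)


def _network_response(
    design: BlockDesign,
    net: Network,
    shift_s: float,
    upsample_per_tr: int = 10,
) -> np.ndarray:
    """Gamma-HRF response of one network on the full acquired volume grid."""
    dt = design.tr_s / upsample_per_tr
    n_fine = design.n_acquired_volumes * upsample_per_tr
    box = boxcar_from_blocks(
        design.blocks_for(net.condition_set), n_fine, dt, shift_s=shift_s
    )
    kernel = hrf_kernel("gamma_no_undershoot", dt)
    return np.convolve(box, kernel)[:n_fine:upsample_per_tr]


def simulate_subject(
    spec: SyntheticSpec, design: BlockDesign, subject_index: int
) -> np.ndarray:
    """One subject's 4D series (x, y, z, t) on the acquired volume grid.

    Deterministic given (spec.seed, subject_index); subjects are mutually
    independent in their noise and heterogeneity draws.
    """
    nx, ny, nz = spec.grid_dims
    n_t = design.n_acquired_volumes
    delta, eta = _subject_factors(spec, subject_index)

    data = np.zeros((nx, ny, nz, n_t))
    for net in spec.networks:
        if net.amplitude == 0:
            continue
        response = net.amplitude * (1.0 + eta) * _network_response(design, net, delta)
        data[net.mask] += response

    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 104729, subject_index])
        phi = spec.ar1_coef
        innov_sd = spec.noise_sd * np.sqrt(1.0 - phi**2)
        noise = rng.normal(0.0, innov_sd, size=(nx * ny * nz, n_t))
        noise[:, 0] = rng.normal(0.0, spec.noise_sd, size=nx * ny * nz)
        for t in range(1, n_t):  # AR(1) recursion, stationary start
            noise[:, t] += phi * noise[:, t - 1]
        data += noise.reshape(nx, ny, nz, n_t)
    return data


def simulate_group(
    spec: SyntheticSpec, design: BlockDesign | None = None
) -> tuple[list[np.ndarray], GroundTruth]:
    """All subjects' series plus the ground truth of what was planted."""
    if spec.n_subjects < 2:
        raise ValueError("a synchronization group needs at least 2 subjects")
    if design is None:
        design = build_default_design()
    series = [simulate_subject(spec, design, s) for s in range(spec.n_subjects)]
    factors = np.array([_subject_factors(spec, s) for s in range(spec.n_subjects)])
    truth = GroundTruth(
        networks=spec.networks,
        latency_shifts_s=factors[:, 0],
        amplitude_factors=1.0 + factors[:, 1],
    )
    return series, truth


# ---------------------------------------------------------------------------
# dataset export

def _rle_encode(flat_bool: np.ndarray) -> list[list[int]]:
    """Run-length encode a flat boolean array as [start, length] runs."""
    idx = np.flatnonzero(flat_bool)
    runs: list[list[int]] = []
    for i in idx:
        if runs and i == runs[-1][0] + runs[-1][1]:
            runs[-1][1] += 1
        else:
            runs.append([int(i), 1])
    return runs


def write_dataset(spec: SyntheticSpec, out_dir, design: BlockDesign | None = None) -> Path:
    """Write one NIfTI per subject, the analysis mask, the events TSV and a
    JSON ground-truth file (network masks run-length encoded, x-fastest)."""
    import nibabel as nib

    if design is None:
        design = build_default_design()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, truth = simulate_group(spec, design)
    affine = np.eye(4)
    for s, vol in enumerate(series):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), out / f"sub-{s:03d}.nii")
    mask = np.ones(spec.grid_dims, dtype=np.uint8)
    nib.save(nib.Nifti1Image(mask, affine), out / "mask.nii")
    write_events(design, out / "events.tsv")
    truth_json = {
        "seed": spec.seed,
        "grid_dims": list(spec.grid_dims),
        "noise_sd": spec.noise_sd,
        "ar1_coef": spec.ar1_coef,
        "latency_jitter_sd_s": spec.latency_jitter_sd_s,
        "amplitude_jitter_sd": spec.amplitude_jitter_sd,
        "latency_shifts_s": truth.latency_shifts_s.tolist(),
        "amplitude_factors": truth.amplitude_factors.tolist(),
        "networks": [
            {
                "condition_set": sorted(net.condition_set),
                "amplitude": net.amplitude,
                "mask_rle": _rle_encode(net.mask.reshape(-1, order="F")),
            }
            for net in truth.networks
        ],
    }
    (out / "truth.json").write_text(json.dumps(truth_json, indent=2))
    return out
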