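"""Blocked task design and HRF-convolved reference functions.

The paradigm modelled here is a single-run blocked design with four
conditions (painful limb pictures, painful faces, and their non-painful
controls), sixteen 16 s picture blocks (four per condition) separated by
jittered 8/10/12 s rest gaps, acquired at TR = 2 s for 218 volumes (436 s)
with the first 10 volumes discarded before analysis.

Reference functions are boxcar regressors convolved with a haemodynamic
response kernel on a fine time grid, sampled back onto the analysed volume
grid.  Two kernels are provided: a single-gamma HRF without a post-peak
undershoot (appropriate for synchronization time courses, which have no
undershoot of their own) and the canonical double-gamma HRF used by the
mass-univariate GLM.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "DEFAULT_CONDITIONS",
    "BlockDesign",
    "ReferenceFunction",
    "build_default_design",
    "boxcar_regressor",
    "hrf_kernel",
    "convolved_reference",
    "default_reference_sets",
    "build_references",
    "read_events",
    "write_events",
]

DEFAULT_CONDITIONS: tuple[str, ...] = (
    "physical_pain",
    "affective_pain",
    "physical_control",
    "affective_control",
)

#: samples per TR used for the fine convolution grid (0.2 s at TR = 2 s)
DEFAULT_UPSAMPLE_PER_TR = 10

#: kernel support in seconds; both HRF shapes have decayed to ~0 by then
HRF_DURATION_S = 32.0


@dataclasses.dataclass(frozen=True)
class BlockDesign:
    """Temporal skeleton of a blocked paradigm.

    ``blocks`` is a time-ordered list of ``(onset_s, duration_s, condition)``
    tuples on the acquisition clock (t = 0 at the first acquired volume).
    """

    condition_labels: tuple[str, ...]
    blocks: tuple[tuple[float, float, str], ...]
    tr_s: float = 2.0
    n_acquired_volumes: int = 218
    n_trim_volumes: int = 10

    def __post_init__(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not (0 <= self.n_trim_volumes < self.n_acquired_volumes):
            raise ValueError("n_trim_volumes must be in [0, n_acquired_volumes)")
        total = self.n_acquired_volumes * self.tr_s
        prev_end = -np.inf
        for onset, dur, cond in self.blocks:
            if cond not in self.condition_labels:
                raise ValueError(f"block condition {cond!r} not in condition_labels")
            if dur <= 0:
                raise ValueError("block duration must be positive")
            if onset < prev_end:
                raise ValueError("blocks must be time-ordered and non-overlapping")
            prev_end = onset + dur
        if self.blocks and prev_end > total + 1e-9:
            raise ValueError("last block extends beyond the acquired run")

    @property
    def n_analyzed_volumes(self) -> int:
        return self.n_acquired_volumes - self.n_trim_volumes

    @property
    def total_duration_s(self) -> float:
        return self.n_acquired_volumes * self.tr_s

    def blocks_for(self, condition_set: Iterable[str]) -> list[tuple[float, float, str]]:
        wanted = _check_condition_set(self, condition_set)
        return [b for b in self.blocks if b[2] in wanted]


@dataclasses.dataclass(frozen=True)
class ReferenceFunction:
    """HRF-convolved condition regressor on the analysed volume grid."""

    condition_set: frozenset[str]
    hrf_kind: str
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


def _check_condition_set(design: BlockDesign, condition_set: Iterable[str]) -> frozenset[str]:
    wanted = frozenset(condition_set)
    unknown = wanted - set(design.condition_labels)
    if unknown:
        raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
    return wanted


def build_default_design(seed: int = 0) -> BlockDesign:
    """Build the default 436 s four-condition blocked design.

    Sixteen 16 s blocks (four per condition) in a seeded pseudorandom order,
    separated by fifteen jittered gaps (five each of 8, 10 and 12 s, seeded
    shuffle), preceded by a 20 s lead-in (covering the 10 discarded volumes)
    and followed by a 10 s tail: 20 + 16*16 + 150 + 10 = 436 s = 218 TRs.

    The published block order is not available, so the default order is a
    fixed seeded surrogate; analyses are order-agnostic given the design.
    """
    rng = np.random.default_rng(seed)
    conditions = list(DEFAULT_CONDITIONS) * 4
    rng.shuffle(conditions)
    gaps = [8.0, 10.0, 12.0] * 5
    rng.shuffle(gaps)

    blocks = []
    t = 20.0
    for i, cond in enumerate(conditions):
        blocks.append((t, 16.0, cond))
        t += 16.0
        if i < len(gaps):
            t += gaps[i]
    return BlockDesign(
        condition_labels=DEFAULT_CONDITIONS,
        blocks=tuple(blocks),
        tr_s=2.0,
        n_acquired_volumes=218,
        n_trim_volumes=10,
    )


def boxcar_from_blocks(
    blocks: Sequence[tuple[float, float, str]],
    n_fine: int,
    dt: float,
    shift_s: float = 0.0,
) -> np.ndarray:
    """0/1 indicator of the given blocks on a fine grid, onsets shifted by
    ``shift_s`` seconds and clamped to the sampled window."""
    out = np.zeros(n_fine)
    t = np.arange(n_fine) * dt
    for onset, dur, _ in blocks:
        on = onset + shift_s
        out[(t >= on) & (t < on + dur)] = 1.0
    return out


def boxcar_regressor(
    design: BlockDesign,
    condition_set: Iterable[str],
    upsample_per_tr: int = DEFAULT_UPSAMPLE_PER_TR,
) -> np.ndarray:
    """Boxcar (0 inside rest, 1 inside blocks of the chosen conditions)
    sampled on the fine pre-convolution grid over the acquired run."""
    wanted = _check_condition_set(design, condition_set)
    dt = design.tr_s / upsample_per_tr
    n_fine = design.n_acquired_volumes * upsample_per_tr
    return boxcar_from_blocks(design.blocks_for(wanted), n_fine, dt)


def hrf_kernel(
    kind: str,
    dt: float,
    lag_s: float = 6.0,
    width_s: float = 3.0,
    undershoot_lag_s: float = 16.0,
    undershoot_ratio: float = 6.0,
    duration_s: float = HRF_DURATION_S,
) -> np.ndarray:
    """Haemodynamic response kernel sampled at step ``dt``, unit sum.

    ``gamma_no_undershoot``: a gamma density with mean ``lag_s`` and standard
    deviation ``width_s`` (shape = (lag/width)^2, scale = width^2/lag) — the
    common default of FSL-style gamma regressors.  Nonnegative everywhere.

    ``double_gamma``: canonical difference of gammas, peak near ``lag_s``,
    undershoot near ``undershoot_lag_s``, peak/undershoot amplitude ratio
    ``undershoot_ratio``; has a negative lobe after the peak.

    Unit-sum normalisation means convolving a constant-1 series returns a
    constant-1 series away from the edges.
    """
    if lag_s <= 0 or width_s <= 0:
        raise ValueError("HRF lag and width must be positive")
    t = np.arange(0.0, duration_s, dt)
    if kind == "gamma_no_undershoot":
        shape = (lag_s / width_s) ** 2
        scale = width_s**2 / lag_s
        h = sstats.gamma.pdf(t, a=shape, scale=scale)
    elif kind == "double_gamma":
        h = sstats.gamma.pdf(t, a=lag_s, scale=1.0)
        h = h - sstats.gamma.pdf(t, a=undershoot_lag_s, scale=1.0) / undershoot_ratio
    else:
        raise ValueError(f"unknown HRF kind {kind!r}")
    s = h.sum()
    if s <= 0:
        raise ValueError("degenerate HRF kernel (non-positive sum)")
    return h / s


def convolved_reference(
    design: BlockDesign,
    condition_set: Iterable[str],
    hrf_kind: str = "gamma_no_undershoot",
    upsample_per_tr: int = DEFAULT_UPSAMPLE_PER_TR,
    shift_s: float = 0.0,
    trim: bool = True,
    **hrf_params: float,
) -> ReferenceFunction:
    """Boxcar -> HRF convolution -> TR grid -> initial-volume trim.

    The boxcar is built on a fine grid (``upsample_per_tr`` samples per TR),
    convolved with the unit-sum kernel, sampled at volume acquisition times
    (t = i * TR), and the first ``n_trim_volumes`` samples are dropped so the
    reference aligns with the analysed data.  ``shift_s`` shifts all block
    onsets (used to model per-subject response latency).
    """
    wanted = _check_condition_set(design, condition_set)
    dt = design.tr_s / upsample_per_tr
    n_fine = design.n_acquired_volumes * upsample_per_tr
    box = boxcar_from_blocks(design.blocks_for(wanted), n_fine, dt, shift_s=shift_s)
    kernel = hrf_kernel(hrf_kind, dt, **hrf_params)
    fine = np.convolve(box, kernel)[:n_fine]
    coarse = fine[:: upsample_per_tr]
    if trim:
        coarse = coarse[design.n_trim_volumes :]
    return ReferenceFunction(condition_set=wanted, hrf_kind=hrf_kind, samples=coarse)


def default_reference_sets(design: BlockDesign) -> dict[str, frozenset[str]]:
    """The eight condition sets used for component-reference association.

    The four single conditions plus the four natural unions: all-physical,
    all-affective, all-pain and all-control.  Requires the default labels.
    """
    labels = set(design.condition_labels)
    if labels != set(DEFAULT_CONDITIONS):
        raise ValueError("default reference sets require the default condition labels")
    return {
        "physical_pain": frozenset({"physical_pain"}),
        "affective_pain": frozenset({"affective_pain"}),
        "physical_control": frozenset({"physical_control"}),
        "affective_control": frozenset({"affective_control"}),
        "physical_all": frozenset({"physical_pain", "physical_control"}),
        "affective_all": frozenset({"affective_pain", "affective_control"}),
        "pain_all": frozenset({"physical_pain", "affective_pain"}),
        "control_all": frozenset({"physical_control", "affective_control"}),
    }


def build_references(
    design: BlockDesign,
    hrf_kind: str = "gamma_no_undershoot",
    condition_sets: Mapping[str, frozenset[str]] | None = None,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Convolved reference sample arrays for each named condition set."""
    if condition_sets is None:
        condition_sets = default_reference_sets(design)
    return {
        name: convolved_reference(design, cset, hrf_kind=hrf_kind, **kwargs).samples
        for name, cset in condition_sets.items()
    }


# ---------------------------------------------------------------------------
# Event-table I/O (BIDS events dialect: onset / duration / trial_type, in s)

def write_events(design: BlockDesign, path) -> None:
    df = pd.DataFrame(
        [(o, d, c) for o, d, c in design.blocks],
        columns=["onset", "duration", "trial_type"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(
    path,
    tr_s: float = 2.0,
    n_acquired_volumes: int = 218,
    n_trim_volumes: int = 10,
    condition_labels: Sequence[str] | None = None,
) -> BlockDesign:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"events table must have columns {sorted(required)}")
    df = df.sort_values("onset")
    labels = (
        tuple(condition_labels)
        if condition_labels is not None
        else tuple(dict.fromkeys(df["trial_type"]))
    )
    blocks = tuple(
        (float(r.onset), float(r.duration), str(r.trial_type)) for r in df.itertuples()
    )
    return BlockDesign(
        condition_labels=labels,
        blocks=blocks,
        tr_s=tr_s,
        n_acquired_volumes=n_acquired_volumes,
        n_trim_volumes=n_trim_volumes,
    )
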