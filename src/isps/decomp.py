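"""Data-driven synchronization networks: spatial ICA on the group sync matrix.

The voxels x time synchronization matrix is decomposed with a fixed-point
negentropy ICA (tanh contrast, PCA/whitening to the requested model order)
under the spatial-ICA convention: the independent sources are spatial maps,
the mixing columns are component time courses.  A component time course is
the degree of group phase synchronization attributed to that network at each
TR — not a BOLD amplitude.

Model order is chosen by split-half replicability: subjects are repeatedly
halved, the sync matrix and ICA are computed per half, components are matched
across halves by Hungarian assignment on absolute spatial correlation, and
the order with the highest mean matched |r| wins.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import skew
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning

from . import sync as _sync

logger = logging.getLogger(__name__)

__all__ = [
    "ICAResult",
    "ComponentLabel",
    "sync_ica",
    "threshold_spatial_map",
    "match_components",
    "replicability_between",
    "split_half_replicability",
    "flag_artifact_components",
]


@dataclasses.dataclass
class ICAResult:
    """Spatial-ICA decomposition of a synchronization matrix.

    ``spatial_maps``: components x voxels, z-scored per component, sign fixed
    so each map's skewness is nonnegative (maps read as clusters of unusually
    high synchronization).  ``time_courses``: components x time.
    """

    spatial_maps: np.ndarray
    time_courses: np.ndarray
    order: int
    seed: int
    n_iter: int
    explained_variance_ratio: float

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]


@dataclasses.dataclass(frozen=True)
class ComponentLabel:
    component: int
    status: str  # "retained" | "unclassified"
    reason: str = ""


def sync_ica(
    sync_matrix: np.ndarray,
    order: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-4,
    n_restarts: int = 5,
) -> ICAResult:
    """Decompose a voxels x time sync matrix into spatial components.

    If ``order`` exceeds the matrix rank the order is reduced to the rank
    with a logged warning (synthetic low-rank inputs are legitimate).
    The fixed-point iteration is restarted from up to ``n_restarts``
    seed-derived initialisations; if none converges within ``max_iter``
    iterations an error reporting the iteration count is raised.
    Deterministic given ``seed``.
    """
    X = np.asarray(sync_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("sync_ica expects a voxels x time matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("sync matrix contains non-finite values")
    n_vox, n_time = X.shape
    if order < 1:
        raise ValueError("order must be >= 1")
    if order >= min(n_vox, n_time):
        raise ValueError("order must be below min(voxels, time)")

    # centre each voxel's time course; whitening centres across voxels
    Xc = X - X.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(Xc)
    if order > rank:
        logger.warning("requested order %d exceeds rank %d; reducing", order, rank)
        order = rank

    pca = PCA(n_components=order, random_state=seed).fit(Xc)
    explained = float(pca.explained_variance_ratio_.sum())

    sources = None
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=order,
            algorithm="deflation",  # one-at-a-time extraction converges more
            fun="logcosh",          # reliably than symmetric updates here
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + 1_000_003 * attempt,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=ConvergenceWarning)
            try:
                sources = ica.fit_transform(Xc)  # voxels x components
                break
            except ConvergenceWarning:
                logger.warning("ICA restart %d: no convergence", attempt + 1)
    if sources is None:
        raise RuntimeError(
            f"ICA did not converge within {max_iter} iterations "
            f"after {n_restarts} restarts"
        )

    maps = sources.T  # components x voxels
    courses = ica.mixing_.T  # components x time

    # empirical z-scoring of each map, skewness-positive sign convention
    maps = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(axis=1, keepdims=True)
    flip = np.where(skew(maps, axis=1) < 0, -1.0, 1.0)
    maps *= flip[:, None]
    courses = courses * flip[:, None]

    return ICAResult(
        spatial_maps=maps,
        time_courses=courses,
        order=order,
        seed=seed,
        n_iter=int(ica.n_iter_),
        explained_variance_ratio=explained,
    )


def threshold_spatial_map(zmap: np.ndarray, z_threshold: float = 2.3) -> np.ndarray:
    """Boolean mask of voxels with z above threshold."""
    return np.asarray(zmap, dtype=float) > z_threshold


def match_components(maps_a: np.ndarray, maps_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of two component sets on absolute spatial correlation.

    Returns (pairing, |r| per matched pair): ``pairing[i]`` is the column of
    ``maps_b`` matched to row ``i`` of ``maps_a``.  Component sets may differ
    in count; the smaller set is fully matched.
    """
    a = np.atleast_2d(maps_a)
    b = np.atleast_2d(maps_b)
    az = (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)
    bz = (b - b.mean(1, keepdims=True)) / b.std(1, keepdims=True)
    corr = np.abs(az @ bz.T) / a.shape[1]
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]


def replicability_between(
    sync_a: np.ndarray,
    sync_b: np.ndarray,
    order: int,
    seed: int = 0,
) -> float:
    """Mean Hungarian-matched |spatial r| between ICAs of two sync matrices."""
    res_a = sync_ica(sync_a, order=order, seed=seed)
    res_b = sync_ica(sync_b, order=order, seed=seed)
    _, rs = match_components(res_a.spatial_maps, res_b.spatial_maps)
    return float(rs.mean())


def split_half_replicability(
    subject_series: Sequence[np.ndarray],
    orders: Sequence[int] = (10, 15, 20),
    n_splits: int = 10,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose the ICA model order by split-half component replicability.

    ``subject_series`` holds one *prepared* voxels x time matrix per subject.
    For each split, subjects are randomly halved (the larger half takes the
    extra subject when the count is odd), a synchronization matrix and ICA
    are computed per half at each order, halves are matched by Hungarian
    assignment on |spatial r|, and replicability(order) is the mean matched
    |r| averaged over splits.  Returns (argmax order, score per order).
    """
    n_sub = len(subject_series)
    if n_sub < 4:
        raise ValueError("split-half replicability needs at least 4 subjects")
    phases = [_sync.analytic_phase(s) for s in subject_series]
    rng = np.random.default_rng(seed)
    scores: dict[int, list[float]] = {int(o): [] for o in orders}
    for split in range(n_splits):
        perm = rng.permutation(n_sub)
        half_b, half_a = perm[: n_sub // 2], perm[n_sub // 2 :]
        sync_a = _sync.sync_map([phases[i] for i in half_a])
        sync_b = _sync.sync_map([phases[i] for i in half_b])
        split_seed = int(rng.integers(2**31))
        for order in orders:
            scores[int(order)].append(
                replicability_between(sync_a, sync_b, order=order, seed=split_seed)
            )
    means = {o: float(np.mean(v)) for o, v in scores.items()}
    best = max(means, key=means.get)
    return best, means


def flag_artifact_components(
    result: ICAResult,
    tissue_masks: Mapping[str, np.ndarray],
    z_threshold: float = 2.3,
    artifact_fraction: float = 0.5,
) -> list[ComponentLabel]:
    """Label components whose suprathreshold voxels sit mostly in non-gray tissue.

    A component is ``unclassified`` when more than ``artifact_fraction`` of
    its z > threshold voxels fall inside white matter, CSF or the brain edge
    (whichever of the masks ``white``, ``csf``, ``edge`` are provided), or
    when it has no suprathreshold voxels at all; otherwise ``retained``.
    """
    bad = np.zeros_like(result.spatial_maps[0], dtype=bool)
    for name in ("white", "csf", "edge"):
        if name in tissue_masks:
            bad |= np.asarray(tissue_masks[name], dtype=bool)
    labels = []
    for k, zmap in enumerate(result.spatial_maps):
        supra = threshold_spatial_map(zmap, z_threshold)
        n = int(supra.sum())
        if n == 0:
            labels.append(ComponentLabel(k, "unclassified", "empty suprathreshold map"))
            continue
        frac = float((supra & bad).sum()) / n
        if frac > artifact_fraction:
            labels.append(
                ComponentLabel(
                    k, "unclassified", f"{100 * frac:.1f}% of suprathreshold voxels in white/CSF/edge"
                )
            )
        else:
            labels.append(ComponentLabel(k, "retained", f"artifact fraction {100 * frac:.1f}%"))
    return labels
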