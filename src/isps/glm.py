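"""Minimal mass-univariate GLM baseline for method comparison.

First level: ordinary least squares per voxel on a design matrix of
double-gamma-convolved condition boxcars, optional nuisance columns, a
discrete-cosine high-pass basis (periods > 128 s) and an intercept.
Second level: per-subject contrast values c'beta, then a one-sample t-test
across subjects per voxel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .design import BlockDesign, convolved_reference

__all__ = [
    "dct_highpass_basis",
    "build_design_matrix",
    "fit_voxelwise",
    "contrast_and_group_ttest",
]


def dct_highpass_basis(n_volumes: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete cosine drift basis: components with period > ``cutoff_s``.

    Basis k (k = 1..K) is cos(pi * k * (2t + 1) / (2N)) with period
    2 * N * TR / k; K = floor(2 * N * TR / cutoff_s) keeps exactly the
    slower-than-cutoff components.
    """
    duration = n_volumes * tr_s
    n_basis = int(np.floor(2.0 * duration / cutoff_s))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, n_basis + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    basis = np.column_stack(cols)
    return basis / np.linalg.norm(basis, axis=0)


def build_design_matrix(
    design: BlockDesign,
    nuisance: np.ndarray | None = None,
    highpass_s: float = 128.0,
) -> pd.DataFrame:
    """Time x regressor matrix on the analysed (trimmed) volume grid.

    Columns: one double-gamma-convolved boxcar per condition, optional
    nuisance columns (e.g. six motion parameters), DCT high-pass basis,
    intercept.  Raises on rank deficiency, naming collinear columns.
    """
    n_t = design.n_analyzed_volumes
    cols: dict[str, np.ndarray] = {}
    for cond in design.condition_labels:
        cols[cond] = convolved_reference(design, {cond}, hrf_kind="double_gamma").samples
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_t:
            raise ValueError("nuisance rows must equal analysed volume count")
        for j in range(nuisance.shape[1]):
            cols[f"nuisance_{j}"] = nuisance[:, j]
    hp = dct_highpass_basis(n_t, design.tr_s, highpass_s)
    for j in range(hp.shape[1]):
        cols[f"dct_{j + 1}"] = hp[:, j]
    cols["intercept"] = np.ones(n_t)

    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # identify offending columns by incremental rank growth
        bad = []
        kept: list[np.ndarray] = []
        for name in X.columns:
            trial = np.column_stack(kept + [X[name].to_numpy()])
            if np.linalg.matrix_rank(trial) == len(kept):
                bad.append(name)
            else:
                kept.append(X[name].to_numpy())
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X


def fit_voxelwise(series: np.ndarray, X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS per voxel.  ``series`` is voxels x time; returns (betas, residual
    variance) with betas voxels x regressors."""
    Xm = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(series, dtype=float))
    if Y.shape[1] != Xm.shape[0]:
        raise ValueError(f"series length {Y.shape[1]} != design rows {Xm.shape[0]}")
    betas, _, rank, _ = np.linalg.lstsq(Xm, Y.T, rcond=None)
    if rank < Xm.shape[1]:
        raise ValueError("design matrix is rank deficient")
    resid = Y.T - Xm @ betas
    dof = Xm.shape[0] - Xm.shape[1]
    resid_var = (resid**2).sum(axis=0) / dof
    return betas.T, resid_var


def contrast_and_group_ttest(
    subject_betas: list[np.ndarray] | np.ndarray,
    contrast: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Group one-sample t-map of per-subject contrast values.

    ``subject_betas`` holds one voxels x regressors beta matrix per subject;
    ``contrast`` is a vector over regressors (zero-padded if shorter, e.g. a
    condition-only contrast).  Returns (t per voxel, boolean flags of voxels
    with zero between-subject variance, where t is undefined and set NaN).
    """
    mats = [np.atleast_2d(np.asarray(b, dtype=float)) for b in subject_betas]
    if len(mats) < 2:
        raise ValueError("group t-test requires at least 2 subjects")
    c = np.zeros(mats[0].shape[1])
    c[: len(contrast)] = np.asarray(contrast, dtype=float)
    con = np.stack([m @ c for m in mats])  # subjects x voxels
    sd = con.std(axis=0, ddof=1)
    flat = sd == 0
    t = np.full(con.shape[1], np.nan)
    ok = ~flat
    t[ok] = con.mean(axis=0)[ok] / (sd[ok] / np.sqrt(len(mats)))
    return t, flat


def group_t_pvalues(t: np.ndarray, n_subjects: int) -> np.ndarray:
    """Two-sided p-values for a group t-map (n - 1 df)."""
    return 2.0 * sstats.t.sf(np.abs(t), df=n_subjects - 1)
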