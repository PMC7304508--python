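"""Percent overlap of thresholded component maps with a labelled parcellation.

Used to situate data-driven synchronization networks relative to a canonical
parcellation (e.g. the Yeo 7-network solution): for each component the
fraction of its suprathreshold voxels falling inside each atlas label is
reported, counting voxels (binary), not weighting by z.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["percent_overlap", "overlap_report"]


def percent_overlap(
    mask: np.ndarray,
    labels: np.ndarray,
    label_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Percent of ``mask`` voxels inside each integer label of ``labels``.

    Label 0 (and any mask voxel outside every positive label) counts as
    ``unassigned``.  Percentages sum to 100 exactly.  Empty masks raise.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    if mask.shape != labels.shape:
        raise ValueError(f"mask shape {mask.shape} != labels shape {labels.shape}")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: overlap undefined")
    inside = labels[mask]
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        count = int((inside == lab).sum())
        rows.append(
            {
                "label": int(lab),
                "name": (label_names or {}).get(int(lab), str(int(lab))),
                "percent": 100.0 * count / n,
            }
        )
    assigned = sum(r["percent"] for r in rows)
    rows.append({"label": 0, "name": "unassigned", "percent": 100.0 - assigned})
    return pd.DataFrame(rows)


def overlap_report(
    component_masks: Mapping[int, np.ndarray],
    labels: np.ndarray,
    label_names: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Overlap table for several components (long format, one row per
    component x label)."""
    frames = []
    for cid, mask in component_masks.items():
        df = percent_overlap(mask, labels, label_names)
        df.insert(0, "component", cid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
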