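"""Component-condition coupling statistics.

Association between a component's synchronization time course and an
HRF-convolved condition reference function is the Pearson correlation, with
two-sided p from the t distribution (n - 2 df) and Bonferroni correction
over conditions x components (default 8 x 9 = 72 tests).

Condition specificity is tested by comparing two correlations with the
independent-samples Fisher r-to-z test:

    Z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1 - 3) + 1/(n2 - 3))

with effect size Cohen's q = |atanh(r1) - atanh(r2)|.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "fisher_z",
    "compare_correlations",
    "component_condition_correlations",
    "correlation_contrasts",
]


def fisher_z(r: float) -> float:
    """Fisher r-to-z transform, atanh(r); requires |r| < 1."""
    if abs(r) >= 1:
        raise ValueError("fisher_z requires |r| < 1")
    return math.atanh(r)


def compare_correlations(
    r1: float, r2: float, n1: int, n2: int
) -> tuple[float, float, float]:
    """Independent-samples Fisher z-test between two correlations.

    Returns (Z, two-sided p, Cohen's q).  Z follows the standard normal
    under the null of equal population correlations; q = |z1 - z2| is the
    scale-free effect size (independent of n).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z-test requires n > 3 in both samples")
    z1, z2 = fisher_z(r1), fisher_z(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    zstat = (z1 - z2) / se
    p = 2.0 * sstats.norm.sf(abs(zstat))
    return zstat, float(p), abs(z1 - z2)


def component_condition_correlations(
    time_courses: np.ndarray,
    references: Mapping[str, np.ndarray],
    m_tests: int | None = None,
    components: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Pearson r of every (component, reference) pair with Bonferroni p.

    ``time_courses`` is components x time; ``references`` maps condition-set
    names to reference sample arrays of the same length.  ``m_tests``
    defaults to n_references x n_components.  Zero-variance series raise.
    """
    tc = np.atleast_2d(np.asarray(time_courses, dtype=float))
    comp_ids = list(components) if components is not None else list(range(tc.shape[0]))
    n = tc.shape[1]
    if n < 4:
        raise ValueError("correlation requires at least 4 timepoints")
    m = m_tests if m_tests is not None else len(references) * len(comp_ids)
    rows = []
    for k, cid in zip(range(tc.shape[0]), comp_ids):
        if tc[k].std() == 0:
            raise ValueError(f"component {cid} time course has zero variance")
        for name, ref in references.items():
            ref = np.asarray(ref, dtype=float)
            if ref.shape[0] != n:
                raise ValueError(f"reference {name!r} length {ref.shape[0]} != {n}")
            if ref.std() == 0:
                raise ValueError(f"reference {name!r} has zero variance")
            r, p = sstats.pearsonr(tc[k], ref)
            rows.append(
                {
                    "component": cid,
                    "condition": name,
                    "r": float(r),
                    "p_raw": float(p),
                    "p_bonferroni": min(1.0, m * float(p)),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def correlation_contrasts(
    table: pd.DataFrame,
    pairs: Sequence[tuple[int, str, str]],
) -> pd.DataFrame:
    """Fisher z contrasts between two conditions of the same component.

    ``pairs`` lists (component id, condition A, condition B) to contrast;
    r and n are looked up in the output of
    :func:`component_condition_correlations`.
    """
    rows = []
    for cid, cond_a, cond_b in pairs:
        sub = table[table["component"] == cid].set_index("condition")
        ra, rb = float(sub.loc[cond_a, "r"]), float(sub.loc[cond_b, "r"])
        na, nb = int(sub.loc[cond_a, "n"]), int(sub.loc[cond_b, "n"])
        zstat, p, q = compare_correlations(ra, rb, na, nb)
        rows.append(
            {
                "component": cid,
                "condition_a": cond_a,
                "condition_b": cond_b,
                "z_a": fisher_z(ra),
                "z_b": fisher_z(rb),
                "Z": zstat,
                "p": p,
                "q": q,
            }
        )
    return pd.DataFrame(rows)
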