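"""Grand averaging and Bonferroni-corrected paired t tests.

Convenience operations for cross-participant analysis: feature matrices
are averaged elementwise after alignment by window index, and per-rule
outcome vectors from two conditions are compared with two-sided paired
t tests under a Bonferroni adjustment (``p_adj = min(1, m * p)``), the
stated multiple-comparison policy; no FDR alternative is offered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = ["grand_average", "paired_tests"]


def grand_average(
    matrices: list[pd.DataFrame],
    participants: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Elementwise mean across participants plus the concatenated long matrix.

    All matrices must share columns and shape (windows are aligned by
    index position).  Returns ``(mean_matrix, long_matrix)`` where the
    long matrix stacks every participant's rows with a ``participant``
    column — the "one big matrix" used for post hoc statistics.
    """
    if not matrices:
        raise ValueError("need at least one participant matrix")
    cols = list(matrices[0].columns)
    shape = matrices[0].shape
    for k, m in enumerate(matrices):
        if list(m.columns) != cols:
            raise ValueError(f"participant {k} has mismatching columns")
        if m.shape != shape:
            raise ValueError(f"participant {k} has shape {m.shape}, expected {shape}")
    stack = np.stack([m.to_numpy(dtype=float) for m in matrices])
    mean = pd.DataFrame(stack.mean(axis=0), columns=cols, index=matrices[0].index)
    if participants is None:
        participants = [f"P{k + 1}" for k in range(len(matrices))]
    long = pd.concat(
        [m.assign(participant=p) for m, p in zip(matrices, participants)],
        ignore_index=True,
    )
    return mean, long


def paired_tests(
    feat_a: pd.DataFrame | np.ndarray,
    feat_b: pd.DataFrame | np.ndarray,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided paired t test per rule/column with Bonferroni adjustment.

    Returns a frame with columns ``t, p, p_adj, significant``; a column
    whose paired differences are identically zero gets t=0, p=1.
    Significance requires ``p_adj < alpha`` (default 0.01, "highly
    significant").
    """
    a = pd.DataFrame(feat_a)
    b = pd.DataFrame(feat_b)
    if a.shape != b.shape:
        raise ValueError(f"paired inputs must share shape, got {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("paired vectors need length >= 3")
    m = a.shape[1]
    rows = []
    for col_a, col_b in zip(a.columns, b.columns):
        x = a[col_a].to_numpy(dtype=float)
        y = b[col_b].to_numpy(dtype=float)
        if np.allclose(x - y, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = _stats.ttest_rel(x, y)
        p_adj = min(1.0, m * float(p))
        rows.append((col_a, float(t), float(p), p_adj, p_adj < alpha))
    return pd.DataFrame(rows, columns=["rule", "t", "p", "p_adj", "significant"]).set_index(
        "rule"
    )
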