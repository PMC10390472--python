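"""Group comparison with the figure-caption star convention.

All tests are conducted at alpha = 0.05 by default. Significance is
annotated ``*`` (p < 0.05), ``**`` (p < 0.01), ``***`` (p < 0.001) and
``†`` for p > alpha, matching the convention used throughout the figures.
No multiplicity correction is applied by default (none is claimed for the
underlying measurements); Holm correction can be switched on.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["significance_stars", "compare_groups"]


def significance_stars(p: float, alpha: float = 0.05) -> str:
    """Map a p-value to the caption annotation."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "†"


def _pairwise_test(a: np.ndarray, b: np.ndarray, method: str) -> float:
    # Degenerate-variance shortcut: identical constant groups are not different.
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    if method == "welch":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    if method == "mannwhitney":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    raise ValueError(f"unknown test method {method!r}")


def compare_groups(
    groups: dict[str, Sequence[float]],
    alpha: float = 0.05,
    method: str = "welch",
    correct: bool = False,
) -> pd.DataFrame:
    """All-pairs two-sided comparison of measurement groups.

    Parameters
    ----------
    groups:
        Mapping of group label to measurement values; every group needs
        n >= 2.
    method:
        ``"welch"`` (default, unequal-variance t test) or ``"mannwhitney"``.
    correct:
        Apply Holm step-down correction across the pairs.

    Returns
    -------
    DataFrame with one row per unordered pair: group labels, group means,
    p-value and star annotation.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")

    rows = []
    for ka, kb in combinations(arrays, 2):
        a, b = arrays[ka], arrays[kb]
        p = _pairwise_test(a, b, method)
        rows.append(
            {
                "group_a": ka,
                "group_b": kb,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "n_a": int(a.size),
                "n_b": int(b.size),
                "pvalue": p,
            }
        )
    out = pd.DataFrame(rows)
    if correct and len(out):
        order = np.argsort(out["pvalue"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["pvalue"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["pvalue"] = adj
    out["significant"] = out["pvalue"] < alpha
    out["stars"] = [significance_stars(p, alpha) for p in out["pvalue"]]
    return out
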