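"""Paired statistical comparison of segmentation methods.

For each structure the paired per-subject metric differences are first
screened for normality with the Shapiro–Wilk test; if normality is not
rejected (p > 0.05) a paired t-test is used, otherwise the Wilcoxon
signed-rank test.  With three methods under comparison, a Bonferroni
correction fixes the per-comparison significance threshold at
0.05 / 3 ≈ 0.0167.  The result records which test fired, so downstream
reports never have to guess.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps


def paired_difference_test(a: np.ndarray, b: np.ndarray, alpha_normality: float = 0.05):
    """Shapiro–Wilk-gated paired test on ``a - b``.

    Returns (test_name, statistic, p_value).  Degenerate all-zero
    differences are reported as ``p = 1`` (no evidence of a difference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.allclose(d, 0.0):
        return "degenerate_zero_diff", 0.0, 1.0
    if np.ptp(d) == 0:  # constant nonzero difference: Shapiro undefined
        t, p = sps.ttest_rel(a, b)
        return "paired_t", float(t), float(p)
    sw_stat, sw_p = sps.shapiro(d)
    if sw_p > alpha_normality:
        t, p = sps.ttest_rel(a, b)
        return "paired_t", float(t), float(p)
    w, p = sps.wilcoxon(d)
    return "wilcoxon_signed_rank", float(w), float(p)


def compare_methods(report_a: pd.DataFrame, report_b: pd.DataFrame,
                    metric: str = "DSC", alpha_family: float = 0.05,
                    n_comparisons: int = 3,
                    structures: Optional[list] = None) -> pd.DataFrame:
    """Per-structure paired comparison of two MetricsReport tables.

    Rows are paired on (subject, structure); structures with fewer than 3
    pairs are marked not testable.  The significance flag uses the
    Bonferroni threshold ``alpha_family / n_comparisons``.
    """
    alpha = alpha_family / n_comparisons
    a = report_a.set_index(["subject", "structure"])
    b = report_b.set_index(["subject", "structure"])
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("reports share no (subject, structure) pairs")
    a, b = a.loc[common], b.loc[common]
    names = structures or sorted({s for _, s in common})

    rows = []
    for name in names:
        sel = [ix for ix in common if ix[1] == name]
        va = a.loc[sel, metric].to_numpy(dtype=float)
        vb = b.loc[sel, metric].to_numpy(dtype=float)
        keep = np.isfinite(va) & np.isfinite(vb)
        va, vb = va[keep], vb[keep]
        row = {"structure": name, "metric": metric, "n_pairs": int(keep.sum()),
               "mean_diff": float(np.mean(va - vb)) if keep.sum() else np.nan,
               "alpha": alpha}
        if keep.sum() < 3:
            row.update({"test": "not_testable", "statistic": np.nan,
                        "p_value": np.nan, "significant": False})
        else:
            test, stat, p = paired_difference_test(va, vb)
            row.update({"test": test, "statistic": stat, "p_value": p,
                        "significant": bool(p < alpha)})
        rows.append(row)
    return pd.DataFrame(rows)
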