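"""Thin statistical summaries used in the consolidated report.

Two-group comparisons use Welch's unequal-variance t-test; within-experiment
pre/post comparisons use Student's paired t-test; depth correlations use
Pearson's r.  Error bars throughout are the standard error of the mean.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["sem", "welch_t", "paired_t", "pearson_r", "group_summary"]


def sem(x) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return float("nan")
    return float(x.std(ddof=1) / np.sqrt(len(x)))


def welch_t(a, b) -> tuple[float, float]:
    """Welch's t-test for two independent samples: (t, p)."""
    r = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(r.statistic), float(r.pvalue)


def paired_t(pre, post) -> tuple[float, float]:
    """Student's paired t-test for pre/post wash comparisons: (t, p)."""
    r = sps.ttest_rel(np.asarray(pre, float), np.asarray(post, float))
    return float(r.statistic), float(r.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    r = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r.statistic), float(r.pvalue)


def group_summary(x) -> dict:
    """n / mean / SEM row for a figure-level quantity."""
    x = np.asarray(x, dtype=float)
    return {"n": int(len(x)), "mean": float(x.mean()) if len(x) else float("nan"), "sem": sem(x)}
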