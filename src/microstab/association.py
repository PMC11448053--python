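"""Feature-level correlation screens with Benjamini-Hochberg FDR.

Links per-feature abundance changes (CLR deltas from a baseline day) to a
covariate such as the percent change in serum 25(OH)D or the community-level
Aitchison distance from baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.stats

from .io import SampleMetadata

__all__ = [
    "clr_change",
    "CorrelationResult",
    "correlate_with_covariate",
    "bh_fdr",
]


def clr_change(
    clr: pd.DataFrame, metadata: SampleMetadata, baseline_day: int = 1
) -> pd.DataFrame:
    """Per-feature CLR change from the baseline day.

    ``clr`` is features x samples. Returns a long-format frame indexed by
    (subject_id, day) with one column per feature holding
    clr(day) - clr(baseline_day). Subjects lacking the baseline day are
    excluded with a warning.
    """
    samples = metadata.samples[metadata.samples.index.isin(clr.columns)]
    out_rows = []
    index = []
    for subject, rows in samples.groupby("subject_id"):
        base_rows = rows[rows["day"] == baseline_day]
        if base_rows.empty:
            warnings.warn(
                f"subject {subject!r} lacks baseline day {baseline_day}; excluded",
                stacklevel=2,
            )
            continue
        base = clr[base_rows.index[0]]
        for sid, day in rows[rows["day"] != baseline_day][["day"]].itertuples():
            out_rows.append((clr[sid] - base).to_numpy())
            index.append((subject, int(day)))
    return pd.DataFrame(
        out_rows,
        index=pd.MultiIndex.from_tuples(index, names=["subject_id", "day"]),
        columns=clr.index,
    )


@dataclass
class CorrelationResult:
    feature_id: str
    coefficient: float
    p_value: float
    q_value: float
    n: int
    method: str
    flag: str | None = None


@lru_cache(maxsize=64)
def _exact_spearman_null(rx: tuple, ry: tuple) -> np.ndarray:
    """Null |rho| distribution by enumerating all permutations of one rank
    vector (feasible for n <= 9; handles ties since actual ranks are used)."""
    ry_arr = np.asarray(ry, dtype=float)
    stats = [
        abs(np.corrcoef(np.asarray(perm, dtype=float), ry_arr)[0, 1])
        for perm in permutations(rx)
    ]
    return np.asarray(stats)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    null = _exact_spearman_null(tuple(rx), tuple(ry))
    p = float((null >= abs(rho) - 1e-12).mean())
    return rho, p


def correlate_with_covariate(
    changes: pd.DataFrame,
    covariate: pd.Series,
    method: str = "pearson",
) -> list[CorrelationResult]:
    """Per-feature correlation of change values with a covariate, BH-adjusted.

    ``changes`` holds observations in rows and features in columns (the
    output of :func:`clr_change`); ``covariate`` is aligned on the same row
    index. Spearman p-values are exact (rank-permutation enumeration) when
    n <= 9, otherwise the usual t-approximation. Features with a constant
    change vector are flagged and excluded from the FDR family.
    """
    cov = covariate.reindex(changes.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some observations")
    x = cov.to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    results: list[CorrelationResult] = []
    testable: list[int] = []
    pvals: list[float] = []
    for i, feat in enumerate(changes.columns):
        y = changes[feat].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            results.append(
                CorrelationResult(feat, float("nan"), float("nan"), float("nan"), n, method, "constant")
            )
            continue
        if method == "pearson":
            r, p = scipy.stats.pearsonr(x, y)
        elif method == "spearman":
            if n <= 9:
                r, p = _spearman_exact_p(x, y)
            else:
                res = scipy.stats.spearmanr(x, y)
                r, p = res.statistic, res.pvalue
        else:
            raise ValueError(f"unknown method {method!r}")
        results.append(CorrelationResult(feat, float(r), float(p), float("nan"), n, method))
        testable.append(len(results) - 1)
        pvals.append(float(p))
    if pvals:
        q = bh_fdr(np.array(pvals))
        for idx, qv in zip(testable, q):
            results[idx].q_value = float(qv)
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q(i) = min_{j >= i} (m * p(j) / j) in sorted order, capped at 1, mapped
    back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q
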