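"""Alpha diversity (Shannon, richness, Faith's PD) and the paired tests
applied to it across study days."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import scipy.stats
import skbio

from .io import FeatureTable

__all__ = [
    "shannon",
    "richness",
    "faith_pd",
    "alpha_diversity_table",
    "paired_wilcoxon",
    "rm_anova",
]


def shannon(sample: np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity −Σ p_i log_base p_i over positive proportions.

    Defaults to base 2 (bits), the common amplicon-pipeline convention.
    """
    x = np.asarray(sample, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundances")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero sample")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def richness(sample: np.ndarray) -> int:
    """Number of features with strictly positive abundance."""
    return int((np.asarray(sample) > 0).sum())


def faith_pd(
    sample: np.ndarray, tree: skbio.TreeNode, feature_ids: list[str]
) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    subtree connecting the observed features to the root.

    The path to the root is included (conventions differ; this one matches
    rooted-tree PD as used in amplicon pipelines). Empty samples have PD 0.
    """
    x = np.asarray(sample, dtype=float)
    observed = [fid for fid, v in zip(feature_ids, x) if v > 0]
    if not observed:
        return 0.0
    tips = {t.name: t for t in tree.tips()}
    missing = [fid for fid in observed if fid not in tips]
    if missing:
        raise ValueError(f"observed feature(s) absent from tree: {missing}")
    seen: set[int] = set()
    total = 0.0
    for fid in observed:
        node = tips[fid]
        while node is not None and id(node) not in seen:
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def alpha_diversity_table(
    table: FeatureTable,
    tree: skbio.TreeNode | None = None,
    shannon_base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample Shannon, richness and (when a tree is given) Faith's PD."""
    rows = {}
    for sid in table.sample_ids:
        col = table.data[sid].to_numpy()
        row = {"shannon": shannon(col, base=shannon_base), "richness": richness(col)}
        if tree is not None:
            row["faith_pd"] = faith_pd(col, tree, table.feature_ids)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_used: int
    n_zero_dropped: int
    mode: str


def paired_wilcoxon(x, y, mode: str = "exact") -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped (reduced-sample convention) and their count
    reported. ``exact`` enumerates all 2^n sign assignments (n <= 25 after
    zero removal); ``normal_approx`` uses the large-sample normal p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    n_zero = int((d == 0).sum())
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero")
    if mode == "exact":
        if n > 25:
            raise ValueError("exact mode limited to n <= 25 after zero removal")
        ranks = scipy.stats.rankdata(np.abs(d))
        w_plus = float(ranks[d > 0].sum())
        # Enumerate the null distribution of W+ over all 2^n sign patterns.
        signs = np.array(list(product((0.0, 1.0), repeat=n)))
        null = signs @ ranks
        p = min(1.0, 2.0 * min((null <= w_plus).mean(), (null >= w_plus).mean()))
        return WilcoxonResult(w_plus, p, n, n_zero, "exact")
    if mode == "normal_approx":
        res = scipy.stats.wilcoxon(d, method="approx", correction=True)
        return WilcoxonResult(float(res.statistic), float(res.pvalue), n, n_zero, mode)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class RMAnovaResult:
    F: float
    p_value: float
    df_time: int
    df_error: int
    note: str = "no sphericity correction applied"


def rm_anova(values, subject, time) -> RMAnovaResult:
    """One-way repeated-measures ANOVA: F = MS_time / MS_(subject x time).

    Requires a complete, balanced subject x time grid. No sphericity
    correction is applied; the result notes this.
    """
    df = pd.DataFrame({"y": values, "subject": subject, "time": time})
    grid = df.pivot_table(index="subject", columns="time", values="y", aggfunc="size")
    if grid.isna().any().any() or (grid != 1).any().any():
        raise ValueError("incomplete or unbalanced subject x time grid")
    wide = df.pivot(index="subject", columns="time", values="y").to_numpy()
    s, t = wide.shape
    grand = wide.mean()
    ss_time = s * ((wide.mean(axis=0) - grand) ** 2).sum()
    ss_subj = t * ((wide.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((wide - grand) ** 2).sum()
    ss_err = ss_total - ss_time - ss_subj
    df_time, df_err = t - 1, (s - 1) * (t - 1)
    ms_time = ss_time / df_time
    ms_err = ss_err / df_err
    if ms_err == 0:
        f = 0.0 if ms_time == 0 else np.inf
    else:
        f = ms_time / ms_err
    p = 1.0 if f == 0 else float(scipy.stats.f.sf(f, df_time, df_err))
    return RMAnovaResult(float(f), p, df_time, df_err)
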