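"""Stability-versus-serum regression and matched-pair randomization.

The headline analysis regresses microbiota stability (reciprocal Aitchison
step distance) on each subject's percent change in serum 25(OH)D. Subjects
were randomized to arms in baseline-serum-matched pairs; that procedure is
reproduced here for design simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .compositional import StabilityRecord

__all__ = [
    "percent_change",
    "RegressionResult",
    "fit_stability_regression",
    "Assignment",
    "randomize_matched_pairs",
]


def percent_change(baseline: float, followup: float) -> float:
    """100 * (followup - baseline) / baseline; baseline must be positive."""
    if baseline <= 0:
        raise ValueError("baseline must be strictly positive")
    return 100.0 * (followup - baseline) / baseline


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    r_squared: float
    adj_r_squared: float
    p_value: float
    n: int
    unit: str
    cluster_robust_p: float | None = None
    note: str = ""


def fit_stability_regression(
    records: list[StabilityRecord],
    serum_change: pd.Series,
    unit: str = "interval",
    cluster_robust: bool = False,
) -> RegressionResult:
    """OLS of stability on percent serum change.

    ``interval`` mode uses every consecutive-interval stability value (the
    subject's single serum change repeated across their intervals, so the
    observations are correlated within subject — flagged in ``note``);
    ``subject_mean`` mode uses one mean-stability point per subject.
    ``cluster_robust`` additionally reports a subject-clustered
    standard-error p-value as an extension of the plain univariable fit.
    """
    rows = [
        (r.subject_id, r.stability)
        for r in records
        if r.stability is not None and r.subject_id in serum_change.index
        and not np.isnan(serum_change[r.subject_id])
    ]
    if unit == "subject_mean":
        df = pd.DataFrame(rows, columns=["subject_id", "stability"])
        df = df.groupby("subject_id", as_index=False)["stability"].mean()
        rows = list(df.itertuples(index=False, name=None))
    elif unit != "interval":
        raise ValueError(f"unknown unit {unit!r}")
    if len(rows) < 3:
        raise ValueError("fewer than 3 usable observations")
    subj = [r[0] for r in rows]
    y = np.array([r[1] for r in rows], dtype=float)
    x = serum_change.loc[subj].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in percent serum change")
    res = scipy.stats.linregress(x, y)
    n = len(y)
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else float("nan")
    note = (
        "interval mode repeats each subject's serum change across intervals; "
        "observations are correlated within subject"
        if unit == "interval"
        else ""
    )
    cluster_p = None
    if cluster_robust:
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": np.array(subj)})
        cluster_p = float(fit.pvalues[1])
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(r2),
        adj_r_squared=float(adj),
        p_value=float(res.pvalue),
        n=n,
        unit=unit,
        cluster_robust_p=cluster_p,
        note=note,
    )


@dataclass
class Assignment:
    group_of: dict[str, str]
    pairs: list[tuple[str, str]]  # (placebo member, treatment member)
    leftover: str | None
    baseline_mean_difference: float
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def randomize_matched_pairs(baseline_serum: pd.Series, seed: int | None = 0) -> Assignment:
    """Matched-pair randomization on baseline serum 25(OH)D.

    Subjects are ordered by baseline serum, consecutive disjoint pairs are
    formed (so each pair has the smallest within-pair difference available),
    and within each pair one subject goes to each arm by a seeded coin flip.
    An odd leftover subject is assigned by a fair coin.
    """
    if len(baseline_serum) < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    ordered = baseline_serum.sort_values(kind="stable")
    ids = list(ordered.index)
    group_of: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    for i in range(0, len(ids) - 1, 2):
        a, b = ids[i], ids[i + 1]
        if rng.integers(2) == 0:
            group_of[a], group_of[b] = "placebo", "treatment"
            pairs.append((a, b))
        else:
            group_of[a], group_of[b] = "treatment", "placebo"
            pairs.append((b, a))
    leftover = None
    if len(ids) % 2 == 1:
        leftover = ids[-1]
        group_of[leftover] = "placebo" if rng.integers(2) == 0 else "treatment"
    means = {
        g: float(baseline_serum[[s for s, gg in group_of.items() if gg == g]].mean())
        for g in ("placebo", "treatment")
    }
    return Assignment(
        group_of=group_of,
        pairs=pairs,
        leftover=leftover,
        baseline_mean_difference=abs(means["placebo"] - means["treatment"]),
        seed=seed,
        extra={"group_means": means},
    )
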