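"""Principal response curves (PRC) and the cross-group score comparison.

PRC is a constrained ordination for longitudinal designs: after removing the
shared time trend, the condition x time effect matrix is fitted by least
squares and reduced to rank one. The dominant singular triplet factors the
fitted response for feature k at condition-time cell d as b_k * c_d — the
per-feature *species scores* b and the *canonical coefficients* c that trace
the response curve, with the baseline level pinned at zero.

Two usage modes:

* two-group mode — condition = arm, partialling out the time main effect;
  the curve is the treatment deviation from the per-time mean.
* single-group mode — condition = day with the first day as baseline and no
  time partialling; features are centred on the baseline-day cell mean so
  the curve reads as change from baseline.

Standardized species scores from per-group PRC fits are cross-compared on
the line of equality; the perpendicular distance |y - x|/sqrt(2) measures a
feature's differential temporal change between arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PRCResult",
    "fit_prc",
    "prc_permutation_test",
    "standardize_scores",
    "PRCComparison",
    "compare_groups",
    "select_top_bins",
]


@dataclass
class PRCResult:
    condition_levels: list[tuple]  # non-baseline (condition, time) cells
    canonical_coefficients: np.ndarray  # one per non-baseline cell
    species_scores: pd.Series  # per feature, unit-norm
    explained_variance_fraction: float
    baseline_level: object
    singular_values: np.ndarray = field(default=None, repr=False)
    fitted: np.ndarray = field(default=None, repr=False)

    def coefficient_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_tuples(self.condition_levels, names=["condition", "time"])
        return pd.Series(self.canonical_coefficients, index=idx)


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    return np.stack([(codes == k).astype(float) for k in range(n_levels)], axis=1)


def fit_prc(
    matrix: pd.DataFrame,
    time,
    condition=None,
    baseline=None,
) -> PRCResult:
    """Fit a first-axis principal response curve.

    ``matrix`` is samples x features (already transformed: Chord, CLR or
    log-centred). ``time`` is the per-sample time factor. In two-group mode
    ``condition`` is the per-sample arm factor and ``baseline`` the reference
    arm; with ``condition=None`` the model runs in single-group mode with
    ``baseline`` a time level (default: the smallest).
    """
    y = matrix.to_numpy(dtype=float)
    features = list(matrix.columns)
    time = np.asarray(time)
    t_levels, t_codes = np.unique(time, return_inverse=True)

    if condition is None:
        # single-group mode: condition := time, baseline := first time level
        if baseline is None:
            baseline = t_levels[0]
        if baseline not in t_levels:
            raise ValueError(f"baseline {baseline!r} not a time level")
        base_mask = time == baseline
        yc = y - y[base_mask].mean(axis=0, keepdims=True)
        design_cells = [(lv, lv) for lv in t_levels if lv != baseline]
        design = np.stack([(time == lv).astype(float) for lv, _ in design_cells], axis=1)
    else:
        condition = np.asarray(condition)
        c_levels = list(np.unique(condition))
        if baseline is None or baseline not in c_levels:
            raise ValueError("two-group mode requires baseline to be a condition level")
        for cl in c_levels:
            for tl in t_levels:
                if not np.any((condition == cl) & (time == tl)):
                    raise ValueError(f"empty design cell ({cl!r}, {tl!r})")
        yc = y - y.mean(axis=0, keepdims=True)
        # partial out the time main effect
        td = _dummies(t_codes, len(t_levels))
        beta, *_ = np.linalg.lstsq(td, yc, rcond=None)
        yr = yc - td @ beta
        design_cells = [
            (cl, tl) for cl in c_levels if cl != baseline for tl in t_levels
        ]
        design = np.stack(
            [((condition == cl) & (time == tl)).astype(float) for cl, tl in design_cells],
            axis=1,
        )
        yc = yr

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient constraint design ({rank} < {design.shape[1]} columns)"
        )
    coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
    fitted = design @ coef

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    b = vt[0]  # unit-norm species scores
    # canonical coefficient per cell = first-axis sample score, constant within cell
    cell_scores = np.empty(len(design_cells))
    axis1 = s[0] * u[:, 0]
    for j, _ in enumerate(design_cells):
        members = design[:, j] > 0
        cell_scores[j] = axis1[members].mean()
    # canonical sign: the largest-|coefficient| entry is positive
    if len(cell_scores) and cell_scores[np.argmax(np.abs(cell_scores))] < 0:
        cell_scores = -cell_scores
        b = -b
    total_fit_ss = float((s**2).sum())
    evf = float(s[0] ** 2 / total_fit_ss) if total_fit_ss > 0 else 0.0
    return PRCResult(
        condition_levels=[tuple(cell) for cell in design_cells],
        canonical_coefficients=cell_scores,
        species_scores=pd.Series(b, index=features),
        explained_variance_fraction=evf,
        baseline_level=baseline,
        singular_values=s,
        fitted=fitted,
    )


def prc_permutation_test(
    matrix: pd.DataFrame,
    time,
    condition,
    baseline,
    subjects,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> dict:
    """Permutation significance of the PRC first axis.

    Whole subjects are freely exchanged between conditions (their samples
    keep their time labels) and the maximum |canonical coefficient| is
    recomputed; p uses the +1 convention.
    """
    rng = np.random.default_rng(seed)
    subjects = np.asarray(subjects)
    condition = np.asarray(condition)
    uniq = pd.unique(subjects)
    subj_cond = pd.Series(condition, index=subjects).groupby(level=0).first()
    obs = fit_prc(matrix, time, condition, baseline)
    stat_obs = float(np.abs(obs.canonical_coefficients).max())
    hits = 0
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_levels = rng.permutation(subj_cond.loc[uniq].to_numpy())
        mapping = dict(zip(uniq, perm_levels))
        cond_perm = np.array([mapping[s] for s in subjects])
        fit = fit_prc(matrix, time, cond_perm, baseline)
        stat = float(np.abs(fit.canonical_coefficients).max())
        null[i] = stat
        if stat >= stat_obs - 1e-12:
            hits += 1
    return {
        "statistic": stat_obs,
        "p_value": (1 + hits) / (1 + n_permutations),
        "null_95th": float(np.quantile(null, 0.95)),
        "n_permutations": n_permutations,
        "seed": seed,
    }


def standardize_scores(scores: pd.Series) -> pd.Series:
    """Z-score to mean 0, SD 1 (population SD, i.e. divide by n)."""
    if len(scores) < 2:
        raise ValueError("need at least 2 features")
    sd = float(np.std(scores.to_numpy(), ddof=0))
    if sd == 0:
        raise ValueError("constant scores cannot be standardized")
    return (scores - scores.mean()) / sd


@dataclass
class PRCComparison:
    table: pd.DataFrame  # columns: score_placebo, score_treatment, distance, quadrant


def compare_groups(scores_a: pd.Series, scores_b: pd.Series) -> PRCComparison:
    """Cross-group comparison of standardized species scores.

    ``scores_a`` (x-axis, placebo) and ``scores_b`` (y-axis, treatment) must
    share the feature set. Perpendicular distance from the line of equality is
    |y - x|/sqrt(2); quadrants follow the convention Q1: x<=0<y (rises under
    treatment only), Q2: x>0,y>0, Q3: x>0,y<=0, Q4: x<=0,y<=0.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("feature sets differ between groups")
    a = scores_a
    b = scores_b.reindex(a.index)
    dist = (b - a).abs() / np.sqrt(2.0)
    quadrant = np.where(
        b > 0,
        np.where(a <= 0, "Q1", "Q2"),
        np.where(a > 0, "Q3", "Q4"),
    )
    return PRCComparison(
        pd.DataFrame(
            {
                "score_placebo": a,
                "score_treatment": b,
                "distance": dist,
                "quadrant": quadrant,
            }
        )
    )


def select_top_bins(
    comparison: PRCComparison,
    annotated: pd.Series,
    n_bins: int = 10,
    n_top_bins: int = 2,
) -> list[str]:
    """Select annotated features in the top histogram bins of |distance|.

    An equal-width histogram over the annotated features' perpendicular
    distances is cut into ``n_bins``; features falling in the ``n_top_bins``
    right-most bins (the largest distances) are returned. If all distances are
    identical there is a single degenerate bin and every annotated feature is
    returned with a warning.
    """
    import warnings

    if n_top_bins > n_bins:
        raise ValueError("n_top_bins cannot exceed n_bins")
    ann = annotated.reindex(comparison.table.index).fillna(False).astype(bool)
    if not ann.any():
        raise ValueError("no annotated features")
    d = comparison.table.loc[ann, "distance"]
    lo, hi = float(d.min()), float(d.max())
    if lo == hi:
        warnings.warn("all distances identical; returning all annotated features", stacklevel=2)
        return list(d.index)
    edges = np.linspace(lo, hi, n_bins + 1)
    cut = edges[n_bins - n_top_bins]
    return list(d.index[d >= cut])
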