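"""PCoA, PERMANOVA and PermDisp with permutation inference.

All three are implemented directly on the distance matrix. PERMANOVA follows
Anderson's pseudo-F partition of squared distances; PermDisp embeds samples
by principal coordinates (keeping imaginary axes from negative eigenvalues)
and tests homogeneity of the distances to group centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.stats
from skbio import DistanceMatrix

from .io import SampleMetadata

__all__ = [
    "Ordination",
    "pcoa",
    "PermutationTestResult",
    "permanova",
    "permdisp",
    "group_distance_summary",
]

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x positive axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (may include negatives)
    negative_coordinates: np.ndarray  # samples x |negative| axes, sqrt(|eigenvalue|)

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def pcoa(dist: DistanceMatrix, tol: float = 1e-9) -> Ordination:
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower-centred matrix -1/2 J D^2 J. Axes with
    positive eigenvalues are scaled by sqrt(eigenvalue); negative eigenvalues
    (non-Euclidean input) are reported and their axes kept separately as
    "imaginary" coordinates for dispersion analysis.
    """
    d = np.asarray(dist.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix is not symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = np.abs(evals)
    pos = evals > tol * scale.max() if scale.max() > 0 else evals > tol
    neg = evals < -tol * scale.max() if scale.max() > 0 else evals < -tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    neg_coords = evecs[:, neg][:, ::-1] * np.sqrt(-evals[neg][::-1])
    return Ordination(list(dist.ids), coords, evals, neg_coords)


@dataclass
class PermutationTestResult:
    statistic_name: str
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False
    extra: dict = field(default_factory=dict)


def _group_info(groups) -> tuple[np.ndarray, list, np.ndarray]:
    labels = np.asarray(groups)
    levels, codes = np.unique(labels, return_inverse=True)
    sizes = np.bincount(codes)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = [lv for lv, s in zip(levels, sizes) if s < 2]
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    return codes, list(levels), sizes


def _permanova_f_batch(d2: np.ndarray, member: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Pseudo-F for a batch of group-membership matrices.

    ``member`` is (n_assignments, n_groups, n_samples) boolean. Uses
    SS_total = (1/n) sum_{i<j} d^2_ij, SS_within = sum_g (1/n_g) sum_{i<j in g} d^2_ij.
    """
    n = d2.shape[0]
    g = member.shape[1]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    # within-group sum over ordered pairs = m D2 m^T; halve for i<j
    within = np.einsum("agi,ij,agj->ag", member.astype(float), d2, member.astype(float)) / 2.0
    ss_within = (within / sizes[None, :]).sum(axis=1)
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def _distinct_relabelings(sizes: np.ndarray) -> int:
    n = int(sizes.sum())
    total = 1
    rem = n
    for s in sizes:
        total *= comb(rem, int(s))
        rem -= int(s)
    return total


def _enumerate_assignments(codes: np.ndarray, levels_n: int) -> np.ndarray:
    """All distinct assignments of the label multiset to positions.

    Returns (n_assignments, n_samples) integer codes. Recursive combinations
    over group slots; only called when the count is <= EXHAUSTIVE_LIMIT.
    """
    n = len(codes)
    sizes = np.bincount(codes, minlength=levels_n)
    out: list[np.ndarray] = []

    def rec(positions: tuple[int, ...], level: int, current: np.ndarray) -> None:
        if level == levels_n - 1:
            filled = current.copy()
            filled[list(positions)] = level
            out.append(filled)
            return
        for chosen in combinations(positions, int(sizes[level])):
            nxt = current.copy()
            nxt[list(chosen)] = level
            rec(tuple(p for p in positions if p not in chosen), level + 1, nxt)

    rec(tuple(range(n)), 0, np.full(n, -1, dtype=int))
    return np.array(out)


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)). The p-value uses label
    permutation with the +1 convention; when the number of distinct
    relabelings is <= 10,000 the null is enumerated exhaustively and the
    p-value is the exact fraction of relabelings with F >= observed.
    """
    codes, levels, sizes = _group_info(groups)
    d2 = np.asarray(dist.data, dtype=float) ** 2
    f_obs = float(_permanova_f_batch(d2, _codes_to_member(codes[None, :], len(levels)), sizes)[0])
    n_distinct = _distinct_relabelings(sizes)
    if n_distinct <= EXHAUSTIVE_LIMIT:
        assignments = _enumerate_assignments(codes, len(levels))
        f_all = _permanova_f_batch(d2, _codes_to_member(assignments, len(levels)), sizes)
        p = float((f_all >= f_obs - 1e-12).mean())
        return PermutationTestResult(
            "pseudo-F", f_obs, p, len(assignments), seed, exhaustive=True,
            extra={"groups": levels},
        )
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    f_perm = _permanova_f_batch(d2, _codes_to_member(perms, len(levels)), sizes)
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_permutations)
    return PermutationTestResult(
        "pseudo-F", f_obs, p, n_permutations, seed, extra={"groups": levels}
    )


def _codes_to_member(codes: np.ndarray, n_levels: int) -> np.ndarray:
    return np.stack([codes == g for g in range(n_levels)], axis=1)


def centroid_distances(dist: DistanceMatrix, groups, center: str = "centroid") -> np.ndarray:
    """Per-sample distance to its own group centroid in PCoA space.

    Negative-eigenvalue axes contribute negatively to the squared distance
    (Anderson's real/imaginary decomposition); the square is floored at zero.
    """
    codes, levels, _ = _group_info(groups)
    ord_ = pcoa(dist)
    real, imag = ord_.coordinates, ord_.negative_coordinates
    z2 = np.empty(len(codes))
    for g in range(len(levels)):
        mask = codes == g
        if center == "centroid":
            c_real = real[mask].mean(axis=0)
            c_imag = imag[mask].mean(axis=0) if imag.size else np.zeros(imag.shape[1])
        elif center == "spatial_median":
            c_real = _spatial_median(real[mask])
            c_imag = imag[mask].mean(axis=0) if imag.size else np.zeros(imag.shape[1])
        else:
            raise ValueError(f"unknown center {center!r}")
        dr2 = ((real[mask] - c_real) ** 2).sum(axis=1)
        di2 = ((imag[mask] - c_imag) ** 2).sum(axis=1) if imag.size else 0.0
        z2[mask] = np.maximum(dr2 - di2, 0.0)
    return np.sqrt(z2)


def _spatial_median(x: np.ndarray, n_iter: int = 200, tol: float = 1e-9) -> np.ndarray:
    # Weiszfeld iteration
    m = x.mean(axis=0)
    for _ in range(n_iter):
        d = np.linalg.norm(x - m, axis=1)
        d = np.where(d < 1e-12, 1e-12, d)
        new = (x / d[:, None]).sum(axis=0) / (1.0 / d).sum()
        if np.linalg.norm(new - m) < tol:
            return new
        m = new
    return m


def _anova_f_batch(values: np.ndarray, member: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for a batch of membership matrices over a fixed vector."""
    n = len(values)
    g = member.shape[1]
    grand = values.mean()
    group_sums = member @ values  # (batch, groups)
    group_means = group_sums / sizes[None, :]
    ss_between = (sizes[None, :] * (group_means - grand) ** 2).sum(axis=1)
    ss_total = ((values - grand) ** 2).sum()
    ss_within = ss_total - ss_between
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permdisp(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 1000,
    seed: int | None = 0,
    center: str = "centroid",
) -> PermutationTestResult:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Computes per-sample distances to the group centroid in PCoA space, then a
    one-way ANOVA F on those distances; the p-value permutes group labels of
    the distance-to-centroid values (+1 convention).
    """
    codes, levels, sizes = _group_info(groups)
    z = centroid_distances(dist, groups, center=center)
    f_obs = float(_anova_f_batch(z, _codes_to_member(codes[None, :], len(levels)).astype(float), sizes)[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_permutations)])
    f_perm = _anova_f_batch(z, _codes_to_member(perms, len(levels)).astype(float), sizes)
    p = (1 + int((f_perm >= f_obs - 1e-12).sum())) / (1 + n_permutations)
    means = {lv: float(z[codes == g].mean()) for g, lv in enumerate(levels)}
    return PermutationTestResult(
        "dispersion-F", f_obs, p, n_permutations, seed,
        extra={"group_mean_dispersion": means},
    )


def group_distance_summary(
    dist: DistanceMatrix, metadata: SampleMetadata
) -> dict[tuple[str, int], np.ndarray]:
    """Within-(group, day) pairwise distance vectors.

    For each stratum with >= 2 samples, the vector of all k(k-1)/2 within-
    stratum pairwise distances, the raw material of the day-by-day
    beta-diversity comparison.
    """
    samples = metadata.samples[metadata.samples.index.isin(set(dist.ids))]
    out: dict[tuple[str, int], np.ndarray] = {}
    for (group, day), rows in samples.groupby(["group", "day"]):
        sids = rows.index.to_list()
        if len(sids) < 2:
            raise ValueError(f"stratum ({group}, {day}) has fewer than 2 samples")
        sub = dist.filter(sids).data
        out[(group, int(day))] = sub[np.triu_indices(len(sids), k=1)]
    return out
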