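"""Compositional geometry: CLR, Aitchison distance, rarefaction, stability.

The centred log-ratio (CLR) transform maps each sample's composition into
Euclidean space, where the ordinary Euclidean metric is the Aitchison
distance. Microbiota *stability* is the reciprocal of the Aitchison distance
between a subject's consecutive time points: small step distances mean a
stable community.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance as ssd
import scipy.stats
from skbio import DistanceMatrix

from .io import FeatureTable, SampleMetadata

__all__ = [
    "clr_transform",
    "chord_transform",
    "rarefy",
    "aitchison_distance",
    "StabilityRecord",
    "stability_series",
    "subject_stability_summary",
    "normalize_metabolites",
    "depth_robustness",
]

DEFAULT_PSEUDOCOUNT = 1.0


def clr_transform(table: FeatureTable, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Centred log-ratio transform, features x samples.

    clr_i = ln((x_i + pc) / g(x + pc)) with g the geometric mean across
    features of the sample. A strictly positive pseudocount is required when
    the table contains zeros. Each sample's CLR values sum to zero.
    """
    x = table.values.astype(float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0 and (x <= 0).any():
        raise ValueError("zeros present: a positive pseudocount is required")
    logx = np.log(x + pseudocount)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=table.feature_ids, columns=table.sample_ids)


def chord_transform(table: FeatureTable) -> pd.DataFrame:
    """Scale each sample vector to unit Euclidean norm (features x samples)."""
    x = table.values.astype(float)
    norms = np.linalg.norm(x, axis=0)
    if (norms == 0).any():
        bad = [s for s, n in zip(table.sample_ids, norms) if n == 0]
        raise ValueError(f"all-zero sample(s): {bad}")
    return pd.DataFrame(x / norms, index=table.feature_ids, columns=table.sample_ids)


@dataclass
class RarefactionResult:
    table: FeatureTable
    depth: int
    dropped: list[str]


def rarefy(table: FeatureTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample each sample's counts to exactly ``depth`` without replacement.

    Samples whose total is below ``depth`` are dropped and reported, not
    errored on. Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.kind != "counts":
        raise ValueError("rarefaction requires a counts table")
    rng = np.random.default_rng(seed)
    counts = table.values.astype(np.int64)
    totals = counts.sum(axis=0)
    keep, dropped, cols = [], [], []
    for j, sid in enumerate(table.sample_ids):
        if totals[j] < depth:
            dropped.append(sid)
            continue
        if totals[j] == depth:
            sub = counts[:, j]
        else:
            sub = rng.multivariate_hypergeometric(counts[:, j], depth)
        keep.append(sid)
        cols.append(sub)
    data = pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((table.shape[0], 0), dtype=np.int64),
        index=table.feature_ids,
        columns=keep,
    )
    return RarefactionResult(FeatureTable(data, kind="counts"), depth, dropped)


def aitchison_distance(
    table: FeatureTable, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples."""
    clr = clr_transform(table, pseudocount).to_numpy().T  # samples x features
    d = ssd.squareform(ssd.pdist(clr, metric="euclidean"))
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass
class StabilityRecord:
    subject_id: str
    group: str
    day_from: int
    day_to: int
    distance: float
    stability: float | None  # 1/distance; None when the interval distance is 0


def stability_series(dist: DistanceMatrix, metadata: SampleMetadata) -> list[StabilityRecord]:
    """Per-subject stability (inverse Aitchison distance) between consecutive days.

    One record per consecutive observed day pair per subject. Subjects with
    fewer than two samples in the distance matrix are skipped with a warning;
    a zero interval distance yields stability ``None`` (flagged) rather than
    infinity.
    """
    ids = set(dist.ids)
    samples = metadata.samples[metadata.samples.index.isin(ids)]
    records: list[StabilityRecord] = []
    for subject, rows in samples.groupby("subject_id"):
        rows = rows.sort_values("day")
        if len(rows) < 2:
            warnings.warn(f"subject {subject!r} has <2 samples; skipped", stacklevel=2)
            continue
        sids = rows.index.to_list()
        days = rows["day"].to_list()
        group = rows["group"].iloc[0]
        for (s0, d0), (s1, d1) in zip(zip(sids, days), zip(sids[1:], days[1:])):
            d = float(dist[s0, s1])
            records.append(
                StabilityRecord(subject, group, d0, d1, d, 1.0 / d if d > 0 else None)
            )
    return records


def subject_stability_summary(records: list[StabilityRecord]) -> pd.DataFrame:
    """Per-subject mean interval distance and mean stability."""
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "distance": r.distance,
                "stability": r.stability,
            }
            for r in records
        ]
    )
    return df.groupby("subject_id").agg(
        group=("group", "first"),
        mean_distance=("distance", "mean"),
        mean_stability=("stability", "mean"),
        n_intervals=("distance", "size"),
    )


def normalize_metabolites(table: FeatureTable, metadata: SampleMetadata) -> pd.DataFrame:
    """Normalize metabolite intensities to per-gram fecal abundance.

    value -> ln(1 + abundance / fecal_weight), then per-feature mean centring
    across samples. Requires a positive ``fecal_weight`` for every sample in
    the table.
    """
    if "fecal_weight" not in metadata.samples.columns:
        raise ValueError("metadata lacks fecal_weight")
    weights = metadata.samples["fecal_weight"].reindex(table.sample_ids)
    if weights.isna().any() or (weights <= 0).any():
        bad = weights.index[weights.isna() | (weights <= 0)].tolist()
        raise ValueError(f"missing or non-positive fecal weight for sample(s) {bad}")
    per_gram = table.values / weights.to_numpy()[None, :]
    logged = np.log1p(per_gram)
    centred = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centred, index=table.feature_ids, columns=table.sample_ids)


def depth_robustness(
    dist: DistanceMatrix,
    read_counts: pd.Series,
    n_permutations: int = 999,
    seed: int = 0,
) -> dict:
    """Diagnostic: does the distance track sequencing-depth differences?

    Spearman correlation between pairwise distance and |Δ read count| over all
    sample pairs, with a permutation p-value obtained by shuffling the
    per-sample read totals. A depth-robust metric (CLR on rarefied counts)
    gives a correlation near zero.
    """
    counts = read_counts.reindex(dist.ids)
    if counts.isna().any():
        raise ValueError("read counts missing for some samples in the distance matrix")
    n = len(dist.ids)
    if n < 3:
        raise ValueError("need at least 3 samples (>=3 pairs) for a correlation")
    c = counts.to_numpy(dtype=float)
    if np.ptp(c) == 0:
        return {"rho": float("nan"), "p_value": float("nan"), "flag": "constant read counts"}
    iu = np.triu_indices(n, k=1)
    d = dist.data[iu]
    delta = np.abs(c[:, None] - c[None, :])[iu]
    rho = scipy.stats.spearmanr(d, delta).statistic
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(c)
        dp = np.abs(perm[:, None] - perm[None, :])[iu]
        r = scipy.stats.spearmanr(d, dp).statistic
        if abs(r) >= abs(rho):
            hits += 1
    return {
        "rho": float(rho),
        "p_value": (1 + hits) / (1 + n_permutations),
        "n_pairs": len(d),
        "flag": None,
    }
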