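"""Readers and writers for the formats the pipeline touches.

Feature tables and metadata are tab-separated text; phylogenies are Newick;
networks are serialized as edge-list TSV. Everything read here is validated
against the invariants the downstream statistics rely on (non-negative
abundances, unique identifiers, one subject per sample).
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "FeatureTableError",
    "MetadataError",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "total_branch_length",
    "read_distance_matrix",
    "write_distance_matrix",
]

GROUPS = ("placebo", "treatment")


class FeatureTableError(ValueError):
    """Raised when a feature table violates its invariants."""


class MetadataError(ValueError):
    """Raised when sample metadata is malformed."""


@dataclass
class FeatureTable:
    """Non-negative feature x sample abundance matrix.

    ``data`` is a pandas DataFrame with feature identifiers as the index and
    sample identifiers as columns. ``kind`` distinguishes integer sequencing
    counts from continuous abundances (e.g. LC-MS feature intensities).
    """

    data: pd.DataFrame
    kind: Literal["counts", "abundance"] = "counts"

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        self.validate()

    def validate(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise FeatureTableError(f"duplicate feature identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FeatureTableError(f"duplicate sample identifiers: {dups}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise FeatureTableError("non-finite value in feature table")
        if (vals < 0).any():
            f, s = np.argwhere(vals < 0)[0]
            raise FeatureTableError(
                f"negative value at feature {self.data.index[f]!r}, "
                f"sample {self.data.columns[s]!r}"
            )
        if self.kind == "counts" and not np.allclose(vals, np.round(vals)):
            raise FeatureTableError("counts table contains non-integral values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        return FeatureTable(self.data[list(sample_ids)], kind=self.kind)


@dataclass
class SampleMetadata:
    """Per-sample design information plus per-subject serum endpoints.

    ``samples`` is indexed by sample identifier with columns ``subject_id``,
    ``group`` (placebo/treatment), ``day`` and optionally ``fecal_weight``
    (grams, metabolite samples). ``subjects`` is indexed by subject identifier
    with optional ``serum_baseline`` / ``serum_end`` (ng/mL 25(OH)D).
    """

    samples: pd.DataFrame
    subjects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"subject_id", "group", "day"}
        missing = required - set(self.samples.columns)
        if missing:
            raise MetadataError(f"missing required metadata columns: {sorted(missing)}")
        if self.samples.index.has_duplicates:
            raise MetadataError("duplicate sample identifiers in metadata")
        bad = set(self.samples["group"]) - set(GROUPS)
        if bad:
            raise MetadataError(
                f"unknown group label(s) {sorted(bad)}; accepted values are {GROUPS}"
            )
        pairs = self.samples[["subject_id", "day"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise MetadataError(
                f"duplicate (subject, day) pair: ({dup['subject_id']!r}, {dup['day']})"
            )
        for col in ("serum_baseline", "serum_end"):
            if col in self.subjects.columns:
                vals = self.subjects[col].dropna()
                if (vals <= 0).any():
                    raise MetadataError(f"{col} must be strictly positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def group_of(self, sample_id: str) -> str:
        return self.samples.at[sample_id, "group"]

    def subject_table(self) -> pd.DataFrame:
        """One row per subject with group and serum columns merged in."""
        per_subj = (
            self.samples.reset_index()
            .groupby("subject_id")
            .agg(group=("group", "first"))
        )
        if len(self.subjects):
            per_subj = per_subj.join(self.subjects, how="left")
        return per_subj

    def percent_serum_change(self) -> pd.Series:
        """Per-subject percent change in serum 25(OH)D, baseline to end."""
        subj = self.subject_table()
        if "serum_baseline" not in subj.columns or "serum_end" not in subj.columns:
            raise MetadataError("serum endpoints absent from metadata")
        base = subj["serum_baseline"]
        if (base.dropna() <= 0).any():
            raise MetadataError("non-positive serum baseline")
        return 100.0 * (subj["serum_end"] - subj["serum_baseline"]) / base


def read_feature_table(
    path: str | Path,
    orientation: Literal["features_in_rows", "samples_in_rows"] = "features_in_rows",
    kind: Literal["counts", "abundance"] = "counts",
) -> FeatureTable:
    """Read a TSV feature table, normalizing orientation to features x samples.

    The first column must hold row identifiers and the header row the column
    identifiers. Ragged rows, duplicate identifiers and negative values raise
    :class:`FeatureTableError` naming the offender.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FeatureTableError(f"{path}: empty file")
    header = lines[0].split("\t")
    width = len(header)
    for i, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != width:
            raise FeatureTableError(f"{path}: ragged row at line {i}")
    df = pd.read_csv(_stdio.StringIO("\n".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FeatureTableError(f"{path}: non-numeric entry ({exc})") from None
    if orientation == "samples_in_rows":
        df = df.T
    return FeatureTable(df, kind=kind)


def read_biom_json(path: str | Path, kind: Literal["counts", "abundance"] = "counts") -> FeatureTable:
    """Read a feature table from the JSON dialect of the BIOM format.

    Supports dense and sparse matrix encodings; the matrix is expected to be
    feature-major (rows = observations), the convention of amplicon pipelines.
    """
    doc = json.loads(Path(path).read_text())
    feature_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(feature_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    return FeatureTable(pd.DataFrame(mat, index=feature_ids, columns=sample_ids), kind=kind)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data
    if table.kind == "counts":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="feature_id")


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read sample metadata TSV.

    Required columns: ``sample_id``, ``subject_id``, ``group``, ``day``.
    Optional per-subject columns ``serum_baseline`` / ``serum_end`` (repeated
    on each of the subject's rows) and per-sample ``fecal_weight``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    required = ["sample_id", "subject_id", "group", "day"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing required column(s) {missing}")
    df["sample_id"] = df["sample_id"].str.strip()
    df["subject_id"] = df["subject_id"].str.strip()
    df["group"] = df["group"].astype(str).str.strip()
    df["day"] = df["day"].astype(int)
    df = df.set_index("sample_id")

    serum_cols = [c for c in ("serum_baseline", "serum_end") if c in df.columns]
    subjects = pd.DataFrame()
    if serum_cols:
        subjects = df.groupby("subject_id")[serum_cols].first()
        for col in serum_cols:
            incons = df.groupby("subject_id")[col].nunique(dropna=True) > 1
            if incons.any():
                raise MetadataError(
                    f"{path}: inconsistent {col} within subject(s) "
                    f"{subjects.index[incons].tolist()}"
                )
    keep = ["subject_id", "group", "day"]
    if "fecal_weight" in df.columns:
        keep.append("fecal_weight")
    return SampleMetadata(df[keep], subjects)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.samples.copy()
    for col in ("serum_baseline", "serum_end"):
        if col in metadata.subjects.columns:
            df[col] = df["subject_id"].map(metadata.subjects[col])
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_newick(path: str | Path) -> skbio.TreeNode:
    """Read a rooted Newick tree; absent branch lengths default to 0."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate leaf names in tree: {dups}")
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def total_branch_length(tree: skbio.TreeNode) -> float:
    return sum(n.length or 0.0 for n in tree.traverse(include_self=True))


def read_distance_matrix(path: str | Path) -> "skbio.DistanceMatrix":
    df = pd.read_csv(path, sep="\t", index_col=0)
    return skbio.DistanceMatrix(df.to_numpy(), ids=list(df.index.astype(str)))


def write_distance_matrix(dm: "skbio.DistanceMatrix", path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def __getattr__(name: str):
    # edge-list I/O lives with the network types; re-exported here so all
    # readers/writers are reachable from one module
    if name in ("write_edge_list", "read_edge_list"):
        from . import networks

        return getattr(networks, name)
    raise AttributeError(name)
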