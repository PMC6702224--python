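"""Readers and writers for the on-disk formats the pipeline touches.

Everything is plain TSV or GMT text.  Expression matrices are features x
samples with a feature-id first column and a sample-id header row; sample
metadata is one row per brain donor; miRNA->target tables follow a
TargetScan-style layout (mirna, gene, transcript, n_sites); gene sets use
the Gene Matrix Transposed (GMT) convention; ranked lists use the two-column
RNK convention.

Readers validate rather than coerce: duplicate identifiers, non-numeric
cells, ragged rows, fractional counts and empty gene sets are all errors.
Writers produce files their readers round-trip bit-faithfully (floats are
serialised with ``repr`` precision).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "TargetMap",
    "GeneSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_table",
    "write_sample_table",
    "read_target_map",
    "write_target_map",
    "read_gmt",
    "write_gmt",
    "read_rank_file",
    "write_rank_file",
]

EXPRESSION_KINDS = ("counts", "cpm", "log_cpm", "continuous")

#: metadata columns every SampleTable carries; missing values are allowed in
#: the optional block (doses, antidepressant, cotinine).
SAMPLE_COLUMNS = [
    "sample_id",
    "age_years",
    "diagnosis",
    "sex",
    "race",
    "batch",
    "ph",
    "pmi_hours",
    "cpze_lifetime",
    "cpze_daily",
    "cpze_last",
    "antidepressant",
    "cotinine",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with identifier metadata.

    ``kind`` records the scale of the values: raw ``counts`` (non-negative
    integers), ``cpm`` (counts per million), ``log_cpm`` or generic
    ``continuous`` (e.g. microarray mRNA intensities).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values)
        if self.kind not in EXPRESSION_KINDS:
            raise ValueError(f"unknown expression kind {self.kind!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.kind == "counts":
            v = self.values
            if not np.issubdtype(v.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(v < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(v, np.round(v)):
                raise ValueError("counts must be integers")
            self.values = np.asarray(np.round(v), dtype=np.int64)
        else:
            self.values = np.asarray(self.values, dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            self.feature_ids, list(sample_ids), self.values[:, cols], self.kind
        )

    def select_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in idx]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        rows = [idx[f] for f in feature_ids]
        return ExpressionMatrix(
            list(feature_ids), self.sample_ids, self.values[rows, :], self.kind
        )


@dataclass
class SampleTable:
    """Per-donor metadata: age (negative = gestational), diagnosis, covariates.

    Ages are post-natal years; fetal samples carry negative ages, bounded
    below by -0.75 so the post-conception age (age + ~280 days) stays
    positive.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in SAMPLE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[SAMPLE_COLUMNS + [c for c in df.columns if c not in SAMPLE_COLUMNS]]
        df["sample_id"] = df["sample_id"].astype(str)
        df["age_years"] = df["age_years"].astype(float)
        _check_unique(df["sample_id"].tolist(), "sample")
        if np.any(df["age_years"] <= -0.75):
            raise ValueError("age_years must exceed -0.75 (post-conception age positive)")
        bad = set(df["diagnosis"].dropna()) - {"control", "case"}
        if bad:
            raise ValueError(f"diagnosis must be 'control' or 'case', got {sorted(bad)}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.data.loc[mask].reset_index(drop=True))

    def cases(self) -> "SampleTable":
        return self.subset(self.data["diagnosis"] == "case")

    def controls(self) -> "SampleTable":
        return self.subset(self.data["diagnosis"] == "control")


@dataclass
class TargetMap:
    """miRNA -> (gene, transcript, n_sites) predicted-binding-site records."""

    records: pd.DataFrame  # columns: mirna_id, gene_id, transcript_id, n_sites

    REQUIRED = ["mirna_id", "gene_id", "transcript_id", "n_sites"]

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"target map missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("target map has no records")
        df = df[self.REQUIRED]
        for c in self.REQUIRED[:3]:
            df[c] = df[c].astype(str)
        df["n_sites"] = df["n_sites"].astype(int)
        if np.any(df["n_sites"] < 1):
            raise ValueError("n_sites must be >= 1")
        dup = df.duplicated(subset=["mirna_id", "transcript_id"])
        if dup.any():
            raise ValueError("duplicate (mirna, transcript) records")
        self.records = df.reset_index(drop=True)

    @property
    def mirnas(self) -> set[str]:
        return set(self.records["mirna_id"])

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene_id"])

    def pairs(self) -> pd.DataFrame:
        """Unique (mirna_id, gene_id) pairs with summed site counts."""
        return (
            self.records.groupby(["mirna_id", "gene_id"], as_index=False)["n_sites"]
            .sum()
            .sort_values(["mirna_id", "gene_id"])
            .reset_index(drop=True)
        )


@dataclass
class GeneSet:
    name: str
    members: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        deduped = list(dict.fromkeys(self.members))
        if len(deduped) != len(self.members):
            warnings.warn(f"gene set {self.name!r}: duplicate members removed")
            self.members = deduped

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} != set name {gs.name!r}")

    @classmethod
    def from_sets(cls, sets: Iterable[GeneSet]) -> "GeneSetCollection":
        out: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.name in out:
                raise ValueError(f"duplicate gene-set name {gs.name!r}")
            out[gs.name] = gs
        return cls(out)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path, kind: str = "counts") -> ExpressionMatrix:
    """Read a features x samples TSV (first column feature ids, header row
    sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError("no features in expression matrix")
    if df.isna().any().any():
        raise ValueError("ragged or missing cells in expression matrix")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in expression matrix: {exc}") from exc
    return ExpressionMatrix(list(df.index), list(df.columns), values, kind)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for fid, row in zip(matrix.feature_ids, matrix.values):
            if matrix.kind == "counts":
                cells = [str(int(v)) for v in row]
            else:
                cells = [repr(float(v)) for v in row]
            fh.write(fid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# sample tables


def read_sample_table(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "batch": str})
    return SampleTable(df)


def write_sample_table(table: SampleTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# target maps


def read_target_map(
    path,
    column_map: Mapping[str, str] | None = None,
) -> TargetMap:
    """Read a TargetScan-style TSV.

    Expected columns: ``mirna``, ``gene``, ``transcript``, ``n_sites``.
    ``column_map`` renames file columns to these names, so either the total
    or the conserved site-count column of a real TargetScan dump can be
    selected.  Duplicate (mirna, transcript) rows are summed with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {"mirna": "mirna_id", "gene": "gene_id", "transcript": "transcript_id"}
    if column_map:
        df = df.rename(columns=dict(column_map))
    df = df.rename(columns=rename)
    missing = [c for c in TargetMap.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"target map file missing columns: {missing}")
    if len(df) and np.any(df["n_sites"].astype(int) < 1):
        raise ValueError("n_sites must be >= 1")
    dup = df.duplicated(subset=["mirna_id", "transcript_id"])
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate (mirna, transcript) rows aggregated by summing n_sites"
        )
        df = df.groupby(
            ["mirna_id", "gene_id", "transcript_id"], as_index=False
        )["n_sites"].sum()
    return TargetMap(df)


def write_target_map(target_map: TargetMap, path) -> None:
    df = target_map.records.rename(
        columns={"mirna_id": "mirna", "gene_id": "gene", "transcript_id": "transcript"}
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets and rank files


def read_gmt(path) -> GeneSetCollection:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {ln}: set with 0 members")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise ValueError(f"GMT line {ln}: set {name!r} with 0 members")
            sets.append(GeneSet(name, members, desc))
    if not sets:
        raise ValueError("empty GMT file")
    return GeneSetCollection.from_sets(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            desc = gs.description or "."
            fh.write("\t".join([gs.name, desc] + list(gs.members)) + "\n")


def write_rank_file(ranked: Sequence[tuple[str, float]], path) -> None:
    """Write an id/score rank file, sorted by descending score, ties broken
    by ascending id (deterministic GSEA input)."""
    for fid, score in ranked:
        if not np.isfinite(score):
            raise ValueError(f"non-finite score for {fid!r}")
    ordered = sorted(ranked, key=lambda t: (-t[1], t[0]))
    with open(path, "w") as fh:
        for fid, score in ordered:
            fh.write(f"{fid}\t{repr(float(score))}\n")


def read_rank_file(path) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"rank file line {ln}: expected 2 columns")
            fid, score = parts[0], float(parts[1])
            if not np.isfinite(score):
                raise ValueError(f"rank file line {ln}: non-finite score")
            out.append((fid, score))
    _check_unique([f for f, _ in out], "ranked feature")
    return out
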