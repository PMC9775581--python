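"""Readers/writers for the package's tabular formats, with strict label handling.

All matrices are TSV with a header row and a first column of row labels.
The canonical in-memory orientation is samples x features; files whose rows
are features (the common TCGA layout, genes x patients) are transposed on
read by declaring ``orientation="features"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "SurvivalTable",
    "GeneSetCollection",
    "read_matrix",
    "write_matrix",
    "align_samples",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
]


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)


@dataclass
class OmicsMatrix:
    """A labeled samples x features numeric matrix for one genomic domain.

    Parameters
    ----------
    sample_ids, feature_ids
        Ordered, unique string labels for rows and columns of ``values``.
    values
        Real matrix of shape ``(len(sample_ids), len(feature_ids))`` with
        only finite entries.
    domain
        Free-text modality tag, e.g. ``"rnaseq"`` or ``"methylation"``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    domain: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite; apply the NA policy before construction")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, ids: Sequence[str]) -> "OmicsMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in idx]
        if missing:
            raise KeyError(f"samples not present: {missing[:5]}")
        rows = [idx[s] for s in ids]
        return OmicsMatrix(list(ids), list(self.feature_ids), self.values[rows], self.domain)

    def subset_features(self, ids: Sequence[str]) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in idx]
        if missing:
            raise KeyError(f"features not present: {missing[:5]}")
        cols = [idx[f] for f in ids]
        return OmicsMatrix(list(self.sample_ids), list(ids), self.values[:, cols], self.domain)


@dataclass
class SurvivalTable:
    """Per-sample right-censored survival records (time in days, event 1=death)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.sample_ids, "sample")
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != self.time.shape:
            raise ValueError("time/event length must match sample_ids")
        bad_t = np.where(self.time < 0)[0]
        if bad_t.size:
            raise ValueError(f"negative survival time at row {bad_t[0]}")
        bad_e = np.where(~np.isin(self.event, (0, 1)))[0]
        if bad_e.size:
            raise ValueError(f"event must be 0 or 1; offending row {bad_e[0]}")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class GeneSetCollection:
    """Named, ordered collection of non-empty feature-id sets (GMT semantics)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_matrix(path, orientation: str = "samples", na_policy: str = "drop", domain: str = "") -> OmicsMatrix:
    """Read a labeled TSV matrix into canonical samples x features orientation.

    ``orientation`` declares what the file's *rows* are: ``"samples"`` or
    ``"features"`` (the latter is transposed).  Features containing any
    non-finite cell after parsing are dropped (``na_policy="drop"``, the only
    policy) with a logged count: the fusion methods need complete matrices.
    """
    if orientation not in ("samples", "features"):
        raise ValueError("orientation must be 'samples' or 'features'")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ncol = len(header) - 1
        col_labels = header[1:]
        row_labels: list[str] = []
        rows: list[list[str]] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != ncol + 1:
                raise ValueError(f"{path}: ragged row at line {lineno} ({len(parts)-1} of {ncol} cells)")
            row_labels.append(parts[0])
            rows.append(parts[1:])
    _check_unique(row_labels, "row")
    _check_unique(col_labels, "column")
    df = pd.DataFrame(rows, index=row_labels, columns=col_labels)
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if orientation == "features":
        values = values.T
        sample_ids, feature_ids = col_labels, row_labels
    else:
        sample_ids, feature_ids = row_labels, col_labels
    bad = ~np.all(np.isfinite(values), axis=0)
    if bad.any():
        if na_policy != "drop":
            raise ValueError(f"unknown NA policy {na_policy!r}")
        logger.info("dropping %d/%d features with non-finite values", int(bad.sum()), len(feature_ids))
        feature_ids = [f for f, b in zip(feature_ids, bad) if not b]
        values = values[:, ~bad]
    return OmicsMatrix(list(sample_ids), list(feature_ids), values, domain=domain)


def write_matrix(m: OmicsMatrix, path, orientation: str = "samples") -> None:
    """Write an OmicsMatrix as labeled TSV; ``orientation`` picks the row axis."""
    df = m.to_frame()
    if orientation == "features":
        df = df.T
    df.to_csv(path, sep="\t", index_label="id")


def align_samples(matrices: Sequence[OmicsMatrix]) -> list[OmicsMatrix]:
    """Restrict all matrices to their common samples, in lexicographic order.

    The shared deterministic order makes downstream factorizations independent
    of input file order.  Raises if fewer than two matrices are given or the
    intersection is empty.
    """
    if len(matrices) < 2:
        raise ValueError("align_samples needs at least two matrices")
    common = set(matrices[0].sample_ids)
    for m in matrices[1:]:
        common &= set(m.sample_ids)
    if not common:
        raise ValueError("no samples shared by all matrices")
    order = sorted(common)
    return [m.subset_samples(order) for m in matrices]


def read_gmt(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name, description, tab-separated members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line {lineno} has fewer than 3 fields")
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene set name {name!r} at line {lineno}")
            if not members:
                raise ValueError(f"{path}: gene set {name!r} at line {lineno} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll:
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_survival(path) -> SurvivalTable:
    """Read a sample/time/event TSV into a validated SurvivalTable."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "time", "event"}
    if not required.issubset(df.columns):
        raise ValueError(f"survival table must have columns {sorted(required)}; got {list(df.columns)}")
    time = pd.to_numeric(df["time"], errors="coerce").to_numpy()
    event = pd.to_numeric(df["event"], errors="coerce").to_numpy()
    for i in range(len(df)):
        if not np.isfinite(time[i]) or time[i] < 0:
            raise ValueError(f"invalid survival time at row {i}: {df['time'].iloc[i]!r}")
        if event[i] not in (0, 1):
            raise ValueError(f"event must be 0 or 1 at row {i}: {df['event'].iloc[i]!r}")
    return SurvivalTable(list(df["sample"].astype(str)), time, event.astype(int))


def write_survival(t: SurvivalTable, path) -> None:
    pd.DataFrame({"sample": t.sample_ids, "time": t.time, "event": t.event}).to_csv(
        path, sep="\t", index=False
    )
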