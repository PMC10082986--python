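"""Expression-matrix containers and delimited-text I/O.

The in-memory convention is samples in rows, genes in columns: each sample
is a p-vector of expression values and carries an integer class label in
``{1..C}``.  Missing values are represented as NaN internally; on disk they
may appear as empty cells or the string ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_NA_VALUES = ["", "NA", "na", "NaN", "nan"]


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad cells, missing labels)."""


class EmptyDatasetError(ValueError):
    """A filtering stage removed every gene (or every sample)."""


@dataclass
class ExpressionDataset:
    """A labelled samples x genes expression matrix.

    Parameters
    ----------
    matrix : (n, p) float array; NaN marks a missing measurement.
    gene_ids : p unique gene identifiers.
    sample_ids : n unique sample identifiers.
    labels : n integer class labels in ``{1..C}``.
    label_mapping : optional record of original label -> integer code.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    label_mapping: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, p = self.matrix.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise FormatError(
                f"matrix has {n} rows but {len(self.sample_ids)} sample ids "
                f"and {len(self.labels)} labels"
            )
        if len(self.gene_ids) != p:
            raise FormatError(f"matrix has {p} columns but {len(self.gene_ids)} gene ids")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if np.unique(self.labels).size < 2:
            raise FormatError("labels must take at least 2 distinct values")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset_genes(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            matrix=self.matrix[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def subset_samples(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            matrix=self.matrix[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
        )


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class RunConfig:
    """Tunable parameters of a selection run.

    Defaults follow the framework's standard operating point: subsets of 30
    genes, 10 bootstrap bags, binomial significance level 0.05, Isomap
    neighbourhood grid 5..20, and conventional subset-GA settings.
    """

    subset_size: int = 30
    pop_size: int = 100
    generations: int = 100
    tournament_size: int = 2
    mutation_rate: float = 0.01
    elitism: int = 1
    bags: int = 10
    alpha: float = 0.05
    k_range: tuple[int, int] = (5, 20)
    mlde_range: tuple[int, int] = (5, 12)
    embedding: str = "isomap"
    seed: int = 0
    outer_folds: int = 5
    validation_top: int = 10

    def validate(self) -> None:
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2")
        if self.bags < 1:
            raise ValueError("bags must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.k_range[0] < 1 or self.k_range[0] > self.k_range[1]:
            raise ValueError("k_range must satisfy 1 <= lo <= hi")
        if self.embedding not in ("isomap", "mds", "none"):
            raise ValueError(f"unknown embedding mode {self.embedding!r}")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.pop_size < 2 or self.generations < 1:
            raise ValueError("pop_size >= 2 and generations >= 1 required")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","


def read_expression(
    path: str | Path,
    orientation: str = "samples_x_genes",
    label_source: str | Path | None = None,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus labels into a dataset.

    ``label_source`` is either the name of a column of the matrix file or
    the path of a two-column (sample_id, label) file.  String labels are
    coded ``1..C`` in lexicographic order and the mapping recorded on the
    returned dataset, so the coding is stable across runs.
    """
    path = Path(path)
    if orientation not in ("samples_x_genes", "genes_x_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    _check_unique(header[1:], "header id")  # before pandas mangles duplicates
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                        na_values=_NA_VALUES, keep_default_na=False)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)

    label_column: pd.Series | None = None
    if label_source is not None and str(label_source) in frame.columns and not Path(
        str(label_source)
    ).exists():
        label_column = frame.pop(str(label_source))
    elif label_source is not None and not Path(str(label_source)).exists() and str(
        label_source
    ) in frame.index:
        label_column = frame.loc[str(label_source)]
        frame = frame.drop(index=str(label_source))

    if orientation == "genes_x_samples":
        frame = frame.T

    matrix = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise FormatError(
                f"non-numeric cell at row {row!r}, column {col!r}: "
                f"{frame.at[row, col]!r}"
            )
        matrix[:, j] = converted.to_numpy()

    sample_ids = [str(s) for s in frame.index]
    gene_ids = [str(g) for g in frame.columns]

    if label_column is None:
        if label_source is None:
            raise FormatError("a label column name or label file path is required")
        label_path = Path(str(label_source))
        if not label_path.exists():
            raise FormatError(
                f"label source {label_source!r} is neither a column nor a file"
            )
        lab = pd.read_csv(label_path, sep=_delimiter_for(label_path, None),
                          dtype=str, header=0)
        if lab.shape[1] < 2:
            raise FormatError("label file must have two columns (sample_id, label)")
        mapping_series = pd.Series(
            lab.iloc[:, 1].to_numpy(), index=lab.iloc[:, 0].astype(str)
        )
        missing = [s for s in sample_ids if s not in mapping_series.index]
        if missing:
            raise FormatError(f"label missing for sample(s): {missing[:5]}")
        raw_labels = [str(mapping_series[s]) for s in sample_ids]
    else:
        if label_column.isna().any():
            bad = label_column.index[label_column.isna()][0]
            raise FormatError(f"label missing for sample {bad!r}")
        raw_labels = [str(v) for v in label_column.tolist()]

    classes = sorted(set(raw_labels))
    mapping = {c: i + 1 for i, c in enumerate(classes)}
    labels = np.array([mapping[v] for v in raw_labels], dtype=int)
    log.info("read %d samples x %d genes from %s (classes: %s)",
             len(sample_ids), len(gene_ids), path, mapping)
    return ExpressionDataset(matrix, gene_ids, sample_ids, labels, mapping)


def write_expression(ds: ExpressionDataset, path: str | Path,
                     label_name: str = "class") -> None:
    """Write a dataset as a delimited matrix with a trailing label column."""
    path = Path(path)
    sep = _delimiter_for(path, None)
    frame = pd.DataFrame(ds.matrix, index=ds.sample_ids, columns=ds.gene_ids)
    frame[label_name] = ds.labels
    frame.to_csv(path, sep=sep, index_label="sample_id")


def write_labels(ds: ExpressionDataset, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"sample_id": ds.sample_ids, "label": ds.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_selection_report(result, path: str | Path) -> None:
    """Write per-gene selection counts and inclusion flags as TSV.

    A ``#``-prefixed metadata block records the tuned neighbourhood size k,
    embedding dimension d, inclusion threshold c, bag count B and seed, so a
    report fully identifies the run that produced it.
    """
    path = Path(path)
    if not result.s_best:
        log.warning("selection result is empty: writing report with no included genes")
    with open(path, "w") as fh:
        fh.write(f"# k={result.k}\n# d={result.d}\n# c={result.threshold.c}\n")
        fh.write(f"# B={result.n_bags}\n# seed={result.seed}\n")
        fh.write("gene_id\tselection_count\tincluded\n")
        best = set(result.s_best)
        for idx, gene in enumerate(result.gene_ids):
            count = result.counts.get(idx, 0)
            fh.write(f"{gene}\t{count}\t{str(idx in best).lower()}\n")


def read_selection_report(path: str | Path) -> tuple[dict[str, int], dict[str, bool], dict[str, str]]:
    """Re-read a selection report: (counts, included, metadata)."""
    counts: dict[str, int] = {}
    included: dict[str, bool] = {}
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("gene_id") or not line:
                continue
            gene, count, inc = line.split("\t")
            counts[gene] = int(count)
            included[gene] = inc == "true"
    return counts, included, meta
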