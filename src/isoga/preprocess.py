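"""Preprocessing chain for expression matrices.

Fixed stage order: drop genes with missing values, drop constant genes,
standardize each gene, then remove genes carrying zero information gain
about the class label.  Stages only remove or rescale columns; samples are
never reordered.  Information gain uses Fayyad–Irani MDL binary-recursive
discretization by default, which yields an exact zero for genes where no
cut point is accepted — the behaviour that makes the zero-IG filter bite on
noise-dominated microarray matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import EmptyDatasetError, ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class PreprocessReport:
    """Bookkeeping for the filtering stages."""

    n_missing_removed: int = 0
    n_constant_removed: int = 0
    n_zero_ig_removed: int = 0
    information_gain: dict[str, float] = field(default_factory=dict)
    p_initial: int = 0
    p_final: int = 0


@dataclass
class StandardizationParams:
    """Per-gene location/scale learned on training data."""

    mean: np.ndarray
    sd: np.ndarray
    ddof: int = 1

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.mean) / self.sd


def remove_missing_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Drop every gene column containing at least one missing value."""
    keep = ~np.isnan(ds.matrix).any(axis=0)
    if not keep.any():
        raise EmptyDatasetError("every gene contains a missing value")
    dropped = int((~keep).sum())
    if dropped:
        log.info("removed %d genes with missing values", dropped)
    return ds.subset_genes(np.flatnonzero(keep))


def remove_constant_genes(ds: ExpressionDataset, tol: float = 1e-12) -> ExpressionDataset:
    """Drop genes whose value is identical (within ``tol``) across samples."""
    rng_width = ds.matrix.max(axis=0) - ds.matrix.min(axis=0)
    keep = rng_width > tol
    if not keep.any():
        raise EmptyDatasetError("every gene is constant across samples")
    dropped = int((~keep).sum())
    if dropped:
        log.info("removed %d constant genes", dropped)
    return ds.subset_genes(np.flatnonzero(keep))


def standardize(
    ds: ExpressionDataset,
    params: StandardizationParams | None = None,
    ddof: int = 1,
) -> tuple[ExpressionDataset, StandardizationParams]:
    """Center and scale each gene to mean 0, sd 1.

    When ``params`` is given (statistics learned on a training fold) they
    are applied unchanged, so test folds are standardized without leaking
    their own statistics.
    """
    if params is None:
        mean = ds.matrix.mean(axis=0)
        sd = ds.matrix.std(axis=0, ddof=ddof)
        if np.any(sd <= 0):
            raise ValueError(
                "zero-variance gene encountered: run remove_constant_genes first"
            )
        params = StandardizationParams(mean=mean, sd=sd, ddof=ddof)
    out = ds.subset_genes(range(ds.p))
    out.matrix = params.apply(ds.matrix)
    return out, params


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _best_split(values: np.ndarray, labels: np.ndarray):
    """Best binary cut of pre-sorted values by class-entropy gain.

    Candidate cuts lie between groups of equal values; returns
    (gain, cut_index, left_entropy, right_entropy) or None when the values
    admit no cut (all equal).
    """
    n = len(values)
    # boundaries between distinct value groups
    change = np.flatnonzero(np.diff(values) > 0) + 1
    if change.size == 0:
        return None
    base = _entropy(labels)
    classes, coded = np.unique(labels, return_inverse=True)
    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), coded] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]

    left = cum[change - 1]                      # class counts left of each cut
    right = total - left
    nl = left.sum(axis=1)
    nr = right.sum(axis=1)

    def _ent(counts, size):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / size[:, None]
            term = np.where(counts > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=1)

    ent_l = _ent(left, nl)
    ent_r = _ent(right, nr)
    cond = (nl / n) * ent_l + (nr / n) * ent_r
    gains = base - cond
    best = int(np.argmax(gains))
    return float(gains[best]), int(change[best]), float(ent_l[best]), float(ent_r[best])


def _mdl_accepts(gain: float, labels, left_labels, right_labels,
                 ent, ent_l, ent_r) -> bool:
    n = len(labels)
    k = np.unique(labels).size
    k1 = np.unique(left_labels).size
    k2 = np.unique(right_labels).size
    delta = np.log2(3.0**k - 2.0) - (k * ent - k1 * ent_l - k2 * ent_r)
    return gain > (np.log2(n - 1) + delta) / n


def mdl_cut_points(values: np.ndarray, labels: np.ndarray) -> list[float]:
    """Fayyad–Irani MDL binary-recursive cut points (ascending)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(values, kind="stable")
    sv, sl = values[order], labels[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        v, l = sv[lo:hi], sl[lo:hi]
        if len(v) < 2 or np.unique(l).size < 2:
            return
        split = _best_split(v, l)
        if split is None:
            return
        gain, cut, ent_l, ent_r = split
        if not _mdl_accepts(gain, l, l[:cut], l[cut:], _entropy(l), ent_l, ent_r):
            return
        cuts.append(float((v[cut - 1] + v[cut]) / 2.0))
        recurse(lo, lo + cut)
        recurse(lo + cut, hi)

    recurse(0, len(sv))
    return sorted(cuts)


def _equalfreq_edges(values: np.ndarray, bins: int = 10) -> np.ndarray:
    qs = np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1])
    return np.unique(qs)


def information_gain(values: np.ndarray, labels: np.ndarray,
                     binning: str = "mdl") -> float:
    """Mutual information (bits) between a discretized gene and the labels.

    ``binning='mdl'`` uses MDL-accepted cut points (no accepted cut → 0
    exactly); ``binning='equalfreq'`` uses 10 equal-frequency bins.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if len(values) < 2:
        raise ValueError("need at least 2 samples")
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes")
    if np.ptp(values) == 0:
        return 0.0
    if binning == "mdl":
        edges = np.asarray(mdl_cut_points(values, labels))
    elif binning == "equalfreq":
        edges = _equalfreq_edges(values)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    if edges.size == 0:
        return 0.0
    bins = np.digitize(values, edges)
    h = _entropy(labels)
    cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        cond += mask.mean() * _entropy(labels[mask])
    return max(float(h - cond), 0.0)


def filter_zero_ig(
    ds: ExpressionDataset, binning: str = "mdl"
) -> tuple[ExpressionDataset, PreprocessReport]:
    """Remove genes whose information gain about the label is exactly zero."""
    report = PreprocessReport(p_initial=ds.p)
    keep = []
    for j, gene in enumerate(ds.gene_ids):
        ig = information_gain(ds.matrix[:, j], ds.labels, binning=binning)
        report.information_gain[gene] = ig
        if ig > 0.0:
            keep.append(j)
    report.n_zero_ig_removed = ds.p - len(keep)
    report.p_final = len(keep)
    if not keep:
        raise EmptyDatasetError("every gene has zero information gain")
    log.info("zero-IG filter: kept %d of %d genes", len(keep), ds.p)
    return ds.subset_genes(keep), report


def flag_outlier_samples(ds: ExpressionDataset, z_threshold: float = 6.0) -> dict[str, int]:
    """Count extreme standardized values per sample (|z| > threshold).

    Reported for manual review only; no samples are removed automatically.
    """
    mean = ds.matrix.mean(axis=0)
    sd = ds.matrix.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    z = np.abs((ds.matrix - mean) / sd)
    counts = (z > z_threshold).sum(axis=1)
    flagged = {s: int(c) for s, c in zip(ds.sample_ids, counts) if c > 0}
    if flagged:
        log.warning("samples with extreme values (|z|>%.1f): %s", z_threshold, flagged)
    return flagged


def preprocess_pipeline(
    ds: ExpressionDataset, binning: str = "mdl", ddof: int = 1
) -> tuple[ExpressionDataset, PreprocessReport, StandardizationParams]:
    """Run the full chain: missing → constant → standardize → zero-IG filter."""
    p0 = ds.p
    ds1 = remove_missing_genes(ds)
    n_missing = p0 - ds1.p
    ds2 = remove_constant_genes(ds1)
    n_const = ds1.p - ds2.p
    ds3, params = standardize(ds2, ddof=ddof)
    flag_outlier_samples(ds3)
    ds4, report = filter_zero_ig(ds3, binning=binning)
    report.n_missing_removed = n_missing
    report.n_constant_removed = n_const
    report.p_initial = p0
    return ds4, report, params
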