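"""Correlation-based hierarchical clustering of expression time courses.

The procedure mirrors a clustermap over a clipped correlation matrix:
fold-change series are log10-transformed, pairwise Pearson correlations are
computed, negative correlations are clipped to zero (clusters should contain
only positively co-varying genes), and the rows of the clipped matrix are
agglomerated with average linkage on euclidean distances.  Cutting the
dendrogram at a height yields flat clusters; genes left as singletons are
reported UNCLUSTERED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "UNCLUSTERED",
    "CorrelationMatrix",
    "ClusterAssignment",
    "correlation_matrix",
    "cluster",
    "assign_patterns",
    "series_pattern",
]

UNCLUSTERED = "UNCLUSTERED"

#: dead-band on |Δlog10 fold| below which an interval is called flat ("0")
DEFAULT_DEADBAND = 0.05


@dataclass
class CorrelationMatrix:
    genes: list[str]
    r_clipped: np.ndarray  # symmetric, unit diagonal, entries in [0, 1]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r_clipped, index=self.genes, columns=self.genes)


@dataclass
class ClusterAssignment:
    assignment: dict  # gene -> int cluster id or UNCLUSTERED
    linkage: np.ndarray
    cut_height: float

    def members(self) -> dict:
        out: dict = {}
        for gene, cid in self.assignment.items():
            out.setdefault(cid, []).append(gene)
        return out

    def clustered_genes(self) -> list[str]:
        return [g for g, c in self.assignment.items() if c != UNCLUSTERED]


def correlation_matrix(series_set: dict, log_base: float = 10) -> CorrelationMatrix:
    """Pairwise Pearson correlation of log-transformed fold-change series,
    negatives clipped to zero.

    ``series_set`` maps gene -> ExpressionSeries (or any object with
    ``times`` and ``fold_change``).  Constant (zero-variance) series yield
    undefined correlations which are recorded as 0 with a warning.
    """
    genes = list(series_set)
    if not genes:
        raise ValueError("empty series set")
    times0 = np.asarray(series_set[genes[0]].times)
    mat = np.empty((len(genes), len(times0)))
    for i, g in enumerate(genes):
        s = series_set[g]
        if not np.array_equal(np.asarray(s.times), times0):
            raise ValueError(f"series for {g!r} covers different time points")
        fc = np.asarray(s.fold_change, dtype=float)
        if (fc <= 0).any():
            raise ValueError(f"non-positive fold change for {g!r}")
        mat[i] = np.log(fc) / np.log(log_base)

    constant = mat.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            "zero-variance series, correlations recorded as 0: "
            + ", ".join(np.array(genes)[constant]),
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.atleast_2d(np.corrcoef(mat))
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r_clipped = np.clip(r, 0.0, 1.0)
    r_clipped = (r_clipped + r_clipped.T) / 2  # enforce exact symmetry
    return CorrelationMatrix(genes=genes, r_clipped=r_clipped)


def cluster(matrix: CorrelationMatrix, cut_height: float) -> ClusterAssignment:
    """Average-linkage agglomeration of the clipped-correlation rows.

    Each gene's feature vector is its row of the clipped matrix; distances
    are euclidean.  Flat clusters are cut at ``cut_height``; singletons are
    assigned UNCLUSTERED and surviving clusters are renumbered 1..k in order
    of first appearance.
    """
    if len(matrix.genes) < 2:
        raise ValueError("clustering requires at least 2 genes")
    Z = hierarchy.linkage(matrix.r_clipped, method="average", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    counts = pd.Series(flat).value_counts()
    relabel: dict[int, int] = {}
    assignment: dict[str, object] = {}
    next_id = 1
    for gene, raw in zip(matrix.genes, flat):
        if counts[raw] < 2:
            assignment[gene] = UNCLUSTERED
            continue
        if raw not in relabel:
            relabel[raw] = next_id
            next_id += 1
        assignment[gene] = relabel[raw]
    return ClusterAssignment(assignment=assignment, linkage=Z, cut_height=cut_height)


def series_pattern(
    fold_change, deadband: float = DEFAULT_DEADBAND
) -> str:
    """Direction-symbol string of one fold-change series on the log10 scale.

    Consecutive-interval differences below ``deadband`` in absolute log10
    units are flattened to '0'.
    """
    logs = np.log10(np.asarray(fold_change, dtype=float))
    diffs = np.diff(logs)
    return "".join(
        "0" if abs(d) < deadband else "+" if d > 0 else "-" for d in diffs
    )


def assign_patterns(
    series_set: dict,
    assignment: ClusterAssignment,
    deadband: float = DEFAULT_DEADBAND,
) -> dict:
    """Per-cluster qualitative pattern descriptor.

    For each cluster the member series' log10 fold changes are averaged per
    time point, then differenced into a symbol string over {+, -, 0} with
    the dead-band ε.  Unclustered genes get individual descriptors keyed by
    gene name.
    """
    patterns: dict = {}
    groups = assignment.members()
    for cid, genes in groups.items():
        if cid == UNCLUSTERED:
            for g in genes:
                patterns[g] = series_pattern(
                    series_set[g].fold_change, deadband
                )
            continue
        logs = np.mean(
            [np.log10(np.asarray(series_set[g].fold_change)) for g in genes],
            axis=0,
        )
        patterns[cid] = series_pattern(10.0 ** logs, deadband)
    return patterns
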