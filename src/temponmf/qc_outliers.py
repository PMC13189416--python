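"""Replicate QC: PCA-based outlier z-scores and correlation clustering.

A replicate is scored by projecting all samples onto principal components of
the gene-standardized expression matrix and, within each (condition,
timepoint) group, forming z = |score - group mean| / population sd on each
of the top PCs.  A replicate is flagged when any of those z-scores exceeds
the threshold (default 2).  Note the arithmetic bound: with N replicates in
a group no single score can exceed sqrt(N - 1), so the default threshold is
only attainable for groups of six or more replicates — a deliberate
conservatism of the method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from temponmf.io_normalize import SampleSheet, TimepointMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAScores:
    """Per-sample principal-component scores of standardized expression."""

    sample_ids: list[str]
    scores: np.ndarray          # samples × components
    variance_fraction: np.ndarray

    def frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)


@dataclass
class OutlierReport:
    """Z-scores per (replicate, PC) and the resulting flag set."""

    table: pd.DataFrame  # sample_id, condition, timepoint_h, replicate, pc, score, z, flagged
    flagged: set[str]
    threshold: float
    n_pcs: int
    variance_fraction: np.ndarray

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r with the associated 1 - r distance."""

    labels: list
    r: np.ndarray

    @property
    def distance(self) -> np.ndarray:
        return 1.0 - self.r

    def frame(self) -> pd.DataFrame:
        idx = pd.Index([str(l) for l in self.labels])
        return pd.DataFrame(self.r, index=idx, columns=idx)


def pca_scores(table: pd.DataFrame) -> PCAScores:
    """PCA of samples with per-gene standardization (zero mean, unit variance).

    Mirrors standardized PCA as done by R's ``prcomp(..., scale = TRUE)``
    on the sample × gene matrix.  Genes with zero variance across samples
    are dropped with a warning.  The sign of each component is fixed so the
    gene loading of largest magnitude is positive.
    """
    X = table.to_numpy(float).T  # samples × genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant gene(s) before PCA", (~keep).sum())
    if not keep.any():
        raise ValueError("no variable genes for PCA")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    # sign convention: largest-magnitude loading positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * S
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    return PCAScores(list(table.columns), scores, frac)


def replicate_zscores(
    scores: PCAScores,
    sheet: SampleSheet,
    n_pcs: int = 4,
    threshold: float = 2.0,
) -> OutlierReport:
    """Z-scores of PC scores within each (condition, timepoint) replicate group.

    The denominator is the population standard deviation (divisor N).
    Groups with a single replicate are skipped with a warning; a group with
    identical scores yields z = 0.
    """
    df = sheet.frame
    score_map = {s: scores.scores[i] for i, s in enumerate(scores.sample_ids)}
    n_pcs = min(n_pcs, scores.scores.shape[1])
    rows = []
    flagged: set[str] = set()
    for (cond, t), grp in df.groupby(["condition", "timepoint_h"], sort=True):
        ids = [s for s in grp["sample_id"] if s in score_map]
        if len(ids) < 2:
            warnings.warn(f"group ({cond}, {t}) has < 2 replicates; skipped")
            continue
        pcs = np.array([score_map[s][:n_pcs] for s in ids])  # N × n_pcs
        mean = pcs.mean(axis=0)
        sd = pcs.std(axis=0)  # population sd, divisor N
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.abs(pcs - mean) / sd
        z[~np.isfinite(z)] = 0.0
        for i, sid in enumerate(ids):
            rep = int(grp.loc[grp["sample_id"] == sid, "replicate"].iloc[0])
            for k in range(n_pcs):
                is_out = z[i, k] > threshold
                rows.append((sid, cond, t, rep, k + 1, pcs[i, k], z[i, k], is_out))
                if is_out:
                    flagged.add(sid)
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "timepoint_h", "replicate", "pc", "score", "z", "flagged"],
    )
    return OutlierReport(table, flagged, threshold, n_pcs, scores.variance_fraction)


def pairwise_timepoint_correlation(tm: TimepointMatrix) -> CorrelationMatrix:
    """Pearson r over genes between every pair of timepoint columns."""
    V = tm.values
    sd = V.std(axis=0)
    if (sd == 0).any():
        bad = tm.labels[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance column {bad}: correlation undefined")
    r = np.corrcoef(V.T)
    return CorrelationMatrix(list(tm.labels), r)


def correlation_matrix(frame: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r between the rows of a labeled matrix."""
    V = frame.to_numpy(float)
    sd = V.std(axis=1)
    if (sd == 0).any():
        bad = frame.index[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance row {bad!r}: correlation undefined")
    return CorrelationMatrix(list(frame.index), np.corrcoef(V))


def hierarchical_cluster(
    dist: CorrelationMatrix, linkage: str = "complete"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering on the 1 - r distance.

    Returns the scipy linkage matrix and the deterministic leaf order
    (items pre-sorted by label so ties break reproducibly).
    """
    order0 = sorted(range(len(dist.labels)), key=lambda i: str(dist.labels[i]))
    D = dist.distance[np.ix_(order0, order0)]
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    condensed = squareform(np.maximum(D, 0.0), checks=False)
    Z = sch.linkage(condensed, method=linkage)
    leaves = sch.leaves_list(Z)
    leaf_labels = [dist.labels[order0[i]] for i in leaves]
    return Z, leaf_labels


def to_newick(Z: np.ndarray, labels: list) -> str:
    """Serialize a linkage matrix as a Newick string."""
    tree = sch.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return str(labels[node.id]).replace(" ", "_")
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:g},{right}:{dr:g})"

    return rec(tree) + ";"
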