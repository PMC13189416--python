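"""Dominant-behavior assignment, ordering, gene lists and TF clustering.

After fitting, every gene is labeled with its dominant behavior (the
largest entry of its weight row; all-zero rows are "unexpressed").
Behaviors are ordered by where they peak — GCSF-peaking before IL3-peaking,
earlier before later — and genes are grouped by ordered dominant behavior,
descending dominant weight within a group, for display.  Per-behavior top
gene lists (default 500, with a normalized-expression floor of 3) feed
downstream ontology tools; transcription-factor subsets are clustered by
1 − Pearson-r distance over the concatenated two-condition trajectories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from temponmf.io_normalize import GCSF, TimepointMatrix
from temponmf.nmf_behaviors import NMFModel
from temponmf.qc_outliers import CorrelationMatrix, correlation_matrix, hierarchical_cluster

UNEXPRESSED = -1  # dominant-behavior label for all-zero weight rows


@dataclass
class BehaviorAssignment:
    gene_ids: list[str]
    dominant: np.ndarray        # behavior index per gene; UNEXPRESSED for zero rows
    dominant_weight: np.ndarray
    weights: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "dominant_behavior": self.dominant,
                "dominant_weight": self.dominant_weight,
                "unexpressed": self.dominant == UNEXPRESSED,
            }
        )


@dataclass
class BehaviorOrdering:
    order: list[int]                      # behavior ids, display order
    keys: dict[int, tuple[int, float]]    # behavior -> (condition rank, peak time)


@dataclass
class GeneList:
    behavior: int
    gene_ids: list[str]
    weights: list[float]
    expr_floor: float

    def write_tsv(self, path) -> None:
        pd.DataFrame({"gene_id": self.gene_ids, "weight": self.weights}).to_csv(
            path, sep="\t", index=False
        )


def dominant_behavior(model: NMFModel) -> BehaviorAssignment:
    """Argmax over behaviors of each gene's weight row.

    Ties break toward the lowest behavior id (np.argmax's convention);
    all-zero rows are labeled unexpressed.
    """
    W = model.W
    dom = W.argmax(axis=1)
    w = W[np.arange(W.shape[0]), dom]
    dom = np.where(W.sum(axis=1) > 0, dom, UNEXPRESSED)
    ids = model.gene_ids or [f"g{i}" for i in range(W.shape[0])]
    return BehaviorAssignment(list(ids), dom, w, W)


def order_behaviors(model: NMFModel) -> BehaviorOrdering:
    """Sort behaviors by (peak condition, peak time).

    The peak condition is the block containing the global maximum of the
    behavior's H row (GCSF wins exact ties, and ranks first); within a
    condition, earlier peaks rank first.  Ties fall back to behavior id.
    """
    if model.labels is None:
        raise ValueError("model carries no timepoint labels")
    keys: dict[int, tuple[int, float]] = {}
    for m in range(model.config.M):
        row = model.H[m]
        peak = int(np.argmax(row))
        cond, t = model.labels[peak]
        keys[m] = (0 if cond == GCSF else 1, float(t))
    order = sorted(keys, key=lambda m: (*keys[m], m))
    return BehaviorOrdering(order, keys)


def sort_genes_for_display(
    assignment: BehaviorAssignment, ordering: BehaviorOrdering
) -> list[str]:
    """Genes grouped by ordered dominant behavior, descending dominant weight.

    Unexpressed genes form a final group.  Ties break by gene id, making
    the permutation deterministic.
    """
    rank = {m: i for i, m in enumerate(ordering.order)}
    rank[UNEXPRESSED] = len(ordering.order)
    idx = sorted(
        range(len(assignment.gene_ids)),
        key=lambda i: (
            rank[int(assignment.dominant[i])],
            -assignment.dominant_weight[i],
            assignment.gene_ids[i],
        ),
    )
    return [assignment.gene_ids[i] for i in idx]


def top_genes(
    model: NMFModel,
    behavior: int,
    normalized_max: pd.Series,
    n: int = 500,
    expr_floor: float = 3.0,
) -> GeneList:
    """Top-n genes by weight for one behavior, above an expression floor.

    ``normalized_max`` is each gene's maximum normalized (pre-scaling)
    expression; genes below ``expr_floor`` are excluded before ranking.
    """
    if not 0 <= behavior < model.config.M:
        raise IndexError(f"behavior {behavior} out of range")
    ids = model.gene_ids or [f"g{i}" for i in range(model.W.shape[0])]
    w = model.W[:, behavior]
    eligible = [
        (ids[i], w[i])
        for i in range(len(ids))
        if float(normalized_max.get(ids[i], 0.0)) >= expr_floor
    ]
    eligible.sort(key=lambda p: (-p[1], p[0]))
    eligible = eligible[:n]
    return GeneList(
        behavior,
        [g for g, _ in eligible],
        [float(x) for _, x in eligible],
        expr_floor,
    )


def cluster_tfs(
    tm: TimepointMatrix,
    tf_ids: list[str],
    assignment: BehaviorAssignment,
    linkage: str = "complete",
) -> tuple[CorrelationMatrix, np.ndarray, list, pd.Series]:
    """Cluster TFs by 1 − r distance over their two-condition trajectories.

    TFs absent from the matrix are dropped with a warning.  Returns the
    correlation matrix, linkage, leaf order and the per-TF dominant
    behavior annotation.
    """
    present = [g for g in tf_ids if g in set(tm.gene_ids)]
    missing = set(tf_ids) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} TF(s) absent from the expression matrix; dropped")
    if len(present) < 2:
        raise ValueError("need at least two TFs present in the matrix")
    frame = tm.to_frame().loc[present]
    corr = correlation_matrix(frame)
    Z, leaves = hierarchical_cluster(corr, linkage=linkage)
    dom = pd.Series(
        dict(zip(assignment.gene_ids, assignment.dominant)), name="dominant_behavior"
    ).reindex(present)
    return corr, Z, leaves, dom


def filter_deg_table(
    table: pd.DataFrame, alpha: float = 0.05, lfc: float = 0.58
) -> tuple[set[str], set[str]]:
    """Split an external differential-expression table into up/down sets.

    Thresholds are strict: adjusted p < alpha and |log2 fold change| > lfc
    (0.58 ≈ a ±50% change).  Expects columns gene (or gene_id),
    log2FoldChange and padj.
    """
    cols = {c.lower(): c for c in table.columns}
    try:
        gene_col = cols.get("gene", cols.get("gene_id"))
        lfc_col = cols["log2foldchange"]
        padj_col = cols["padj"]
        if gene_col is None:
            raise KeyError("gene")
    except KeyError as e:
        raise ValueError(f"DE table missing column: {e}") from None
    sig = table[table[padj_col] < alpha]
    up = set(sig.loc[sig[lfc_col] > lfc, gene_col])
    down = set(sig.loc[sig[lfc_col] < -lfc, gene_col])
    return up, down


def dominant_recovery(model: NMFModel, dataset) -> tuple[float, np.ndarray]:
    """Fraction of dynamic fixture genes assigned their true dominant behavior.

    The fitted H rows are first max-normalized (absorbing the scale into W)
    to pin the per-behavior scaling gauge, then matched to the generating
    behaviors by best correlation.  Flat (stably expressed) fixture genes
    are excluded: their true weight row is a near-tie across behaviors, so
    an argmax label is not meaningful for them.  Returns the recovery
    fraction and the per-behavior matching correlations.
    """
    hmax = model.H.max(axis=1)
    if (hmax == 0).any():
        raise ValueError("fitted model has an all-zero behavior row")
    H_n = model.H / hmax[:, None]
    W_n = model.W * hmax[None, :]
    mapping, r = match_behaviors(H_n, dataset.true_H)
    to_true = {int(j): i for i, j in enumerate(mapping)}
    pos = {gid: i for i, gid in enumerate(dataset.gene_ids)}
    n_dynamic_total = len(dataset.gene_ids) - dataset.n_flat
    truth = dataset.designated_behavior
    ids = model.gene_ids or []
    fitted_dom = W_n.argmax(axis=1)
    hits = total = 0
    for row, gid in enumerate(ids):
        idx = pos[gid]
        if idx >= n_dynamic_total:  # flat gene
            continue
        total += 1
        hits += to_true.get(int(fitted_dom[row]), -1) == truth[idx]
    if total == 0:
        raise ValueError("no dynamic genes present in the model")
    return hits / total, r


def match_behaviors(H_fit: np.ndarray, H_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-correlation assignment of fitted behaviors to reference ones.

    NMF is identifiable only up to permutation and positive per-behavior
    scaling, so comparisons to a reference must first match rows.  Returns
    (mapping, r) where mapping[i] is the fitted row assigned to reference
    row i and r[i] its Pearson correlation.
    """
    K = H_true.shape[0]
    if H_fit.shape[0] < K:
        raise ValueError("fewer fitted behaviors than reference behaviors")
    C = np.zeros((K, H_fit.shape[0]))
    for i in range(K):
        for j in range(H_fit.shape[0]):
            a, b = H_true[i], H_fit[j]
            if a.std() == 0 or b.std() == 0:
                C[i, j] = 0.0
            else:
                C[i, j] = np.corrcoef(a, b)[0, 1]
    row, col = linear_sum_assignment(-C)
    mapping = np.empty(K, dtype=int)
    r = np.empty(K)
    for i, j in zip(row, col):
        mapping[i] = j
        r[i] = C[i, j]
    return mapping, r
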