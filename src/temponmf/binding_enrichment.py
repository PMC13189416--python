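"""TF-binding enrichment in TSS windows of gene sets.

For each gene (represented by the transcript with the highest baseline
expression) two windows around the TSS are considered: proximal (±1 kb,
inclusive) and distal (±50 kb minus the proximal zone).  A gene is bound in
a window when any peak overlaps it by at least one base pair.  Enrichment
of a gene set against a background set is the ratio of bound fractions

    (T_p / T_n) / (A_p / A_n),

with significance from the one-sided (upper tail) Fisher's exact test on
the set vs background-minus-set 2×2 table.  Windows are strand-agnostic;
peaks and windows use 0-based half-open coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

PROXIMAL_BP = 1000
DISTAL_BP = 50_000


@dataclass
class EnrichmentResult:
    window: str
    T_p: int
    T_n: int
    A_p: int
    A_n: int
    ratio: float | None
    p_value: float

    def as_row(self) -> dict:
        return {
            "window": self.window,
            "T_p": self.T_p,
            "T_n": self.T_n,
            "A_p": self.A_p,
            "A_n": self.A_n,
            "ratio": self.ratio,
            "p_value": self.p_value,
        }


def select_representative_transcript(ann: pd.DataFrame) -> pd.DataFrame:
    """One transcript per gene: the one with the highest baseline expression.

    Ties break toward the lexicographically smallest transcript_id.
    """
    df = ann.sort_values(
        ["gene_id", "baseline_expr", "transcript_id"],
        ascending=[True, False, True],
        kind="stable",
    )
    return df.drop_duplicates("gene_id", keep="first").reset_index(drop=True)


def _window_intervals(
    tss: int, proximal_bp: int, distal_bp: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Half-open proximal and distal intervals around a TSS, clipped at 0.

    The inclusive ±w window [tss−w, tss+w] converts to [tss−w, tss+w+1);
    the distal region excludes the proximal zone entirely.
    """
    prox = [(max(0, tss - proximal_bp), tss + proximal_bp + 1)]
    distal = []
    left = (max(0, tss - distal_bp), max(0, tss - proximal_bp))
    if left[1] > left[0]:
        distal.append(left)
    right = (tss + proximal_bp + 1, tss + distal_bp + 1)
    if right[1] > right[0]:
        distal.append(right)
    return prox, distal


class _ChromIndex:
    """Peaks of one chromosome, sorted by end, with suffix-min of starts."""

    def __init__(self, starts: np.ndarray, ends: np.ndarray) -> None:
        order = np.argsort(ends, kind="stable")
        self.starts = starts[order]
        self.ends = ends[order]
        self.suffix_min_start = np.minimum.accumulate(self.starts[::-1])[::-1]

    def any_overlap(self, lo: int, hi: int) -> bool:
        """True if any peak [s, e) intersects the half-open window [lo, hi)."""
        i = int(np.searchsorted(self.ends, lo, side="right"))
        if i >= len(self.ends):
            return False
        return bool(self.suffix_min_start[i] < hi)


def assign_windows(
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    proximal_bp: int = PROXIMAL_BP,
    distal_bp: int = DISTAL_BP,
) -> pd.DataFrame:
    """Per-gene bound_proximal / bound_distal booleans.

    ``tss`` must already contain one representative transcript per gene.
    Peak chromosomes absent from the annotation are ignored with a warning.
    """
    if tss["gene_id"].duplicated().any():
        raise ValueError("tss must contain one representative transcript per gene")
    index: dict[str, _ChromIndex] = {}
    for chrom, grp in peaks.groupby("chrom"):
        index[chrom] = _ChromIndex(
            grp["start"].to_numpy(np.int64), grp["end"].to_numpy(np.int64)
        )
    orphans = set(index) - set(tss["chrom"])
    if orphans:
        warnings.warn(f"peak chromosome(s) absent from annotation: {sorted(orphans)}")
    rows = []
    for gene, chrom, pos in zip(tss["gene_id"], tss["chrom"], tss["tss_pos"]):
        ci = index.get(chrom)
        prox_iv, dist_iv = _window_intervals(int(pos), proximal_bp, distal_bp)
        bp = ci is not None and any(ci.any_overlap(lo, hi) for lo, hi in prox_iv)
        bd = ci is not None and any(ci.any_overlap(lo, hi) for lo, hi in dist_iv)
        rows.append((gene, bp, bd))
    return pd.DataFrame(rows, columns=["gene_id", "bound_proximal", "bound_distal"]).set_index(
        "gene_id"
    )


def fisher_one_sided(T_p: int, T_n: int, A_p: int, A_n: int) -> float:
    """Upper-tail Fisher's exact p for the set vs background-minus-set table.

    P(X >= T_p) where X ~ Hypergeom(population A_n, successes A_p, draws
    T_n); computed by exact hypergeometric summation.
    """
    if not (0 <= T_p <= T_n <= A_n and 0 <= A_p <= A_n and T_p <= A_p):
        raise ValueError("invalid counts")
    if A_p - T_p > A_n - T_n:
        raise ValueError("set not contained in background")
    return float(hypergeom.sf(T_p - 1, A_n, A_p, T_n))


def enrichment(
    bound: pd.Series, gene_set: set[str], background: set[str], window: str = "proximal"
) -> EnrichmentResult:
    """Bound-fraction enrichment of a gene set over its background.

    ``bound`` is a per-gene boolean Series for one window class.  The gene
    set must be contained in the background.  The ratio is reported missing
    (None) when either bound fraction is undefined.
    """
    if not gene_set:
        raise ValueError("empty gene_set")
    if not gene_set <= background:
        raise ValueError("gene_set must be a subset of background")
    b = bound.reindex(list(background)).fillna(False).astype(bool)
    T_n = len(gene_set)
    A_n = len(background)
    T_p = int(b.loc[list(gene_set)].sum())
    A_p = int(b.sum())
    ratio = None
    if A_p > 0 and T_n > 0:
        ratio = (T_p / T_n) / (A_p / A_n)
    p = fisher_one_sided(T_p, T_n, A_p, A_n)
    return EnrichmentResult(window, T_p, T_n, A_p, A_n, ratio, p)


def enrichment_report(
    gene_sets: dict[str, set[str] | dict[str, set[str]]],
    peaks: pd.DataFrame,
    tss: pd.DataFrame,
    background: set[str],
    proximal_bp: int = PROXIMAL_BP,
    distal_bp: int = DISTAL_BP,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Enrichment of every gene set in proximal and distal windows.

    A plain set yields one row per window (direction "all"); a dict of
    direction -> set (e.g. up/down DEG splits) yields one row per window
    and direction.  Raw one-sided p-values are reported; an optional
    Benjamini-Hochberg column can be added.
    """
    rep = select_representative_transcript(tss)
    bound = assign_windows(peaks, rep, proximal_bp, distal_bp)
    rows = []
    for name, sets in gene_sets.items():
        directions = sets if isinstance(sets, dict) else {"all": sets}
        for direction, members in directions.items():
            members = set(members) & background
            if not members:
                continue
            for window, col in (("proximal", "bound_proximal"), ("distal", "bound_distal")):
                res = enrichment(bound[col], members, background, window)
                rows.append({"set": name, "direction": direction, **res.as_row()})
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        p = out["p_value"].to_numpy()
        order = np.argsort(p)
        n = len(p)
        adj = np.empty(n)
        running = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * n / (rank_idx + 1))
            adj[i] = running
        out["p_adj_bh"] = adj
    return out
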