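"""Synthetic two-condition time-course generator.

Builds datasets with the statistical structure the pipeline assumes: a small
number of ground-truth temporal behaviors (pulses, late rises, drops) on the
experimental sampling grid, sparse non-negative per-gene weights,
multiplicative lognormal replicate noise, optional planted outlier
replicates, and toy peak/TSS geometry for the enrichment stage.  Every
fixture used in the test suite comes from here; nothing is downloaded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from temponmf.io_normalize import (
    CONDITIONS,
    GCSF,
    IL3,
    SampleSheet,
    build_timepoint_grid,
)

SHAPES = ("pulse", "late_rise", "early_drop", "sustained", "oscillating")

#: Default fixture dimensions: 2,000 genes, 5 behaviors, 3 replicates.
DEFAULT_G = 2000
DEFAULT_K = 5
DEFAULT_REPLICATES = 3
DEFAULT_CV = 0.1
DEFAULT_COUNT_SCALE = 200.0
DEFAULT_SEED = 20240101

#: Logistic half-width (hours) of pulse edges.
PULSE_WIDTH_H = 2.0


@dataclass(frozen=True)
class BehaviorSpec:
    """Ground-truth temporal behavior for simulation."""

    behavior_id: int
    condition_mask: tuple[str, ...]
    shape: str
    onset_h: float = 0.0
    offset_h: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not self.condition_mask:
            raise ValueError("empty condition_mask")
        if any(c not in CONDITIONS for c in self.condition_mask):
            raise ValueError(f"unknown condition in mask: {self.condition_mask}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "pulse" and not self.onset_h < self.offset_h:
            raise ValueError("pulse requires onset_h < offset_h")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class SyntheticDataset:
    """Per-replicate expression with its generating truth."""

    expression: pd.DataFrame
    sheet: SampleSheet
    labels: list[tuple[str, int]]
    true_W: np.ndarray
    true_H: np.ndarray
    noise_cv: float
    count_scale: float
    planted_outliers: list[tuple[str, float]] = field(default_factory=list)
    seed: int = DEFAULT_SEED
    #: number of trailing genes that are flat (stable) mixtures; their
    #: "dominant" behavior is a near-tie and not a meaningful label
    n_flat: int = 0

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    @property
    def designated_behavior(self) -> np.ndarray:
        """Per-gene index of the largest true weight."""
        return self.true_W.argmax(axis=1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def _shape_values(spec: BehaviorSpec, t: np.ndarray, t_min: float) -> np.ndarray:
    w = PULSE_WIDTH_H
    if spec.shape == "pulse":
        return _sigmoid((t - spec.onset_h) / w) * _sigmoid((spec.offset_h - t) / w)
    if spec.shape == "late_rise":
        return _sigmoid((t - spec.onset_h) / (4 * w))
    if spec.shape == "early_drop":
        return 1.0 - _sigmoid((t - spec.onset_h) / w)
    if spec.shape == "sustained":
        u = t - t_min
        return u / (u + 24.0)  # nondecreasing saturation within the block
    if spec.shape == "oscillating":
        base = _sigmoid((t - spec.onset_h) / w) * _sigmoid((spec.offset_h - t) / w)
        tail = 0.4 * _sigmoid((t - spec.offset_h) / w) * (
            0.5 * (1.0 + np.sin(2 * np.pi * (t - spec.offset_h) / 32.0))
        )
        return base + tail
    raise AssertionError(spec.shape)


def make_behaviors(
    specs: list[BehaviorSpec], grids: dict[str, list[int]] | None = None
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Evaluate behavior specs on the sampling grid.

    Returns the K × (T_G + T_I) behavior matrix (row maxima equal each
    spec's amplitude; zero outside the spec's condition mask) and the
    ordered (condition, timepoint) column labels.
    """
    if grids is None:
        grids = {c: build_timepoint_grid(c) for c in CONDITIONS}
    labels = [(c, t) for c in CONDITIONS for t in grids[c]]
    H = np.zeros((len(specs), len(labels)))
    for i, spec in enumerate(specs):
        for cond in spec.condition_mask:
            t = np.asarray(grids[cond], dtype=float)
            cols = [j for j, (c, _) in enumerate(labels) if c == cond]
            H[i, cols] = _shape_values(spec, t, t.min())
        m = H[i].max()
        if m <= 0:
            raise ValueError(f"behavior {spec.behavior_id} is identically zero")
        H[i] *= spec.amplitude / m
    return H, labels


def default_behavior_specs() -> list[BehaviorSpec]:
    """Five behaviors echoing the taxonomy seen in myeloid differentiation,
    together tiling both condition blocks: a shared progenitor program shut
    off early, an early pulse per arm, a shared mid pulse (8-80 h) and a
    shared late rise switching on around 80 h."""
    return [
        BehaviorSpec(0, (GCSF, IL3), "early_drop", onset_h=2.0, amplitude=1.0),
        BehaviorSpec(1, (GCSF,), "pulse", onset_h=0.0, offset_h=12.0, amplitude=1.0),
        BehaviorSpec(2, (IL3,), "pulse", onset_h=0.0, offset_h=8.0, amplitude=1.0),
        BehaviorSpec(3, (GCSF, IL3), "pulse", onset_h=8.0, offset_h=80.0, amplitude=1.0),
        BehaviorSpec(4, (GCSF, IL3), "late_rise", onset_h=80.0, amplitude=1.0),
    ]


def make_weights(
    G: int, K: int, sparsity: float, seed: int
) -> np.ndarray:
    """Sparse non-negative gene weights with one designated dominant entry.

    Gene g's designated behavior is g mod K; its weight is drawn from a
    heavy-tailed positive law.  Every other entry is zeroed with probability
    ``sparsity`` and otherwise drawn strictly below the dominant weight, so
    the designated behavior is always the row argmax.
    """
    if not 0 <= sparsity <= 1:
        raise ValueError("sparsity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    designated = np.arange(G) % K
    dominant = 1.0 + rng.pareto(3.0, size=G)
    W = rng.uniform(0.0, 0.6, size=(G, K)) * dominant[:, None]
    W *= rng.random((G, K)) >= sparsity
    W[np.arange(G), designated] = dominant
    return W


def make_flat_weights(H: np.ndarray, n: int, seed: int) -> np.ndarray:
    """Weight rows approximating a stably expressed (flat) trajectory.

    Real transcriptomes are dominated by genes whose expression barely
    changes; the median-of-ratios normalization relies on that majority.
    Each flat gene's weight row is the non-negative least-squares projection
    of a constant trajectory onto the behavior matrix H — so it stays
    exactly within the planted rank — scaled by a lognormal expression
    level.  Such genes carry weight on several behaviors at once, like the
    constant-expression group seen in real data.
    """
    from scipy.optimize import nnls

    base, _ = nnls(H.T, np.ones(H.shape[1]))
    if base.sum() == 0:
        raise ValueError("behaviors cannot represent a flat trajectory")
    rng = np.random.default_rng(seed)
    levels = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    return np.outer(levels, base)


def compose_expression(
    true_W: np.ndarray,
    true_H: np.ndarray,
    labels: list[tuple[str, int]],
    noise_cv: float = DEFAULT_CV,
    count_scale: float = DEFAULT_COUNT_SCALE,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = DEFAULT_SEED,
) -> SyntheticDataset:
    """Per-replicate expression = count_scale × (W·H) × LogNormal(0, CV).

    One sample per (condition, timepoint, replicate) on the supplied grid;
    values are kept as non-negative reals (normalized abundances, not raw
    counts).
    """
    G, K = true_W.shape
    if true_H.shape != (K, len(labels)):
        raise ValueError("true_W, true_H and labels are not conformable")
    rng = np.random.default_rng(seed)
    clean = count_scale * (true_W @ true_H)
    gene_ids = [f"gene{g:05d}" for g in range(G)]
    cols: dict[str, np.ndarray] = {}
    rows = []
    for j, (cond, t) in enumerate(labels):
        for r in range(1, replicates + 1):
            sid = f"{cond}_t{t}_r{r}"
            noise = (
                rng.lognormal(mean=0.0, sigma=noise_cv, size=G)
                if noise_cv > 0
                else np.ones(G)
            )
            cols[sid] = clean[:, j] * noise
            rows.append((sid, cond, t, r))
    expr = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    sheet = SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "condition", "timepoint_h", "replicate"])
    )
    return SyntheticDataset(
        expression=expr,
        sheet=sheet,
        labels=list(labels),
        true_W=true_W,
        true_H=true_H,
        noise_cv=noise_cv,
        count_scale=count_scale,
        seed=seed,
    )


#: Fraction of fixture genes that are stably expressed (flat mixtures);
#: keeps the median-of-ratios assumption satisfied, as in real data.
DEFAULT_FLAT_FRACTION = 0.55


def make_dataset(
    G: int = DEFAULT_G,
    K: int = DEFAULT_K,
    replicates: int = DEFAULT_REPLICATES,
    noise_cv: float = DEFAULT_CV,
    count_scale: float = DEFAULT_COUNT_SCALE,
    sparsity: float = 0.7,
    flat_fraction: float = DEFAULT_FLAT_FRACTION,
    seed: int = DEFAULT_SEED,
    specs: list[BehaviorSpec] | None = None,
) -> SyntheticDataset:
    """Default fixture: behaviors on the full sampling grid plus weights.

    The first ``(1 - flat_fraction) · G`` genes are sparse dynamic mixtures
    dominated by one designated behavior; the rest are stably expressed
    flat mixtures (see :func:`make_flat_weights`).  Everything remains an
    exact rank-K product W·H before noise.
    """
    if specs is None:
        specs = default_behavior_specs()
        if K != len(specs):
            raise ValueError("K must match the number of behavior specs")
    if not 0 <= flat_fraction < 1:
        raise ValueError("flat_fraction must lie in [0, 1)")
    H, labels = make_behaviors(specs)
    n_flat = int(round(G * flat_fraction))
    W = make_weights(G - n_flat, len(specs), sparsity=sparsity, seed=seed)
    if n_flat:
        W = np.vstack([W, make_flat_weights(H, n_flat, seed + 1)])
    ds = compose_expression(
        W, H, labels, noise_cv=noise_cv, count_scale=count_scale,
        replicates=replicates, seed=seed,
    )
    ds.n_flat = n_flat
    return ds


def plant_outlier(
    ds: SyntheticDataset, sample_id: str, shift: float, seed: int | None = None
) -> SyntheticDataset:
    """Multiply a random 30% gene subset of one sample by (1 + shift)."""
    if sample_id not in ds.expression.columns:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    if shift == 0:
        return ds
    rng = np.random.default_rng(ds.seed + 9973 if seed is None else seed)
    G = ds.expression.shape[0]
    mask = rng.random(G) < 0.3
    expr = ds.expression.copy()
    expr.loc[mask, sample_id] = expr.loc[mask, sample_id] * (1.0 + shift)
    return replace(
        ds,
        expression=expr,
        planted_outliers=[*ds.planted_outliers, (sample_id, shift)],
    )


# --- toy peak / TSS geometry -------------------------------------------------

#: TSS spacing on the toy chromosome; > 2 × 50 kb so distal windows never overlap.
TSS_SPACING_BP = 150_000
PEAK_WIDTH_BP = 200


def make_peaks_and_annotation(
    G: int,
    bound_fraction_fg: float,
    bound_fraction_bg: float,
    seed: int,
    n_fg: int | None = None,
    proximal_bp: int = 1000,
    distal_bp: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Toy chromosome with designated foreground genes bound at a higher rate.

    Genes are spaced ``TSS_SPACING_BP`` apart so ±50 kb windows never
    overlap.  For each gene and each window class (proximal, distal)
    independently, a peak is dropped with the class's bound fraction
    (foreground vs background).  Each gene carries two transcripts with
    distinct baseline expression; peaks are placed relative to the
    higher-baseline (representative) transcript.

    Returns (peaks BED-like frame, TSS annotation frame, foreground ids).
    """
    for frac in (bound_fraction_fg, bound_fraction_bg):
        if not 0 <= frac <= 1:
            raise ValueError("bound fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_fg is None:
        # keep the foreground a small minority so the background's bound
        # fraction stays close to bound_fraction_bg
        n_fg = max(1, G // 20)
    gene_ids = [f"gene{g:05d}" for g in range(G)]
    fg = set(gene_ids[:n_fg])
    ann_rows = []
    peak_rows = []
    for g, gid in enumerate(gene_ids):
        tss = 200_000 + g * TSS_SPACING_BP
        alt_tss = tss + 300
        hi, lo = rng.uniform(50, 100), rng.uniform(1, 40)
        ann_rows.append(("chrT", tss, "+", gid, f"{gid}.T1", hi))
        ann_rows.append(("chrT", alt_tss, "+", gid, f"{gid}.T2", lo))
        p = bound_fraction_fg if gid in fg else bound_fraction_bg
        if rng.random() < p:  # proximal peak
            off = rng.integers(-proximal_bp + PEAK_WIDTH_BP, proximal_bp - PEAK_WIDTH_BP)
            start = max(0, tss + off - PEAK_WIDTH_BP // 2)
            peak_rows.append(("chrT", start, start + PEAK_WIDTH_BP, 100.0))
        if rng.random() < p:  # distal peak, clear of the proximal zone
            mag = rng.integers(proximal_bp + 2000, distal_bp - 2000)
            off = int(mag) * (1 if rng.random() < 0.5 else -1)
            start = max(0, tss + off - PEAK_WIDTH_BP // 2)
            peak_rows.append(("chrT", start, start + PEAK_WIDTH_BP, 100.0))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "score"])
    peaks = peaks.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    ann = pd.DataFrame(
        ann_rows,
        columns=["chrom", "tss_pos", "strand", "gene_id", "transcript_id", "baseline_expr"],
    )
    return peaks, ann, fg


# --- file round-trips --------------------------------------------------------

def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the fixture to TSV/CSV/JSON files; returns the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(outdir / "expression.tsv"),
        "sample_sheet": str(outdir / "sample_sheet.csv"),
        "true_W": str(outdir / "true_W.tsv"),
        "true_H": str(outdir / "true_H.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    ds.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    ds.sheet.write(paths["sample_sheet"])
    pd.DataFrame(ds.true_W, index=ds.gene_ids).to_csv(paths["true_W"], sep="\t")
    pd.DataFrame(
        ds.true_H, columns=[f"{c}:{t}" for c, t in ds.labels]
    ).to_csv(paths["true_H"], sep="\t")
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": ds.seed,
                "noise_cv": ds.noise_cv,
                "count_scale": ds.count_scale,
                "planted_outliers": ds.planted_outliers,
                "true_W": paths["true_W"],
                "true_H": paths["true_H"],
            },
            fh,
            indent=2,
        )
    return paths


def write_bed(peaks: pd.DataFrame, path) -> None:
    peaks.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None)
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "score"][: df.shape[1]]
    return df


def write_tss(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_tss(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
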