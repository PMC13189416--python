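"""Reading, normalization and assembly of the gene × timepoint matrix.

Expression tables are plain pandas DataFrames (genes in rows, samples in
columns, non-negative values).  The pipeline normalizes by median-of-ratios
size factors, filters low-expressed genes, averages replicates per
(condition, timepoint) and concatenates the two condition blocks — all GCSF
timepoints (ascending) followed by all IL3 timepoints (ascending) — into a
:class:`TimepointMatrix`, the input of the NMF stage.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GCSF = "GCSF"
IL3 = "IL3"
CONDITIONS = (GCSF, IL3)

#: Hours after induction at which samples are drawn: hourly to 4 h, every
#: 4 h to 24 h, then every 8 h to the end of the seventh day (168 h).
POST_INDUCTION_HOURS = tuple(
    list(range(1, 5)) + list(range(8, 25, 4)) + list(range(32, 169, 8))
)


def build_timepoint_grid(condition: str) -> list[int]:
    """Sampling grid (hours) for one condition.

    Both conditions share 27 post-induction timepoints.  The GCSF arm
    additionally carries the undifferentiated baseline (-48 h, before
    cytokine conditioning) and the post-conditioning 0 h point; the IL3 arm
    carries its 0 h baseline only.
    """
    if condition == GCSF:
        return [-48, 0, *POST_INDUCTION_HOURS]
    if condition == IL3:
        return [0, *POST_INDUCTION_HOURS]
    raise ValueError(f"unknown condition {condition!r}")


@dataclass(frozen=True)
class SampleSheet:
    """Experimental design: one row per sequenced sample."""

    frame: pd.DataFrame  # columns: sample_id, condition, timepoint_h, replicate

    REQUIRED = ("sample_id", "condition", "timepoint_h", "replicate")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        bad = set(df["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition(s): {sorted(bad)}")
        if (df["replicate"] < 1).any():
            raise ValueError("replicate indices must be positive")

    @classmethod
    def read(cls, path) -> "SampleSheet":
        """Read a CSV or TSV sample sheet (delimiter sniffed from header)."""
        with open(path, encoding="utf-8") as fh:
            head = fh.readline()
        sep = "\t" if "\t" in head else ","
        df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
        df["timepoint_h"] = df["timepoint_h"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        return cls(df)

    def write(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def timepoints(self, condition: str) -> list[int]:
        """Sorted unique timepoints present for one condition."""
        sub = self.frame[self.frame["condition"] == condition]
        return sorted(sub["timepoint_h"].unique())

    def samples_at(self, condition: str, timepoint_h: int) -> list[str]:
        sub = self.frame[
            (self.frame["condition"] == condition)
            & (self.frame["timepoint_h"] == timepoint_h)
        ]
        return list(sub["sample_id"])


@dataclass
class TimepointMatrix:
    """Replicate-averaged expression on the concatenated condition blocks.

    ``labels`` is the ordered list of (condition, timepoint_h) column labels,
    every GCSF timepoint preceding every IL3 timepoint, time ascending
    within each block.  When ``scaled`` each non-zero row has maximum 1 and
    ``per_gene_max`` records the pre-scaling row maxima.
    """

    gene_ids: list[str]
    labels: list[tuple[str, int]]
    values: np.ndarray
    scaled: bool = False
    per_gene_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.labels)):
            raise ValueError("TimepointMatrix shape mismatch")
        if (self.values < 0).any():
            raise ValueError("negative value in TimepointMatrix")
        conds = [c for c, _ in self.labels]
        n_g = sum(1 for c in conds if c == GCSF)
        if any(c == GCSF for c in conds[n_g:]):
            raise ValueError("GCSF columns must precede IL3 columns")

    @property
    def n_gcsf(self) -> int:
        return sum(1 for c, _ in self.labels if c == GCSF)

    @property
    def n_il3(self) -> int:
        return len(self.labels) - self.n_gcsf

    def block(self, condition: str) -> slice:
        """Column slice of one condition block."""
        if condition == GCSF:
            return slice(0, self.n_gcsf)
        return slice(self.n_gcsf, len(self.labels))

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.labels, names=["condition", "timepoint_h"])
        return pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"), columns=cols)

    def write_tsv(self, path) -> None:
        """Write with two header rows (condition, timepoint_h)."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("condition\t" + "\t".join(c for c, _ in self.labels) + "\n")
            fh.write("timepoint_h\t" + "\t".join(str(t) for _, t in self.labels) + "\n")
            for g, row in zip(self.gene_ids, self.values):
                fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path, scaled: bool = False) -> "TimepointMatrix":
        with open(path, encoding="utf-8") as fh:
            conds = fh.readline().rstrip("\n").split("\t")[1:]
            times = [int(t) for t in fh.readline().rstrip("\n").split("\t")[1:]]
            rest = fh.read()
        df = pd.read_csv(io.StringIO(rest), sep="\t", header=None, index_col=0)
        labels = list(zip(conds, times))
        return cls(list(df.index.astype(str)), labels, df.to_numpy(float), scaled=scaled)


def read_expression(path, sheet: SampleSheet) -> pd.DataFrame:
    """Read an expression TSV (first column gene_id, one column per sample).

    Columns are reordered to the sample-sheet order.  Missing samples,
    duplicate gene ids and negative values are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id: {dup!r}")
    missing = [s for s in sheet.sample_ids if s not in df.columns]
    if missing:
        raise ValueError(f"missing sample id(s) in expression table: {missing}")
    df = df[sheet.sample_ids].astype(float)
    if (df.to_numpy() < 0).any():
        gene = df.index[(df.to_numpy() < 0).any(axis=1)][0]
        raise ValueError(f"negative value in expression table (gene {gene!r})")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def size_factors(table: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, pinned to geometric mean 1.

    For every gene with strictly positive expression in all samples (the
    reference set) the ratio of its value in sample j to its geometric mean
    across samples is formed; s_j is the median of these ratios.  The
    factors are then rescaled to geometric mean 1, which pins the global
    scale so that re-estimating factors on an already-normalized table
    returns exactly 1 for every sample.  The method assumes a majority of
    stably expressed genes; size factors are not meaningful on tables where
    most genes vary strongly across samples.
    """
    values = table.to_numpy(float)
    ref = (values > 0).all(axis=1)
    if not ref.any():
        raise ValueError("no reference genes: every gene has a zero in some sample")
    logs = np.log(values[ref])
    log_geomean = logs.mean(axis=1, keepdims=True)
    log_s = np.median(logs - log_geomean, axis=0)
    s = np.exp(log_s - log_s.mean())
    return pd.Series(s, index=table.columns, name="size_factor")


def normalize(table: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    if not table.columns.equals(s.index):
        s = s.reindex(table.columns)
        if s.isna().any():
            raise ValueError("size factors do not cover all samples")
    return table / s


def filter_low_expressed(table: pd.DataFrame, floor: float = 5.0) -> pd.DataFrame:
    """Drop genes whose normalized count is below ``floor`` in every sample.

    A gene is kept exactly when its maximum across samples is >= floor.
    """
    keep = table.max(axis=1) >= floor
    if not keep.any():
        raise ValueError("empty matrix: all genes below the expression floor")
    return table.loc[keep]


def average_replicates(
    table: pd.DataFrame, sheet: SampleSheet, share_baseline: bool = True
) -> TimepointMatrix:
    """Average replicate columns into one column per (condition, timepoint).

    With ``share_baseline`` (the experimental design's convention) the
    undifferentiated sample serves as both the GCSF -48 h and the IL3 0 h
    point: if the sheet has no IL3 0 h samples the averaged GCSF -48 h
    column is duplicated into that slot.
    """
    labels: list[tuple[str, int]] = []
    cols: list[np.ndarray] = []
    for cond in CONDITIONS:
        tps = sheet.timepoints(cond)
        if (
            share_baseline
            and cond == IL3
            and 0 not in tps
            and -48 in sheet.timepoints(GCSF)
        ):
            tps = [0, *tps]
        for t in tps:
            ids = sheet.samples_at(cond, t)
            if not ids and cond == IL3 and t == 0:
                ids = sheet.samples_at(GCSF, -48)
            if not ids:
                raise ValueError(f"no replicates for ({cond}, {t})")
            labels.append((cond, t))
            cols.append(table[ids].to_numpy(float).mean(axis=1))
    values = np.column_stack(cols)
    return TimepointMatrix(list(table.index), labels, values, scaled=False)


def max_scale(tm: TimepointMatrix) -> TimepointMatrix:
    """Scale each gene so its maximum over all timepoints and conditions is 1.

    All-zero rows are left as zeros.  The pre-scaling row maxima are kept in
    ``per_gene_max`` so normalized-count thresholds remain applicable.
    """
    if tm.scaled:
        raise ValueError("matrix already scaled")
    row_max = tm.values.max(axis=1)
    safe = np.where(row_max > 0, row_max, 1.0)
    return TimepointMatrix(
        tm.gene_ids,
        tm.labels,
        tm.values / safe[:, None],
        scaled=True,
        per_gene_max=row_max,
    )
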