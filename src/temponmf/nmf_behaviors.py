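"""Non-negative matrix factorization into temporal behaviors.

The gene × timepoint matrix X (max-scaled per gene) is approximated as
X ≈ W H with W (G × M) the per-gene behavior weights and H (M × T) the
behavior expression patterns.  Fitting uses the Frobenius multiplicative
update rules

    W ← W ∘ (X Hᵀ) ⊘ (W H Hᵀ),    H ← H ∘ (Wᵀ X) ⊘ (Wᵀ W H),

applied alternately (H sees the freshly updated W), with uniform [0, 1)
initialization and the stopping rule |F_k − F_{k−1}| < θ on the Frobenius
gap F_k = ‖X − W H‖_F (default θ = 0.05).  A Poisson-likelihood objective
Σ (X log(WH) − WH) is reported alongside as a diagnostic trace.

Rank selection sweeps M, measuring the RMSE between the reconstructions at
consecutive ranks; robustness repeats the factorization from random starts
and compares pairwise reconstruction RMSEs to the reconstruction-to-data
RMSE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from temponmf.io_normalize import TimepointMatrix


@dataclass(frozen=True)
class NMFConfig:
    M: int = 10
    theta: float = 0.05
    max_iter: int = 10_000
    seed: int = 0
    epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.theta <= 0:
            raise ValueError("theta must be positive")


@dataclass
class NMFModel:
    W: np.ndarray
    H: np.ndarray
    frobenius_trace: list[float]
    objective_trace: list[float]
    iterations: int
    converged: bool
    config: NMFConfig
    gene_ids: list[str] | None = None
    labels: list[tuple[str, int]] | None = None

    @property
    def approximation(self) -> np.ndarray:
        return self.W @ self.H

    def metadata(self) -> dict:
        return {
            "M": self.config.M,
            "theta": self.config.theta,
            "seed": self.config.seed,
            "iterations": self.iterations,
            "converged": self.converged,
            "frobenius_trace": self.frobenius_trace,
            "objective_trace": self.objective_trace,
        }

    def write(self, w_path, h_path, meta_path) -> None:
        import pandas as pd

        ids = self.gene_ids or [f"g{i}" for i in range(self.W.shape[0])]
        beh = [f"behavior{m + 1}" for m in range(self.config.M)]
        pd.DataFrame(self.W, index=ids, columns=beh).to_csv(w_path, sep="\t")
        cols = [f"{c}:{t}" for c, t in self.labels] if self.labels else None
        pd.DataFrame(self.H, index=beh, columns=cols).to_csv(h_path, sep="\t")
        with open(meta_path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata(), fh, indent=2)


@dataclass
class ModelSelectionResult:
    """RMSE curves over a range of ranks M.

    ``rmse_successive[i]`` compares the reconstructions at ``M_values[i]``
    and ``M_values[i] + 1`` (the error of "stepping past" rank M); its
    interior strict local minima are candidate ranks.  ``rmse_fit`` is the
    reconstruction-to-data RMSE at each M.
    """

    M_values: list[int]
    rmse_successive: dict[int, float]
    rmse_fit: dict[int, float]
    local_minima: list[int]
    plateaus: list[int] = field(default_factory=list)
    non_converged: list[int] = field(default_factory=list)


@dataclass
class RobustnessResult:
    n_runs: int
    rmse_pairwise: np.ndarray
    rmse_to_data: np.ndarray


def init(G: int, M: int, T: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform [0, 1) initialization of W (G × M) and H (M × T)."""
    rng = np.random.default_rng(seed)
    return rng.random((G, M)), rng.random((M, T))


def objective(X: np.ndarray, W: np.ndarray, H: np.ndarray, epsilon: float = 1e-12) -> float:
    """Poisson-likelihood objective Σ (X log(WH + ε) − WH) (diagnostic)."""
    WH = W @ H
    return float(np.sum(X * np.log(WH + epsilon) - WH))


def update_step(
    X: np.ndarray, W: np.ndarray, H: np.ndarray, epsilon: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """One alternating multiplicative update; zero entries remain zero.

    Denominators are floored at ``epsilon`` (guarding 0/0 without
    perturbing non-degenerate entries, so the update is exactly the
    printed multiplicative rule wherever the denominator is nonzero).
    """
    W = W * (X @ H.T) / np.maximum(W @ H @ H.T, epsilon)
    H = H * (W.T @ X) / np.maximum(W.T @ W @ H, epsilon)
    return W, H


def frobenius_gap(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """F = ‖X − W H‖_F."""
    return float(np.linalg.norm(X - W @ H))


def rmse(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square difference: ‖A − B‖_F / sqrt(#entries)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    return float(np.linalg.norm(A - B) / np.sqrt(A.size))


def fit(
    X: TimepointMatrix | np.ndarray,
    config: NMFConfig,
    allow_unscaled: bool = False,
) -> NMFModel:
    """Iterate the multiplicative updates until the Frobenius gap stalls.

    ``X`` is expected max-scaled (every non-zero row peaking at 1); pass
    ``allow_unscaled=True`` to factor raw normalized values instead.
    """
    gene_ids = labels = None
    if isinstance(X, TimepointMatrix):
        if not X.scaled and not allow_unscaled:
            raise ValueError("TimepointMatrix is not max-scaled (use allow_unscaled=True)")
        gene_ids, labels = X.gene_ids, X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    G, T = X.shape
    W, H = init(G, config.M, T, config.seed)
    f_prev = frobenius_gap(X, W, H)
    f_trace = [f_prev]
    o_trace = [objective(X, W, H, config.epsilon)]
    converged = False
    iterations = 0
    for k in range(1, config.max_iter + 1):
        W, H = update_step(X, W, H, config.epsilon)
        if not (np.isfinite(W).all() and np.isfinite(H).all()):
            raise FloatingPointError(f"non-finite factor entries at iteration {k}")
        f_k = frobenius_gap(X, W, H)
        f_trace.append(f_k)
        o_trace.append(objective(X, W, H, config.epsilon))
        iterations = k
        if abs(f_k - f_prev) < config.theta:
            converged = True
            break
        f_prev = f_k
    return NMFModel(
        W=W,
        H=H,
        frobenius_trace=f_trace,
        objective_trace=o_trace,
        iterations=iterations,
        converged=converged,
        config=config,
        gene_ids=gene_ids,
        labels=labels,
    )


def fit_restarts(
    X: TimepointMatrix | np.ndarray,
    config: NMFConfig,
    n_restarts: int = 10,
    allow_unscaled: bool = False,
) -> NMFModel:
    """Fit from several random starts and keep the lowest final Frobenius gap.

    Multiplicative updates can stall in poor local minima, especially on
    exactly low-rank matrices; restarting from fresh seeded initializations
    (config.seed, config.seed + 1, ...) and keeping the best run is the
    standard remedy.
    """
    best: NMFModel | None = None
    for i in range(n_restarts):
        cfg = NMFConfig(
            M=config.M, theta=config.theta, max_iter=config.max_iter,
            seed=config.seed + i, epsilon=config.epsilon,
        )
        model = fit(X, cfg, allow_unscaled=allow_unscaled)
        if best is None or model.frobenius_trace[-1] < best.frobenius_trace[-1]:
            best = model
    assert best is not None
    return best


def sweep_M(
    X: TimepointMatrix | np.ndarray,
    M_range,
    config: NMFConfig,
    allow_unscaled: bool = False,
) -> ModelSelectionResult:
    """Fit at every rank in ``M_range`` and compare consecutive reconstructions.

    Each rank gets a fresh deterministic seed (config.seed + M).  The
    successive RMSE is keyed by the lower rank of each consecutive pair, so
    a strict interior local minimum at M reads "adding an (M+1)-th behavior
    changes the reconstruction least around here".  Non-convergent fits are
    recorded, not fatal.
    """
    M_range = list(M_range)
    if sorted(M_range) != M_range or len(set(M_range)) != len(M_range):
        raise ValueError("M_range must be strictly increasing")
    if len(M_range) < 3:
        raise ValueError("M_range must contain at least 3 ranks")
    Xv = X.values if isinstance(X, TimepointMatrix) else np.asarray(X, float)
    approx: dict[int, np.ndarray] = {}
    rmse_fit: dict[int, float] = {}
    non_converged = []
    for M in M_range:
        cfg = NMFConfig(
            M=M, theta=config.theta, max_iter=config.max_iter,
            seed=config.seed + M, epsilon=config.epsilon,
        )
        model = fit(X, cfg, allow_unscaled=allow_unscaled)
        if not model.converged:
            non_converged.append(M)
        approx[M] = model.approximation
        rmse_fit[M] = rmse(approx[M], Xv)
    rmse_successive = {
        lo: rmse(approx[hi], approx[lo])
        for lo, hi in zip(M_range[:-1], M_range[1:])
    }
    keys = sorted(rmse_successive)
    local_minima, plateaus = [], []
    for prev, cur, nxt in zip(keys[:-2], keys[1:-1], keys[2:]):
        a, b, c = rmse_successive[prev], rmse_successive[cur], rmse_successive[nxt]
        if b < a and b < c:
            local_minima.append(cur)
        elif b <= a and b <= c:
            plateaus.append(cur)
    return ModelSelectionResult(
        M_values=M_range,
        rmse_successive=rmse_successive,
        rmse_fit=rmse_fit,
        local_minima=local_minima,
        plateaus=plateaus,
        non_converged=non_converged,
    )


def robustness(
    X: TimepointMatrix | np.ndarray,
    config: NMFConfig,
    n_runs: int = 100,
    allow_unscaled: bool = False,
) -> RobustnessResult:
    """Repeat the factorization from ``n_runs`` seeded random starts.

    Collects the RMSE between every pair of reconstructions and the RMSE of
    each reconstruction to the data; robustness shows as the pairwise
    values sitting below the to-data values.
    """
    Xv = X.values if isinstance(X, TimepointMatrix) else np.asarray(X, float)
    approx = []
    to_data = []
    for run in range(n_runs):
        cfg = NMFConfig(
            M=config.M, theta=config.theta, max_iter=config.max_iter,
            seed=config.seed + run, epsilon=config.epsilon,
        )
        model = fit(X, cfg, allow_unscaled=allow_unscaled)
        approx.append(model.approximation)
        to_data.append(rmse(model.approximation, Xv))
    pairwise = [
        rmse(approx[i], approx[j])
        for i in range(n_runs)
        for j in range(i + 1, n_runs)
    ]
    return RobustnessResult(n_runs, np.array(pairwise), np.array(to_data))


def reconstruct_gene(
    model: NMFModel, gene: str, behavior_order: list[int] | None = None
) -> np.ndarray:
    """Cumulative reconstruction of one gene's trajectory.

    Row k (1-based) is the partial sum of the first k weighted behaviors in
    the given order; the last row equals the model's full approximation of
    the gene.
    """
    if model.gene_ids is None or gene not in model.gene_ids:
        raise KeyError(f"unknown gene {gene!r}")
    g = model.gene_ids.index(gene)
    order = behavior_order if behavior_order is not None else list(range(model.config.M))
    terms = np.array([model.W[g, m] * model.H[m] for m in order])
    return np.cumsum(terms, axis=0)
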