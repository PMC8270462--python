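"""Model selection by repeated bi-cross-validation.

The number of discovered signatures K and the regularization fraction
lambda are chosen by hold-out prediction: a random subset of *cells* of
the count matrix (1% by default) is zeroed out, the factorization is run
on the remainder, the held-out cells are imputed from the reconstruction
``alpha0 beta0 + alpha beta``, and fitting/imputation is repeated a few
rounds so the imputed values stabilize. The mean squared error between
the final imputed values and the true held-out values scores the
(K, lambda) pair; the whole procedure is repeated with fresh hold-out
masks, and the pair that achieves the lowest error in the most
repetitions wins.

Unlike selection by residual error — which always improves with more
signatures — held-out prediction error penalizes overfitting, giving an
unambiguous criterion for K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .background import BackgroundSignature
from .factorization import (
    _as_array,
    fit,
    initialize_signatures,
)

logger = logging.getLogger(__name__)

#: lambda grid used for the published real-data runs
DEFAULT_LAMBDA_GRID = (0.01, 0.025, 0.05, 0.075, 0.1)


@dataclass
class CVConfig:
    """Configuration of the repeated bi-cross-validation grid search."""

    k_grid: tuple[int, ...]
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    holdout_fraction: float = 0.01
    repetitions: int = 10
    imputation_rounds: int = 5
    inner_iterations: int = 20
    restarts: int = 10
    seed: int = 0
    # relative-objective early stop for the inner fits; inner_iterations is
    # then a cap on the alternation, which usually converges much sooner
    tol: float = 1e-4
    solver: str = "cd"
    n_jobs: int = 1

    def __post_init__(self) -> None:
        self.k_grid = tuple(int(k) for k in self.k_grid)
        self.lambda_grid = tuple(float(l) for l in self.lambda_grid)
        if not self.k_grid or not self.lambda_grid:
            raise ValueError("k_grid and lambda_grid must be non-empty")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.repetitions < 1 or self.imputation_rounds < 1:
            raise ValueError("repetitions and imputation_rounds must be >= 1")


@dataclass
class CVResult:
    """Grid of held-out-cell MSEs indexed by (K, lambda, repetition)."""

    k_grid: tuple[int, ...]
    lambda_grid: tuple[float, ...]
    mse: np.ndarray  # (len(k_grid), len(lambda_grid), repetitions)
    masks: list[np.ndarray] = field(default_factory=list)
    selected: tuple[int, float] | None = None
    rule: str = "modal"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, lam, rep, self.mse[ik, il, rep])
            for ik, k in enumerate(self.k_grid)
            for il, lam in enumerate(self.lambda_grid)
            for rep in range(self.mse.shape[2])
        ]
        return pd.DataFrame(rows, columns=["K", "lambda", "repetition", "mse"])

    def summary(self) -> dict:
        k, lam = self.selected if self.selected is not None else (None, None)
        return {
            "selected_k": k,
            "selected_k_total_with_background": None if k is None else k + 1,
            "selected_lambda": lam,
            "rule": self.rule,
            "k_grid": list(self.k_grid),
            "lambda_grid": list(self.lambda_grid),
            "repetitions": int(self.mse.shape[2]),
        }


def holdout_mask(
    M, fraction: float, seed: int, max_retries: int = 100
) -> np.ndarray:
    """Boolean mask of ceil(fraction * N * 96) cells sampled uniformly.

    Cells are drawn without replacement. A draw is rejected (and redrawn,
    up to ``max_retries`` times) if it would remove every nonzero cell of
    some sample, which would leave that row unconstrained during fitting.
    """
    M = _as_array(M)
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n, m = M.shape
    n_cells = math.ceil(fraction * n * m)
    rng = np.random.default_rng(seed)
    nonzero = M > 0
    for _ in range(max_retries):
        flat = rng.choice(n * m, size=n_cells, replace=False)
        mask = np.zeros(n * m, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(n, m)
        rows_ok = ((nonzero & ~mask).sum(axis=1) > 0) | (~nonzero.any(axis=1))
        if rows_ok.all():
            return mask
    raise ValueError(
        f"could not draw a {fraction:.3f} hold-out mask leaving every sample "
        f"with at least one nonzero cell after {max_retries} attempts"
    )


def _as_mask(mask, shape: tuple[int, int]) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape != shape:
            raise ValueError(f"mask shape {mask.shape} does not match M {shape}")
        return mask
    # iterable of (row, col) cells
    cells = np.atleast_2d(mask)
    out = np.zeros(shape, dtype=bool)
    for i, j in cells:
        if not (0 <= i < shape[0] and 0 <= j < shape[1]):
            raise ValueError(f"mask cell ({i}, {j}) out of range for M {shape}")
        out[int(i), int(j)] = True
    return out


def cv_error(
    M,
    mask,
    beta0: BackgroundSignature | None,
    K: int,
    lambda_fraction: float,
    config: CVConfig,
    beta_init: np.ndarray | None = None,
    init_seed: int = 0,
) -> float:
    """Held-out prediction MSE for one (K, lambda) pair on one mask.

    Masked cells are zeroed, the model is fit, the masked cells are
    replaced by the reconstruction, and the fit is repeated for
    ``config.imputation_rounds`` rounds (rounds after the first warm-start
    from the previous round's signatures). Returns the mean squared error
    between the final round's predictions and the true held-out values.
    """
    M_true = _as_array(M)
    mask = _as_mask(mask, M_true.shape)
    work = M_true.copy()
    work[mask] = 0.0
    if beta_init is None and K > 0:
        beta_init = initialize_signatures(
            M_true, K, restarts=config.restarts, seed=init_seed
        )
    current_init = beta_init
    pred = None
    for _ in range(config.imputation_rounds):
        res = fit(
            work, beta0, K, lambda_fraction,
            iterations=config.inner_iterations,
            seed=init_seed, beta_init=current_init,
            tol=config.tol, solver=config.solver,
        )
        pred = res.reconstruction()
        work[mask] = pred[mask]
        if K > 0:
            # warm-start next round; rows the penalty zeroed out fall back
            # to their original initialization so they can re-enter
            nz = res.signatures.sum(axis=1) > 0
            current_init = np.where(nz[:, None], res.signatures, beta_init)
    return float(((pred[mask] - M_true[mask]) ** 2).mean())


def _grid_for_repetition(args):
    (M, mask, beta0, config, inits, init_seeds) = args
    out = np.zeros((len(config.k_grid), len(config.lambda_grid)))
    for ik, K in enumerate(config.k_grid):
        for il, lam in enumerate(config.lambda_grid):
            out[ik, il] = cv_error(
                M, mask, beta0, K, lam, config,
                beta_init=inits[K], init_seed=init_seeds[K],
            )
    return out


def cross_validate(
    M, beta0: BackgroundSignature | None, config: CVConfig
) -> CVResult:
    """Full repeated bi-cross-validation over the (K, lambda) grid.

    The repeated-NMF initialization is computed once per K on the complete
    matrix and reused across lambda values and repetitions; within one
    repetition the same hold-out mask is used for every grid cell so pairs
    are compared on identical held-out data. Deterministic given
    ``config.seed``.
    """
    M = _as_array(M)
    root = np.random.SeedSequence(config.seed)
    init_ss, mask_ss = root.spawn(2)
    init_seeds = {
        K: int(s.generate_state(1)[0] % (2**31 - 1))
        for K, s in zip(config.k_grid, init_ss.spawn(len(config.k_grid)))
    }
    inits = {
        K: (
            initialize_signatures(M, K, restarts=config.restarts, seed=init_seeds[K])
            if K > 0 else None
        )
        for K in config.k_grid
    }
    mask_seeds = [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in mask_ss.spawn(config.repetitions)
    ]
    masks = [
        holdout_mask(M, config.holdout_fraction, seed) for seed in mask_seeds
    ]
    tasks = [(M, mask, beta0, config, inits, init_seeds) for mask in masks]
    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        grids = Parallel(n_jobs=config.n_jobs)(
            delayed(_grid_for_repetition)(t) for t in tasks
        )
    else:
        grids = [_grid_for_repetition(t) for t in tasks]
    mse = np.stack(grids, axis=2)
    result = CVResult(
        k_grid=config.k_grid, lambda_grid=config.lambda_grid,
        mse=mse, masks=masks,
    )
    result.selected = select_model(result)
    return result


def select_model(result: CVResult, rule: str = "modal") -> tuple[int, float]:
    """Pick (K, lambda) from a CV grid.

    ``rule="modal"`` (default): per repetition, find the grid cell with the
    lowest held-out MSE; return the pair chosen most often. Ties are broken
    by lower median MSE across repetitions, then smaller K, then larger
    lambda. ``rule="median"``: the cell minimizing the median MSE across
    repetitions (the criterion reported in the published CV tables), same
    downstream tie-breaks.
    """
    if result.mse.size == 0:
        raise ValueError("empty CV result")
    k_grid, lambda_grid, mse = result.k_grid, result.lambda_grid, result.mse
    medians = np.median(mse, axis=2)

    def ladder(cells):
        """smaller median MSE, then smaller K, then larger lambda"""
        return min(
            cells,
            key=lambda c: (medians[c[0], c[1]], k_grid[c[0]], -lambda_grid[c[1]]),
        )

    if rule == "median":
        best = np.min(medians)
        cells = [tuple(c) for c in np.argwhere(medians <= best)]
        ik, il = ladder(cells)
    elif rule == "modal":
        wins: dict[tuple[int, int], int] = {}
        for rep in range(mse.shape[2]):
            grid = mse[:, :, rep]
            best = grid.min()
            cells = [tuple(c) for c in np.argwhere(grid <= best)]
            # within-repetition tie: smaller K, then larger lambda
            cell = min(cells, key=lambda c: (k_grid[c[0]], -lambda_grid[c[1]]))
            wins[cell] = wins.get(cell, 0) + 1
        top = max(wins.values())
        ik, il = ladder([c for c, w in wins.items() if w == top])
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    result.rule = rule
    return (k_grid[ik], lambda_grid[il])
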