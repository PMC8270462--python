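"""Penalized alternating factorization with a fixed background signature.

The model is ``M ~ alpha0 beta0 + alpha beta`` with all factors
non-negative: M is the N x 96 count matrix, beta0 a fixed 1 x 96
background signature with per-sample exposures alpha0, beta the K x 96
matrix of discovered signatures and alpha the N x K exposure matrix. The
fitted objective is

    || M - (alpha0 beta0 + alpha beta) ||_F^2  +  lambda ||beta||_1

subject to alpha, alpha0, beta >= 0, with beta0 never penalized or
modified. The objective is bi-convex — convex in the exposures for fixed
signatures and vice versa — so it is minimized by alternating exact
solutions of the two convex subproblems:

* exposures: per-sample non-negative least squares (samples separate);
* signatures: a non-negative LASSO, solved by cyclic coordinate descent
  over signature rows (the 96 categories separate, so a whole row update
  is an exact coordinate step for every column at once).

The user-facing regularization weight is a *fraction* of lambda_max, the
smallest penalty at which the signature subproblem's minimizer is the zero
matrix; this makes the setting comparable across datasets and K.

Scale convention: beta is initialized with rows summing to 1 and the
product alpha beta fixes the remaining scale ambiguity; output rows are
renormalized to sum 1 (with alpha rescaled so alpha beta is unchanged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import nnls as _scipy_nnls
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .background import BackgroundSignature
from .categories import CATEGORIES, CountMatrix

logger = logging.getLogger(__name__)

#: relative-objective convergence tolerance of the inner coordinate descents
CD_TOL = 1e-8
#: inner-iteration cap for the coordinate-descent solvers
CD_MAX_SWEEPS = 20_000


class ConvergenceError(RuntimeError):
    """Inner solver failed to converge; carries the partial state."""

    def __init__(self, message: str, partial: np.ndarray):
        super().__init__(message)
        self.partial = partial


@dataclass
class ExposureSet:
    """Background exposures alpha0 (N, or None) and exposures alpha (N x K)."""

    alpha0: np.ndarray | None
    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha0 is not None:
            self.alpha0 = np.asarray(self.alpha0, dtype=float)
            if self.alpha0.shape != (self.alpha.shape[0],):
                raise ValueError("alpha0 length must match alpha rows")

    @property
    def n_samples(self) -> int:
        return self.alpha.shape[0]


def _as_array(M) -> np.ndarray:
    if isinstance(M, CountMatrix):
        return np.asarray(M.counts, dtype=float)
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be a 2-d matrix")
    return M


def _beta0_vec(beta0: BackgroundSignature | np.ndarray | None) -> np.ndarray | None:
    if beta0 is None:
        return None
    if isinstance(beta0, BackgroundSignature):
        return beta0.probs
    return np.asarray(beta0, dtype=float)


def initialize_signatures(
    M, K: int, restarts: int = 10, seed: int = 0
) -> np.ndarray:
    """Initial K signatures from repeated NMF, rows normalized to sum 1.

    Runs ``restarts`` randomly-initialized NMF factorizations of M and keeps
    the one with the lowest reconstruction error. Deterministic given seed.
    """
    M = _as_array(M)
    n, m = M.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if K > min(n, m):
        raise ValueError(f"K={K} exceeds min(N, categories)={min(n, m)}")
    if not M.any():
        raise ValueError("cannot initialize signatures from an all-zero matrix")
    if int(np.count_nonzero(M.sum(axis=1))) < K:
        raise ValueError(f"fewer than K={K} samples with nonzero mutation counts")
    children = np.random.SeedSequence(seed).spawn(restarts)
    best_err, best_H = np.inf, None
    for child in children:
        state = int(child.generate_state(1)[0] % (2**31 - 1))
        model = NMF(
            n_components=K, init="random", random_state=state,
            max_iter=240, tol=1e-4,
        )
        with warnings.catch_warnings():
            # the NMF here is only a starting point; the alternation below
            # refines it far past what extra NMF iterations would buy
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(M)
        if model.reconstruction_err_ < best_err:
            best_err = model.reconstruction_err_
            best_H = model.components_
    beta = np.maximum(best_H, 0.0)
    sums = beta.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return beta / sums


def _stack_design(beta0_vec: np.ndarray | None, beta: np.ndarray) -> np.ndarray:
    rows = [] if beta0_vec is None else [beta0_vec]
    if beta.size:
        rows.append(beta)
    if not rows:
        raise ValueError("no signatures: need a background and/or K >= 1")
    return np.vstack(rows) if len(rows) > 1 else np.atleast_2d(rows[0])


@njit(cache=True)
def _cd_kernel(G, C, A, norm_M, penalty, tol, max_sweeps):  # pragma: no cover
    """Cyclic CD for min ||X - A D||_F^2 + penalty * sum(A), A >= 0.

    G = D D^T, C = X D^T, norm_M = ||X||_F^2. Rows of X are independent,
    so each coordinate update is applied to the whole column of A at once.
    Returns (A, converged).
    """
    n, p = A.shape
    prev_obj = np.inf
    for sweep in range(max_sweeps):
        max_step = 0.0
        scale = 1.0
        for k in range(p):
            gkk = G[k, k]
            if gkk <= 0.0:
                for i in range(n):
                    A[i, k] = 0.0
                continue
            for i in range(n):
                r = C[i, k] + A[i, k] * gkk
                for k2 in range(p):
                    r -= A[i, k2] * G[k2, k]
                new = (r - penalty / 2.0) / gkk
                if new < 0.0:
                    new = 0.0
                step = abs(new - A[i, k])
                if step > max_step:
                    max_step = step
                if new > scale:
                    scale = new
                A[i, k] = new
        obj = norm_M + penalty * A.sum()
        for i in range(n):
            for k in range(p):
                s = 0.0
                for k2 in range(p):
                    s += A[i, k2] * G[k2, k]
                obj += A[i, k] * (s - 2.0 * C[i, k])
        if prev_obj - obj <= tol * max(1.0, abs(obj)) or max_step <= 1e-12 * scale:
            return A, True
        prev_obj = obj
    return A, False


def _nnls_cd(
    M: np.ndarray,
    B: np.ndarray,
    A_init: np.ndarray | None = None,
    tol: float = CD_TOL,
) -> np.ndarray:
    """min ||M - A B||_F^2 over A >= 0, by cyclic coordinate descent.

    Samples (rows of M) are independent, so every coordinate update is
    applied across all of them. Converges to the per-sample NNLS solution;
    on ill-conditioned designs (near-duplicate signatures) where the
    descent stalls, the exact per-sample active-set solver finishes the
    job.
    """
    n, p = M.shape[0], B.shape[0]
    G = B @ B.T
    C = M @ B.T
    A = np.zeros((n, p)) if A_init is None else np.array(A_init, dtype=float)
    norm_M = float(np.einsum("ij,ij->", M, M))
    A, converged = _cd_kernel(G, C, A, norm_M, 0.0, tol, 2000)
    if converged:
        return A
    logger.debug("exposure coordinate descent stalled; active-set fallback")
    return _nnls_active_set(M, B)


def _nnls_active_set(M: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.zeros((M.shape[0], B.shape[0]))
    design = B.T
    for i in range(M.shape[0]):
        A[i], _ = _scipy_nnls(design, M[i])
    return A


def update_exposures(
    M,
    beta0: BackgroundSignature | np.ndarray | None,
    beta: np.ndarray,
    solver: str = "cd",
    warm_start: ExposureSet | None = None,
    tol: float | None = None,
) -> ExposureSet:
    """Exact exposure update: per-sample NNLS with beta0 and beta fixed.

    ``solver="cd"`` (default) uses coordinate descent vectorized across
    samples; ``solver="active-set"`` uses Lawson–Hanson NNLS per sample.
    Both reach the same minimizer (the subproblem is convex and separable
    over samples).
    """
    M = _as_array(M)
    beta = np.atleast_2d(np.asarray(beta, dtype=float)) if np.size(beta) else np.zeros((0, M.shape[1]))
    b0 = _beta0_vec(beta0)
    B = _stack_design(b0, beta)
    if B.shape[1] != M.shape[1]:
        raise ValueError(
            f"signature length {B.shape[1]} does not match M columns {M.shape[1]}"
        )
    if solver == "active-set":
        A = _nnls_active_set(M, B)
    elif solver == "cd":
        A_init = None
        if warm_start is not None:
            parts = []
            if b0 is not None:
                parts.append(warm_start.alpha0[:, None])
            parts.append(warm_start.alpha)
            A_init = np.hstack(parts)
        # run to numerical stall by default so the public update is exact
        A = _nnls_cd(M, B, A_init, tol=1e-15 if tol is None else tol)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    if b0 is None:
        return ExposureSet(alpha0=None, alpha=A)
    return ExposureSet(alpha0=A[:, 0], alpha=A[:, 1:])


def lambda_max(
    M,
    beta0: BackgroundSignature | np.ndarray | None,
    exposures: ExposureSet,
) -> float:
    """Smallest penalty at which the signature subproblem minimizer is 0.

    For the non-negative LASSO ``min ||R - alpha beta||_F^2 + lam ||beta||_1``
    with residual ``R = M - alpha0 beta0``, stationarity of beta = 0 requires
    ``lam >= 2 (alpha^T R)_kj`` for every entry, so

        lambda_max = 2 * max(0, max_entries(alpha^T R)).

    The factor 2 follows from the squared-Frobenius loss carrying no 1/2.
    """
    M = _as_array(M)
    b0 = _beta0_vec(beta0)
    alpha = exposures.alpha
    if alpha.size == 0 or not alpha.any():
        logger.warning("lambda_max: all exposures are zero; returning 0")
        return 0.0
    R = M if b0 is None else M - np.outer(exposures.alpha0, b0)
    return float(2.0 * max(0.0, (alpha.T @ R).max()))


def _solve_beta(
    R: np.ndarray,
    alpha: np.ndarray,
    beta_init: np.ndarray,
    penalty: float,
    tol: float = 1e-15,
) -> np.ndarray:
    """Non-negative LASSO in beta by cyclic coordinate descent over rows.

    Columns of beta (the 96 categories) decouple given the other rows, so
    updating an entire row at once is an exact coordinate step:

        beta_k = max(0, (alpha_k^T R - sum_{k'!=k} G_kk' beta_k' - lam/2) / G_kk)

    with Gram matrix G = alpha^T alpha. Each sweep cannot increase the
    objective; convergence is declared at relative objective change CD_TOL.
    """
    K = beta_init.shape[0]
    if K == 0:
        return beta_init.copy()
    # transposed problem: rows of R^T (the 96 categories) are independent
    # observations, beta^T the coefficient matrix, alpha^T the design
    G = alpha.T @ alpha
    C = R.T @ alpha
    bT = np.array(beta_init.T, dtype=float)
    norm_R = float(np.einsum("ij,ij->", R, R))
    bT, converged = _cd_kernel(G, C, bT, norm_R, penalty, tol, CD_MAX_SWEEPS)
    if not converged:
        raise ConvergenceError(
            f"signature coordinate descent did not converge in {CD_MAX_SWEEPS} sweeps",
            bT.T.copy(),
        )
    return np.ascontiguousarray(bT.T)


def update_signatures(
    M,
    beta0: BackgroundSignature | np.ndarray | None,
    exposures: ExposureSet,
    beta_init: np.ndarray,
    lambda_fraction: float,
) -> np.ndarray:
    """Signature update: non-negative LASSO with effective penalty
    ``lambda_fraction * lambda_max(M, beta0, exposures)``.

    beta0 is never penalized or modified; only the K discovered signatures
    are updated.
    """
    if not 0.0 <= lambda_fraction <= 1.0:
        raise ValueError("lambda_fraction must lie in [0, 1]")
    M = _as_array(M)
    b0 = _beta0_vec(beta0)
    R = M if b0 is None else M - np.outer(exposures.alpha0, b0)
    penalty = lambda_fraction * lambda_max(M, beta0, exposures)
    return _solve_beta(R, exposures.alpha, np.atleast_2d(beta_init), penalty)


@dataclass
class DecompositionResult:
    """Final factors and bookkeeping of one ``fit`` run."""

    background: BackgroundSignature | None
    signatures: np.ndarray  # (K, 96), rows sum to 1 (or are structurally zero)
    exposures: ExposureSet
    lambda_fraction: float
    lambda_max_: float
    objective_trace: list[float] = field(default_factory=list)
    mse: float = float("nan")
    effective_k: int = 0

    def reconstruction(self) -> np.ndarray:
        rec = self.exposures.alpha @ self.signatures if self.signatures.size else 0.0
        if self.background is not None:
            rec = rec + np.outer(self.exposures.alpha0, self.background.probs)
        return np.asarray(rec)

    # -- TSV serialization ---------------------------------------------------

    def signatures_frame(self, include_background: bool = True) -> pd.DataFrame:
        rows, index = [], []
        if include_background and self.background is not None:
            rows.append(self.background.probs)
            index.append("Background")
        for k in range(self.signatures.shape[0]):
            rows.append(self.signatures[k])
            index.append(f"Signature_{k + 1}")
        return pd.DataFrame(rows, index=index, columns=list(CATEGORIES))

    def exposures_frame(
        self, sample_ids: list[str] | None = None, normalized: bool = False
    ) -> pd.DataFrame:
        cols, names = [], []
        if self.background is not None:
            cols.append(self.exposures.alpha0)
            names.append("Background")
        for k in range(self.signatures.shape[0]):
            cols.append(self.exposures.alpha[:, k])
            names.append(f"Signature_{k + 1}")
        table = pd.DataFrame(np.column_stack(cols), columns=names)
        if sample_ids is not None:
            table.index = pd.Index(sample_ids, name="sample")
        if normalized:
            totals = table.sum(axis=1).replace(0, 1.0)
            table = table.div(totals, axis=0)
        return table


def fit(
    M,
    beta0: BackgroundSignature | np.ndarray | None,
    K: int,
    lambda_fraction: float,
    iterations: int = 20,
    restarts: int = 10,
    seed: int = 0,
    beta_init: np.ndarray | None = None,
    tol: float = 0.0,
    solver: str = "cd",
) -> DecompositionResult:
    """Alternating minimization of the penalized objective.

    Starting from a repeated-NMF initialization of beta (or ``beta_init``),
    each iteration first refits the exposures (per-sample NNLS) and then the
    signatures (non-negative LASSO at penalty lambda_fraction * lambda_max,
    with lambda_max computed once from the initial exposures so the
    effective penalty is fixed for the whole run). The penalized objective
    is recorded after every half-step and is non-increasing. With
    ``tol > 0`` the alternation stops early once the relative objective
    improvement over a full iteration drops below tol.

    ``K = 0`` with a background gives the background-only NNLS fit. Output
    signature rows are renormalized to sum 1 with alpha rescaled so the
    product alpha beta is unchanged; rows driven entirely to zero by the
    penalty are kept as structural zeros (``effective_k`` counts survivors).
    """
    M = _as_array(M)
    n, m = M.shape
    if K < 0:
        raise ValueError("K must be >= 0")
    if K == 0 and beta0 is None:
        raise ValueError("K = 0 requires a fixed background signature")
    if not 0.0 <= lambda_fraction <= 1.0:
        raise ValueError("lambda_fraction must lie in [0, 1]")

    b0 = _beta0_vec(beta0)
    bg = (
        beta0 if isinstance(beta0, BackgroundSignature) or beta0 is None
        else BackgroundSignature(np.asarray(beta0, float) / np.asarray(beta0, float).sum())
    )

    if K == 0:
        exposures = update_exposures(M, bg, np.zeros((0, m)), solver=solver)
        rec = np.outer(exposures.alpha0, b0)
        mse = float(((M - rec) ** 2).mean())
        obj = float(((M - rec) ** 2).sum())
        return DecompositionResult(
            background=bg, signatures=np.zeros((0, m)), exposures=exposures,
            lambda_fraction=lambda_fraction, lambda_max_=0.0,
            objective_trace=[obj], mse=mse, effective_k=0,
        )

    beta = (
        np.array(beta_init, dtype=float)
        if beta_init is not None
        else initialize_signatures(M, K, restarts=restarts, seed=seed)
    )
    if beta.shape != (K, m):
        raise ValueError(f"beta_init must be {K} x {m}, got {beta.shape}")

    exposures = update_exposures(M, bg, beta, solver=solver, tol=CD_TOL)
    lam_max = lambda_max(M, bg, exposures)
    penalty = lambda_fraction * lam_max

    def residual_bg() -> np.ndarray:
        return M if b0 is None else M - np.outer(exposures.alpha0, b0)

    def objective(b: np.ndarray) -> float:
        rec = exposures.alpha @ b
        if b0 is not None:
            rec = rec + np.outer(exposures.alpha0, b0)
        return float(((M - rec) ** 2).sum() + penalty * b.sum())

    trace = [objective(beta)]
    for it in range(iterations):
        if it > 0:
            exposures = update_exposures(
                M, bg, beta, solver=solver, warm_start=exposures, tol=CD_TOL
            )
            trace.append(objective(beta))
        beta = _solve_beta(residual_bg(), exposures.alpha, beta, penalty, tol=CD_TOL)
        trace.append(objective(beta))
        if tol > 0 and len(trace) >= 3:
            prev, cur = trace[-3], trace[-1]
            if prev - cur <= tol * max(1.0, abs(cur)):
                break

    # output scale convention: signature rows sum to 1, alpha absorbs scale
    row_sums = beta.sum(axis=1)
    beta_out = np.zeros_like(beta)
    nz = row_sums > 0
    beta_out[nz] = beta[nz] / row_sums[nz, None]
    alpha_out = exposures.alpha * row_sums[None, :]
    exposures_out = ExposureSet(alpha0=exposures.alpha0, alpha=alpha_out)

    rec = alpha_out @ beta_out
    if b0 is not None:
        rec = rec + np.outer(exposures_out.alpha0, b0)
    mse = float(((M - rec) ** 2).mean())
    return DecompositionResult(
        background=bg, signatures=beta_out, exposures=exposures_out,
        lambda_fraction=lambda_fraction, lambda_max_=lam_max,
        objective_trace=trace, mse=mse, effective_k=int(nz.sum()),
    )
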