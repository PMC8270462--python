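"""Benchmark metrics for signature recovery and fit quality.

Recovery of known (simulated) signatures is scored by matching each true
signature to a discovered one and reporting per-pair cosine similarity and
exposure mean squared error. Fit quality on any dataset is summarized by
reconstruction MSE, explained variance, signature-matrix sparsity at a
threshold, cross-signature similarity (mean pairwise cosine among the
discovered signatures), background contamination (mean cosine between the
background and each discovered signature), and the per-patient Pearson
correlation between observed and reconstructed 96-spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .factorization import DecompositionResult, _as_array


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Scale-invariant cosine similarity of two non-negative spectra."""
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(u @ v / (nu * nv))


@dataclass
class MatchReport:
    """Pairing of true signatures to discovered ones."""

    pairs: list[tuple[int, int, float]]  # (true index, estimated index, cosine)
    method: str = "per_true_best"

    @property
    def cosines(self) -> np.ndarray:
        return np.array([c for _, _, c in self.pairs])


def _cosine_matrix(true_beta: np.ndarray, est_beta: np.ndarray) -> np.ndarray:
    t = np.atleast_2d(np.asarray(true_beta, float))
    e = np.atleast_2d(np.asarray(est_beta, float))
    tn = np.linalg.norm(t, axis=1, keepdims=True)
    en = np.linalg.norm(e, axis=1, keepdims=True)
    tn[tn == 0] = 1.0
    en[en == 0] = 1.0
    return (t / tn) @ (e / en).T


def match_signatures(
    true_beta: np.ndarray, est_beta: np.ndarray, method: str = "per_true_best"
) -> MatchReport:
    """Match true to discovered signatures (background rows excluded by caller).

    ``per_true_best`` pairs each true signature with its highest-cosine
    estimate, allowing one estimate to serve several true signatures — the
    convention of the published benchmark. ``one_to_one`` solves the
    maximum-total-cosine assignment instead (distinct estimates).
    """
    t = np.atleast_2d(np.asarray(true_beta, float))
    e = np.atleast_2d(np.asarray(est_beta, float))
    if t.size == 0 or e.size == 0:
        raise ValueError("cannot match empty signature matrices")
    cos = _cosine_matrix(t, e)
    if method == "per_true_best":
        pairs = [
            (i, int(cos[i].argmax()), float(cos[i].max())) for i in range(t.shape[0])
        ]
    elif method == "one_to_one":
        if e.shape[0] < t.shape[0]:
            raise ValueError(
                "one_to_one matching needs at least as many estimates as truths"
            )
        rows, cols = linear_sum_assignment(cos, maximize=True)
        pairs = [(int(i), int(j), float(cos[i, j])) for i, j in zip(rows, cols)]
    else:
        raise ValueError(f"unknown matching method {method!r}")
    return MatchReport(pairs=pairs, method=method)


def exposure_error(
    true_alpha: np.ndarray, est_alpha: np.ndarray, report: MatchReport
) -> np.ndarray:
    """Per-matched-pair mean (over samples) squared exposure difference.

    Exposures are compared on the count scale: entry p is
    ``mean_i (true_alpha[i, t_p] - est_alpha[i, e_p])^2`` for matched pair
    p = (t_p, e_p).
    """
    true_alpha = np.atleast_2d(np.asarray(true_alpha, float))
    est_alpha = np.atleast_2d(np.asarray(est_alpha, float))
    if true_alpha.shape[0] != est_alpha.shape[0]:
        raise ValueError("true and estimated exposures differ in sample count")
    return np.array([
        float(((true_alpha[:, i] - est_alpha[:, j]) ** 2).mean())
        for i, j, _ in report.pairs
    ])


def sparsity(beta: np.ndarray, threshold: float) -> float:
    """Fraction of signature-matrix entries below ``threshold``.

    The benchmark uses 1e-3 on simulated data and 1e-4 on real-data
    tables; the threshold is always explicit. Background rows should be
    excluded by the caller when that is the convention wanted.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    beta = np.atleast_2d(np.asarray(beta, float))
    if beta.size == 0:
        raise ValueError("empty signature matrix")
    return float((beta < threshold).mean())


@dataclass
class FitDiagnostics:
    mse: float
    explained_variance: float
    sparsity: float
    cross_signature_similarity: float  # NaN when fewer than 2 signatures
    background_contamination: float    # NaN without a background
    per_patient_correlation: np.ndarray  # NaN where undefined

    def summary(self) -> dict:
        med = (
            float(np.nanmedian(self.per_patient_correlation))
            if np.isfinite(self.per_patient_correlation).any() else float("nan")
        )
        return {
            "mse": self.mse,
            "explained_variance": self.explained_variance,
            "sparsity": self.sparsity,
            "cross_signature_similarity": self.cross_signature_similarity,
            "background_contamination": self.background_contamination,
            "median_per_patient_correlation": med,
        }


def fit_diagnostics(
    M,
    result: DecompositionResult,
    sparsity_threshold: float = 1e-3,
    include_background_in_sparsity: bool = False,
) -> FitDiagnostics:
    """All fit-quality diagnostics of one decomposition on its data."""
    M = _as_array(M)
    rec = result.reconstruction()
    resid = float(((M - rec) ** 2).sum())
    total = float((M ** 2).sum())
    beta = result.signatures

    if include_background_in_sparsity and result.background is not None:
        sp_matrix = np.vstack([result.background.probs, beta]) if beta.size else result.background.probs[None]
    else:
        sp_matrix = beta
    sp = sparsity(sp_matrix, sparsity_threshold) if sp_matrix.size else float("nan")

    k = beta.shape[0]
    if k >= 2:
        cos = _cosine_matrix(beta, beta)
        iu = np.triu_indices(k, 1)
        cross = float(cos[iu].mean())
    else:
        cross = float("nan")

    if result.background is not None and k >= 1:
        contamination = float(np.mean([
            cosine_similarity(result.background.probs, beta[i])
            for i in range(k) if beta[i].any()
        ])) if any(beta[i].any() for i in range(k)) else float("nan")
    else:
        contamination = float("nan")

    corr = np.full(M.shape[0], np.nan)
    for i in range(M.shape[0]):
        obs, pred = M[i], rec[i]
        if np.ptp(obs) == 0 or np.ptp(pred) == 0:
            continue  # correlation undefined for a constant spectrum
        corr[i] = pearsonr(obs, pred).statistic
    return FitDiagnostics(
        mse=float(((M - rec) ** 2).mean()),
        explained_variance=1.0 - (resid / total if total > 0 else np.nan),
        sparsity=sp,
        cross_signature_similarity=cross,
        background_contamination=contamination,
        per_patient_correlation=corr,
    )


def rare_signature_summary(
    reports: list[MatchReport],
    presence_fractions: list[np.ndarray],
    mutation_totals: list[np.ndarray] | None = None,
    presence_bins: tuple[float, ...] = (0.0, 0.35, 0.7, 1.0),
    total_bins: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Median recovery cosine stratified by how rare each true signature is.

    ``presence_fractions[d][t]`` is the fraction of samples in dataset d
    exposed to true signature t, and ``mutation_totals[d][t]`` (optional)
    its total contributed mutations. Strata with no member are reported
    with a NaN median and zero count.
    """
    if len(reports) != len(presence_fractions):
        raise ValueError("one presence-fraction vector per report is required")
    rows = []
    for d, rep in enumerate(reports):
        pf = np.asarray(presence_fractions[d], float)
        totals = (
            np.asarray(mutation_totals[d], float) if mutation_totals is not None else None
        )
        for t, _, cos in rep.pairs:
            rows.append({
                "dataset": d,
                "true_signature": t,
                "cosine": cos,
                "presence_fraction": pf[t],
                "mutation_total": totals[t] if totals is not None else np.nan,
            })
    table = pd.DataFrame(rows)
    table["presence_bin"] = pd.cut(table["presence_fraction"], presence_bins)
    group_keys = ["presence_bin"]
    if total_bins is not None:
        table["total_bin"] = pd.cut(table["mutation_total"], total_bins)
        group_keys.append("total_bin")
    out = (
        table.groupby(group_keys, observed=False)["cosine"]
        .agg(median_cosine="median", n="count")
        .reset_index()
    )
    return out
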