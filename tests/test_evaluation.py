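"""Recovery and fit-quality metrics."""

import itertools

import numpy as np
import pytest

from sparsesig import (
    cosine_similarity,
    exposure_error,
    fit,
    fit_diagnostics,
    load_preset,
    match_signatures,
    rare_signature_summary,
    sparsity,
)
from sparsesig.evaluation import MatchReport
from sparsesig.factorization import DecompositionResult, ExposureSet

from conftest import random_signatures


class TestCosine:
    def test_self_similarity_is_one(self, rng):
        v = rng.random(96)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        u, v = np.zeros(96), np.zeros(96)
        u[:48], v[48:] = 1.0, 1.0
        assert cosine_similarity(u, v) == 0.0

    def test_hand_computed_value(self):
        u = np.zeros(96); u[:3] = [1, 2, 2]
        v = np.zeros(96); v[:3] = [2, 1, 2]
        assert cosine_similarity(u, v) == pytest.approx(8 / 9)

    def test_scale_invariance(self, rng):
        u, v = rng.random(96), rng.random(96)
        assert cosine_similarity(3 * u, v) == pytest.approx(cosine_similarity(u, 7 * v))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity(np.zeros(96), np.ones(96))


class TestMatchSignatures:
    def test_permutation_recovered_with_unit_cosines(self, rng):
        beta = random_signatures(rng, 4)
        perm = [2, 0, 3, 1]
        report = match_signatures(beta, beta[perm])
        assert [j for _, j, _ in report.pairs] == [1, 3, 0, 2]
        np.testing.assert_allclose(report.cosines, 1.0)

    def test_per_true_best_allows_repeats(self, rng):
        truths = random_signatures(rng, 2)
        blended = (truths[0] + truths[1]) / 2
        est = np.vstack([blended, np.roll(truths[0], 48)])
        report = match_signatures(truths, est, method="per_true_best")
        assert [j for _, j, _ in report.pairs] == [0, 0]

    def test_one_to_one_matches_brute_force(self, rng):
        for _ in range(5):
            t = rng.random((3, 96))
            e = rng.random((3, 96))
            report = match_signatures(t, e, method="one_to_one")
            total = sum(c for _, _, c in report.pairs)
            best = max(
                sum(cosine_similarity(t[i], e[p[i]]) for i in range(3))
                for p in itertools.permutations(range(3))
            )
            assert total == pytest.approx(best)
            assert len({j for _, j, _ in report.pairs}) == 3

    def test_empty_matrices_error(self):
        with pytest.raises(ValueError, match="empty"):
            match_signatures(np.zeros((0, 96)), np.ones((1, 96)))


class TestExposureError:
    def _identity_report(self, k):
        return MatchReport(pairs=[(i, i, 1.0) for i in range(k)])

    def test_exact_estimate_gives_zero(self, rng):
        alpha = rng.random((5, 3))
        err = exposure_error(alpha, alpha, self._identity_report(3))
        np.testing.assert_allclose(err, 0.0)

    def test_constant_shift_gives_squared_shift(self, rng):
        alpha = rng.random((5, 2))
        err = exposure_error(alpha, alpha + 7.0, self._identity_report(2))
        np.testing.assert_allclose(err, 49.0, rtol=1e-12)

    def test_matches_direct_formula(self, rng):
        t = rng.random((5, 3))
        e = rng.random((5, 3))
        report = MatchReport(pairs=[(0, 2, 0.9), (1, 0, 0.8), (2, 1, 0.7)])
        err = exposure_error(t, e, report)
        for p, (i, j, _) in enumerate(report.pairs):
            assert err[p] == pytest.approx(((t[:, i] - e[:, j]) ** 2).mean())

    def test_sample_count_mismatch_errors(self, rng):
        with pytest.raises(ValueError, match="sample"):
            exposure_error(np.ones((4, 2)), np.ones((5, 2)), self._identity_report(2))


class TestSparsity:
    def test_all_zero_matrix_is_fully_sparse(self):
        assert sparsity(np.zeros((4, 96)), 1e-3) == 1.0

    def test_identity_like_count(self):
        beta = np.zeros((4, 96))
        beta[np.arange(4), np.arange(4)] = 0.5
        assert sparsity(beta, 1e-3) == pytest.approx((384 - 4) / 384)

    def test_monotone_in_threshold(self, rng):
        beta = rng.random((3, 96)) * 1e-2
        assert sparsity(beta, 1e-4) <= sparsity(beta, 1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="threshold"):
            sparsity(np.ones((1, 96)), 0.0)
        with pytest.raises(ValueError, match="empty"):
            sparsity(np.zeros((0, 96)), 1e-3)


class TestFitDiagnostics:
    def test_exact_reconstruction_limits(self, rng, germline):
        """Perfect fit: explained variance 1 and unit per-patient correlation."""
        beta = random_signatures(rng, 2)
        alpha = rng.uniform(100, 1000, size=(6, 2))
        alpha0 = rng.uniform(100, 1000, size=6)
        M = alpha @ beta + np.outer(alpha0, germline.probs)
        result = DecompositionResult(
            background=germline, signatures=beta,
            exposures=ExposureSet(alpha0=alpha0, alpha=alpha),
            lambda_fraction=0.0, lambda_max_=0.0,
        )
        diag = fit_diagnostics(M, result)
        assert diag.explained_variance == pytest.approx(1.0, abs=1e-12)
        assert diag.mse == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(diag.per_patient_correlation, 1.0, atol=1e-9)

    def test_single_signature_has_no_cross_similarity(self, rng, germline):
        beta = random_signatures(rng, 1)
        result = DecompositionResult(
            background=germline, signatures=beta,
            exposures=ExposureSet(alpha0=np.ones(3), alpha=np.ones((3, 1))),
            lambda_fraction=0.0, lambda_max_=0.0,
        )
        diag = fit_diagnostics(np.ones((3, 96)), result)
        assert np.isnan(diag.cross_signature_similarity)

    def test_two_signature_cross_similarity_is_pairwise_cosine(self, rng, germline):
        beta = random_signatures(rng, 2)
        result = DecompositionResult(
            background=germline, signatures=beta,
            exposures=ExposureSet(alpha0=np.ones(3), alpha=np.ones((3, 2))),
            lambda_fraction=0.0, lambda_max_=0.0,
        )
        diag = fit_diagnostics(np.ones((3, 96)), result)
        assert diag.cross_signature_similarity == pytest.approx(
            cosine_similarity(beta[0], beta[1])
        )

    def test_diagnostics_on_real_fit_are_sane(self, rng, germline):
        beta = random_signatures(rng, 2)
        alpha = rng.uniform(500, 3000, size=(12, 2)) * (rng.random((12, 2)) < 0.7)
        alpha0 = rng.uniform(1000, 5000, size=12)
        M = rng.poisson(alpha @ beta + np.outer(alpha0, germline.probs)).astype(float)
        res = fit(M, germline, 2, 0.05, seed=0)
        diag = fit_diagnostics(M, res, sparsity_threshold=1e-3)
        assert 0.9 < diag.explained_variance <= 1.0
        assert 0.0 <= diag.sparsity <= 1.0
        assert diag.background_contamination < 0.5
        assert np.nanmedian(diag.per_patient_correlation) > 0.9


class TestRareSignatureSummary:
    def test_unit_cosines_everywhere(self):
        reports = [MatchReport(pairs=[(0, 0, 1.0), (1, 1, 1.0)]) for _ in range(3)]
        presence = [np.array([0.2, 0.9])] * 3
        table = rare_signature_summary(reports, presence)
        filled = table.dropna(subset=["median_cosine"])
        assert np.allclose(filled["median_cosine"], 1.0)

    def test_known_median_in_single_bin(self):
        reports = [MatchReport(pairs=[(0, 0, c)]) for c in (0.9, 0.95, 1.0)]
        presence = [np.array([0.3])] * 3
        table = rare_signature_summary(reports, presence)
        row = table[table["n"] > 0].iloc[0]
        assert row["median_cosine"] == pytest.approx(0.95)
        assert row["n"] == 3

    def test_matches_brute_force_group_by(self, rng):
        reports, presence = [], []
        for _ in range(10):
            cos = rng.uniform(0.8, 1.0, size=3)
            reports.append(MatchReport(pairs=[(i, i, c) for i, c in enumerate(cos)]))
            presence.append(rng.uniform(0.05, 1.0, size=3))
        bins = (0.0, 0.35, 0.7, 1.0)
        table = rare_signature_summary(reports, presence, presence_bins=bins)
        # independent group-by
        values = {i: [] for i in range(len(bins) - 1)}
        for rep, pf in zip(reports, presence):
            for t, _, c in rep.pairs:
                b = int(np.digitize(pf[t], bins, right=True)) - 1
                values[b].append(c)
        for i in range(len(bins) - 1):
            row = table.iloc[i]
            if values[i]:
                assert row["median_cosine"] == pytest.approx(np.median(values[i]))
                assert row["n"] == len(values[i])
            else:
                assert row["n"] == 0
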