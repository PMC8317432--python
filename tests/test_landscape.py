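"""Distances, collinearity pruning, Mantel, MMRR, commonality."""

import numpy as np
import pandas as pd
import pytest

import tetrapop as tp
from tetrapop.landscape import (
    commonality_two,
    environmental_distance,
    geographic_distance,
    haversine_km,
    linearize_fst,
    lower_triangle,
    mantel,
    mmrr,
    partial_mantel,
    prune_collinear,
)


def _random_distance_matrix(rng, n):
    """Symmetric zero-diagonal matrix with iid normal off-diagonals."""
    M = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    M[iu] = rng.normal(size=len(iu[0]))
    return M + M.T


def _pops_frame(lat, lon):
    return pd.DataFrame(
        {"locality": [f"L{i}" for i in range(len(lat))],
         "region": "r", "lat": lat, "lon": lon}
    )


class TestGeographicDistance:
    def test_one_degree_longitude_at_equator(self):
        d = haversine_km(0.0, 0.0, 0.0, 1.0)
        assert d == pytest.approx(111.19, abs=0.1)

    def test_log_transform_and_zero_rejection(self):
        pops = _pops_frame([0.0, 0.0], [0.0, 1.0])
        D = geographic_distance(pops, log_transform=True)
        assert D.iloc[0, 1] == pytest.approx(np.log(111.19), abs=0.01)
        dup = _pops_frame([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            geographic_distance(dup, log_transform=True)
        assert geographic_distance(dup, log_transform=False).iloc[0, 1] == 0.0

    def test_triangle_inequality_raw_km(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            lat = rng.uniform(-60, 60, 3)
            lon = rng.uniform(-170, 170, 3)
            D = geographic_distance(_pops_frame(lat, lon), log_transform=False).to_numpy()
            assert D[0, 1] <= D[0, 2] + D[2, 1] + 1e-6


class TestPruneCollinear:
    def test_duplicate_covariate_reduced_to_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=20)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=20)})
        kept = prune_collinear(table, 0.9)
        assert "c" in kept and len(kept) == 2

    def test_no_violation_identity(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        assert prune_collinear(table, 0.9) == list("abcde")

    def test_postcondition_no_retained_pair_exceeds_cutoff(self):
        rng = np.random.default_rng(4)
        for rep in range(20):
            base = rng.normal(size=(15, 4))
            mix = rng.normal(size=(4, 19))
            table = pd.DataFrame(
                base @ mix + 0.3 * rng.normal(size=(15, 19)),
                columns=[f"v{k:02d}" for k in range(19)],
            )
            kept = prune_collinear(table, 0.9)
            corr = table[kept].corr().abs().to_numpy()
            np.fill_diagonal(corr, 0.0)
            assert corr.max() <= 0.9 + 1e-12

    def test_constant_covariate_removed(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0]})
        assert prune_collinear(table) == ["b"]


class TestEnvironmentalDistance:
    def test_hand_computed_two_localities(self):
        cov = pd.DataFrame({"x": [0.0, 3.0]}, index=["a", "b"])
        D = environmental_distance(cov)
        assert D.iloc[0, 1] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_identical_rows_zero(self):
        cov = pd.DataFrame({"x": [1.0, 1.0, 2.0], "y": [0.0, 0.0, 1.0]})
        D = environmental_distance(cov)
        assert D.iloc[0, 1] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        cov = pd.DataFrame(rng.normal(size=(8, 2)), columns=["x", "y"])
        D1 = environmental_distance(cov)
        cov2 = cov.copy()
        cov2["x"] *= 10
        D2 = environmental_distance(cov2)
        np.testing.assert_allclose(D1.to_numpy(), D2.to_numpy(), atol=1e-12)


class TestMantel:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(6)
        A = _random_distance_matrix(rng, 10)
        r, p = mantel(A, A, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(7)
        A = _random_distance_matrix(rng, 10)
        B = -A + 5 - 5 * np.eye(10)
        r, _ = mantel(A, B, n_perm=99, seed=1)
        assert r == pytest.approx(-1.0)

    def test_type_one_error_calibrated(self):
        """Rejection rate at alpha = 0.05 over 1,000 null replicates."""
        rng = np.random.default_rng(8)
        rejections = 0
        for rep in range(1000):
            A = _random_distance_matrix(rng, 12)
            B = _random_distance_matrix(rng, 12)
            _, p = mantel(A, B, n_perm=99, seed=rep)
            rejections += p <= 0.05
        assert 0.035 <= rejections / 1000 <= 0.065

    def test_constant_matrix_rejected(self):
        A = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError):
            mantel(A, A, n_perm=9, seed=0)


class TestPartialMantel:
    def test_full_control_gives_zero(self):
        rng = np.random.default_rng(9)
        A = _random_distance_matrix(rng, 12)
        B = _random_distance_matrix(rng, 12)
        r, _ = partial_mantel(A, B, A, n_perm=99, seed=2)
        assert abs(r) < 1e-9

    def test_uncorrelated_control_matches_simple(self):
        rng = np.random.default_rng(10)
        rs, rp = [], []
        for rep in range(30):
            A = _random_distance_matrix(rng, 14)
            B = A + 0.5 * _random_distance_matrix(rng, 14)
            C = _random_distance_matrix(rng, 14)
            rs.append(mantel(A, B, n_perm=9, seed=rep)[0])
            rp.append(partial_mantel(A, B, C, n_perm=9, seed=rep)[0])
        assert abs(np.mean(rs) - np.mean(rp)) < 0.02

    def test_degenerate_residual_rejected(self):
        rng = np.random.default_rng(11)
        B = _random_distance_matrix(rng, 10)
        A = _random_distance_matrix(rng, 10)
        with pytest.raises(ValueError):
            partial_mantel(A, B, B, n_perm=9, seed=0)


class TestMmrr:
    def test_exact_linear_construction(self):
        rng = np.random.default_rng(12)
        X1 = _random_distance_matrix(rng, 12)
        X2 = _random_distance_matrix(rng, 12)
        Y = 2.0 * X1
        res = mmrr(Y, [X1, X2], n_perm=99, seed=3, names=["a", "b"])
        assert res.betas[1] == pytest.approx(2.0, abs=1e-9)
        assert res.r_squared > 0.99
        assert res.beta_pvalues[0] <= 0.05

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_reps = 1000
        for rep in range(n_reps):
            Y = _random_distance_matrix(rng, 10)
            X1 = _random_distance_matrix(rng, 10)
            X2 = _random_distance_matrix(rng, 10)
            res = mmrr(Y, [X1, X2], n_perm=99, seed=rep)
            rejections += res.model_pvalue <= 0.05
        assert 0.035 <= rejections / n_reps <= 0.065

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(14)
        X1 = _random_distance_matrix(rng, 10)
        with pytest.raises(ValueError, match="prune"):
            mmrr(_random_distance_matrix(rng, 10), [X1, 2 * X1], n_perm=9, seed=0)

    def test_null_environment_rarely_significant(self):
        """IBD-only genetic distances rarely flag a selectively neutral
        environmental predictor.

        The covariate here is spatially unstructured, isolating the null
        from geography/environment collinearity.  The rejection rate sits
        somewhat above the nominal 5% (~9.5% over 200 pilot replicates)
        because permuting the response ignores its spatial
        autocorrelation; the test bounds it below 17%.
        """
        hits = 0
        for rep in range(100):
            pops = tp.simulate_landscape(10, 500, 1, seed=600 + rep)
            truth = tp.simulate_allele_frequencies(pops, 600, seed=700 + rep)
            rng = np.random.default_rng(800 + rep)
            dosage = rng.binomial(4, truth.freq[:, np.repeat(np.arange(10), 8)].T)
            from .conftest import genotypes_from_dosage

            g = genotypes_from_dosage(dosage)
            memb = pd.Series(
                np.repeat(pops.locality_ids, 8), index=g.individual_ids
            )
            gen = linearize_fst(tp.pairwise_fst(g, memb))
            geo = geographic_distance(pops)
            cov = pd.DataFrame({"X": rng.normal(size=10)}, index=pops.locality_ids)
            env = environmental_distance(cov)
            res = mmrr(gen, [geo, env], n_perm=99, seed=rep, names=["GEO", "ENV"])
            hits += res.beta_pvalues[1] <= 0.05
        assert hits <= 16


class TestCommonality:
    def test_orthogonal_noise_predictor(self):
        rng = np.random.default_rng(15)
        X1 = _random_distance_matrix(rng, 20)
        Y = X1 * 1.5
        X2 = _random_distance_matrix(rng, 20)
        res = commonality_two(Y, X1, X2)
        assert res.unique["GEO"] == pytest.approx(res.r_squared, abs=0.02)
        assert abs(res.common) < 0.02

    def test_identical_predictors_all_common(self):
        rng = np.random.default_rng(16)
        X = _random_distance_matrix(rng, 12)
        Y = X + 0.2 * _random_distance_matrix(rng, 12)
        res = commonality_two(Y, X, X)
        assert res.unique["GEO"] == pytest.approx(0.0, abs=1e-9)
        assert res.common == pytest.approx(res.r_squared, abs=1e-9)

    def test_identity_against_independent_refits(self):
        rng = np.random.default_rng(17)
        for rep in range(20):
            Y = _random_distance_matrix(rng, 10)
            X1 = _random_distance_matrix(rng, 10)
            X2 = 0.5 * X1 + _random_distance_matrix(rng, 10)
            res = commonality_two(Y, X1, X2)
            # independent refits of the three sub-models
            y, x1, x2 = (lower_triangle(M) for M in (Y, X1, X2))

            def r2(*cols):
                X = np.column_stack([np.ones(len(y)), *cols])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
                return 1 - resid @ resid / ((y - y.mean()) ** 2).sum()

            full, r1, r2_ = r2(x1, x2), r2(x1), r2(x2)
            assert res.r_squared == pytest.approx(full, abs=1e-9)
            assert res.unique["GEO"] == pytest.approx(full - r2_, abs=1e-9)
            assert res.unique["ENV"] == pytest.approx(full - r1, abs=1e-9)
            total = res.unique["GEO"] + res.unique["ENV"] + res.common
            assert total == pytest.approx(res.r_squared, abs=1e-9)
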