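"""Polysomic diversity statistics, F_ST, private alleles, aggregation."""

import numpy as np
import pandas as pd
import pytest

import tetrapop as tp
from tetrapop.datasets import example_diversity_table
from tetrapop.diversity import (
    diversity_table,
    gene_diversity_site,
    pairwise_fst,
    pop_allele_freq,
    private_alleles,
    region_summary,
)

from .conftest import genotypes_from_dosage


def _membership(genotypes, groups):
    """Assign individuals to groups by equal consecutive blocks."""
    n = len(genotypes.individual_ids)
    per = n // len(groups)
    return pd.Series(
        np.repeat(groups, per)[:n], index=genotypes.individual_ids
    )


class TestAlleleFreq:
    def test_hand_computed_frequency(self):
        g = genotypes_from_dosage(np.array([[1], [3]]))
        q, m, labels = pop_allele_freq(g, _membership(g, ["A"]))
        assert q.iloc[0, 0] == pytest.approx(0.5)
        assert m.iloc[0, 0] == 8

    def test_missing_locality_cell(self):
        g = genotypes_from_dosage(np.array([[1], [3]]))
        g.dosage[:, 0] = tp.MISSING
        g.dosage = np.hstack([g.dosage, np.array([[2], [2]])])
        g.posterior_max = np.ones_like(g.dosage, dtype=float)
        g.site_ids = ["site1", "site2"]
        q, m, _ = pop_allele_freq(g, _membership(g, ["A"]))
        assert np.isnan(q.iloc[0, 0]) and q.iloc[0, 1] == 0.5

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 5, size=(30, 40))
        g = genotypes_from_dosage(dosage)
        memb = _membership(g, ["A", "B", "C"])
        q, m, labels = pop_allele_freq(g, memb)
        for lab in labels:
            rows = np.flatnonzero((memb == lab).to_numpy())
            np.testing.assert_allclose(
                q.loc[lab].to_numpy(), dosage[rows].sum(axis=0) / (4 * len(rows))
            )


class TestGeneDiversity:
    def test_unbiased_formula(self):
        assert gene_diversity_site(0.5, 8) == pytest.approx(8 / 7 * 0.5)

    def test_monomorphic_and_limit(self):
        assert gene_diversity_site(0.0, 8) == 0.0
        assert gene_diversity_site(0.5, 1e9) == pytest.approx(0.5, abs=1e-8)

    def test_small_m_is_nan(self):
        assert np.isnan(gene_diversity_site(0.5, 1))


class TestDiversityTable:
    def test_pi_hand_computation(self):
        # one SNP, Hs = (8/7)*2*0.5*0.5 over 94 bp
        g = genotypes_from_dosage(np.array([[1], [3]]))
        div = diversity_table(g, _membership(g, ["A"]), total_callable_bp=94)
        assert div.loc["A", "pi"] == pytest.approx((8 / 7 * 0.5) / 94)

    def test_within_individual_heterozygosity_values(self):
        g = genotypes_from_dosage(np.array([[2], [0], [4]]))
        div = diversity_table(g, _membership(g, ["A"]))
        assert div.loc["A", "ho"] == pytest.approx((2 / 3 + 0 + 0) / 3)

    def test_consistency_identity_pi_vs_he(self, tet_dataset):
        truth, _, genotypes, _ = tet_dataset
        keep = genotypes.complete_case_sites()
        g = genotypes_from_dosage(genotypes.dosage[:, keep])
        memb = truth.membership.copy()
        memb.index = g.individual_ids
        bp = 94 * int(keep.sum())
        div = diversity_table(g, memb, total_callable_bp=bp)
        # sum of site Hs / bp equals mean Hs * n_snps / bp exactly
        np.testing.assert_allclose(
            div["pi"] * bp / keep.sum(), div["he"], rtol=1e-12
        )

    def test_fis_near_zero_under_hwe(self):
        rng = np.random.default_rng(7)
        q = rng.uniform(0.05, 0.95, 5000)
        dosage = rng.binomial(4, q[None, :].repeat(150, axis=0))
        g = genotypes_from_dosage(dosage)
        div = diversity_table(g, _membership(g, ["A"]))
        assert abs(div.loc["A", "fis"]) < 0.02

    def test_truth_based_pi_recovery(self, tet_dataset):
        truth, _, genotypes, info = tet_dataset
        memb = truth.membership
        bp = 94 * len(genotypes.site_ids)
        div = diversity_table(genotypes, memb, total_callable_bp=bp)
        from .conftest import truth_site_indices

        cols = truth_site_indices(genotypes)
        for k, loc in enumerate(truth.pops.locality_ids[:4]):
            qt = truth.freq[cols, k]
            pi_true = (2 * qt * (1 - qt)).sum() / bp
            assert div.loc[loc, "pi"] == pytest.approx(pi_true, rel=0.07)


class TestPairwiseFst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(9)
        q = rng.uniform(0.2, 0.8, 3000)
        dosage = rng.binomial(4, q[None, :].repeat(120, axis=0))
        g = genotypes_from_dosage(dosage)
        F = pairwise_fst(g, _membership(g, ["A", "B"]))
        assert F.iloc[0, 1] < 0.005

    def test_fixed_difference_limit(self):
        dosage = np.vstack([np.zeros((40, 200)), np.full((40, 200), 4)]).astype(int)
        g = genotypes_from_dosage(dosage)
        F = pairwise_fst(g, _membership(g, ["A", "B"]))
        assert F.iloc[0, 1] > 0.97

    def test_matrix_structure(self, tet_dataset):
        truth, _, genotypes, _ = tet_dataset
        F = pairwise_fst(genotypes, truth.membership)
        A = F.to_numpy()
        np.testing.assert_allclose(A, A.T)
        assert (np.diag(A) == 0).all()
        assert (A >= 0).all() and (A <= 1).all()

    def test_matches_independent_per_site_oracle(self):
        rng = np.random.default_rng(11)
        dosage = rng.binomial(4, rng.uniform(0.1, 0.9, (60, 50)))
        g = genotypes_from_dosage(dosage)
        memb = _membership(g, ["A", "B"])
        F = pairwise_fst(g, memb)
        # brute-force recomputation, summing numerator/denominator per site
        ga, gb = dosage[:30], dosage[30:]
        num = den = 0.0
        for j in range(50):
            q1, q2 = ga[:, j].sum() / 120, gb[:, j].sum() / 120
            hs1 = 120 / 119 * 2 * q1 * (1 - q1)
            hs2 = 120 / 119 * 2 * q2 * (1 - q2)
            qb = (q1 + q2) / 2
            ht = 2 * qb * (1 - qb) + (hs1 / 120 + hs2 / 120) / 4
            num += ht - (hs1 + hs2) / 2
            den += ht
        assert F.iloc[0, 1] == pytest.approx(max(num / den, 0.0), abs=1e-12)

    def test_drift_increases_fst_and_decreases_he(self):
        means = {}
        for sd in (0.3, 0.8):
            pops = tp.simulate_landscape(6, 400, 1, seed=50)
            truth = tp.simulate_allele_frequencies(pops, 1500, base_sd=sd, seed=51)
            tp.draw_genotypes(truth, 10, seed=52)
            g = genotypes_from_dosage(truth.dosage)
            memb = truth.membership.copy()
            memb.index = g.individual_ids
            F = pairwise_fst(g, memb)
            div = diversity_table(g, memb)
            means[sd] = (F.to_numpy()[np.triu_indices(6, 1)].mean(), div.he.mean())
        assert means[0.8][0] > means[0.3][0]
        assert means[0.8][1] < means[0.3][1]


class TestPrivateAlleles:
    def test_correction_factor(self):
        # alt allele present only in group A at two sites; n = 9
        dosage = np.zeros((18, 2), dtype=int)
        dosage[0, 0] = 1
        dosage[1, 1] = 2
        g = genotypes_from_dosage(dosage)
        out = private_alleles(g, _membership(g, ["A", "B"]))
        assert out.loc["A", "raw"] == 2
        assert out.loc["A", "corrected"] == pytest.approx(2 * 10 / 9)

    def test_shared_allele_not_private(self):
        dosage = np.ones((10, 1), dtype=int)
        g = genotypes_from_dosage(dosage)
        out = private_alleles(g, _membership(g, ["A", "B"]))
        assert (out["raw"] == 0).all()

    def test_matches_brute_force_set_oracle(self):
        rng = np.random.default_rng(13)
        dosage = rng.binomial(4, 0.15, size=(24, 60))
        g = genotypes_from_dosage(dosage)
        memb = _membership(g, ["A", "B", "C"])
        out = private_alleles(g, memb)
        for lab in ("A", "B", "C"):
            rows = (memb == lab).to_numpy()
            expect = 0
            for j in range(60):
                for allele_present in (
                    lambda d: (d > 0).any(),
                    lambda d: (d < 4).any(),
                ):
                    mine = allele_present(dosage[rows, j])
                    others = allele_present(dosage[~rows, j])
                    expect += mine and not others
            assert out.loc[lab, "raw"] == expect


class TestRegionSummary:
    def test_reference_survey_aggregates(self):
        """Regional means recomputed from the bundled per-locality table."""
        table = example_diversity_table()
        at = table[table.species == "tinctoria"]
        he = region_summary(at["he"], at["region"])
        assert he.loc["Southern-Central", "mean"] == pytest.approx(0.0996, abs=5e-5)
        assert he.loc["Northern", "mean"] == pytest.approx(0.121, abs=5e-4)
        # printed SE 0.0037 was computed from unrounded cells; from the
        # printed cells it is 0.00375, agreeing to the last printed digit
        assert he.loc["Southern-Central", "se"] == pytest.approx(0.0037, abs=1e-4)
        pi = region_summary(at["pi"], at["region"])
        assert pi.loc["Southern-Central", "mean"] == pytest.approx(0.0069, abs=5e-5)

    def test_constant_vector_zero_se(self):
        vals = pd.Series([0.1, 0.1, 0.1], index=list("abc"))
        reg = pd.Series(["R", "R", "R"], index=list("abc"))
        out = region_summary(vals, reg)
        assert out.loc["R", "se"] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_region_missing_se(self):
        vals = pd.Series([0.1, 0.2], index=list("ab"))
        reg = pd.Series(["R", "S"], index=list("ab"))
        out = region_summary(vals, reg)
        assert np.isnan(out.loc["R", "se"])
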