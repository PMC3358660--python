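"""Deletion genotyping: spanning sets, likelihoods, and the population LRT."""

import numpy as np
import pytest
from scipy import stats

from alupoly.deletions import (
    SpanningSet,
    collect_spanning_set,
    genotype_deletion,
    population_lrt,
    scan_deletions,
)
from alupoly.insertmodel import InsertSizeModel
from alupoly.records import AlignmentTable, AluAnnotation, GenotypeLikelihoods


def _spanning(inserts, weights=None):
    t = np.asarray(inserts, dtype=float)
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)
    return SpanningSet("chr1:0-300", "S0", t, w, (0, 0))


def _table(pairs, L=100):
    pos1 = np.array([p[0] for p in pairs])
    pos2 = np.array([p[1] for p in pairs])
    n = len(pairs)
    return AlignmentTable(
        "chr1", L, pos1, pos2, np.zeros(n, bool), np.ones(n, bool),
        np.ones(n, int), np.ones(n, int),
    )


class TestCollect:
    LOCUS = AluAnnotation("chr1", 5000, 5300, "AluY", "AluYa5")

    def test_spanning_pair_included(self, gaussian_model):
        # both ends inside the window and the fragment spans the element
        table = _table([(4700, 5400)])
        s = collect_spanning_set(self.LOCUS, table, gaussian_model)
        assert s.n == 1 and s.inserts[0] == 5500 - 4700

    def test_one_ended_non_mate_ignored(self, gaussian_model):
        table = _table([(4700, -1)])
        table.pos2[:] = -1
        s = collect_spanning_set(self.LOCUS, table, gaussian_model)
        assert s.n == 0

    def test_flanking_pair_uninformative(self, gaussian_model):
        # both ends left of the element: says nothing about the genotype
        table = _table([(4300, 4600)])
        s = collect_spanning_set(self.LOCUS, table, gaussian_model)
        assert s.n == 0

    def test_empty_window(self, gaussian_model):
        table = _table([(100_000, 100_300)])
        s = collect_spanning_set(self.LOCUS, table, gaussian_model)
        assert s.n == 0

    def test_locus_outside_reference_rejected(self, gaussian_model):
        table = _table([(4700, 5400)])
        with pytest.raises(ValueError, match="outside"):
            collect_spanning_set(
                AluAnnotation("chr1", 5000, 5300, "AluY"),
                table, gaussian_model, ref_length=4000,
            )

    def test_alu_mate_realigned(self, gaussian_model):
        from alupoly.records import AluMate

        table = _table([(4700, 5400)])
        mate = AluMate("chr1", 4800, "l", "AluYa5", "AluY", offset=100,
                       individual="S0", insert_mean=300, insert_sd=50)
        s = collect_spanning_set(
            self.LOCUS, table, gaussian_model, alu_mates=[mate]
        )
        # realigned insert: (5000 + 100 + 100) - 4800 = 400
        assert s.n == 2 and 400.0 in s.inserts


class TestGenotype:
    @pytest.mark.parametrize(
        "inserts,expected_g",
        [([400.0], 0), ([700.0], 2), ([400.0, 700.0], 1)],
    )
    def test_calls_match_direct_computation(self, gaussian_model, inserts, expected_g):
        # oracle: recompute every factor with scipy pdfs
        g = genotype_deletion(_spanning(inserts), gaussian_model, 300)
        assert g.genotype == expected_g
        y = stats.norm.pdf(inserts, 400, 50)
        z = stats.norm.pdf(inserts, 700, 50)
        np.testing.assert_allclose(g.loglik[0], np.sum(np.log(y)), rtol=1e-6)
        np.testing.assert_allclose(
            g.loglik[1], np.sum(np.log(z / 3 + 2 * y / 3)), rtol=1e-6
        )
        np.testing.assert_allclose(g.loglik[2], np.sum(np.log(z)), rtol=1e-6)

    def test_single_pair_likelihood_values(self, gaussian_model):
        g = genotype_deletion(_spanning([400.0]), gaussian_model, 300)
        assert np.exp(g.loglik[0]) == pytest.approx(0.0079788, rel=1e-4)
        assert np.exp(g.loglik[1]) == pytest.approx(0.0053192, rel=1e-3)
        assert np.exp(g.loglik[2]) == pytest.approx(1.22e-10, rel=0.01)

    def test_empty_set_is_no_call(self, gaussian_model):
        g = genotype_deletion(_spanning([]), gaussian_model, 300)
        assert g.no_call and np.all(g.loglik == 0.0) and g.genotype == 0

    def test_positive_l_alu_required(self, gaussian_model):
        with pytest.raises(ValueError):
            genotype_deletion(_spanning([400.0]), gaussian_model, 0)

    def test_weights_scale_log_factors(self, gaussian_model):
        a = genotype_deletion(_spanning([500.0], [0.5]), gaussian_model, 300)
        b = genotype_deletion(_spanning([500.0], [1.0]), gaussian_model, 300)
        np.testing.assert_allclose(a.loglik, 0.5 * b.loglik)

    def test_monotonicity_appending_z_reads(self, gaussian_model, rng):
        # a read near mean(Y) + l_alu never decreases logP2 - logP0
        base = list(rng.normal(400, 50, 5))
        g0 = genotype_deletion(_spanning(base), gaussian_model, 300)
        g1 = genotype_deletion(_spanning(base + [700.0]), gaussian_model, 300)
        d0 = g0.loglik[2] - g0.loglik[0]
        d1 = g1.loglik[2] - g1.loglik[0]
        assert d1 >= d0


def _geno(logs, locus="L0", ind="S0"):
    ll = np.asarray(logs, dtype=float)
    return GenotypeLikelihoods(locus, ind, ll, int(np.argmax(ll)), 10)


class TestPopulationLRT:
    def test_null_attained_at_boundary(self):
        genos = [_geno([-1.0, -20.0, -40.0], ind=f"S{i}") for i in range(5)]
        call = population_lrt(genos)
        assert call.allele_freq == pytest.approx(0.0, abs=1e-4)
        assert call.statistic == pytest.approx(0.0, abs=1e-6)
        assert call.p_value == 1.0

    def test_boundary_optimum_closed_form(self):
        # P(D|0)=1e-10, P(D|2)=1e-2 -> p=1, stat = 2 ln(1e8)
        genos = [_geno(np.log([1e-10, 1e-6, 1e-2]))]
        call = population_lrt(genos)
        assert call.allele_freq == pytest.approx(1.0, abs=1e-4)
        assert call.statistic == pytest.approx(2 * np.log(1e8), rel=1e-4)
        assert call.df == 1

    def test_statistic_invariant_to_ordering(self, rng):
        genos = [
            _geno(np.sort(rng.normal(-15, 5, 3)), ind=f"S{i}") for i in range(8)
        ]
        a = population_lrt(genos)
        b = population_lrt(genos[::-1])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-6)
        assert a.statistic >= 0.0

    def test_two_df_form_fits_genotype_freqs(self):
        genos = [_geno(np.log([1e-8, 1e-2, 1e-8]), ind=f"S{i}") for i in range(6)]
        call = population_lrt(genos, hwe=False)
        assert call.df == 2
        f = call.genotype_freqs
        assert f is not None and f.sum() == pytest.approx(1.0)
        assert f[1] > 0.9  # all individuals look heterozygous

    def test_allele_frequency_recovery(self, gaussian_model, rng):
        # cohort of 40 at true p = 0.4: MLE within 3 binomial SE
        p_true = 0.4
        genos = []
        for i in range(40):
            g = rng.binomial(1, p_true) + rng.binomial(1, p_true)
            mean = {0: 400, 1: None, 2: 700}[g]
            if g == 1:
                t = np.concatenate(
                    [rng.normal(400, 50, 5), rng.normal(700, 50, 5)]
                )
            else:
                t = rng.normal(mean, 50, 10)
            genos.append(genotype_deletion(_spanning(t), gaussian_model, 300))
        call = population_lrt(genos)
        se = np.sqrt(p_true * (1 - p_true) / 80)
        assert abs(call.allele_freq - p_true) < 3 * se + 0.05

    def test_requires_individuals(self):
        with pytest.raises(ValueError):
            population_lrt([])


class TestScanDeletions:
    def test_empty_annotations(self, gaussian_model):
        assert scan_deletions([], [_table([(0, 300)])], gaussian_model) == []

    def test_reference_supporting_cohort_not_flagged(self, gaussian_model, rng):
        locus = AluAnnotation("chr1", 5000, 5300, "AluY")
        tables = []
        for i in range(4):
            # pairs with one end inside the element, Y-distributed inserts
            starts = rng.integers(4700, 4950, 12)
            tabs = _table([(int(s), int(s) + 300) for s in sorted(starts)])
            tabs.individual = f"S{i}"
            tables.append(tabs)
        calls = scan_deletions([locus], tables, gaussian_model)
        assert len(calls) == 1 and not calls[0].significant
        assert all(g.alu_copies == 2 for g in calls[0].genotypes)
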