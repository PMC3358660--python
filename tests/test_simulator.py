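"""Simulator: planting, read generation, population/trio construction."""

import numpy as np
import pytest
from scipy import stats

from alupoly.library import AluLibrary
from alupoly.mates import scan_alu_mates
from alupoly.simulate import (
    SimulationConfig,
    _HaploidLayout,
    build_population_and_trios,
    plant_alus,
    simulate_reads,
)


def _plant(config, seed=3):
    rng = np.random.default_rng(seed)
    library = AluLibrary.synthetic(rng, length=config.alu_length)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref = bases[rng.integers(0, 4, config.ref_length)]
    sites, seqs, carriers = plant_alus(ref, config, rng, library)
    return ref, library, sites, seqs, carriers


class TestPlanting:
    def test_default_design_counts_and_spacing(self):
        config = SimulationConfig(ref_length=2_000_000, n_haploids=100)
        _ref, _lib, sites, seqs, carriers = _plant(config)
        assert len(sites) == 50
        assert carriers.shape == (50, 100)
        model = config.insert_model()
        gaps = np.diff(sites["pos"].to_numpy())
        assert (gaps >= model.q_hi).all()
        # each consensus planted at 10 sites; each frequency used 5 times
        assert (sites.groupby("name").size() == 10).all()
        assert (sites.groupby("freq").size() == 5).all()

    def test_expected_alus_per_chromosome(self):
        # ladder expectation: 5 sites x sum(f)/100 = 24.95 per haploid
        config = SimulationConfig(ref_length=2_000_000, n_haploids=100)
        _ref, _lib, sites, _seqs, carriers = _plant(config, seed=5)
        per_hap = carriers.sum(axis=0)
        assert abs(per_hap.mean() - 24.95) < 1.5

    def test_mutation_rate_zero_keeps_consensus(self):
        config = SimulationConfig(
            ref_length=300_000, n_haploids=4, sites_per_consensus=2,
            mutation_rate=0.0,
        )
        _ref, lib, sites, seqs, _carriers = _plant(config)
        for row, seq in zip(sites.itertuples(), seqs):
            assert seq.tobytes().decode() == lib.sequence(row.name)

    def test_mutation_rate_applied(self):
        config = SimulationConfig(
            ref_length=300_000, n_haploids=4, sites_per_consensus=2,
            mutation_rate=0.03,
        )
        _ref, lib, sites, seqs, _carriers = _plant(config)
        diffs = [
            np.mean(
                seq != np.frombuffer(lib.sequence(row.name).encode(), np.uint8)
            )
            for row, seq in zip(sites.itertuples(), seqs)
        ]
        assert 0.005 < np.mean(diffs) < 0.07

    def test_full_frequency_everyone_carries(self):
        config = SimulationConfig(
            ref_length=300_000, n_haploids=6, sites_per_consensus=2,
            frequencies=(99.9999,),
        )
        _ref, _lib, _sites, _seqs, carriers = _plant(config)
        assert carriers.all()

    def test_too_short_reference_rejected(self):
        config = SimulationConfig(ref_length=10_000, n_haploids=2)
        with pytest.raises(ValueError, match="too short"):
            _plant(config)

    def test_carrier_counts_binomial(self):
        # chi-square goodness of fit of per-site carrier counts vs Binomial
        config = SimulationConfig(ref_length=2_000_000, n_haploids=100)
        _ref, _lib, sites, _seqs, carriers = _plant(config, seed=11)
        f = sites["freq"].to_numpy() / 100.0
        k = carriers.sum(axis=1)
        # normal approximation per site, combine as chi-square
        z = (k - 100 * f) / np.sqrt(100 * f * (1 - f))
        stat = float(np.sum(z**2))
        p = stats.chi2.sf(stat, len(f))
        assert p > 0.01


class TestReads:
    def _layout(self, config, seed=3):
        ref, lib, sites, seqs, carriers = _plant(config, seed)
        return _HaploidLayout(sites, seqs, carriers[:, 0], ref), lib

    def test_deterministic_pair_count(self):
        config = SimulationConfig(
            ref_length=200_000, n_haploids=2, sites_per_consensus=1
        )
        layout, lib = self._layout(config)
        ps = simulate_reads(layout, config, np.random.default_rng(0))
        expected = round(config.coverage * layout.length / (2 * config.read_len))
        assert len(ps.starts) == expected

    def test_error_free_reads_are_substrings(self):
        config = SimulationConfig(
            ref_length=200_000, n_haploids=2, sites_per_consensus=1,
            error_rate=0.0,
        )
        layout, _lib = self._layout(config)
        ps = simulate_reads(
            layout, config, np.random.default_rng(0), with_sequences=True
        )
        hap = layout.sequence().tobytes().decode()
        comp = str.maketrans("ACGT", "TGCA")
        for i in list(ps.seqs)[:200]:
            s1, s2 = ps.seqs[i]
            assert s1 in hap
            assert s2.translate(comp)[::-1] in hap

    def test_insert_mean_matches_model(self):
        config = SimulationConfig(
            ref_length=1_000_000, n_haploids=2, sites_per_consensus=1
        )
        layout, _lib = self._layout(config)
        ps = simulate_reads(layout, config, np.random.default_rng(0))
        assert len(ps.inserts) >= 10_000
        assert abs(ps.inserts.mean() - 400.0) < 1.5

    def test_alu_interior_reads_unmapped_on_alu_free_reference(self):
        config = SimulationConfig(
            ref_length=200_000, n_haploids=2, sites_per_consensus=1,
            frequencies=(99.9999,),
        )
        layout, _lib = self._layout(config)
        ps = simulate_reads(layout, config, np.random.default_rng(0))
        interior = ps.map1["interior"]
        assert interior.sum() > 0
        assert (ps.map1["pos_ref"][interior] == -1).all()
        assert (ps.map1["pos_all"][interior] >= 0).all()


class TestPopulation:
    def test_sequential_diploid_pairing(self, small_cohort):
        truth = small_cohort.truth
        assert truth.individuals["S00"] == (0, 1)
        assert truth.individuals["S01"] == (2, 3)
        assert len(small_cohort.individuals) == 5

    def test_odd_haploid_count_rejected(self):
        config = SimulationConfig(
            ref_length=200_000, n_haploids=3, sites_per_consensus=1
        )
        with pytest.raises(ValueError, match="even"):
            build_population_and_trios(config)

    def test_trio_transmission_exact(self, trio_cohort):
        truth = trio_cohort.truth
        for fa, mo, ch in truth.trios:
            hf, hm = truth.individuals[ch]
            assert hf in truth.individuals[fa]
            assert hm in truth.individuals[mo]
            # child carrier status equals the transmitted haplotypes
            np.testing.assert_array_equal(
                truth.carriers[:, hf] | truth.carriers[:, hm],
                truth.diploid_copies(ch) >= 1,
            )

    def test_seed_reproducibility(self):
        config = SimulationConfig(
            ref_length=200_000, n_haploids=4, sites_per_consensus=1, seed=9
        )
        a = build_population_and_trios(config)
        b = build_population_and_trios(config)
        np.testing.assert_array_equal(a.reference, b.reference)
        np.testing.assert_array_equal(a.truth.carriers, b.truth.carriers)
        ta, tb = a.tables_ref["S00"], b.tables_ref["S00"]
        np.testing.assert_array_equal(ta.pos1, tb.pos1)
        np.testing.assert_array_equal(ta.pos2, tb.pos2)
        assert ta.seqs == tb.seqs

    def test_scanner_round_trip(self, small_cohort):
        # every individual's table passes through the scanner cleanly
        model = small_cohort.insert_model()
        for name in small_cohort.individuals:
            res = scan_alu_mates(
                small_cohort.tables_ref[name], small_cohort.library, model
            )
            assert res.n_pairs == small_cohort.tables_ref[name].n_pairs
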