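"""Alu-read classification and the Alu-mate scan."""

import time

import numpy as np
import pytest

from alupoly.library import AluLibrary, ClassifyParams, classify_alu_read, revcomp
from alupoly.insertmodel import InsertSizeModel
from alupoly.mates import is_improper_pair, scan_alu_mates
from alupoly.records import AlignmentTable, ReadEnd, ReadPairRecord


def _pair(start1, start2, rev1=False, rev2=True, mapped1=True, mapped2=True,
          chrom1="chr1", chrom2="chr1", L=100):
    e1 = ReadEnd(chrom1, start1 if mapped1 else -1,
                 start1 + L if mapped1 else -1, rev1, mapped1)
    e2 = ReadEnd(chrom2, start2 if mapped2 else -1,
                 start2 + L if mapped2 else -1, rev2, mapped2)
    ins = -1.0
    if mapped1 and mapped2 and chrom1 == chrom2:
        ins = float(max(e1.end, e2.end) - min(e1.start, e2.start))
    return ReadPairRecord("p", e1, e2, insert_length=ins)


class TestClassify:
    def test_exact_substring_gives_offset(self, library):
        cons = library.entries[2][2]
        read = cons[120:220]
        res = classify_alu_read(read, library)
        assert res.is_alu
        assert res.name == library.entries[2][0]
        assert res.offset == 120

    def test_reverse_complement_detected(self, library):
        read = revcomp(library.entries[0][2][50:150])
        res = classify_alu_read(read, library)
        assert res.is_alu and res.offset == 50 and res.strand == "-"

    def test_random_reads_never_pass(self, rng, library):
        # score a batch of random reads; none should reach 90% identity
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        hits = 0
        for _ in range(1000):
            read = bases[rng.integers(0, 4, 100)].tobytes().decode()
            if classify_alu_read(read, library).is_alu:
                hits += 1
        assert hits == 0

    def test_mutated_read_still_classified(self, rng, library):
        cons = np.frombuffer(library.entries[1][2].encode(), np.uint8).copy()
        read = cons[30:130]
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in rng.choice(100, size=5, replace=False):  # 5% divergence
            read[i] = bases[(np.searchsorted(bases, read[i]) + 1) % 4]
        res = classify_alu_read(read.tobytes().decode(), library)
        assert res.is_alu and res.identity >= 0.9

    def test_tie_broken_to_lowest_index(self):
        shared = "ACGTACGTGG" * 12
        lib = AluLibrary([("A1", "AluY", shared), ("A2", "AluY", shared)])
        res = classify_alu_read(shared[:100], lib)
        assert res.is_alu and res.name == "A1"

    def test_empty_inputs_rejected(self, library):
        with pytest.raises(ValueError):
            classify_alu_read("", library)
        with pytest.raises(ValueError):
            AluLibrary([])

    def test_prefilter_consistent_with_aligner(self, rng, library):
        # the k-mer screen never drops a read the aligner would accept
        for name, _fam, cons in library:
            read = cons[10:110]
            assert library.prefilter(read)


class TestImproperPair:
    def test_proper_pair(self, gaussian_model):
        assert not is_improper_pair(_pair(1000, 1300), gaussian_model)

    def test_long_insert_improper(self, gaussian_model):
        # insert 900 exceeds the 0.995 quantile (~529)
        assert is_improper_pair(_pair(1000, 1800), gaussian_model)

    def test_mate_unmapped_improper(self, gaussian_model):
        assert is_improper_pair(_pair(1000, 0, mapped2=False), gaussian_model)

    def test_wrong_orientation_improper(self, gaussian_model):
        assert is_improper_pair(
            _pair(1000, 1300, rev1=True, rev2=False), gaussian_model
        )

    def test_different_chromosomes_improper(self, gaussian_model):
        assert is_improper_pair(_pair(1000, 1300, chrom2="chr2"), gaussian_model)


def _table(pairs, seqs=None, L=100):
    n = len(pairs)
    pos1 = np.array([p[0] for p in pairs])
    pos2 = np.array([p[1] for p in pairs])
    rev1 = np.array([p[2] for p in pairs])
    rev2 = np.array([p[3] for p in pairs])
    return AlignmentTable(
        "chr1", L, pos1, pos2, rev1, rev2,
        np.ones(n, int), np.ones(n, int), seqs=seqs or {},
    )


class TestScan:
    def test_alu_mate_emitted_with_left_label(self, library, gaussian_model):
        alu_seq = library.entries[0][2][50:150]
        table = _table(
            [(10_000, -1, False, False)], seqs={0: ("A" * 100, alu_seq)}
        )
        res = scan_alu_mates(table, library, gaussian_model)
        assert len(res.mates) == 1
        m = res.mates[0]
        assert m.label == "l" and m.position == 10_000 and m.offset == 50

    def test_reverse_anchor_gets_right_label(self, library, gaussian_model):
        alu_seq = library.entries[0][2][50:150]
        table = _table([(-1, 10_000, False, True)], seqs={0: (alu_seq, "A" * 100)})
        res = scan_alu_mates(table, library, gaussian_model)
        assert len(res.mates) == 1 and res.mates[0].label == "r"

    def test_proper_non_alu_pair_ignored(self, library, gaussian_model):
        table = _table([(1000, 1300, False, True)])
        res = scan_alu_mates(table, library, gaussian_model)
        assert res.mates == [] and res.n_improper == 0

    def test_both_ends_alu_gives_no_anchor(self, library, gaussian_model):
        a = library.entries[0][2][0:100]
        b = library.entries[1][2][0:100]
        table = _table([(-1, 10_000, False, True)], seqs={0: (a, b)})
        # force the mapped end to be an Alu read too
        res = scan_alu_mates(table, library, gaussian_model)
        assert res.mates == []

    def test_counts_consistent(self, small_cohort):
        model = small_cohort.insert_model()
        table = small_cohort.tables_ref["S00"]
        res = scan_alu_mates(table, small_cohort.library, model)
        assert res.n_reads == 2 * res.n_pairs == 2 * table.n_pairs
        assert len(res.mates) <= res.n_improper
        for chrom, idx in res.chrom_index.items():
            total = len(idx["l"]["mates"]) + len(idx["r"]["mates"])
            assert total == sum(m.chrom == chrom for m in res.mates)

    def test_determinism(self, small_cohort):
        model = small_cohort.insert_model()
        table = small_cohort.tables_ref["S01"]
        a = scan_alu_mates(table, small_cohort.library, model)
        b = scan_alu_mates(table, small_cohort.library, model)
        assert a.to_frame().equals(b.to_frame())

    def test_unsorted_input_rejected(self, library, gaussian_model):
        table = _table([(1000, 1300, False, True), (500, 800, False, True)])
        table.pos1 = table.pos1[::-1].copy()  # corrupt the sort
        table.pos2 = table.pos2[::-1].copy()
        with pytest.raises(ValueError, match="sorted"):
            scan_alu_mates(table, library, gaussian_model)

    def test_scan_time_grows_no_worse_than_linearly(self, library, gaussian_model):
        def make(n):
            pos1 = np.arange(n) * 10
            return AlignmentTable(
                "chr1", 100, pos1, pos1 + 300,
                np.zeros(n, bool), np.ones(n, bool),
                np.ones(n, int), np.ones(n, int),
            )

        small, big = make(10_000), make(160_000)
        t0 = time.perf_counter()
        scan_alu_mates(small, library, gaussian_model)
        t_small = time.perf_counter() - t0
        t0 = time.perf_counter()
        scan_alu_mates(big, library, gaussian_model)
        t_big = time.perf_counter() - t0
        # 16x the input: linear ~16x, quadratic ~256x; allow generous slack
        assert t_big < 60 * max(t_small, 1e-3)
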