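"""Shared domain types.

Coordinates are 0-based half-open throughout the package.  The insert
length of a pair is the outer distance: rightmost end minus leftmost
start.  ``b`` is the number of equally-best mappings the aligner reported
for a read; a read with ``b`` best mappings carries weight ``1/b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

__all__ = [
    "ReadEnd",
    "ReadPairRecord",
    "AluMate",
    "AluAnnotation",
    "GenotypeLikelihoods",
    "PopulationCall",
    "AlignmentTable",
]


@dataclass
class ReadEnd:
    chrom: Optional[str]
    start: int  # -1 when unmapped
    end: int
    is_reverse: bool
    mapped: bool
    b: int = 1  # number of best mappings

    @property
    def weight(self) -> float:
        return 1.0 / max(self.b, 1)


@dataclass
class ReadPairRecord:
    pair_id: str
    end1: ReadEnd
    end2: ReadEnd
    insert_length: float = -1.0  # outer distance; -1 when undefined
    seq1: Optional[str] = None
    seq2: Optional[str] = None

    @property
    def weight(self) -> float:
        return min(self.end1.weight, self.end2.weight)


@dataclass
class AluMate:
    """Uniquely mapped read whose mate is an Alu read.

    ``label`` follows the covering geometry: an ``l`` read lies to the
    LEFT of the implied Alu, an ``r`` read to its RIGHT.  ``position`` is
    the anchor's start (``c_t``); ``offset`` is where within the matched
    consensus the Alu end aligned (``a_t``, bp from the 5' end).
    ``insert_mean``/``insert_sd`` (``m_t``/``s_t``) come from the
    individual's insert-size model.
    """

    chrom: str
    position: int
    label: str  # 'l' or 'r'
    alu: str
    family: str
    offset: int
    individual: str
    insert_mean: float
    insert_sd: float
    weight: float = 1.0
    read_len: int = 100
    pair_index: int = -1

    @property
    def l_r(self) -> int:
        """Right endpoint of an l read (anchor start + read length)."""
        return self.position + self.read_len

    @property
    def r_l(self) -> int:
        """Left endpoint of an r read (anchor start)."""
        return self.position


@dataclass
class AluAnnotation:
    chrom: str
    start: int
    end: int
    family: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"annotation end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def l_alu(self) -> int:
        return self.end - self.start


@dataclass
class GenotypeLikelihoods:
    """Per-individual log-likelihoods log P(D|g) for g in {0,1,2}.

    ``g`` counts haplotypes carrying the non-reference allele (for a
    deletion locus, the deleted haplotypes).  With no informative pairs
    all three log-likelihoods are zero and the locus is a no-call.
    """

    locus_id: str
    individual: str
    loglik: np.ndarray  # shape (3,), log P(D|0), log P(D|1), log P(D|2)
    genotype: int
    n_pairs: int

    @property
    def no_call(self) -> bool:
        return self.n_pairs == 0

    @property
    def alu_copies(self) -> int:
        """Copies of the annotated Alu carried (2 - g for deletion loci)."""
        return 2 - self.genotype


@dataclass
class PopulationCall:
    locus_id: str
    genotypes: List[GenotypeLikelihoods]
    allele_freq: float
    statistic: float
    p_value: float
    df: int
    genotype_freqs: Optional[np.ndarray] = None  # (f0, f1, f2) without HWE
    significant: bool = False


class AlignmentTable:
    """Columnar store of one individual's read pairs against one reference.

    Arrays are parallel over pairs and sorted by the leftmost mapped
    coordinate.  Unmapped ends have position -1.  Sequences are held in a
    sparse per-pair dict (``seqs[pair_index] = (seq1, seq2)``); they are
    only needed for ends an Alu-read classifier may inspect.
    """

    def __init__(
        self,
        chrom: str,
        read_len: int,
        pos1: np.ndarray,
        pos2: np.ndarray,
        rev1: np.ndarray,
        rev2: np.ndarray,
        b1: np.ndarray,
        b2: np.ndarray,
        individual: str = "S0",
        seqs: Optional[Dict[int, tuple]] = None,
        pair_ids: Optional[np.ndarray] = None,
    ) -> None:
        self.chrom = chrom
        self.read_len = int(read_len)
        self.pos1 = np.asarray(pos1, dtype=np.int64)
        self.pos2 = np.asarray(pos2, dtype=np.int64)
        self.rev1 = np.asarray(rev1, dtype=bool)
        self.rev2 = np.asarray(rev2, dtype=bool)
        self.b1 = np.asarray(b1, dtype=np.int32)
        self.b2 = np.asarray(b2, dtype=np.int32)
        self.individual = individual
        self.seqs = {} if seqs is None else seqs
        self.pair_ids = pair_ids
        self._sort()

    def _sort(self) -> None:
        key = self.leftmost_start
        order = np.argsort(key, kind="stable")
        if np.array_equal(order, np.arange(len(order))):
            return
        remap = {int(old): new for new, old in enumerate(order)}
        for name in ("pos1", "pos2", "rev1", "rev2", "b1", "b2"):
            setattr(self, name, getattr(self, name)[order])
        if self.pair_ids is not None:
            self.pair_ids = self.pair_ids[order]
        self.seqs = {remap[i]: s for i, s in self.seqs.items() if i in remap}

    # -- derived columns ---------------------------------------------

    @property
    def n_pairs(self) -> int:
        return len(self.pos1)

    @property
    def mapped1(self) -> np.ndarray:
        return self.pos1 >= 0

    @property
    def mapped2(self) -> np.ndarray:
        return self.pos2 >= 0

    @property
    def leftmost_start(self) -> np.ndarray:
        """Leftmost mapped start of the pair (large sentinel if none mapped)."""
        p1 = np.where(self.mapped1, self.pos1, np.iinfo(np.int64).max)
        p2 = np.where(self.mapped2, self.pos2, np.iinfo(np.int64).max)
        return np.minimum(p1, p2)

    @property
    def rightmost_end(self) -> np.ndarray:
        p1 = np.where(self.mapped1, self.pos1 + self.read_len, np.iinfo(np.int64).min)
        p2 = np.where(self.mapped2, self.pos2 + self.read_len, np.iinfo(np.int64).min)
        return np.maximum(p1, p2)

    @property
    def insert(self) -> np.ndarray:
        """Outer insert length; -1 where either end is unmapped."""
        both = self.mapped1 & self.mapped2
        ins = self.rightmost_end - self.leftmost_start
        return np.where(both, ins, -1)

    @property
    def fr_inward(self) -> np.ndarray:
        """True where the pair is forward-reverse inward oriented."""
        both = self.mapped1 & self.mapped2
        first_is_1 = self.pos1 <= self.pos2
        fwd_rev = np.where(first_is_1, ~self.rev1 & self.rev2, ~self.rev2 & self.rev1)
        return both & fwd_rev

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / np.maximum(np.maximum(self.b1, self.b2), 1)

    # -- record interface --------------------------------------------

    def get_seqs(self, i: int) -> tuple:
        return self.seqs.get(i, (None, None))

    def record(self, i: int) -> ReadPairRecord:
        s1, s2 = self.get_seqs(i)
        pid = str(self.pair_ids[i]) if self.pair_ids is not None else f"p{i}"
        ins = self.insert[i]
        return ReadPairRecord(
            pair_id=pid,
            end1=ReadEnd(self.chrom, int(self.pos1[i]),
                         int(self.pos1[i]) + self.read_len if self.pos1[i] >= 0 else -1,
                         bool(self.rev1[i]), bool(self.pos1[i] >= 0), int(self.b1[i])),
            end2=ReadEnd(self.chrom, int(self.pos2[i]),
                         int(self.pos2[i]) + self.read_len if self.pos2[i] >= 0 else -1,
                         bool(self.rev2[i]), bool(self.pos2[i] >= 0), int(self.b2[i])),
            insert_length=float(ins),
            seq1=s1,
            seq2=s2,
        )

    def __iter__(self):
        for i in range(self.n_pairs):
            yield self.record(i)

    @classmethod
    def from_records(cls, records, chrom: str, read_len: int,
                     individual: str = "S0") -> "AlignmentTable":
        recs = list(records)
        n = len(recs)
        pos1 = np.full(n, -1, dtype=np.int64)
        pos2 = np.full(n, -1, dtype=np.int64)
        rev1 = np.zeros(n, dtype=bool)
        rev2 = np.zeros(n, dtype=bool)
        b1 = np.ones(n, dtype=np.int32)
        b2 = np.ones(n, dtype=np.int32)
        seqs: Dict[int, tuple] = {}
        ids = []
        for i, r in enumerate(recs):
            ids.append(r.pair_id)
            if r.end1.mapped:
                pos1[i] = r.end1.start
            if r.end2.mapped:
                pos2[i] = r.end2.start
            rev1[i], rev2[i] = r.end1.is_reverse, r.end2.is_reverse
            b1[i], b2[i] = r.end1.b, r.end2.b
            if r.seq1 is not None or r.seq2 is not None:
                seqs[i] = (r.seq1, r.seq2)
        return cls(chrom, read_len, pos1, pos2, rev1, rev2, b1, b2,
                   individual=individual, seqs=seqs,
                   pair_ids=np.asarray(ids, dtype=object))
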