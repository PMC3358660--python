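"""Single-pass scan of an individual's alignments for Alu mates.

An *improper* pair maps inconsistently with the insert-size distribution
(mate unmapped, different chromosomes, wrong orientation, or insert
outside the epsilon quantiles).  When exactly one end of an improper pair
is an Alu read and the other end maps uniquely, that mapped end is an
*Alu mate*: an anchor telling us an Alu lies nearby.  Anchors on the +
strand expect their mate downstream, so the implied Alu is to the right
and the anchor is labelled ``l``; anchors on the - strand are labelled
``r``.  The scan touches each pair exactly once and runs in time linear
in the number of reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .insertmodel import InsertSizeModel
from .library import AluLibrary, ClassifyParams, classify_alu_read
from .records import AlignmentTable, AluMate, ReadPairRecord

__all__ = ["AluMateScanResult", "is_improper_pair", "scan_alu_mates"]


@dataclass
class AluMateScanResult:
    mates: List[AluMate]
    n_pairs: int = 0
    n_reads: int = 0
    n_alu_reads: int = 0
    n_improper: int = 0
    chrom_index: Dict[str, dict] = field(default_factory=dict)

    def build_index(self) -> None:
        """Per-chromosome sorted position arrays for l and r mates."""
        self.chrom_index = {}
        for chrom in sorted({m.chrom for m in self.mates}):
            sub = [m for m in self.mates if m.chrom == chrom]
            idx = {}
            for lab in ("l", "r"):
                ms = sorted((m for m in sub if m.label == lab), key=lambda m: m.position)
                idx[lab] = {
                    "position": np.array([m.position for m in ms], dtype=np.int64),
                    "weight": np.array([m.weight for m in ms], dtype=float),
                    "mates": ms,
                }
            self.chrom_index[chrom] = idx
        self.mates = sorted(self.mates, key=lambda m: (m.chrom, m.position, m.label))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [m.chrom for m in self.mates],
                "pos": [m.position for m in self.mates],
                "label": [m.label for m in self.mates],
                "alu": [m.alu for m in self.mates],
                "family": [m.family for m in self.mates],
                "a_t": [m.offset for m in self.mates],
                "weight": [m.weight for m in self.mates],
                "individual": [m.individual for m in self.mates],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def is_improper_pair(pair: ReadPairRecord, model: InsertSizeModel) -> bool:
    """A pair is improper if it cannot have been drawn from Y.

    True iff the mate is unmapped, the ends map to different chromosomes,
    the orientation is not forward-reverse inward, or the insert length
    falls outside ``[q_lo, q_hi]``.
    """
    e1, e2 = pair.end1, pair.end2
    if not (e1.mapped or e2.mapped):
        return True
    if not (e1.mapped and e2.mapped):
        return True
    if e1.chrom != e2.chrom:
        return True
    left, right = (e1, e2) if e1.start <= e2.start else (e2, e1)
    if left.is_reverse or not right.is_reverse:
        return True
    return not model.is_proper_length(pair.insert_length)


def _improper_mask(table: AlignmentTable, model: InsertSizeModel) -> np.ndarray:
    both = table.mapped1 & table.mapped2
    ins = table.insert
    bad_len = both & ((ins < model.q_lo) | (ins > model.q_hi))
    bad_orient = both & ~table.fr_inward
    return ~both | bad_len | bad_orient


def scan_alu_mates(
    alignments,
    library: AluLibrary,
    model: InsertSizeModel,
    params: ClassifyParams = ClassifyParams(),
    check_sorted: bool = True,
) -> AluMateScanResult:
    """Classify improper-pair ends against the Alu library and emit mates.

    ``alignments`` is an :class:`AlignmentTable` or an iterable of
    :class:`ReadPairRecord` (converted internally).  Records must be
    coordinate sorted.  Each pair is examined once; only ends of improper
    pairs are ever aligned against the library, and those only after a
    shared-k-mer prefilter, keeping the scan linear with a small constant.
    """
    if not isinstance(alignments, AlignmentTable):
        recs = list(alignments)
        chrom = next((r.end1.chrom or r.end2.chrom for r in recs), "chr1")
        rl = 100
        for r in recs:
            if r.end1.mapped:
                rl = r.end1.end - r.end1.start
                break
        table = AlignmentTable.from_records(recs, chrom=chrom, read_len=rl)
    else:
        table = alignments

    if check_sorted:
        key = table.leftmost_start
        mapped_any = table.mapped1 | table.mapped2
        kk = key[mapped_any]
        if len(kk) > 1:
            diffs = np.diff(kk)
            bad = np.flatnonzero(diffs < 0)
            if len(bad):
                raise ValueError(
                    f"alignments are not coordinate sorted: pair index "
                    f"{int(np.flatnonzero(mapped_any)[bad[0] + 1])} is out of order"
                )

    improper = _improper_mask(table, model)
    mates: List[AluMate] = []
    n_alu_reads = 0
    m_t = model.mean - table.read_len  # start-to-start mean distance
    s_t = model.sd

    for i in np.flatnonzero(improper):
        i = int(i)
        s1, s2 = table.get_seqs(i)
        ends = [
            (table.pos1[i] >= 0, int(table.pos1[i]), bool(table.rev1[i]),
             int(table.b1[i]), s1),
            (table.pos2[i] >= 0, int(table.pos2[i]), bool(table.rev2[i]),
             int(table.b2[i]), s2),
        ]
        alu_hits = []
        for j, (mapped, _pos, _rev, b, seq) in enumerate(ends):
            if seq is None:
                continue
            if not library.prefilter(seq, k=params.kmer):
                continue
            res = classify_alu_read(seq, library, params, b=b)
            if res.is_alu:
                alu_hits.append((j, res))
        n_alu_reads += len(alu_hits)
        if len(alu_hits) != 1:
            continue  # no Alu end, or no unique anchor (both ends Alu)
        j, res = alu_hits[0]
        anchor = ends[1 - j]
        a_mapped, a_pos, a_rev, a_b, _ = anchor
        if not a_mapped or a_b != 1:
            continue  # anchor must map uniquely
        label = "r" if a_rev else "l"
        mates.append(
            AluMate(
                chrom=table.chrom,
                position=a_pos,
                label=label,
                alu=res.name,
                family=res.family,
                offset=res.offset,
                individual=table.individual,
                insert_mean=m_t,
                insert_sd=s_t,
                weight=1.0 / max(a_b, 1),
                read_len=table.read_len,
                pair_index=i,
            )
        )

    result = AluMateScanResult(
        mates=mates,
        n_pairs=table.n_pairs,
        n_reads=2 * table.n_pairs,
        n_alu_reads=n_alu_reads,
        n_improper=int(improper.sum()),
    )
    result.build_index()
    return result
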