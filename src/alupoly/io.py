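"""Format adapters: SAM, BED / RepeatMasker, VCF, FASTA/FASTQ, reports.

All coordinates are converted to 0-based half-open on the way in.  The
best-mapping count ``b`` is read from an integer SAM tag (default
``X0``); records lacking the tag fall back to ``b > 1`` when MAPQ is 0.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence

import numpy as np
import pysam

from .records import (
    AlignmentTable,
    AluAnnotation,
    GenotypeLikelihoods,
    PopulationCall,
    ReadEnd,
    ReadPairRecord,
)

__all__ = [
    "read_alignments",
    "alignment_table_from_sam",
    "write_sam",
    "read_annotations",
    "write_calls",
    "family_tally",
]

BEST_HIT_TAG = "X0"


class UnsortedInputError(ValueError):
    pass


def read_alignments(
    path, best_hit_tag: str = BEST_HIT_TAG
) -> Iterator[ReadPairRecord]:
    """Yield paired records from a coordinate-sorted SAM/BAM.

    Mates are joined on the query name.  Raises on missing mate
    information and on the first out-of-order record (naming it).
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    pending: Dict[str, pysam.AlignedSegment] = {}
    last_pos = -1
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for n, seg in enumerate(fh):
            if seg.is_secondary or seg.is_supplementary:
                continue
            if not seg.is_paired:
                raise ValueError(f"record {seg.query_name} (line {n + 1}) is unpaired")
            if not seg.is_unmapped:
                if seg.reference_start < last_pos:
                    raise UnsortedInputError(
                        f"input not coordinate sorted at record "
                        f"{seg.query_name!r} (record {n + 1})"
                    )
                last_pos = seg.reference_start
            name = seg.query_name
            if name in pending:
                yield _make_pair(pending.pop(name), seg, best_hit_tag)
            else:
                pending[name] = seg
    for name, seg in pending.items():
        # mate never seen: emit with a synthetic unmapped mate
        yield _make_pair(seg, None, best_hit_tag)


def _end_of(seg: Optional[pysam.AlignedSegment], tag: str) -> ReadEnd:
    if seg is None or seg.is_unmapped:
        chrom = None if seg is None else seg.reference_name
        return ReadEnd(chrom, -1, -1, False, False, 1)
    if seg.has_tag(tag):
        b = int(seg.get_tag(tag))
    else:
        b = 2 if (seg.mapping_quality == 0) else 1
    return ReadEnd(
        seg.reference_name,
        seg.reference_start,
        seg.reference_end,
        seg.is_reverse,
        True,
        max(b, 1),
    )


def _make_pair(
    a: pysam.AlignedSegment, b: Optional[pysam.AlignedSegment], tag: str
) -> ReadPairRecord:
    first, second = (a, b) if (b is None or a.is_read1) else (b, a)
    e1 = _end_of(first, tag)
    e2 = _end_of(second, tag)
    ins = -1.0
    if e1.mapped and e2.mapped and e1.chrom == e2.chrom:
        ins = float(max(e1.end, e2.end) - min(e1.start, e2.start))
    s1 = first.query_sequence if first is not None else None
    s2 = second.query_sequence if second is not None else None
    return ReadPairRecord(
        pair_id=a.query_name, end1=e1, end2=e2, insert_length=ins,
        seq1=s1, seq2=s2,
    )


def alignment_table_from_sam(
    path, individual: str = "S0", best_hit_tag: str = BEST_HIT_TAG
) -> AlignmentTable:
    recs = list(read_alignments(path, best_hit_tag))
    chrom = next(
        (r.end1.chrom or r.end2.chrom for r in recs if r.end1.chrom or r.end2.chrom),
        "chr1",
    )
    read_len = 100
    for r in recs:
        if r.end1.mapped:
            read_len = r.end1.end - r.end1.start
            break
    return AlignmentTable.from_records(
        recs, chrom=chrom, read_len=read_len, individual=individual
    )


def write_sam(
    table: AlignmentTable,
    path,
    ref_length: int,
    best_hit_tag: str = BEST_HIT_TAG,
) -> None:
    """Write an alignment table as coordinate-sorted SAM.

    Unmapped ends are placed at their mate's coordinate with the unmapped
    flag set (the conventional representation).  Sequences are written
    where the table holds them, '*' otherwise.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": table.chrom, "LN": int(ref_length)}],
        }
    )
    segs: List[pysam.AlignedSegment] = []
    L = table.read_len
    for i in range(table.n_pairs):
        s1, s2 = table.get_seqs(i)
        ends = [
            (int(table.pos1[i]), bool(table.rev1[i]), int(table.b1[i]), s1, True),
            (int(table.pos2[i]), bool(table.rev2[i]), int(table.b2[i]), s2, False),
        ]
        mate_pos = [ends[1][0], ends[0][0]]
        for (pos, rev, b, seq, is_read1), mpos in zip(ends, mate_pos):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"p{i}"
            seg.is_paired = True
            seg.is_read1 = is_read1
            seg.is_read2 = not is_read1
            place = pos if pos >= 0 else (mpos if mpos >= 0 else 0)
            seg.reference_id = 0
            seg.reference_start = place
            if pos >= 0:
                seg.is_reverse = rev
                seg.cigarstring = f"{L}M"
                seg.mapping_quality = 60 if b == 1 else 0
                seg.set_tag(best_hit_tag, b)
            else:
                seg.is_unmapped = True
                seg.mapping_quality = 0
            mate_unmapped = mpos < 0
            seg.next_reference_id = 0
            seg.next_reference_start = mpos if mpos >= 0 else place
            seg.mate_is_unmapped = mate_unmapped
            if seq is not None:
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            ins = table.insert[i]
            if pos >= 0 and mpos >= 0:
                seg.template_length = int(ins) if pos <= mpos else -int(ins)
            segs.append(seg)
    segs.sort(key=lambda s: s.reference_start)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for seg in segs:
            out.write(seg)


# -- annotations ------------------------------------------------------


def read_annotations(path) -> List[AluAnnotation]:
    """Read an Alu annotation track (BED or RepeatMasker .out).

    BED: ``chrom start end name`` (0-based half-open).  RepeatMasker
    .out: the standard 1-based columns; converted to 0-based half-open.
    Returns annotations sorted by position; malformed lines raise with
    their line number.
    """
    path = Path(path)
    text = path.read_text().splitlines()
    is_rm = path.suffix == ".out" or (
        text and text[0].lstrip().lower().startswith(("sw", "score"))
    )
    out: List[AluAnnotation] = []
    if is_rm:
        for n, line in enumerate(text, 1):
            s = line.split()
            if not s or not s[0].replace(".", "").isdigit():
                continue  # header / blank lines
            try:
                chrom, start, end = s[4], int(s[5]) - 1, int(s[6])
                name = s[9]
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed RepeatMasker line {n}: {line!r}") from exc
            out.append(
                AluAnnotation(chrom, start, end, _family_of(name), name=name)
            )
    else:
        for n, line in enumerate(text, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            s = line.split()
            try:
                chrom, start, end = s[0], int(s[1]), int(s[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"malformed BED line {n}: {line!r}") from exc
            name = s[3] if len(s) > 3 else ""
            out.append(AluAnnotation(chrom, start, end, _family_of(name), name=name))
    return sorted(out, key=lambda a: (a.chrom, a.start))


def _family_of(name: str) -> str:
    for prefix in ("AluY", "AluS", "AluJ"):
        if name.startswith(prefix):
            return prefix
    return name or "Alu"


def family_tally(items: Iterable) -> Dict[str, int]:
    """Count calls per family group (AluY / AluS / AluJ / other prefixes)."""
    tally: Dict[str, int] = {}
    for it in items:
        name = it if isinstance(it, str) else getattr(it, "family", "")
        fam = _family_of(name)
        tally[fam] = tally.get(fam, 0) + 1
    return tally


# -- VCF --------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=alupoly
##ALT=<ID=DEL:ME:ALU,Description="Deletion of Alu element">
##ALT=<ID=INS:ME:ALU,Description="Insertion of Alu element">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">
##INFO=<ID=FAMILY,Number=1,Type=String,Description="Alu family">
##INFO=<ID=LRT,Number=1,Type=Float,Description="Likelihood ratio statistic">
##INFO=<ID=PV,Number=1,Type=Float,Description="LRT p-value">
##INFO=<ID=AF,Number=A,Type=Float,Description="Estimated allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GL,Number=G,Type=Float,Description="Log10 genotype likelihoods">
"""


def _gt_string(g: GenotypeLikelihoods) -> str:
    if g.no_call:
        return "./."
    return {0: "0/0", 1: "0/1", 2: "1/1"}[g.genotype]


def _gl_string(g: GenotypeLikelihoods) -> str:
    gl = g.loglik / math.log(10.0)
    return ",".join(f"{x:.2f}" for x in gl)


def write_calls(
    calls: Sequence[PopulationCall],
    path,
    kind: str = "deletion",
    loci: Optional[Sequence[AluAnnotation]] = None,
    chrom: str = "chr1",
    contig_length: Optional[int] = None,
    only_significant: bool = False,
) -> None:
    """Write population calls as VCF with symbolic mobile-element alleles.

    ``kind`` selects ``<DEL:ME:ALU>`` (annotated loci; pass ``loci``
    parallel to ``calls``) or ``<INS:ME:ALU>``.
    """
    samples = [g.individual for g in calls[0].genotypes] if calls else []
    lines = [_VCF_HEADER]
    if contig_length:
        lines.append(f"##contig=<ID={chrom},length={int(contig_length)}>\n")
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT"] + samples
    lines.append("\t".join(cols) + "\n")
    for i, call in enumerate(calls):
        if only_significant and not call.significant:
            continue
        if kind == "deletion" and loci is not None:
            locus = loci[i]
            pos = locus.start  # 0-based; VCF POS is 1-based
            end = locus.end
            svlen = -locus.l_alu
            family = locus.family
            alt = "<DEL:ME:ALU>"
        else:
            pos = int(round(float(call.locus_id.split(":")[1].split("<")[0])))
            end = pos
            svlen = 0
            family = "AluY"
            alt = "<INS:ME:ALU>"
        info = (
            f"END={end};SVLEN={svlen};FAMILY={family};"
            f"LRT={call.statistic:.3f};PV={call.p_value:.3g};AF={call.allele_freq:.4f}"
        )
        # POS is the base before the SV: a 0-based element start equals the
        # 1-based coordinate of the preceding base
        fields = [
            chrom, str(pos), call.locus_id, "N", alt, ".",
            "PASS" if call.significant else ".", info, "GT:GL",
        ] + [f"{_gt_string(g)}:{_gl_string(g)}" for g in call.genotypes]
        lines.append("\t".join(fields) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def write_summary_tsv(calls: Sequence[PopulationCall], path) -> None:
    """Per-individual counts of non-reference calls plus a family line."""
    import pandas as pd

    counts: Dict[str, int] = {}
    for call in calls:
        for g in call.genotypes:
            if g.genotype >= 1 and not g.no_call:
                counts[g.individual] = counts.get(g.individual, 0) + 1
    df = pd.DataFrame(
        {"individual": list(counts), "n_calls": list(counts.values())}
    )
    df.to_csv(path, sep="\t", index=False)
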