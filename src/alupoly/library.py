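"""Alu consensus library and Alu-read classification.

A read is an *Alu read* when it aligns well to one of the consensus
sequences of the known Alu (sub)families, or when the genome aligner
reported multiple equally good mappings and the read also matches the
library.  Classification uses semi-global (infix) alignment of the full
read against each consensus, on both strands; identity is
``1 - edit_distance / read_length``.  A read hanging over a consensus
boundary, or only partly Alu-derived (a junction read), pays edits for
the non-matching part and falls below threshold, which is the desired
behaviour: junction reads carry no usable insert-length information in
this framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import edlib
import numpy as np

__all__ = ["AluLibrary", "ClassifyParams", "ClassifyResult", "classify_alu_read"]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Synthetic default library: names of subfamilies active (AluY*) or
#: ancient (AluJo) in the human genome; sequences are seeded random
#: ~300-mers standing in for the licensed consensus database.
DEFAULT_FAMILY_NAMES = [
    ("AluYa5", "AluY"),
    ("AluYb8", "AluY"),
    ("AluYb9", "AluY"),
    ("AluYk13", "AluY"),
    ("AluJo", "AluJ"),
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ClassifyParams:
    min_identity: float = 0.90
    min_cover: float = 0.80  # fraction of the read the alignment must span
    kmer: int = 13  # prefilter seed length


@dataclass
class ClassifyResult:
    is_alu: bool
    name: Optional[str] = None
    family: Optional[str] = None
    offset: int = -1  # a_t: alignment start within the consensus, 5' coords
    identity: float = 0.0
    strand: str = "+"


class AluLibrary:
    """Named consensus sequences with family labels."""

    def __init__(self, entries: Sequence[Tuple[str, str, str]]) -> None:
        if not entries:
            raise ValueError("Alu library must contain at least one entry")
        names = [e[0] for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("Alu library names must be unique")
        for name, _fam, seq in entries:
            if not seq:
                raise ValueError(f"library entry {name} has an empty sequence")
        self.entries: List[Tuple[str, str, str]] = [
            (n, f, s.upper()) for n, f, s in entries
        ]
        self._kmers: Optional[set] = None
        self._kmer_size: Optional[int] = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def sequence(self, name: str) -> str:
        for n, _f, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)

    def family(self, name: str) -> str:
        for n, f, _s in self.entries:
            if n == name:
                return f
        raise KeyError(name)

    # -- construction -------------------------------------------------

    @classmethod
    def synthetic(cls, rng: np.random.Generator, length: int = 300) -> "AluLibrary":
        """Seeded random ~300-mers named after real Alu subfamilies.

        Stand-ins for the consensus database: the algorithms depend on the
        similarity structure between reads and library, not on the actual
        Alu alphabet.
        """
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        entries = []
        for name, fam in DEFAULT_FAMILY_NAMES:
            seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
            entries.append((name, fam, seq))
        return cls(entries)

    @classmethod
    def from_fasta(cls, path, family_from_name: bool = True) -> "AluLibrary":
        from Bio import SeqIO

        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fam = _family_prefix(rec.id) if family_from_name else rec.id
            entries.append((rec.id, fam, str(rec.seq).upper()))
        return cls(entries)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, _fam, seq in self.entries:
                fh.write(f">{name}\n{seq}\n")

    # -- k-mer prefilter ----------------------------------------------

    def _build_kmers(self, k: int) -> None:
        kmers = set()
        for _n, _f, seq in self.entries:
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - k + 1):
                    kmers.add(s[i:i + k])
        self._kmers = kmers
        self._kmer_size = k

    def prefilter(self, seq: str, k: int = 13, stride: int = 4) -> bool:
        """Cheap screen: does the read share any exact k-mer with the library?

        A true Alu read (3% divergence + 2% sequencing error) retains many
        intact 13-mers; a random read shares essentially none.  Used by the
        scanner before the exact aligner; never rejects what the aligner
        would accept in practice, and `classify_alu_read` itself stays exact.
        """
        if self._kmers is None or self._kmer_size != k:
            self._build_kmers(k)
        seq = seq.upper()
        n = len(seq)
        if n < k:
            return False
        for i in range(0, n - k + 1, stride):
            if seq[i:i + k] in self._kmers:
                return True
        return seq[n - k:] in self._kmers


def _family_prefix(name: str) -> str:
    for prefix in ("AluY", "AluS", "AluJ"):
        if name.startswith(prefix):
            return prefix
    return name


def classify_alu_read(
    seq: str,
    library: AluLibrary,
    params: ClassifyParams = ClassifyParams(),
    b: int = 1,
) -> ClassifyResult:
    """Align a read against every library entry (both strands).

    Returns the best hit by identity, ties broken toward the lowest
    library index then the + strand.  ``is_alu`` is true when the best
    identity reaches ``min_identity`` (a multi-mapping read, ``b > 1``,
    is subject to the same alignment requirement).
    """
    if not seq:
        raise ValueError("cannot classify an empty read sequence")
    seq = seq.upper()
    n = len(seq)
    max_dist = int(n * (1.0 - params.min_identity * params.min_cover))
    best: Optional[ClassifyResult] = None
    for idx, (name, fam, cons) in enumerate(library.entries):
        for strand, query in (("+", seq), ("-", revcomp(seq))):
            aln = edlib.align(query, cons, mode="HW", task="locations", k=max_dist)
            dist = aln["editDistance"]
            if dist < 0:
                continue
            ident = 1.0 - dist / n
            if best is None or ident > best.identity + 1e-12:
                start = aln["locations"][0][0]
                best = ClassifyResult(
                    is_alu=False, name=name, family=fam,
                    offset=int(start), identity=ident, strand=strand,
                )
    if best is None:
        return ClassifyResult(is_alu=False)
    best.is_alu = best.identity >= params.min_identity
    if not best.is_alu:
        return ClassifyResult(is_alu=False, identity=best.identity)
    return best


def count_library_matches(
    seq: str, library: AluLibrary, params: ClassifyParams = ClassifyParams()
) -> int:
    """Number of library entries the read matches above threshold.

    The simulator uses this as the best-hit count ``b`` for Alu-derived
    reads (no external genome aligner is in the loop).
    """
    seq = seq.upper()
    n = len(seq)
    max_dist = int(n * (1.0 - params.min_identity))
    count = 0
    for _name, _fam, cons in library.entries:
        for query in (seq, revcomp(seq)):
            aln = edlib.align(query, cons, mode="HW", task="distance", k=max_dist)
            if aln["editDistance"] >= 0:
                count += 1
                break
    return count
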