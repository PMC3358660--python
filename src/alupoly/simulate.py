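"""Diploid population / trio simulator with planted polymorphic Alus.

The generator builds the benchmark this package is validated on, end to
end and without any download:

* a reference chromosome (synthetic uniform-random sequence by default,
  or a user FASTA),
* a library of ~300 bp consensus elements (seeded random stand-ins named
  for real subfamilies, or a user FASTA),
* 50 insertion sites (10 per consensus), each an independently 3%-mutated
  copy planted at a uniformly random position subject to the spacing
  constraint (no two sites within ``Y_{1-eps}`` bp) and an N-content cap,
* a frequency ladder {2,4,5,10,20,80,90,94,96,98}% — each consensus's ten
  sites receive the ten frequencies once, and every haploid chromosome
  carries each site's Alu independently with its frequency,
* haploids paired sequentially into diploids (or trio mode: two fresh
  haploids per parent, the child receiving one uniformly chosen haploid
  from each parent),
* paired-end reads at 5x per haploid (read length 100 bp, Gaussian(400,
  50) outer inserts, 0% or 2% substitution error), with truth alignments
  computed by construction against both the Alu-free reference and the
  reference carrying every planted Alu.

Alignment semantics mirror what a mapper produces on such data: a read
fully inside a planted element has no home on the Alu-free reference and
is reported unmapped (its sequence is retained for the scanner's
classifier); a read crossing an insertion/deletion junction of the target
reference would be split and is reported unmapped; everything else maps
uniquely at its true position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .insertmodel import InsertSizeModel
from .library import AluLibrary, ClassifyParams, count_library_matches
from .records import AlignmentTable, AluAnnotation

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "Cohort",
    "plant_alus",
    "simulate_reads",
    "build_population_and_trios",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_FREQUENCIES = (2.0, 4.0, 5.0, 10.0, 20.0, 80.0, 90.0, 94.0, 96.0, 98.0)


@dataclass
class SimulationConfig:
    ref_length: int = 2_000_000
    ref_fasta: Optional[str] = None
    library_fasta: Optional[str] = None
    alu_length: int = 300
    mutation_rate: float = 0.03
    sites_per_consensus: int = 10
    n_haploids: int = 100
    frequencies: Tuple[float, ...] = DEFAULT_FREQUENCIES  # percent
    coverage: float = 5.0  # per haploid chromosome
    read_len: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    epsilon: float = 0.005
    seed: int = 0
    chrom: str = "chr1"
    n_trios: int = 0  # 0 -> plain diploid population

    def __post_init__(self) -> None:
        for f in self.frequencies:
            if not (0.0 < f < 100.0):
                raise ValueError(f"frequencies must lie in (0, 100): {f}")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation rate must lie in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    @property
    def n_sites(self) -> int:
        n_cons = 5 if self.library_fasta is None else None
        if n_cons is None:
            raise ValueError("site count depends on the supplied library")
        return n_cons * self.sites_per_consensus

    def insert_model(self) -> InsertSizeModel:
        return InsertSizeModel(
            mean=self.insert_mean, sd=self.insert_sd, epsilon=self.epsilon
        )


class TruthTable:
    """Planted-site ground truth for benchmarking.

    ``sites`` rows are sorted by position; ``carriers[s, h]`` says whether
    haploid ``h`` carries site ``s``.  ``individuals`` maps an individual
    id to its haplotype pair; ``trios`` lists (father, mother, child) ids.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        carriers: np.ndarray,
        individuals: Dict[str, Tuple[int, int]],
        trios: Optional[List[Tuple[str, str, str]]] = None,
        chrom: str = "chr1",
    ) -> None:
        self.sites = sites
        self.carriers = carriers
        self.individuals = individuals
        self.trios = trios or []
        self.chrom = chrom

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def alus_per_haploid(self) -> np.ndarray:
        """Planted-Alu count per haploid chromosome."""
        return self.carriers.sum(axis=0)

    def diploid_copies(self, individual: str) -> np.ndarray:
        h1, h2 = self.individuals[individual]
        return self.carriers[:, h1].astype(int) + self.carriers[:, h2].astype(int)

    def annotations_all_alu(self) -> List[AluAnnotation]:
        """The planted elements as loci on the all-Alu reference."""
        return [
            AluAnnotation(
                chrom=self.chrom,
                start=int(r.allalu_start),
                end=int(r.allalu_end),
                family=r.family,
                name=r.name,
            )
            for r in self.sites.itertuples()
        ]

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)


def _random_reference(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if rate <= 0:
        return out
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return out


def plant_alus(
    reference: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    library: AluLibrary,
    max_tries: int = 1000,
):
    """Choose admissible sites, mutate one copy per site, assign frequencies.

    Returns ``(sites DataFrame, site_seqs, carriers)`` where ``carriers``
    is the (n_sites, n_haploids) boolean matrix of per-haploid carrier
    status.  Fails explicitly if the spacing/N constraints cannot be met.
    """
    model = config.insert_model()
    q_hi = model.q_hi
    n_sites = len(library) * config.sites_per_consensus
    ref_len = len(reference)
    if ref_len < 100 * q_hi:
        raise ValueError(
            f"reference too short to place sites: need >= {int(100 * q_hi)} bp"
        )
    is_n = reference == ord("N")
    margin = int(q_hi) + config.read_len

    positions = None
    for _ in range(max_tries):
        cand = np.sort(rng.integers(margin, ref_len - margin, size=n_sites))
        if np.min(np.diff(cand)) < q_hi:
            continue
        if is_n.any():
            w = int(q_hi)
            frac = np.array([is_n[p - w: p + w].mean() for p in cand])
            if (frac > 0.01).any():
                continue
        positions = cand
        break
    if positions is None:
        raise RuntimeError(
            f"could not place {n_sites} sites with spacing {q_hi:.0f} bp "
            f"after {max_tries} tries"
        )

    # consensus assignment and per-consensus frequency ladder
    cons_idx = rng.permutation(np.repeat(np.arange(len(library)), config.sites_per_consensus))
    freqs = np.empty(n_sites)
    ladder = np.asarray(config.frequencies, dtype=float)
    for c in range(len(library)):
        sites_c = np.flatnonzero(cons_idx == c)
        # each consensus's sites receive the ladder once (truncated/tiled
        # when the per-consensus site count differs from the ladder length)
        perm = rng.permutation(ladder)
        freqs[sites_c] = np.resize(perm, len(sites_c))

    site_seqs: List[np.ndarray] = []
    names, families, lens = [], [], []
    for s in range(n_sites):
        name, fam, seq = library.entries[cons_idx[s]]
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        site_seqs.append(_mutate(arr, config.mutation_rate, rng))
        names.append(name)
        families.append(fam)
        lens.append(len(arr))

    lens = np.asarray(lens)
    allalu_start = positions + np.concatenate([[0], np.cumsum(lens)[:-1]])
    sites = pd.DataFrame(
        {
            "site_id": [f"site{s:03d}" for s in range(n_sites)],
            "pos": positions,
            "name": names,
            "family": families,
            "freq": freqs,
            "l_alu": lens,
            "allalu_start": allalu_start,
            "allalu_end": allalu_start + lens,
        }
    )
    n_hap = config.n_haploids
    carriers = rng.random((n_sites, n_hap)) < (freqs[:, None] / 100.0)
    return sites, site_seqs, carriers


class _HaploidLayout:
    """Coordinate bookkeeping for one haploid chromosome."""

    def __init__(self, sites: pd.DataFrame, site_seqs, carried: np.ndarray,
                 ref: np.ndarray) -> None:
        self.ref = ref
        self.site_pos = sites["pos"].to_numpy()
        self.site_len = sites["l_alu"].to_numpy()
        self.allalu_start = sites["allalu_start"].to_numpy()
        self.carried_idx = np.flatnonzero(carried)
        self.site_seqs = site_seqs
        pc = self.site_pos[self.carried_idx]
        lc = self.site_len[self.carried_idx]
        self.cum_excl = np.concatenate([[0], np.cumsum(lc)[:-1]])  # before alu i
        self.cum_incl = np.cumsum(lc) if len(lc) else np.zeros(0, dtype=int)
        self.hap_alu_start = pc + self.cum_excl
        self.hap_alu_end = self.hap_alu_start + lc
        self.length = len(ref) + int(lc.sum())
        self.all_cum = np.concatenate([[0], np.cumsum(self.site_len)])

    def sequence(self) -> np.ndarray:
        parts = []
        prev = 0
        for i in self.carried_idx:
            p = self.site_pos[i]
            parts.append(self.ref[prev:p])
            parts.append(self.site_seqs[i])
            prev = p
        parts.append(self.ref[prev:])
        return np.concatenate(parts)

    def map_reads(self, starts: np.ndarray, L: int) -> dict:
        """Vectorised mapping of hap-coordinate reads to both references."""
        n = len(starts)
        ends = starts + L
        n_c = len(self.hap_alu_start)
        if n_c:
            idx = np.searchsorted(self.hap_alu_start, starts, side="right") - 1
            alu_end = np.where(idx >= 0, self.hap_alu_end[np.maximum(idx, 0)], 0)
            in_alu = (idx >= 0) & (starts < alu_end)
            interior = in_alu & (ends <= alu_end)
            next_start = np.where(
                idx + 1 < n_c,
                self.hap_alu_start[np.minimum(idx + 1, n_c - 1)],
                self.length,
            )
        else:
            idx = np.full(n, -1, dtype=np.int64)
            in_alu = np.zeros(n, dtype=bool)
            interior = in_alu
            next_start = np.full(n, self.length)
        junction_alu = in_alu & ~interior
        flank = ~in_alu & (ends <= next_start)
        junction_flank = ~in_alu & ~flank

        cum = np.concatenate([[0], self.cum_incl])
        r_coord = np.where(in_alu, -1, starts - cum[idx + 1])
        pos_ref = np.where(flank, r_coord, -1)

        site_of = np.full(n, -1, dtype=np.int64)
        a_t = np.full(n, -1, dtype=np.int64)
        sel = np.flatnonzero(interior)
        if len(sel):
            site_of[sel] = self.carried_idx[idx[sel]]
            a_t[sel] = starts[sel] - self.hap_alu_start[idx[sel]]

        # all-Alu reference: contiguity breaks only where the read's
        # Alu-free projection crosses a NON-carried site's insertion point
        start_all = np.zeros(n, dtype=np.int64)
        split = np.zeros(n, dtype=bool)
        selA = np.flatnonzero(in_alu)
        if len(selA):
            site = self.carried_idx[idx[selA]]
            start_all[selA] = self.allalu_start[site] + (
                starts[selA] - self.hap_alu_start[idx[selA]]
            )
        selF = np.flatnonzero(~in_alu)
        if len(selF):
            r = r_coord[selF]
            shift = self.all_cum[np.searchsorted(self.site_pos, r, side="right")]
            start_all[selF] = r + shift
            carried_mask = np.zeros(len(self.site_pos), dtype=bool)
            carried_mask[self.carried_idx] = True
            lo = np.searchsorted(self.site_pos, r, side="right")
            hi = np.searchsorted(self.site_pos, r + L - 1, side="right")
            ncs = np.cumsum(np.concatenate([[0], (~carried_mask).astype(int)]))
            split[selF] = (ncs[hi] - ncs[lo]) > 0
        pos_all = np.where(split, -1, start_all)
        return {
            "pos_ref": pos_ref,
            "pos_all": pos_all,
            "interior": interior,
            "junction": junction_alu | junction_flank,
            "site": site_of,
            "a_t": a_t,
        }


@dataclass
class _PairSet:
    """Raw per-haploid simulated pairs (positions in both references)."""

    starts: np.ndarray  # fragment start, hap coords
    inserts: np.ndarray
    map1: dict
    map2: dict
    seqs: Dict[int, tuple]  # pair -> (seq1, seq2) where materialised
    b1: np.ndarray
    b2: np.ndarray
    swap: np.ndarray  # end order in the emitted pair


def simulate_reads(
    layout: _HaploidLayout,
    config: SimulationConfig,
    rng: np.random.Generator,
    with_sequences: bool = False,
    seq_margin: float = 50.0,
    classify_params: ClassifyParams = ClassifyParams(),
    library: Optional[AluLibrary] = None,
) -> _PairSet:
    """Simulate one haploid chromosome's read pairs.

    The fragment count is deterministic: ``coverage * length / (2 L)``.
    Outer inserts are Gaussian; the forward read sits at the fragment
    start, the reverse-complemented read at its far end.  Sequences are
    materialised (with substitution errors at ``config.error_rate``) for
    every pair a downstream scanner may inspect: pairs with an unmapped
    or multi-mapped end on either reference, and pairs whose insert falls
    outside the model quantiles by more than ``seq_margin`` bp.  With
    ``with_sequences=True`` every sequence is materialised.
    """
    L = config.read_len
    n_pairs = int(round(config.coverage * layout.length / (2 * L)))
    model = config.insert_model()
    inserts = np.rint(rng.normal(config.insert_mean, config.insert_sd, n_pairs))
    inserts = np.clip(inserts, 2 * L, None).astype(np.int64)
    starts = rng.integers(0, np.maximum(layout.length - inserts, 1))
    r1 = starts  # forward read
    r2 = starts + inserts - L  # reverse read
    map1 = layout.map_reads(r1, L)
    map2 = layout.map_reads(r2, L)
    swap = rng.random(n_pairs) < 0.5

    # which pairs need sequences?
    any_unmapped = (
        (map1["pos_ref"] < 0) | (map2["pos_ref"] < 0)
        | (map1["pos_all"] < 0) | (map2["pos_all"] < 0)
    )
    ins_ref = np.where(
        (map1["pos_ref"] >= 0) & (map2["pos_ref"] >= 0),
        np.abs(map2["pos_ref"] - map1["pos_ref"]) + L,
        -1,
    )
    ins_all = np.where(
        (map1["pos_all"] >= 0) & (map2["pos_all"] >= 0),
        np.abs(map2["pos_all"] - map1["pos_all"]) + L,
        -1,
    )
    lo, hi = model.q_lo - seq_margin, model.q_hi + seq_margin
    odd_insert = ((ins_ref >= 0) & ((ins_ref < lo) | (ins_ref > hi))) | (
        (ins_all >= 0) & ((ins_all < lo) | (ins_all > hi))
    )
    need = any_unmapped | odd_insert
    if with_sequences:
        need = np.ones(n_pairs, dtype=bool)

    hap = layout.sequence()
    seqs: Dict[int, tuple] = {}
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    err = config.error_rate
    for i in np.flatnonzero(need):
        i = int(i)
        s1 = hap[r1[i]: r1[i] + L].copy()
        s2 = comp[hap[r2[i]: r2[i] + L]][::-1].copy()  # reverse strand read
        if err > 0:
            for s in (s1, s2):
                hit = np.flatnonzero(rng.random(L) < err)
                for j in hit:
                    choices = _BASES[_BASES != s[j]]
                    s[j] = choices[rng.integers(0, len(choices))]
        seqs[i] = (s1.tobytes().decode(), s2.tobytes().decode())

    # best-hit counts: Alu-derived reads are scored against the library
    b1 = np.ones(n_pairs, dtype=np.int32)
    b2 = np.ones(n_pairs, dtype=np.int32)
    if library is not None:
        for i in np.flatnonzero(map1["interior"] | map2["interior"]):
            i = int(i)
            s1, s2 = seqs[i]
            if map1["interior"][i]:
                b1[i] = max(1, count_library_matches(s1, library, classify_params))
            if map2["interior"][i]:
                b2[i] = max(1, count_library_matches(s2, library, classify_params))
    return _PairSet(
        starts=starts, inserts=inserts, map1=map1, map2=map2,
        seqs=seqs, b1=b1, b2=b2, swap=swap,
    )


def _pairsets_to_table(
    pairsets: Sequence[_PairSet],
    target: str,
    config: SimulationConfig,
    individual: str,
) -> AlignmentTable:
    key = "pos_ref" if target == "ref" else "pos_all"
    pos1_parts, pos2_parts, rev1_parts, rev2_parts = [], [], [], []
    b1_parts, b2_parts = [], []
    seqs: Dict[int, tuple] = {}
    offset = 0
    for ps in pairsets:
        n = len(ps.starts)
        p1 = ps.map1[key]
        p2 = ps.map2[key]
        rev_a = np.zeros(n, dtype=bool)  # forward read
        rev_b = np.ones(n, dtype=bool)
        sw = ps.swap
        pos1 = np.where(sw, p2, p1)
        pos2 = np.where(sw, p1, p2)
        rev1 = np.where(sw, rev_b, rev_a)
        rev2 = np.where(sw, rev_a, rev_b)
        b1 = np.where(sw, ps.b2, ps.b1)
        b2 = np.where(sw, ps.b1, ps.b2)
        for i, (s1, s2) in ps.seqs.items():
            seqs[offset + i] = (s2, s1) if sw[i] else (s1, s2)
        pos1_parts.append(pos1)
        pos2_parts.append(pos2)
        rev1_parts.append(rev1)
        rev2_parts.append(rev2)
        b1_parts.append(b1)
        b2_parts.append(b2)
        offset += n
    return AlignmentTable(
        chrom=config.chrom,
        read_len=config.read_len,
        pos1=np.concatenate(pos1_parts),
        pos2=np.concatenate(pos2_parts),
        rev1=np.concatenate(rev1_parts),
        rev2=np.concatenate(rev2_parts),
        b1=np.concatenate(b1_parts),
        b2=np.concatenate(b2_parts),
        individual=individual,
        seqs=seqs,
    )


@dataclass
class Cohort:
    config: SimulationConfig
    library: AluLibrary
    reference: np.ndarray  # Alu-free reference, uint8
    truth: TruthTable
    tables_ref: Dict[str, AlignmentTable] = field(default_factory=dict)
    tables_all: Dict[str, AlignmentTable] = field(default_factory=dict)

    @property
    def individuals(self) -> List[str]:
        return list(self.truth.individuals)

    def insert_model(self) -> InsertSizeModel:
        return self.config.insert_model()

    def reference_str(self) -> str:
        return self.reference.tobytes().decode()

    def all_alu_reference(self) -> np.ndarray:
        parts, prev = [], 0
        for i, r in enumerate(self.truth.sites.itertuples()):
            parts.append(self.reference[prev: r.pos])
            parts.append(self._site_seqs[i])
            prev = r.pos
        parts.append(self.reference[prev:])
        return np.concatenate(parts)

    _site_seqs: List[np.ndarray] = field(default_factory=list, repr=False)


def build_population_and_trios(
    config: SimulationConfig,
    with_sequences: bool = False,
    targets: Tuple[str, ...] = ("ref", "all"),
) -> Cohort:
    """Simulate the full cohort (population or trios) from one seed.

    Haploids are paired sequentially (0+1, 2+3, ...) into diploids named
    ``S00, S01, ...``; in trio mode (``config.n_trios > 0``) each trio
    contributes father/mother (two fresh haploids each) and a child that
    receives one uniformly chosen haploid per parent.  Identical seeds
    give byte-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    if config.library_fasta is not None:
        library = AluLibrary.from_fasta(config.library_fasta)
    else:
        library = AluLibrary.synthetic(rng, length=config.alu_length)
    if config.ref_fasta is not None:
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(config.ref_fasta), "fasta"))
        reference = np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8)
    else:
        reference = _random_reference(rng, config.ref_length)

    if config.n_trios > 0:
        n_hap = 4 * config.n_trios
    else:
        if config.n_haploids % 2 != 0:
            raise ValueError("haploid count must be even to pair diploids")
        n_hap = config.n_haploids
    cfg = replace(config, n_haploids=n_hap)
    sites, site_seqs, carriers = plant_alus(reference, cfg, rng, library)

    individuals: Dict[str, Tuple[int, int]] = {}
    trios: List[Tuple[str, str, str]] = []
    hap_pairs: List[Tuple[int, int]] = []
    if config.n_trios > 0:
        for t in range(config.n_trios):
            h = 4 * t
            fa, mo, ch = f"T{t:02d}F", f"T{t:02d}M", f"T{t:02d}C"
            individuals[fa] = (h, h + 1)
            individuals[mo] = (h + 2, h + 3)
            ch_f = h + int(rng.integers(0, 2))
            ch_m = h + 2 + int(rng.integers(0, 2))
            individuals[ch] = (ch_f, ch_m)
            trios.append((fa, mo, ch))
    else:
        for d in range(n_hap // 2):
            individuals[f"S{d:02d}"] = (2 * d, 2 * d + 1)

    truth = TruthTable(sites, carriers, individuals, trios, chrom=config.chrom)
    cohort = Cohort(
        config=config, library=library, reference=reference, truth=truth
    )
    cohort._site_seqs = site_seqs

    for name, (h1, h2) in individuals.items():
        pairsets = []
        for h in (h1, h2):
            layout = _HaploidLayout(sites, site_seqs, carriers[:, h], reference)
            pairsets.append(
                simulate_reads(
                    layout, config, rng,
                    with_sequences=with_sequences, library=library,
                )
            )
        if "ref" in targets:
            cohort.tables_ref[name] = _pairsets_to_table(
                pairsets, "ref", config, name
            )
        if "all" in targets:
            cohort.tables_all[name] = _pairsets_to_table(
                pairsets, "all", config, name
            )
    return cohort
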