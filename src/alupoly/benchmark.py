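"""End-to-end pipelines over simulated cohorts, with truth-table scoring.

These drivers wire the stages together the way the method is validated:

* ``insertion_benchmark`` — per individual: estimate the insert model,
  scan for Alu mates against the Alu-free reference, sweep + cover to
  nominate candidate insertions, refine position/length, genotype by
  reduction to the deletion algorithm, then score the detected
  (site, individual) events against the planted truth.
* ``deletion_benchmark`` — per individual: genotype every annotated locus
  against the reference containing all planted Alus and score recovered
  deletion events.
* ``trio_benchmark`` — genotype all trio members at the annotated loci
  and measure Mendelian concordance of the child's calls.

An *event* is one (site, individual) pair where the truth table has at
least one carrier haplotype (insertions) or at least one deleted
haplotype (deletions); sensitivity is events found / events expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cover import (
    CoverInstance,
    DEFAULT_K,
    DEFAULT_SWEEP_THRESHOLD,
    solve_cover_single,
    sweep_candidate_regions,
)
from .deletions import collect_spanning_set, genotype_deletion, population_lrt
from .insertmodel import InsertSizeModel, estimate_insert_model
from .mates import AluMateScanResult, scan_alu_mates
from .records import AlignmentTable, AluMate, GenotypeLikelihoods
from .refine import CandidateInsertion, genotype_insertion, refine_candidate, split_candidate
from .simulate import Cohort

__all__ = [
    "estimate_model_for_individual",
    "discover_insertions_individual",
    "insertion_benchmark",
    "deletion_benchmark",
    "trio_benchmark",
    "zero_fp_operating_point",
    "BenchmarkResult",
]

MATCH_WINDOW = 150  # bp between a called and a planted position


@dataclass
class BenchmarkResult:
    expected: int
    found: int
    false_positives: int
    details: pd.DataFrame

    @property
    def sensitivity(self) -> float:
        """Percent of expected events recovered."""
        return 100.0 * self.found / self.expected if self.expected else float("nan")


def estimate_model_for_individual(
    table: AlignmentTable, epsilon: float = 0.005
) -> InsertSizeModel:
    """Fit the insert-size model from the individual's proper unique pairs."""
    both = table.mapped1 & table.mapped2
    unique = (table.b1 == 1) & (table.b2 == 1)
    ok = both & unique & table.fr_inward
    return estimate_insert_model(table.insert[ok].astype(float), epsilon=epsilon)


def discover_insertions_individual(
    scan: AluMateScanResult,
    model: InsertSizeModel,
    k: float = DEFAULT_K,
    threshold: float = DEFAULT_SWEEP_THRESHOLD,
    read_len: int = 100,
    alu_lengths: Optional[Dict[str, int]] = None,
) -> List[CandidateInsertion]:
    """Sweep for candidate windows, solve the covering DP, merge, refine.

    The cover intervals locate the Alu *read* rather than the insertion
    point, so one true insertion typically yields an l-side and an r-side
    cover position up to an Alu length apart; positions within the
    ``2 q_hi`` evidence window are therefore merged into one candidate
    whose supports pool both read labels, and the refinement stage then
    pins down the actual insertion point.
    """
    windows = sweep_candidate_regions(scan, model, threshold=threshold)
    mates = scan.mates
    raw: List[Tuple[float, List[AluMate]]] = []
    for w0, w1 in windows:
        local = [
            m for m in mates if w0 - model.q_hi <= m.position <= w1 + model.q_hi
        ]
        if not local:
            continue
        l_ends = np.array([m.l_r for m in local if m.label == "l"], dtype=float)
        r_starts = np.array([m.r_l for m in local if m.label == "r"], dtype=float)
        ordered = [m for m in local if m.label == "l"] + [
            m for m in local if m.label == "r"
        ]
        inst = CoverInstance(
            chrom=local[0].chrom, l_ends=l_ends, r_starts=r_starts,
            read_len=read_len, q_lo=model.q_lo, q_hi=model.q_hi, k=k,
        )
        sol = solve_cover_single(inst)
        for pi, alpha in enumerate(sol.positions):
            supports = [
                ordered[ri] for ri, ai in sol.assignment.items() if ai == pi
            ]
            if supports:
                raw.append((float(alpha), supports))
    # merge cover positions belonging to one insertion
    raw.sort(key=lambda x: x[0])
    candidates: List[CandidateInsertion] = []
    i = 0
    while i < len(raw):
        j = i + 1
        while j < len(raw) and raw[j][0] - raw[j - 1][0] <= 2 * model.q_hi:
            j += 1
        group = raw[i:j]
        i = j
        supports: List[AluMate] = []
        seen = set()
        for _a, sup in group:
            for m in sup:
                key = (m.position, m.label, m.pair_index)
                if key not in seen:
                    seen.add(key)
                    supports.append(m)
        names = [m.alu for m in supports]
        top = max(set(names), key=names.count)
        fam = next(m.family for m in supports if m.alu == top)
        l_alu = (alu_lengths or {}).get(top, 300)
        alpha0 = float(np.mean([a for a, _s in group]))
        candidates.append(
            CandidateInsertion(
                chrom=supports[0].chrom, position=alpha0,
                alu=top, family=fam, l_alu=l_alu, supports=supports,
            )
        )
    final: List[CandidateInsertion] = []
    for cand in candidates:
        refine_candidate(cand)
        if cand.converged:
            final.append(cand)
            continue
        # inconsistent supports usually mean two nearby true insertions
        # merged into one window: split on the implied-position gap
        parts = split_candidate(cand)
        if len(parts) == 1:
            final.append(cand)
            continue
        for part in parts:
            refine_candidate(part)
            final.append(part)
    return final


def insertion_benchmark(
    cohort: Cohort,
    threshold: float = DEFAULT_SWEEP_THRESHOLD,
    k: float = DEFAULT_K,
    match_window: int = MATCH_WINDOW,
    scans: Optional[Dict[str, AluMateScanResult]] = None,
    models: Optional[Dict[str, InsertSizeModel]] = None,
) -> BenchmarkResult:
    """Per-individual insertion discovery + genotyping scored against truth."""
    truth = cohort.truth
    site_pos = truth.sites["pos"].to_numpy()
    alu_len = {n: len(cohort.library.sequence(n)) for n, _f, _s in cohort.library}
    rows = []
    found = 0
    fps = 0
    expected = 0
    for name in cohort.individuals:
        table = cohort.tables_ref[name]
        model = (models or {}).get(name) or estimate_model_for_individual(table)
        scan = (scans or {}).get(name) or scan_alu_mates(table, cohort.library, model)
        cands = discover_insertions_individual(
            scan, model, k=k, threshold=threshold, read_len=table.read_len,
            alu_lengths=alu_len,
        )
        truth_copies = truth.diploid_copies(name)
        expected += int((truth_copies >= 1).sum())
        hit_sites = set()
        for cand in cands:
            call = genotype_insertion(
                cand, [table], model,
                supports_by_individual={name: cand.supports},
            )
            g = call.genotypes[0]
            copies = 2 - g.genotype
            if copies < 1:
                continue
            d = np.abs(site_pos - cand.position)
            s = int(np.argmin(d))
            if d[s] <= match_window:
                if truth_copies[s] >= 1:
                    hit_sites.add(s)
                rows.append((name, s, cand.position, copies, truth_copies[s]))
            else:
                fps += 1
                rows.append((name, -1, cand.position, copies, 0))
        found += len(hit_sites)
    details = pd.DataFrame(
        rows, columns=["individual", "site", "position", "copies", "truth_copies"]
    )
    return BenchmarkResult(expected, found, fps, details)


def zero_fp_operating_point(
    cohort: Cohort,
    thresholds: Sequence[float] = (3.0, 4.0, 5.0, 6.0, 8.0, 10.0),
    scans: Optional[Dict[str, AluMateScanResult]] = None,
    models: Optional[Dict[str, InsertSizeModel]] = None,
) -> Tuple[float, BenchmarkResult]:
    """Raise the detection threshold until no false positives remain.

    Returns the threshold reached and the benchmark at that operating
    point (the last threshold if zero FP is never reached).
    """
    result = None
    for thr in thresholds:
        result = insertion_benchmark(cohort, threshold=thr, scans=scans, models=models)
        if result.false_positives == 0:
            return thr, result
    return thresholds[-1], result


def deletion_genotypes(
    cohort: Cohort,
    models: Optional[Dict[str, InsertSizeModel]] = None,
    use_weights: bool = True,
) -> Dict[str, List[GenotypeLikelihoods]]:
    """Per-individual deletion genotypes at every planted locus (all-Alu ref)."""
    annotations = cohort.truth.annotations_all_alu()
    out: Dict[str, List[GenotypeLikelihoods]] = {}
    for name in cohort.individuals:
        table = cohort.tables_all[name]
        model = (models or {}).get(name) or estimate_model_for_individual(table)
        genos = []
        for locus in annotations:
            spanning = collect_spanning_set(locus, table, model)
            genos.append(
                genotype_deletion(spanning, model, locus.l_alu, use_weights=use_weights)
            )
        out[name] = genos
    return out


def deletion_benchmark(
    cohort: Cohort,
    models: Optional[Dict[str, InsertSizeModel]] = None,
    genotypes: Optional[Dict[str, List[GenotypeLikelihoods]]] = None,
) -> BenchmarkResult:
    """Annotated-locus deletion genotyping scored against truth."""
    truth = cohort.truth
    if genotypes is None:
        genotypes = deletion_genotypes(cohort, models=models)
    rows = []
    expected = found = fps = 0
    for name in cohort.individuals:
        copies = truth.diploid_copies(name)  # Alu copies carried
        deleted = 2 - copies
        for s, g in enumerate(genotypes[name]):
            if deleted[s] >= 1:
                expected += 1
                if g.genotype >= 1:
                    found += 1
            elif g.genotype >= 1:
                fps += 1
            rows.append((name, s, g.genotype, int(deleted[s]), g.n_pairs))
    details = pd.DataFrame(
        rows, columns=["individual", "site", "called_g", "truth_g", "n_pairs"]
    )
    return BenchmarkResult(expected, found, fps, details)


@dataclass
class TrioConcordance:
    hom_total: int
    hom_match: int
    het_total: int
    het_match: int

    @property
    def hom_pct(self) -> float:
        return 100.0 * self.hom_match / self.hom_total if self.hom_total else float("nan")

    @property
    def het_pct(self) -> float:
        return 100.0 * self.het_match / self.het_total if self.het_total else float("nan")


def trio_benchmark(
    cohort: Cohort,
    genotypes: Optional[Dict[str, List[GenotypeLikelihoods]]] = None,
) -> TrioConcordance:
    """Mendelian concordance of child deletion calls with parental calls.

    A homozygote-deleted child call is consistent when both parents carry
    at least one called deletion allele; a heterozygote call is
    consistent unless both parents are called homozygote-reference or
    both homozygote-deleted.
    """
    if not cohort.truth.trios:
        raise ValueError("cohort contains no trios")
    if genotypes is None:
        genotypes = deletion_genotypes(cohort)
    hom_total = hom_match = het_total = het_match = 0
    n_sites = cohort.truth.n_sites
    for fa, mo, ch in cohort.truth.trios:
        for s in range(n_sites):
            gc = genotypes[ch][s]
            if gc.no_call:
                continue
            gf = genotypes[fa][s].genotype
            gm = genotypes[mo][s].genotype
            if gc.genotype == 2:
                hom_total += 1
                if gf >= 1 and gm >= 1:
                    hom_match += 1
            elif gc.genotype == 1:
                het_total += 1
                if not ((gf == 0 and gm == 0) or (gf == 2 and gm == 2)):
                    het_match += 1
    return TrioConcordance(hom_total, hom_match, het_total, het_match)


def population_deletion_calls(
    cohort: Cohort,
    alpha: float = 0.05,
    hwe: bool = True,
    genotypes: Optional[Dict[str, List[GenotypeLikelihoods]]] = None,
):
    """Joint LRT call per annotated locus across the cohort."""
    if genotypes is None:
        genotypes = deletion_genotypes(cohort)
    names = cohort.individuals
    calls = []
    for s in range(cohort.truth.n_sites):
        per_ind = [genotypes[n][s] for n in names]
        calls.append(population_lrt(per_ind, hwe=hwe, alpha=alpha))
    return calls
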