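"""Refinement and genotyping of candidate Alu insertions.

The true inserted element is modelled as the matched consensus of length
``l_Alu`` extended by signed offsets ``lambda`` (left) and ``rho``
(right).  Each supporting Alu-mate pair t gives a noisy linear equation
relating the anchor position ``c_t``, the within-Alu offset ``a_t``, the
individual's mean start-to-start insert ``m_t`` (sd ``s_t``) and the
insertion point ``p_Alu``:

    left supports  (anchor in [p_Alu - q_hi, p_Alu]):
        lambda^t = m_t - d_t - a_t,          d_t = p_Alu - c_t
    right supports (anchor in [p_Alu, p_Alu + q_hi]):
        rho^t    = m_t - d_t - a_t^-,        d_t = c_t - p_Alu,
                                             a_t^- = l_Alu - a_t

Maximum-likelihood estimates under Gaussian insert noise are the
inverse-variance weighted means; the position is re-estimated by
isolating ``p_Alu`` from the same equations.  Length and position
estimation alternate until the position stabilises, the element is then
spliced into the reference in silico, whereupon every individual can be
genotyped with the deletion machinery (an individual carrying the
insertion on both haplotypes matches the in-silico reference, so g
deleted haplotypes corresponds to ``2 - g`` copies of the Alu).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .deletions import SpanningSet, genotype_deletion, population_lrt
from .insertmodel import InsertSizeModel
from .records import AlignmentTable, AluMate, GenotypeLikelihoods, PopulationCall

__all__ = [
    "CandidateInsertion",
    "estimate_lambda",
    "estimate_rho",
    "reestimate_position",
    "refine_candidate",
    "insert_in_silico",
    "genotype_insertion",
]

DEFAULT_TOL = 1.0  # bp
DEFAULT_MAX_ITER = 10


@dataclass
class CandidateInsertion:
    chrom: str
    position: float  # p_Alu, insertion point on the reference
    alu: str
    family: str
    l_alu: int
    supports: List[AluMate] = field(default_factory=list)
    lam: float = 0.0
    rho: float = 0.0
    lam_se: float = np.inf
    rho_se: float = np.inf
    converged: bool = False
    iterations: int = 0

    @property
    def length(self) -> float:
        """Estimated inserted length l_Alu + lambda + rho."""
        return self.l_alu + self.lam + self.rho


def _split_supports(
    supports: Sequence[AluMate], p_alu: float
) -> Tuple[List[AluMate], List[AluMate]]:
    """Left/right supports of the insertion point.

    An ``l`` mate anchors left of the implied element and an ``r`` mate
    right of it, so the label fixes the side; unlabeled supports fall
    back to their anchor position (ties go left).
    """
    left, right = [], []
    for m in supports:
        side = m.label if m.label in ("l", "r") else (
            "l" if m.position <= p_alu else "r"
        )
        (left if side == "l" else right).append(m)
    return left, right


def _ivw(estimates: np.ndarray, sds: np.ndarray) -> Tuple[float, float]:
    prec = 1.0 / sds ** 2
    return float(np.sum(estimates * prec) / np.sum(prec)), float(np.sum(prec) ** -0.5)


def estimate_lambda(
    supports: Sequence[AluMate], p_alu: float
) -> Tuple[float, float]:
    """Left length offset from supports anchored left of ``p_alu``.

    Returns (lambda, standard error); with no left supports, (0, inf).
    """
    if not supports:
        return 0.0, np.inf
    est = np.array([m.insert_mean - (p_alu - m.position) - m.offset for m in supports])
    sds = np.array([m.insert_sd for m in supports])
    return _ivw(est, sds)


def estimate_rho(
    supports: Sequence[AluMate], p_alu: float, l_alu: int
) -> Tuple[float, float]:
    """Right length offset from supports anchored right of ``p_alu``."""
    if not supports:
        return 0.0, np.inf
    est = np.array(
        [m.insert_mean - (m.position - p_alu) - (l_alu - m.offset) for m in supports]
    )
    sds = np.array([m.insert_sd for m in supports])
    return _ivw(est, sds)


def _position_estimates(
    supports: Sequence[AluMate], lam: float, rho: float, l_alu: int, p_alu: float
) -> Tuple[np.ndarray, np.ndarray]:
    left, right = _split_supports(supports, p_alu)
    est, sds = [], []
    for m in left:
        est.append(m.position + m.insert_mean - m.offset - lam)
        sds.append(m.insert_sd)
    for m in right:
        est.append(m.position - m.insert_mean + (l_alu - m.offset) + rho)
        sds.append(m.insert_sd)
    return np.asarray(est, dtype=float), np.asarray(sds, dtype=float)


def reestimate_position(
    supports: Sequence[AluMate],
    lam: float,
    rho: float,
    l_alu: int,
    p_alu: float,
) -> float:
    """Inverse-variance combined position estimate given (lambda, rho)."""
    if not supports:
        raise ValueError("position re-estimation requires at least one support")
    est, sds = _position_estimates(supports, lam, rho, l_alu, p_alu)
    val, _se = _ivw(est, sds)
    return val


def refine_candidate(
    candidate: CandidateInsertion,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> CandidateInsertion:
    """Alternate (lambda, rho) and position estimation until stable.

    Convergence: the position moves by less than ``tol`` bp between
    iterations.  Oscillation beyond ``max_iter`` leaves the last iterate
    with ``converged=False``.
    """
    if not candidate.supports:
        candidate.converged = False
        return candidate
    # The (p, lambda, rho) system is only identified up to a shift (p+d,
    # lambda-d, rho+d): the alternation leaves the initial position on that
    # ridge.  Anchor it by an initial position pass at lambda = rho = 0,
    # i.e. assume the element matches its consensus length until the data
    # say otherwise.
    p = reestimate_position(
        candidate.supports, 0.0, 0.0, candidate.l_alu, candidate.position
    )
    candidate.position = p
    for it in range(1, max_iter + 1):
        left, right = _split_supports(candidate.supports, p)
        lam, lam_se = estimate_lambda(left, p)
        rho, rho_se = estimate_rho(right, p, candidate.l_alu)
        p_new = reestimate_position(candidate.supports, lam, rho, candidate.l_alu, p)
        candidate.lam, candidate.lam_se = lam, lam_se
        candidate.rho, candidate.rho_se = rho, rho_se
        candidate.iterations = it
        if abs(p_new - p) < tol:
            candidate.position = p_new
            candidate.converged = _supports_consistent(candidate)
            return candidate
        p = p_new
        candidate.position = p
    candidate.converged = False
    return candidate


def _supports_consistent(candidate: CandidateInsertion, factor: float = 3.0) -> bool:
    """Reject stabilised fits whose per-read position estimates disagree
    far beyond the insert noise, or whose implied element length is not
    positive (both symptoms of two merged true insertions)."""
    if candidate.length <= 0:
        return False
    est, sds = _position_estimates(
        candidate.supports, candidate.lam, candidate.rho,
        candidate.l_alu, candidate.position,
    )
    if len(est) <= 1:
        return True
    spread = float(np.sqrt(np.mean((est - candidate.position) ** 2)))
    return spread <= factor * float(np.mean(sds))


def split_candidate(
    candidate: CandidateInsertion, min_reads: int = 2, factor: float = 3.0
) -> List[CandidateInsertion]:
    """Split a candidate whose supports point at two distinct insertions.

    Per-read implied positions (at lambda = rho = 0) are sorted and cut at
    the largest gap when it exceeds ``factor`` times the mean insert sd;
    each half becomes its own candidate.  Returns the original candidate
    unchanged when no convincing split exists.
    """
    sups = candidate.supports
    if len(sups) < 2 * min_reads:
        return [candidate]
    est, sds = _position_estimates(
        sups, 0.0, 0.0, candidate.l_alu, candidate.position
    )
    # _position_estimates orders left supports before right ones
    left, right = _split_supports(sups, candidate.position)
    ordered = left + right
    order = np.argsort(est)
    gaps = np.diff(est[order])
    gi = int(np.argmax(gaps))
    if gaps[gi] <= factor * float(np.mean(sds)):
        return [candidate]
    groups = [order[: gi + 1], order[gi + 1:]]
    if any(len(g) < min_reads for g in groups):
        return [candidate]
    out = []
    for g in groups:
        out.append(
            CandidateInsertion(
                chrom=candidate.chrom,
                position=float(np.mean(est[g])),
                alu=candidate.alu,
                family=candidate.family,
                l_alu=candidate.l_alu,
                supports=[ordered[i] for i in g],
            )
        )
    return out


@dataclass
class CoordinateMap:
    """Translation between original and Alu-inserted coordinates."""

    insertion_point: int
    inserted_length: int

    def to_modified(self, pos):
        pos = np.asarray(pos)
        out = np.where(pos >= self.insertion_point, pos + self.inserted_length, pos)
        return out if out.ndim else int(out)

    def to_original(self, pos):
        pos = np.asarray(pos)
        out = np.where(pos >= self.insertion_point, pos - self.inserted_length, pos)
        return out if out.ndim else int(out)


def insert_in_silico(
    segment: str,
    candidate: CandidateInsertion,
    consensus: str,
    segment_offset: int = 0,
) -> Tuple[str, CoordinateMap]:
    """Splice the estimated element into a reference segment.

    The consensus is trimmed (negative offsets) or padded with copies of
    its flanking bases (positive offsets) to the estimated length.
    ``segment_offset`` is the reference coordinate of ``segment[0]``.
    """
    length = int(round(candidate.length))
    if length <= 0:
        raise ValueError(f"estimated insertion length must be positive, got {length}")
    lam = int(round(candidate.lam))
    rho = int(round(candidate.rho))
    seq = consensus
    if lam < 0:
        seq = seq[-lam:]
    elif lam > 0:
        seq = seq[:1] * lam + seq
    if rho < 0:
        seq = seq[: len(seq) + rho] if rho > -len(seq) else seq[:1]
    elif rho > 0:
        seq = seq + seq[-1:] * rho
    p = int(round(candidate.position)) - segment_offset
    if not (0 <= p <= len(segment)):
        raise ValueError("insertion point lies outside the provided segment")
    modified = segment[:p] + seq + segment[p:]
    return modified, CoordinateMap(
        insertion_point=p + segment_offset, inserted_length=len(seq)
    )


def spanning_set_for_insertion(
    candidate: CandidateInsertion,
    alignments: AlignmentTable,
    model: InsertSizeModel,
    supports: Optional[Sequence[AluMate]] = None,
) -> SpanningSet:
    """Informative pairs at the candidate site, in in-silico coordinates.

    Ordinary pairs with both ends in the window keep their insert if both
    ends fall on one side of the insertion point and gain the inserted
    length if they straddle it (reads overlapping the point itself would
    be split on the in-silico reference and are ignored).  The
    individual's Alu mates realign into the inserted element via their
    within-consensus offsets.
    """
    M = int(round(candidate.length))
    p = candidate.position
    L = alignments.read_len
    w0 = p - model.q_hi - L
    w1 = p + model.q_hi + L
    lstart = alignments.leftmost_start
    rend = alignments.rightmost_end
    both = alignments.mapped1 & alignments.mapped2
    lo = np.searchsorted(lstart, w0, side="left")
    hi = np.searchsorted(lstart, w1, side="right")
    sel = np.arange(lo, hi)
    sel = sel[both[sel] & (rend[sel] <= w1)]
    ls, re_ = lstart[sel], rend[sel]
    left_read_end = np.minimum(ls + L, re_)  # end of the leftmost read
    right_read_start = re_ - L
    # informative ordinary pairs are those whose fragment spans the
    # insertion point with neither read crossing it (reads over the point
    # would be split on the in-silico reference); their insert gains the
    # inserted length.  One-sided flanking pairs carry no information.
    straddle = (left_read_end <= p) & (right_read_start >= p)
    inserts = (re_ - ls)[straddle].astype(float) + M
    weights = alignments.weight[sel][straddle]

    extra_t: List[float] = []
    extra_w: List[float] = []
    for m in supports or []:
        # implied Alu-read start inside the in-silico element
        a = min(max(m.offset + int(round(candidate.lam)), 0), max(M - L, 0))
        pos_in = p + a
        if m.label == "l":
            tt = (pos_in + L) - m.position
        else:
            tt = (m.position + M + L) - pos_in
        if tt > 0:
            extra_t.append(float(tt))
            extra_w.append(m.weight)
    if extra_t:
        inserts = np.concatenate([inserts, extra_t])
        weights = np.concatenate([weights, extra_w])
    return SpanningSet(
        locus_id=f"{candidate.chrom}:{int(round(p))}<INS>",
        individual=alignments.individual,
        inserts=inserts,
        weights=weights,
        window=(w0, w1),
    )


def genotype_insertion(
    candidate: CandidateInsertion,
    individuals: Sequence[AlignmentTable],
    models,
    supports_by_individual: Optional[Dict[str, Sequence[AluMate]]] = None,
    hwe: bool = True,
    alpha: float = 0.05,
    use_weights: bool = True,
) -> PopulationCall:
    """Genotype all individuals at a refined insertion.

    Reduction to the deletion algorithm against the in-silico reference:
    an individual's number of inserted-Alu copies is ``2 - g`` where g is
    the deletion genotype on the in-silico reference.
    """
    M = max(int(round(candidate.length)), 1)
    genos: List[GenotypeLikelihoods] = []
    for table in individuals:
        model = models[table.individual] if isinstance(models, dict) else models
        sup = None
        if supports_by_individual is not None:
            sup = supports_by_individual.get(table.individual, [])
        spanning = spanning_set_for_insertion(candidate, table, model, supports=sup)
        genos.append(genotype_deletion(spanning, model, M, use_weights=use_weights))
    return population_lrt(genos, hwe=hwe, alpha=alpha)
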