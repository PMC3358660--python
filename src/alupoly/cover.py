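"""Candidate-insertion discovery by interval covering.

Every ``l``/``r`` Alu mate constrains the position alpha of the implied
Alu to an interval: an alpha covers an l read when
``l_r + q_lo - L <= alpha <= l_r + q_hi`` and an r read when
``r_l - q_hi <= alpha <= r_l - q_lo + L`` (``L`` the read length).  The
single-individual problem asks for a set ``A`` of Alu positions and a set
``E`` of error-labelled reads minimising ``|E| + k|A|`` with every read
covered or in ``E``; on a line this is interval stabbing with outliers,
solved exactly by dynamic programming over interval endpoints.  Across
individuals the objective becomes ``|E| + k1|A| + k2*sum_j |A_j|`` (cost
per population Alu plus cost per individual carrying it), for which a
windowing/merging heuristic is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .insertmodel import InsertSizeModel
from .records import AluMate

__all__ = [
    "CoverInstance",
    "CoverSolution",
    "cover_interval",
    "solve_cover_single",
    "sweep_candidate_regions",
    "solve_cover_multi",
    "verify_cover",
]

DEFAULT_K = 3
DEFAULT_K1 = 2
DEFAULT_K2 = 2
DEFAULT_SWEEP_THRESHOLD = 3.0


@dataclass
class CoverInstance:
    """One chromosome's l/r reads plus the model constants."""

    chrom: str
    l_ends: np.ndarray  # right endpoints l_r of l reads
    r_starts: np.ndarray  # left endpoints r_l of r reads
    read_len: int
    q_lo: float
    q_hi: float
    k: float = DEFAULT_K
    l_weights: Optional[np.ndarray] = None
    r_weights: Optional[np.ndarray] = None

    def intervals(self) -> np.ndarray:
        """(n, 2) array of admissible alpha intervals, l reads first."""
        ivs = [
            cover_interval(float(e), "l", self.q_lo, self.q_hi, self.read_len)
            for e in self.l_ends
        ] + [
            cover_interval(float(s), "r", self.q_lo, self.q_hi, self.read_len)
            for s in self.r_starts
        ]
        return np.asarray(ivs, dtype=float).reshape(-1, 2)


@dataclass
class CoverSolution:
    positions: List[float]  # A
    errors: List[int]  # E, indices into the instance's reads (l first)
    assignment: Dict[int, int] = field(default_factory=dict)  # read -> index in A
    objective: float = 0.0
    individuals: Dict[float, set] = field(default_factory=dict)  # A_j for multi


def cover_interval(
    endpoint: float, kind: str, q_lo: float, q_hi: float, read_len: int
) -> Tuple[float, float]:
    """Admissible Alu positions for one read.

    ``endpoint`` is ``l_r`` (right endpoint) for an l read and ``r_l``
    (left endpoint) for an r read.
    """
    if kind == "l":
        return (endpoint + q_lo - read_len, endpoint + q_hi)
    if kind == "r":
        return (endpoint - q_hi, endpoint - q_lo + read_len)
    raise ValueError(f"kind must be 'l' or 'r', got {kind!r}")


def _components(intervals: np.ndarray) -> List[np.ndarray]:
    """Groups of reads whose intervals overlap transitively."""
    if len(intervals) == 0:
        return []
    order = np.argsort(intervals[:, 0], kind="stable")
    groups: List[List[int]] = []
    cur: List[int] = []
    reach = -np.inf
    for i in order:
        a, b = intervals[i]
        if cur and a > reach:
            groups.append(cur)
            cur = []
            reach = -np.inf
        cur.append(int(i))
        reach = max(reach, b)
    if cur:
        groups.append(cur)
    return [np.asarray(g) for g in groups]


def _solve_component(
    a: np.ndarray, b: np.ndarray, k: float
) -> Tuple[float, int, List[float], np.ndarray]:
    """Exact DP on one overlapping component.

    Returns (objective, n_errors, chosen positions, covering position per
    read, -1 for errors).  Ties broken toward fewer errors, then the
    lexicographically leftmost position set.
    """
    n = len(a)
    cand = np.unique(a)  # some optimum stabs at interval left endpoints
    c = len(cand)

    # best[j] = (cost, errors, positions) with cand[j] the last chosen point,
    # accounting only reads finished (b_i < cand[j]).
    INF = (np.inf, 0, ())
    best: List[Tuple[float, int, tuple]] = [INF] * (c + 1)
    best[0] = (0.0, 0, ())  # no point chosen yet

    def miss_between(p_prev: Optional[float], p_next: Optional[float]) -> int:
        """Reads whose interval ends before p_next and that p_prev missed."""
        lo = -np.inf if p_prev is None else p_prev
        hi = np.inf if p_next is None else p_next
        mask = (b >= lo) & (b < hi)
        if p_prev is not None:
            mask &= a > p_prev
        return int(mask.sum())

    for j in range(1, c + 1):
        pj = cand[j - 1]
        options = []
        cost0, err0, pos0 = best[0]
        m = miss_between(None, pj)
        options.append((cost0 + m + k, err0 + m, pos0 + (pj,)))
        for jp in range(1, j):
            pprev = cand[jp - 1]
            costp, errp, posp = best[jp]
            if not np.isfinite(costp):
                continue
            m = miss_between(pprev, pj)
            options.append((costp + m + k, errp + m, posp + (pj,)))
        best[j] = min(options, key=lambda t: (t[0], t[1], t[2]))

    finals = []
    for j in range(0, c + 1):
        costj, errj, posj = best[j]
        if not np.isfinite(costj):
            continue
        pj = None if j == 0 else cand[j - 1]
        lo = -np.inf if pj is None else pj
        mask = b >= lo
        if pj is not None:
            mask &= a > pj
        m = int(mask.sum())
        finals.append((costj + m, errj + m, posj))
    obj, nerr, positions = min(finals, key=lambda t: (t[0], t[1], t[2]))

    cover_pos = np.full(n, np.nan)
    for p in positions:
        covered = (a <= p) & (p <= b) & np.isnan(cover_pos)
        cover_pos[covered] = p
    return obj, nerr, list(positions), cover_pos


def solve_cover_single(instance: CoverInstance) -> CoverSolution:
    """Optimal |E| + k|A| covering for one individual's reads."""
    ivs = instance.intervals()
    n = len(ivs)
    if n == 0:
        return CoverSolution(positions=[], errors=[], objective=0.0)
    positions: List[float] = []
    errors: List[int] = []
    assignment: Dict[int, int] = {}
    objective = 0.0
    for comp in _components(ivs):
        a, b = ivs[comp, 0], ivs[comp, 1]
        obj, _nerr, pos, cover_pos = _solve_component(a, b, instance.k)
        objective += obj
        base = len(positions)
        positions.extend(pos)
        pos_index = {p: base + i for i, p in enumerate(pos)}
        for local, read in enumerate(comp):
            p = cover_pos[local]
            if np.isnan(p):
                errors.append(int(read))
            else:
                assignment[int(read)] = pos_index[p]
    return CoverSolution(
        positions=positions, errors=sorted(errors),
        assignment=assignment, objective=objective,
    )


def verify_cover(instance: CoverInstance, solution: CoverSolution) -> bool:
    """Independent feasibility check: every read covered or in E."""
    ivs = instance.intervals()
    err = set(solution.errors)
    for i, (a, b) in enumerate(ivs):
        if i in err:
            continue
        if not any(a <= p <= b for p in solution.positions):
            return False
    expected = len(solution.errors) + instance.k * len(solution.positions)
    return abs(expected - solution.objective) < 1e-9


def sweep_candidate_regions(
    mates,
    model: InsertSizeModel,
    threshold: float = DEFAULT_SWEEP_THRESHOLD,
) -> List[Tuple[int, int]]:
    """Single left-to-right pass locating likely Alu regions.

    The indicator at position p is the (1/b-weighted) number of l anchors
    whose right endpoint lies within ``q_hi`` to the left of p plus the
    number of r anchors starting within ``q_hi`` to the right of p; it is
    piecewise constant, so it is evaluated only at read endpoints.
    Maximal runs with indicator >= ``threshold`` become candidate windows.

    ``mates`` may be an :class:`~alupoly.mates.AluMateScanResult` or a
    sequence of :class:`AluMate`.
    """
    mate_list = mates.mates if hasattr(mates, "mates") else list(mates)
    if not mate_list:
        return []
    q_hi = model.q_hi
    l_ends = np.array(sorted(m.l_r for m in mate_list if m.label == "l"), dtype=float)
    l_w = np.ones_like(l_ends)
    r_starts = np.array(sorted(m.r_l for m in mate_list if m.label == "r"), dtype=float)
    r_w = np.ones_like(r_starts)
    # weights sorted along with positions
    lw = sorted(((m.l_r, m.weight) for m in mate_list if m.label == "l"))
    rw = sorted(((m.r_l, m.weight) for m in mate_list if m.label == "r"))
    l_w = np.array([w for _p, w in lw], dtype=float)
    r_w = np.array([w for _p, w in rw], dtype=float)
    l_cum = np.concatenate([[0.0], np.cumsum(l_w)])
    r_cum = np.concatenate([[0.0], np.cumsum(r_w)])

    events = np.unique(
        np.concatenate([l_ends, l_ends + q_hi, r_starts, r_starts - q_hi])
    )

    def indicator(p: np.ndarray) -> np.ndarray:
        # l anchors with l_r in [p - q_hi, p]
        hi = np.searchsorted(l_ends, p, side="right")
        lo = np.searchsorted(l_ends, p - q_hi, side="left")
        li = l_cum[hi] - l_cum[lo]
        # r anchors with r_l in [p, p + q_hi]
        hi = np.searchsorted(r_starts, p + q_hi, side="right")
        lo = np.searchsorted(r_starts, p, side="left")
        ri = r_cum[hi] - r_cum[lo]
        return li + ri

    vals = indicator(events)
    above = vals >= threshold
    windows: List[Tuple[int, int]] = []
    start = None
    for p, ok in zip(events, above):
        if ok and start is None:
            start = p
        elif not ok and start is not None:
            windows.append((int(start), int(p)))
            start = None
    if start is not None:
        windows.append((int(start), int(events[-1]) + 1))
    return windows


def _cluster_positions(
    positions: np.ndarray, max_span: float
) -> List[np.ndarray]:
    """Single-linkage clusters where consecutive gaps keep span <= max_span."""
    if len(positions) == 0:
        return []
    order = np.argsort(positions, kind="stable")
    clusters: List[List[int]] = [[int(order[0])]]
    for i in order[1:]:
        cur = clusters[-1]
        if positions[i] - positions[cur[0]] <= max_span:
            cur.append(int(i))
        else:
            clusters.append([int(i)])
    return [np.asarray(c) for c in clusters]


def solve_cover_multi(
    per_individual: Dict[str, Sequence[AluMate]],
    model: InsertSizeModel,
    k1: float = DEFAULT_K1,
    k2: float = DEFAULT_K2,
    merge_dist: Optional[float] = None,
    min_reads: int = 2,
    read_len: int = 100,
) -> CoverSolution:
    """Heuristic for the multi-individual covering objective.

    Per individual, windows of size ``2*q_hi`` holding at least
    ``min_reads`` l/r reads nominate a candidate position (midpoint of the
    intersection of the reads' cover intervals, or their mean when the
    intersection is empty); candidates within ``merge_dist`` across
    individuals merge into one population Alu; an individual joins an
    Alu's carrier set ``A_j`` when its local evidence reaches
    ``min_reads``, otherwise its reads are error-labelled.
    """
    if merge_dist is None:
        merge_dist = model.q_hi
    cand_pos: List[float] = []
    cand_indiv: List[str] = []
    cand_reads: List[List[AluMate]] = []
    errors: List[AluMate] = []
    for indiv, mates in per_individual.items():
        mates = sorted(mates, key=lambda m: m.position)
        if not mates:
            continue
        pos = np.array([m.position for m in mates], dtype=float)
        for cluster in _cluster_positions(pos, 2 * model.q_hi):
            cluster_mates = [mates[i] for i in cluster]
            if len(cluster_mates) < min_reads:
                errors.extend(cluster_mates)
                continue
            ivs = np.array(
                [
                    cover_interval(
                        m.l_r if m.label == "l" else m.r_l,
                        m.label, model.q_lo, model.q_hi, read_len,
                    )
                    for m in cluster_mates
                ]
            )
            # pick the interval start covering the most cluster reads
            # (ties toward the leftmost); reads it misses are errors, so
            # the heuristic always returns a feasible covering
            starts = np.unique(ivs[:, 0])
            n_cov = (
                (ivs[:, 0][:, None] <= starts[None, :])
                & (starts[None, :] <= ivs[:, 1][:, None])
            ).sum(axis=0)
            alpha = float(starts[int(np.argmax(n_cov))])
            covered = (ivs[:, 0] <= alpha) & (alpha <= ivs[:, 1])
            missed = [m for m, c in zip(cluster_mates, covered) if not c]
            kept = [m for m, c in zip(cluster_mates, covered) if c]
            if len(kept) < min_reads:
                errors.extend(cluster_mates)
                continue
            errors.extend(missed)
            cand_pos.append(alpha)
            cand_indiv.append(indiv)
            cand_reads.append(kept)

    solution = CoverSolution(positions=[], errors=[], objective=0.0)
    if cand_pos:
        arr = np.asarray(cand_pos)
        for cluster in _cluster_positions(arr, merge_dist):
            members = [(cand_indiv[i], cand_reads[i], arr[i]) for i in cluster]
            weights = np.array([len(r) for _i, r, _p in members], dtype=float)
            pos = float(np.average([p for _i, _r, p in members], weights=weights))
            solution.positions.append(pos)
            solution.individuals[pos] = {i for i, _r, _p in members}
    n_err = len(errors)
    solution.errors = list(range(n_err))  # error reads counted as units
    solution.error_mates = errors  # type: ignore[attr-defined]
    solution.objective = (
        n_err + k1 * len(solution.positions)
        + k2 * sum(len(s) for s in solution.individuals.values())
    )
    return solution
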