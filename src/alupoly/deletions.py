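"""Genotyping annotated Alu loci for deletion, per individual and jointly.

At an annotated locus, read pairs with both ends inside a window
stretching ``q_hi`` beyond the locus form the informative set ``T``.  On
a haplotype carrying the Alu, spanning inserts follow ``Y``; on a
haplotype where the Alu is deleted they follow ``Z = Y + l_Alu``.  With
``g`` the number of deletion-bearing haplotypes::

    log P(D|0) = sum_t log Y(t)
    log P(D|1) = sum_t log( (1/3) Z(t) + (2/3) Y(t) )
    log P(D|2) = sum_t log Z(t)

The heterozygote mixture weights come from the sampling argument that a
pair landing in the window arises in one of three equally likely ways:
from the deleted haplotype (a Z insert), or from the Alu haplotype with
one end inside the element and the other to its left or to its right
(both Y inserts).  Across individuals a likelihood-ratio statistic tests
whether any deletion allele segregates; under Hardy-Weinberg equilibrium
the alternative has one free parameter (the allele frequency p) and the
statistic is compared to chi-square with 1 df (2 df in the
unconstrained genotype-frequency form).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .insertmodel import InsertSizeModel
from .records import (
    AlignmentTable,
    AluAnnotation,
    GenotypeLikelihoods,
    PopulationCall,
)

__all__ = [
    "SpanningSet",
    "collect_spanning_set",
    "genotype_deletion",
    "population_lrt",
    "scan_deletions",
]


@dataclass
class SpanningSet:
    """Informative pairs at one locus for one individual."""

    locus_id: str
    individual: str
    inserts: np.ndarray  # observed insert length t per pair
    weights: np.ndarray
    window: tuple  # (start, end) used

    @property
    def n(self) -> int:
        return len(self.inserts)


def collect_spanning_set(
    locus: AluAnnotation,
    alignments: AlignmentTable,
    model: InsertSizeModel,
    alu_mates: Optional[Sequence] = None,
    ref_length: Optional[int] = None,
) -> SpanningSet:
    """Pairs with both ends inside the locus window.

    The window is ``[start - q_hi, end + q_hi]``.  ``l``/``r`` Alu mates
    anchored in the window (passed in from the scanner) are realigned to
    the locus Alu: their insert is recomputed against the Alu coordinates
    from the within-Alu offset ``a_t``.  Pairs with only one end in the
    window that are not Alu mates are ignored.
    """
    if locus.start < 0 or (ref_length is not None and locus.end > ref_length):
        raise ValueError(
            f"locus {locus.chrom}:{locus.start}-{locus.end} lies outside the reference"
        )
    w0 = locus.start - model.q_hi
    w1 = locus.end + model.q_hi
    lstart = alignments.leftmost_start
    rend = alignments.rightmost_end
    both = alignments.mapped1 & alignments.mapped2
    lo = np.searchsorted(lstart, w0, side="left")
    hi = np.searchsorted(lstart, w1, side="right")
    sel = np.arange(lo, hi)
    sel = sel[both[sel] & (rend[sel] <= w1)]
    # only pairs interacting with the element are informative: a pair with
    # one end inside it (Y on an Alu haplotype) or spanning the locus
    # (Z on a deleted haplotype); purely flanking pairs say nothing
    touches = (lstart[sel] < locus.end) & (rend[sel] > locus.start)
    sel = sel[touches]
    inserts = (rend[sel] - lstart[sel]).astype(float)
    weights = alignments.weight[sel]

    extra_t: List[float] = []
    extra_w: List[float] = []
    if alu_mates:
        L = alignments.read_len
        for m in alu_mates:
            if not (w0 <= m.position <= w1):
                continue
            # realign the Alu end onto the annotated element
            alu_read_start = locus.start + min(m.offset, max(locus.l_alu - L, 0))
            if m.label == "l":
                t = (alu_read_start + L) - m.position
            else:
                t = (m.position + L) - alu_read_start
            if t > 0:
                extra_t.append(float(t))
                extra_w.append(m.weight)
    if extra_t:
        inserts = np.concatenate([inserts, extra_t])
        weights = np.concatenate([weights, extra_w])
    return SpanningSet(
        locus_id=f"{locus.chrom}:{locus.start}-{locus.end}",
        individual=alignments.individual,
        inserts=inserts,
        weights=weights,
        window=(w0, w1),
    )


def genotype_deletion(
    spanning: SpanningSet,
    model: InsertSizeModel,
    l_alu: float,
    use_weights: bool = True,
) -> GenotypeLikelihoods:
    """Per-individual genotype likelihoods at one annotated locus.

    Ties in the argmax go to the smaller ``g``.  An empty spanning set
    yields all-zero log-likelihoods and a no-call.
    """
    if l_alu <= 0:
        raise ValueError(f"l_alu must be positive, got {l_alu}")
    t = spanning.inserts
    if len(t) == 0:
        return GenotypeLikelihoods(
            locus_id=spanning.locus_id, individual=spanning.individual,
            loglik=np.zeros(3), genotype=0, n_pairs=0,
        )
    w = spanning.weights if use_weights else np.ones_like(t)
    log_y = np.log(model.density(t))
    log_z = np.log(model.shifted_density(t, l_alu))
    log_het = logsumexp(
        np.stack([log_z + np.log(1.0 / 3.0), log_y + np.log(2.0 / 3.0)]), axis=0
    )
    loglik = np.array(
        [np.sum(w * log_y), np.sum(w * log_het), np.sum(w * log_z)]
    )
    g = int(np.argmax(np.round(loglik, 12)))  # ties -> smaller g
    return GenotypeLikelihoods(
        locus_id=spanning.locus_id, individual=spanning.individual,
        loglik=loglik, genotype=g, n_pairs=len(t),
    )


def _hwe_loglik(p: float, ll: np.ndarray) -> float:
    """Joint log-likelihood under HWE weights ((1-p)^2, 2p(1-p), p^2)."""
    w = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
    with np.errstate(divide="ignore"):
        logw = np.log(w)
    return float(np.sum(logsumexp(ll + logw[None, :], axis=1)))


def _fit_genotype_freqs(ll: np.ndarray, n_iter: int = 500, tol: float = 1e-10):
    """EM for the unconstrained mixture over (f0, f1, f2) on the simplex."""
    f = np.full(3, 1.0 / 3.0)
    last = -np.inf
    for _ in range(n_iter):
        with np.errstate(divide="ignore"):
            logpost = ll + np.log(f)[None, :]
        norm = logsumexp(logpost, axis=1)
        resp = np.exp(logpost - norm[:, None])
        f = resp.mean(axis=0)
        cur = float(norm.sum())
        if cur - last < tol:
            break
        last = cur
    return f, float(np.sum(logsumexp(ll + np.log(np.maximum(f, 1e-300))[None, :], axis=1)))


def population_lrt(
    per_individual: Sequence[GenotypeLikelihoods],
    hwe: bool = True,
    alpha: float = 0.05,
) -> PopulationCall:
    """Likelihood-ratio test for a segregating deletion across individuals.

    With ``hwe=True`` (default) the alternative maximises over the allele
    frequency p in [0, 1] and the statistic is referred to chi-square
    with 1 df; otherwise the genotype frequencies (f0, f1, f2) are free
    on the simplex and 2 df are used.  The null is every individual
    homozygous for the reference (all weight on P(D_i|0)); since the null
    lies on the alternative's boundary the test is conservative.
    """
    if not per_individual:
        raise ValueError("population_lrt requires at least one individual")
    ll = np.stack([g.loglik for g in per_individual])  # (m, 3)
    null = float(ll[:, 0].sum())
    if hwe:
        res = optimize.minimize_scalar(
            lambda p: -_hwe_loglik(p, ll), bounds=(0.0, 1.0),
            method="bounded", options={"xatol": 1e-6},
        )
        cand = [0.0, 1.0, float(res.x)]
        lls = [_hwe_loglik(p, ll) for p in cand]
        best = int(np.argmax(lls))
        p_hat, alt = cand[best], lls[best]
        df = 1
        freqs = None
    else:
        freqs, alt = _fit_genotype_freqs(ll)
        p_hat = float(freqs[2] + freqs[1] / 2.0)
        df = 2
    statistic = max(0.0, 2.0 * (alt - null))
    p_value = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return PopulationCall(
        locus_id=per_individual[0].locus_id,
        genotypes=list(per_individual),
        allele_freq=p_hat,
        statistic=statistic,
        p_value=p_value,
        df=df,
        genotype_freqs=None if freqs is None else np.asarray(freqs),
        significant=p_value <= alpha,
    )


def scan_deletions(
    annotations: Sequence[AluAnnotation],
    individuals: Sequence[AlignmentTable],
    models,
    alpha: float = 0.05,
    hwe: bool = True,
    use_weights: bool = True,
) -> List[PopulationCall]:
    """Genotype every annotated locus in every individual and test jointly.

    ``models`` is a single :class:`InsertSizeModel` shared by all
    individuals or a mapping from individual id to model.  Loci passing
    the LRT threshold are flagged ``significant``; the per-individual
    Alu copy number is ``2 - g``.
    """
    annotations = sorted(annotations, key=lambda a: (a.chrom, a.start))
    calls: List[PopulationCall] = []
    for locus in annotations:
        genos = []
        for table in individuals:
            model = models[table.individual] if isinstance(models, dict) else models
            spanning = collect_spanning_set(locus, table, model)
            genos.append(
                genotype_deletion(spanning, model, locus.l_alu, use_weights=use_weights)
            )
        calls.append(population_lrt(genos, hwe=hwe, alpha=alpha))
    return calls
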