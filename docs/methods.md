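# Methods

This note records the model, the numerical choices, and what the
simulated benchmark does and does not demonstrate.

## Insert-size model

All inference is driven by the distribution *Y* of paired-end outer
insert lengths (rightmost end − leftmost start; all coordinates in the
package are 0-based half-open). `estimate_insert_model` fits *Y* from
proper, uniquely mapped pairs with robust statistics: mean = median,
sd = 1.4826 × MAD, and the ε / 1−ε quantiles taken empirically
(ε = 0.005, configurable; at least 100 pairs are required and a
zero-spread input is rejected). Two density forms are available: a
Gaussian parameterised by the robust estimates (default) and an opt-in
smoothed-histogram empirical form. The Gaussian default reflects how
the mean/sd pair is used by the downstream inverse-variance estimators;
nothing else in the likelihood machinery assumes normality. Both forms
are floored at 1e-300 so that log-likelihood sums over many pairs stay
finite. The shifted distribution is evaluated exactly as
Z(t) = Y(t − l_Alu).

## Alu-read classification and the mate scan

A read is an Alu read when a semi-global (infix) alignment of the full
read against a library consensus — both strands, via edlib — reaches
90% identity (identity = 1 − edit distance / read length; threshold
configurable). Reads only partly Alu-derived (junction reads) pay edits
for the non-Alu part and fail the threshold, which is intended: they
carry no usable insert-length signal here and split-read evidence is out
of scope. The scanner touches each pair once; only ends of improper
pairs are ever classified, and those only after a shared-13-mer screen,
so the scan stays linear in the number of reads with a small constant.
Anchors on the + strand expect their mate downstream, so the implied
element is to the right and the anchor is an `l` read; − strand anchors
are `r` reads. The anchor must map uniquely (b = 1); multi-mapping
reads contribute elsewhere only through their weight 1/b.

## Deletion genotyping

The informative set *T* at an annotated locus holds pairs with both ends
inside the window (element ± Y_{1−ε}) **that interact with the
element**: one end inside it, or the fragment spanning it. Purely
flanking pairs are excluded — they are equally likely under every
genotype and, left in, their Y-likelihood mass systematically pulls
homozygous-deleted calls toward the heterozygote. `l`/`r` Alu mates
anchored in the window are realigned to the locus element through their
within-consensus offsets and contribute a recomputed insert. The
heterozygote per-pair mixture is ⅓Z + ⅔Y, from the sampling argument
that a window pair arises in three equally likely ways (deleted
haplotype; Alu haplotype anchored left; Alu haplotype anchored right).
Read weights 1/b multiply the per-pair log factors (configurable off).
Ties in the genotype argmax go to the smaller g; an empty *T* is an
explicit no-call.

The population test maximises the joint likelihood over the allele
frequency p (HWE form, scipy bounded scalar minimisation to 1e-6) or
over the genotype-frequency simplex (EM), and refers the statistic to
χ² with 1 or 2 df. The null (p = 0) sits on the boundary of the
alternative, so the test is conservative; the acceptance suite verifies
empirical type-I ≤ 0.06 at α = 0.05. Multiple-testing control across
loci defaults to Bonferroni in the CLI layer and is configurable.

## Insertion discovery

Candidate regions come from a single sweep: at position p the indicator
sums (1/b-weighted) `l` anchors ending within Y_{1−ε} to the left and
`r` anchors starting within Y_{1−ε} to the right; runs above the
threshold (default 3, mirroring k) become windows. Within a window the
exact interval-stabbing DP minimises |E| + k|A| over candidate positions
restricted to interval left endpoints (a standard exchange argument
preserves optimality); ties break toward fewer errors, then the leftmost
position set. Because a mate's cover interval locates the Alu *read*
rather than the insertion point, one true insertion yields an l-side and
an r-side cover position up to an element length apart; cover positions
within 2·Y_{1−ε} are therefore merged into a single candidate pooling
both labels before refinement. The multi-individual heuristic windows
each individual (≥ 2 reads within 2·Y_{1−ε}), picks the interval start
covering the most cluster reads, sends uncovered reads to E (so its
output is always a feasible cover and its objective bounds the pooled
single-individual optimum from below by construction), and merges
per-individual candidates within Y_{1−ε}.

## Refinement

Each support gives a linear equation in (p_Alu, λ, ρ); λ and ρ are
inverse-variance weighted means and the position the analogous combined
estimate. The system is only identified up to the shift
(p + d, λ − d, ρ + d), so the alternation cannot move the position off
its starting ridge; refinement therefore begins with a position pass at
λ = ρ = 0 — i.e. the element is assumed consensus-length until the data
say otherwise — and then alternates (tol 1 bp, max 10 iterations).
Support sides are fixed by the l/r label, not the anchor's position
relative to the current estimate, which keeps the estimators valid while
the position is still mislocalised. A stabilised fit is rejected
(non-converged) when the implied element length is non-positive or when
the per-read position estimates scatter more than three times the mean
insert sd — both symptoms of two true insertions merged into one
candidate; such candidates are split at the largest gap in the per-read
implied positions and each half refined separately. In-silico insertion
splices the consensus (trimmed or flank-padded by the rounded λ, ρ) at
the estimated point and returns an exact coordinate map; genotyping then
reduces to the deletion algorithm, with ordinary straddling pairs gaining
the inserted length and Alu mates realigned into the element. Reads
overlapping the insertion point itself would be split on the in-silico
reference and are ignored. Inserted-Alu copy number is reported as
2 − g.

## Simulator

The generator reproduces the published benchmark design, which is also
its default configuration: a 2 Mb uniform-random reference (a FASTA may
be substituted), five ~300 bp consensus entries (seeded random stand-ins
named for AluYa5/AluYb8/AluYb9/AluYk13/AluJo; a real consensus FASTA may
be supplied), 10 sites per consensus each carrying an independent 3%
per-base mutated copy, one frequency from
{2, 4, 5, 10, 20, 80, 90, 94, 96, 98}% per site (each consensus's ten
sites receive the ladder once), 100 haploid chromosomes with independent
Bernoulli carrier status, sequential pairing into 50 diploids, 5×
coverage per haploid, 100 bp reads, Gaussian(400, 50) outer inserts, and
0% or 2% uniform substitution error. Sites keep at least Y_{1−ε} bp
apart and avoid N-rich windows. Trio mode simulates two fresh haploids
per parent and transmits one uniformly chosen haploid from each parent
to the child, whose reads are simulated independently. Read length
(100 bp) and the insert model (Gaussian(400, 50)) are this package's
declared, configurable assumptions, typical of Illumina paired-end
libraries of the era this benchmark design reflects.

Alignments are produced by construction rather than by running a mapper:
a read wholly inside a planted element is unmapped on the Alu-free
reference (its sequence is kept for the classifier), a read crossing an
insertion/deletion junction of the target reference is unmapped
(split-read evidence is a non-goal), and every other read maps uniquely
at its true position, against both the Alu-free and the all-Alu
reference. Sequences are materialised exactly for the pairs a scanner
can ever inspect — unmapped or multi-mapped ends and pairs with inserts
outside the model quantiles by a 50 bp margin — with substitution errors
drawn at materialisation; `with_sequences=True` materialises everything
for SAM/FASTQ export. Best-hit counts for Alu-derived reads are the
number of library entries matched above threshold; with mutually
dissimilar consensi and a random reference this is almost always 1, so
weights are exercised by dedicated tests rather than by the cohort runs.

What the benchmark consequently does **not** show: robustness to
mapping artifacts around pre-existing reference Alus (the synthetic
reference contains none, so every improper pair is either planted signal
or insert-size tail), chimeric fragments, indel/quality error structure,
GC or coverage bias, or allelic length heterogeneity at one site (a
single insertion event per site is assumed). Real-data use should
expect lower precision than the simulated zero-false-positive point.

## Benchmark scoring and problem sizes

An event is one (site, individual) pair with ≥ 1 carrier haplotype
(insertions) or ≥ 1 deleted haplotype (deletions); sensitivity is the
percentage of expected events recovered, requiring a detected position
within 150 bp of truth (insertions; the refined positions are typically
within ~20 bp) and a non-reference genotype call. The zero-FP operating
point raises the sweep threshold stepwise until no called insertion
falls outside the truth windows. Trio concordance checks child calls
against Mendelian possibility given both parental calls (homozygote
deleted: both parents carry ≥ 1 called deletion allele; heterozygote:
parents not both homozygous in the same direction). The acceptance run
uses the full default cohorts (two cohorts of 50 diploids plus 10
trios, ~15 million read pairs in total) and completes in about a minute
on one CPU; unit and integration tests use 150-400 kb cohorts of 4-10
haploids.
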