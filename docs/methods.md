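# Methods

This note documents the models, parameters and numerical choices behind
`ldprscan`, and what the synthetic validation does and does not establish.

## 1. LDPR detection model

An LDPR (long-duplication-prone region) is operationally defined as an
interval with an elevated concentration of *locally repeated, Kbp-scale*
sequence, detected from off-diagonal local self-alignments of each
chromosome.

**Alignment filter.** Only intra-chromosomal alignments with length
strictly greater than `min_len` (default 5,000 bp) whose two intervals fall
fully within `max_mate_sep` (default 200,000 bp) of one another are scored.
"Fully within ... of one another" is read strictly: both intervals must fit
inside a single 200 Kbp span, i.e. `max(a_end, b_end) − min(a_start,
b_start) ≤ 200,000`. A looser gap-based reading (`b_start − a_end ≤
200,000`) is available via `mate_sep_mode="gap"`. The *length* of an
alignment for the filter is the larger of its two interval spans (they can
differ when imported gapped alignments are used; the built-in aligner is
ungapped, so they coincide).

The 5 Kbp floor is what makes the method specific to large duplications: a
single LTR retrotransposon's terminal-repeat self-hit (~0.1–2 Kbp) does not
pass, whereas a tandem array of n Kbp-scale units produces unit-shifted
self-alignments of length up to (n−1) × unit, which do.

**Interrogation points.** Points sit at every multiple of `spacing`
(default 1,000 bp). A filtered alignment contributes the span of whichever
of its intervals covers the point; an alignment whose two intervals both
cover a point contributes twice (its local copy number is locally two).
`count_once=True` switches to single counting; the default is double
because the raw score is meant to approximate total repeated bases covering
the point.

**Smoothing and thresholding.** Per 2 Mbp window (200 Kbp overlap), the
density at point p is the score-weighted Gaussian KDE over the window's
points, divided by the window's total score:

    density(p) = Σ_q w_q K((p − q)/h) / (h Σ_q w_q),   h = 10,000 bp.

The per-window normalisation makes densities comparable between windows
regardless of their absolute repeat content; windows with zero total weight
yield no flags. The KDE is evaluated exactly (full O(n²) kernel, no
truncation) at the interrogation points only. Each chromosome position
takes its density from the single window whose non-overlap core contains it
(overlap halves are split at their midpoint), with the 200 Kbp overlap
serving as smoothing context; away from chromosome ends this makes the
result invariant to the window decomposition.

**Threshold.** The minimum density is a free parameter of the method; no
canonical value exists because its natural scale depends on the genome's
repeat landscape. It is expressed as a multiple of the uniform density
`1/window` (so multiplier 1 is the density of mass spread evenly over a
window; default multiplier 5). `calibrate_threshold` chooses the multiplier
from a fixed grid by maximising base-pair-level F1 of the calls against a
truth interval set on simulated data; ties resolve to the largest
(most conservative) multiplier. Runs of consecutive points with density
strictly above threshold become candidate regions `[first, last + spacing)`.

**Merge and trim.** Candidate runs (possibly overlapping across window
seams) are unioned; each merged interval is trimmed inward to the first and
last base covered by any filtered-alignment interval, so every reported
region begins and ends in repeated sequence, and intervals with no covered
base, or shorter than 2 × spacing after trimming, are dropped. The BED
score column is `1000 × peak_density × spacing`, capped at 1000 — peak
density re-expressed per interrogation-point interval so it lands in BED's
integer score range.

## 2. Self-alignment

At desk scale the built-in aligner stands in for a genome-to-genome
aligner: exact k-mer seeding (k = 15; k-mers occurring > 100 times skipped
as low-complexity), seeds grouped by diagonal, ungapped x-drop extension
(+1 match / −1 mismatch, x-drop 50), emitting off-diagonal alignments of
length ≥ `min_out_len` (default 1,000 bp). Scores are matching bases.
Reverse-orientation (palindromic) hits are found by seeding the forward
sequence against its reverse complement and are retained and scored like
forward hits; the caller's filter can drop them (`drop_reverse`). Mirror
duplicates are collapsed and the trivial full-length diagonal is never
stored. The aligner is ungapped by design — recovering Kbp-scale planted
duplications with percent-level substitution divergence does not require
gapped extension — while imported `lastz`/PAF alignments may be gapped.

Inside a tandem array the correct ungapped result is one long alignment per
unit-shift diagonal (copies 1..n−k against copies k+1..n), not a separate
record per copy pair; the truth-recall tests therefore check that each
planted pair is covered ≥ 95 % on its diagonal by some reported alignment.

## 3. Protein clustering

Greedy first-match centroid clustering mirroring published UCLUST
semantics: sequences in decreasing length order (ties: lexicographic ID),
each assigned to the first centroid with global identity ≥ cutoff (default
0.5), else founding a new cluster. Identity is matching columns over all
alignment columns (terminal gaps included) along one optimal
Needleman–Wunsch path with match +1 / mismatch −1 / gap −1 (linear gaps);
the traceback tie priority is diagonal, then gap-in-second, then
gap-in-first, and the argument pair is ordered canonically before
alignment so identity is symmetric. A length-ratio bound
(identity ≤ min/max of lengths) skips hopeless candidate alignments without
changing results. Exact agreement with any particular UCLUST release's
cluster boundaries on real data is not claimed.

## 4. Association statistics

Genes are flagged in/out of LDPRs by ≥ 1 bp overlap between any LDPR and
the CDS span (min CDS start to max CDS end) of the longest transcript
(greatest summed CDS length; ties by transcript ID); genes without CDS are
excluded with a warning. Each cluster's 2×2 table (members / non-members ×
in / out) is tested with a two-sided Fisher exact test: the p-value sums
hypergeometric probabilities of all tables at the observed margins whose
probability does not exceed the observed one, with a 1e-7 relative tie
tolerance; any zero margin gives p = 1 by convention. The hypergeometric
pmf is computed from a cached log-factorial table. Bonferroni control
divides alpha by the number of clusters with more than one member — the
only clusters that could reject.

**Eligibility.** A cluster is eligible when at least two of its members lie
inside the union of LDPRs. The stricter per-region reading (≥ 2 members in
*each* overlapped region) is supported through a caller-supplied per-region
member count, but is not the default because it would disqualify nearly
every cluster. Ineligible clusters carry p = NA and are never significant.

## 5. Pool enrichment

Pools are built function-first: genes whose GO terms fall under a root term
(default GO:0044419, via a user-supplied term → ancestor closure table —
an ontology-parsing dependency is deliberately avoided, and the closure is
testable as a fixture), plus genes whose descriptors match a configurable
regex vocabulary of cereal resistance domains (NBS-LRR, NB-ARC,
leucine-rich repeat, receptor-like kinase, pathogenesis-related, thionin,
jacalin, jasmonate-induced, powdery mildew, chitinase, defensin — a
documented approximation, not a reproduction of any specific published
list). The housekeeping control pool is built from a precomputed homology
table: a gene qualifies if any splice variant's aligned length exceeds 80 %
of the combined original sequence lengths, where "combined" is read as the
mean of query and subject lengths (`denominator="max"` gives the
alternative reading).

Clusters with a strict majority (> 0.5) of pool members are pool clusters.
The enrichment test regresses the binary cluster label on x = −log p of the
cluster's Fisher test (natural log; the base only rescales the slope and
leaves the LRT invariant) by Newton/IRLS with step halving to a gradient
norm ≤ 1e-10, and compares against the intercept-only null with a
likelihood-ratio test (chi-square, 1 df). Quasi-complete separation
(non-convergence or |beta| > 30) triggers a warning and a weakly
ridge-penalised refit (lambda = 1e-4) from which the LRT is still reported.
A constant predictor or single-class response short-circuits to
LRT = 0, p = 1. Clusters with NA p-values are excluded by default;
`impute_ineligible=True` instead imputes p = 1 (x = 0, "no evidence"). The
end-to-end pipeline uses imputation so the regression sees every cluster:
on desk-scale genomes the eligible set is nearly identical to the
truly-associated set, and a regression restricted to it has no contrast.

## 6. The synthetic genome generator

The generator's defaults are the study conditions of the validation suite;
they emulate the structures the method targets, at a size a single CPU
handles in seconds.

- **Background**: i.i.d. nucleotides at GC 0.44, so the self-alignment
  noise floor is negligible and planted structure dominates.
- **Planted arrays** (default 6 sites on 2 × 2 Mbp chromosomes): each
  duplication-prone family has one ancestral unit (2–4 Kbp, one embedded
  single-exon gene) dispersed to 1–3 distant loci; each locus grows an
  independent tandem array (4–8 units) by repeatedly duplicating a
  contiguous block of 1–3 existing units in place, each new copy acquiring
  substitutions at 1 % per copy. Fresh flanking sequence per site makes the
  sites dissimilar except for the unit itself — the migrate-and-expand
  signature.
- **TE-like elements** (2 per Mbp): two near-identical 1–2 Kbp terminal
  direct repeats flanking a 3–7 Kbp internal body, the paired-repeat
  self-alignment signature of an LTR retrotransposon. A lone element's
  self-hit is sub-filter by design, mirroring why the 5 Kbp floor exists.
- **Background families** (total families 60, 67 % singletons): members
  share only a sub-Kbp CDS (450–900 bp), so a genome with nothing planted
  contains no repeated segment ≥ 1 Kbp.
- **Labels**: arms-race labels are drawn at family level with the log-odds
  for planted-array families exceeding background families by
  log(association_strength) (default 25; 1 encodes the null), with the
  background rate solved numerically so the overall arms-race fraction
  matches its target (0.15). A fixed 20 % of remaining families get
  housekeeping labels, independent of placement — the negative control.
  Descriptors and GO terms are assigned per family from fixed vocabularies
  that the default pool selectors target exactly, so pool construction can
  be validated against the truth labels.
- Mutations are substitutions only (no indels), keeping truth alignments
  coordinate-exact while still diversifying copies. All genes are on the
  forward strand with a single CDS. Repeat-bearing features are separated
  by ≥ 50 Kbp so KDE mass from neighbouring features does not bridge;
  infeasible configurations raise a capacity error rather than silently
  truncating.

What passing on this simulator does **not** show: robustness to indel-rich
divergence, nested TE clusters that themselves form legitimate
duplication-prone regions, centromeric tandem-satellite seas, annotation
noise (split/merged gene models), or genome-scale compute behaviour. The
statistical layers' calibration (family-wise error of the Fisher screen,
size and power of the LRT) is established on the flag/label-level
simulators with 200–1,000 replicates, not on full genome replicates, whose
per-replicate cost would be prohibitive and whose extra realism is
irrelevant to the tests' null distributions.

## 7. Problem sizes used in validation

Planted-genome recovery runs on 2 chromosomes × 2 Mbp with 6 planted
arrays; clustering recovery on 20 families with 2–30 members (~300
proteins, lengths 120–400 aa, within-family identity ≈ 0.9); Fisher/
enumeration agreement on all 2×2 tables with N ≤ 60; the KDE oracle on
2,000 grid points; null calibration on 200 flag replicates and 1,000 label
sets of 300 clusters; power at slope 1 on 100 (rejection rate) and 500
(median slope) replicates; and end-to-end determinism on a 2 × 1 Mbp
genome run twice. These sizes were chosen so the whole validation runs on
one CPU in about a minute while leaving each test's statistical target
well-identified.
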