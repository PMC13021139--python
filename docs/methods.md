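# Methods

FLARE analyzes cell-free DNA (cfDNA) from long-read nanopore sequencing.
Long reads span whole cfDNA molecules, so the native read length is the
fragment length, fragment ends are preserved, and 5mC methylation arrives
directly in the alignment's MM/ML tags without bisulfite conversion.  The
package implements five analysis layers over a shared alignment model, plus
a simulator that generates cohorts with known ground truth.

## Alignment model and filtering (`ionmodel`)

Records are reduced to coordinates, strand, CIGAR clip structure and
decoded methylation calls.  Coordinates are 0-based half-open throughout.
Clip bookkeeping is strand-aware: for a reverse-strand record the stored
sequence is the reverse complement of the basecalled read, so the read's
5' end corresponds to the *trailing* CIGAR clip.

The retention policy keeps primary, mapped records with mapping quality of
at least 20 (boundary inclusive).  The fragment-length cut defaults to
retaining reads of at most 700 bp — the direction consistent with cfDNA
biology, where sub-nucleosomal and mononucleosomal fragments dominate — and
a `length_filter_mode="min"` switch inverts it for users who want the
opposite convention.  Drop reasons are checked in a fixed order (mapped →
primary → supplementary → mapq → length) so the per-reason counts partition
the input deterministically; the retained *set* does not depend on the
order because the predicates are conjunctive.

MM/ML decoding follows the SAM base-modification specification: skip counts
are consumed over occurrences of the target base in the read's original
orientation (for reverse records, the reverse complement of the stored
sequence), and each 8-bit ML byte k is decoded to the probability-bin
midpoint (k + 0.5)/256.  Entries describing modifications on the opposite
strand of the read, or entries inconsistent with the read sequence, raise a
malformed-tag error; such records are excluded from methylation analyses
but retained elsewhere.  For implicit-skip tags (no `?` flag) the unlisted
target bases are skipped by default; an option can emit them as
probability-0 calls.  Decoding is cross-checked against pysam's independent
decoder in the tests.

## Fragment-size profiling (`fragprofile`)

Lengths are summarized by mean, median, N50 (smallest length L such that
reads of length ≥ L contain at least half of all sequenced bases, computed
by descending cumulative sum) and a 10 bp histogram.  Reads are stratified
into short (< 150 bp), intermediate (150–300 bp, both endpoints included)
and long (> 300 bp) classes; the class streams partition the input and feed
the per-class copy-number re-estimation.

## 5' end motifs (`endmotif`)

Nucleases leave characteristic k-mers at cfDNA 5' ends (DNASE1L3 favors
CC-starting motifs such as CCCA; CAD/DFFB, active in apoptosis, favors
A-ends).  For each retained read the 4-mer at the fragment's 5' terminus is
extracted: forward-strand reads contribute their first four stored bases;
reverse-strand reads contribute the reverse complement of the reference at
[ref_end − 4, ref_end).  This read/reference asymmetry is deliberate and
reproduced as printed workflows do it; an all-reference mode exists for
users who want symmetry.  Reads clipped at the 5' end, motifs containing N,
and windows extending past a chromosome end are excluded.  Per-sample
counts are normalized by the number of retained motif reads into a fixed
256-column matrix (lexicographic motif order, absent motifs exactly 0).
End-base composition is the first-character marginal of that matrix, which
makes the composition/matrix consistency exact by construction.

## NMF profile decomposition (`motifnmf`)

The samples × 256 matrix V is factorized as V ≈ W H with Lee–Seung
multiplicative updates on the Frobenius objective ½‖V − WH‖²; the
objective is non-increasing per iteration and iterations stop at a relative
change below 1e-6 or 2000 iterations.  An ensemble of random restarts
(default 100, run r seeded with base + r) yields: the reported factors
(lowest final objective), a consensus matrix of dominant-profile
co-assignments (argmax of each sample's W row), and its cophenetic
correlation as the stability summary used in the rank survey (k = 2…6
reported, default pipeline rank 3).  After convergence H rows are
L1-normalized with W rescaled compensatorily, leaving W·H unchanged;
permutation indeterminacy is resolved in comparisons by Hungarian matching
on cosine distance.  Top profile motifs are ranked by weight with
lexicographic tie-breaks.  Paired contrasts of W columns use the exact
Wilcoxon signed-rank test.

## Copy number and tumor fraction (`cnvtf`)

Reads are counted in fixed bins (default 100 kb in the simulated setting;
1 Mb is conventional for shallow human WGS), GC-corrected by a lowess fit
of count against GC (span 0.3; bins outside GC 0.2–0.8 or with zero
coverage masked), and converted to log2 ratios against a panel of normals
with median-of-sample / median-of-panel scaling.

The HMM has copy states c ∈ {0, 1, 2, 3} (no subclonal states, maximum
copy number 3) with Gaussian emissions centered at

    μ_c(n, φ) = log2( (2n + (1−n)c) / (2n + (1−n)φ) )

where n is the normal fraction and φ the tumor ploidy; tumor fraction is
1 − n.  Gaussian emissions were chosen over a Student-t for closed-form
M-steps; the emission interface is pluggable.  Transitions are sticky with
off-diagonal probability e = 1e-3.  A much stickier chain (e = 1e-6) makes
the *initial* E-step at high-n restarts merge neutral and aberrant
segments — the state means are separated by far less than the noise there —
and the EM then converges to a displaced optimum; e = 1e-3 still yields
clean segments at realistic noise while keeping the first segmentation
emission-driven.  The chain restarts at every chromosome boundary with an
initial distribution favoring the neutral state (0.05/0.10/0.75/0.10): when
a genome is effectively flat all four means collapse as n → 1 and a uniform
start would make the constant-path decode arbitrary.

Fitting is MAP-EM.  Each restart n₀ ∈ {0.95, 0.99, 0.995, 0.999} (ploidy
restart 2) defines a weak Beta prior on n centered at n₀ (strength
equivalent to ~2 bins); the prior leaves informative data unchanged but
pins n when the aberrant states carry no posterior mass, where the plain
ML update is unidentifiable.  The E-step is scaled forward–backward
(cross-checked against exhaustive path enumeration); the M-step maximizes
the expected penalized complete-data likelihood — a closed form in
per-state posterior moments — by a global (n, φ) grid scan plus L-BFGS-B
polish, because the joint Q surface has EM-trapping local optima.  φ is
frozen at its restart value until first convergence and then freed within
[1.5, 3]; widening the feasible set preserves monotonicity of the penalized
log-likelihood, which is asserted every iteration.  σ² has a closed-form
update (floor 1e-6) and is initialized from the MAD of successive
log-ratio differences, which is robust to the copy-number structure
itself.  Because the EM basin from high-n starts can miss the global MAP
when aberrant segments are short, each restart additionally tries initial
normal fractions {n₀, 0.8, 0.6} and keeps its best penalized solution; the
restart with the highest penalized log-likelihood is reported (the data
log-likelihood is stored alongside).  States come from Viterbi; adjacent
equal states merge into segments that never span a chromosome boundary.
Sex-chromosome bins (chrX) are decoded but excluded from parameter updates
by default.  Tumor fractions are always reported as proportions in [0, 1].

## Methylation-based tumor fraction (`methtf`)

Reads intersecting a marker panel (BED, non-overlapping, autosomes only by
default) contribute per-marker (x, y) pairs: y CpG calls with decoded
probability, of which x are ≥ 0.5 (the midpoint of the ML scale).  Marker
means are pooled Σx/Σy across reads, weighting reads by evidence.  Marker
beta parameters can be trained from labeled methylation fractions by
method of moments per class (fractions clamped to [0.01, 0.99], variance
floored at 1e-4, concentration floored at 0.01), with markers lacking three
samples in either class dropped.

Each read's class likelihood is the beta-binomial kernel
L(x, y | α, β) = B(α+x, β+y−x)/B(α, β), computed in log space; the
binomial coefficient cancels between classes.  The tumor fraction θ
maximizes Σ_j w_j log(θ L_t(j) + (1−θ) L_n(j)) on a grid over [0, 1] with
step 5e-4 (global on the grid by construction; ties break toward smaller
θ).  The regularization against uninformative markers is implemented as
the bounded per-read weight w_j = d_j/(λ + d_j) with
d_j = |log L_t − log L_n| and λ = 0.5 by default.  This functional form is
an interpretation — it is monotone in read informativeness, continuous,
and reduces to the unweighted likelihood as λ → 0, where the estimate
provably matches an independent beta-binomial grid maximizer — and is
flagged as such.  Likelihoods are per-read; reads spanning two markers
contribute one summary per marker under the model's marker-independence
assumption.

## Nonparametric statistics (`stats`)

Signed-rank and rank-sum tests compute exact two-sided p-values by
enumerating the null distribution of the rank statistic via dynamic
programming over rank sums (identical to full enumeration of the 2^n sign
assignments or C(N, n1) group assignments, and verified against literal
enumeration at small n); exactness applies up to n = 25 paired / N = 20
pooled observations without ties, beyond which a normal approximation with
mid-rank tie correction and continuity correction is used.  Zero paired
differences are dropped (classical convention, not Pratt).  Spearman's ρ
is the Pearson correlation of mid-ranks with a 95% CI from the Fisher
z-transform using the Fieller-adjusted standard error sqrt(1.06/(n−3)) and
a t-approximation p-value on n−2 degrees of freedom; the CI method is a
choice, since reported CIs in this setting rarely name one.

## Synthetic cohorts (`simdata`)

The simulator generates what the pipeline consumes, with truth recorded:

- **Reference**: random sequence with per-bin GC targets drawn from
  U(0.35, 0.55); all outputs are pure functions of (config, seed).
- **Fragments**: each read is tumor-class with probability θ*; tumor reads
  are placed with per-bin intensity proportional to the planted copy state
  and normal reads uniformly, so aggregate bin intensity is proportional
  to 2n + (1−n)c, matching the emission model.  Lengths are lognormal
  mixtures over tumor-short (~145 bp), mononucleosomal (~167 bp) and
  dinucleosomal (~320 bp) components; class weights default to
  (0.45, 0.35, 0.20) for tumor and (0.10, 0.62, 0.28) for normal reads,
  echoing the known shift toward short fragments in tumor-derived cfDNA.
  Fragments that would overrun a chromosome end are clamped to fit rather
  than redrawn (a negligible edge effect at these genome sizes).
- **End motifs**: each fragment's 5' 4-mer is drawn from its class profile
  and written into the reference before any read sequence is extracted
  (reverse-complemented at the 3' genomic end for reverse-strand
  fragments), so read and reference stay consistent on both strands.  All
  samples' rewrites happen before any SAM is emitted, making the
  read-equals-reference-substring invariant exhaustive.  A paired-strand
  mode emits every motif draw as both a forward and a reverse record so
  strand-extraction consistency can be measured without sampling noise.
- **Methylation**: markers are CpG-enriched intervals (a CpG planted every
  15 bp); each read×marker draws a methylation level from the class beta
  distribution (defaults Beta(8,2) tumor vs Beta(2,8) normal), each CpG is
  methylated with that probability, and calls are encoded as MM/ML with
  bytes from the high (180–255) or low (0–75) range.  Reverse-strand reads
  carry their calls on the G of the CpG (the C of the opposite strand), as
  a basecaller would report them.
- **Panel of normals**: per-bin medians of GC-corrected multinomial
  coverage over simulated normal samples.
- **Cohorts**: paired two-timepoint samples per subject with a manifest
  and a truth JSON.

Reads are error-free and clip-free by construction: the tests target the
pipeline's logic, not aligner behavior.  Consequences: filtering drop
paths are exercised by dedicated toy inputs rather than the cohort;
end-motif extraction never disagrees between read and reference; and
recovery results say nothing about basecalling or alignment artifacts in
real data.  Real cfDNA also has sequence-dependent coverage structure,
correlated GC and mappability effects, and marker panels whose tumor/normal
separation is far less clean than the defaults here.

## Problem sizes and numerical choices

The test and acceptance workloads use two 4 Mb chromosomes at 100 kb bins
(80 bins), 8,000–12,000 reads per sample, 50 markers, 3,000-bin CNV
recovery problems and 100-run NMF ensembles — sizes chosen so the full
suite exercises every stage end-to-end on one CPU in minutes while keeping
every recovery bound comfortably attainable.  Key tolerances: NMF tol 1e-6
/ max 2000 iterations; EM tol 1e-6 / max 200 iterations with a 1e-8
monotonicity guard; θ grid step 5e-4; variance floors as above.  The
report JSON contains no timestamps, so a rerun under the same seed is
byte-identical.

## Known limitations

- The HMM is a simplified ichorCNA-style model: no subclonal states, no
  Student-t emissions, no allele-specific copy number, no
  mappability/centromere masking (a hook exists for mappability).
- Tumor fractions below ~1% are at the resolution limit of the CNV route
  at these bin counts; the methylation route is the sensitive one there,
  mirroring the division of labor between the corresponding published
  tools.
- The λ-weighting functional form in `methtf` is one reasonable reading of
  a regularizer described only by its purpose and value.
- The NMF consensus uses dominant-profile co-assignment; soft co-clustering
  variants would differ for strongly mixed samples.
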