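# Methods

`regcircuit` infers stage-specific transcriptional regulators of a
regenerating cell population by integrating four data layers over a
regeneration timecourse (uninjured, 6, 24 and 72 hours post amputation):
chromatin accessibility (ATAC-seq peak counts), motif occurrence in peak
sequences, bulk expression per stage, and single-cell expression before
and after injury.  This note describes the statistical models, the
defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical conventions.

## Differential accessibility

The first modelled object is a peak-by-sample matrix of fragment counts
with a few replicates per timepoint.  Counts for peak *g* in sample *i*
are negative binomial with mean μ_gi and a common dispersion φ, so that
Var = μ + φμ².  φ = 0 is the Poisson limit.  The pairwise testing path
is the classic small-replicate workflow:

1. **Filtering.** A peak is kept if it has ≥ 1 count per million (CPM)
   in at least *n* − 1 of the *n* samples entering the contrast.  The
   filter is applied per contrast, over exactly the samples being
   compared.
2. **TMM normalisation.** The reference sample is the one whose
   75th-percentile CPM is closest to the mean of those quantiles.  For
   each sample, M = log2 ratio and A = mean log2 abundance against the
   reference are computed over peaks positive in both; 30% of M values
   and 5% of A values are trimmed from each tail, and the remaining M
   are averaged with inverse-asymptotic-variance (binomial) weights.
   Factors are rescaled to geometric mean one.
3. **Library equalisation.** Counts are linearly rescaled to the
   geometric-mean *effective* library size (raw size × TMM factor) and
   rounded half to even.  This plays the role of pseudo-count
   equalisation: it is simpler than quantile adjustment, keeps the
   matrix integral, and its adequacy is validated behaviourally — the
   null calibration and dispersion-recovery properties below are the
   acceptance surface, not numeric identity with any external tool.
4. **Dispersion.** A single φ is estimated by maximising the summed
   per-peak conditional log-likelihood, conditioning within each group
   on the group total at the equalised library sizes.  The likelihood is
   evaluated on a log-spaced grid over [1e-4, 10] and refined by bounded
   scalar optimisation.  Peaks with zero group totals are skipped;
   counts that are constant within every group carry no dispersion
   information and produce the grid minimum with a warning.
5. **Exact test.** Conditional on the two-group total *t*, the group-A
   sum follows a Dirichlet-type law depending only on n_A/φ and n_B/φ
   (the NB success probability cancels, exactly as the binomial
   parameter cancels at φ = 0).  The two-sided p-value sums the
   probabilities of all outcomes no more likely than the observed split
   (small-p method, with a 1e-7 relative tolerance absorbing
   floating-point ties, the convention exact binomial tests use).
   t = 0 gives p = 1.
6. **FDR and direction.** Benjamini–Hochberg across peaks; a peak is
   directional (`up_in_1` / `up_in_2`) iff FDR ≤ α = 0.05 (a
   configurable field default; the significance threshold is otherwise
   a free choice).

Measured behaviour at the default study conditions (10,000 peaks, φ =
0.1, 3 vs 3): raw p ≤ 0.05 in ~5.0% of null peaks with zero FDR calls;
≥ 95% of peaks planted at |log2FC| = 2 recovered with the correct
direction; φ recovered within [0.08, 0.12].

**MDS.** Sample structure is summarised by classical metric MDS
(eigendecomposition of the double-centred squared-distance matrix) on
Euclidean distances between log2(CPM+1) profiles restricted to the 500
most variable peaks.  Classical MDS reproduces the input distances
exactly in ≤ n−1 dimensions; axis signs are fixed deterministically.

## Peak annotation and interval arithmetic

Peaks are BED-convention half-open intervals; gene annotation is read
from GFF3 and converted (start − 1) on input.  A peak is assigned to the
gene whose TSS minimises |midpoint − TSS|, with midpoint =
floor((start+end)/2).  The distance convention is midpoint-to-TSS,
signed by gene strand so upstream is negative; the midpoint convention
is the common choice for ATAC peaks, and ties are broken by smaller
absolute distance then lexicographic gene id so output is deterministic.
Merging treats bookended intervals (end == start) as joinable, matching
the common merging default.  Set contrasts count an interval as shared
iff it overlaps ≥ 1 bp of the other set, reported from each side.

## Motif scanning

A PWM is a width × 4 probability matrix with a mononucleotide
background (uniform by default; estimable from peak sequences).  Scores
are log2((p + 0.01·bg) / (1.01·bg)) per position, summed over each
window on both strands; minus-strand hits are reported in forward
coordinates (offset′ = L − w − offset).  Windows containing N are
skipped, not imputed.  The default detection threshold is 0.8 × the
motif's maximum attainable score.  Per-motif detection thresholds of
known-motif scanners are not portable across libraries; the
fraction-of-max rule is a standard proxy, and the planted-instance
recall property makes the choice auditable.  Motif files are read and
written in MEME-minimal format; a converter for HOMER-style probability
rows is provided.

## Enrichment and semantic reduction

Gene-to-term annotations are propagated to all ancestors (true-path
rule) over a DAG; term frequencies p(t) are computed over the annotated
universe supplied with the data rather than an external organism table,
which keeps the analysis self-contained while using the same formula.
Enrichment of a query against a universe is the upper-tail
hypergeometric probability P(X ≥ k), BH-corrected across terms; terms
absent from the universe are skipped.

Semantic similarity is SimRel: with IC(t) = −ln p(t) and MICA the
common ancestor of maximal IC,

    simrel(a, b) = (2·IC(MICA) / (IC(a) + IC(b))) · (1 − p(MICA)),

zero without a common informative ancestor.  The log base cancels in
the ratio.  Redundancy reduction sweeps significant terms in ascending
p-value; a term founds a new family iff its similarity to every
existing representative is ≤ the cutoff (default 0.4, the "tiny"
allowed-similarity setting), otherwise it joins its most similar
representative.  Under this rule a larger cutoff can only create more
families (cutoff 1 isolates every term); the reduction therefore grows
stricter as the cutoff is lowered.

## Single-cell statistics

Counts are normalised as ln(1 + 10⁴·count/libsize) (the standard
log-normalisation with its documented default scale factor).  Cluster
labels and timepoints are *inputs*: embedding, anchor integration and
graph clustering are named-package procedures outside this package's
scope, and every statistic here is computed from the labels.

**Module score / cell-cycle phases.** Genes are ranked by mean
normalised expression and cut into 24 equal-frequency bins; for each
signature gene, up to 100 control genes are drawn (seeded, without
replacement) from its bin, excluding the signature itself.  The score
is mean signature expression minus mean control expression per cell.
Phase assignment: G1 iff both S and G2M scores ≤ 0, otherwise the
phase with the larger score.  Scores are invariant to gene and cell
order at a fixed seed.

**Markers and differential expression.** Genes detected (count > 0) in
≥ 30% of either group are tested with a two-sided Wilcoxon rank-sum on
the normalised layer — full permutation enumeration when the number of
group splits is small (≤ 1000), the tie-corrected normal approximation
otherwise.  log2 fold change uses expm1 means with a pseudo-mean of 1
(stable at zero means, base 2 for consistency with the accessibility
tables); adjustment is Bonferroni over tested genes; `only_pos` drops
non-positive fold changes.

## Regulatory-circuit inference

Per stage, a regulator table joins peaks gaining accessibility at that
stage (the stage vs its predecessor contrast, direction up at the
stage) with their motif hits and nearest genes; rows are kept only when
both the TF gene *and* the candidate target are bulk-expressed (CPM ≥
1, configurable) at the stage.  Vetting both genes is the stricter of
the two readings of "genes expressed at the given timepoint" and is
the default; expression thresholds below 1 CPM are not meaningful at
bulk depth.

Chaining: the earliest stage contributes *entry evidence* only — a TF
may open a chain at the second stage iff its motif also occurs in a
first-stage table row (the reading in which the early stage supplies
TF-activity evidence and the next stage supplies its targets; the
alternative region-side reading is implementable from the same
operations).  From the second stage on, an edge extends a chain when
its TF's gene is the previous edge's target and that target is itself
TF-coding (membership in the motif library's TF map; no external TF
catalog).  Every maximal chain is emitted, including length-1 chains;
self-loops are flagged and never revisit a stage.

The single-cell filter keeps circuits whose genes are all measured in
the single-cell data and in which at least one node is differentially
expressed between the uninjured and injured timepoints at adjusted
p ≤ α (the conjunctive reading — every node DE — is available behind
`strict_de`).  Exports are a deterministic TSV edge list and a DOT
graph.

Pruning is monotone: raising the expression threshold or motif
threshold, or lowering α, never adds edges.

## The synthetic study

The generator emits a complete miniature study from one seed, fanned
out into independent substreams per file so adding one file never
perturbs another; identical configurations give byte-identical files.

* **Genome/annotation:** 1000 genes on two chromosomes, evenly spaced
  (4 kb), alternating strands; TSS spacing makes nearest-gene
  assignment of planted peaks unambiguous.
* **Peaks/counts:** 400 consensus peaks, width 200 bp, NB fragment
  counts (baseline mean 100, φ = 0.1, per-peak abundances log-normal).
  A peak planted for stage *t* sits at its baseline at *t* and at
  baseline/2^2 elsewhere, i.e. a |log2FC| = 2 gain flanked on both
  sides, making it transient in the flanking contrasts like the
  stage-specific peaks the pipeline is designed to find.
* **Sequences/motifs:** i.i.d. uniform background with motif instances
  planted by substituting the consensus (or its reverse complement) at
  recorded offsets — scanner ground truth is exact.  The four PWMs are
  width 14 and sharply peaked (p = 0.985), so at the 0.8·max threshold
  only the exact consensus scores above threshold and chance hits are
  vanishingly rare (~4^-14 per window).
* **Planted circuit:** two TFs and four targets across 24 hpa and
  72 hpa, with early-stage (6 hpa) linkage peaks for the entry TF.
  Each edge is supported by two accessible elements: per-peak FDR power
  at these conditions is ~98%, so a single supporting peak would make
  end-to-end recovery fail on a few percent of seeds, whereas real
  regulatory links are typically supported by more than one element.
  200 decoy genes each violate exactly one edge criterion (peak not
  differential, motif absent, TF not bulk-expressed, no DE node), and
  six regions carry both TF motifs to exercise the target-overlap
  summary without creating admissible edges.
* **Single cell:** two timepoints × 600 cells (composition and
  cell-cycle fractions shifting between them with the planted values
  30/16/54% → 17/7/76% for S/G2M/G1), four clusters with five planted
  markers each (log2FC 2), circuit targets differentially expressed
  after injury, log-normal library sizes, NB counts at φ = 0.4.
  Cell-cycle signatures are 40 + 40 genes with low off-phase baselines
  (log-normal around 0.25) boosted 2^4.5 in the matching phase —
  strongly phase-restricted markers, the regime in which binned-control
  scoring separates phases.  Keeping signatures a small fraction of the
  gene universe matters: if they dominate the expression bins, the
  matched controls degenerate into the opposite signature and null
  scores lose their negative margin.
* **Ontology:** a three-level DAG (1 root, 5 families, 24 leaves, some
  multi-parent) with random leaf annotations.

Not emulated: read-level ATAC structure (fragment-length periodicity,
GC bias), doublets and ambient RNA, batch effects, trended or tagwise
dispersion, and any spatial genome organisation.  Passing tests on this
generator therefore validate the statistical machinery and the
integration logic, not robustness to those artefacts in real data.

## Numerical conventions and problem sizes

Rounding is half-to-even wherever counts are rescaled.  All random
draws flow from `numpy` Generators seeded from explicit `SeedSequence`
spawns.  Ties are broken lexicographically (gene ids, term ids, peak
names) so every table has a deterministic row order, and repeated runs
are byte-identical.  The test suite and the acceptance script run the
calibration and power simulations at 10,000 peaks, the phase-recovery
check at 3,000 cells, and the end-to-end study at the 400-peak /
1000-gene defaults; these sizes give the properties being measured
comfortable Monte-Carlo margins while keeping a full run in minutes on
one CPU.

## Known limitations

* The common-dispersion model understates per-peak variability when
  true dispersions are heterogeneous; the exact test is then
  anti-conservative for high-dispersion peaks.
* The exact test requires integral pseudo-counts; the half-to-even
  rounding introduces an error of at most half a count per sample.
* SimRel frequencies derive from the supplied annotation universe, so
  small universes quantise information content coarsely.
* The entry-linkage reading of the first stage is one of two defensible
  interpretations of chaining across three stages (see above); both
  are expressible with the same operations.
* `target_overlap` counts regions among stage-table rows, i.e. regions
  that already passed the accessibility and expression filters.
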