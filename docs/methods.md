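# Methods

## Model

Labeled transcripts stop being produced once the pulse ends, so over the
chase each pool decays exponentially. For a gene with expression X(t)
(normalized reads per kilobase at chase time t) the one-component model
is X(t) = X̂(t₀)·e^{−β(t−t₀)}, fitted in log space by weighted least
squares with weights wᵢ = X(tᵢ):

    β: minimize Σᵢ X(tᵢ)·[ln X(tᵢ) − ln X̂(t₀) + β(tᵢ − t₀)]²

Weighting by the measured value approximates inverse-variance weighting
for counting noise (Var[ln X] ≈ 1/X for Poisson counts); weights are the
measured values, not iteratively reweighted. The objective is an exactly
solvable weighted linear regression — β and ln X̂(t₀) have closed forms —
so no iterative optimizer is involved, and with exactly two time points
the fit interpolates: β = ln(X(t₁)/X(t₂))/(t₂−t₁).

The mixture model treats the labeled pool as spliced plus
intron-retained components with separate rates. The gene-level intron
retention index estimates the retained fraction, which identifies the
decomposition X₁ = X·(1−IRI), X₂ = X·IRI (with uniform per-base coverage
the density ratio and the transcript fraction coincide). The stated
double objective is separable, so the mixture fit is two independent
one-component fits on X₁ and X₂. A junction-read variant fits β_S on
exon–exon and β_IR on exon–intron junction counts (each multiplied by
the library's normalization factor), giving an estimate independent of
the IRI decomposition.

t₀ is the first used chase time (0.5 h); the labeling window itself is
not modeled, since X̂(t₀) is a free intercept and shifting the origin
only rescales it. Rates are reported per hour.

## Region classes and junction reads

All isoforms of a gene are consolidated: positions exonic in every
isoform form the constitutive exonic regions (CERs), positions intronic
in every isoform the constitutive intronic regions (CIRs); positions
exonic in some isoforms and intronic in others belong to neither, under
a strict shared-by-all reading (the permissive alternative would inflate
the IRI). A constitutive junction (CJ) is a boundary where a CER
directly abuts a CIR; a CIR edge touching ambiguous sequence is not a
CJ because a read there is uninterpretable as retention evidence.
Coordinates are 0-based half-open throughout; GTF input is converted on
read. Genes are processed independently; a read overlapping two genes
counts toward both. For isoforms with different extents we consolidate
over the union span without trimming alternative first/last segments.

An exon–intron read must cover a CJ with at least `min_overlap` (default
8) aligned bases on each side; an exon–exon read must bridge one CIR
exactly (gap edges matching the CIR edges, zero tolerance) with at least
`min_overlap` bases in each flanking CER. Soft-clipped bases do not
count toward the overlap; only aligned blocks are considered. The
counting unit is the read: a read overlapping several CIRs of one gene
increments that gene's CIR count once.

## Normalization

Each library is rescaled by factor = 10⁶ / (summed CER reads of a
housekeeping set), default: B2M, GAPDH, HPRT1, ACTB, SDHA, HSP90AB1,
YWHAB, YWHAQ, PTMA — genes validated as stable on the relevant time
scale, consumed as a configurable list. Normalized expression is
reads-per-kilobase × factor; the factor supplies the per-million
scaling, anchored to housekeeping reads instead of the library total.
This choice makes X invariant under a uniform depth change of one
library (library-total RPKM × factor is not, because the factor shrinks
as counts grow), and when all libraries have equal depth the two
compositions differ only by a global constant that the free intercept
absorbs — fitted rates are identical either way. The IRI, a ratio of
densities within one library, is unaffected by normalization. The 0 h
library is normalized like the others but excluded from fitting by
default; decay is measured between 0.5 h and 2 h.

## Filters and derived statistics

A gene enters the expressed set when its IRI is ≤ 1 at every used time
point and its rate is determinable (all X(tᵢ) > 0, fitted rate finite
and positive). Negative fitted rates are reported and flagged, never
clamped — clamping would hide data problems that the filter should
surface. Half-life is ln2/β for positive rates only. PST is taken as
1 − IRI(0.5 h): the early-chase IRI estimates the fraction of
transcripts still carrying introns, so its complement proxies splicing
efficiency (we read the alternative literal equation of PST with the
IRI itself as shorthand, since PST rises exactly when IRI falls).

Condition categories use configurable cutoffs with defaults
|Δβ_S| ≥ 0.2/h (stabilized/destabilized), ΔPST ≥ 0.05, fold > 1.5
(strict) for Pol II and nascent-transcription RPKM, and upregulation =
steady-state fold > 1.5 with RPKM > 1 in at least one condition. Fold
changes use normalized values with no pseudocount; zero-denominator
genes are excluded (conservative). Distribution contrasts use the
one-sided Mann–Whitney U test — exact when the combined sample is ≤ 20
without ties, normal approximation with tie correction otherwise — and
2×2 contrasts the one-sided Fisher exact test. No per-gene multiple
testing correction is applied: the contrasts are single global tests.

## RBP ranking

Upregulated genes are ranked by relative stability change
(β_S,act − β_S,rest)/β_S,rest; the k = 1000 most negative form the
most-stabilized set and the k largest the least-stabilized set (ties
broken by gene id; k shrinks symmetrically when genes are scarce). An
RBP's binding score per gene is the summed narrowPeak signalValue
(column 7, the ENCODE enrichment field) of its peaks overlapping the
gene's 3′UTR, taken as the union of annotated 3′UTRs across isoforms.
RBPs are ranked by ascending one-sided rank-sum p (stabilized set
binding higher). Replicate-consensus peaks are replicate-1 peaks
overlapping any replicate-2 peak by ≥ 1 bp (configurable). The
polyA-proximal profile assigns each peak midpoint to its nearest
same-strand polyA site (unstranded peaks match either strand) and
reports binding events per kilobase per million total binding events;
offsets are signed 5′→3′ along the transcript, negative inside the
3′UTR.

## Synthetic data generator

The generator is the study's ground-truth counterpart of the decay
model. Per gene it draws a transcription level α ~ logU(1, 100)
(arbitrary expression units spanning two decades, as in a typical
expressed-gene RPKM distribution), a retained fraction at t₀
p_ir ~ Beta(2, 8) (mean 0.2, mode near 0.1), and rates
β_S ~ U(0.1, 1.0)/h, β_IR ~ U(0.5, 3.0)/h — spliced half-lives of
0.7–7 h and systematically faster retained-pool decay. Gene structures
are single-isoform with 2–8 introns, exons 100–400 bp and introns
500–3000 bp (typical mammalian scale; chosen once, not fitted to
anything). Nine housekeeping genes carry β_S = 0.005/h, p_ir = 0 and a
high fixed α = 100 so the normalization anchor is well-measured.
Activation multiplies β_S by 0.6 for 70% of genes, halves p_ir for 30%
and doubles α for 30%, leaving β_IR untouched.

Labeled pools evolve as N_S(t) = α(1−p_ir)e^{−β_S(t−t₀)} and
N_IR(t) = α·p_ir·e^{−β_IR(t−t₀)} with t₀ = 0.5 h. Expected reads are
proportional to pool × region length (CERs see both pools, CIRs only
the retained pool) and, for junctions, to pool × footprint per
junction, with the footprint equal to read_length − 2·min_overlap =
84 bp — the number of start positions from which a 100 bp read covers a
junction with the required flanks, which keeps count-mode expectations
consistent with the read-mode simulator. Each library's expected total
is scaled to its depth before Poisson sampling, deliberately erasing
absolute pool sizes the way sequencing does; the housekeeping genes
carry the recoverable scale. Noise is Poisson per region with no
overdispersion, matching the weighted-least-squares variance heuristic.
Read mode materializes BED alignments (uniform placement inside
regions; junction reads straddling annotated junctions) to exercise the
read-level classifiers.

What the simulator does not emulate: multi-isoform genes and ambiguous
regions, non-uniform coverage (fragment-length, GC or positional bias),
overdispersed counts, mappability gaps, and sequence-level errors.
Passing tests therefore demonstrate correctness of the estimators under
the generative model's assumptions, not robustness to every artifact of
real libraries.

## Problem sizes and numerical choices

Validation runs use 500-gene cohorts at depth 10⁶ per library (the
statistics stabilize well below that scale; a 500-gene fit completes in
seconds) and two chase points, where the weighted fit is exact
interpolation. Degenerate inputs are handled by flags rather than
exceptions: any zero expression value → `insufficient_points`; IRI > 1
at any used point → `iri_gt_1`, gene excluded from fitting; a retained
component that is zero anywhere → `zero_component` with β_S still
fitted; negative rates → `negative_rate`. Gene-set ties break
lexicographically by gene id so rankings are deterministic. All
simulator randomness flows through a single integer seed; identical
seeds give byte-identical fixtures.

## Known limitations

- The IRI-based decomposition assumes uniform per-base coverage; 3′
  bias in real libraries would distort the retained-fraction estimate.
- Junction-based β_IR is noisy for genes with few exon–intron reads at
  the late chase point; at depth 10⁶ over 500 genes the junction vs
  all-read β_S correlation plateaus near r ≈ 0.83 because Poisson noise
  on junction counts attenuates it (more depth, not more method, is the
  remedy).
- Two chase points give exact fits but no residual degrees of freedom;
  goodness-of-fit assessment needs ≥ 3 points.
- Extreme-set extraction for the RBP screen is parameterized (top and
  bottom k) rather than tied to fixed rate thresholds.
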