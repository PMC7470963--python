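# brudecay

Transcriptome-wide mRNA stability analysis for bromouridine pulse-chase
sequencing (BruChase-seq), with explicit handling of intron retention.

## The problem

In a BruChase-seq experiment, nascent RNA is metabolically labeled with
bromouridine for a short pulse and then chased; sequencing the labeled
fraction at increasing chase times (here 0.5 h and 2 h) watches a single
cohort of transcripts age. A conventional analysis treats each gene's
labeled RNA as one pool decaying at a single rate β. But freshly made
RNA is a mixture: fully spliced transcripts and intron-retained (IR)
transcripts, which can turn over at very different rates. Ignoring the
IR fraction biases the apparent stability of exactly the genes where
retention matters.

`brudecay` implements the two-component view end to end for people
analyzing pulse-chase stability data (or building methods on top of it):

- **Gene models** — collapse all annotated isoforms of a gene into
  constitutive exonic regions (CERs), constitutive intronic regions
  (CIRs), and the constitutive junctions (CJs) between them.
- **Quantification** — count reads over CERs/CIRs; classify junction
  reads as exon–exon (spliced evidence) or exon–intron (retention
  evidence, ≥ 8 bp on each side of the junction); compute the intron
  retention index `IRI = (CIR reads/CIR length) / (CER reads/CER length)`
  per gene and genome-wide; RPKM and Pol II gene-body levels.
- **Normalization** — rescale chase-time libraries by
  `factor = 10⁶ / (summed CER reads of nine housekeeping genes)` so that
  decay is measurable across time points.
- **Decay kinetics** — per-gene weighted least squares in log space,

      β:  minimize Σᵢ X(tᵢ) · [ln X(tᵢ) − ln X̂(t₀) + β(tᵢ − t₀)]²

  for the one-component model; the mixture model splits
  `X₁ = X·(1−IRI)` (spliced, rate β_S) and `X₂ = X·IRI` (intron-retained,
  rate β_IR) and fits each component; a junction-read variant fits β_S
  and β_IR on normalized exon–exon / exon–intron junction counts.
  Half-life `t½ = ln2/β`; percentage of spliced transcripts
  `PST = 1 − IRI(0.5 h)`.
- **Condition contrasts** — stabilized / destabilized (|Δβ_S| ≥ 0.2/h),
  splicing-improved (ΔPST ≥ 0.05), transcription-up (fold > 1.5),
  upregulated calls; three-way overlap summaries; one-sided
  Mann–Whitney and Fisher exact tests.
- **RBP ranking** — score each RNA-binding protein by summed eCLIP peak
  signal in 3′UTRs of the 1000 most- vs least-stabilized upregulated
  genes, rank by one-sided rank-sum p; replicate-consensus peaks and
  polyA-proximal binding metaprofiles.
- **Synthetic data** — a generative simulator with known per-gene
  (α, p_ir, β_S, β_IR) so every stage is testable without downloads.

## Worked example

```bash
python examples/01_simulate_and_fit.py
```

```
expressed genes (IRI <= 1, determinable rates): 195/200
median beta_S: fitted 0.531 /h, true 0.528 /h
median relative error of beta_S: 4.8%
Spearman rank correlation with truth: 0.980

example gene G0185: beta_S = 0.846 /h, beta_IR = 2.108 /h, spliced-transcript half-life = 0.82 h
```

The simulator draws 200 genes with known kinetics, samples Poisson read
counts for two chase times at depth 10⁶, and the pipeline recovers the
spliced-transcript decay rates to ~5% median error; the fitted β_IR
exceeding β_S reflects the generated regime in which intron-retained
transcripts are the less stable species. The other examples cover
read-level intron-retention quantification (`02`), the two-condition
stabilization contrast (`03`), and RBP ranking with a polyA-proximal
binding profile (`04`).

A thin CLI wraps the same library calls:

```bash
brudecay simulate --n-genes 100 --depth 100000 --seed 1 --outdir fixture/
brudecay fit --fixture fixture/ --outdir results/
```

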