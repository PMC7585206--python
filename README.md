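# spliceorder

Infer the most likely **intron splicing order** of multi-intron transcripts
from spliced RNA-seq alignments.

Splicing is largely co-transcriptional, but introns are not necessarily
excised in the order they are transcribed. Total/nascent RNA-seq captures
partially spliced molecules, and a single fragment — one long read, or two
mates of a short-read pair — can show that intron *i* is already excised (its
exon–exon junction is present) while intron *j* is still retained. Each such
fragment is one observation that *i* was spliced before *j*. `spliceorder`
aggregates these observations per transcript and reconstructs the full
splicing order, for anyone studying co-transcriptional splicing regulation in
bulk or single-cell data.

## The model

For a transcript with *n* introns, fragment observations fill an *n* × *n*
count matrix *A*, where *A*ᵢⱼ is the number of fragments supporting
"*i* spliced before *j*". With a symmetric pseudo count *a* = 0.1 the
frequency matrix

> *D*ᵢⱼ = (*A*ᵢⱼ + *a*) / (*A*ᵢⱼ + *A*ⱼᵢ + 2*a*)

is the MAP estimate of the per-pair splicing probability under a
Beta(1.1, 1.1) prior. The likelihood of a splicing order
θ = O₁, …, Oₙ (O₁ spliced first) is the product of *D*ᵢⱼ over the
*n*(*n*−1)/2 pairs it orders, and the most likely order is

> θ\* = argmax over all *n*! permutations of Σ ln *D*ᵢⱼ,

an instance of the linear ordering (Kemeny) problem. It is solved exactly by
search over all permutations for *n* < 12 and by binary integer linear
programming with triangle (transitivity) constraints for 12 ≤ *n* < 100.
The reverse of θ\* is the *least* likely order. Three diagnostics accompany
θ\*:

- **relative log-likelihood** R = ln L(1→2→⋯→*n* | D) − ln L(θ\* | D) ≤ 0:
  0 means splicing follows transcription exactly; strongly negative means it
  does not;
- **uniqueness**: whether θ\* is the only optimum (ties arise when pairs lack
  reads);
- **normalized entropy** ∈ [0, 1]: the Shannon entropy of the
  likelihood-weighted distribution over all *n*! orders, divided by
  log₂(*n*!) — a measure of splicing-order heterogeneity (*n* < 12).

Transcripts are filtered by pair retention (fraction of intron pairs with any
read support; default threshold 0.95), intron count (≥ 3) and, when an
expression table is given, TPM > 0.1. A retained-intron bias correction
max(*b* − PSI·(*b*+*c*+*d*), 0) subtracts mature-isoform reads that mimic
late splicing.

## Worked example

```python
import numpy as np
from spliceorder import SplicingOrderModel

A = np.zeros((4, 4))            # A[i-1, j-1]: reads supporting i before j
A[3, 0] = 12; A[0, 3] = 1       # intron 4 before intron 1: 12 vs 1 reads
A[0, 1] = 9;  A[0, 2] = 7;  A[1, 2] = 6
A[3, 1] = 8;  A[3, 2] = 5;  A[2, 1] = 1

res = SplicingOrderModel(A, transcript_id="demo").fit()
print(res.summary())
```

```
Most likely intron splicing order
============================================
transcript:              demo
introns (n):             4
method:                  exhaustive
most likely order:       4->1->2->3
most unlikely order:     3->2->1->4
log-likelihood:          -0.3094
relative log-likelihood: -10.7242
unique optimum:          True
pair retention:          1.000
normalized entropy:      0.2458
```

Intron 4 is spliced first (12 of 13 informative reads place it before
intron 1), then introns 1, 2, 3. R = −10.72 says this transcript is very
unlikely to be spliced in transcription order; the low entropy (0.25) says
one order clearly dominates. The frequency-matrix entry behind the first
call is D₄₁ = 12.1/13.2 ≈ 0.9.

## Command line

```bash
spliceorder simulate --outdir sim --seed 7            # FASTA+GTF+SAM+truth bundle
spliceorder detect --alignments sim/reads.sam --gtf sim/annotation.gtf --out pairs.tsv
spliceorder correct-ri --pairs pairs.tsv --psi ri_psi.tsv --out corrected.tsv
spliceorder infer --pairs pairs.tsv --out orders.tsv  # --min-retention 0.95 --adjust-value 0.1
spliceorder evaluate --orders orders.tsv --true-orders sim/true_orders.tsv --out summary.tsv
spliceorder stability --alignments sim/reads.sam --gtf sim/annotation.gtf --out stability.tsv
```

The built-in simulator generates a synthetic multi-intron transcriptome,
assigns each transcript a uniformly random true splicing order, enumerates
the *n*+1 pre-mRNA intermediates that order implies, and samples
short-paired-end, mate-pair or long reads from them — so the whole
detect → infer → evaluate pipeline can be validated end to end with no
downloads. A matrix mode (`--mode matrix`) instead draws Poisson read counts
per intron pair directly, with optional random pair erasure to emulate
undetected pairs.

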