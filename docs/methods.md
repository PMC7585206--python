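# Methods

## Evidence model

A sequenced fragment from a partially spliced transcript carries joint
information about several introns. Per fragment and intron, the status is:

- **SPLICED** — some splice gap in the alignment matches the intron's
  boundaries exactly (0 bp tolerance on both ends);
- **UNSPLICED** — an aligned block crosses an exon–intron boundary of the
  intron with at least `min_anchor` aligned bases on each side, and no gap in
  the fragment matches the intron;
- **UNKNOWN** otherwise.

Mates of a read pair are merged *before* classification, so one mate can
supply the junction and the other the retained intron. Every
(SPLICED *i*, UNSPLICED *j*) combination yields one "i before j" observation;
a fragment contributes at most one count per ordered pair and, because a gap
forbids the UNSPLICED call for the same intron, can never support both
directions of a pair. Fragments containing a splice gap that matches no
annotated intron of the isoform under consideration are discarded for that
isoform — this guards against alternative 5′/3′ splice-site artefacts
masquerading as order evidence.

`min_anchor` defaults to 6 bp: junction-adjacent alignment is prone to
slippage, and requiring a short anchor on both sides of the boundary keeps
spurious UNSPLICED calls out without discarding much real evidence. Junction
matching itself is exact; tolerance windows would re-admit exactly the
wobble the anchor rule excludes.

Intron indices count in the direction of transcription (intron 1 is
promoter-proximal), so on minus-strand transcripts the intron with the
largest genomic coordinate has index 1. Coordinates are 0-based half-open
internally; GTF input is converted on read. One isoform is analyzed at a
time; isoforms sharing introns are not merged.

## Frequency matrix and likelihood

Counts A become frequencies D via
`D[i,j] = (A[i,j] + a) / (A[i,j] + A[j,i] + 2a)` with pseudo count
`a = 0.1` on both sides — the MAP of a binomial proportion under a
Beta(1+a, 1+a) prior, so pairs with no reads sit at exactly 0.5 and no
entry ever reaches 0 or 1. With `a = 0` explicitly configured, a pair with
no reads in either direction is a no-evidence marker and contributes a
factor of 1 to every order's likelihood.

The log-likelihood of an order is the sum of ln D over the pairs it orders.
Natural log is used for likelihoods and the relative log-likelihood
R = ln L(in-order)/L(θ\*); log base 2 appears only inside the entropy, whose
normalizer is log₂(n!). The entropy is the standard Shannon form
−Σ p log₂ p of the likelihood-normalized distribution over all n! orders,
so it lies in [0, 1] and *increases* with splicing-order heterogeneity;
float accumulation error is clamped to the bound. It is computed only for
n < 12 (enumeration of n! likelihood values) and reported as missing above.

## Optimisation

- **n < 12** (`method="exhaustive"`): the optimum over all n! permutations is
  found with an exact dynamic program over intron subsets
  (O(2ⁿ·n²)): placing intron k first among a remaining set R contributes
  Σ_{j∈R∖{k}} ln D[k,j], so the best completion of each subset is computed
  once. The DP also counts the number of optimal orders (ties compared at
  1e−9) and reconstructs the lexicographically smallest optimum, which is the
  one reported with `unique=False` when ties exist. This is algebraically
  identical to literal enumeration and is cross-checked against one in the
  tests for n ≤ 7.
- **12 ≤ n < 100** (`method="ilp"`): binary variables y[i,j] (i<j; 1 ⇔ i
  before j), objective Σ y·ln D[i,j] + (1−y)·ln D[j,i], and triangle
  constraints y[i,j] + y[j,k] − y[i,k] ∈ [0,1] for all i<j<k, generated
  eagerly (≤ 161,700 at n = 99). The backend is HiGHS branch-and-cut via
  `scipy.optimize.milp`, an exact solver. θ\* is recovered by sorting introns
  by their number of pairwise wins. Uniqueness is checked by re-solving with
  a no-good cut excluding the first solution and comparing optima within
  1e−6; for ILP-sized transcripts uniqueness is reported but not used as a
  downstream filter. −∞ objective coefficients (possible only at `a = 0`)
  are clamped to −1e12 for solver stability.

The least likely order is the reversal of θ\* — the pairwise objective is
antisymmetric under reversal — and this identity is tested by enumeration.

## Filters and the retained-intron correction

Pair retention = (# unordered intron pairs with ≥ 1 read, before pseudo
counts) / (n(n−1)/2). The default inference threshold is 0.95: the
count-matrix erasure simulation shows order recovery degrades quickly below
that. Default transcript filters: ≥ 3 introns; TPM > 0.1 when an expression
table is supplied.

A retained intron RI inflates the evidence that RI is spliced *after* other
introns, because reads from the mature retained-intron isoform look like
"other intron spliced, RI not". With b = A[other, RI], c = A[RI, other] and
d = fragments in which both introns are spliced, the corrected count is
max(b − PSI·(b+c+d), 0), where PSI is the fraction of mature transcripts
retaining the intron (from an external intron-retention caller; the package
consumes a `transcript_id, intron_index, PSI` table). b, c and d are always
taken from the uncorrected counts, the correction is applied against each
other intron, never yields a negative count, and runs before pseudo counts
and after retention is computed (retention describes raw detection). The
detector exports d per pair in a side table, since A itself stores only
ordered pairs.

## Simulator

The simulator's role is validation: does the detect → infer pipeline recover
a known truth?

- **Transcriptome**: non-overlapping transcripts on one synthetic contig,
  random strand, with compact fission-yeast-like architecture by default —
  100 transcripts, 3–8 introns each (uniform), exon lengths
  ~Normal(150, 30) bp floored at 30, intron lengths uniform 50–100 bp.
  Deterministic FASTA/GTF for a given seed.
- **Truth**: each transcript gets an independent, uniformly random splicing
  order θ.
- **Intermediates**: the n+1 pre-mRNA species implied by θ (species k lacks
  the first k introns), at equal abundance — no kinetic model of
  intermediate lifetimes is imposed, which is the simplest assumption
  consistent with sampling every species.
- **Reads**: per species, Poisson(depth) fragments (depth default 100);
  fragment lengths rounded Normal(mean, sd) with sd defaulting to mean/10,
  truncated at 2×read_length for paired modes and clipped to the molecule;
  starts uniform. Paired modes emit two terminal mates of `read_length`;
  long-read mode emits one read of `read_length` entering from either
  fragment end with equal probability (unstranded cDNA — with a fixed 5′
  anchor, molecules longer than the read would never expose their 3′
  introns). Reads are emitted as already-aligned records (blocks + splice
  gaps) and optionally written as SAM/FASTQ; no sequencing errors or indels
  are simulated, so alignment is exercised only through coordinates, not
  base calls. Passing tests therefore demonstrate correctness of the
  inference given correct alignments, not robustness to alignment error.
- **Matrix mode**: Poisson(15) reads per intron pair in the θ-consistent
  direction, intron counts ~Poisson(7) clipped to [2, 11] so the exhaustive
  path applies to every replicate, with optional uniform random erasure of a
  fixed number of unordered pairs.

Reference sequencing modes mirror common platforms: 150 bp paired-end with
800 bp fragments; ~800 bp long reads; ~5000–12000 bp long reads;
mate-pair with ~15 kb fragments.

## Validation suite sizes

The stochastic validations run at sizes chosen to make their qualitative
outcome stable across seeds: 200 replicates for the count-matrix erasure
design (retention 100/95/90/80%), 100 random instances for the
ILP-vs-enumeration equivalence (n = 4–8), 200 random matrices for the
reverse-order identity (n = 3–7), and 100 transcripts × 3 read-length modes
at depth 100 for the end-to-end read simulation. At full pair retention and
Poisson-15 counts the true order is recovered essentially always; with
full-molecule long reads, end-to-end recovery on the default transcriptome
is ≥ 90%.

## Known limitations

- Exactly one isoform per transcript id; no quantitative handling of
  overlapping isoforms beyond the unannotated-junction discard.
- No heuristic ordering for n ≥ 100 introns (such transcripts are skipped
  with a reason).
- PSI values, TPM values and per-intron features (splice-site scores, GC,
  FPKM) are consumed as externally computed tables, never computed here.
- The simulator does not emulate sequencing error, coverage decay along the
  gene body, or unequal intermediate abundances; conclusions about real
  data robustness to those effects must come from real data.
- Non-unique optima are reported (lexicographically smallest order,
  `unique=False`) and excluded from recovery statistics; downstream users
  should filter on `unique` for n < 12, as the order columns are otherwise
  tie-broken arbitrarily.
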