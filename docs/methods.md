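# Methods

## The problem

A sequencing read that lies inside a transposon consensus cannot be
assigned to a genomic copy, and — more importantly — cannot distinguish
autonomous transposon transcription from host-gene transcripts that have
spliced into an intronic insertion. `techimera` resolves this with
breakpoint-spanning evidence: contiguous sequences that physically join a
unique genomic locus to a transposon consensus. All downstream statistics
(insertion calls, penetrance, autonomy, co-expression enrichment) are built
on that evidence.

## Reference model

The analysis reference is the repeat-masked genome plus one copy of each
transposon consensus appended as an extra named sequence. Masking is exact
seed-and-extend: all maximal exact matches (seed 25 nt, reported at ≥ 50 nt,
both strands) between genome and any consensus are soft-masked (lowercase;
hard-masking to N is available). This is deterministic and exactly
recoverable by a brute-force shared-window oracle, which the test suite
exploits; it does not reach the sensitivity of alignment-based repeat
maskers on diverged copies, so for real genomes a pre-masked FASTA can be
supplied instead (`build-ref --premasked`). Masked bases are excluded from
alignment seeding, which forces every repeat-derived read onto the single
appended consensus — the property the whole design relies on.

Gene annotation (GFF3, or refFlat) is indexed into exon/intron/UTR interval
lookups and a splice-site catalog (donor = transcription-wise exon end,
acceptor = exon start, both as 0-based half-open boundary coordinates).
Internally all coordinates are 0-based half-open; human-facing TSVs are
1-based inclusive, BED stays 0-based.

## Detection

1. **Merging.** Read pairs are merged by the best overlap of read 1 with
   the reverse complement of read 2 (lowest mismatch ratio, ties to the
   longer overlap), accepting overlaps of 10–170 nt with mismatch ratio
   ≤ 0.15. Unmerged pairs pass through as two independent contigs by
   default (`--merged-only` drops them): long fragments that marginally
   fail to overlap still carry usable junction sequence.
2. **In-silico pairs.** Each contig yields one pair of 100-nt ends (end 2
   reverse-complemented). 100 nt comfortably exceeds the 20-nt minimum
   chimeric segment while keeping end classification unambiguous.
3. **Alignment.** An exact-seed (k = 31) index over the combined reference
   classifies each end as genome / te / multi / unmapped; extension allows
   ≤ 2 mismatches and no indels, which is sufficient for error-free
   synthetic data. Real data should be aligned externally with any
   split-read-capable aligner and imported as SAM; the downstream contract
   is identical.
4. **Refinement.** For candidates (exactly one genome end, one te end) the
   parent contig is re-anchored on both references and the two alignments
   extended maximally towards each other. Microhomology at the junction
   (both references matching the same contig bases) is assigned to the
   genome side — deterministic and auditable, since the homology length is
   recorded per read. Junctions with either segment < 20 nt are dropped.
   gDNA contigs are unstranded and normalized so the genome side reads
   along the reference '+' strand; cDNA contigs keep transcript
   orientation, so the contig-order of genome and TE segments gives the
   chimera direction (gene→TE vs TE→gene) and the genome-side alignment
   strand gives the transcript strand.
5. **Dedup + clustering.** One evidence record per source read (exact
   resolution preferred); PCR duplicates are deliberately *not* collapsed —
   read counts feed the IGE threshold, which absorbs amplification effects
   — though identical-fragment collapsing can be added at the counting
   stage. Evidence is grouped by (sequence, TE, direction, transcript
   strand, TE strand) and chained along the genome with a 20-nt
   single-linkage window; representative breakpoints are modal member
   values (ties to the smallest coordinate), preserving single-nucleotide
   information through aggregation.

## Germline insertion calls

Upstream (genome→TE) and downstream (TE→genome) gDNA clusters of the same
TE and orientation are paired within 50 nt (TSDs are short; the window is a
package choice). The overlap `upstream_bp − downstream_bp` is the TSD.
Population frequency is the fraction of individuals contributing ≥ 1
supporting read when read names carry individual tags (the simulator's
convention, `:i<k>:`); otherwise a read-ratio fallback
`support / (support + reference-spanning reads)` is used. Calls under the
frequency cutoff (default 0.5) are routed to a secondary output, not
discarded. One-sided calls (missing mate cluster) are emitted with a null
TSD and flagged.

## IGE artifact FDR

Library amplification ligates unrelated cDNA fragments, creating chimera
look-alikes. Immobile genetic elements — single-copy exons matched to each
TE's expression within 2-fold bins (widened once to 4-fold before failing)
— are appended as decoy references with their loci masked, exactly
mirroring consensus handling, and the identical detection path is re-run.
Exons of genes that already carry detected TE chimera loci are excluded
from candidacy: they are not clean immobile decoys, and masking them would
erase the junctions under study. IGE chimeras landing inside the decoy's
own gene (± 1 kb) are genuine splice junctions and are not counted as
artifacts.

`fdr(T)` is the mean over sets of IGE clusters with support ≥ T divided by
the **unfiltered** total cluster count; the fixed denominator makes the
FDR non-increasing in T by construction, and the reported threshold is the
smallest T with `fdr(T)` at or below the target (default 0.05%). Pooled
and per-set rates are both reported, since per-sample thresholding and
pooled accounting give slightly different quotients.

## Quantification

* **Junction-window counting.** Penetrance and LTR ratios count reads by
  containment of a reconstructed 60-mer spanning the junction (30 nt per
  side, both orientations searched). Chimeric and canonical junctions are
  counted by the same mechanism so their detection efficiencies cancel;
  counting chimeric reads from cluster membership but canonical reads by
  substring would bias penetrance downward, because clustering requires
  clean in-silico ends while substring counting does not.
* **Penetrance.** Per (gene, TE) locus and side:
  `chimeric / (chimeric + canonical)` junction reads, where the canonical
  junction is the spliced exon–exon window when the breakpoint sits on an
  annotated splice site and the contiguous genomic window otherwise
  (UTR/exonic read-through); the combined value is read-weighted.
* **Autonomy.** TE-only reads are in-silico pairs with both ends entirely
  on one consensus, normalized per consensus nucleotide; TE–gene reads are
  breakpoint-spanning cluster members. For LTR elements, gene–LTR reads
  (genomic sequence outward of an LTR end) versus LTR–TE reads (spanning
  the LTR/core boundary inside the consensus) are reported per end as a
  percentage capped at 100 with the raw ratio retained; autonomous
  transcription gives ~0, promoter read-through gives ~1.
* **Splice motifs.** Breakpoints on the transcript-oriented consensus are
  screened for donor (MAG|GTRAGT-like) and acceptor (pyrimidine-rich
  NCAG|G-like) contexts with fixed position-weight matrices shipped in the
  package, scored as log-odds (bits) against a uniform background. The
  invariant dinucleotide is classified separately: GT → consensus,
  GC donor with an otherwise strong context → noncanonical_GC. Because
  microhomology makes the exact frame ambiguous by a few nucleotides, the
  scanner takes the best frame within ± 3 nt. The significance threshold
  defaults to the 99th percentile of best-frame scores on shuffled copies
  of the scanned windows (deterministic internal seeding); a fixed
  threshold can be passed instead.
* **Isoform enumeration.** Given host donors/acceptors around an intronic
  insertion and TE-internal sites, isoforms are donor→acceptor chains with
  strictly increasing coordinates that start at a host donor and terminate
  at the first host acceptor reached; sites are never reused. Intron
  retention counts as one extra isoform only when requested, since
  published isoform tallies rarely state their retention convention. The
  enumeration is verified against exhaustive path enumeration on all site
  sets of ≤ 12 sites.

## Coexpression disequilibrium

Per feature, UMI counts are binarized at the 33.33rd percentile across all
cells (zeros included, linear interpolation) — cells above the threshold
are ON. The per-feature (rather than global) threshold matters because
transposon and gene abundances differ by orders of magnitude. For features
A and X on one replicate's cells, `CD = P(A∧X) − P(A)P(X)`
(range ± 0.25), normalized by its attainable extreme given the marginals —
`min(P_A,P_X) − P_A P_X` for positive CD, `P_A P_X − max(P_A+P_X−1, 0)`
for negative — giving CD′ ∈ [−1, 1]. Within each replicate a transposon's
CD′ against every feature is ranked descending (ties averaged); each
pair's per-replicate ranks are tested with a one-sample t-test against
µ = (n+1)/2, the mean rank of a complete ranking (testing ranks rather
than raw CD values is the only reading in which µ is on the rank scale).
Zero-variance rank vectors are flagged degenerate with p = 1 if centred on
µ and the smallest representable double otherwise. Benjamini–Hochberg runs
across one transposon's pairs. Enrichment compares significant
TE–resident-gene pairs against the mean over 10 equal-size random gene
assignments with a two-category goodness-of-fit χ² (expected 0 replaced by
0.5, flagged).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study design the toolkit targets: an inbred
population with polymorphic germline insertions. The emitted FASTA is the
insertion-free reference; each insertion lives on individual haplotypes,
flanked by a duplicated target site (`ref[:p+t] + TE + ref[p:]`), carried
by `floor(freq·n + 0.5)` of n individuals. Defaults mirror the assayed
library design: 250-nt paired reads, ~350-nt fragments, stranded cDNA with
mate 1 on the transcript strand, gDNA coverage counted per individual.
Chimeric isoforms are built from TE-internal donor/acceptor sites at a
per-gene splicing fraction; fragment yield per isoform scales with molar
abundance × valid start positions so junction-read fractions are unbiased
estimators of the splicing fraction. Artifacts ligate two random expressed
fragments at a uniform internal position — the simplest model that makes
artifact incidence track the partners' expression product. Single-cell
matrices draw OFF cells from Poisson(0.05) noise and ON cells from
1 + Poisson(depth−1), with planted pairs co-ON at a stated joint
probability per replicate.

Not emulated: sequencing errors and quality variation (a knob exists but
defaults off — the pipeline logic, not error correction, is under test),
consensus divergence of individual TE copies, UMI collisions, doublets,
heterozygous carriers, and genes on the '−' strand in generated models
(the detection code handles both strands; the generator plants '+' genes
and varies TE orientation instead). Passing tests therefore demonstrate
correctness of the breakpoint arithmetic, bookkeeping and statistics — not
robustness to divergent repeats or base-calling noise, which on real data
are delegated to an external aligner via SAM import.

The generator plants junctions with zero cross-junction sequence identity
(points and splice sites are nudged by a few nt until no chance
microhomology remains). Planted breakpoints are then exactly recoverable;
without this, calls would be exact only up to the recorded deterministic
microhomology assignment.

## Numerical and design choices

* Exact-match extension everywhere (no indels); ≤ 2 mismatches for end
  classification only.
* Cluster representatives: modal breakpoint, ties to the smallest value.
* Tie-break at junctions: genome-maximal split.
* Frequency estimator prefers per-individual evidence over read ratios.
* FDR denominator fixed at the unfiltered total (monotonicity by
  construction).
* Degenerate inputs: all-zero features binarize to all-OFF (logged);
  CD′ of a degenerate marginal is 0; empty cluster lists raise in
  `compute_fdr`; contigs shorter than the in-silico read length are
  skipped and counted.
* Test and validation problem sizes (200-kb genomes, tens of genes,
  hundreds of fragments per gene, 20-seed sweeps) were chosen so every
  property check carries enough events to be sharp while the whole suite
  runs in minutes on one CPU.

## Known limitations

* The internal aligner is for controlled benchmarks; real libraries need
  an external split-read aligner (SAM import path).
* Masking misses diverged repeat copies by design; supply a pre-masked
  genome for real references.
* Identical 5′/3′ LTRs make reads wholly within an LTR ambiguous (class
  multi); junction evidence inside LTRs therefore requires the contig to
  reach the LTR/core boundary, which lowers—but does not bias—LTR-end
  evidence counts.
* The isoform count depends on the stated chain-termination and retention
  conventions; alternative conventions give different absolute counts for
  the same locus.
* The read-ratio frequency fallback assumes homozygous carriers and equal
  detectability of junction and reference alleles.
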