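# Methods

This note records the models behind `reflank`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions a maintainer would need.

## The protocol being modeled

Genomic DNA is digested with a restriction cocktail chosen so that each
young-retroelement copy releases a fragment consisting of part of the
element plus 25–800 bp of unique genomic flank (the 5' flank for Alu
subfamilies, the 3' flank for L1HS). A stem-loop adapter carrying a random
10-nt UMI is ligated to every fragment before any amplification, so the
number of distinct UMIs at a junction estimates the number of contributing
cells. Nested PCR with subfamily-specific primers enriches target flanks;
paired-end 150+150 sequencing reads the element side (mate 1) and the
adapter/UMI/flank side (mate 2).

Enzyme definitions shipped as editable defaults: FspBI C^TAG, Csp6I
G^TAC, TaqI T^CGA (Alu libraries use FspBI+Csp6I, L1 libraries
TaqI+FspBI). All three cut one base into a four-base site; coordinates are
0-based half-open throughout and a "junction" is the reference coordinate
where the amplified flank meets the element.

### Read layout (a declared convention)

The amplicon, read in mate-1 orientation, is

```
[20-nt subfamily primer][30-nt diagnostic RE tail][flank][rc(UMI)][rc(stem remnant)]
```

so mate 1 = primer + diagnostic tail + junction-proximal flank, and mate 2
= 8-nt stem-loop remnant + UMI + cut-site-proximal flank. Which mate
carries the UMI is a free choice of the assay design; the parser honors
this layout and no other. Six fixed positions inside the diagnostic tail
are checked exactly to confirm the subfamily (primer matching allows ≤ 2
mismatches, no indels; UMIs containing N are rejected because molecule
counting requires exact UMI identity). Near-duplicate UMIs (1 mismatch)
are *not* merged by default; a merge flag exists but sequencing error at
10 nt and these depths makes exact counting the safer default.

## The mini-genome generator

A random backbone (default 60 kb) receives, per subfamily, a configurable
number of reference copies (default 5) with 3% per-copy divergence —
protected over the 60 edge bases nearest the amplified junction so primers
and diagnostic positions stay intact, exactly as young-subfamily copies
keep their primer sites. Synthetic consensi (L1HS 1000 bp, Alu 300 bp —
mini-genome scale stand-ins for 6 kb/300 bp elements) avoid all
recognition sites so digestion cannot sever primer from junction.
Polymorphic germline insertions (default 2 per subfamily; heterozygous
with probability 0.6; 25% "private", i.e. absent from the known-insertion
database) and somatic events are placed ≥ 1.2 kb from everything else, at
positions whose flank passes the 25–800 bp size-selection window — planted
events are recoverable by design, while reference copies may land with
unamplifiable flanks and are then simply absent from libraries (and
logged), as in real data. Target-site duplications are supported per event
but default to 0; with the amplified-side junction defined as the
insertion point they do not move the reported coordinate.

Molecules: one tagged molecule per cell per haplotype carrying each
junction (reference copies: two haplotypes; heterozygous germline: one;
somatic: per-cell Bernoulli(cell_fraction) on one haplotype, tumor role
only). Default 100 cells per sample.

### PCR model and per-locus efficiency

Copy numbers follow per-cycle Bernoulli doubling over the 26 nested-PCR
cycles. Efficiency is **locus-intrinsic**: each junction draws a per-cycle
efficiency uniformly from 0.9 ± 0.1, fixed across samples and replicates
(derived from the event id). Compounded over 26 cycles this yields the
orders-of-magnitude between-locus count differences seen in real targeted
libraries, and it is what makes the Q1 rule and the partial mixture
detection behave realistically: without it all loci amplify identically
and every quantile-based filter degenerates.

### Artifacts

- **Off-target molecules** (default rate 0.08): correct primer, two
  diagnostic positions mutated — older-subfamily copies amplified
  spuriously. The parser rejects them (`offtarget_re`), which is what
  makes library specificity land in the realistic 0.85–0.95 range.
- **Ligation chimeras** (default 0.01/molecule): an intact RE part joined
  to a random genomic window whose ends do not fall on restriction cut
  sites, each with a fresh UMI.
- **Template-switch chimeras** (default 0.005/read): during amplification
  a read keeps its molecule's RE part and UMI but acquires a foreign
  flank — either another molecule's flank or an interior window of an
  annotated copy. Switching is restricted to molecules of the same
  library (same enzyme cocktail): AluYa5 and AluYb8 co-amplify in one
  tube and can recombine; L1 cannot cross into Alu.

The published rates of these artifacts are not known; the defaults are
placeholders chosen to stress the filters without dominating libraries.

## Calling

Flanks are mapped by a k-mer (k=13) seed table with pigeonhole seeding and
Hamming verification, mismatch budget 2% of flank length; ties across loci
are reported unmapped — conservative for somatic calling. Junctions within
10 bp on the same subfamily/strand merge into one call (modal position).
The 10 bp window is a coordinate-matching tolerance accommodating
TSD/clustering jitter; it is configurable and used consistently for
clustering, database lookup, and tumor/normal matching.

**Chimera filtering** implements the two artifact signatures:

- *(a) ligation signature*: the flank's distal (adapter-side) end must
  abut a cut site of the library's cocktail. The distal coordinate comes
  from the parsed full flank length when a mate reveals it (mate-1 adapter
  anchor, or the rc of the RE part on mate 2), otherwise from mapping the
  mate-2 distal segment, retried with a 20-nt tail trim for flanks
  slightly longer than a mate. Unplaceable distal ends are retained — the
  filter never removes a read it cannot indict, trading recall for
  precision.
- *(b) template-switch signature*: the junction lies strictly inside an
  annotated RE copy — of any subfamily, because a cross-subfamily switch
  within one tube leaves the same footprint under another family label.

The generator and filter are deliberately self-consistent here: the
simulator's ligation chimeras join fragments at non-cut positions, which
is exactly what signature (a) detects. Real ligation chimeras formed from
two complete restriction fragments *do* end at cut sites and would evade
(a); in the real protocol they are suppressed biochemically (anti-adapter
plus continued digestion during ligation), which the simulator represents
only as the low ligation rate. This is this package's interpretation of
the two published artifact classes, not a reproduction of any specific
production pipeline's heuristics.

**Candidate criteria**: a call is a tumor-specific candidate iff it is (1)
not within the window of any reference-copy junction or known polymorphic
insertion, (2) absent — zero support of any subfamily — from the matched
normal, (3) absent from the cohort (other samples of the run plus optional
prior-run tables), and (4) supported by ≥ 2 distinct UMIs. Database and
normal matching are by locus alone (family-blind): a wrong-subfamily call
at a known junction is a template-switch signature, not a novel insertion.
Unmatched (tumor-only) calling is refused.

**Validation PCR** is a genotype-level truth table: junction reactions
(one for L1, two for Alu) band iff an insertion allele is present; the
GSP-F+GSP-R control bands iff an empty allele is present, or size-shifted
when a homozygous insertion is still within amplifiable size (default cap
3 kb — full-length L1 exceeds it, Alu does not).

## Sensitivity protocol

Q1 uses the linear-interpolation (type-7) quantile — the convention is not
dictated by the protocol, so it is documented and configurable.
Discriminating insertions require count ≥ Q1 in donor 1 (inclusive) and
exactly 0 in donor 2 (a locus missing from a metatable counts as zero).
Flank search uses edlib infix alignment, ≤ 1 edit (mismatch *or* indel),
both strands, each read counted at most once per flank; per-pair counts
are reported as a secondary column since whether mates were counted
separately in the original experiment is unspecified. Detection defaults
to ≥ 2 raw reads, with the ≥ 2-distinct-UMI criterion reported alongside.

The mixture itself runs at desk scale: 40 minor-donor cells into 4,000
major-donor cells (0.99% — the design's 500:50,000 preserved in ratio) at
3,000 read pairs, two replicates. Depth ladders reuse one sequencing run
per replicate and evaluate read prefixes, so detection is non-decreasing
in depth run by run (common random numbers); likewise somatic-titration
carrier sets are coupled across cell fractions through shared per-cell
uniforms.

## Expression quantification

QC follows PRINSEQ-style semantics: truncate to 75+75, drop a pair when
either mate's mean quality is strictly below 20 or exceeds 3% N, and
deduplicate by exact concatenated mate sequence (quality-blind), first
occurrence kept. Batching shuffles deterministically under the seed and
splits into exactly 4,500,000-read batches (a pair counts two reads by
default; a flag switches to pair units), discarding the remainder; an
input smaller than one batch returns a single truncated batch with a
warning flag.

A pair counts toward a subfamily iff both mates align with zero
mismatches/indels to the same active-set element, on opposite strands, in
convergent orientation, with insert 50–600 bp ("proper pair" made
explicit because no aligner is involved), once per subfamily regardless of
how many elements match. The synthetic reference carries 12 L1HS + 8
L1PA2 active elements of 1,200 bp (desk-scale stand-ins for the 151 + 85
full-length elements of the curated database; a real FASTA can be supplied
by path) plus 20 decoys at 5% divergence with mutations spaced ≤ 70 bp, so
no decoy has a mutation-free 75-mer window — an error-free decoy read can
never count.

The two-group contrast simulates 7 samples per group at 3,000 pairs,
active share 0.2 of transcripts, duplicate fraction 0.1, sequencing error
2×10⁻³, and log-normal per-sample biological variability σ = 0.3 — a
typical bulk-RNA-seq biological CV for a homogeneous tissue, which makes
per-sample subfamily counts of ~200–320 dominated by biology rather than
Poisson noise. Group comparisons use the two-sided Mann–Whitney U (exact
null when tie-free, tie-corrected normal approximation otherwise; p = 1
when pooled values are all identical) with BH adjustment across exactly
the comparisons of one invocation.

## Determinism and problem sizes

All randomness flows from one root seed through named substreams
(SeedSequence spawn keys per stage), so stages are independently
reproducible and identical configurations give byte-identical outputs
(FASTQ gzip mtime is pinned). The studies run at these sizes: 60 kb
genomes with 15 reference copies; 80–200 cells and 12,000–25,000 read
pairs per library; 20 negative-control pairs; 10 titration seeds ×
3 cell fractions × 3 depths; mixture 40:4,000 cells at 1,000–9,000 reads;
expression 14 samples × 3,000 pairs. These choices keep a full
reproduction in the minutes range on a single CPU.

## What the synthetic data does not show

Uniform substitution error only (no quality-dependent or indel error
profiles); no thermodynamic primer/hybridization modeling, no
whole-genome pre-amplification step, no FACS losses beyond exact cell
counts; mini-genomes lack genome-scale repeat structure, so mapping
ambiguity is milder than against a real reference; chimera rates are
assumptions, not measurements. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated generative
model — not the wet-lab performance of the assay on patient material.
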