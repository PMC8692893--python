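# Methods

`ignarkit` re-creates, as tested reusable code, the computational analysis
of a heavy-chain-only antibody (IgNAR) repertoire study in the white-spotted
bamboo shark: germline cluster mining from a genome, V(D)J annotation of
vNAR amplicon reads, repertoire diversity/clonality statistics, and
cysteine-pattern typing of vNAR domains.  Because the study's raw
sequencing data (~10^8 reads) are not reproducible at desk scale, every
pipeline stage is validated by *parameter recovery*: a ground-truthed
simulator generates inputs at the study's published composition and the
pipeline must recover each configured quantity within sampling tolerance.

## Germline mining (`ignarkit.germline`)

Shark immunoglobulin loci are cluster-type: each locus carries its own V,
D, J and C segments.  A complete IgNAR cluster is 1 V, 3 D, 1 J, 5 C, one
secretory-tail (Sec) and one transmembrane-tail (Tm) exon in genomic order;
recombination signal sequences (RSS: heptamer + 12/22/23-bp spacer +
nonamer) flank V/D/J.

**RSS scanning.** `find_rss` is an exhaustive Hamming scan of both strands
for every configured motif and spacer class, vectorised with NumPy
sliding-window comparisons.  Defaults: canonical heptamer `CACAGTG`,
nonamer `ACAAAAACC`, spacers {12, 22, 23}, budgets of 2 heptamer and 3
nonamer mismatches.  `N` or any non-ACGT character never matches a motif
base, so it consumes budget; hits are deduplicated per
(contig, start, strand, spacer) keeping the lowest-mismatch assignment.
The scanner is property-tested against an independent naive per-window
oracle (10,000 seeded genomes, lengths mostly 60–400 bp with a sampled
10 kb tail — sizes chosen so the deliberately slow oracle stays honest),
and for strand-mirror symmetry and budget monotonicity.

**Segment search.** `scan_segments` is seed-and-extend: exact 8-mers
clustered by diagonal, candidate windows aligned with an affine-gap
Smith–Waterman (match 2, mismatch −3, gap open −5, extend −2; Biopython
`PairwiseAligner`).  Hits need ≥ 0.8 identity over ≥ 0.8 of the reference.
Two specificity rules matter at genome scale:

* a diagonal qualifies only with two seeds ≥ k apart — a single chance
  match of k+1..2k−1 bases produces overlapping seeds and would otherwise
  flood the aligner;
* references shorter than 3k (D segments, ~9–15 bp) are located by exact
  full-length match only.  A local alignment of a 12-bp query has no
  genome-scale specificity; tolerance for short segments comes from their
  RSS evidence instead.

Overlapping same-kind hits collapse to the highest identity (ties: leftmost
start, then + strand).  Each V/D/J hit is annotated with its nearest
compatible RSS within a 10-bp flank (RSS physically abut their segments;
the genomic-right flank carries a +-oriented motif hit, the left flank a
−-oriented one).

**Cluster assembly.** Segments on one contig/strand with successive gaps
≤ 50 kb (configurable; the real clusters sit ~110 kb apart within 0.8 Mb)
form a cluster, named `IgNAR1..n` in genomic order.  Completeness is the
exact composition-and-order rule above.  Robustness rules: an isolated
group consisting only of RSS-less D hits is background, not a locus;
RSS-less D hits outside their cluster's V–J interval are dropped (germline
D sits between V and J); a D is called *pre-joined* unless it carries both
flanking RSS, which is robust to sloppy chance RSS hits landing on one
side.  Export produces `germline.fasta` (records `IGNARV1`, `IGNARD1-1`…,
matching the field's naming), a lossless TSV (coordinates, identity, RSS
evidence as JSON, CDR3 anchors) and an optional GFF3 (RSS as
`recombination_feature`).

## Read annotation (`ignarkit.annotate`)

Reads are single-end ~400-bp vNAR amplicons.  QC removes reads shorter
than 200 bp, with > 2% N, or mean quality < 20 (quality rule skipped with a
note for FASTA input).  Annotation is two-stage, reflecting the high
similarity of IgNAR cluster paralogs:

1. *Primary*: every germline V and J is aligned to the read by edit
   distance in infix mode (edlib).  The best V hit over both strands fixes
   the read orientation; top-3 candidates per gene type are kept
   (identity ≥ 0.75), J candidates restricted to start after the best V
   ends.
2. *Refinement*: each candidate's full alignment path is recomputed,
   junction-side germline-only columns (junctional trimming) stripped, and
   the boundary then extended base-by-base toward the junction while the
   read matches the germline — the maximal germline-attributable span.
   The call maximises (identity, aligned length, database order).

D is called by the longest end-trimmed germline-D core of ≥ 6 bp matching
the junction with ≤ 1 mismatch, else `none`.  CDR3 runs from the codon
after the FR3b canonical cysteine codon of the V (anchor stored per
germline segment) to the codon before the conserved FR4 tryptophan codon
of the J, mapped through the refined alignment and translated in the V
frame; `productive` requires an in-frame junction and no stop codon across
the assembled region.  The clonotype key is `(v_call, j_call, cdr3_aa)`.
Every read lands in exactly one table row; QC failures keep their row with
empty calls and a reason (`unassigned`, `overlapping calls`, `anchor not
covered`…).  On mined germlines without simulator anchors, the V anchor
falls back to the last in-frame TGY codon and the J anchor to the first
TGG — a heuristic that is exact for the synthetic germline family and
should be checked against curated references on real data.

## Statistics (`ignarkit.stats`)

Clonotype diversity is the Shannon–Wiener index H = −Σ pᵢ ln pᵢ (nats; the
log base is a convention, so Pielou evenness H/ln k is reported alongside,
and both read-weighted and clonotype-collapsed variants are emitted since
the weighting convention is itself a choice).  Positional variability is
Wu–Kabat: (number of distinct residues)/(frequency of the most common
residue), gaps excluded, undefined at zero coverage.  Other statistics:
V×J pairing matrix (read-weighted by default, clonotype-weighted on
option), cumulative top-n clonotype frequency (ties by key order),
sequence uniqueness (distinct/total as primary definition plus singleton
fraction), clonotype overlap (|A∩B|/min(|A|,|B|) by default — symmetric,
1.0 for nested samples — with Jaccard as an option), and clonotype
tracking over the union of per-time-point top-n keys with residual mass as
`other` (columns sum to 1).  Statistics default to productive
rearrangements only (switchable).  Plots are intentionally out of scope;
every statistic is emitted as tidy TSV/JSON for downstream plotting.

## vNAR typing (`ignarkit.vnar_types`)

Regions follow the vNAR convention FR1, CDR1, FR2, HV2, FR3a, FR3b, CDR3,
FR4.  A region-annotated reference template (~100 aa; canonical cysteines
at the ends of FR1 and FR3b, conserved tryptophans in FR2 and at the FR4
start) ships as YAML-editable data.  Region assignment uses a fast path —
when the framework prefix (FR1..FR3b) and FR4 suffix each match the
template at ≥ 0.8 ungapped identity over framework positions, only CDR3
length differs and labels transfer directly — falling back to a global
BLOSUM62 alignment whose insertion columns inherit the neighbouring
region, preferring hypervariable labels at boundaries.  Sequences below
0.5 framework identity are unalignable and excluded with a reason.

The type rule table (a partition, verified by exhaustive enumeration over
cysteine placements):

| type | rule (all require exactly one Cys in FR1 and one in FR3b, none in HV2/FR3a) |
|------|------|
| I    | Cys in FR2 and FR4, even count ≥ 2 in CDR3, none in CDR1 |
| II   | exactly one CDR1 Cys and ≥ 1 CDR3 Cys, none in FR2/FR4, no CDR1 Trp |
| III  | the type II pattern with a conserved CDR1 Trp |
| IV   | canonical pair only |
| new  | anything else, including a missing canonical pair |

Classification depends only on cysteine placement and the CDR1 tryptophan,
so it is invariant to all other substitutions (tested).

## Simulator (`ignarkit.simulate`)

The simulator is first-class code defining the study conditions; all
defaults are the published quantities where printed, and stated choices
where not.

**Germline.** Seven clusters on one contig: 1/2/5/6 complete, 3/4/7
lacking V and D, pre-joined final D in 2/5/6 — the published germline
organisation.  V covers FR1..FR3b plus two germline CDR3 codons (anchor =
FR3b Cys codon); J contributes two CDR3-tail codons plus FR4 (anchor = FR4
Trp codon).  Cluster paralogs diverge by 5% neutral substitutions with
anchors protected, and are guaranteed ≥ 2 substitutions apart *within the
span junctional trimming can never remove* — otherwise paralogs differing
only in trimmable tails would be fundamentally unidentifiable from reads.
Spacer classes: V 23, D 12/12, J 22 (which spacer class attaches to which
segment kind is not printed; this assignment is the package's choice).
RSS are planted with exactly the configured mismatch counts; intersegment
gap 200 bp, inter-cluster gap 110 kb (7 clusters ≈ 0.8 Mb).

**Repertoire.** Each read draws its V–J pair from the pair table
(defaults: IGNARV1:IGNARJ1 0.96, then 0.02/0.01/0.01 for clusters 2/5/6 —
the dominant share is the published 96%; the minor split is a stated
choice), then a clone within that pair's pool under a discrete power law
(rank^−0.8 over 10,000 clones at baseline).  This factorisation makes
read-weighted pair usage exactly multinomial — the scale on which recovery
is asserted — while clonality statistics keep power-law structure.  The
junction model is geometric V/J trimming (mean 2, capped at the 6-nt
germline CDR3 head/tail so anchors survive), optional D (probability 0.8,
geometric end-trimming, ≥ 6-bp cores when called), and Poisson N-insertions
(mean 3 per side); the shark junction statistics are not published, so
these are standard placeholder choices.  SHM is a per-clone per-base
substitution rate (default 1%), sequencing error per-read (default 0.1%),
reads single-end 400 bp at constant Q30, optional flanking study primers.
`simulate_timecourse` shares clone pools across samples and multiplies
programmed clones' weights to emulate antigen-driven expansion.

*Validation mode*: with trimming plus random N-insertions, V/J boundary
attribution is inherently ambiguous (junction bases chance-continue the
germline; insertions chance-imitate D cores), so no annotator can recover
truth exactly.  The `identifiable_junctions` flag rejection-samples
junctions until the planted parse is the unique parsimonious one; the
exact-recovery test combines it with zero trimming, SHM 0 and error 0.
This mode exists to make "100% recovery" a well-posed claim and is off by
default.

**Library.** Type mixture defaults to the published profile — II 79.0%,
new 18.8%, IV 1.9% — with the unprinted 0.3% residual assigned to type I.
Type II receives one CDR3 cysteine (the classic 4-cysteine pattern) with
probability 0.745/0.790 and two otherwise, so the published 74.5%
four-cysteine share emerges from type II exactly as described; "new" is
realised as canonical pair + lone FR2 cysteine (3 Cys), I as 6 Cys, IV as
2.  Randomised positions exclude C/W so placement controls type identity.
Each emitted slot is a fresh draw with probability equal to the configured
uniqueness (0.838), else a uniform resample of an earlier sequence, making
distinct/total binomial around the configured value.

What the simulator does *not* emulate: platform-specific error profiles,
PCR bias and chimeras, indel SHM, allelic variation beyond the planted
paralogs, and real junction statistics.  Passing recovery tests therefore
demonstrates pipeline correctness under the stated generative model, not
performance on real BGISEQ data.

## Problem sizes and numerics

Acceptance-scale runs use n = 50,000 reads/sequences (the scale at which
3σ sampling tolerance is meaningful for the published percentages) and
n = 10,000 for exact recovery; unit tests use hundreds.  Frequency tables
must sum to 1 within 1e-9; Shannon closed forms hold to 1e-9.  Ties are
always broken deterministically (documented per operation), and every
generator and pipeline output is byte-identical under a fixed seed.

## Known limitations

* Anchor heuristics on mined (non-synthetic) germlines assume the FR3b
  cysteine is the last in-frame TGY codon of V.
* The D caller cannot distinguish a true short D core from an identical
  chance N-insertion — an information-theoretic limit, handled honestly by
  the validation mode rather than hidden.
* Overlapping refined V/J extensions fail QC (`overlapping calls`) rather
  than being re-split; this costs ~3% of reads at default trimming.
* The typing fast path assumes framework/CDR1/HV2 lengths match the
  template; length variants there take the slower alignment path.
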