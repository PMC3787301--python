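# Methods

## Overview

`melacog` re-implements, as a tested library, the comparative-genomics
computations used to characterise a small set of related genome bins: the
construction of cross-genome ortholog clusters from reciprocal best hits,
best-hit taxonomic voting, KEGG pathway-category assignment, single-copy-
marker completeness grading, assembly statistics, RnpB/TLR5 marker scans,
and 16S survey abundance tallying.  Every stage runs end-to-end on a
seeded synthetic-data generator with planted ground truth, so the whole
pipeline is testable without any external database.

## Pairwise search

The bundled aligner computes optimal affine-gap Smith–Waterman local
alignments over BLOSUM62 (taken from biotite's standard table) with gap
existence 11 and extension 1: a gap of length L costs 11 + L.  Score
statistics use the Karlin–Altschul gapped constants λ = 0.267, K = 0.041:

    bitscore = (λ·S − ln K) / ln 2
    E        = K·m·n·exp(−λ·S)

with m the query length and n the total residue count of the subject set
of the call, mirroring database-size scaling.  These constants are
conventional for BLOSUM62/11/1 and are configuration, not fitted values.
Alignment length counts gapped columns, so `length × pident/100` equals
the number of identical columns — the convention of the 12-column tabular
hit format, and the quantity the voting rule consumes.

Determinism: traceback ties resolve in fixed operator order (diagonal,
then gap-in-subject, then gap-in-query) and the alignment is anchored at
the first maximal cell in row-major order.  There is no heuristic seeding:
every query–subject pair is aligned (a score-only linear-memory pass
first; full traceback only for pairs passing the e-value cut).  This is
exact and fast enough for proteome-scale inputs; genuinely large searches
should import an external hit table instead.

## Ortholog clustering

Proteins of different genomes are joined by an edge when each is the
other's best hit (bitscore, ties by e-value then subject id).  Candidate
clusters take exactly one member per genome; a candidate is valid when at
least two members are connected to all other members and every member is
connected to all but at most one (for four genomes: ≥ 2 nodes of induced
degree 3, minimum degree 2).  The rule is generalised to G genomes as
(≥ 2 members of degree G−1, all of degree ≥ G−2), reducing to the quad
rule at G = 4.

Overlapping valid candidates inside a connected component are resolved by
a deterministic greedy: rank by induced edge count (descending), summed
mean-bitscore of edges (descending), then lexicographic member ids, and
accept subject to member disjointness.  Disjointness itself is a design
choice — a protein joins at most one cluster — made for auditability;
self-comparisons of a genome against itself are never computed.

## Taxonomic voting

Per gene: reference hits with e-value ≤ 1e−5 are ranked by bitscore; the
top two are compared by identical positions IP = length × %identity/100.
The top hit wins outright when IP1 ≥ IP2 × 1.05 ("at least 5% more",
inclusive); otherwise the gene is "Multiple".  No passing hit gives
"No hit"; a single passing hit assigns its phylum (one unambiguous hit is
stronger evidence than none).  The comparison carries an absolute slack
of 1e−9 so the inclusive boundary survives float rounding.  Two
non-separable top hits from the same phylum still yield "Multiple" by
default (the literal rule); `collapse_same_phylum` toggles that.

Per cluster: unique plurality phylum over member labels wins; all-"No hit"
gives "No hit"; a tied plurality, or ≥ 2 member-level "Multiple" votes
(`multiple_threshold`, the minimal reading of "several" with four votes),
gives "Multiple".  One uncovered corner: a label vector with hit evidence
but no phylum votes at all (e.g. one "Multiple" plus three "No hit")
resolves to "Multiple" — evidence exists but is ambiguous.

Raising the margin can only move per-gene outcomes from a phylum toward
"Multiple", never the reverse; this monotonicity is property-tested.

## KEGG assignment

The cluster representative is its member from the first genome in the
configured order.  The KO of the representative's best passing hit against
a KO-labelled reference is assigned; no hit means category "unknown".  A
KO in no pathway is "Undecided"; pathways spanning several categories give
"Multiple"; otherwise the shared category is assigned.  In summaries, "no
functional assignment" pools "unknown" with "Undecided" (they are also
reported separately).  The KO mapping ships as three TSVs (gene2ko,
ko2pathway, pathway2category); there is no live database access.

## Genome grading and assembly statistics

Marker inventory is similarity-based: each protein counts toward at most
one marker, the one holding its top-bitscore hit at e-value ≤ 1e−5.  The
bundled default marker set is the core of 16 syntenic ribosomal proteins
(rpL2, 3, 4, 5, 6, 14, 15, 16, 18, 22, 24; rpS3, 8, 10, 17, 19); its
representative sequences are synthetic (deterministic background-frequency
draws at realistic lengths), suitable for simulation studies where the
same representatives are planted in the graded genomes — supply curated
representatives for real data.

Status: Complete requires every marker present and all scaffolds in one
linkage component; Near Complete requires the full marker set and a
largest linkage component covering ≥ 90% of scaffolds ("almost all" is
not quantified in the original definitions; 0.9 is a configurable knob);
anything else is Partial.  Adding linkage never demotes the grade, and
losing any marker forces Partial.

N50 is the largest L such that scaffolds of length ≥ L sum to at least
half the assembly; %GC is computed over unambiguous bases only.

## Marker scans

RnpB loci are exact matches to GAGGAAAGTCC (U ≡ T) on both strands, with
coordinates 1-based inclusive on the forward strand and flanks of 500 bp
truncated at scaffold ends; an optional ≤ 1-mismatch mode exists but
defaults off.  The flagellin TLR5 region is the query's columns globally
aligned (BLOSUM62, 11/1, via biotite) to reference residues 88–103;
`gapped` records whether any reference position in the span aligns to a
gap.  Whether TLR5 would recognise a flagellin is deliberately not
computed — that call requires inspection of the alignment — so the module
only emits regions, ordered for display by average-linkage clustering on
column identity (the ordering algorithm is a stand-in; any deterministic
similarity ordering would serve).

## 16S survey

Hits are retained at ≥ 97% identity (inclusive), one assignment per read
by top bitscore.  Relative abundance is 100·target/total per sample.
Zero-read samples are removed and whole sample types with fewer than five
summed retained reads are dropped before plotting; abundances are reported
log10-transformed (0.1% ↦ −1).  The two-group comparison is a two-tailed
Student t-test with pooled variance (the unadorned "t-test" convention);
Welch's variant is available by flag.  Sample-type merging is driven by a
user-supplied map, since such grouping is editorial rather than
algorithmic.

## Synthetic data: what it emulates, and what it does not

Defaults are the study conditions exercised by the tests: 4 genomes, 200
ortholog families, per-copy per-site substitution probability 0.05, no
duplication or loss (both available as knobs, with paralogs at +0.2
divergence), protein lengths Normal(250, 50) truncated at 60.  Ancestral
sequences are background-frequency draws (Robinson–Robinson); mutation is
i.i.d. replacement by a background draw, so a copy's expected identity to
its ancestor is (1−d) + d·Σf² ≈ 95.3% at d = 0.05, and two sibling
copies sit near (1−d)² + 2d(1−d)Σf² + d²Σf² ≈ 91%.  Identity levels are
all the downstream decision rules see, so no rate matrix is used.

The reference database plants, per family, one close homolog (divergence
0.10 from the ancestor) carrying the family's nearest phylum and one decoy
per other phylum at divergence 0.35, so the margin rule must actually
separate competing hits.  Phylum fractions default to Firmicutes 0.30,
Cyanobacteria 0.15, Proteobacteria 0.30, Bacteroidetes 0.15, the remaining
10% of families having no reference counterpart ("No hit") — echoing a
study where the dominant best-match phyla were Firmicutes (~30%) and
Cyanobacteria (~15%).  70% of referenced families carry a KO; 10% of KOs
belong to no pathway and 10% to pathways of two categories, covering all
three branches of the category rule.

Scaffolds are uniform-codon back-translations joined by random spacers
(50–200 bp) and cut at gene boundaries near a 50 kb target; three RnpB
motifs per genome are planted at recorded positions and strands; linkage
chains a configurable fraction of scaffolds (1.0 by default, so default
genomes grade Complete).  The survey draws per-sample abundances from
per-type log-normals — foregut-fermenter feces at median 0.60%, hindgut at
0.15% (so the two-group test has a real effect to find), water 1.0%, soil
0.02%, and air at 0.0005%, which lands under the five-read type threshold
and exercises the type-removal rule; 10% of target reads get sub-97%
decoy identities.

One integer seed drives a hierarchical `SeedSequence` stream with one
substream per stage, so stages regenerate independently and identical
seeds give byte-identical files.

What the generator does *not* emulate: phylogenetically realistic
evolution (no rate heterogeneity, indels, or domain structure), database
composition bias, assembly or read-level artefacts, chimeras, or amplicon
primer effects.  Passing recovery tests therefore demonstrates the
correctness of the decision rules and their implementation under
controlled identity structure — not robustness to real metagenomic noise.

## Problem sizes and numerical choices

The recovery checks run the default 200-family study once (a few minutes
on one core); the degenerate-limit and byte-determinism checks use
smaller generated studies (60 and 25 families) since the properties they
assert are size-independent.  The exhaustive oracles (64 quad graphs, 625
vote tuples, 10,000 randomized hit sets, 500 brute-force alignments) are
seeded and deterministic.  Degenerate inputs fail loudly: empty sequences,
empty scaffold sets, missing taxonomy or KO labels, and missing pair hit
tables all raise with the offending entity named.

## Known limitations

* The all-vs-all aligner is exhaustive by design; nr-scale searches are
  out of scope (import external hit tables).
* Marker detection is similarity-to-representative, not profile-based;
  remote homologs of markers will be under-counted on real data.
* The greedy quad selection is order-deterministic but not globally
  optimal when many valid quads overlap.
* TLR5 recognition calls and RNA secondary-structure typing are
  intentionally absent.
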