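# Methods

## The analysis model

The pipeline targets selfing diploid species, so every accession is
treated as a homozygous haplotype. Variant discovery is pairwise and
reference-free: accession X's reads are aligned to accession R's assembled
unigenes, and a transcript column becomes a call iff

* read depth is strictly greater than 10, and
* one non-reference allele (a base, an inserted string, or a deleted span)
  accounts for strictly more than 95% of the aligned bases at the column.

Indels are left-aligned and anchored at the base preceding the event; the
consensus fraction for an indel is its supporting-read count over the
depth at the anchor column. Base and mapping qualities are not consulted —
the rule filters on depth and consensus only. Because a self-comparison
(R's reads vs R's transcripts) can only produce calls through systematic
error (assembly miscalls, recurrent misalignment), any pairwise call whose
(transcript, position, class, alt) key recurs in the self-comparison is
removed. Per-reference non-redundant (NR) sets are the alt-aware
deduplicated union over read accessions; keeping the alternate allele in
the key preserves information and is isolated behind one function should a
position-only key ever be preferred.

Anchoring lifts each NR variant through its transcript's best placement on
each of two related-species genomes by block-offset arithmetic ("−"-strand
placements reverse the within-block direction). Indels are anchored by the
lifted position of their anchor base alone; this deliberately anchors a
variant whose span is a reference-private insertion (the span does not
exist in the genome, but the anchor base does). SNP or anchor positions
falling in unaligned gaps stay unanchored. Integration partitions the NR
set into both / A-only / B-only / neither and builds a union preferring
genome A's coordinates (configurable).

Cross-species analysis builds a site × accession matrix of consensus
bases, keeping only sites where *every* accession (both ingroup panels and
the outgroup) passes the same depth/consensus filters, dropping sites with
more than two alleles panel-wide. Two comparable-length definitions are
exposed: `L_comparable` (all sites passing filters — the default
denominator for per-site θ and π) and the SNP-only row count; both are
reported because either reading of a "number of sites" is defensible.
From the matrix: S, singleton and non-singleton counts, θ_W = S/a₁,
π as the average pairwise difference, and Tajima's D with the standard
normalization (b₁, b₂, c₁, c₂, e₁, e₂). D is undefined at S = 0 and is
reported as 0 for n = 2, where its numerator vanishes identically and the
normalizing variance is 0. π is computed because D needs it, although θ is
the headline statistic. Significance annotation for D is out of scope; the
value is reported unadorned.

Polarization uses a single outgroup accession: at a site polymorphic
within an ingroup, if the outgroup allele equals one of the two segregating
alleles the other is derived; a third outgroup allele makes the site
unpolarizable. Classes plus unpolarizable always sum to S.

Trees: pairwise distance is the count (or proportion) of differing matrix
columns; neighbor-joining agglomeration is delegated to scikit-bio (it
reproduces the three-taxon closed form exactly); bootstrap support is
computed in-repo by resampling matrix columns with replacement (default
1000 replicates, seeded) and counting internal bipartitions. Output trees
are rooted at the outgroup.

Orthology is reciprocal best hit under the in-repo seed-and-extend scorer
(match +1, mismatch −1, gap −2 per base; configurable), with query
coverage strictly over 0.80 required in both directions and tied best
scores discarding the query. FPKM counts fragments whose mates both map
concordantly to one transcript: FPKM = fragments × 10⁹ / (length × total
counted fragments). Kendall's τ-b with a two-sided p-value (scipy) backs
all rank correlations; the test suite checks it against exhaustive pair
enumeration.

Marker selection takes anchored indels of length ≥ 4 bp ("longer than
3 bp", read strictly, consistent with the strict depth and consensus
thresholds). Primer design is a deterministic heuristic — 18–24-mers in
150 bp flanks, GC 40–60%, no mononucleotide run over 4, Wallace-rule
Tm = 2(A+T) + 4(G+C) balanced within 3 °C, amplicon 100–300 bp preferring
the middle of that range — a dependency-free stand-in for a full
thermodynamic design tool, adequate for size-difference genotyping where
the amplicon gap equals the indel length by construction.

## The toy aligner

`toyalign` exists so synthetic bundles run end-to-end with no external
tools; it is not a general-purpose aligner. Exact k-mer seeds (k = 21)
vote for (sequence, diagonal) placements; the best candidates are resolved
by banded edit-distance alignment (edlib) over a ±12 bp window, allowing
indels up to ~10 bp; reads beyond a 15% edit budget are unmapped (the
budget accommodates one 10 bp indel plus the worst-case SNP load of a
100 bp read). Ties across distinct locations break toward the smallest
(transcript, position) and are flagged ambiguous with mapping quality 0.

Two guards keep pileups faithful near read boundaries, where an alignment
cannot represent an indel it only partially covers:

* **End soft-clipping.** If two or more non-match columns fall within
  18 bp of an alignment end — the smear a truncated indel leaves — the end
  is clipped through the last offending operation. A single mismatch or
  1 bp gap (a legitimate variant near the read end) is left alone.
* **Pileup end trim.** The outer 12 bp of each read's aligned span
  (measured inside soft-clips) contribute neither base counts nor indel
  evidence, and an indel is accepted only if its anchor base lies in the
  counted window, so a read can never add anchor depth while its event
  evidence was discarded.

Transcript-to-genome mapping reuses the same machinery per strand, derives
gapless blocks from the extended CIGAR, trims unaligned query overhangs,
and keeps the best locus by identity × coverage (defaults: identity ≥ 0.9,
coverage ≥ 0.5; "mapped" has no standard definition in this setting, so
the thresholds are explicit and logged). Only the best locus per
transcript is kept, matching the one-anchor-per-genome contract.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes —
it is the ground truth for every end-to-end test, not a fitted model of
any real dataset.

* **Coordinates.** All interspecies divergence (between the two ingroups,
  to the outgroup, and between the two genomes) is substitutional, so
  every species base sequence and both genomes share the ancestral
  coordinate frame; only intra-species indel polymorphisms shift
  coordinates, and only in carrier accessions. Truth genome coordinates
  are therefore exact, and the anchoring round-trip is an equality check,
  not a tolerance check.
* **Site-frequency modes.** Derived-allele counts i ∈ 1..n−1 are drawn
  with weights 1/i (neutral — the standard equilibrium expectation, which
  makes E[π − θ_W] = 0 exactly under this sampler), 1/i² (expansion —
  rare-allele excess), or i(n−i) (structured — intermediate-frequency
  excess). Analytically these give E[D] ≈ 0, −1.0 to −1.2, and +1.3 to
  +1.5 for n = 10–12, chosen up front so the sign contrast between the
  two demographic regimes is unambiguous. They are stand-ins for the
  qualitative negative/positive contrast, not inferred histories — no
  demographic model is fitted anywhere. Because sites are drawn
  independently, panel-to-panel variance of D is smaller than a coalescent
  with linkage would give; an msprime cross-check in the test suite covers
  the genuinely correlated case.
* **Planting rules.** Variants keep ≥ 25 bp spacing, stay one fragment
  length (2 × read length + 10) from transcript ends, indels are ≥ one
  read length apart (so no read spans two), and indel content is built
  from the two bases absent from both immediate flanks — making the
  left-aligned representation unique against shifts of any step size and
  against splitting into smaller gaps. These rules are what turn
  "precision = recall = 1.0" from a statistical hope into a designed
  property; real data violates all of them, which is exactly why the
  error-bearing and artifact modes exist.
* **Reads.** Fragments are fixed at 2 × read length (mates tile the
  fragment contiguously) with stratified, jittered starts; with uniform
  expression the per-transcript fragment count is deterministic, so
  interior coverage concentrates near the target depth and the strict
  depth filter cannot stochastically drop a planted site at the default
  depth of 20. With expression dispersion > 0, weights are log-normal and
  counts Poisson — coverage guarantees are then statistical, which is the
  intended regime for FPKM rank-recovery checks. Errors are uniform
  per-base substitutions; no quality-score model is simulated (the caller
  ignores qualities by design).
* **Artifacts.** `assembly_error_rate` plants wrong bases in the
  *assemblies only* (reads are drawn from the true haplotypes), emulating
  per-accession assembly miscalls — the recurrent artifact class the
  self-comparison filter removes. Bundles carry both the assemblies and
  the true haplotypes plus an artifact truth table.
* **Genomes.** Seven chromosomes per genome, genes concatenated in
  conserved order with N-spacers; genome B genes carry independent
  substitutions and random strands; per-genome gene missingness produces
  the one-genome-only anchoring classes. Missingness is configured per
  genome (the single-probability field split in two) because asymmetric
  missingness is what the integration analysis needs to exercise.

What passing tests on these bundles shows: the calling rule, coordinate
arithmetic, filters and statistics are implemented correctly and the
pipeline is internally consistent at realistic scales. What they do not
show: performance under real Illumina error profiles, isoform mixtures,
paralogy, spliced alignment, or assembly fragmentation — all explicitly
out of scope (isoforms are collapsed to one unigene per gene upstream of
this pipeline's contract).

## Scales and numerical choices

The acceptance run uses 500 genes of 500–900 bp and a 12-accession panel
at depth 20 for recovery/anchoring, 150 genes with 2% read error and
5 × 10⁻⁴ assembly errors for the filter check, 200 genotype panels per
demographic mode (n = 10, 20 kb, 5 × 10⁻³ per-bp polymorphism), 2000 sites
per polarization spectrum, 200 bootstrap replicates for tree support
(1000 remains the library default), and 50 random matrices for the
estimator-vs-oracle comparison at 10⁻¹⁰ tolerance. All randomness in the
package flows through numpy Generators seeded from configuration; repeated
runs are byte-identical.
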