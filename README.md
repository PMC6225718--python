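# synvar

Reference-free comparative transcriptomics for species without a genome
assembly: pairwise SNP/indel discovery from RNA-seq read-vs-transcript
alignments, synteny-based anchoring of the variants onto related species'
pseudomolecules ("virtual chromosomes"), and a two-species
population-genetics comparison — segregating sites, Watterson's θ,
nucleotide diversity π, Tajima's D, outgroup-polarized site-frequency
spectra, fixed differences, neighbor-joining trees with bootstrap,
reciprocal-best-hit orthology, FPKM expression, and indel-derived PCR
markers.

The intended user works on a wild crop relative (a selfing diploid with a
large repetitive genome) where de novo transcript assembly per accession is
feasible but whole-genome assembly is not. Each accession's unigene set
serves as a reference; every other accession's reads are aligned to it;
conserved gene order lets the chromosome-scale assemblies of two related
species act as positional scaffolds for the variants.

## The core rules and statistics

* **Calling rule.** A transcript position yields a SNP or indel call iff
  read depth > 10 and a single non-reference allele accounts for > 95% of
  the aligned bases (both strict). The material is treated as homozygous.
* **Artifact filter.** Variants also found when an accession's own reads
  are aligned to its own transcripts are artifacts (assembly errors,
  systematic misalignment) and are removed from every pairwise set.
* **Non-redundant (NR) set.** The deduplicated union of pairwise calls
  against one fixed reference accession, keyed by (transcript, position,
  class, alternate allele), with supporting read accessions retained.
* **Diversity.** For a sample of n sequences with S segregating sites,
  θ_W = S/a₁ with a₁ = Σ_{i<n} 1/i; π is the mean number of pairwise
  differences; Tajima's D = (π − S/a₁) / √(e₁S + e₂S(S−1)) with the
  standard constants. The derived allele at a polymorphic site is the one
  differing from the outgroup.
* **Orthology.** Two transcripts form an ortholog pair iff each is the
  other's unique best nucleotide-alignment hit with query coverage > 80%
  in both directions. FPKM counts concordantly mapped fragments only.

A built-in generator (`synvar.synthdata`) produces two-ingroup + outgroup
bundles with planted variants, truth tables, syntenic genomes and paired
reads, so every stage is testable against known truth; site-frequency
modes (`neutral`, `expansion`, `structured`) control the allele-frequency
spectrum and hence the sign of Tajima's D.

## Worked example

```bash
synvar --run-dir demo all --seed 5 --n-genes 30 --reference A01 --bootstrap 25
```

simulates a bundle (6 accessions of species A drawn with the expansion
spectrum, 5 of species B with the structured spectrum, one outgroup),
aligns all reads to accession A01's transcripts, calls and consolidates
variants, anchors them to both genomes, and prints the population-genetics
report, ending with:

```json
{
  "L_comparable": 14270,
  "n_sites": 243,
  "diversity_A": {
    "group": "A", "n": 6, "S": 17, "singletons": 10, "non_singletons": 7,
    "theta_w": 7.445255474452555, "theta_w_per_site": 0.0005217417991907887,
    "pi": 7.333333333333333, "pi_per_site": 0.0005138986218173324,
    "tajimas_d": -0.09324468821603883, "L": 14270
  },
  "diversity_B": {
    "group": "B", "n": 5, "S": 17, "singletons": 9, "non_singletons": 8,
    "theta_w": 8.160000000000002, "theta_w_per_site": 0.0005718290119131046,
    "pi": 8.4, "pi_per_site": 0.0005886475122634899,
    "tajimas_d": 0.21615059744726112, "L": 14270
  },
  "fixed_differences_AB": 50
}
```

Read it as: of 14,270 transcript positions comparable in every accession,
243 are high-confidence biallelic SNPs (most of them interspecies
differences, monomorphic within each panel). Within species A (expansion
spectrum) 17 sites segregate, with an excess of singletons, so π < θ_W
and Tajima's D is negative; within species B (structured spectrum) the
intermediate-frequency excess makes D positive — the qualitative contrast
the pipeline is built to detect, clearer at larger panel sizes (the
acceptance run's 200-panel means are about −1.1 and +1.3). 50 sites are
fixed between the species. The run directory also
holds the NJ tree (`nj_A01.nwk`, outgroup-rooted, bootstrap percentages on
internal nodes), per-chromosome variant densities, ortholog pairs, FPKM
tables, indel marker candidates with primer pairs, and a manifest with
checksums of every output.

Each stage is also available as a library call (`synvar.variants.call_variants`,
`synvar.popgen.diversity_summary`, ...) and as an individual subcommand
(`simulate`, `align`, `call`, `consolidate`, `anchor`, `popgen`, `ortho`,
`markers`).

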