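"""Generator contracts: determinism, SFS shape, truth-table consistency."""

import numpy as np
import pytest
from scipy import stats

from synvar import synthdata
from synvar.synthdata import SimConfig, sample_derived_counts, sfs_weights, simulate_dataset, simulate_reads
from synvar.seqio import TranscriptSet


def test_zero_rate_config_yields_identical_accessions_and_empty_truth():
    cfg = SimConfig(seed=5, n_genes=10, snp_rate_intra=0.0, indel_rate_intra=0.0,
                    divergence_AB=0.0, divergence_outgroup=0.0,
                    n_accessions_A=3, n_accessions_B=2)
    b = simulate_dataset(cfg)
    assert len(b.truth) == 0
    seqs = [ts.records for ts in b.transcript_sets.values()]
    assert all(s == seqs[0] for s in seqs)


def test_same_seed_gives_identical_bundles():
    mk = lambda: simulate_dataset(SimConfig(seed=7, n_genes=15, n_accessions_A=3,
                                            n_accessions_B=2, indel_rate_intra=2e-3))
    b1, b2 = mk(), mk()
    assert b1.truth.to_frame().equals(b2.truth.to_frame())
    assert b1.genomes == b2.genomes
    assert all(
        b1.transcript_sets[a].records == b2.transcript_sets[a].records
        for a in b1.accessions
    )
    r1a, _ = synthdata.simulate_bundle_reads(b1, "A01")
    r1b, _ = synthdata.simulate_bundle_reads(b2, "A01")
    assert r1a == r1b


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimConfig(snp_rate_intra=1.5)
    with pytest.raises(ValueError):
        SimConfig(divergence_AB=0.05, divergence_outgroup=0.01)
    with pytest.raises(ValueError):
        SimConfig(n_accessions_A=1)
    with pytest.raises(ValueError):
        SimConfig(sfs_mode_A="bottleneck")
    with pytest.raises(ValueError):
        SimConfig(gene_length_range=(100, 200))


def test_neutral_sfs_matches_one_over_i_expectation(rng):
    """Neutral derived counts follow p(i) ∝ 1/i within multinomial error."""
    n, sites = 10, 2000
    counts = sample_derived_counts(n, sites, "neutral", rng)
    observed = np.bincount(counts, minlength=n)[1:n]
    expected = sfs_weights(n, "neutral") * sites
    chi2, p = stats.chisquare(observed, expected)
    assert p > 0.01


def test_sfs_mode_singleton_ordering(rng):
    """Expansion piles onto singletons, structure depletes them."""
    n, sites = 10, 1000
    frac = {}
    for mode in ("neutral", "expansion", "structured"):
        c = sample_derived_counts(n, sites, mode, rng)
        frac[mode] = np.mean(c == 1)
    assert frac["expansion"] > frac["neutral"] > frac["structured"]


def test_truth_outgroup_allele_is_ancestral(small_bundle):
    """At intra-species sites the outgroup carries the ancestral allele."""
    truth = small_bundle.truth
    out_idx = truth.accessions.index(small_bundle.outgroup)
    intra = truth.df["scope"].str.startswith("intra")
    assert not truth.genotypes[intra.to_numpy(), out_idx].any()


def test_truth_coordinates_inside_genome_bounds(small_bundle):
    sizes = {**small_bundle.chrom_sizes("A"), **small_bundle.chrom_sizes("B")}
    df = small_bundle.truth.df
    for chrom_col, pos_col in (("chrom_A", "pos_A"), ("chrom_B", "pos_B")):
        present = df[chrom_col].notna()
        for chrom, pos in zip(df.loc[present, chrom_col], df.loc[present, pos_col]):
            assert 1 <= int(pos) <= sizes[chrom]


def test_genome_gene_content_matches_missingness(small_bundle):
    gt = small_bundle.gene_table
    # genome A has every gene, genome B drops the absent ones
    assert gt.present_A.all()
    for gid, present in zip(gt.gene, gt.present_B):
        assert (gt.loc[gt.gene == gid, "start_B"].notna().iloc[0]) == present


def test_error_free_reads_are_exact_substrings(rng):
    ts = TranscriptSet("X", {"t1": "ACGT" * 100})
    r1, r2 = simulate_reads(ts, depth=4.0, read_length=50, error_rate=0.0, seed=rng)
    assert len(r1) == len(r2) > 0
    seq = ts["t1"]
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    for _, s, _ in r1:
        assert s in seq
    for _, s, _ in r2:
        assert s in rc


def test_zero_depth_gives_no_reads(rng):
    ts = TranscriptSet("X", {"t1": "ACGT" * 100})
    r1, r2 = simulate_reads(ts, depth=0.0, read_length=50, error_rate=0.0, seed=rng)
    assert r1 == [] and r2 == []


def test_short_transcript_skipped_with_warning(rng):
    ts = TranscriptSet("X", {"t1": "ACGTACGT"})
    with pytest.warns(UserWarning):
        r1, _ = simulate_reads(ts, depth=5.0, read_length=50, error_rate=0.0, seed=rng)
    assert r1 == []


def test_error_rate_recovered_within_binomial_bounds(rng):
    """Observed mismatch fraction vs truth within 3 SD of the error rate."""
    ts = TranscriptSet("X", {"t1": "".join(rng.choice(list("ACGT"), 2000))})
    err = 0.01
    r1, r2 = simulate_reads(ts, depth=30.0, read_length=100, error_rate=err, seed=rng)
    seq = ts["t1"]
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    mismatches = bases = 0
    for reads, template in ((r1, seq), (r2, rc)):
        for name, s, _ in reads:
            _, _, _, start, fl = name.split("|")
            start, fl = int(start), int(fl)
            true = (
                template[len(seq) - start - fl : len(seq) - start - fl + 100]
                if template is rc
                else seq[start : start + 100]
            )
            mismatches += sum(a != b for a, b in zip(s, true))
            bases += len(s)
    assert bases >= 5e4
    sd = np.sqrt(err * (1 - err) / bases)
    assert abs(mismatches / bases - err) < 3 * sd
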