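"""Shared fixtures: small synthetic bundles and a cached pairwise pipeline."""

import numpy as np
import pytest

from synvar import seqio, synthdata, toyalign, variants


@pytest.fixture(scope="session")
def small_bundle():
    """A modest two-species bundle with indels, strands and missing genes."""
    cfg = synthdata.SimConfig(
        seed=11,
        n_genes=40,
        n_accessions_A=5,
        n_accessions_B=4,
        indel_rate_intra=1.5e-3,
        missing_gene_fraction_B=0.2,
    )
    return synthdata.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_ref(small_bundle):
    return small_bundle.transcript_sets["A01"]


@pytest.fixture(scope="session")
def small_index(small_ref):
    return toyalign.SeedIndex(small_ref.records, k=21)


@pytest.fixture(scope="session")
def pipeline(small_bundle, small_ref, small_index):
    """Aligned pileups and calls for each accession vs A01, computed once."""
    cache = {}

    def run(accession):
        if accession not in cache:
            r1, r2 = synthdata.simulate_bundle_reads(small_bundle, accession)
            aln = toyalign.align_read_pairs(
                [(n, s) for n, s, _ in r1],
                [(n, s) for n, s, _ in r2],
                small_ref,
                index=small_index,
            )
            piles = seqio.pileup_from_alignments(aln, small_ref)
            calls = variants.call_variants(piles, accession, "A01")
            cache[accession] = (aln, piles, calls)
        return cache[accession]

    return run


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
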