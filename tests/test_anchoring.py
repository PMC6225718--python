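"""Coordinate liftover, per-chromosome tallies, two-genome integration."""

import pytest

from synvar import anchoring, synthdata, toyalign, variants
from synvar.anchoring import (
    anchor_variants,
    anchored_to_bed_intervals,
    integrate_two_genomes,
    lift_variant,
    tally_per_chromosome,
)
from synvar.seqio import Block, MappingRecord
from synvar.variants import NonRedundantSet, NRRecord, VariantCall


def _call(tid="t1", pos=50, cls="SNP", ref="A", alt="G"):
    return VariantCall("x", "r", tid, pos, ref, alt, cls, 20, 1.0)


def _single_block_mapping(start=1001, length=200, strand="+", chrom="chr1"):
    return MappingRecord(
        "t1", "A", chrom, start, start + length - 1, strand,
        [Block(1, length, start, start + length - 1)], 1.0, 1.0,
    )


def test_plus_strand_offset_arithmetic():
    av = lift_variant(_call(pos=50), _single_block_mapping(start=1001), 200)
    assert (av.chrom, av.pos, av.strand) == ("chr1", 1050, "+")


def test_minus_strand_reverses_within_block():
    # aligned orientation is the reverse complement: transcript position p
    # maps to start + (L - p)
    av = lift_variant(_call(pos=50), _single_block_mapping(strand="-"), 200)
    assert av.pos == 1001 + (200 - 50)


def test_position_in_unaligned_gap_is_unanchored():
    m = MappingRecord(
        "t1", "A", "chr1", 1001, 1200, "+",
        [Block(1, 80, 1001, 1080), Block(101, 200, 1101, 1200)], 0.9, 0.9,
    )
    assert lift_variant(_call(pos=90), m, 200) is None
    assert lift_variant(_call(pos=120), m, 200).pos == 1120


def test_position_outside_transcript_rejected():
    with pytest.raises(ValueError, match="outside"):
        lift_variant(_call(pos=500), _single_block_mapping(), 200)
    with pytest.raises(ValueError, match="mapping"):
        lift_variant(_call(tid="other"), _single_block_mapping(), 200)


def test_round_trip_against_truth_on_both_genomes(small_bundle, pipeline):
    """Every anchorable NR variant lands on its planted genome coordinate."""
    b = small_bundle
    ref = b.transcript_sets["A01"]
    nr = variants.consolidate_nonredundant(
        [pipeline(a)[2] for a in b.accessions_A[1:]]
    )
    tl = {t: len(ref[t]) for t in ref.ids()}
    truth = b.truth
    i_ref = truth.accessions.index("A01")
    for label in ("A", "B"):
        maps = toyalign.map_transcripts(ref, b.genomes[label], genome_label=label)
        anchored = anchor_variants(nr, maps, tl)
        checked = 0
        for av in anchored:
            gene = av.key[0]
            shifts = synthdata._ref_shift(truth.df, truth.genotypes, i_ref, gene)
            hit = None
            for rr in truth.df[truth.df.gene == gene].itertuples():
                if rr.pos + sum(s for p, s in shifts if p < rr.pos) == av.key[1]:
                    hit = rr
                    break
            assert hit is not None, av
            chrom, pos = getattr(hit, f"chrom_{label}"), getattr(hit, f"pos_{label}")
            assert (av.chrom, av.pos) == (chrom, int(pos)), av
            checked += 1
        assert checked == len(anchored) > 0


def test_tally_partitions_anchored_set():
    anchored = [
        anchoring.AnchoredVariant(("t", i, "SNP", "G"), "r", "A", "chr1", 100 + i, "+", "SNP", "A", "G")
        for i in range(10)
    ]
    counts, density = tally_per_chromosome(anchored, bin_size=1000)
    assert counts["chr1"] == 10 and counts.sum() == 10
    assert density["count"].sum() == 10


def test_tally_empty_set():
    counts, density = tally_per_chromosome([])
    assert counts.empty and density.empty


def _nr_from_keys(keys):
    records = {
        k: NRRecord(k[0], k[1], "A", k[3], k[2], ["x"]) for k in keys
    }
    return NonRedundantSet("r", records)


def _av(key, genome, chrom, pos):
    return anchoring.AnchoredVariant(key, "r", genome, chrom, pos, "+", key[2], "A", key[3])


def test_integration_partition_and_union_preference():
    k1, k2, k3, k4 = [(f"t{i}", 10 * i, "SNP", "G") for i in range(1, 5)]
    nr = _nr_from_keys([k1, k2, k3, k4])
    anchors_a = [_av(k1, "A", "chr1A", 100), _av(k2, "A", "chr1A", 200)]
    anchors_b = [_av(k1, "B", "chr1B", 150), _av(k3, "B", "chr2B", 300)]
    integ = integrate_two_genomes(anchors_a, anchors_b, nr)
    assert integ.both == {k1}
    assert integ.a_only == {k2} and integ.b_only == {k3} and integ.neither == {k4}
    assert integ.n_total == len(nr)
    assert len(integ.union) == 3
    chosen = {a.key: a for a in integ.union}
    assert chosen[k1].genome_label == "A"  # prefers genome A when both anchor


def test_integration_rejects_unknown_keys():
    nr = _nr_from_keys([("t1", 10, "SNP", "G")])
    rogue = _av(("zz", 1, "SNP", "C"), "A", "chr1A", 5)
    with pytest.raises(ValueError, match="unknown NR key"):
        integrate_two_genomes([rogue], [], nr)


def test_empty_b_anchor_set():
    k1 = ("t1", 10, "SNP", "G")
    nr = _nr_from_keys([k1])
    integ = integrate_two_genomes([_av(k1, "A", "chr1A", 100)], [], nr)
    assert integ.fractions()["both"] == 0.0
    assert [a.key for a in integ.union] == [k1]


def test_bed_intervals_follow_conventions():
    snp = _av(("t", 5, "SNP", "G"), "A", "chr1", 1050)
    deletion = anchoring.AnchoredVariant(
        ("t", 9, "deletion", "A"), "r", "A", "chr1", 99, "+", "deletion", "GGG", "A"
    )
    bed = anchored_to_bed_intervals([deletion, snp])
    assert ("chr1", 1049, 1050, "t:5:SNP") in bed
    # 3 bp deletion anchored at base 99: deleted genome span 100-102 -> BED 99-102
    assert ("chr1", 99, 102, "t:9:deletion") in bed
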