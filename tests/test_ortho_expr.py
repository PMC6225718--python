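"""RBH orthology, FPKM arithmetic, Kendall's tau."""

import itertools
import math

import numpy as np
import pytest

from synvar import ortho_expr, synthdata, toyalign
from synvar.ortho_expr import (
    fpkm,
    fpkm_value,
    kendall_tau,
    ortho_theta_scatter,
    OrthologPair,
    rbh_orthologs,
)
from synvar.seqio import AlignmentRecord, TranscriptSet


def test_identical_sets_pair_every_transcript(rng):
    records = {
        f"t{i}": "".join(rng.choice(list("ACGT"), 400)) for i in range(8)
    }
    s1 = TranscriptSet("x", records)
    s2 = TranscriptSet("y", dict(records))
    pairs = rbh_orthologs(s1, s2)
    assert len(pairs) == 8
    assert all(p.id1 == p.id2 and p.coverage_fwd == 1.0 for p in pairs)


def test_true_pairs_recovered_at_two_percent_divergence(rng):
    base = {f"g{i}": "".join(rng.choice(list("ACGT"), 500)) for i in range(10)}
    diverged = {}
    for tid, seq in base.items():
        s = list(seq)
        for p in rng.choice(500, size=10, replace=False):  # 2% substitutions
            s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
        diverged[tid] = "".join(s)
    pairs = rbh_orthologs(TranscriptSet("x", base), TranscriptSet("y", diverged))
    assert {(p.id1, p.id2) for p in pairs} == {(f"g{i}", f"g{i}") for i in range(10)}


def test_coverage_exactly_80_percent_rejected(rng):
    """'over 80%' is strict: a pair at exactly 0.80 coverage is dropped."""
    full = "".join(rng.choice(list("ACGT"), 500))
    s1 = TranscriptSet("x", {"q": full})
    s2 = TranscriptSet("y", {"h": full[:400]})  # 400/500 = 0.80 exactly
    pairs = rbh_orthologs(s1, s2)
    keys = [(p.id1, p.id2, p.coverage_fwd, p.coverage_rev) for p in pairs]
    assert pairs == [] , keys
    # one base more clears the threshold
    s2b = TranscriptSet("y", {"h": full[:401]})
    pairs = rbh_orthologs(s1, s2b)
    assert len(pairs) == 1 and pairs[0].coverage_fwd > 0.80


def test_rbh_symmetric_under_swap(small_bundle):
    s1 = small_bundle.transcript_sets["A01"]
    s2 = small_bundle.transcript_sets["B01"]
    fwd = {(p.id1, p.id2) for p in rbh_orthologs(s1, s2)}
    rev = {(p.id2, p.id1) for p in rbh_orthologs(s2, s1)}
    assert fwd == rev
    assert fwd == {(g, g) for g in s1.ids()}  # planted orthology is 1:1 by id


# ---------------------------------------------------------------------------
# FPKM


def test_fpkm_formula_identity():
    assert fpkm_value(100, 2000, 10_000_000) == pytest.approx(5.0)
    assert fpkm_value(0, 2000, 10_000_000) == 0.0
    assert fpkm_value(10, 1000, 0) == 0.0


def _pair(qname, tid, proper=True):
    f1 = 0x1 | 0x40 | (0x2 if proper else 0)
    f2 = 0x1 | 0x80 | 0x10 | (0x2 if proper else 0)
    return [
        AlignmentRecord(qname, f1, tid, 0, 60, [("=", 50)], "A" * 50),
        AlignmentRecord(qname, f2, tid, 100, 60, [("=", 50)], "A" * 50),
    ]


def test_fpkm_counts_only_concordant_fragments():
    ts = TranscriptSet("x", {"t1": "A" * 1000, "t2": "A" * 2000})
    aln = (
        _pair("f1", "t1") + _pair("f2", "t1") + _pair("f3", "t2")
        + _pair("f4", "t2", proper=False)
    )
    recs = {r.transcript_id: r for r in fpkm(aln, ts)}
    assert recs["t1"].fragments == 2 and recs["t2"].fragments == 1
    total = 3
    assert recs["t1"].fpkm == pytest.approx(fpkm_value(2, 1000, total))
    # conservation: sum(FPKM * L) / 1e9 * total == counted fragments
    s = sum(r.fpkm * r.length for r in recs.values())
    assert s / 1e9 * total == pytest.approx(total)


def test_fpkm_rejects_unpaired_input():
    ts = TranscriptSet("x", {"t1": "A" * 100})
    single = AlignmentRecord("q", 0, "t1", 0, 60, [("=", 50)], "A" * 50)
    with pytest.raises(ValueError, match="unpaired"):
        fpkm([single], ts)


def test_fpkm_rank_recovery_from_simulated_expression():
    """FPKM ranks track the generator's expression weights (tau > 0.9)."""
    cfg = synthdata.SimConfig(
        seed=19, n_genes=60, n_accessions_A=2, n_accessions_B=2,
        snp_rate_intra=0.0, indel_rate_intra=0.0, divergence_AB=0.0,
        divergence_outgroup=0.0, fragment_depth=30.0, expression_dispersion=1.0,
    )
    b = synthdata.simulate_dataset(cfg)
    ts = b.transcript_sets["A01"]
    r1, r2 = synthdata.simulate_bundle_reads(b, "A01")
    aln = toyalign.align_read_pairs(
        [(n, s) for n, s, _ in r1], [(n, s) for n, s, _ in r2], ts
    )
    recs = {r.transcript_id: r for r in fpkm(aln, ts)}
    weights = [b.expression[g] for g in ts.ids()]
    values = [recs[g].fpkm for g in ts.ids()]
    tau, p = kendall_tau(weights, values)
    assert tau > 0.9 and p < 1e-6


# ---------------------------------------------------------------------------
# Kendall's tau


def brute_force_tau_b(x, y):
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    return (concordant - discordant) / math.sqrt((n0 - tx) * (n0 - ty))


def test_tau_on_monotone_vectors():
    x = list(range(20))
    tau, _ = kendall_tau(x, x)
    assert tau == pytest.approx(1.0)
    tau, _ = kendall_tau(x, x[::-1])
    assert tau == pytest.approx(-1.0)


def test_tau_matches_exhaustive_enumeration_with_ties(rng):
    for _ in range(10):
        x = rng.integers(0, 6, size=20).astype(float)
        y = rng.integers(0, 6, size=20).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)


def test_constant_vector_gives_undefined_tau():
    tau, p = kendall_tau([1.0] * 5, [1, 2, 3, 4, 5])
    assert math.isnan(tau) and math.isnan(p)


# ---------------------------------------------------------------------------
# ortholog theta join


def test_identical_theta_vectors_give_tau_one():
    pairs = [OrthologPair(f"a{i}", f"b{i}", 1.0, 1.0, 100) for i in range(10)]
    theta1 = {f"a{i}": float(i) for i in range(10)}
    theta2 = {f"b{i}": float(i) for i in range(10)}
    df, tau, p = ortho_theta_scatter(pairs, theta1, theta2)
    assert tau == pytest.approx(1.0)
    assert len(df) == 9  # the all-zero pair is dropped (no polymorphism)


def test_unknown_transcript_in_pair_rejected():
    pairs = [OrthologPair("a", "zz", 1.0, 1.0, 10)]
    with pytest.raises(ValueError, match="unknown"):
        ortho_theta_scatter(pairs, {"a": 0.1}, {"b": 0.2})


def test_independent_theta_gives_near_zero_tau(rng):
    pairs = [OrthologPair(f"a{i}", f"b{i}", 1.0, 1.0, 100) for i in range(500)]
    theta1 = {f"a{i}": float(v) for i, v in enumerate(rng.random(500))}
    theta2 = {f"b{i}": float(v) for i, v in enumerate(rng.random(500))}
    df, tau, p = ortho_theta_scatter(pairs, theta1, theta2)
    assert abs(tau) < 0.1
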