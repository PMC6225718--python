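"""Diversity estimators vs an independent brute-force oracle, SFS
polarization, fixed differences, and NJ tree recovery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from synvar import popgen, synthdata
from synvar.popgen import (
    SnpMatrix,
    diversity_summary,
    distance_matrix,
    fixed_differences,
    nj_tree_with_bootstrap,
    polarize_sfs,
    species_bipartition_support,
    tajima_constants,
    theta_per_transcript,
)


# ---------------------------------------------------------------------------
# independent oracle: direct transliteration of the standard formulas,
# computing pi by explicit pairwise sequence comparison


def oracle_pi(alleles: np.ndarray) -> float:
    n = alleles.shape[1]
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((alleles[:, i] != alleles[:, j]).sum())
    return total / (n * (n - 1) / 2)


def oracle_tajima_d(alleles: np.ndarray):
    n = alleles.shape[1]
    S = sum(1 for row in alleles if len(set(row)) > 1)
    if S == 0:
        return None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (oracle_pi(alleles) - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def random_matrix(rng, n, S):
    """Random biallelic panel matrix with group 'A' for everyone."""
    alleles = np.empty((S, n), dtype="<U1")
    for s in range(S):
        a, d = rng.choice(list("ACGT"), 2, replace=False)
        k = int(rng.integers(1, n))  # 1..n-1 derived copies
        row = np.array([d] * k + [a] * (n - k))
        rng.shuffle(row)
        alleles[s] = row
    sites = pd.DataFrame(
        {"transcript_id": ["t1"] * S, "pos": np.arange(1, S + 1), "ref": alleles[:, 0]}
    )
    accs = [f"a{i}" for i in range(n)]
    return SnpMatrix("a0", sites, alleles, accs, {a: "A" for a in accs}, L_comparable=10 * S)


def test_estimators_match_brute_force_oracle(rng):
    """theta_W, pi and D agree with the independent oracle to 1e-10."""
    for _ in range(50):
        n = int(rng.integers(4, 13))
        S = int(rng.integers(1, 101))
        m = random_matrix(rng, n, S)
        summ = diversity_summary(m, "A")
        assert summ.S == S
        assert summ.pi == pytest.approx(oracle_pi(m.alleles), abs=1e-10)
        a1 = sum(1 / i for i in range(1, n))
        assert summ.theta_w == pytest.approx(S / a1, abs=1e-10)
        assert summ.tajimas_d == pytest.approx(oracle_tajima_d(m.alleles), abs=1e-10)


def test_two_sequences_give_zero_d(rng):
    # n = 2: a1 = 1 so pi = S and the D numerator vanishes identically
    m = random_matrix(rng, 2, 10)
    summ = diversity_summary(m, "A")
    assert summ.pi == pytest.approx(summ.S)
    assert summ.tajimas_d == pytest.approx(0.0, abs=1e-12)


def test_no_segregating_sites_gives_undefined_d():
    alleles = np.full((5, 4), "A", dtype="<U1")
    sites = pd.DataFrame({"transcript_id": ["t"] * 5, "pos": range(1, 6), "ref": ["A"] * 5})
    accs = [f"a{i}" for i in range(4)]
    m = SnpMatrix("a0", sites, alleles, accs, {a: "A" for a in accs}, L_comparable=50)
    summ = diversity_summary(m, "A")
    assert summ.S == 0 and summ.theta_w == 0.0 and summ.tajimas_d is None


def test_singletons_plus_nonsingletons_equals_s(rng):
    m = random_matrix(rng, 8, 60)
    summ = diversity_summary(m, "A")
    assert summ.singletons + summ.non_singletons == summ.S


def test_constants_identity():
    c = tajima_constants(10)
    assert c["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))
    with pytest.raises(ValueError):
        tajima_constants(1)


# ---------------------------------------------------------------------------
# polarization


def _two_group_matrix(rows, accs, species):
    alleles = np.array(rows, dtype="<U1")
    sites = pd.DataFrame(
        {"transcript_id": ["t"] * len(rows), "pos": range(1, len(rows) + 1),
         "ref": [r[0] for r in rows]}
    )
    return SnpMatrix(accs[0], sites, alleles, accs, species, L_comparable=len(rows) * 10)


def test_polarization_definitions():
    accs = [f"u{i}" for i in range(10)] + ["out"]
    species = {a: "A" for a in accs[:10]} | {"out": "outgroup"}
    rows = [
        list("AAAAAAAAAG") + ["A"],  # derived G, singleton
        list("GGGGAAAAAA") + ["A"],  # derived G, count 4
        list("AAAAAGGGGG") + ["C"],  # outgroup carries a third allele
        list("AAAAAAAAAA") + ["G"],  # monomorphic: not a segregating site
    ]
    m = _two_group_matrix(rows, accs, species)
    sfs = polarize_sfs(m, "A", "out")
    assert sfs.counts[0] == 1  # singleton class
    assert sfs.counts[3] == 1  # count-4 class
    assert sfs.unpolarizable == 1
    assert sfs.S == 3  # classes + unpolarizable cover every segregating site


def test_polarized_classes_sum_to_s_on_simulated_panel(small_bundle):
    matrix = popgen.SnpMatrix(
        "A01", *(_matrix_from_truth(small_bundle, "A01")),
        accessions=small_bundle.accessions,
        species=small_bundle.species_map,
        L_comparable=1000,
    )
    summ = diversity_summary(matrix, "A")
    sfs = polarize_sfs(matrix, "A", small_bundle.outgroup)
    assert sfs.S == summ.S


def _matrix_from_truth(bundle, ref_acc):
    df = synthdata.truth_snp_sites(bundle, ref_acc)
    alleles = df[bundle.accessions].to_numpy(dtype="<U1")
    sites = pd.DataFrame(
        {"transcript_id": df["gene"], "pos": df["pos"], "ref": df[ref_acc]}
    )
    return sites, alleles


def test_expansion_mode_has_excess_singletons_vs_neutral(rng):
    n, sites = 12, 2000
    neutral = synthdata.sample_derived_counts(n, sites, "neutral", rng)
    expansion = synthdata.sample_derived_counts(n, sites, "expansion", rng)
    f_n = np.mean(neutral == 1)
    f_e = np.mean(expansion == 1)
    assert f_e > f_n


# ---------------------------------------------------------------------------
# fixed differences


def test_fixed_difference_definitions():
    accs = ["u1", "u2", "t1", "t2"]
    species = {"u1": "A", "u2": "A", "t1": "B", "t2": "B"}
    rows = [
        list("AAGG"),  # fixed difference
        list("AGGG"),  # polymorphic in group A: not fixed
        list("AAAA"),  # identical: not fixed
    ]
    m = _two_group_matrix(rows, accs, species)
    assert fixed_differences(m, "A", "B") == 1


# ---------------------------------------------------------------------------
# distances and trees


def test_three_taxon_closed_form():
    """d(A,B)=2, d(A,C)=4, d(B,C)=4 gives pendant branches 1, 1, 3."""
    accs = ["A", "B", "C"]
    # 1 site private to A, 1 private to B, 3 private to C
    alleles = np.array(
        [list("GAA")] + [list("AGA")] + [list("AAG")] * 3, dtype="<U1"
    )
    sites = pd.DataFrame({"transcript_id": ["t"] * 5, "pos": range(1, 6), "ref": ["A"] * 5})
    m = SnpMatrix("A", sites, alleles, accs, {a: "A" for a in accs}, L_comparable=50)
    dm = distance_matrix(m, scale="count")
    assert dm["A", "B"] == 2 and dm["A", "C"] == 4 and dm["B", "C"] == 4
    tree, _ = nj_tree_with_bootstrap(m, replicates=10, seed=1, scale="count")
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(1.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_identical_accessions_get_zero_branch(rng):
    m = random_matrix(rng, 5, 30)
    m.alleles[:, 4] = m.alleles[:, 3]  # duplicate the last accession
    dm = distance_matrix(m)
    assert dm["a3", "a4"] == 0.0
    assert np.allclose(dm.data, dm.data.T) and np.all(np.diag(dm.data) == 0)


def test_species_bipartition_recovered_with_full_support(small_bundle):
    """Two species + outgroup: the species split gets 100% bootstrap."""
    sites, alleles = _matrix_from_truth(small_bundle, "A01")
    m = SnpMatrix("A01", sites, alleles, small_bundle.accessions,
                  small_bundle.species_map, L_comparable=1000)
    tree, support = nj_tree_with_bootstrap(
        m, replicates=100, seed=3, outgroup=small_bundle.outgroup
    )
    assert species_bipartition_support(support, m, "A") == pytest.approx(1.0)
    tips = {t.name for t in tree.tips()}
    assert tips == set(small_bundle.accessions)


def test_tree_requires_three_accessions(rng):
    m = random_matrix(rng, 2, 5)
    with pytest.raises(ValueError):
        nj_tree_with_bootstrap(m, replicates=5, seed=0)


def test_theta_per_transcript_counts_polymorphic_rows(rng):
    m = random_matrix(rng, 6, 20)
    m.sites["transcript_id"] = ["tA"] * 12 + ["tB"] * 8
    theta = theta_per_transcript(m, "A")
    a1 = tajima_constants(6)["a1"]
    assert theta["tA"] == pytest.approx(12 / a1)
    assert theta["tB"] == pytest.approx(8 / a1)


# ---------------------------------------------------------------------------
# sampler-level coalescent sanity


def test_neutral_sampler_mean_d_near_zero_and_theta_unbiased():
    """Mean Tajima's D over neutral panels sits near 0; theta_W tracks the
    planted site count."""
    rng = np.random.default_rng(77)
    n, L, rate = 10, 20000, 0.005
    ds, thetas = [], []
    for _ in range(120):
        S = rng.binomial(L, rate)
        counts = synthdata.sample_derived_counts(n, S, "neutral", rng)
        m = _panel_from_counts(counts, n, rng)
        summ = diversity_summary(m, "A")
        ds.append(summ.tajimas_d)
        thetas.append(summ.theta_w)
    a1 = tajima_constants(n)["a1"]
    assert abs(np.mean(ds)) < 0.15
    assert np.mean(thetas) == pytest.approx(L * rate / a1, rel=0.05)


def _panel_from_counts(counts, n, rng):
    S = len(counts)
    alleles = np.empty((S, n), dtype="<U1")
    for s, k in enumerate(counts):
        anc, der = rng.choice(list("ACGT"), 2, replace=False)
        row = np.array([der] * int(k) + [anc] * (n - int(k)))
        rng.shuffle(row)
        alleles[s] = row
    sites = pd.DataFrame({"transcript_id": ["t"] * S, "pos": range(1, S + 1),
                          "ref": alleles[:, 0]})
    accs = [f"a{i}" for i in range(n)]
    return SnpMatrix("a0", sites, alleles, accs, {a: "A" for a in accs}, L_comparable=S * 10)


def test_msprime_coalescent_cross_check():
    """Panels from a real coalescent reproduce the estimator's expectations."""
    msprime = pytest.importorskip("msprime")
    theta = 30.0
    ds, thetas = [], []
    for seed in range(1, 121):
        ts = msprime.sim_ancestry(
            samples=5, ploidy=2, sequence_length=1.0,
            recombination_rate=0.0, random_seed=seed,
        )
        mts = msprime.sim_mutations(
            ts, rate=theta / 4, random_seed=seed, discrete_genome=False
        )
        G = mts.genotype_matrix()  # sites x 10 haplotypes
        S = G.shape[0]
        if S == 0:
            continue
        alleles = np.where(G > 0, "G", "A").astype("<U1")
        sites = pd.DataFrame({"transcript_id": ["t"] * S, "pos": range(1, S + 1),
                              "ref": ["A"] * S})
        accs = [f"h{i}" for i in range(10)]
        m = SnpMatrix("h0", sites, alleles, accs, {a: "A" for a in accs}, L_comparable=S)
        summ = diversity_summary(m, "A")
        ds.append(summ.tajimas_d)
        thetas.append(summ.theta_w)
    assert abs(np.mean(ds)) < 0.25  # coalescent D has mild negative bias
    assert np.mean(thetas) == pytest.approx(theta, rel=0.1)
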