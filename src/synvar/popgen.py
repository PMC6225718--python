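"""Population-genetic summaries on a cross-species high-confidence SNP matrix.

The matrix holds one consensus base per (site, accession) for sites that
pass, in *every* accession, the same strict filters used for calling:
depth > 10 and a single unambiguous allele (> 95% consensus).  Sites with
more than two alleles across the panel are dropped.  From the matrix we
compute, per species group: segregating sites S, singleton and
non-singleton counts, Watterson's theta, nucleotide diversity pi, and
Tajima's D; across groups: fixed differences; against the outgroup: the
derived-allele frequency spectrum; and over all accessions: a
neighbor-joining tree with bootstrap support.

Tajima's D follows the standard normalization

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1))

with a1 = sum_{i<n} 1/i, a2 = sum_{i<n} 1/i^2, b1 = (n+1)/(3(n-1)),
b2 = 2(n^2+n+3)/(9n(n-1)), c1 = b1 - 1/a1, c2 = b2 - (n+2)/(a1 n) + a2/a1^2,
e1 = c1/a1, e2 = c2/(a1^2 + a2).  D is undefined when S = 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .seqio import TranscriptSet
from .variants import TranscriptPileup

log = logging.getLogger(__name__)

_BASE_ORDER = "ACGT"


@dataclass
class SnpMatrix:
    """High-confidence biallelic site x accession allele table.

    ``alleles`` is (n_sites, n_accessions) of single characters; ``sites``
    aligns row-wise with columns transcript_id, pos, ref.  ``L_comparable``
    counts every position (monomorphic included) that passed the coverage
    and consensus filters in all accessions; per-site statistics divide by
    it.  ``n_snp_sites`` (== number of matrix rows) is the alternative,
    SNP-only site count; both are reported.
    """

    reference_accession: str
    sites: pd.DataFrame
    alleles: np.ndarray
    accessions: List[str]
    species: Dict[str, str]
    L_comparable: int
    n_multiallelic_dropped: int = 0

    def __post_init__(self):
        if self.alleles.shape != (len(self.sites), len(self.accessions)):
            raise ValueError("allele matrix shape does not match sites/accessions")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def columns_for(self, group: Optional[str]) -> List[int]:
        """Accession column indices for a species group (None = all)."""
        if group is None:
            return list(range(len(self.accessions)))
        idx = [i for i, a in enumerate(self.accessions) if self.species[a] == group]
        if not idx:
            raise ValueError(f"no accessions in group {group!r}")
        return idx

    def group_alleles(self, group: Optional[str]) -> np.ndarray:
        return self.alleles[:, self.columns_for(group)]

    def to_frame(self) -> pd.DataFrame:
        out = self.sites.copy()
        for j, acc in enumerate(self.accessions):
            out[acc] = self.alleles[:, j]
        return out


def build_snp_matrix(
    pileups_by_accession: Mapping[str, Mapping[str, TranscriptPileup]],
    reference: TranscriptSet,
    species_map: Mapping[str, str],
    reference_accession: str,
    depth_min: int = 10,
    consensus_min: float = 0.95,
) -> SnpMatrix:
    """Assemble the high-confidence SNP matrix from per-accession pileups.

    Every accession (both ingroup panels and the outgroup) must have been
    aligned to the same reference transcript set.  A site enters the
    comparable length L iff every accession has depth > ``depth_min`` and a
    single consensus base above ``consensus_min``; the reference accession
    contributes its reference base at every site (its own pileup, if
    supplied, is still used for the coverage filter).  Polymorphic biallelic
    sites become matrix rows; sites with >2 alleles are dropped and counted.
    """
    accessions = list(pileups_by_accession)
    for acc in accessions:
        if acc not in species_map:
            raise ValueError(f"accession {acc!r} missing from species map")
    tids = reference.ids()
    consensus: Dict[str, np.ndarray] = {}
    for acc in accessions:
        piles = pileups_by_accession[acc]
        per_tid = []
        for tid in tids:
            ref_len = len(reference[tid])
            pile = piles.get(tid)
            if pile is None:
                per_tid.append(np.full(ref_len, -1, dtype=np.int8))
                continue
            acgt = pile.counts[:4]
            depth = pile.counts.sum(axis=0)  # N counts toward depth
            best = acgt.argmax(axis=0)
            best_count = acgt[best, np.arange(acgt.shape[1])]
            with np.errstate(divide="ignore", invalid="ignore"):
                ok = (depth > depth_min) & (
                    best_count / np.maximum(depth, 1) > consensus_min
                )
            cons = np.where(ok, best, -1).astype(np.int8)
            per_tid.append(cons)
        consensus[acc] = np.concatenate(per_tid)
    # reference accession contributes its reference base where covered
    ref_codes = np.concatenate(
        [np.array([_BASE_ORDER.find(b) for b in reference[tid]], dtype=np.int8) for tid in tids]
    )
    if reference_accession in consensus:
        covered = consensus[reference_accession] >= 0
        consensus[reference_accession] = np.where(covered, ref_codes, -1).astype(np.int8)
    site_tid = np.concatenate(
        [np.full(len(reference[tid]), i, dtype=np.int32) for i, tid in enumerate(tids)]
    )
    site_pos = np.concatenate(
        [np.arange(1, len(reference[tid]) + 1, dtype=np.int32) for tid in tids]
    )

    stack = np.vstack([consensus[a] for a in accessions])  # (n_acc, total_len)
    comparable = (stack >= 0).all(axis=0)
    L = int(comparable.sum())
    sub = stack[:, comparable]
    # allele diversity per column
    poly = (sub != sub[0]).any(axis=0)
    n_alleles = np.zeros(sub.shape[1], dtype=np.int8)
    for code in range(4):
        n_alleles += (sub == code).any(axis=0)
    biallelic = poly & (n_alleles == 2)
    dropped = int((poly & (n_alleles > 2)).sum())
    keep_cols = np.nonzero(biallelic)[0]
    full_idx = np.nonzero(comparable)[0][keep_cols]
    sites = pd.DataFrame(
        {
            "transcript_id": [tids[site_tid[i]] for i in full_idx],
            "pos": site_pos[full_idx],
            "ref": [_BASE_ORDER[ref_codes[i]] if ref_codes[i] >= 0 else "N" for i in full_idx],
        }
    )
    allele_chars = np.array(list(_BASE_ORDER))[sub[:, keep_cols]].T
    return SnpMatrix(
        reference_accession,
        sites,
        allele_chars.astype("<U1"),
        accessions,
        dict(species_map),
        L,
        dropped,
    )


# ---------------------------------------------------------------------------
# diversity


def tajima_constants(n: int) -> Dict[str, float]:
    if n < 2:
        raise ValueError("need at least 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


@dataclass
class DiversitySummary:
    group: Optional[str]
    n: int
    S: int
    singletons: int
    non_singletons: int
    theta_w: float
    theta_w_per_site: float
    pi: float
    pi_per_site: float
    tajimas_d: Optional[float]
    L: int
    constants: Dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "S": self.S,
            "singletons": self.singletons,
            "non_singletons": self.non_singletons,
            "theta_w": self.theta_w,
            "theta_w_per_site": self.theta_w_per_site,
            "pi": self.pi,
            "pi_per_site": self.pi_per_site,
            "tajimas_d": self.tajimas_d,
            "L": self.L,
        }


def _minor_counts(alleles: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-column (derived-or-minor allele count k, polymorphic mask)."""
    first = alleles[:, [0]]
    diff = (alleles != first).sum(axis=1)
    n = alleles.shape[1]
    k = np.minimum(diff, n - diff)
    return diff, diff > 0


def diversity_summary(
    matrix: SnpMatrix, group: Optional[str] = None, site_count: str = "comparable"
) -> DiversitySummary:
    """S, singletons, Watterson's theta, pi and Tajima's D for one group.

    ``site_count`` selects the denominator for per-site values:
    "comparable" (all sites passing filters; default) or "snp" (matrix
    rows only).
    """
    alleles = matrix.group_alleles(group)
    n = alleles.shape[1]
    if n < 2:
        raise ValueError("diversity requires n >= 2")
    const = tajima_constants(n)
    diff, poly = _minor_counts(alleles)
    k = diff[poly]
    S = int(poly.sum())
    minor = np.minimum(k, n - k)
    singletons = int((minor == 1).sum())
    pi = float((2.0 * k * (n - k) / (n * (n - 1))).sum())
    theta_w = S / const["a1"]
    L = matrix.L_comparable if site_count == "comparable" else matrix.n_sites
    if S > 0:
        var = const["e1"] * S + const["e2"] * S * (S - 1)
        if var > 0:
            d = (pi - theta_w) / math.sqrt(var)
        else:
            # n = 2: e1 = e2 = 0 and the numerator is identically zero
            d = 0.0 if abs(pi - theta_w) < 1e-9 else None
    else:
        d = None
    return DiversitySummary(
        group,
        n,
        S,
        singletons,
        S - singletons,
        theta_w,
        theta_w / L if L else float("nan"),
        pi,
        pi / L if L else float("nan"),
        d,
        L,
        const,
    )


@dataclass
class PolarizedSfs:
    n: int
    counts: np.ndarray  # derived-count classes 1..n-1
    unpolarizable: int

    @property
    def S(self) -> int:
        return int(self.counts.sum()) + self.unpolarizable

    def singleton_fraction(self) -> float:
        tot = self.counts.sum()
        return float(self.counts[0] / tot) if tot else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"derived_count": np.arange(1, self.n), "sites": self.counts}
        )


def polarize_sfs(
    matrix: SnpMatrix, group: str, outgroup_accession: str
) -> PolarizedSfs:
    """Outgroup-polarized derived-allele frequency spectrum for one group.

    For each site polymorphic within the group: if the outgroup allele
    matches one of the two segregating alleles, the other is the derived
    allele and the site increments its derived-count class; an outgroup
    allele matching neither makes the site unpolarizable.
    """
    if outgroup_accession not in matrix.accessions:
        raise ValueError(f"outgroup {outgroup_accession!r} not in matrix")
    sub = matrix.group_alleles(group)
    out_col = matrix.alleles[:, matrix.accessions.index(outgroup_accession)]
    n = sub.shape[1]
    counts = np.zeros(n - 1, dtype=int)
    unpol = 0
    for row, out_allele in zip(sub, out_col):
        uniq = np.unique(row)
        if len(uniq) < 2:
            continue
        if out_allele not in uniq:
            unpol += 1
            continue
        derived = uniq[0] if uniq[1] == out_allele else uniq[1]
        i = int((row == derived).sum())
        counts[i - 1] += 1
    return PolarizedSfs(n, counts, unpol)


def fixed_differences(matrix: SnpMatrix, group1: str, group2: str) -> int:
    """Sites monomorphic within each group but for different alleles."""
    a = matrix.group_alleles(group1)
    b = matrix.group_alleles(group2)
    mono_a = (a == a[:, [0]]).all(axis=1)
    mono_b = (b == b[:, [0]]).all(axis=1)
    return int((mono_a & mono_b & (a[:, 0] != b[:, 0])).sum())


# ---------------------------------------------------------------------------
# distances, NJ tree, bootstrap


def distance_matrix(
    matrix: SnpMatrix, scale: str = "proportion", alleles: Optional[np.ndarray] = None
) -> DistanceMatrix:
    """Pairwise distance: differing matrix columns, count or proportion."""
    al = matrix.alleles if alleles is None else alleles
    n_acc = al.shape[1]
    if al.shape[0] == 0:
        raise ValueError("no comparable columns for distance computation")
    d = np.zeros((n_acc, n_acc))
    for i in range(n_acc):
        for j in range(i + 1, n_acc):
            diff = float((al[:, i] != al[:, j]).sum())
            if scale == "proportion":
                diff /= al.shape[0]
            d[i, j] = d[j, i] = diff
    return DistanceMatrix(d, ids=matrix.accessions)


def _bipartitions(tree: TreeNode, taxa: frozenset) -> set:
    """Canonical internal bipartitions (smaller side excluding an anchor)."""
    anchor = min(taxa)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(taxa - side) < 2:
            continue
        if anchor in side:
            side = taxa - side
        parts.add(side)
    return parts


def nj_tree_with_bootstrap(
    matrix: SnpMatrix,
    replicates: int = 1000,
    seed: int = 0,
    scale: str = "proportion",
    outgroup: Optional[str] = None,
) -> Tuple[TreeNode, Dict[frozenset, float]]:
    """Neighbor-joining tree with bootstrap support on internal bipartitions.

    Bootstrap replicates resample matrix columns with replacement; support
    for each internal edge of the NJ tree is the fraction of replicate
    trees containing the same bipartition, written into the node name as a
    percentage.  If ``outgroup`` is given the returned tree is rooted with
    it.
    """
    if len(matrix.accessions) < 3:
        raise ValueError("need at least 3 accessions for a tree")
    dm = distance_matrix(matrix, scale=scale)
    tree = nj(dm)
    taxa = frozenset(matrix.accessions)
    rng = np.random.default_rng(seed)
    part_counts: Dict[frozenset, int] = {}
    S = matrix.alleles.shape[0]
    for _ in range(replicates):
        idx = rng.integers(0, S, size=S)
        bdm = distance_matrix(matrix, scale=scale, alleles=matrix.alleles[idx])
        btree = nj(bdm)
        for part in _bipartitions(btree, taxa):
            part_counts[part] = part_counts.get(part, 0) + 1
    support = {p: c / replicates for p, c in part_counts.items()}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if min(taxa) in side:
            side = taxa - side
        if len(side) >= 2 and len(taxa - side) >= 2:
            node.name = f"{100 * support.get(side, 0.0):.0f}"
    if outgroup is not None:
        out_tip = tree.find(outgroup)
        if out_tip.parent is not None and out_tip.parent.parent is not None:
            tree = tree.root_at(out_tip.parent)
    return tree, support


def species_bipartition_support(
    support: Mapping[frozenset, float], matrix: SnpMatrix, group: str
) -> float:
    """Support for the split separating one species group from the rest."""
    taxa = frozenset(matrix.accessions)
    side = frozenset(a for a in matrix.accessions if matrix.species[a] == group)
    if min(taxa) in side:
        side = taxa - side
    return support.get(side, 0.0)


def theta_per_transcript(
    matrix: SnpMatrix, group: str, lengths: Optional[Mapping[str, int]] = None
) -> pd.Series:
    """Watterson's theta per transcript within one species group.

    Returns S_t / a1 per transcript (divided by transcript length when
    ``lengths`` is given).  Transcripts with no matrix rows get 0.
    """
    sub = matrix.group_alleles(group)
    n = sub.shape[1]
    a1 = tajima_constants(n)["a1"]
    poly = (sub != sub[:, [0]]).any(axis=1)
    df = pd.DataFrame({"tid": matrix.sites["transcript_id"], "poly": poly})
    s = df.groupby("tid")["poly"].sum() / a1
    if lengths is not None:
        s = s / pd.Series(lengths).reindex(s.index)
    s.name = f"theta_{group}"
    return s
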