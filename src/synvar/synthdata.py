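"""Synthetic two-ingroup-species + outgroup transcriptome bundles.

The generator emulates the statistical structure the downstream analysis
assumes: an ancestral gene set; two ingroup species (A and B) diverged from
the ancestor by fixed substitutions, plus a more distant outgroup; within
each species a panel of fully homozygous accessions whose polymorphic sites
are drawn from a parameterized site-frequency spectrum; and two syntenic,
intronless "virtual chromosome" genomes onto which every planted variant
has known truth coordinates.

Key design properties (see docs/methods.md for rationale):

* All interspecies divergence is substitutional, so every species and both
  genomes share the ancestral coordinate frame; only intra-species indel
  polymorphisms shift coordinates, and only in the accessions carrying them.
* Planted variants keep >= 25 bp spacing, stay one fragment length
  (2 x read_length + 10) away from transcript ends, and indel content is
  chosen so each indel has a unique left-aligned representation.  Together
  these make error-free recovery an exact, not statistical, expectation.
* The SFS sampler draws a derived-allele count i in 1..n-1 per site with
  weights 1/i (neutral; the standard coalescent expectation), 1/i^2
  (expansion; excess rare alleles, negative Tajima's D) or i(n-i)
  (structured; excess intermediate frequencies, positive Tajima's D).
* Read simulation tiles fragments evenly along each transcript (with
  jitter), so at the default depth the strict depth filter cannot
  stochastically drop an interior site when expression is uniform.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import TranscriptSet, write_fasta, write_fastq, write_tsv
from .toyalign import revcomp

log = logging.getLogger(__name__)

BASES = "ACGT"
SFS_MODES = ("neutral", "expansion", "structured")
MIN_SPACING = 25          # bp between planted events
END_MARGIN_EXTRA = 10     # planted sites stay 2*read_length + this from ends
# (positions closer to an end than one fragment length see only one mate's
# tiling, where coverage is not guaranteed to clear the depth filter)
MAX_INDEL_LEN = 10


@dataclass
class SimConfig:
    """Parameters of one synthetic bundle; the seed fully determines output."""

    seed: int = 0
    n_genes: int = 100
    gene_length_range: Tuple[int, int] = (500, 900)
    n_accessions_A: int = 12
    n_accessions_B: int = 10
    snp_rate_intra: float = 0.003
    indel_rate_intra: float = 5e-4
    divergence_AB: float = 0.01
    divergence_outgroup: float = 0.03
    sfs_mode_A: str = "neutral"
    sfs_mode_B: str = "neutral"
    read_length: int = 100
    fragment_depth: float = 20.0
    error_rate: float = 0.0
    expression_dispersion: float = 0.0
    missing_gene_fraction_A: float = 0.0
    missing_gene_fraction_B: float = 0.0
    assembly_error_rate: float = 0.0
    n_chromosomes: int = 7
    spacer_length: int = 200

    def __post_init__(self):
        rates = {
            "snp_rate_intra": self.snp_rate_intra,
            "indel_rate_intra": self.indel_rate_intra,
            "divergence_AB": self.divergence_AB,
            "divergence_outgroup": self.divergence_outgroup,
            "error_rate": self.error_rate,
            "missing_gene_fraction_A": self.missing_gene_fraction_A,
            "missing_gene_fraction_B": self.missing_gene_fraction_B,
            "assembly_error_rate": self.assembly_error_rate,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.divergence_AB > 0 and not self.divergence_outgroup > self.divergence_AB:
            raise ValueError("divergence_outgroup must exceed divergence_AB")
        if self.n_accessions_A < 2 or self.n_accessions_B < 2:
            raise ValueError("each ingroup panel needs at least 2 accessions")
        if self.sfs_mode_A not in SFS_MODES or self.sfs_mode_B not in SFS_MODES:
            raise ValueError(f"sfs modes must be one of {SFS_MODES}")
        lo, hi = self.gene_length_range
        margin = 2 * self.read_length + END_MARGIN_EXTRA
        if lo > hi or lo < 2 * margin + 2 * MIN_SPACING:
            raise ValueError(
                "gene_length_range too short for read length: need at least "
                f"{2 * margin + 2 * MIN_SPACING} bp"
            )
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        d["gene_length_range"] = tuple(d["gene_length_range"])
        return cls(**d)


def sfs_weights(n: int, mode: str) -> np.ndarray:
    """Probability of derived-allele count i = 1..n-1 under each demography."""
    i = np.arange(1, n, dtype=float)
    if mode == "neutral":
        w = 1.0 / i
    elif mode == "expansion":
        w = 1.0 / i**2
    elif mode == "structured":
        w = i * (n - i)
    else:
        raise ValueError(f"unknown sfs mode {mode!r}")
    return w / w.sum()


def sample_derived_counts(
    n: int, n_sites: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    return rng.choice(np.arange(1, n), size=n_sites, p=sfs_weights(n, mode))


@dataclass
class TruthTable:
    """One record per planted variant, plus the carrier matrix.

    ``df`` rows align with ``genotypes`` rows; genotype columns follow
    ``accessions`` order and hold True where the accession carries the
    derived allele.  ``ref_allele`` is the ancestral-state representation
    (anchor base for insertions, deleted span for deletions) and
    ``alt_allele`` the derived one; the ancestral allele always equals the
    outgroup allele at the site by construction.
    """

    df: pd.DataFrame
    genotypes: np.ndarray
    accessions: List[str]

    def __len__(self) -> int:
        return len(self.df)

    def carriers(self, row: int) -> List[str]:
        return [a for a, g in zip(self.accessions, self.genotypes[row]) if g]

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out["genotypes"] = [
            "".join("1" if g else "0" for g in row) for row in self.genotypes
        ]
        return out


@dataclass
class SimBundle:
    """Everything one synthetic run produces.

    ``transcript_sets`` are the per-accession *assemblies* (the reference
    transcript datasets the pipeline aligns against); ``haplotypes`` are the
    true sequences reads are drawn from.  They differ only at planted
    assembly errors (``assembly_error_rate``), which are the recurrent
    artifacts the self-comparison filter is designed to remove.
    """

    config: SimConfig
    gene_table: pd.DataFrame
    ancestor: Dict[str, str]
    transcript_sets: Dict[str, TranscriptSet]
    haplotypes: Dict[str, TranscriptSet]
    accessions_A: List[str]
    accessions_B: List[str]
    outgroup: str
    species_map: Dict[str, str]
    genomes: Dict[str, Dict[str, str]]
    truth: TruthTable
    expression: Dict[str, float]
    assembly_errors: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def accessions(self) -> List[str]:
        return self.accessions_A + self.accessions_B + [self.outgroup]

    def chrom_sizes(self, genome_label: str) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genomes[genome_label].items()}

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(self.config.to_json())
        for label, chroms in self.genomes.items():
            write_fasta(chroms.items(), outdir / f"genome_{label}.fasta")
        for acc, ts in self.transcript_sets.items():
            write_fasta(ts.records.items(), outdir / f"transcripts_{acc}.fasta")
        write_tsv(self.truth.to_frame(), outdir / "truth.tsv")
        write_tsv(self.gene_table, outdir / "genes.tsv")
        expr = pd.DataFrame(
            {"gene": list(self.expression), "weight": list(self.expression.values())}
        )
        write_tsv(expr, outdir / "expression.tsv")


def _random_seq(rng: np.random.Generator, length: int) -> List[str]:
    return [BASES[c] for c in rng.integers(0, 4, size=length)]


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in BASES if b not in exclude]
    return choices[rng.integers(0, len(choices))]


def _indel_fill(
    rng: np.random.Generator, left_flank: str, right_flank: str, length: int
) -> List[str]:
    """Indel content that cannot realign: alternating bases disjoint from
    both flanking bases, so the event has a unique left-aligned placement
    (no shift of any step size, no split into smaller gaps)."""
    allowed = [b for b in BASES if b not in (left_flank, right_flank)]
    if len(allowed) > 2:
        allowed = list(rng.permutation(allowed))[:2]
    elif rng.integers(0, 2):
        allowed = allowed[::-1]
    return [allowed[i % 2] for i in range(length)]


def _pick_positions(
    rng: np.random.Generator, lo: int, hi: int, n: int, spacing: int = MIN_SPACING
) -> List[int]:
    """Draw up to n 1-based positions in [lo, hi] pairwise >= spacing apart."""
    if n <= 0 or hi < lo:
        return []
    pool = rng.permutation(np.arange(lo, hi + 1))
    accepted: List[int] = []
    for p in pool:
        if len(accepted) == n:
            break
        if all(abs(p - q) >= spacing for q in accepted):
            accepted.append(int(p))
    return sorted(accepted)


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate the full synthetic bundle for one configuration.

    Returns genomes, per-accession transcript sets (ingroup panels A and B
    plus one outgroup accession), expression weights and the truth table.
    Identical configs produce identical bundles.
    """
    rng = np.random.default_rng(config.seed)
    nA, nB = config.n_accessions_A, config.n_accessions_B
    acc_A = [f"A{i + 1:02d}" for i in range(nA)]
    acc_B = [f"B{i + 1:02d}" for i in range(nB)]
    outgroup = "OUT1"
    accessions = acc_A + acc_B + [outgroup]
    species_map = {a: "A" for a in acc_A} | {a: "B" for a in acc_B} | {outgroup: "outgroup"}

    margin = 2 * config.read_length + END_MARGIN_EXTRA
    lo_len, hi_len = config.gene_length_range
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    lengths = rng.integers(lo_len, hi_len + 1, size=config.n_genes)

    ancestor: Dict[str, str] = {}
    truth_rows: List[dict] = []
    genotype_rows: List[np.ndarray] = []
    genomeB_subs: Dict[str, List[Tuple[int, str]]] = {}

    idx_of = {a: i for i, a in enumerate(accessions)}

    for g, gid in enumerate(gene_ids):
        L = int(lengths[g])
        seq = _random_seq(rng, L)
        L_eff = L - 2 * margin
        counts = {
            "snp_A": rng.binomial(L_eff, config.snp_rate_intra),
            "indel_A": rng.binomial(L_eff, config.indel_rate_intra),
            "snp_B": rng.binomial(L_eff, config.snp_rate_intra),
            "indel_B": rng.binomial(L_eff, config.indel_rate_intra),
            "div_AB": rng.binomial(L_eff, config.divergence_AB),
            "div_out": rng.binomial(L_eff, config.divergence_outgroup),
        }
        total = sum(counts.values())
        positions = _pick_positions(rng, margin + 1, L - margin, total)
        classes: List[str] = []
        for name, c in counts.items():
            classes.extend([name] * c)
        rng.shuffle(classes)
        classes = classes[: len(positions)]

        # keep indels at least a read length apart within a gene so no read
        # ever spans two of them (two large indels in one read would exceed
        # any sensible alignment edit budget); crowded ones become SNPs
        events: List[Tuple[int, str]] = []
        last_indel = -(10**9)
        for pos, cls in sorted(zip(positions, classes)):
            if cls in ("indel_A", "indel_B"):
                if pos - last_indel < config.read_length + 20:
                    cls = "snp_A" if cls == "indel_A" else "snp_B"
                else:
                    last_indel = pos
            events.append((pos, cls))

        for pos, cls in events:
            p0 = pos - 1  # 0-based index of the site / anchor base
            genotype = np.zeros(len(accessions), dtype=bool)
            if cls in ("snp_A", "snp_B"):
                anc = seq[p0]
                alt = _other_base(rng, anc)
                if cls == "snp_A":
                    i = int(sample_derived_counts(nA, 1, config.sfs_mode_A, rng)[0])
                    for a in rng.choice(nA, size=i, replace=False):
                        genotype[a] = True
                    scope = "intra_A"
                else:
                    i = int(sample_derived_counts(nB, 1, config.sfs_mode_B, rng)[0])
                    for a in rng.choice(nB, size=i, replace=False):
                        genotype[nA + a] = True
                    scope = "intra_B"
                row = dict(ref_allele=anc, alt_allele=alt, var_class="SNP", scope=scope)
            elif cls in ("indel_A", "indel_B"):
                length = int(rng.integers(1, MAX_INDEL_LEN + 1))
                is_ins = bool(rng.integers(0, 2))
                if is_ins:
                    pos = pos - 1  # anchor base precedes the insertion point
                    p0 = pos - 1
                    # inserted between seq[p0] and seq[p0+1]
                    s = _indel_fill(rng, seq[p0], seq[p0 + 1], length)
                    row = dict(
                        ref_allele=seq[p0],
                        alt_allele="".join(s),
                        var_class="insertion",
                    )
                else:
                    # deleted span seq[p0+1 .. p0+length]; rewrite its
                    # content so the placement is unique
                    fill = _indel_fill(rng, seq[p0], seq[p0 + length + 1], length)
                    seq[p0 + 1 : p0 + 1 + length] = fill
                    row = dict(
                        ref_allele="".join(seq[p0 + 1 : p0 + 1 + length]),
                        alt_allele=seq[p0],
                        var_class="deletion",
                    )
                if cls == "indel_A":
                    i = int(sample_derived_counts(nA, 1, config.sfs_mode_A, rng)[0])
                    for a in rng.choice(nA, size=i, replace=False):
                        genotype[a] = True
                    row["scope"] = "intra_A"
                else:
                    i = int(sample_derived_counts(nB, 1, config.sfs_mode_B, rng)[0])
                    for a in rng.choice(nB, size=i, replace=False):
                        genotype[nA + a] = True
                    row["scope"] = "intra_B"
            elif cls == "div_AB":
                anc = seq[p0]
                alt = _other_base(rng, anc)
                branch = "A" if rng.integers(0, 2) == 0 else "B"
                if branch == "A":
                    genotype[:nA] = True
                else:
                    genotype[nA : nA + nB] = True
                row = dict(
                    ref_allele=anc,
                    alt_allele=alt,
                    var_class="SNP",
                    scope=f"divergence_{branch}",
                )
            else:  # div_out
                anc = seq[p0]
                alt = _other_base(rng, anc)
                genotype[idx_of[outgroup]] = True
                row = dict(
                    ref_allele=anc, alt_allele=alt, var_class="SNP", scope="outgroup"
                )
            row.update(gene=gid, pos=pos)
            truth_rows.append(row)
            genotype_rows.append(genotype)

        ancestor[gid] = "".join(seq)
        nsub = rng.binomial(L, config.divergence_AB)
        subs = []
        for p in rng.choice(L, size=min(nsub, L), replace=False):
            subs.append((int(p), _other_base(rng, seq[p])))
        genomeB_subs[gid] = subs

    # --- genomes -----------------------------------------------------------
    present_A = rng.random(config.n_genes) >= config.missing_gene_fraction_A
    present_B = rng.random(config.n_genes) >= config.missing_gene_fraction_B
    chrom_of = [g * config.n_chromosomes // config.n_genes for g in range(config.n_genes)]
    spacer = "N" * config.spacer_length

    strands_B = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    def build_genome(
        label: str, present: np.ndarray, mutate: bool, strands: Optional[np.ndarray]
    ) -> Tuple[Dict[str, str], Dict[str, Tuple[str, int, str]]]:
        chroms: Dict[str, List[str]] = {
            f"chr{c + 1}{label}": [] for c in range(config.n_chromosomes)
        }
        offsets: Dict[str, Tuple[str, int, str]] = {}
        lens = {c: 0 for c in chroms}
        for g, gid in enumerate(gene_ids):
            if not present[g]:
                continue
            cname = f"chr{chrom_of[g] + 1}{label}"
            gene_seq = ancestor[gid]
            if mutate:
                s = list(gene_seq)
                for p, b in genomeB_subs[gid]:
                    s[p] = b
                gene_seq = "".join(s)
            strand = strands[g] if strands is not None else "+"
            if strand == "-":
                gene_seq = revcomp(gene_seq)
            parts = chroms[cname]
            parts.append(spacer)
            lens[cname] += len(spacer)
            offsets[gid] = (cname, lens[cname] + 1, strand)  # 1-based gene start
            parts.append(gene_seq)
            lens[cname] += len(gene_seq)
        for cname in chroms:
            chroms[cname].append(spacer)
        return {c: "".join(parts) for c, parts in chroms.items()}, offsets

    genome_A, offsets_A = build_genome("A", present_A, mutate=False, strands=None)
    genome_B, offsets_B = build_genome("B", present_B, mutate=True, strands=strands_B)

    # --- truth table with genome coordinates -------------------------------
    df = pd.DataFrame(
        truth_rows,
        columns=["gene", "pos", "ref_allele", "alt_allele", "var_class", "scope"],
    )
    genotypes = (
        np.vstack(genotype_rows)
        if genotype_rows
        else np.zeros((0, len(accessions)), dtype=bool)
    )

    gene_len = {gid: int(l) for gid, l in zip(gene_ids, lengths)}

    def coord(gid: str, pos: int, offsets) -> Tuple[Optional[str], Optional[int]]:
        if gid not in offsets:
            return None, None
        chrom, start, strand = offsets[gid]
        if strand == "-":
            return chrom, start + gene_len[gid] - pos
        return chrom, start + pos - 1

    if len(df):
        coords_A = [coord(g, p, offsets_A) for g, p in zip(df["gene"], df["pos"])]
        coords_B = [coord(g, p, offsets_B) for g, p in zip(df["gene"], df["pos"])]
        df["chrom_A"] = [c for c, _ in coords_A]
        df["pos_A"] = [p for _, p in coords_A]
        df["chrom_B"] = [c for c, _ in coords_B]
        df["pos_B"] = [p for _, p in coords_B]
    else:
        df["chrom_A"] = []
        df["pos_A"] = []
        df["chrom_B"] = []
        df["pos_B"] = []
    truth = TruthTable(df, genotypes, accessions)

    # --- per-accession transcripts ------------------------------------------
    rows_by_gene: Dict[str, List[int]] = {}
    if len(df):
        for gid, idx in df.groupby("gene").indices.items():
            rows_by_gene[gid] = [int(i) for i in idx]
    transcript_sets: Dict[str, TranscriptSet] = {}
    for acc in accessions:
        ai = idx_of[acc]
        records: Dict[str, str] = {}
        for gid in gene_ids:
            seq = ancestor[gid]
            rows = rows_by_gene.get(gid, [])
            carried = [r for r in rows if genotypes[r, ai]]
            if carried:
                s = list(seq)
                # apply bottom-up so indels do not shift pending coordinates
                for r in sorted(carried, key=lambda r: -int(df.at[r, "pos"])):
                    p = int(df.at[r, "pos"])
                    vc = df.at[r, "var_class"]
                    if vc == "SNP":
                        s[p - 1] = df.at[r, "alt_allele"]
                    elif vc == "insertion":
                        ins = df.at[r, "alt_allele"]
                        s[p:p] = list(ins)
                    else:  # deletion
                        span = df.at[r, "ref_allele"]
                        del s[p : p + len(span)]
                records[gid] = "".join(s)
            else:
                records[gid] = seq
        transcript_sets[acc] = TranscriptSet(acc, records, note="synthetic")

    # --- assembly errors: wrong bases in the assemblies, absent from reads --
    haplotypes = transcript_sets
    err_rows: List[dict] = []
    if config.assembly_error_rate > 0:
        assemblies: Dict[str, TranscriptSet] = {}
        event_pos = {
            gid: df.loc[rows_by_gene.get(gid, []), "pos"].tolist() for gid in gene_ids
        }
        for acc in accessions:
            ai = idx_of[acc]
            recs: Dict[str, str] = {}
            for gid in gene_ids:
                seq_acc = list(haplotypes[acc][gid])
                L = len(ancestor[gid])
                n_err = rng.binomial(L - 2 * margin, config.assembly_error_rate)
                taken = event_pos[gid]
                placed = 0
                for p in rng.permutation(np.arange(margin + 1, L - margin + 1)):
                    if placed == n_err:
                        break
                    # substitution-only artifacts: a short buffer from real
                    # events (and each other) is enough
                    if any(abs(int(p) - q) < 6 for q in taken):
                        continue
                    shift = sum(
                        (len(df.at[r, "alt_allele"]) if df.at[r, "var_class"] == "insertion"
                         else -len(df.at[r, "ref_allele"]))
                        for r in rows_by_gene.get(gid, [])
                        if genotypes[r, ai]
                        and df.at[r, "var_class"] != "SNP"
                        and int(df.at[r, "pos"]) < int(p)
                    )
                    ap = int(p) + shift  # position in this accession's frame
                    true_base = seq_acc[ap - 1]
                    wrong = _other_base(rng, true_base)
                    seq_acc[ap - 1] = wrong
                    err_rows.append(
                        dict(accession=acc, gene=gid, pos=int(p), pos_assembly=ap,
                             true_base=true_base, wrong_base=wrong)
                    )
                    taken = taken + [int(p)]
                    placed += 1
                recs[gid] = "".join(seq_acc)
            assemblies[acc] = TranscriptSet(acc, recs, note="synthetic assembly")
        transcript_sets = assemblies
    assembly_errors = pd.DataFrame(
        err_rows,
        columns=["accession", "gene", "pos", "pos_assembly", "true_base", "wrong_base"],
    )

    # --- expression ---------------------------------------------------------
    if config.expression_dispersion > 0:
        weights = rng.lognormal(0.0, config.expression_dispersion, size=config.n_genes)
    else:
        weights = np.ones(config.n_genes)
    expression = {gid: float(w) for gid, w in zip(gene_ids, weights)}

    gene_table = pd.DataFrame(
        {
            "gene": gene_ids,
            "length": lengths,
            "chrom_A": [f"chr{c + 1}A" for c in chrom_of],
            "present_A": present_A,
            "start_A": [offsets_A.get(g, (None, None, None))[1] for g in gene_ids],
            "chrom_B": [f"chr{c + 1}B" for c in chrom_of],
            "present_B": present_B,
            "start_B": [offsets_B.get(g, (None, None, None))[1] for g in gene_ids],
            "strand_B": strands_B,
            "expression": weights,
        }
    )

    return SimBundle(
        config=config,
        gene_table=gene_table,
        ancestor=ancestor,
        transcript_sets=transcript_sets,
        haplotypes=haplotypes,
        accessions_A=acc_A,
        accessions_B=acc_B,
        outgroup=outgroup,
        species_map=species_map,
        genomes={"A": genome_A, "B": genome_B},
        truth=truth,
        expression=expression,
        assembly_errors=assembly_errors,
    )


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    transcripts: TranscriptSet,
    depth: float,
    read_length: int,
    error_rate: float,
    seed,
    expression: Optional[Mapping[str, float]] = None,
    count_mode: str = "auto",
) -> Tuple[List[Tuple[str, str, str]], List[Tuple[str, str, str]]]:
    """Simulate inward-facing paired reads from a transcript set.

    Fragment counts per transcript have mean ``expression weight x depth x
    L / (2 read_length)``; with uniform expression (``count_mode`` "auto"
    resolving to "deterministic") the count is the rounded mean and fragment
    starts are stratified along the transcript, so interior coverage is
    tightly concentrated around ``depth``.  With "poisson" counts are
    Poisson-distributed.  Read names record the true transcript, fragment
    index, start and fragment length.  Transcripts shorter than
    ``read_length`` are skipped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if count_mode not in ("auto", "deterministic", "poisson"):
        raise ValueError(f"bad count_mode {count_mode!r}")
    if count_mode == "auto":
        varying = expression is not None and len(set(expression.values())) > 1
        count_mode = "poisson" if varying else "deterministic"
    reads1: List[Tuple[str, str, str]] = []
    reads2: List[Tuple[str, str, str]] = []
    qual_cache = "I" * read_length
    for tid, seq in transcripts.records.items():
        L = len(seq)
        if L < read_length:
            warnings.warn(f"transcript {tid} shorter than read length; skipped")
            continue
        w = expression.get(tid, 1.0) if expression is not None else 1.0
        mean = w * depth * L / (2.0 * read_length)
        n = int(rng.poisson(mean)) if count_mode == "poisson" else int(round(mean))
        fl = min(2 * read_length, L)  # fixed length: mates tile contiguously
        for j in range(n):
            u = (j + 0.25 + 0.5 * rng.random()) / n
            start = int(u * (L - fl + 1))
            start = min(max(start, 0), L - fl)
            frag = seq[start : start + fl]
            name = f"{transcripts.accession}|{tid}|{j}|{start}|{fl}"
            reads1.append((name, frag[:read_length], qual_cache))
            reads2.append((name, revcomp(frag[-read_length:]), qual_cache))
    if error_rate > 0:
        reads1 = _apply_errors(reads1, error_rate, rng)
        reads2 = _apply_errors(reads2, error_rate, rng)
    return reads1, reads2


def _apply_errors(reads, error_rate, rng):
    out = []
    for name, seq, qual in reads:
        mask = rng.random(len(seq)) < error_rate
        if mask.any():
            s = list(seq)
            for i in np.nonzero(mask)[0]:
                s[i] = _other_base(rng, s[i])
            seq = "".join(s)
        out.append((name, seq, qual))
    return out


def simulate_bundle_reads(
    bundle: SimBundle, accession: str, seed_offset: int = 0
) -> Tuple[List[Tuple[str, str, str]], List[Tuple[str, str, str]]]:
    """Reads for one accession of a bundle, with a per-accession seed stream."""
    cfg = bundle.config
    acc_index = bundle.accessions.index(accession)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 1000 + acc_index, seed_offset])
    )
    expr = bundle.expression if cfg.expression_dispersion > 0 else None
    return simulate_reads(
        bundle.haplotypes[accession],  # reads come from the true sequences
        cfg.fragment_depth,
        cfg.read_length,
        cfg.error_rate,
        rng,
        expression=expr,
    )


# ---------------------------------------------------------------------------
# truth utilities


def _ref_shift(df: pd.DataFrame, genotypes: np.ndarray, acc_idx: int, gene: str) -> List[Tuple[int, int]]:
    """(anchor pos, signed length) of indels carried by the accession in a gene."""
    shifts = []
    rows = df.index[df["gene"] == gene]
    for r in rows:
        if not genotypes[r, acc_idx]:
            continue
        vc = df.at[r, "var_class"]
        if vc == "insertion":
            shifts.append((int(df.at[r, "pos"]), len(df.at[r, "alt_allele"])))
        elif vc == "deletion":
            shifts.append((int(df.at[r, "pos"]), -len(df.at[r, "ref_allele"])))
    return shifts


def expected_pairwise_calls(
    bundle: SimBundle, ref_accession: str, read_accession: str
) -> Dict[Tuple[str, int, str, str], dict]:
    """Calls the pipeline should make for one (reads, reference) pair.

    Derived from the truth table: every site where the two accessions carry
    different alleles, expressed in the *reference accession's* transcript
    coordinates (shifted by the reference's own upstream indels) with
    classes flipped where the reference carries the derived indel.
    Returns a dict keyed like :attr:`VariantCall.key`.
    """
    truth = bundle.truth
    df, genotypes = truth.df, truth.genotypes
    i_ref = truth.accessions.index(ref_accession)
    i_read = truth.accessions.index(read_accession)
    out: Dict[Tuple[str, int, str, str], dict] = {}
    if not len(df):
        return out
    shifts_cache: Dict[str, List[Tuple[int, int]]] = {}
    for r in range(len(df)):
        g_ref = bool(genotypes[r, i_ref])
        g_read = bool(genotypes[r, i_read])
        if g_ref == g_read:
            continue
        gene = df.at[r, "gene"]
        pos = int(df.at[r, "pos"])
        vc = df.at[r, "var_class"]
        anc = df.at[r, "ref_allele"]
        der = df.at[r, "alt_allele"]
        if gene not in shifts_cache:
            shifts_cache[gene] = _ref_shift(df, genotypes, i_ref, gene)
        shift = sum(s for p, s in shifts_cache[gene] if p < pos)
        rpos = pos + shift
        if vc == "SNP":
            ref_allele, alt_allele = (der, anc) if g_ref else (anc, der)
            key = (gene, rpos, "SNP", alt_allele)
            out[key] = dict(ref=ref_allele, alt=alt_allele, var_class="SNP", pos=rpos)
        elif vc == "insertion":
            if g_read:  # reads carry extra bases relative to the reference
                key = (gene, rpos, "insertion", der)
                out[key] = dict(ref=anc, alt=der, var_class="insertion", pos=rpos)
            else:  # reference carries them: reads show a deletion
                key = (gene, rpos, "deletion", anc)
                out[key] = dict(ref=der, alt=anc, var_class="deletion", pos=rpos)
        else:  # deletion of span `anc` after the anchor
            if g_read:
                key = (gene, rpos, "deletion", der)
                out[key] = dict(ref=anc, alt=der, var_class="deletion", pos=rpos)
            else:
                key = (gene, rpos, "insertion", anc)
                out[key] = dict(ref=der, alt=anc, var_class="insertion", pos=rpos)
    return out


def truth_snp_sites(
    bundle: SimBundle, reference_accession: str
) -> pd.DataFrame:
    """SNP-class truth rows in the reference accession's coordinates.

    Adds per-accession allele columns (the base each accession carries).
    """
    truth = bundle.truth
    df, genotypes = truth.df, truth.genotypes
    rows = []
    i_ref = truth.accessions.index(reference_accession)
    shifts_cache: Dict[str, List[Tuple[int, int]]] = {}
    for r in range(len(df)):
        if df.at[r, "var_class"] != "SNP":
            continue
        gene = df.at[r, "gene"]
        if gene not in shifts_cache:
            shifts_cache[gene] = _ref_shift(df, genotypes, i_ref, gene)
        pos = int(df.at[r, "pos"])
        shift = sum(s for p, s in shifts_cache[gene] if p < pos)
        row = {
            "gene": gene,
            "pos": pos + shift,
            "ancestral": df.at[r, "ref_allele"],
            "derived": df.at[r, "alt_allele"],
            "scope": df.at[r, "scope"],
        }
        for j, acc in enumerate(truth.accessions):
            row[acc] = df.at[r, "alt_allele"] if genotypes[r, j] else df.at[r, "ref_allele"]
        rows.append(row)
    return pd.DataFrame(rows)
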