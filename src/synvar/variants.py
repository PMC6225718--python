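"""Pairwise SNP/indel calling from transcript pileups.

The calling rule is a strict consensus filter: a position yields a call iff
its read depth exceeds 10 and a single non-reference allele (base,
insertion, or deletion) accounts for more than 95% of the aligned bases at
that column.  Both inequalities are strict.  The rule treats the material
as effectively homozygous (selfing species), so no genotype likelihoods are
computed.

Comparisons of an accession's reads against its own transcripts
("self-comparisons") flag systematic artifacts; any variant key also found
in the self-comparison is removed.  Per-reference non-redundant (NR) sets
are the deduplicated union of pairwise calls across all read accessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

# default thresholds: depth strictly greater than 10, consensus strictly
# greater than 0.95
DEPTH_MIN = 10
CONSENSUS_MIN = 0.95

BASES = "ACGTN"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def encode_seq(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes (A=0..N=4)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def decode_seq(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


@dataclass
class PileupColumn:
    """Per-position observation counts from one read-set-vs-transcript alignment.

    ``pos`` is 1-based on the reference transcript.  Insertions are keyed by
    the inserted string and anchored at the base *preceding* the event;
    deletions are keyed by the deleted span, anchored the same way.  Depth
    equals the sum of base counts (reads contributing an aligned base at the
    column).
    """

    transcript_id: str
    pos: int
    ref: str
    counts: Dict[str, int]
    insertions: Dict[str, int] = field(default_factory=dict)
    deletions: Dict[str, int] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class TranscriptPileup:
    """Dense pileup over one reference transcript.

    Stores base counts as a (5, L) array and indels in dictionaries keyed by
    0-based anchor index.  This is the efficient in-memory form;
    :meth:`columns` materializes the :class:`PileupColumn` view.
    """

    def __init__(self, transcript_id: str, ref_seq: str):
        self.transcript_id = transcript_id
        self.ref_seq = ref_seq
        self.ref_codes = encode_seq(ref_seq)
        self.counts = np.zeros((5, len(ref_seq)), dtype=np.int32)
        # (anchor0, inserted string) -> count ; (anchor0, deleted span) -> count
        self.insertions: Dict[Tuple[int, str], int] = {}
        self.deletions: Dict[Tuple[int, str], int] = {}

    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def add_base(self, pos0: int, code: int, n: int = 1) -> None:
        self.counts[code, pos0] += n

    def add_insertion(self, anchor0: int, inserted: str, n: int = 1) -> None:
        key = (anchor0, inserted)
        self.insertions[key] = self.insertions.get(key, 0) + n

    def add_deletion(self, anchor0: int, span: str, n: int = 1) -> None:
        key = (anchor0, span)
        self.deletions[key] = self.deletions.get(key, 0) + n

    def column(self, pos: int) -> PileupColumn:
        """Materialize the 1-based column ``pos``."""
        i = pos - 1
        counts = {BASES[c]: int(self.counts[c, i]) for c in range(5)}
        ins = {s: n for (a, s), n in self.insertions.items() if a == i}
        dels = {s: n for (a, s), n in self.deletions.items() if a == i}
        return PileupColumn(self.transcript_id, pos, self.ref_seq[i], counts, ins, dels)

    def columns(self, skip_empty: bool = True) -> Iterator[PileupColumn]:
        depth = self.depth()
        ins_by_anchor: Dict[int, Dict[str, int]] = {}
        for (a, s), n in self.insertions.items():
            ins_by_anchor.setdefault(a, {})[s] = n
        del_by_anchor: Dict[int, Dict[str, int]] = {}
        for (a, s), n in self.deletions.items():
            del_by_anchor.setdefault(a, {})[s] = n
        for i in range(len(self.ref_seq)):
            if skip_empty and depth[i] == 0 and i not in ins_by_anchor and i not in del_by_anchor:
                continue
            counts = {BASES[c]: int(self.counts[c, i]) for c in range(5)}
            yield PileupColumn(
                self.transcript_id,
                i + 1,
                self.ref_seq[i],
                counts,
                ins_by_anchor.get(i, {}),
                del_by_anchor.get(i, {}),
            )


@dataclass(frozen=True)
class VariantCall:
    """A SNP or indel call at a 1-based transcript coordinate.

    For indels ``pos`` is the anchor base (the base preceding the event),
    ``ref`` is the anchor base for insertions or the deleted span for
    deletions, and ``alt`` is the inserted string for insertions or the
    anchor base for deletions (left-aligned representation).
    """

    read_accession: str
    ref_accession: str
    transcript_id: str
    pos: int
    ref: str
    alt: str
    var_class: str  # "SNP" | "insertion" | "deletion"
    depth: int
    non_ref_fraction: float

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.transcript_id, self.pos, self.var_class, self.alt)

    @property
    def indel_length(self) -> int:
        if self.var_class == "insertion":
            return len(self.alt)
        if self.var_class == "deletion":
            return len(self.ref)
        return 0


@dataclass
class PairwiseCallSet:
    read_accession: str
    ref_accession: str
    calls: List[VariantCall]

    def __len__(self) -> int:
        return len(self.calls)

    def keys(self) -> set:
        return {c.key for c in self.calls}


@dataclass
class NRRecord:
    transcript_id: str
    pos: int
    ref: str
    alt: str
    var_class: str
    supporters: List[str]

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.transcript_id, self.pos, self.var_class, self.alt)

    @property
    def indel_length(self) -> int:
        if self.var_class == "insertion":
            return len(self.alt)
        if self.var_class == "deletion":
            return len(self.ref)
        return 0


@dataclass
class NonRedundantSet:
    """Deduplicated union of calls against one fixed reference accession.

    Keys are alt-aware: two different alternate alleles at one position are
    two NR records.
    """

    ref_accession: str
    records: Dict[Tuple[str, int, str, str], NRRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[NRRecord]:
        return iter(self.records.values())

    def snps(self) -> List[NRRecord]:
        return [r for r in self.records.values() if r.var_class == "SNP"]

    def indels(self) -> List[NRRecord]:
        return [r for r in self.records.values() if r.var_class != "SNP"]


def _call_from_pileup(
    pile: TranscriptPileup,
    read_accession: str,
    ref_accession: str,
    depth_min: int,
    consensus_min: float,
) -> List[VariantCall]:
    calls: List[VariantCall] = []
    depth = pile.depth()
    # SNPs, vectorized: best non-reference base per column
    acgt = pile.counts[:4]
    cols = np.arange(acgt.shape[1])
    masked = acgt.copy()
    ref_ok = pile.ref_codes < 4
    masked[pile.ref_codes[ref_ok], cols[ref_ok]] = 0  # zero out the reference base row
    best = masked.argmax(axis=0)
    best_count = masked[best, cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
    hits = np.nonzero((depth > depth_min) & (frac > consensus_min))[0]
    for i in hits:
        calls.append(
            VariantCall(
                read_accession,
                ref_accession,
                pile.transcript_id,
                int(i) + 1,
                pile.ref_seq[i],
                BASES[best[i]],
                "SNP",
                int(depth[i]),
                float(frac[i]),
            )
        )
    # indels: fraction relative to depth at the anchor column
    for (a, inserted), n in pile.insertions.items():
        d = int(depth[a])
        if d > depth_min and n / d > consensus_min:
            calls.append(
                VariantCall(
                    read_accession,
                    ref_accession,
                    pile.transcript_id,
                    a + 1,
                    pile.ref_seq[a],
                    inserted,
                    "insertion",
                    d,
                    n / d,
                )
            )
    for (a, span), n in pile.deletions.items():
        d = int(depth[a])
        if d > depth_min and n / d > consensus_min:
            calls.append(
                VariantCall(
                    read_accession,
                    ref_accession,
                    pile.transcript_id,
                    a + 1,
                    span,
                    pile.ref_seq[a],
                    "deletion",
                    d,
                    n / d,
                )
            )
    calls.sort(key=lambda c: (c.transcript_id, c.pos, c.var_class, c.alt))
    return calls


def call_variants(
    pileups,
    read_accession: str = "reads",
    ref_accession: str = "reference",
    depth_min: int = DEPTH_MIN,
    consensus_min: float = CONSENSUS_MIN,
) -> PairwiseCallSet:
    """Apply the strict consensus rule to pileups from one read/reference pair.

    ``pileups`` may be a mapping of transcript id to :class:`TranscriptPileup`
    or an iterable of :class:`PileupColumn` (the column form is converted).
    A column yields a call iff ``depth > depth_min`` and one non-reference
    allele accounts for ``> consensus_min`` of the depth; both strict.
    """
    if isinstance(pileups, Mapping):
        piles = pileups.values()
    elif isinstance(pileups, TranscriptPileup):
        piles = [pileups]
    else:
        piles = _pileups_from_columns(pileups).values()
    calls: List[VariantCall] = []
    for pile in piles:
        calls.extend(
            _call_from_pileup(pile, read_accession, ref_accession, depth_min, consensus_min)
        )
    return PairwiseCallSet(read_accession, ref_accession, calls)


def _pileups_from_columns(columns: Iterable[PileupColumn]) -> Dict[str, TranscriptPileup]:
    """Rebuild dense pileups from a column stream (positions may be sparse)."""
    grouped: Dict[str, List[PileupColumn]] = {}
    for col in columns:
        grouped.setdefault(col.transcript_id, []).append(col)
    piles: Dict[str, TranscriptPileup] = {}
    for tid, cols in grouped.items():
        length = max(c.pos for c in cols)
        ref = ["N"] * length
        for c in cols:
            ref[c.pos - 1] = c.ref
        pile = TranscriptPileup(tid, "".join(ref))
        for c in cols:
            i = c.pos - 1
            for base, n in c.counts.items():
                if n:
                    pile.add_base(i, _BASE_TO_CODE[base], n)
            for s, n in c.insertions.items():
                pile.add_insertion(i, s, n)
            for s, n in c.deletions.items():
                pile.add_deletion(i, s, n)
        piles[tid] = pile
    return piles


def filter_artifacts(
    pairwise: PairwiseCallSet, self_calls: PairwiseCallSet
) -> PairwiseCallSet:
    """Remove calls whose key recurs in the reference accession's self-comparison.

    Variants found when an accession's own reads are compared against its own
    transcripts cannot be real differences; any pairwise call sharing a
    (transcript, position, class, alt) key with such a self-call is dropped.
    """
    if self_calls.ref_accession != pairwise.ref_accession:
        raise ValueError(
            "self-comparison reference %r does not match pairwise reference %r"
            % (self_calls.ref_accession, pairwise.ref_accession)
        )
    bad = self_calls.keys()
    kept = [c for c in pairwise.calls if c.key not in bad]
    return PairwiseCallSet(pairwise.read_accession, pairwise.ref_accession, kept)


def consolidate_nonredundant(pairwise_sets: Sequence[PairwiseCallSet]) -> NonRedundantSet:
    """Union pairwise call sets sharing one reference accession, deduplicated.

    The dedup key is (transcript, position, class, alt); the list of read
    accessions supporting each NR variant is retained.
    """
    if not pairwise_sets:
        raise ValueError("no pairwise call sets given")
    ref = pairwise_sets[0].ref_accession
    for ps in pairwise_sets:
        if ps.ref_accession != ref:
            raise ValueError("pairwise sets mix reference accessions")
    records: Dict[Tuple[str, int, str, str], NRRecord] = {}
    for ps in pairwise_sets:
        for c in ps.calls:
            rec = records.get(c.key)
            if rec is None:
                records[c.key] = NRRecord(
                    c.transcript_id, c.pos, c.ref, c.alt, c.var_class, [ps.read_accession]
                )
            elif ps.read_accession not in rec.supporters:
                rec.supporters.append(ps.read_accession)
    return NonRedundantSet(ref, records)


def pairwise_count_table(
    callsets: Mapping[Tuple[str, str], PairwiseCallSet], var_class: str | None = None
) -> pd.DataFrame:
    """Reference (rows) x read accession (columns) call-count matrix.

    Mirrors the published pairwise-count layout; ``var_class`` of "SNP"
    restricts to SNPs, "indel" to insertions+deletions, None counts all.
    """
    refs = sorted({k[0] for k in callsets})
    reads = sorted({k[1] for k in callsets})
    table = pd.DataFrame(0, index=pd.Index(refs, name="reference"), columns=reads)
    for (ref, read), ps in callsets.items():
        if var_class == "SNP":
            n = sum(1 for c in ps.calls if c.var_class == "SNP")
        elif var_class == "indel":
            n = sum(1 for c in ps.calls if c.var_class != "SNP")
        else:
            n = len(ps.calls)
        table.loc[ref, read] = n
    return table


def callset_to_frame(ps: PairwiseCallSet) -> pd.DataFrame:
    rows = [
        {
            "read_accession": c.read_accession,
            "ref_accession": c.ref_accession,
            "transcript_id": c.transcript_id,
            "pos": c.pos,
            "ref": c.ref,
            "alt": c.alt,
            "var_class": c.var_class,
            "depth": c.depth,
            "non_ref_fraction": c.non_ref_fraction,
        }
        for c in ps.calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "read_accession",
            "ref_accession",
            "transcript_id",
            "pos",
            "ref",
            "alt",
            "var_class",
            "depth",
            "non_ref_fraction",
        ],
    )


def nr_to_frame(nr: NonRedundantSet) -> pd.DataFrame:
    rows = [
        {
            "ref_accession": nr.ref_accession,
            "transcript_id": r.transcript_id,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "var_class": r.var_class,
            "supporters": ",".join(r.supporters),
        }
        for r in sorted(nr, key=lambda r: r.key)
    ]
    return pd.DataFrame(
        rows,
        columns=["ref_accession", "transcript_id", "pos", "ref", "alt", "var_class", "supporters"],
    )
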