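"""Readers and writers for the formats the pipeline touches.

FASTA/FASTQ go through biopython, SAM through pysam (text mode), trees
through scikit-bio.  All coordinates are 1-based inclusive internally; BED
output is 0-based half-open.  Validation is strict: duplicate ids and
non-ACGTN characters are errors that name the offending record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .variants import TranscriptPileup, encode_seq

log = logging.getLogger(__name__)

_VALID = set("ACGTN")

# CIGAR operation codes as used by pysam / the SAM spec
_CIGAR_OPS = "MIDNSHP=X"
_CONSUMES_QUERY = {"M", "I", "S", "=", "X"}
_CONSUMES_REF = {"M", "D", "N", "=", "X"}


def _validate_seq(name: str, seq: str) -> str:
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"record {name!r} contains non-IUPAC characters: {sorted(bad)}"
        )
    return s


@dataclass
class TranscriptSet:
    """An accession's reference transcripts (one unigene per gene)."""

    accession: str
    records: Dict[str, str]
    note: str = ""

    def __post_init__(self):
        clean: Dict[str, str] = {}
        for tid, seq in self.records.items():
            if tid in clean:
                raise ValueError(f"duplicate transcript id {tid!r}")
            clean[tid] = _validate_seq(tid, seq)
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, tid: str) -> str:
        return self.records[tid]

    def __contains__(self, tid: str) -> bool:
        return tid in self.records

    def ids(self) -> List[str]:
        return list(self.records)

    @classmethod
    def from_fasta(cls, path, accession: str, note: str = "") -> "TranscriptSet":
        return cls(accession, dict(read_fasta(path)), note=note)

    def to_fasta(self, path) -> None:
        write_fasta(self.records.items(), path)


@dataclass
class Block:
    """One gapless aligned block of a transcript-to-genome mapping.

    Query coordinates are in the *aligned orientation*: for "-" strand
    mappings they refer to the reverse-complemented transcript.  All
    intervals are 1-based inclusive and ascend in both systems.
    """

    q_start: int
    q_end: int
    g_start: int
    g_end: int


@dataclass
class MappingRecord:
    """Best placement of one transcript on one genome."""

    transcript_id: str
    genome_label: str
    chrom: str
    start: int  # 1-based inclusive on the chromosome
    end: int
    strand: str  # "+" or "-"
    blocks: List[Block]
    identity: float
    coverage: float

    def __post_init__(self):
        prev_q, prev_g = 0, 0
        for b in self.blocks:
            if not (b.q_start > prev_q and b.g_start > prev_g):
                raise ValueError(
                    f"mapping blocks for {self.transcript_id} not monotone"
                )
            if b.q_end - b.q_start != b.g_end - b.g_start:
                raise ValueError(
                    f"mapping block length mismatch for {self.transcript_id}"
                )
            prev_q, prev_g = b.q_end, b.g_end


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read FASTA into (id, sequence) pairs; validates ids and alphabet."""
    out: List[Tuple[str, str]] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, _validate_seq(rec.id, str(rec.seq))))
    return out


def write_fasta(records: Iterable[Tuple[str, str]], path) -> None:
    recs = [
        SeqRecord(Seq(_validate_seq(rid, seq)), id=rid, description="")
        for rid, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> List[Tuple[str, str, str]]:
    """Read FASTQ into (name, sequence, quality) triples."""
    out = []
    with open(path) as fh:
        for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
            out.append((title, seq.upper(), qual))
    return out


def write_fastq(reads: Iterable[Tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM


@dataclass
class AlignmentRecord:
    """A single-end alignment of a read to a reference transcript.

    ``pos`` is 0-based on the reference; ``cigar`` is a list of
    (operation, length) with operations from MIDNSHP=X.  ``flag`` follows
    the SAM flag bits.
    """

    qname: str
    flag: int
    ref_id: Optional[str]
    pos: int
    mapq: int
    cigar: List[Tuple[str, int]]
    seq: str
    tags: Dict[str, object] = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & 0x800)

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar) if self.cigar else "*"


def cigar_from_string(s: str):
    if s == "*":
        return []
    out = []
    n = ""
    for ch in s:
        if ch.isdigit():
            n += ch
        elif ch in _CIGAR_OPS:
            out.append((ch, int(n)))
            n = ""
        else:
            raise ValueError(f"malformed CIGAR {s!r}")
    if n:
        raise ValueError(f"malformed CIGAR {s!r}")
    return out


def write_sam(
    alignments: Iterable[AlignmentRecord], reference: TranscriptSet, path
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid, seq in reference.records.items():
            fh.write(f"@SQ\tSN:{tid}\tLN:{len(seq)}\n")
        for a in alignments:
            rname = a.ref_id if a.ref_id is not None else "*"
            pos = a.pos + 1 if not a.is_unmapped else 0
            fields = [
                a.qname,
                str(a.flag),
                rname,
                str(pos),
                str(a.mapq),
                a.cigar_string(),
                "*",
                "0",
                "0",
                a.seq,
                "*",
            ]
            for k, v in a.tags.items():
                t = "i" if isinstance(v, int) else "Z"
                fields.append(f"{k}:{t}:{v}")
            fh.write("\t".join(fields) + "\n")


def read_sam(path, reference: Optional[TranscriptSet] = None) -> List[AlignmentRecord]:
    """Parse a text SAM file into alignment records.

    If ``reference`` is given, reference names in the SAM must be a subset
    of the transcript set's ids.
    """
    out: List[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, rec in enumerate(sam):
            rname = rec.reference_name if rec.reference_id >= 0 else None
            if reference is not None and rname is not None and rname not in reference:
                raise ValueError(
                    f"SAM reference {rname!r} not in transcript set "
                    f"{reference.accession!r} (record {i})"
                )
            cigar = (
                [(_CIGAR_OPS[op], ln) for op, ln in rec.cigartuples]
                if rec.cigartuples
                else []
            )
            out.append(
                AlignmentRecord(
                    rec.query_name,
                    rec.flag,
                    rname,
                    rec.reference_start if rec.reference_start is not None else 0,
                    rec.mapping_quality,
                    cigar,
                    rec.query_sequence or "",
                    dict(rec.get_tags()),
                )
            )
    return out


def _left_align_deletion(ref: str, anchor0: int, length: int) -> Tuple[int, str]:
    """Shift a deletion left while the flanking base repeats the span's end.

    ``anchor0`` is the 0-based index of the base preceding the deleted span.
    """
    a = anchor0
    while a > 0 and ref[a] == ref[a + length]:
        a -= 1
    return a, ref[a + 1 : a + 1 + length]


def _left_align_insertion(ref: str, anchor0: int, inserted: str) -> Tuple[int, str]:
    a, s = anchor0, inserted
    while a > 0 and s[-1] == ref[a]:
        s = ref[a] + s[:-1]
        a -= 1
    return a, s


def pileup_from_alignments(
    alignments: Iterable[AlignmentRecord],
    reference: TranscriptSet,
    end_trim: int = 12,
) -> Dict[str, TranscriptPileup]:
    """Accumulate per-transcript pileups from alignment records.

    Unmapped, secondary and supplementary records are ignored.  Base
    qualities and mapping qualities are not consulted.  Indels are
    left-aligned against the reference and anchored at the preceding base;
    events at the very first reference base are discarded (no anchor).

    ``end_trim`` query bases at each read end are excluded from both base
    counts and indel evidence: alignments are least reliable at read ends
    (an indel truncated by the read boundary degrades into mismatches),
    and trimming keeps the consensus fraction at indel anchors faithful.
    """
    piles: Dict[str, TranscriptPileup] = {
        tid: TranscriptPileup(tid, seq) for tid, seq in reference.records.items()
    }
    for a in alignments:
        if a.is_unmapped or a.is_secondary or a.is_supplementary or a.ref_id is None:
            continue
        pile = piles.get(a.ref_id)
        if pile is None:
            raise ValueError(f"alignment references unknown transcript {a.ref_id!r}")
        ref_len = len(pile.ref_seq)
        codes = encode_seq(a.seq)
        qlen = len(a.seq)
        # the usable window is measured from the *aligned* span: a soft-clip
        # boundary is as unreliable as a physical read end
        lead_s = a.cigar[0][1] if a.cigar and a.cigar[0][0] == "S" else 0
        tail_s = a.cigar[-1][1] if a.cigar and a.cigar[-1][0] == "S" else 0
        q_lo, q_hi = lead_s + end_trim, qlen - tail_s - end_trim
        rpos = a.pos  # reference, 0-based
        qpos = 0
        for op, ln in a.cigar:
            if op in ("M", "=", "X"):
                # clip to the usable query window and reference bounds
                lo = max(qpos, q_lo)
                hi = min(qpos + ln, q_hi)
                r_lo = rpos + (lo - qpos)
                r_hi = min(r_lo + max(hi - lo, 0), ref_len)
                if r_hi > r_lo:
                    # index pairs are unique (positions strictly increase)
                    pile.counts[
                        codes[lo : lo + (r_hi - r_lo)], np.arange(r_lo, r_hi)
                    ] += 1
                rpos += ln
                qpos += ln
            elif op == "I":
                # evidence accepted iff the anchor base (query qpos-1) is in
                # the counted window, matching the base-count criterion
                if q_lo <= qpos - 1 < q_hi and 0 < rpos <= ref_len:
                    anc, s = _left_align_insertion(
                        pile.ref_seq, rpos - 1, a.seq[qpos : qpos + ln]
                    )
                    pile.add_insertion(anc, s)
                qpos += ln
            elif op in ("D", "N"):
                if q_lo <= qpos - 1 < q_hi and 0 < rpos and rpos + ln <= ref_len:
                    anc, span = _left_align_deletion(pile.ref_seq, rpos - 1, ln)
                    pile.add_deletion(anc, span)
                rpos += ln
            elif op == "S":
                qpos += ln
            elif op == "H" or op == "P":
                pass
            else:
                raise ValueError(f"unsupported CIGAR op {op!r} in read {a.qname}")
    return piles


def read_sam_pileup(path, reference: TranscriptSet) -> Dict[str, TranscriptPileup]:
    """Read a SAM file and build per-transcript pileups against ``reference``."""
    return pileup_from_alignments(read_sam(path, reference), reference)


# ---------------------------------------------------------------------------
# BED / TSV / newick


def write_bed(intervals: Iterable[Tuple[str, int, int, str]], path,
              chrom_sizes: Optional[Mapping[str, int]] = None) -> None:
    """Write (chrom, start0, end0, name) intervals as BED (0-based half-open).

    If ``chrom_sizes`` is given, intervals outside chromosome bounds raise.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            if start < 0 or end <= start:
                raise ValueError(f"invalid BED interval {chrom}:{start}-{end}")
            if chrom_sizes is not None:
                size = chrom_sizes.get(chrom)
                if size is None or end > size:
                    raise ValueError(
                        f"interval {chrom}:{start}-{end} outside chromosome bounds"
                    )
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def mapping_records_to_frame(records: Sequence[MappingRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "genome": r.genome_label,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "identity": r.identity,
                "coverage": r.coverage,
                "blocks": ";".join(
                    f"{b.q_start}-{b.q_end}:{b.g_start}-{b.g_end}" for b in r.blocks
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "genome", "chrom", "start", "end",
            "strand", "identity", "coverage", "blocks",
        ],
    )


def mapping_records_from_frame(df: pd.DataFrame, genome_label: str | None = None) -> List[MappingRecord]:
    out = []
    for row in df.itertuples():
        blocks = []
        for part in str(row.blocks).split(";"):
            q, g = part.split(":")
            qs, qe = (int(x) for x in q.split("-"))
            gs, ge = (int(x) for x in g.split("-"))
            blocks.append(Block(qs, qe, gs, ge))
        out.append(
            MappingRecord(
                row.transcript_id,
                genome_label or row.genome,
                row.chrom,
                int(row.start),
                int(row.end),
                row.strand,
                blocks,
                float(row.identity),
                float(row.coverage),
            )
        )
    return out
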