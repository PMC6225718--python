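"""Indel-derived PCR marker selection and flanking primer design.

Eligible markers are anchored indels strictly longer than 3 bp (>= 4 bp).
Primer design is a deterministic heuristic: 18-24-mers inside 150 bp
flanks with 40-60% GC, Wallace-rule melting temperatures (2(A+T)+4(G+C))
within 3 degrees of each other, no mononucleotide run over 4, and an
expected amplicon of 100-300 bp on the reference allele.  The amplicon
size difference between alleles always equals the indel length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .anchoring import AnchorIntegration, AnchoredVariant
from .toyalign import revcomp
from .variants import NonRedundantSet, NRRecord

log = logging.getLogger(__name__)

MIN_INDEL_LEN = 4  # "longer than 3 bp", strict
PRIMER_LEN_RANGE = (18, 24)
FLANK = 150
GC_RANGE = (0.40, 0.60)
TM_MAX_DIFF = 3.0
MAX_RUN = 4
AMPLICON_RANGE = (100, 300)


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C)."""
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    return 2.0 * at + 4.0 * gc


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0


def max_mononucleotide_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def _primer_ok(seq: str) -> bool:
    return (
        GC_RANGE[0] <= gc_fraction(seq) <= GC_RANGE[1]
        and max_mononucleotide_run(seq) <= MAX_RUN
    )


@dataclass
class PrimerPair:
    left_seq: str
    left_start: int  # 1-based on the reference transcript, forward strand
    right_seq: str   # reverse-complement primer as synthesized
    right_start: int  # 1-based position of the primer's 3' end region start
    tm_left: float
    tm_right: float
    amplicon_ref: int
    amplicon_alt: int


@dataclass
class IndelMarker:
    marker_id: str
    record: NRRecord
    anchored: AnchoredVariant
    primers: Optional[PrimerPair]


def select_marker_indels(
    nr: NonRedundantSet,
    integration: AnchorIntegration,
    genome: str = "B",
    min_length: int = MIN_INDEL_LEN,
) -> List[NRRecord]:
    """Indels eligible as markers: length >= min_length and anchored.

    ``genome`` selects which genome's anchoring is required ("A", "B", or
    "any"); the published workflow required anchoring to the more distant
    pseudomolecule set, our genome B analog.
    """
    if genome == "A":
        anchored_keys = integration.both | integration.a_only
    elif genome == "B":
        anchored_keys = integration.both | integration.b_only
    elif genome == "any":
        anchored_keys = integration.both | integration.a_only | integration.b_only
    else:
        raise ValueError(f"bad genome selector {genome!r}")
    out = [
        rec
        for rec in nr
        if rec.var_class in ("insertion", "deletion")
        and rec.indel_length >= min_length
        and rec.key in anchored_keys
    ]
    out.sort(key=lambda r: r.key)
    return out


def design_primers(
    indel: NRRecord,
    transcript_seq: str,
    primer_len_range: Tuple[int, int] = PRIMER_LEN_RANGE,
    flank: int = FLANK,
    amplicon_range: Tuple[int, int] = AMPLICON_RANGE,
) -> Optional[PrimerPair]:
    """Pick a flanking primer pair for one indel, or None if no window fits.

    Scans left and right flanks for the innermost windows satisfying the
    GC / run / Tm constraints, then checks amplicon size on the reference
    allele.  The alternate-allele amplicon differs by exactly the indel
    length (larger for insertions, smaller for deletions).
    """
    L = len(transcript_seq)
    anchor = indel.pos  # 1-based anchor base
    event_start = anchor + 1  # first base after the anchor
    event_end = anchor + (len(indel.ref) if indel.var_class == "deletion" else 0)
    pmin, pmax = primer_len_range
    if anchor < pmin + 10 or L - event_end < pmin + 10:
        log.debug("indel %s too close to a transcript end", indel.key)
        return None

    left_lo = max(0, anchor - flank)
    candidates_left = []  # (start0, seq); at most one per end position
    for end in range(anchor, left_lo + pmin - 1, -1):  # end = 0-based exclusive
        for plen in range(pmin, pmax + 1):
            start = end - plen
            if start < left_lo:
                continue
            seq = transcript_seq[start:end]
            if _primer_ok(seq):
                candidates_left.append((start, seq))
                break
    right_hi = min(L, event_end + flank)
    candidates_right = []
    for start in range(event_end, right_hi - pmin + 1):
        for plen in range(pmin, pmax + 1):
            if start + plen > right_hi:
                continue
            seq = transcript_seq[start : start + plen]
            if _primer_ok(seq):
                candidates_right.append((start, seq))
                break
    target_amp = sum(amplicon_range) // 2
    best = None
    best_rank = None
    for lstart, lseq in candidates_left:
        for rstart, rseq in candidates_right:
            tm_l, tm_r = wallace_tm(lseq), wallace_tm(rseq)
            if abs(tm_l - tm_r) > TM_MAX_DIFF:
                continue
            amplicon = rstart + len(rseq) - lstart
            if not amplicon_range[0] <= amplicon <= amplicon_range[1]:
                continue
            shift = indel.indel_length
            amp_alt = amplicon + shift if indel.var_class == "insertion" else amplicon - shift
            rank = (abs(amplicon - target_amp), abs(tm_l - tm_r))
            if best_rank is None or rank < best_rank:
                best_rank = rank
                best = PrimerPair(
                    lseq,
                    lstart + 1,
                    revcomp(rseq),
                    rstart + 1,
                    tm_l,
                    tm_r,
                    amplicon,
                    amp_alt,
                )
    return best


def build_markers(
    nr: NonRedundantSet,
    integration: AnchorIntegration,
    transcripts: Dict[str, str],
    genome: str = "B",
) -> List[IndelMarker]:
    """Select eligible indels and design primers for each."""
    anchored_by_key = {a.key: a for a in integration.union}
    out = []
    for i, rec in enumerate(select_marker_indels(nr, integration, genome=genome)):
        primers = design_primers(rec, transcripts[rec.transcript_id])
        out.append(
            IndelMarker(f"IND{i + 1:03d}", rec, anchored_by_key[rec.key], primers)
        )
    return out


def markers_to_frame(markers: Sequence[IndelMarker]) -> pd.DataFrame:
    rows = []
    for m in markers:
        row = {
            "marker_id": m.marker_id,
            "transcript_id": m.record.transcript_id,
            "pos": m.record.pos,
            "var_class": m.record.var_class,
            "indel_length": m.record.indel_length,
            "chrom": m.anchored.chrom,
            "chrom_pos": m.anchored.pos,
        }
        if m.primers:
            row.update(
                left_primer=m.primers.left_seq,
                right_primer=m.primers.right_seq,
                tm_left=m.primers.tm_left,
                tm_right=m.primers.tm_right,
                amplicon_ref=m.primers.amplicon_ref,
                amplicon_alt=m.primers.amplicon_alt,
            )
        rows.append(row)
    return pd.DataFrame(rows)
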