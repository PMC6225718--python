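"""Minimal seed-and-extend alignment for synthetic, low-divergence data.

Two entry points: :func:`align_reads` places reads on reference transcripts
(emitting SAM-style records), and :func:`map_transcripts` places whole
transcripts on an intronless genome (emitting mapping records with aligned
blocks).  Both share the same machinery: exact k-mer seeds vote for a
(sequence, diagonal) placement and the winning window is resolved by
banded edit-distance alignment (edlib), giving an extended CIGAR.

This is deliberately not a spliced or repeat-aware aligner: it exists so
the pipeline runs end-to-end on simulated bundles without external tools.
Real-scale alignments are imported as SAM / mapping tables instead.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import edlib
import numpy as np

from .seqio import AlignmentRecord, Block, MappingRecord, TranscriptSet, cigar_from_string

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_K = 21
INDEL_SLACK = 12  # window padding; permits indels up to ~10 bp
MAX_CANDIDATES = 4
EDGE_CLIP = 18  # soft-clip alignment ends containing non-matches this close


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SeedIndex:
    """Exact k-mer index over a set of named sequences."""

    def __init__(self, sequences: Mapping[str, str], k: int = DEFAULT_K, stride: int = 1):
        if not sequences:
            raise ValueError("empty reference")
        self.k = k
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for sid, seq in sequences.items():
            for off in range(0, max(len(seq) - k + 1, 0), stride):
                kmer = seq[off : off + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((sid, off))

    def lookup(self, kmer: str) -> List[Tuple[str, int]]:
        return self.index.get(kmer, [])


def _seed_positions(length: int, k: int) -> List[int]:
    """Seed offsets: both ends plus every k bases in between."""
    if length < k:
        return []
    positions = list(range(0, length - k + 1, k))
    if positions[-1] != length - k:
        positions.append(length - k)
    return positions


def _vote(seq: str, index: SeedIndex) -> Dict[Tuple[str, int], int]:
    votes: Dict[Tuple[str, int], int] = {}
    for qoff in _seed_positions(len(seq), index.k):
        kmer = seq[qoff : qoff + index.k]
        hits = index.lookup(kmer)
        if len(hits) > 50:  # promiscuous seed, skip
            continue
        for sid, roff in hits:
            key = (sid, roff - qoff)
            votes[key] = votes.get(key, 0) + 1
    return votes


def _parse_extended_cigar(path: str) -> List[Tuple[str, int]]:
    return [(op, n) for op, n in cigar_from_string(path)]


def _leading_noise(cigar: Sequence[Tuple[str, int]], edge: int) -> Tuple[int, int]:
    """(query, ref) clip extent for edge noise at the alignment start.

    Counts non-match columns among ops starting within ``edge`` query
    bases; a single such column (an isolated SNP or 1 bp indel) is trusted
    and left alone, while two or more (the smear an end-truncated indel
    leaves behind) clip through the last offending op.
    """
    q = r = 0
    clip_q = clip_r = 0
    noise_cols = 0
    for op, n in cigar:
        if q >= edge:
            break
        if op == "=":
            q += n
            r += n
        elif op in ("X", "M"):
            q += n
            r += n
            noise_cols += n
            clip_q, clip_r = q, r
        elif op == "I":
            q += n
            noise_cols += n
            clip_q, clip_r = q, r
        elif op == "D":
            r += n
            noise_cols += n
            clip_q, clip_r = q, r
        else:
            q += n
    if noise_cols < 2:
        return 0, 0
    return clip_q, clip_r


def _drop_prefix(cigar: Sequence[Tuple[str, int]], q_drop: int) -> List[Tuple[str, int]]:
    """Remove the alignment prefix covering exactly ``q_drop`` query bases
    (and any ref-only ops inside it); ``q_drop`` falls on an op boundary."""
    out = list(cigar)
    q = 0
    while out and q < q_drop:
        op, n = out[0]
        if op in ("=", "X", "M", "I", "S"):
            q += n
        out.pop(0)
    # drop ref-only ops left dangling at the new start
    while out and out[0][0] in ("D", "N"):
        out.pop(0)
    return out


def clip_noisy_ends(
    cigar: List[Tuple[str, int]], edge: int = EDGE_CLIP
) -> Tuple[List[Tuple[str, int]], int]:
    """Soft-clip mismatch/indel noise at alignment ends.

    A read whose boundary truncates an indel cannot represent the event;
    the optimizer smears it into mismatches and short gaps near the read
    end.  Any non-match operation starting within ``edge`` query bases of
    either end is clipped through (replaced by S), so such reads neither
    support nor dilute variant columns there.  Fully matching reads are
    unaffected.  Returns the new CIGAR and the reference offset of the
    clipped leading part.
    """
    if all(op == "=" for op, _ in cigar):
        return cigar, 0
    lead_q, lead_r = _leading_noise(cigar, edge)
    middle = _drop_prefix(cigar, lead_q) if lead_q else list(cigar)
    rev = middle[::-1]
    tail_q, _tail_r = _leading_noise(rev, edge)
    if tail_q:
        middle = _drop_prefix(rev, tail_q)[::-1]
    out: List[Tuple[str, int]] = []
    if lead_q:
        out.append(("S", lead_q))
    out.extend(middle)
    if tail_q:
        out.append(("S", tail_q))
    return out, lead_r


def align_reads(
    reads: Iterable[Tuple[str, str]],
    reference: TranscriptSet,
    k: int = DEFAULT_K,
    max_mismatch_frac: float = 0.15,
    index: Optional[SeedIndex] = None,
) -> List[AlignmentRecord]:
    """Align single-end reads to reference transcripts.

    ``reads`` yields (name, sequence).  Each read is placed at the
    seed-supported location with minimal edit distance (both orientations
    tried); reads whose best distance exceeds ``max_mismatch_frac`` x length
    are reported unmapped.  Score ties across distinct locations are broken
    toward the smallest (transcript id, position) and tagged ``ZA:i:1``.
    Only the primary placement is emitted.
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    if index is None:
        index = SeedIndex(reference.records, k=k)
    out: List[AlignmentRecord] = []
    refs = reference.records
    for name, seq in reads:
        seq = seq.upper()
        best = None  # (dist, tid, start, cigar, flag)
        ambiguous = False
        max_dist = int(max_mismatch_frac * len(seq))
        for flag_rc, oriented in ((0, seq), (0x10, revcomp(seq))):
            votes = _vote(oriented, index)
            if not votes:
                continue
            cands = sorted(votes.items(), key=lambda kv: -kv[1])[:MAX_CANDIDATES]
            for (tid, diag), n_votes in cands:
                if best is not None and best[0] == 0 and n_votes < cands[0][1]:
                    break  # an exact hit cannot be beaten by weaker seeds
                ref = refs[tid]
                # fast path: exact substring at the voted diagonal
                if 0 <= diag and diag + len(oriented) <= len(ref) and ref[
                    diag : diag + len(oriented)
                ] == oriented:
                    cand = (0, tid, diag, [("=", len(oriented))], flag_rc)
                else:
                    lo = max(0, diag - INDEL_SLACK)
                    hi = min(len(ref), diag + len(oriented) + INDEL_SLACK)
                    res = edlib.align(oriented, ref[lo:hi], mode="HW", task="path",
                                      k=max_dist if max_dist >= 0 else -1)
                    if res["editDistance"] < 0:
                        continue
                    start = lo + res["locations"][0][0]
                    cand = (
                        res["editDistance"],
                        tid,
                        start,
                        _parse_extended_cigar(res["cigar"]),
                        flag_rc,
                    )
                if best is None or cand[0] < best[0]:
                    best = cand
                    ambiguous = False
                elif cand[0] == best[0] and cand[1:3] != best[1:3]:
                    ambiguous = True
                    if cand[:3] < best[:3]:
                        best = cand
            if best is not None and best[0] == 0:
                break
        if best is None or best[0] > max_dist:
            out.append(AlignmentRecord(name, 0x4, None, 0, 0, [], seq))
            continue
        dist, tid, start, cigar, flag_rc = best
        cigar, lead_r = clip_noisy_ends(cigar)
        start += lead_r
        if not any(op == "=" for op, _ in cigar):
            out.append(AlignmentRecord(name, 0x4, None, 0, 0, [], seq))
            continue
        oriented = revcomp(seq) if flag_rc else seq
        tags: Dict[str, object] = {"NM": dist}
        if ambiguous:
            tags["ZA"] = 1
        out.append(
            AlignmentRecord(
                name, flag_rc, tid, start, 0 if ambiguous else 60, cigar, oriented, tags
            )
        )
    return out


def align_read_pairs(
    reads1: Sequence[Tuple[str, str]],
    reads2: Sequence[Tuple[str, str]],
    reference: TranscriptSet,
    k: int = DEFAULT_K,
    max_mismatch_frac: float = 0.15,
    max_fragment: int = 2000,
    index: Optional[SeedIndex] = None,
) -> List[AlignmentRecord]:
    """Align mate pairs independently, then set pairing/concordance flags.

    A pair is flagged concordant (0x2) when both mates map to the same
    transcript on opposite strands facing inward within ``max_fragment``.
    """
    if len(reads1) != len(reads2):
        raise ValueError("unpaired input: mate lists differ in length")
    if index is None:
        index = SeedIndex(reference.records, k=k)
    a1 = align_reads(reads1, reference, k=k, max_mismatch_frac=max_mismatch_frac, index=index)
    a2 = align_reads(reads2, reference, k=k, max_mismatch_frac=max_mismatch_frac, index=index)
    out: List[AlignmentRecord] = []
    for r1, r2 in zip(a1, a2):
        r1.flag |= 0x1 | 0x40
        r2.flag |= 0x1 | 0x80
        proper = False
        if not (r1.is_unmapped or r2.is_unmapped) and r1.ref_id == r2.ref_id:
            if r1.is_reverse != r2.is_reverse:
                fwd, rev = (r1, r2) if not r1.is_reverse else (r2, r1)
                if fwd.pos <= rev.pos and rev.pos - fwd.pos <= max_fragment:
                    proper = True
        if proper:
            r1.flag |= 0x2
            r2.flag |= 0x2
        out.extend((r1, r2))
    return out


# ---------------------------------------------------------------------------
# transcript-to-genome mapping


def _trim_overhang(cigar: List[Tuple[str, int]]) -> Tuple[List[Tuple[str, int]], int, int]:
    """Strip terminal insertions (unaligned query overhang) from a CIGAR.

    Returns (trimmed cigar, leading query bases trimmed, trailing trimmed).
    """
    lead = trail = 0
    ops = list(cigar)
    while ops and ops[0][0] == "I":
        lead += ops.pop(0)[1]
    while ops and ops[-1][0] == "I":
        trail += ops.pop()[1]
    return ops, lead, trail


def alignment_stats(cigar: List[Tuple[str, int]]) -> Dict[str, int]:
    out = {"=": 0, "X": 0, "I": 0, "D": 0}
    for op, n in cigar:
        if op in out:
            out[op] += n
    return out


def local_alignment(
    query: str,
    target: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> Optional[Dict[str, object]]:
    """Glocal alignment of ``query`` inside ``target`` with overhang trimming.

    The full query is aligned into the target (edlib HW); terminal query
    overhangs come back as insertions and are trimmed off, approximating a
    local alignment.  Returns score, identity, query coverage, target
    interval (0-based half-open) and the trimmed CIGAR, or None when the
    sequences share no alignment.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    cigar = _parse_extended_cigar(res["cigar"])
    cigar, lead, trail = _trim_overhang(cigar)
    if not cigar:
        return None
    stats = alignment_stats(cigar)
    aligned_q = stats["="] + stats["X"] + stats["I"]
    denom = stats["="] + stats["X"] + stats["I"] + stats["D"]
    identity = stats["="] / denom if denom else 0.0
    coverage = aligned_q / len(query)
    score = match * stats["="] + mismatch * stats["X"] + gap * (stats["I"] + stats["D"])
    t_start, t_end = res["locations"][0][0], res["locations"][0][1] + 1
    return {
        "score": score,
        "identity": identity,
        "coverage": coverage,
        "q_start": lead,            # 0-based on the oriented query
        "q_end": len(query) - trail,
        "t_start": t_start,
        "t_end": t_end,
        "cigar": cigar,
        "edit_distance": res["editDistance"],
    }


def _blocks_from_cigar(
    cigar: List[Tuple[str, int]], q_start0: int, g_start0: int
) -> List[Block]:
    """Gapless blocks (1-based inclusive, aligned-orientation query coords)."""
    blocks: List[Block] = []
    q, g = q_start0, g_start0
    cur_q = cur_g = None
    for op, n in cigar:
        if op in ("=", "X", "M"):
            if cur_q is None:
                cur_q, cur_g = q, g
            q += n
            g += n
        elif op == "I":
            if cur_q is not None:
                blocks.append(Block(cur_q + 1, q, cur_g + 1, g))
                cur_q = None
            q += n
        elif op == "D":
            if cur_q is not None:
                blocks.append(Block(cur_q + 1, q, cur_g + 1, g))
                cur_q = None
            g += n
    if cur_q is not None:
        blocks.append(Block(cur_q + 1, q, cur_g + 1, g))
    return blocks


def map_transcripts(
    transcripts: TranscriptSet,
    genome: Mapping[str, str],
    genome_label: str = "genome",
    k: int = DEFAULT_K,
    min_identity: float = 0.9,
    min_coverage: float = 0.5,
) -> List[MappingRecord]:
    """Place each transcript at its best locus on an intronless genome.

    At most one record per transcript (best identity x coverage over both
    strands); placements failing ``min_identity`` or ``min_coverage`` are
    omitted.  Block query coordinates are in the aligned orientation
    (reverse-complement coordinates for "-" strand records).
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    index = SeedIndex(genome, k=k)
    records: List[MappingRecord] = []
    for tid, seq in transcripts.records.items():
        best = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            votes = _vote(oriented, index)
            if not votes:
                continue
            cands = sorted(votes.items(), key=lambda kv: -kv[1])[:MAX_CANDIDATES]
            for (chrom, diag), _n in cands:
                chrom_seq = genome[chrom]
                lo = max(0, diag - 50)
                hi = min(len(chrom_seq), diag + len(oriented) + 50)
                res = local_alignment(oriented, chrom_seq[lo:hi])
                if res is None:
                    continue
                blocks = _blocks_from_cigar(
                    res["cigar"], res["q_start"], lo + res["t_start"]
                )
                if not blocks:
                    continue
                rec = MappingRecord(
                    tid,
                    genome_label,
                    chrom,
                    blocks[0].g_start,
                    blocks[-1].g_end,
                    strand,
                    blocks,
                    res["identity"],
                    res["coverage"],
                )
                rank = (rec.identity * rec.coverage, -rec.start)
                if best is None or rank > best[0]:
                    best = (rank, rec)
        if best is None:
            continue
        rec = best[1]
        if rec.identity >= min_identity and rec.coverage >= min_coverage:
            records.append(rec)
        else:
            log.debug("transcript %s failed identity/coverage filters", tid)
    return records
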