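"""Orthology by reciprocal best hits, FPKM expression, and rank correlation.

RBH pairing uses the in-repo seed-and-extend scorer (match +1, mismatch -1,
gap -2 per base by default): a pair is emitted iff each transcript is the
other's unique best hit and query coverage strictly exceeds the threshold
(default 0.80) in both directions.  FPKM counts only concordantly aligned
fragments (both mates on one transcript, inward).  Kendall's tau is the
tie-corrected tau-b with a two-sided p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import AlignmentRecord, TranscriptSet
from .toyalign import SeedIndex, local_alignment, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologPair:
    id1: str
    id2: str
    coverage_fwd: float  # aligned fraction of id1 when used as the query
    coverage_rev: float
    score: int


@dataclass
class ExpressionRecord:
    transcript_id: str
    fragments: int
    length: int
    fpkm: float


def _best_hits(
    queries: TranscriptSet,
    targets: TranscriptSet,
    k: int,
    match: int,
    mismatch: int,
    gap: int,
    max_candidates: int = 5,
) -> Dict[str, Tuple[Optional[str], float, int, bool]]:
    """Per query: (best target or None, coverage, score, tie flag)."""
    index = SeedIndex(targets.records, k=k)
    out: Dict[str, Tuple[Optional[str], float, int, bool]] = {}
    for qid, qseq in queries.records.items():
        # vote per target sequence over both strands
        votes: Dict[str, int] = {}
        for oriented in (qseq, revcomp(qseq)):
            for off in range(0, max(len(oriented) - k + 1, 1), k):
                for sid, _ in index.lookup(oriented[off : off + k]):
                    votes[sid] = votes.get(sid, 0) + 1
        cands = sorted(votes, key=lambda s: -votes[s])[:max_candidates]
        best: Optional[Tuple[int, float, str]] = None
        tie = False
        for tid in cands:
            tseq = targets.records[tid]
            res_f = local_alignment(qseq, tseq, match, mismatch, gap)
            res_r = local_alignment(revcomp(qseq), tseq, match, mismatch, gap)
            res = max(
                (r for r in (res_f, res_r) if r is not None),
                key=lambda r: r["score"],
                default=None,
            )
            if res is None:
                continue
            entry = (int(res["score"]), float(res["coverage"]), tid)
            if best is None or entry[0] > best[0]:
                best = entry
                tie = False
            elif entry[0] == best[0] and tid != best[2]:
                tie = True
        if best is None:
            out[qid] = (None, 0.0, 0, False)
        elif tie:
            log.debug("query %s has tied best hits; skipped", qid)
            out[qid] = (None, 0.0, 0, True)
        else:
            out[qid] = (best[2], best[1], best[0], False)
    return out


def rbh_orthologs(
    set1: TranscriptSet,
    set2: TranscriptSet,
    min_coverage: float = 0.80,
    k: int = 21,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> List[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two transcript sets.

    A pair (t1, t2) is emitted iff t2 is t1's unique best hit, t1 is t2's
    unique best hit, and query coverage is strictly greater than
    ``min_coverage`` in both directions.
    """
    if len(set1) == 0 or len(set2) == 0:
        raise ValueError("both transcript sets must be non-empty")
    fwd = _best_hits(set1, set2, k, match, mismatch, gap)
    rev = _best_hits(set2, set1, k, match, mismatch, gap)
    pairs: List[OrthologPair] = []
    for q1, (t2, cov_f, score, _tie) in fwd.items():
        if t2 is None:
            continue
        t1_back, cov_r, _score_r, _tie_r = rev.get(t2, (None, 0.0, 0, False))
        if t1_back != q1:
            continue
        if cov_f > min_coverage and cov_r > min_coverage:
            pairs.append(OrthologPair(q1, t2, cov_f, cov_r, score))
    pairs.sort(key=lambda p: (p.id1, p.id2))
    return pairs


def ortholog_frame(pairs: Sequence[OrthologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id1": p.id1,
                "id2": p.id2,
                "coverage_fwd": p.coverage_fwd,
                "coverage_rev": p.coverage_rev,
                "score": p.score,
            }
            for p in pairs
        ],
        columns=["id1", "id2", "coverage_fwd", "coverage_rev", "score"],
    )


# ---------------------------------------------------------------------------
# expression


def fpkm_value(fragments: int, length: int, total_fragments: int) -> float:
    """FPKM = fragments x 1e9 / (length x total mapped fragments)."""
    if total_fragments <= 0:
        return 0.0
    return fragments * 1e9 / (length * total_fragments)


def fpkm(
    alignments: Iterable[AlignmentRecord], transcripts: TranscriptSet
) -> List[ExpressionRecord]:
    """FPKM per transcript from concordantly aligned fragments.

    A fragment counts iff both mates are mapped to the same transcript with
    the concordant-pair flag set (0x2).  FPKM = fragments x 1e9 /
    (length x total counted fragments).
    """
    mates: Dict[str, List[AlignmentRecord]] = {}
    for a in alignments:
        if not a.flag & 0x1:
            raise ValueError(f"unpaired alignment {a.qname!r} in FPKM input")
        mates.setdefault(a.qname, []).append(a)
    counts: Dict[str, int] = {tid: 0 for tid in transcripts.ids()}
    for qname, recs in mates.items():
        if len(recs) != 2:
            continue
        r1, r2 = recs
        if r1.is_unmapped or r2.is_unmapped:
            continue
        if r1.ref_id != r2.ref_id or not (r1.flag & 0x2):
            continue
        counts[r1.ref_id] += 1
    total = sum(counts.values())
    return [
        ExpressionRecord(tid, counts[tid], len(transcripts[tid]),
                         fpkm_value(counts[tid], len(transcripts[tid]), total))
        for tid in transcripts.ids()
    ]


def expression_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "fragments": r.fragments,
                "length": r.length,
                "fpkm": r.fpkm,
            }
            for r in records
        ],
        columns=["transcript_id", "fragments", "length", "fpkm"],
    )


# ---------------------------------------------------------------------------
# rank correlation


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Tie-corrected Kendall's tau-b with a two-sided p-value.

    Constant input in either vector leaves tau undefined (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    if np.all(x == x[0]) or np.all(y == y[0]):
        log.warning("constant vector: Kendall's tau undefined")
        return float("nan"), float("nan")
    res = stats.kendalltau(x, y)
    return float(res.statistic), float(res.pvalue)


def ortho_theta_scatter(
    pairs: Sequence[OrthologPair],
    theta1: Mapping[str, float],
    theta2: Mapping[str, float],
    require_polymorphic: bool = True,
) -> Tuple[pd.DataFrame, float, float]:
    """Join per-transcript theta across ortholog pairs and correlate.

    Rows are restricted (by default) to pairs where at least one species is
    polymorphic.  Returns the joined table, tau and its p-value.
    """
    rows = []
    for p in pairs:
        if p.id1 not in theta1 or p.id2 not in theta2:
            raise ValueError(f"ortholog pair ({p.id1}, {p.id2}) references unknown transcript")
        t1, t2 = float(theta1[p.id1]), float(theta2[p.id2])
        if require_polymorphic and t1 == 0.0 and t2 == 0.0:
            continue
        rows.append({"id1": p.id1, "id2": p.id2, "theta1": t1, "theta2": t2})
    df = pd.DataFrame(rows, columns=["id1", "id2", "theta1", "theta2"])
    if len(df) >= 2:
        tau, p = kendall_tau(df["theta1"], df["theta2"])
    else:
        tau, p = float("nan"), float("nan")
    return df, tau, p
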