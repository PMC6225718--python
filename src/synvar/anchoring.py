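"""Lift transcript-coordinate variants onto pseudomolecule coordinates.

A variant anchored through a transcript's mapping inherits (genome label,
chromosome, 1-based position, mapping strand).  Positions falling in
unaligned gaps between mapping blocks stay unanchored, as do indels whose
anchor base or span crosses a block edge.  The integration step partitions
a non-redundant variant set into both / A-only / B-only / neither classes
and builds the union with configurable genome preference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .seqio import MappingRecord
from .variants import NonRedundantSet, NRRecord, VariantCall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchoredVariant:
    key: Tuple[str, int, str, str]  # (transcript, pos, class, alt)
    ref_accession: str
    genome_label: str
    chrom: str
    pos: int  # 1-based chromosome coordinate
    strand: str
    var_class: str
    ref: str
    alt: str

    @property
    def indel_length(self) -> int:
        if self.var_class == "insertion":
            return len(self.alt)
        if self.var_class == "deletion":
            return len(self.ref)
        return 0


def _lift_position(mapping: MappingRecord, tpos: int, tlen: int) -> Optional[int]:
    """Lift a 1-based transcript position through the mapping blocks."""
    if mapping.strand == "-":
        q = tlen - tpos + 1  # aligned-orientation coordinate
    else:
        q = tpos
    for b in mapping.blocks:
        if b.q_start <= q <= b.q_end:
            return b.g_start + (q - b.q_start)
    return None


def lift_variant(
    call, mapping: MappingRecord, transcript_length: int, ref_accession: str = ""
) -> Optional[AnchoredVariant]:
    """Lift one call through its transcript's mapping, or None if unanchored.

    ``call`` needs transcript_id/pos/var_class/ref/alt attributes (either a
    pairwise call or an NR record).  SNPs lift by their own base; indels by
    the anchor base, and additionally require the event span (anchor plus
    deleted bases) to sit inside one aligned block.
    """
    if mapping.transcript_id != call.transcript_id:
        raise ValueError(
            f"mapping is for {mapping.transcript_id!r}, call for {call.transcript_id!r}"
        )
    if not 1 <= call.pos <= transcript_length:
        raise ValueError(
            f"position {call.pos} outside transcript {call.transcript_id} "
            f"(length {transcript_length})"
        )
    g = _lift_position(mapping, call.pos, transcript_length)
    if g is None:
        # SNP base or indel anchor base in an unaligned gap: unanchored
        log.debug("%s:%d falls in an unaligned gap", call.transcript_id, call.pos)
        return None
    return AnchoredVariant(
        (call.transcript_id, call.pos, call.var_class, call.alt),
        getattr(call, "ref_accession", ref_accession),
        mapping.genome_label,
        mapping.chrom,
        int(g),
        mapping.strand,
        call.var_class,
        call.ref,
        call.alt,
    )


def anchor_variants(
    nr: NonRedundantSet,
    mappings: Sequence[MappingRecord],
    transcript_lengths: Mapping[str, int],
) -> List[AnchoredVariant]:
    """Anchor every NR variant whose transcript has a mapping record."""
    by_tid = {m.transcript_id: m for m in mappings}
    out: List[AnchoredVariant] = []
    for rec in nr:
        m = by_tid.get(rec.transcript_id)
        if m is None:
            continue
        av = lift_variant(rec, m, transcript_lengths[rec.transcript_id], nr.ref_accession)
        if av is not None:
            out.append(av)
    return out


def tally_per_chromosome(
    anchored: Sequence[AnchoredVariant], bin_size: int = 1000
) -> Tuple[pd.Series, pd.DataFrame]:
    """Per-chromosome counts and bedgraph-style binned densities."""
    if not anchored:
        return pd.Series(dtype=int), pd.DataFrame(
            columns=["chrom", "start", "end", "count"]
        )
    df = pd.DataFrame({"chrom": [a.chrom for a in anchored], "pos": [a.pos for a in anchored]})
    counts = df.groupby("chrom").size().sort_index()
    counts.name = "n_variants"
    bins = []
    for chrom, sub in df.groupby("chrom"):
        b = (sub["pos"] - 1) // bin_size
        for bi, n in b.value_counts().sort_index().items():
            bins.append(
                {
                    "chrom": chrom,
                    "start": int(bi) * bin_size,
                    "end": (int(bi) + 1) * bin_size,
                    "count": int(n),
                }
            )
    return counts, pd.DataFrame(bins, columns=["chrom", "start", "end", "count"])


@dataclass
class AnchorIntegration:
    """Partition of an NR set by anchorability to the two genomes."""

    both: set
    a_only: set
    b_only: set
    neither: set
    union: List[AnchoredVariant]
    preferred: str = "A"

    @property
    def n_total(self) -> int:
        return len(self.both) + len(self.a_only) + len(self.b_only) + len(self.neither)

    def fractions(self) -> Dict[str, float]:
        tot = self.n_total
        if tot == 0:
            return {"both": 0.0, "a_only": 0.0, "b_only": 0.0, "neither": 0.0}
        return {
            "both": len(self.both) / tot,
            "a_only": len(self.a_only) / tot,
            "b_only": len(self.b_only) / tot,
            "neither": len(self.neither) / tot,
        }

    def to_dict(self) -> dict:
        f = self.fractions()
        return {
            "n_total": self.n_total,
            "n_both": len(self.both),
            "n_a_only": len(self.a_only),
            "n_b_only": len(self.b_only),
            "n_neither": len(self.neither),
            "n_union": len(self.union),
            "fractions": f,
            "preferred_genome": self.preferred,
        }


def integrate_two_genomes(
    anchors_a: Sequence[AnchoredVariant],
    anchors_b: Sequence[AnchoredVariant],
    nr: NonRedundantSet,
    prefer: str = "A",
) -> AnchorIntegration:
    """Partition the NR set by anchor status and build the union.

    The union contains one anchored variant per NR key anchored to at least
    one genome, preferring the ``prefer`` genome's coordinates when both
    exist.
    """
    keys = set(nr.records)
    map_a = {a.key: a for a in anchors_a}
    map_b = {b.key: b for b in anchors_b}
    for extra in (set(map_a) | set(map_b)) - keys:
        raise ValueError(f"anchor references unknown NR key {extra!r}")
    both = set(map_a) & set(map_b)
    a_only = set(map_a) - set(map_b)
    b_only = set(map_b) - set(map_a)
    neither = keys - set(map_a) - set(map_b)
    primary, secondary = (map_a, map_b) if prefer == "A" else (map_b, map_a)
    union = [primary.get(k) or secondary[k] for k in sorted(set(map_a) | set(map_b))]
    return AnchorIntegration(both, a_only, b_only, neither, union, prefer)


def anchored_to_bed_intervals(
    anchored: Sequence[AnchoredVariant],
) -> List[Tuple[str, int, int, str]]:
    """BED intervals (0-based half-open): SNPs one base, deletions their span."""
    out = []
    for a in sorted(anchored, key=lambda a: (a.chrom, a.pos)):
        name = f"{a.key[0]}:{a.key[1]}:{a.var_class}"
        if a.var_class == "deletion":
            l = len(a.ref)
            if a.strand == "-":
                # deleted genome span sits below the lifted anchor base
                out.append((a.chrom, a.pos - 1 - l, a.pos - 1, name))
            else:
                out.append((a.chrom, a.pos, a.pos + l, name))
        else:
            out.append((a.chrom, a.pos - 1, a.pos, name))
    return out
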