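"""Copy-number estimation and boundary-consensus filtering.

A genuine SINE family leaves many near-identical genomic copies. Aligning a
candidate sequence against the genome yields one alignment per copy; the
*boundary shift* of a copy is how far its alignment endpoints on the
candidate deviate from the consensus. Copies whose boundaries agree within
``s`` bp support the candidate; candidates with fewer than ``minc``
supporting copies are discarded, and surviving candidates have their
boundaries snapped to the copy consensus.

Alignment footprints are measured on the candidate (query) sequence and
expressed in genome coordinates by translating with the candidate's genomic
start, so boundary agreement is always judged in a common frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence as TypingSequence

from .alignio import Tab6Record
from .formats import GenomicInterval
from .structure import SineCandidate

__all__ = [
    "CopySupport",
    "count_copies",
    "filter_by_copy_number",
    "adjust_boundaries",
]


@dataclass
class CopySupport:
    """Consensus-boundary support for one candidate."""

    candidate_id: str
    copies: list[GenomicInterval] = field(default_factory=list)
    boundary_mode_start: int = 0
    boundary_mode_end: int = 0
    copy_count: int = 0


def _lower_median(values: TypingSequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def count_copies(
    candidate: SineCandidate,
    alignments: Iterable[Tab6Record],
    s: int = 10,
    min_cov: float = 0.8,
) -> CopySupport:
    """Count genomic copies whose boundaries agree within ``s`` bp.

    Only alignments covering at least ``min_cov`` of the candidate length
    participate. The consensus is anchored on the hit with the most
    neighbours within ``s`` at both boundaries (ties: smaller (start, end));
    its neighbourhood members are the copies, and the reported modal
    boundaries are the lower medians of the member boundaries. The
    candidate's self-hit is an ordinary member and so is always counted.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    iv = candidate.interval
    qlen = len(iv)
    mapped: list[tuple[int, int]] = []
    for rec in alignments:
        q0 = min(rec.qstart, rec.qend) - 1
        q1 = max(rec.qstart, rec.qend)
        if (q1 - q0) / qlen >= min_cov:
            mapped.append((iv.start + q0, iv.start + q1))
    if not mapped:
        return CopySupport(
            candidate_id=candidate.id,
            boundary_mode_start=iv.start,
            boundary_mode_end=iv.end,
            copy_count=0,
        )
    mapped.sort()

    def neighbours(center: tuple[int, int]) -> list[tuple[int, int]]:
        c0, c1 = center
        return [
            g for g in mapped if abs(g[0] - c0) <= s and abs(g[1] - c1) <= s
        ]

    # the center hit maximizes its s-neighbourhood; ties resolve to the
    # smaller (start, end) pair, making the result independent of hit order
    center = max(mapped, key=lambda g: (len(neighbours(g)), (-g[0], -g[1])))
    members = neighbours(center)
    return CopySupport(
        candidate_id=candidate.id,
        copies=[GenomicInterval(iv.seq_id, g0, g1) for g0, g1 in members],
        boundary_mode_start=_lower_median([g[0] for g in members]),
        boundary_mode_end=_lower_median([g[1] for g in members]),
        copy_count=len(members),
    )


def filter_by_copy_number(
    supports: Iterable[CopySupport], minc: int = 2
) -> set[str]:
    """Candidate ids whose copy count reaches ``minc``."""
    if minc < 1:
        raise ValueError("minc must be >= 1")
    return {sp.candidate_id for sp in supports if sp.copy_count >= minc}


def adjust_boundaries(
    candidate: SineCandidate, support: CopySupport, s: int = 10
) -> SineCandidate:
    """Snap a candidate's interval to the consensus copy boundaries.

    The shift applied is at most ``s`` at each end; if the consensus lies
    further away the candidate is returned unchanged with
    ``boundary_flagged`` set. The original interval is retained either way.
    """
    if support.copy_count < 1:
        raise ValueError("cannot adjust boundaries without supporting copies")
    iv = candidate.interval
    new_start = support.boundary_mode_start
    new_end = support.boundary_mode_end
    if abs(new_start - iv.start) > s or abs(new_end - iv.end) > s:
        return replace(candidate, original_interval=iv, boundary_flagged=True)
    if (new_start, new_end) == (iv.start, iv.end):
        return replace(candidate, original_interval=iv)
    return replace(
        candidate,
        interval=GenomicInterval(iv.seq_id, new_start, new_end, iv.strand),
        original_interval=iv,
    )
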