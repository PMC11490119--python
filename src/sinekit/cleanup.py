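"""Library hygiene: nested-redundancy removal and non-SINE purging.

Redundancy removal drops any library sequence that is essentially contained
in a longer retained one (coverage >= 0.95 of the shorter sequence, identity
>= 80%, alignment length >= 50 bp by default). Purging removes candidates
dominated by LINE/LTR-matched (masked) sequence (masked fraction > 0.8),
after trimming terminal masked and N runs; trimmed survivors shorter than 50
bp are dropped. Masking itself is delegated to an external masker — the
operations consume mask intervals, keeping them hermetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as TypingSequence

import numpy as np

from .alignio import Tab6Record
from .formats import Sequence

__all__ = [
    "remove_nested_redundancy",
    "purge_nonsine",
    "PurgeOutcome",
]


def remove_nested_redundancy(
    library: TypingSequence[Sequence],
    alignments: Iterable[Tab6Record],
    cov: float = 0.95,
    miniden: float = 80.0,
    minlen: int = 50,
) -> list[Sequence]:
    """Drop sequences nested inside longer retained library members.

    Sequences are processed in decreasing-length order (ties: lexicographically
    earlier id first), so the retained set is independent of input order and a
    mutually redundant pair loses exactly one member. A sequence is removed
    iff some single alignment to an already-retained sequence covers >= ``cov``
    of its own length with identity >= ``miniden`` and alignment length >=
    ``minlen``. Coverage is always measured on the (shorter) sequence being
    tested. Self-alignments are ignored.
    """
    lengths = {seq.id: len(seq) for seq in library}
    # spans each sequence receives from alignments against each partner
    spans: dict[str, dict[str, list[tuple[int, float, int]]]] = {}
    for rec in alignments:
        if rec.qseqid == rec.sseqid:
            continue
        q_span = abs(rec.qend - rec.qstart) + 1
        s_span = abs(rec.send - rec.sstart) + 1
        spans.setdefault(rec.qseqid, {}).setdefault(rec.sseqid, []).append(
            (q_span, rec.pident, rec.length)
        )
        spans.setdefault(rec.sseqid, {}).setdefault(rec.qseqid, []).append(
            (s_span, rec.pident, rec.length)
        )
    order = sorted(library, key=lambda s: (-len(s), s.id))
    retained_ids: set[str] = set()
    for seq in order:
        removed = False
        for partner, hits in spans.get(seq.id, {}).items():
            if partner not in retained_ids:
                continue
            for span, pident, alen in hits:
                if (
                    span / lengths[seq.id] >= cov
                    and pident >= miniden
                    and alen >= minlen
                ):
                    removed = True
                    break
            if removed:
                break
        if not removed:
            retained_ids.add(seq.id)
    return [seq for seq in library if seq.id in retained_ids]


@dataclass
class PurgeOutcome:
    """Per-candidate record of a purge pass."""

    kept: bool
    lead_trim: int = 0
    tail_trim: int = 0
    masked_fraction: float = 0.0
    reason: str = ""


def purge_nonsine(
    candidates: TypingSequence[Sequence],
    mask_intervals: Mapping[str, TypingSequence[tuple[int, int]]],
    nr: float = 0.8,
    minlen: int = 50,
    return_report: bool = False,
) -> list[Sequence] | tuple[list[Sequence], dict[str, PurgeOutcome]]:
    """Remove LINE/LTR-dominated candidates and trim masked/N termini.

    Terminal runs of masked-or-N positions are trimmed first; a trimmed
    candidate is removed when its masked fraction exceeds ``nr`` or its
    length falls below ``minlen``. Trimming first makes the operation
    idempotent: a survivor has no terminal masked/N run left to trim.
    """
    out: list[Sequence] = []
    report: dict[str, PurgeOutcome] = {}
    for seq in candidates:
        n = len(seq)
        flagged = np.zeros(n, dtype=bool)
        for start, end in mask_intervals.get(seq.id, ()):
            if start < 0 or end > n or start >= end:
                raise ValueError(
                    f"mask interval ({start},{end}) outside candidate "
                    f"{seq.id!r} of length {n}"
                )
            flagged[start:end] = True
        trimmable = flagged | (
            np.frombuffer(seq.residues.encode(), dtype=np.uint8) == ord("N")
        )
        lo, hi = 0, n
        while lo < hi and trimmable[lo]:
            lo += 1
        while hi > lo and trimmable[hi - 1]:
            hi -= 1
        if hi - lo < minlen:
            report[seq.id] = PurgeOutcome(False, lo, n - hi, reason="minlen")
            continue
        frac = float(flagged[lo:hi].sum()) / (hi - lo)
        if frac > nr:
            report[seq.id] = PurgeOutcome(
                False, lo, n - hi, masked_fraction=frac, reason="masked"
            )
            continue
        out.append(Sequence(seq.id, seq.residues[lo:hi]))
        report[seq.id] = PurgeOutcome(True, lo, n - hi, masked_fraction=frac)
    if return_report:
        return out, report
    return out
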